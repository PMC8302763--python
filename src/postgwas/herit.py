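"""Heritability explained by susceptibility loci, and lifetime-risk scaling.

A single SNP's contribution to heritability is measured against the total
phenotypic variance implied by the familial relative risk lambda:

    h = beta^2 * 2 f (1 - f) / ln(lambda^2)

with beta the per-allele log-odds ratio and f the effect-allele frequency.
The logarithm is natural.  Conventional lambda values are 4 for
father-to-son relative risk and 8 for brothers, so every locus yields two
heritability shares; they sum across loci.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "snp_heritability",
    "total_heritability",
    "lifetime_risk",
    "LAMBDA_FATHER",
    "LAMBDA_BROTHER",
]

LAMBDA_FATHER = 4.0
LAMBDA_BROTHER = 8.0


def snp_heritability(beta: float, freq: float, lam: float) -> float:
    """Per-SNP heritability share h = beta^2 * 2f(1-f) / ln(lambda^2).

    Symmetric under allele recoding (f -> 1-f with beta -> -beta), zero for
    a null effect, and vanishing as the allele becomes monomorphic.
    ``lam`` must exceed 1 so the denominator is positive.
    """
    if not (lam > 1.0):
        raise ValueError("familial relative risk lambda must exceed 1")
    if not (0.0 < freq < 1.0):
        raise ValueError("effect-allele frequency must lie in (0, 1)")
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return float(beta * beta * 2.0 * freq * (1.0 - freq) / math.log(lam * lam))


def total_heritability(
    loci: pd.DataFrame,
    lam: float,
    or_col: str = "odds_ratio",
    freq_col: str = "a1_freq",
) -> tuple[float, list[str]]:
    """Sum of per-locus heritability shares over a loci table.

    ``loci`` needs an odds-ratio column (converted to beta = ln(OR)) and an
    effect-allele frequency column.  X-chromosome loci are included exactly
    like autosomal ones.  Loci with missing frequency or OR are skipped with
    a warning and reported in the returned list.
    """
    skipped: list[str] = []
    total = 0.0
    for idx, row in loci.iterrows():
        orr, f = row.get(or_col), row.get(freq_col)
        label = str(row.get("rsid", idx))
        if pd.isna(orr) or pd.isna(f):
            skipped.append(label)
            continue
        total += snp_heritability(math.log(float(orr)), float(f), lam)
    if skipped:
        warnings.warn(f"skipped loci with missing data: {skipped}")
    return total, skipped


def lifetime_risk(relative_risk: float, baseline: float = 0.005) -> float:
    """Absolute lifetime risk from a relative risk and a baseline risk.

    Uses the rare-disease approximation OR ~ RR, so risk = RR * baseline,
    capped at 1.  The default baseline is the assumed 0.5% lifetime risk.
    """
    if not (0.0 < baseline < 1.0):
        raise ValueError("baseline risk must lie in (0, 1)")
    if relative_risk < 0:
        raise ValueError("relative risk must be non-negative")
    risk = relative_risk * baseline
    if risk > 1.0:
        warnings.warn("relative risk times baseline exceeds 1; capping at 1.0")
        return 1.0
    return float(risk)
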