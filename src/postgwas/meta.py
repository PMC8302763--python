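"""Fixed-effects inverse-variance meta-analysis with heterogeneity control.

Study effect estimates are pooled with weights w_i = 1/SE_i^2, the scheme
used by METAL-style GWAS meta-analysis.  Cochran's Q and I^2 quantify
between-study heterogeneity; variants whose Q-test P falls below 0.001 are
flagged for removal *before* genome-wide significance (P <= 5e-8) is
declared.  Allele alignment across studies (sign flips, strand flips,
strand-ambiguous policy, presence-in-all-studies rule) lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import StudySummary, wald_p_from_z

__all__ = [
    "MetaResult",
    "meta_fixed",
    "meta_scan",
    "align_alleles",
    "HET_P_THRESHOLD",
    "GWS_P_THRESHOLD",
]

HET_P_THRESHOLD = 1e-3   # Cochran Q-test removal threshold
GWS_P_THRESHOLD = 5e-8   # genome-wide significance

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class MetaResult:
    """Pooled association record with heterogeneity statistics."""

    snp: str
    beta: float
    se: float
    z: float
    p: float
    neglog10_p: float
    q: float
    q_p: float
    i2: float                 # percent, in [0, 100]
    direction: str            # one of +/-/? per study, input order
    k: int
    weights: np.ndarray = field(repr=False, default=None)
    heterogeneity_fail: bool = False
    significant: bool = False


def meta_fixed(studies: list[StudySummary]) -> MetaResult:
    """Inverse-variance-weighted fixed-effects pooling of aligned studies.

    beta = sum(w_i b_i) / sum(w_i) with w_i = SE_i^-2, pooled
    SE = sum(w_i)^-1/2, Q = sum(w_i (b_i - beta)^2) and
    I^2 = max(0, (Q - (k-1))/Q) * 100.  Effect alleles must already be
    aligned (see :func:`align_alleles`).
    """
    if len(studies) == 0:
        raise ValueError("meta-analysis requires at least one study")
    usable = [s for s in studies if s.converged and np.isfinite(s.beta)]
    direction = "".join(
        "?" if not (s.converged and np.isfinite(s.beta))
        else ("+" if s.beta > 0 else "-" if s.beta < 0 else "?")
        for s in studies
    )
    if not usable:
        raise ValueError("no usable study estimates")
    b = np.array([s.beta for s in usable])
    se = np.array([s.se for s in usable])
    if np.any(se <= 0):
        raise ValueError("non-positive SE in meta input")
    w = se ** -2.0
    if len(usable) == 1:
        beta, pooled_se = float(b[0]), float(se[0])  # exact identity
    else:
        beta = float(np.sum(w * b) / np.sum(w))
        pooled_se = float(np.sum(w) ** -0.5)
    z = beta / pooled_se
    p, nlp = wald_p_from_z(z)
    k = len(usable)
    q = float(np.sum(w * (b - beta) ** 2)) if k > 1 else 0.0
    q_p = float(stats.chi2.sf(q, df=k - 1)) if k > 1 else 1.0
    i2 = float(max(0.0, (q - (k - 1)) / q) * 100.0) if q > 0 else 0.0
    het_fail = k > 1 and q_p < HET_P_THRESHOLD
    return MetaResult(
        snp=usable[0].snp,
        beta=beta,
        se=pooled_se,
        z=float(z),
        p=float(p),
        neglog10_p=float(nlp),
        q=q,
        q_p=q_p,
        i2=i2,
        direction=direction,
        k=k,
        weights=w,
        heterogeneity_fail=het_fail,
        significant=(not het_fail) and float(p) <= GWS_P_THRESHOLD,
    )


def _orientation(a1: str, a2: str, ref1: str, ref2: str) -> str | None:
    """How (a1, a2) maps onto the reference pair: same, swap, or None."""
    if (a1, a2) == (ref1, ref2):
        return "same"
    if (a1, a2) == (ref2, ref1):
        return "swap"
    c1, c2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
    if (c1, c2) == (ref1, ref2):
        return "same"
    if (c1, c2) == (ref2, ref1):
        return "swap"
    return None


def align_alleles(
    studies: list[pd.DataFrame],
    strict_ambiguous: bool = True,
    freq_diff_max: float = 0.2,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Align effect alleles across study summary tables.

    The first study fixes the reference orientation.  Swapped records get
    their beta negated and frequency mapped to 1-f; strand flips are
    resolved through base complements.  Variants absent from any study are
    dropped (only SNPs present in all studies are meta-analysed), as are
    multiallelic records and irreconcilable allele pairs.  Strand-ambiguous
    A/T and C/G variants are dropped under the default strict policy; the
    permissive policy orients them by allele frequency and requires the
    oriented frequencies to agree within ``freq_diff_max``.

    Returns the aligned tables (equal SNP sets, identical order) and a drop
    report with one reason per removed SNP.
    """
    if not studies:
        raise ValueError("no studies to align")
    drops: dict[str, str] = {}

    per_study: list[dict[str, pd.Series]] = []
    for df in studies:
        dup = df["SNP"].duplicated(keep=False)
        for snp in df.loc[dup, "SNP"].unique():
            drops.setdefault(snp, "multiallelic")
        per_study.append(
            {r.SNP: r for r in df.loc[~dup].itertuples(index=False)}
        )

    all_snps = set().union(*(set(d) for d in per_study))
    common = set.intersection(*(set(d) for d in per_study))
    for snp in all_snps - common:
        drops.setdefault(snp, "not_in_all_studies")

    ref = per_study[0]
    order = [s for s in studies[0]["SNP"] if s in common and s not in drops]
    aligned_rows: list[list[dict]] = [[] for _ in studies]
    for snp in order:
        r0 = ref[snp]
        ambiguous = frozenset((r0.A1, r0.A2)) in _AMBIGUOUS
        if ambiguous and strict_ambiguous:
            drops[snp] = "strand_ambiguous"
            continue
        recs = []
        ok = True
        for d in per_study:
            r = d[snp]
            orient = _orientation(r.A1, r.A2, r0.A1, r0.A2)
            if orient is None:
                drops[snp] = "irreconcilable_alleles"
                ok = False
                break
            rec = r._asdict()
            if ambiguous:
                # permissive: orient by frequency agreement with reference
                if abs(rec["FREQ1"] - r0.FREQ1) > abs((1 - rec["FREQ1"]) - r0.FREQ1):
                    orient = "swap"
                else:
                    orient = "same"
            if orient == "swap":
                rec["BETA"] = -rec["BETA"]
                rec["FREQ1"] = 1.0 - rec["FREQ1"]
                rec["A1"], rec["A2"] = r0.A1, r0.A2
            else:
                rec["A1"], rec["A2"] = r0.A1, r0.A2
            if ambiguous and abs(rec["FREQ1"] - r0.FREQ1) > freq_diff_max:
                drops[snp] = "ambiguous_freq_mismatch"
                ok = False
                break
            recs.append(rec)
        if ok:
            for i, rec in enumerate(recs):
                aligned_rows[i].append(rec)

    aligned = [pd.DataFrame(rows, columns=studies[0].columns) for rows in aligned_rows]
    drop_df = pd.DataFrame(
        sorted(drops.items()), columns=["SNP", "reason"]
    )
    return aligned, drop_df


def meta_scan(aligned: list[pd.DataFrame]) -> pd.DataFrame:
    """Meta-analyse every SNP across pre-aligned study tables.

    Vectorised across variants: all study tables must share the same SNP
    order (the contract of :func:`align_alleles`).  Emits the meta dialect:
    summary columns plus Q, Q_P, I2, DIRECTION, K_STUDIES, HET_FAIL and
    SIGNIFICANT.
    """
    if not aligned:
        raise ValueError("no aligned studies")
    snps = aligned[0]["SNP"].to_numpy()
    for df in aligned[1:]:
        if not np.array_equal(df["SNP"].to_numpy(), snps):
            raise ValueError("aligned study tables must share one SNP order")

    B = np.vstack([df["BETA"].to_numpy(dtype=float) for df in aligned])   # k x m
    SE = np.vstack([df["SE"].to_numpy(dtype=float) for df in aligned])
    F = np.vstack([df["FREQ1"].to_numpy(dtype=float) for df in aligned])
    N = np.vstack([df["N"].to_numpy(dtype=float) for df in aligned])
    usable = np.isfinite(B) & np.isfinite(SE) & (SE > 0)
    W = np.where(usable, SE ** -2.0, 0.0)
    wsum = W.sum(axis=0)
    if np.any(wsum == 0):
        raise ValueError("variants with no usable study estimates")
    beta = (W * np.where(usable, B, 0.0)).sum(axis=0) / wsum
    se = wsum ** -0.5
    z = beta / se
    p, nlp = wald_p_from_z(z)
    k = usable.sum(axis=0)
    q = np.where(k > 1, (W * np.where(usable, (B - beta) ** 2, 0.0)).sum(axis=0), 0.0)
    q_p = np.where(k > 1, stats.chi2.sf(q, df=np.maximum(k - 1, 1)), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        i2 = np.where(q > 0, np.maximum(0.0, (q - (k - 1)) / np.where(q > 0, q, 1.0)) * 100.0, 0.0)
    het_fail = (k > 1) & (q_p < HET_P_THRESHOLD)

    sign = np.where(~usable | (B == 0), "?", np.where(B > 0, "+", "-"))
    direction = ["".join(col) for col in sign.T]

    r0 = aligned[0]
    return pd.DataFrame(
        {
            "SNP": snps,
            "CHR": r0["CHR"].to_numpy() if "CHR" in r0 else ".",
            "POS": r0["POS"].to_numpy() if "POS" in r0 else -1,
            "A1": r0["A1"].to_numpy(),
            "A2": r0["A2"].to_numpy(),
            "FREQ1": np.nanmean(np.where(usable, F, np.nan), axis=0),
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": np.where(usable, N, 0.0).sum(axis=0).astype(int),
            "NEGLOG10P": nlp,
            "Q": q,
            "Q_P": q_p,
            "I2": i2,
            "DIRECTION": direction,
            "K_STUDIES": k,
            "HET_FAIL": het_fail,
            "SIGNIFICANT": ~het_fail & (p <= GWS_P_THRESHOLD),
        }
    )
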