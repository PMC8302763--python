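"""Polygenic risk scores, percentile-bin odds ratios, and cross-validated AUC.

The score is the weighted count of risk alleles: S_j = sum_k dosage_jk *
beta_k, with weights taken from an external meta-analysis (never re-fit on
the scored samples).  Score strata are compared to the 45-55th percentile
reference bin via 2x2 odds ratios with Woolf confidence intervals, and
discrimination is summarised by the concordance-probability AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .herit import lifetime_risk
from .simulate import CohortMatrix

__all__ = [
    "PRSModel",
    "PRSReport",
    "prs_score",
    "percentile_or",
    "auc",
    "auc_loocv",
    "DEFAULT_BIN_EDGES",
    "REFERENCE_BIN",
]

DEFAULT_BIN_EDGES = tuple(range(0, 105, 5))
REFERENCE_BIN = (45.0, 55.0)


@dataclass
class PRSModel:
    """External PRS weights: one (variant, effect allele, beta) per locus."""

    weights: pd.DataFrame        # columns: SNP, A1, BETA
    baseline_risk: float = 0.005

    def __post_init__(self) -> None:
        need = {"SNP", "A1", "BETA"}
        if not need <= set(self.weights.columns):
            raise ValueError(f"weights table needs columns {sorted(need)}")
        if self.weights["SNP"].duplicated().any():
            raise ValueError("duplicate variant ids in PRS weights")
        if not np.all(np.isfinite(self.weights["BETA"])):
            raise ValueError("non-finite PRS weights")


def prs_score(
    matrix: CohortMatrix,
    model: PRSModel,
    max_missing_fraction: float = 0.2,
) -> np.ndarray:
    """Per-sample weighted allele count.

    Dosages are reconciled to each weight's effect allele (a variant typed
    on the opposite allele contributes 2 - dosage); missing dosages are
    replaced by the expected dosage 2f estimated from the non-missing calls.
    More than ``max_missing_fraction`` of model variants absent from the
    cohort is a hard failure, since scores would not be comparable.
    """
    var = matrix.variants.set_index("id")
    present = model.weights["SNP"].isin(var.index)
    if (~present).mean() > max_missing_fraction:
        raise ValueError(
            f"{(~present).sum()} of {len(model.weights)} PRS variants absent "
            "from the cohort; scores not comparable"
        )
    if (~present).any():
        warnings.warn(
            f"{(~present).sum()} PRS variant(s) absent from cohort; skipped"
        )
    S = np.zeros(matrix.n_samples)
    col_of = {v: j for j, v in enumerate(matrix.variants["id"])}
    for w in model.weights[present].itertuples(index=False):
        j = col_of[w.SNP]
        g = matrix.dosage[:, j].astype(float)
        f = np.nanmean(g) / 2.0
        g = np.where(np.isnan(g), 2.0 * f, g)
        row = var.loc[w.SNP]
        if w.A1 == row["a1"]:
            pass
        elif w.A1 == row["a2"]:
            g = 2.0 - g
        else:
            raise ValueError(
                f"effect allele {w.A1} of {w.SNP} matches neither cohort allele"
            )
        S += g * w.BETA
    return S


@dataclass
class PRSReport:
    """Percentile-bin odds ratios against the mid-distribution reference."""

    bins: pd.DataFrame           # lo, hi, n_case, n_control, odds_ratio, ci_low, ci_high, lifetime_risk
    reference: tuple[float, float]
    auc: float
    baseline_risk: float
    extra: dict = field(default_factory=dict)


def _woolf_ci(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """OR with Woolf 95% CI; Haldane-Anscombe 0.5 correction on zero cells."""
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = orr * np.exp(-1.959963984540054 * se)
    hi = orr * np.exp(+1.959963984540054 * se)
    return float(orr), float(lo), float(hi)


def percentile_or(
    scores: np.ndarray,
    status: np.ndarray,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    reference: tuple[float, float] = REFERENCE_BIN,
    baseline_risk: float = 0.005,
) -> PRSReport:
    """Odds ratios of PRS percentile bins versus the reference stratum.

    Percentiles are computed on the combined case+control score
    distribution.  Each bin [lo, hi) (the last bin closed on the right) is
    compared to the reference bin (default 45-55th percentile) through the
    case/control 2x2 table; the reference bin's OR is exactly 1 by
    construction.  Per-bin lifetime risks apply the rare-disease scaling
    OR x baseline.  Empty bins are flagged with missing ORs.
    """
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=int)
    if set(np.unique(status)) != {0, 1}:
        raise ValueError("status must contain both cases (1) and controls (0)")
    edges = np.asarray(bin_edges, dtype=float)
    if edges[0] != 0 or edges[-1] != 100 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must increase from 0 to 100")

    cuts = np.percentile(scores, edges)
    cuts[0], cuts[-1] = -np.inf, np.inf
    which = np.clip(np.searchsorted(cuts, scores, side="right") - 1, 0, len(edges) - 2)

    lo_ref, hi_ref = reference
    in_ref = (scores >= np.percentile(scores, lo_ref)) & (
        scores < np.percentile(scores, hi_ref)
    )
    ref_case = int(np.sum(status[in_ref] == 1))
    ref_ctrl = int(np.sum(status[in_ref] == 0))
    if ref_case == 0 or ref_ctrl == 0:
        raise ValueError("reference bin lacks cases or controls")

    rows = []
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        sel = which == i
        n_case = int(np.sum(status[sel] == 1))
        n_ctrl = int(np.sum(status[sel] == 0))
        if lo >= lo_ref and hi <= hi_ref:
            orr, ci_lo, ci_hi, flag = 1.0, 1.0, 1.0, "reference"
        elif n_case + n_ctrl == 0:
            orr = ci_lo = ci_hi = np.nan
            flag = "empty"
        else:
            orr, ci_lo, ci_hi = _woolf_ci(n_case, n_ctrl, ref_case, ref_ctrl)
            flag = ""
        risk = lifetime_risk(orr, baseline_risk) if np.isfinite(orr) else np.nan
        rows.append((lo, hi, n_case, n_ctrl, orr, ci_lo, ci_hi, risk, flag))

    bins = pd.DataFrame(
        rows,
        columns=["lo", "hi", "n_case", "n_control", "odds_ratio", "ci_low",
                 "ci_high", "lifetime_risk", "flag"],
    )
    return PRSReport(
        bins=bins,
        reference=reference,
        auc=auc(scores, status),
        baseline_risk=baseline_risk,
    )


def auc(scores: np.ndarray, status: np.ndarray) -> float:
    """Concordance-probability AUC (ties count one half).

    Equivalent to the normalised Mann-Whitney U statistic; computed through
    midranks so it is exact under ties.
    """
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=int)
    n1 = int(np.sum(status == 1))
    n0 = int(np.sum(status == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = stats.rankdata(scores)
    u = ranks[status == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc_loocv(
    scores: np.ndarray, status: np.ndarray, refit: bool = False
) -> float:
    """Leave-one-out cross-validated AUC of the score.

    With fixed external weights the score needs no re-estimation, so the
    LOOCV AUC equals the plain concordance AUC (``refit=False``, the
    default).  ``refit=True`` re-fits a univariate logistic calibration of
    case status on the score with each sample held out and scores the
    held-out sample with its own model; this interpretation is mildly
    pessimistic at small n (a held-out case is always scored by a model
    that has not seen it) and converges to the plain AUC as n grows.
    """
    if not refit:
        return auc(scores, status)
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=int)
    from .assoc import _irls_logistic

    n = len(scores)
    loo = np.empty(n)
    X = np.column_stack([np.ones(n), scores])
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        beta, _, ok = _irls_logistic(X[mask], status[mask].astype(float))
        if not ok:
            raise RuntimeError("logistic calibration failed during LOOCV")
        eta = beta[0] + beta[1] * scores[i]
        loo[i] = 1.0 / (1.0 + np.exp(-eta))
    return auc(loo, status)
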