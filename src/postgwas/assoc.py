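"""Per-study additive logistic association and auxiliary exact tests.

The association test is the standard additive-model logistic regression of
case status on dosage with principal components and study center as
covariates, with a two-sided Wald test on the dosage coefficient.  The
fitter is a small IRLS Newton routine (max 50 iterations, log-likelihood
tolerance 1e-8) so that genome-wide scans of thousands of variants stay
fast; a cross-check against statsmodels lives in the test suite.

P-values are carried both as floats and as -log10 values computed in log
space, so extreme associations (P ~ 1e-150) do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CohortMatrix

__all__ = [
    "StudySummary",
    "logistic_assoc",
    "assoc_scan",
    "genomic_inflation",
    "direction_consistency",
    "allele_freq_fisher",
    "wald_p_from_z",
]

CHI2_1_MEDIAN = 0.4549364  # median of the 1-df chi-square distribution


@dataclass
class StudySummary:
    """Per-variant, per-study association record."""

    snp: str
    a1: str
    a2: str
    freq1: float
    beta: float
    se: float
    p: float
    n: int
    study: str
    neglog10_p: float = np.nan
    converged: bool = True
    flag: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if not (self.se > 0):
                raise ValueError("SE must be positive")
            if not (0.0 < self.freq1 < 1.0):
                raise ValueError("frequency must lie in (0, 1)")


def wald_p_from_z(z: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Wald P and -log10 P, computed in log space."""
    z = np.asarray(z, dtype=float)
    logsf = stats.norm.logsf(np.abs(z))
    log10p = (logsf + np.log(2.0)) / np.log(10.0)
    return np.exp(log10p * np.log(10.0)), -log10p


def _irls_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton/IRLS fit; returns (beta, se, converged).

    Convergence is declared on the change in log-likelihood.  Quasi-complete
    separation shows up as diverging coefficients or a singular information
    matrix; both are reported as non-convergence rather than as estimates.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        H = (X.T * W) @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, np.full(p, np.nan), False
        beta = beta + step
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        if np.abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    if not converged or np.max(np.abs(beta)) > 30:
        return beta, np.full(p, np.nan), False
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    H = (X.T * (mu * (1.0 - mu))) @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return beta, np.full(p, np.nan), False
    return beta, np.sqrt(np.diag(cov)), True


def _covariate_design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    """Expand covariates into a numeric design block (dummy-coded factors)."""
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((n, 0))
    cols = []
    for c in covariates.columns:
        col = covariates[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(dtype=float))
        else:
            cols.append(col.to_numpy(dtype=float))
    if not cols:
        return np.empty((n, 0))
    return np.column_stack(cols)


def logistic_assoc(
    matrix: CohortMatrix,
    variant: int | str,
    covariates: pd.DataFrame | None = None,
) -> StudySummary:
    """Additive logistic association for one variant.

    Returns a :class:`StudySummary` with the per-allele log-odds ratio, its
    standard error from the observed information, and a two-sided Wald P.
    Non-convergence or separation yields a flagged record with missing
    estimates; a constant dosage yields a ``monomorphic`` flag.  Missing
    dosages are mean-imputed.
    """
    if isinstance(variant, str):
        hits = np.where(matrix.variants["id"].to_numpy() == variant)[0]
        if hits.size == 0:
            raise KeyError(f"variant {variant!r} not in cohort")
        j = int(hits[0])
    else:
        j = int(variant)
    y = matrix.phenotype.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype must contain both cases and controls")
    row = matrix.variants.iloc[j]
    cov_block = _covariate_design(covariates, matrix.n_samples)
    return _assoc_one(matrix, j, row, y, cov_block)


def _assoc_one(
    matrix: CohortMatrix,
    j: int,
    row: pd.Series,
    y: np.ndarray,
    cov_block: np.ndarray,
) -> StudySummary:
    g = matrix.dosage[:, j].astype(float)
    mean = np.nanmean(g)
    g = np.where(np.isnan(g), mean, g)
    if np.allclose(g, g[0]):
        return StudySummary(
            snp=row["id"], a1=row["a1"], a2=row["a2"], freq1=np.nan,
            beta=np.nan, se=np.nan, p=np.nan, n=matrix.n_samples,
            study=matrix.study_id, converged=False, flag="monomorphic",
        )
    X = np.column_stack([np.ones_like(g), g, cov_block])
    f = float(mean / 2.0)
    beta, se, ok = _irls_logistic(X, y)
    if not ok:
        return StudySummary(
            snp=row["id"], a1=row["a1"], a2=row["a2"], freq1=f,
            beta=np.nan, se=np.nan, p=np.nan, n=matrix.n_samples,
            study=matrix.study_id, converged=False, flag="non_convergence",
        )
    z = beta[1] / se[1]
    p, nlp = wald_p_from_z(z)
    return StudySummary(
        snp=row["id"], a1=row["a1"], a2=row["a2"], freq1=f,
        beta=float(beta[1]), se=float(se[1]), p=float(p), n=matrix.n_samples,
        study=matrix.study_id, neglog10_p=float(nlp),
    )


def assoc_scan(
    matrix: CohortMatrix, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Association scan over all variants; one summary row per variant.

    Output follows the summary-statistic table dialect (columns SNP, CHR,
    POS, A1, A2, FREQ1, BETA, SE, P, N, STUDY plus NEGLOG10P and FLAG).
    """
    y = matrix.phenotype.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype must contain both cases and controls")
    cov_block = _covariate_design(covariates, matrix.n_samples)
    rows = []
    for j in range(matrix.n_variants):
        s = _assoc_one(matrix, j, matrix.variants.iloc[j], y, cov_block)
        rows.append(
            (s.snp, matrix.variants.iloc[j]["chrom"], matrix.variants.iloc[j]["pos"],
             s.a1, s.a2, s.freq1, s.beta, s.se, s.p, s.n, s.study,
             s.neglog10_p, s.flag)
        )
    return pd.DataFrame(
        rows,
        columns=["SNP", "CHR", "POS", "A1", "A2", "FREQ1", "BETA", "SE", "P",
                 "N", "STUDY", "NEGLOG10P", "FLAG"],
    )


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median association chi-square over 0.4549.

    ``lambda_GC = median(qchisq(1 - P, df=1)) / 0.4549364``.  Requires at
    least 100 P-values in (0, 1] for a stable median.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 100:
        raise ValueError("need at least 100 P-values for lambda_GC")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def direction_consistency(betas: np.ndarray) -> bool:
    """True iff all non-missing study effects share a strict sign.

    A zero effect carries no direction and renders the set inconsistent.
    Requires at least two non-missing effects.
    """
    b = np.asarray(betas, dtype=float)
    b = b[~np.isnan(b)]
    if b.size < 2:
        raise ValueError("need at least two study effects")
    return bool(np.all(b > 0) or np.all(b < 0))


def allele_freq_fisher(table: np.ndarray) -> float:
    """Two-tailed Fisher exact P comparing allele counts of two populations.

    ``table`` is 2x2: rows are populations, columns allele counts.  An empty
    margin makes the comparison vacuous and returns P = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        import warnings

        warnings.warn("empty margin in allele count table; P = 1")
        return 1.0
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)
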