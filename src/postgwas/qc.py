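"""Genotype quality control: exact HWE, variant and sample filters, PCA.

Filters follow the conventions of array-based case-control studies: variant
filters run in a fixed order (call rate, differential missingness by case
status, Hardy-Weinberg in controls, minor allele frequency, duplicate
position) and each dropped record carries the first failing reason code, so
the same input always yields the same report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact

from .simulate import CohortMatrix

__all__ = [
    "QCThresholds",
    "hwe_exact_test",
    "variant_qc",
    "sample_qc",
    "pca_genotypes",
]


@dataclass(frozen=True)
class QCThresholds:
    """Default thresholds mirror standard array QC practice."""

    sample_call_rate_min: float = 0.98
    variant_call_rate_min: float = 0.99
    maf_min: float = 0.01
    hwe_p_min: float = 1e-5
    diff_missing_p_min: float = 1e-5
    het_sd: float = 3.0
    ancestry_sd: float = 6.0
    batch_maf_diff_max: float = 0.10

    def __post_init__(self) -> None:
        for name in ("sample_call_rate_min", "variant_call_rate_min",
                     "maf_min", "hwe_p_min", "diff_missing_p_min"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.het_sd <= 0 or self.ancestry_sd <= 0:
            raise ValueError("SD multipliers must be positive")


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed configuration (the standard exact HWE test).
    Monomorphic input returns 1.0 by convention.

    Parameters are genotype counts: ``n_aa`` homozygous for the first
    allele, ``n_ab`` heterozygous, ``n_bb`` homozygous for the second.
    """
    for c in (n_aa, n_ab, n_bb):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n_aa, n_ab, n_bb = int(n_aa), int(n_ab), int(n_bb)
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("total genotype count must be positive")

    # minor-allele orientation
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0  # monomorphic: single possible configuration

    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    # log conditional probability (hypergeometric-type, up to a constant)
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(n_common_hom + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = n_ab
    p_obs = probs[hets == obs][0]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def _call_rates(dosage: np.ndarray, axis: int) -> np.ndarray:
    return 1.0 - np.isnan(dosage).mean(axis=axis)


def variant_qc(
    matrix: CohortMatrix, th: QCThresholds | None = None
) -> pd.DataFrame:
    """Apply variant filters in documented order; one reason per drop.

    Order: call rate → differential missingness (two-sided Fisher on the
    missing-by-status 2x2 table) → HWE exact test in controls → MAF →
    duplicate physical position.  Returns a frame with columns ``id``,
    ``kept`` and ``reason`` (empty string when kept).
    """
    th = th or QCThresholds()
    D = matrix.dosage
    y = matrix.phenotype
    n_var = D.shape[1]
    reasons = np.array([""] * n_var, dtype=object)

    call = _call_rates(D, axis=0)
    reasons[(reasons == "") & (call < th.variant_call_rate_min)] = "call_rate"

    miss = np.isnan(D)
    cases, ctrls = y == 1, y == 0
    for j in range(n_var):
        if reasons[j]:
            continue
        mc, mu = int(miss[cases, j].sum()), int(miss[ctrls, j].sum())
        if mc + mu == 0:
            continue
        table = [[mc, int(cases.sum()) - mc], [mu, int(ctrls.sum()) - mu]]
        _, p = fisher_exact(table, alternative="two-sided")
        if p < th.diff_missing_p_min:
            reasons[j] = "diff_missingness"

    for j in range(n_var):
        if reasons[j]:
            continue
        g = D[ctrls, j]
        g = g[~np.isnan(g)]
        counts = [(g == k).sum() for k in (0, 1, 2)]
        if sum(counts) == 0:
            continue
        if hwe_exact_test(*counts) < th.hwe_p_min:
            reasons[j] = "hwe"

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f = np.nanmean(D, axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    reasons[(reasons == "") & (maf < th.maf_min)] = "maf"

    pos_key = matrix.variants["chrom"].astype(str) + ":" + matrix.variants["pos"].astype(str)
    dup = pos_key.duplicated(keep="first").to_numpy()
    reasons[(reasons == "") & dup] = "duplicate_position"

    return pd.DataFrame(
        {"id": matrix.variants["id"].to_numpy(), "kept": reasons == "", "reason": reasons}
    )


def sample_qc(
    matrix: CohortMatrix,
    th: QCThresholds | None = None,
    pc_scores: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sample filters: call rate, heterozygosity outliers, ancestry distance.

    Heterozygosity rate is the fraction of non-missing calls that are
    heterozygous; samples beyond ``het_sd`` standard deviations from the
    mean are dropped.  The ancestry filter measures Euclidean distance from
    the centroid on the first two principal components (computed here if
    ``pc_scores`` is not supplied) and drops samples beyond ``ancestry_sd``
    SDs of that distance.  With fewer than 10 samples the SD-based filters
    are skipped with a warning.
    """
    th = th or QCThresholds()
    D = matrix.dosage
    n = D.shape[0]
    reasons = np.array([""] * n, dtype=object)

    call = _call_rates(D, axis=1)
    reasons[call < th.sample_call_rate_min] = "call_rate"

    if n < 10:
        warnings.warn("fewer than 10 samples: heterozygosity and ancestry filters skipped")
    else:
        het = np.nansum(D == 1, axis=1) / np.maximum((~np.isnan(D)).sum(axis=1), 1)
        mu, sd = het.mean(), het.std(ddof=1)
        if sd > 0:
            out = np.abs(het - mu) > th.het_sd * sd
            reasons[(reasons == "") & out] = "heterozygosity"

        if pc_scores is None:
            pc_scores = pca_genotypes(matrix, k=2)
        pc2 = pc_scores[:, :2]
        dist = np.linalg.norm(pc2 - pc2.mean(axis=0), axis=1)
        dsd = dist.std(ddof=1)
        if dsd > 0:
            out = dist > dist.mean() + th.ancestry_sd * dsd
            reasons[(reasons == "") & out] = "ancestry"

    index = (
        matrix.covariates.index.to_numpy()
        if len(matrix.covariates) == n
        else np.arange(n)
    )
    return pd.DataFrame({"sample": index, "kept": reasons == "", "reason": reasons})


def pca_genotypes(matrix: CohortMatrix | np.ndarray, k: int = 3) -> np.ndarray:
    """Top-k principal component scores of the standardized dosage matrix.

    Dosages are mean-imputed and scaled by sqrt(2 f (1-f)); monomorphic
    variants are excluded.  The sign of each component is fixed so the
    loading of largest magnitude is positive, making scores deterministic.
    Requesting more components than the matrix rank truncates with a
    warning.
    """
    D = matrix.dosage if isinstance(matrix, CohortMatrix) else matrix
    X = np.array(D, dtype=float)
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    f = col_mean / 2.0
    scale = np.sqrt(2.0 * f * (1.0 - f))
    keep = scale > 0
    X = (X[:, keep] - col_mean[keep]) / scale[keep]

    max_rank = min(X.shape)
    if k > max_rank:
        warnings.warn(f"k={k} exceeds rank bound {max_rank}; truncating")
        k = max_rank

    if k <= 10 and max_rank > 3 * k and min(X.shape) > 50:
        from scipy.sparse.linalg import svds

        v0 = np.full(min(X.shape), 1.0 / np.sqrt(min(X.shape)))
        u, s, vt = svds(X, k=k, v0=v0)
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]
    else:
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        u, s, vt = u[:, :k], s[:k], vt[:k]

    # deterministic sign: largest-magnitude loading positive
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    return u * s
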