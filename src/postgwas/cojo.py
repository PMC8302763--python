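"""Approximate conditional and joint analysis from summary statistics.

Given marginal per-allele effects and an LD reference, joint multi-SNP
effects are recovered on the standardized-genotype scale: marginal betas
are multiplied by sqrt(2 f (1-f)), the vector is premultiplied by the
inverse of the candidates' LD correlation matrix R, and standard errors
come from the diagonal of R^-1 scaled by each candidate's marginal sampling
variance.  This is the linear approximation used by summary-statistic
conditional analysis of binary traits; its accuracy against a direct
multivariable logistic fit is characterised in the test suite (within 15%
relative error for |beta| <= 0.3 at n >= 20,000).

Stepwise selection starts from the smallest marginal P and keeps adding the
variant with the smallest conditional P while it stays genome-wide
significant, with deterministic (P, position) tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import wald_p_from_z
from .ld import LDReference
from .meta import GWS_P_THRESHOLD

__all__ = ["CollinearityError", "ConditionalResult", "cojo_joint", "cojo_select"]

COLLINEARITY_R2_CAP = 0.9
CONDITION_NUMBER_CAP = 1e8


class CollinearityError(ValueError):
    """Raised when the candidate LD matrix is too ill-conditioned to invert."""

    def __init__(self, message: str, pairs: list[tuple[str, str, float]] | None = None):
        super().__init__(message)
        self.pairs = pairs or []


def _check_collinearity(R: np.ndarray, ids: list[str], cap: float) -> None:
    pairs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if R[i, j] ** 2 >= cap:
                pairs.append((ids[i], ids[j], float(R[i, j] ** 2)))
    if pairs:
        raise CollinearityError(
            f"{len(pairs)} candidate pair(s) exceed the collinearity cap r^2 >= {cap}",
            pairs,
        )
    if np.linalg.cond(R) > CONDITION_NUMBER_CAP:
        raise CollinearityError(
            f"LD matrix condition number exceeds {CONDITION_NUMBER_CAP:g}"
        )


def cojo_joint(
    candidates: pd.DataFrame,
    ref: LDReference | None = None,
    R: np.ndarray | None = None,
    collinearity_cap: float = COLLINEARITY_R2_CAP,
) -> pd.DataFrame:
    """Joint effect estimates for a set of candidate SNPs.

    ``candidates`` needs columns SNP, FREQ1, BETA, SE (the marginal,
    allele-aligned summary statistics).  LD comes either from ``ref`` or an
    explicit correlation matrix ``R`` in candidate order.  Returns a frame
    with joint BETA_J, SE_J, P_J (per-allele scale) alongside the marginals.

    With an orthogonal (diagonal) R the joint estimates equal the marginal
    ones exactly.
    """
    ids = candidates["SNP"].tolist()
    if len(ids) == 0:
        raise ValueError("no candidates")
    if R is None:
        if ref is None:
            raise ValueError("provide either an LD reference or an R matrix")
        R = ref.corr_matrix(ids)
    R = np.asarray(R, dtype=float)
    if R.shape != (len(ids), len(ids)):
        raise ValueError("R shape does not match candidate count")
    _check_collinearity(R, ids, collinearity_cap)

    f = candidates["FREQ1"].to_numpy(dtype=float)
    b = candidates["BETA"].to_numpy(dtype=float)
    se = candidates["SE"].to_numpy(dtype=float)
    if np.any(se <= 0):
        raise ValueError("non-positive SE among candidates")
    s = np.sqrt(2.0 * f * (1.0 - f))   # per-allele -> standardized scale

    Rinv = np.linalg.inv(R)
    b_std = b * s
    bj_std = Rinv @ b_std
    var_j_std = np.diag(Rinv) * (se * s) ** 2
    beta_j = bj_std / s
    se_j = np.sqrt(var_j_std) / s
    z = beta_j / se_j
    p, nlp = wald_p_from_z(z)

    out = candidates.copy()
    out["BETA_J"] = beta_j
    out["SE_J"] = se_j
    out["P_J"] = p
    out["NEGLOG10P_J"] = nlp
    return out


@dataclass
class ConditionalResult:
    """Outcome of stepwise forward selection."""

    selected: list[str]
    steps: pd.DataFrame        # step, SNP, conditional beta/se/p at selection
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (SNP, reason)
    status: str = "ok"


def cojo_select(
    region: pd.DataFrame,
    ref: LDReference,
    p_threshold: float = GWS_P_THRESHOLD,
    collinearity_cap: float = COLLINEARITY_R2_CAP,
) -> ConditionalResult:
    """Stepwise selection of independent signals in a region.

    Starts with the variant of smallest marginal P (ties broken by
    position, then id).  At each step every remaining candidate is jointly
    modelled with the selected set; the candidate with the smallest
    conditional P joins if that P stays at or below ``p_threshold``.
    Candidates collinear with the selected set (pairwise r^2 above the cap)
    are set aside and reported.  The result is invariant to the input row
    order.
    """
    df = region.copy()
    needed = {"SNP", "POS", "FREQ1", "BETA", "SE", "P"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    df = df.sort_values(["P", "POS", "SNP"], kind="mergesort").reset_index(drop=True)

    if df["P"].min() > p_threshold:
        return ConditionalResult(
            selected=[], steps=pd.DataFrame(
                columns=["step", "SNP", "BETA_C", "SE_C", "P_C"]
            ), status="no_significant_variant",
        )

    selected: list[str] = []
    excluded: list[tuple[str, str]] = []
    step_rows = []
    first = df.iloc[0]
    selected.append(first["SNP"])
    step_rows.append((1, first["SNP"], first["BETA"], first["SE"], first["P"]))
    remaining = df.iloc[1:].copy()

    step = 1
    while len(remaining):
        step += 1
        best = None  # (p, pos, snp, beta, se)
        drop_now = []
        for r in remaining.itertuples(index=False):
            # collinearity screen against the selected set
            collinear = False
            for s_id in selected:
                rr = ref.r(s_id, r.SNP)
                if rr * rr >= collinearity_cap:
                    collinear = True
                    break
            if collinear:
                drop_now.append((r.SNP, "collinear_with_selected"))
                continue
            cand = pd.concat(
                [
                    df[df["SNP"].isin(selected)],
                    df[df["SNP"] == r.SNP],
                ]
            )
            try:
                joint = cojo_joint(cand, ref=ref, collinearity_cap=collinearity_cap)
            except CollinearityError:
                drop_now.append((r.SNP, "ill_conditioned"))
                continue
            row = joint[joint["SNP"] == r.SNP].iloc[0]
            key = (float(row["P_J"]), int(r.POS), str(r.SNP))
            if best is None or key < best[0]:
                best = (key, row)
        for snp, why in drop_now:
            excluded.append((snp, why))
            remaining = remaining[remaining["SNP"] != snp]
        if best is None:
            break
        (p_c, _, _), row = best
        if p_c > p_threshold:
            break
        selected.append(row["SNP"])
        step_rows.append((step, row["SNP"], row["BETA_J"], row["SE_J"], row["P_J"]))
        remaining = remaining[remaining["SNP"] != row["SNP"]]

    steps = pd.DataFrame(
        step_rows, columns=["step", "SNP", "BETA_C", "SE_C", "P_C"]
    )
    return ConditionalResult(selected=selected, steps=steps, excluded=excluded)
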