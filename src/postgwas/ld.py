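"""LD against a reference panel, credible-risk-variant sets, gene regions.

A locus is anchored by its most strongly associated ("lead") variant; the
credible risk variant (CRV) set collects every panel variant with LD
r^2 >= 0.80 to the lead within a +/-1 Mb window, and the span of the CRV
set demarcates the gene region used for target-gene adjudication.
Coordinates are 1-based inclusive throughout; BED conversion happens only
at I/O boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LDReference",
    "Locus",
    "ld_r2",
    "define_crv_set",
    "count_region_genes",
    "classify_signal_location",
    "CRV_R2_THRESHOLD",
]

CRV_R2_THRESHOLD = 0.80


class LDReference:
    """Dosage panel with on-demand pairwise LD.

    ``genotypes`` is samples x variants (0/1/2, NaN allowed and
    mean-imputed); ``variants`` must carry id, chrom, pos.  Correlations are
    plain Pearson r of dosage vectors, as summary-statistic conditional
    analysis tools compute them.
    """

    def __init__(self, genotypes: np.ndarray, variants: pd.DataFrame):
        X = np.asarray(genotypes, dtype=float)
        col_mean = np.nanmean(X, axis=0)
        mask = np.isnan(X)
        if mask.any():
            X = np.where(mask, np.take(col_mean, np.indices(X.shape)[1]), X)
        self.genotypes = X
        self.variants = variants.reset_index(drop=True)
        self._index = {v: j for j, v in enumerate(variants["id"])}
        sd = X.std(axis=0)
        self._sd = sd

    def column(self, variant: str) -> int:
        try:
            return self._index[variant]
        except KeyError:
            raise KeyError(f"variant {variant!r} not in LD reference") from None

    def is_monomorphic(self, variant: str) -> bool:
        return self._sd[self.column(variant)] == 0.0

    def r(self, v1: str, v2: str) -> float:
        """Signed Pearson correlation of the two dosage vectors."""
        j1, j2 = self.column(v1), self.column(v2)
        if self._sd[j1] == 0 or self._sd[j2] == 0:
            raise ValueError("LD undefined for monomorphic variant")
        x, y = self.genotypes[:, j1], self.genotypes[:, j2]
        return float(np.corrcoef(x, y)[0, 1])

    def corr_matrix(self, variant_ids: list[str]) -> np.ndarray:
        cols = [self.column(v) for v in variant_ids]
        for v, j in zip(variant_ids, cols):
            if self._sd[j] == 0:
                raise ValueError(f"LD undefined for monomorphic variant {v}")
        R = np.corrcoef(self.genotypes[:, cols], rowvar=False)
        return np.atleast_2d(R)

    def freq(self, variant: str) -> float:
        return float(self.genotypes[:, self.column(variant)].mean() / 2.0)


def ld_r2(ref: LDReference, v1: str, v2: str) -> tuple[float, float]:
    """Signed r and r^2 between two panel variants."""
    r = ref.r(v1, v2)
    return r, r * r


@dataclass
class Locus:
    """Lead variant, its CRV set, and the gene region they demarcate."""

    lead: str
    crvs: pd.DataFrame          # columns: id, pos, r2 (lead included, r2=1)
    chrom: str
    region_start: int
    region_end: int
    genes: list[str] | None = None

    @property
    def n_crvs(self) -> int:
        return len(self.crvs)

    @property
    def n_genes(self) -> int:
        return len(self.genes) if self.genes is not None else 0


def define_crv_set(
    lead: str,
    ref: LDReference,
    r2_threshold: float = CRV_R2_THRESHOLD,
    window: int = 1_000_000,
) -> Locus:
    """Credible risk variants: all panel SNPs with r^2 >= threshold to the lead.

    The search is restricted to the lead's chromosome within ``window`` bp.
    The lead itself is always a member (r^2 = 1); a lead with no qualifying
    neighbours yields a singleton set whose region degenerates to the lead
    position.
    """
    if ref.is_monomorphic(lead):
        raise ValueError(f"lead variant {lead} is monomorphic in the reference")
    jl = ref.column(lead)
    lead_row = ref.variants.iloc[jl]
    chrom, lpos = str(lead_row["chrom"]), int(lead_row["pos"])
    cand = ref.variants[
        (ref.variants["chrom"].astype(str) == chrom)
        & (ref.variants["pos"].between(lpos - window, lpos + window))
    ]
    rows = []
    for r in cand.itertuples(index=False):
        if ref.is_monomorphic(r.id):
            continue
        if r.id == lead:
            rows.append((r.id, int(r.pos), 1.0))
            continue
        _, r2 = ld_r2(ref, lead, r.id)
        if r2 >= r2_threshold:
            rows.append((r.id, int(r.pos), float(r2)))
    crvs = pd.DataFrame(rows, columns=["id", "pos", "r2"]).sort_values("pos")
    return Locus(
        lead=lead,
        crvs=crvs.reset_index(drop=True),
        chrom=chrom,
        region_start=int(crvs["pos"].min()),
        region_end=int(crvs["pos"].max()),
    )


def count_region_genes(
    locus: Locus, annotation: pd.DataFrame
) -> tuple[int, list[str]]:
    """Genes overlapping the CRV region by at least 1 bp.

    ``annotation`` uses 1-based inclusive spans (columns gene, chrom, start,
    end).  A region in a gene desert legitimately returns zero genes.
    Fills ``locus.genes`` as a side effect and returns (n, gene list).
    """
    chroms = annotation["chrom"].astype(str)
    if locus.chrom not in set(chroms):
        warnings.warn(f"annotation has no chromosome {locus.chrom}")
        locus.genes = []
        return 0, []
    sub = annotation[chroms == locus.chrom]
    hit = sub[
        (sub["start"] <= locus.region_end) & (sub["end"] >= locus.region_start)
    ]
    genes = hit["gene"].tolist()
    locus.genes = genes
    return len(genes), genes


def classify_signal_location(
    lead_pos: int,
    gene: pd.Series | dict,
    exons: pd.DataFrame | None = None,
    near_bp: int = 10_000,
) -> str:
    """Locate the lead variant relative to a candidate gene.

    Returns one of ``exonic``, ``intronic``, ``within_10kb`` or ``outside``.
    With no exon model, any position inside the gene span counts as
    intronic; the +/-10 kb window is inclusive and measured from the span
    ends.
    """
    start, end = int(gene["start"]), int(gene["end"])
    if start <= lead_pos <= end:
        if exons is not None and len(exons):
            inside_exon = (
                (exons["start"] <= lead_pos) & (exons["end"] >= lead_pos)
            ).any()
            return "exonic" if inside_exon else "intronic"
        return "intronic"
    if start - near_bp <= lead_pos <= end + near_bp:
        return "within_10kb"
    return "outside"
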