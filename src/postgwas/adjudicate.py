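"""Multi-evidence target-gene scoring, testis specificity, set enrichment.

Candidate genes inside a CRV-demarcated region are scored on five evidence
components and binned into likelihood categories:

* region:     2 = single gene in the region, 1 = two or more, 0 = none;
* location:   1 = lead signal exonic, intronic or within +/-10 kb of the gene;
* eQTL:       0/0.5/1 for none/one/two-plus significant colocalizations in
              non-testis tissues, +1 for a significant testis colocalization
              (component ceiling 2);
* expression: 1/0.5/0 for high/medium/low fetal germ-cell expression by
              tertile;
* contacts:   1/0.5/0 for an open-chromatin promoter connection in
              two-plus/one/no cell lines.

Total >= 3.0 is *highly likely*, 2.0 or 2.5 *moderately likely*, anything
below *unlikely*.  A colocalization is significant when PP3 + PP4 > 0.8
and PP4 / (PP3 + PP4) > 0.9, both strict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "ColocPosterior",
    "GeneEvidence",
    "GeneScore",
    "coloc_significant",
    "eqtl_score",
    "expression_tertiles",
    "expression_score",
    "capture_c_connections",
    "capc_score",
    "region_score",
    "location_score",
    "adjudicate",
    "testis_specificity",
    "set_enrichment",
]

LOCATION_CLASSES = ("exonic", "intronic", "within_10kb", "outside")


@dataclass(frozen=True)
class ColocPosterior:
    """Colocalization posterior for one (gene, tissue) pair."""

    gene: str
    tissue: str
    is_testis: bool
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float

    def __post_init__(self) -> None:
        pps = (self.pp0, self.pp1, self.pp2, self.pp3, self.pp4)
        if any(p < 0 or p > 1 for p in pps):
            raise ValueError("posterior probabilities must lie in [0, 1]")
        if abs(sum(pps) - 1.0) > 1e-9:
            raise ValueError("posterior probabilities must sum to 1")


def coloc_significant(pp: ColocPosterior) -> bool:
    """Strict decision rule: PP3+PP4 > 0.8 and PP4/(PP3+PP4) > 0.9.

    Both inequalities are strict; a zero PP3+PP4 denominator fails.
    """
    s = pp.pp3 + pp.pp4
    if s <= 0.8:
        return False
    return pp.pp4 / s > 0.9


def eqtl_score(posteriors: list[ColocPosterior]) -> float:
    """eQTL colocalization component.

    Base score from the count of distinct non-testis tissues with a
    significant colocalization (0 -> 0, 1 -> 0.5, >=2 -> 1), plus 1 if any
    testis colocalization is significant.  Maximum 2.
    """
    sig_nontestis = {p.tissue for p in posteriors if not p.is_testis and coloc_significant(p)}
    testis_hit = any(p.is_testis and coloc_significant(p) for p in posteriors)
    base = 0.0 if not sig_nontestis else (0.5 if len(sig_nontestis) == 1 else 1.0)
    return base + (1.0 if testis_hit else 0.0)


def expression_tertiles(values: np.ndarray) -> tuple[float, float]:
    """Tertile cutoffs (1/3 and 2/3 empirical quantiles) of expression values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3:
        raise ValueError("need at least three values for tertile cutoffs")
    lo, hi = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0])
    if lo == hi:
        warnings.warn("degenerate tertiles (constant values); all genes medium")
    return float(lo), float(hi)


def expression_score(value: float, cutoffs: tuple[float, float]) -> float:
    """0 / 0.5 / 1 for low / medium / high expression relative to cutoffs.

    Low is value <= first cutoff, high is value > second cutoff (so with
    the published integer cutoffs 698/2348, 2349 scores high and 2348
    medium).
    """
    lo, hi = cutoffs
    if value <= lo:
        return 0.0
    if value <= hi:
        return 0.5
    return 1.0


def region_score(n_genes: int) -> float:
    """2 for a single gene in the region, 1 for two or more, 0 for none."""
    if n_genes < 0:
        raise ValueError("gene count must be non-negative")
    if n_genes == 0:
        return 0.0
    return 2.0 if n_genes == 1 else 1.0


def location_score(location_class: str) -> float:
    """1 for exonic/intronic/within 10 kb of the gene, 0 otherwise."""
    if location_class not in LOCATION_CLASSES:
        raise ValueError(f"unknown location class {location_class!r}")
    return 1.0 if location_class in ("exonic", "intronic", "within_10kb") else 0.0


def capc_score(connection_count: int) -> float:
    """1 for connections in two or more cell lines, 0.5 for one, 0 for none."""
    if connection_count < 0:
        raise ValueError("connection count must be non-negative")
    if connection_count == 0:
        return 0.0
    return 0.5 if connection_count == 1 else 1.0


def _overlaps_any(pos_start: int, pos_end: int, intervals: pd.DataFrame) -> bool:
    """1-based inclusive interval overlap of >= 1 bp."""
    if len(intervals) == 0:
        return False
    return bool(
        ((intervals["start"] <= pos_end) & (intervals["end"] >= pos_start)).any()
    )


def capture_c_connections(
    proxies: pd.DataFrame,
    peaks: pd.DataFrame,
    contacts: pd.DataFrame,
    promoters: pd.DataFrame,
    cell_lines: list[str] | None = None,
) -> pd.Series:
    """Count cell lines with an open SNP-to-open-promoter chromatin loop.

    For each cell line, a gene has a *connection* when some proxy SNP falls
    inside an open-chromatin peak of that line, the SNP also falls inside a
    loop's distal fragment (loops come from the Capture-C line), and the
    gene's promoter interval overlaps a peak of that line by >= 1 bp.
    Returns a per-gene count of cell lines with at least one connection.

    ``proxies``: chrom, pos. ``peaks``: cell_line, chrom, start, end
    (1-based inclusive internally).  ``contacts``: chrom, start, end,
    promoter_gene.  ``promoters``: gene, chrom, start, end.  A cell line
    named in ``cell_lines`` but missing from the peak table contributes 0
    with a warning.
    """
    if cell_lines is None:
        cell_lines = sorted(peaks["cell_line"].unique())
    counts: dict[str, int] = {g: 0 for g in promoters["gene"]}
    prom = promoters.set_index("gene")
    for line in cell_lines:
        line_peaks = peaks[peaks["cell_line"] == line]
        if len(line_peaks) == 0:
            warnings.warn(f"no ATAC peaks for cell line {line}; contributes 0")
            continue
        connected: set[str] = set()
        for c in contacts.itertuples(index=False):
            gene = c.promoter_gene
            if gene not in counts or gene in connected:
                continue
            # proxy SNP inside the loop's distal fragment...
            frag_proxies = proxies[
                (proxies["chrom"].astype(str) == str(c.chrom))
                & (proxies["pos"] >= c.start)
                & (proxies["pos"] <= c.end)
            ]
            if len(frag_proxies) == 0:
                continue
            # ...and open in this cell line
            chrom_peaks = line_peaks[line_peaks["chrom"].astype(str) == str(c.chrom)]
            snp_open = any(
                _overlaps_any(int(p), int(p), chrom_peaks)
                for p in frag_proxies["pos"]
            )
            if not snp_open:
                continue
            pr = prom.loc[gene]
            prom_peaks = line_peaks[
                line_peaks["chrom"].astype(str) == str(pr["chrom"])
            ]
            if _overlaps_any(int(pr["start"]), int(pr["end"]), prom_peaks):
                connected.add(gene)
        for g in connected:
            counts[g] += 1
    return pd.Series(counts, name="connection_count")


@dataclass
class GeneEvidence:
    """Evidence components for one candidate gene at one signal."""

    gene: str
    n_genes_in_region: int
    location_class: str
    posteriors: list[ColocPosterior] = field(default_factory=list)
    fetal_expression: float | None = None
    connection_count: int | None = None


@dataclass
class GeneScore:
    """Component scores, exact total, and likelihood category."""

    gene: str
    s_region: float
    s_location: float
    s_eqtl: float
    s_expr: float
    s_capc: float
    total: float
    category: str
    missing: tuple[str, ...] = ()


def _categorize(total: float) -> str:
    if total >= 3.0:
        return "highly"
    if total >= 2.0:   # totals move in 0.5 steps, so this is {2.0, 2.5}
        return "moderately"
    return "unlikely"


def adjudicate(
    evidence: GeneEvidence,
    expression_cutoffs: tuple[float, float] | None = None,
) -> GeneScore:
    """Score one candidate gene and assign its likelihood category.

    Missing evidence components contribute 0 and are listed in
    ``missing`` — mirroring the reduced scheme used when a data type (for
    instance X-chromosome eQTLs) is unavailable.
    """
    missing: list[str] = []
    s_region = region_score(evidence.n_genes_in_region)
    s_location = location_score(evidence.location_class)
    if evidence.posteriors:
        s_eqtl = eqtl_score(evidence.posteriors)
    else:
        s_eqtl = 0.0
        missing.append("eqtl")
    if evidence.fetal_expression is not None and expression_cutoffs is not None:
        s_expr = expression_score(evidence.fetal_expression, expression_cutoffs)
    else:
        s_expr = 0.0
        missing.append("expression")
    if evidence.connection_count is not None:
        s_capc = capc_score(evidence.connection_count)
    else:
        s_capc = 0.0
        missing.append("capture_c")
    total = s_region + s_location + s_eqtl + s_expr + s_capc
    return GeneScore(
        gene=evidence.gene,
        s_region=s_region,
        s_location=s_location,
        s_eqtl=s_eqtl,
        s_expr=s_expr,
        s_capc=s_capc,
        total=total,
        category=_categorize(total),
        missing=tuple(missing),
    )


def testis_specificity(profile: pd.Series, testis_key: str = "testis") -> str:
    """Classify a tissue TPM profile as enriched, enhanced, or neither.

    *Enriched*: testis >= 1 TPM and >= 5x the maximum of every other
    tissue.  *Enhanced*: not enriched, testis >= 1 TPM and >= 5x the mean
    of the other tissues.  Checked in that order, so the classes partition.
    """
    if testis_key not in profile.index:
        raise ValueError(f"profile lacks a {testis_key!r} entry")
    if len(profile) < 2:
        raise ValueError("need at least two tissues")
    t = float(profile[testis_key])
    others = profile.drop(testis_key).astype(float)
    if (others < 0).any() or t < 0:
        raise ValueError("TPM values must be non-negative")
    if t >= 1.0 and t >= 5.0 * others.max():
        return "enriched"
    if t >= 1.0 and t >= 5.0 * others.mean():
        return "enhanced"
    return "neither"


def set_enrichment(
    selected: set[str], background: set[str], trait_members: set[str]
) -> float:
    """Hypergeometric upper-tail P for trait over-representation.

    Tests whether ``selected`` (a subset of ``background``) contains more
    trait members than expected by drawing |selected| genes without
    replacement.  The upper tail includes the observed count, so zero
    overlap gives P = 1.
    """
    if not background:
        raise ValueError("background gene set is empty")
    if not selected <= background:
        raise ValueError("selected genes must be a subset of the background")
    M = len(background)
    K = len(trait_members & background)
    n = len(selected)
    k = len(selected & trait_members)
    return float(hypergeom.sf(k - 1, M, K, n))
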