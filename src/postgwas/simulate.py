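"""Synthetic cohorts with known ground truth.

This module generates the inputs the rest of the toolkit consumes: an
LD-structured haplotype reference panel, multi-study case-control cohorts
drawn from an additive logistic disease model, and per-gene functional
evidence tables (eQTL colocalization posteriors, fetal germ-cell expression,
open-chromatin peaks and promoter-contact loops, and a tissue-by-gene TPM
matrix).  Every generator is deterministic for a fixed seed, and each
returns a *truth record* so downstream estimates can be compared against
what was simulated.

The disease model is a standard rare-disease case-control design: genotype
dosages act additively on the log-odds scale, the intercept is calibrated
so the population case probability equals the assumed lifetime risk
(default 0.5%), and case/control samples are obtained by rejection sampling
from the population model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "PanelSpec",
    "DiseaseModel",
    "CohortMatrix",
    "Panel",
    "EvidenceTables",
    "simulate_panel",
    "solve_intercept",
    "simulate_cohort",
    "simulate_evidence",
    "genotypes_from_panel",
]


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelSpec:
    """Parameters of the haplotype reference panel.

    ``within_block_rho`` is the probability that a haplotype copies the
    allele of the previous variant inside an LD block; 0 gives linkage
    equilibrium, values near 1 give long stretches of near-perfect LD.
    """

    n_haplotypes: int = 10_000
    n_variants: int = 100
    block_size: int = 20
    within_block_rho: float = 0.7
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.n_haplotypes < 2:
            raise ValueError("n_haplotypes must be >= 2")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if not (0.0 <= self.within_block_rho < 1.0):
            raise ValueError("within_block_rho must lie in [0, 1)")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele frequencies must lie strictly inside (0, 1)")


@dataclass
class Panel:
    """Haplotype panel plus variant metadata.

    ``haplotypes`` is a (n_haplotypes, n_variants) uint8 matrix of alleles;
    ``freqs`` holds the theoretical marginal allele-1 frequency of each
    variant under the generating chain.
    """

    haplotypes: np.ndarray
    freqs: np.ndarray
    variants: pd.DataFrame  # columns: id, chrom, pos, a1, a2

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]


def simulate_panel(spec: PanelSpec) -> Panel:
    """Generate an LD-structured haplotype panel.

    Within each block of ``spec.block_size`` variants, a haplotype copies the
    previous variant's allele with probability ``within_block_rho`` and
    otherwise draws a fresh Bernoulli allele at that variant's base
    frequency.  Blocks are independent, so correlation across block
    boundaries is zero in expectation.  The returned theoretical frequencies
    follow the chain recursion p_j = rho * p_{j-1} + (1 - rho) * f_j.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.n_variants, spec.n_haplotypes
    lo, hi = spec.allele_freq_range
    base_freq = rng.uniform(lo, hi, size=m)

    hap = np.empty((n, m), dtype=np.uint8)
    freqs = np.empty(m)
    for j in range(m):
        fresh = (rng.random(n) < base_freq[j]).astype(np.uint8)
        if j % spec.block_size == 0:
            hap[:, j] = fresh
            freqs[j] = base_freq[j]
        else:
            copy = rng.random(n) < spec.within_block_rho
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
            freqs[j] = (
                spec.within_block_rho * freqs[j - 1]
                + (1.0 - spec.within_block_rho) * base_freq[j]
            )

    variants = pd.DataFrame(
        {
            "id": [f"var{j:05d}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000,
            "a1": "A",
            "a2": "G",
        }
    )
    return Panel(haplotypes=hap, freqs=freqs, variants=variants)


def genotypes_from_panel(
    panel: Panel, n_samples: int, rng: np.random.Generator, x_linked: bool = False
) -> np.ndarray:
    """Dosages drawn from the panel with replacement.

    Autosomal mode sums two independent haplotypes (Hardy-Weinberg by
    construction).  X-linked mode models hemizygous males: one haplotype,
    dosage doubled to {0, 2} so the per-allele effect scale matches the
    autosomes.
    """
    if x_linked:
        idx = rng.integers(0, panel.n_haplotypes, size=n_samples)
        return (2 * panel.haplotypes[idx]).astype(np.int8)
    idx = rng.integers(0, panel.n_haplotypes, size=(n_samples, 2))
    return (panel.haplotypes[idx[:, 0]] + panel.haplotypes[idx[:, 1]]).astype(np.int8)


# ---------------------------------------------------------------------------
# disease model
# ---------------------------------------------------------------------------

@dataclass
class DiseaseModel:
    """Additive logistic disease model.

    ``causal_effects`` maps variant id to a per-allele log-odds ratio.  The
    intercept is *solved* (see :func:`solve_intercept`) so that the
    population case probability equals the prevalence ``k`` — the assumed
    lifetime risk, 0.5% by default.
    """

    causal_effects: Mapping[str, float] = field(default_factory=dict)
    k: float = 0.005
    intercept: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.k < 1.0):
            raise ValueError("prevalence k must lie in (0, 1)")
        for vid, b in self.causal_effects.items():
            if not np.isfinite(b):
                raise ValueError(f"non-finite effect for {vid}")

    def causal_indices(self, panel: Panel) -> tuple[np.ndarray, np.ndarray]:
        """Column indices and betas of causal variants present in the panel."""
        id_to_col = {v: j for j, v in enumerate(panel.variants["id"])}
        missing = [v for v in self.causal_effects if v not in id_to_col]
        if missing:
            raise KeyError(f"causal variants absent from panel: {missing}")
        cols = np.array([id_to_col[v] for v in self.causal_effects], dtype=int)
        betas = np.array(list(self.causal_effects.values()), dtype=float)
        return cols, betas


def solve_intercept(
    model: DiseaseModel,
    panel: Panel,
    n_mc: int = 200_000,
    mc_seed: int = 12345,
    x_linked: bool = False,
) -> float:
    """Calibrate the logistic intercept to the model prevalence.

    The mean predicted case probability over a Monte-Carlo genotype sample
    from the panel equals ``model.k`` to within 1e-6 (Brent root-finding on
    the intercept).  With no causal effects this reduces to logit(k).
    """
    if not model.causal_effects:
        return float(np.log(model.k / (1.0 - model.k)))
    cols, betas = model.causal_indices(panel)
    rng = np.random.default_rng(mc_seed)
    sub = panel.haplotypes[:, cols]
    if x_linked:
        idx = rng.integers(0, panel.n_haplotypes, size=n_mc)
        eta = (2.0 * sub[idx]).astype(float) @ betas
    else:
        idx = rng.integers(0, panel.n_haplotypes, size=(n_mc, 2))
        eta = (sub[idx[:, 0]] + sub[idx[:, 1]]).astype(float) @ betas

    def mean_risk(b0: float) -> float:
        return float(np.mean(expit(b0 + eta))) - model.k

    b0 = brentq(mean_risk, -60.0, 60.0, xtol=1e-10)
    return float(b0)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortMatrix:
    """Samples-by-variants dosage matrix with phenotype and covariates.

    Dosages are float (0/1/2 with NaN for missing); ``phenotype`` is 1 for
    cases, 0 for controls; ``covariates`` carries at least the study-center
    label and gains principal components during QC.
    """

    dosage: np.ndarray
    phenotype: np.ndarray
    covariates: pd.DataFrame
    variants: pd.DataFrame
    study_id: str = "S1"

    def __post_init__(self) -> None:
        if self.dosage.shape[0] != len(self.phenotype):
            raise ValueError("dosage rows and phenotype length differ")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosages must lie in {0, 1, 2} or be missing")
        if not set(np.unique(self.phenotype)) <= {0, 1}:
            raise ValueError("phenotype must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]


def simulate_cohort(
    panel: Panel,
    model: DiseaseModel,
    n_cases: int,
    n_controls: int,
    n_studies: int = 1,
    seed: int = 0,
    missing_rate: float = 0.0,
    max_draws: int = 50_000_000,
    x_linked: bool = False,
) -> tuple[list[CohortMatrix], dict]:
    """Draw multi-study case-control cohorts by rejection sampling.

    Individuals are sampled from the population model (two panel haplotypes,
    case status Bernoulli at the model's predicted risk) until each study
    has exactly ``n_cases`` cases and ``n_controls`` controls.  Only causal
    dosages are materialised during rejection; full genotype rows are built
    for accepted samples only.  Per-study randomness comes from spawned
    substreams of the master seed, so adding a study never perturbs earlier
    ones.

    Returns the list of cohorts (center labels ``S1``..``Sk``) and a truth
    record holding the causal effects, solved intercept and panel
    frequencies.
    """
    if model.intercept is None:
        b0 = solve_intercept(model, panel, x_linked=x_linked)
    else:
        b0 = model.intercept
    expected_pool = n_cases / model.k
    if n_studies * expected_pool > max_draws:
        raise ValueError(
            f"requested {n_cases} cases/study at prevalence {model.k} needs "
            f"~{int(n_studies * expected_pool)} population draws, over the "
            f"max_draws guard ({max_draws}); raise max_draws explicitly"
        )

    if model.causal_effects:
        cols, betas = model.causal_indices(panel)
        sub = panel.haplotypes[:, cols].astype(float)
    else:
        cols, betas, sub = None, None, None

    streams = np.random.SeedSequence(seed).spawn(n_studies)
    cohorts: list[CohortMatrix] = []
    for s in range(n_studies):
        rng = np.random.default_rng(streams[s])
        case_idx: list[np.ndarray] = []
        ctrl_idx: list[np.ndarray] = []
        got_cases = got_ctrls = 0
        drawn = 0
        batch = max(10_000, int(2.2 * n_cases / model.k / 10))
        while got_cases < n_cases or got_ctrls < n_controls:
            if drawn >= max_draws:
                raise RuntimeError(
                    f"study {s}: exhausted {max_draws} draws with "
                    f"{got_cases}/{n_cases} cases — counts unreachable"
                )
            if x_linked:
                idx = rng.integers(0, panel.n_haplotypes, size=(batch, 1))
            else:
                idx = rng.integers(0, panel.n_haplotypes, size=(batch, 2))
            if sub is not None:
                if x_linked:
                    dos = 2.0 * sub[idx[:, 0]]
                else:
                    dos = sub[idx[:, 0]] + sub[idx[:, 1]]
                p = expit(b0 + dos @ betas)
            else:
                p = np.full(batch, model.k)
            is_case = rng.random(batch) < p
            drawn += batch
            if got_cases < n_cases:
                take = idx[is_case][: n_cases - got_cases]
                case_idx.append(take)
                got_cases += len(take)
            if got_ctrls < n_controls:
                take = idx[~is_case][: n_controls - got_ctrls]
                ctrl_idx.append(take)
                got_ctrls += len(take)

        idx_all = np.vstack(case_idx + ctrl_idx)
        if x_linked:
            G = 2.0 * panel.haplotypes[idx_all[:, 0]].astype(np.float64)
        else:
            G = (
                panel.haplotypes[idx_all[:, 0]].astype(np.float64)
                + panel.haplotypes[idx_all[:, 1]]
            )
        y = np.concatenate(
            [np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)]
        )
        if missing_rate > 0:
            miss = rng.random(G.shape) < missing_rate
            G[miss] = np.nan
        label = f"S{s + 1}"
        samples = [f"{label}_{i:06d}" for i in range(n_cases + n_controls)]
        cov = pd.DataFrame({"center": label}, index=samples)
        cohorts.append(
            CohortMatrix(
                dosage=G,
                phenotype=y,
                covariates=cov,
                variants=panel.variants.copy(),
                study_id=label,
            )
        )

    truth = {
        "causal_effects": dict(model.causal_effects),
        "intercept": b0,
        "prevalence": model.k,
        "panel_freqs": panel.freqs.tolist(),
        "seed": seed,
        "n_studies": n_studies,
        "n_cases_per_study": n_cases,
        "n_controls_per_study": n_controls,
        "x_linked": x_linked,
    }
    return cohorts, truth


# ---------------------------------------------------------------------------
# evidence tables
# ---------------------------------------------------------------------------

@dataclass
class EvidenceTables:
    """Per-gene functional evidence with generation truth.

    All coordinates are 1-based inclusive; BED conversion happens at I/O.
    ``regions`` carries one association signal per target gene (lead
    position and the CRV-demarcated interval).  ``truth`` records the
    category and component scores each gene was generated to realise.
    """

    annotation: pd.DataFrame   # gene, chrom, start, end, strand
    regions: pd.DataFrame      # signal_id, gene, chrom, lead_pos, region_start, region_end
    coloc: pd.DataFrame        # gene, tissue, pp0..pp4
    fetal_expression: pd.DataFrame  # gene, value
    expression_cutoffs: tuple[float, float]
    proxies: pd.DataFrame      # signal_id, chrom, pos
    peaks: pd.DataFrame        # cell_line, chrom, start, end
    contacts: pd.DataFrame     # cell_line, chrom, start, end, promoter_gene
    tpm: pd.DataFrame          # genes x tissues
    truth: pd.DataFrame        # gene, category, s_region, s_location, s_eqtl, s_expr, s_capc


_CELL_LINES = ("NT2-D1", "2102EP", "TCAM2", "NCCIT")
_TISSUES = (
    "testis", "whole_blood", "lung", "liver", "brain_cortex",
    "skin", "thyroid", "adipose", "muscle", "colon",
)

# Component tuples (s_region, s_location, s_eqtl, s_expr, s_capc) realisable by
# the geometric construction below, keyed by target category.
_CATEGORY_COMPONENTS = {
    "highly": [
        (2, 1, 1, 0.5, 0.5),
        (2, 1, 2, 1, 1),
        (2, 1, 1.5, 0, 0),
        (1, 1, 1, 0.5, 0.5),
        (2, 0, 1, 0.5, 0.5),
        (1, 1, 2, 1, 1),
    ],
    "moderately": [
        (2, 0, 0, 0, 0),
        (1, 1, 0, 0, 0),
        (1, 1, 0.5, 0, 0),
        (1, 0, 1, 0, 0.5),
        (1, 0, 0.5, 0.5, 0),
    ],
    "unlikely": [
        (1, 0, 0, 0, 0),
        (1, 0, 0.5, 0, 0),
        (1, 0, 0, 0.5, 0),
        (0, 1, 0, 0.5, 0),
        (0, 0, 0, 0, 0.5),
    ],
}

_NULL_PP = (0.90, 0.04, 0.03, 0.02, 0.01)  # non-significant colocalization


def _significant_pp(rng: np.random.Generator) -> tuple[float, ...]:
    """A posterior vector passing PP3+PP4 > 0.8 with PP4/(PP3+PP4) > 0.9."""
    pp4 = rng.uniform(0.88, 0.95)
    pp3 = rng.uniform(0.0, min(0.98 - pp4, pp4 / 9.0 * 0.9))
    rest = 1.0 - pp3 - pp4
    pp0 = rest * 0.5
    pp1 = rest * 0.3
    pp2 = rest * 0.2
    return (pp0, pp1, pp2, pp3, pp4)


def simulate_evidence(
    genes: Sequence[str],
    scenario: str | Mapping,
    seed: int = 0,
) -> EvidenceTables:
    """Generate functional-evidence tables realising target categories.

    ``scenario`` is either the name ``"all-null"`` (every evidence component
    zero except the region score) or a mapping with an ``assignments`` dict
    of gene → category (``highly`` / ``moderately`` / ``unlikely``) and an
    optional ``expression_cutoffs`` pair used both to place simulated
    expression values and later to score them.  The geometric layout places
    each gene in its own 1 Mb tile so signals never interfere.
    """
    rng = np.random.default_rng(seed)
    if isinstance(scenario, str):
        if scenario == "all-null":
            assignments = {g: "null" for g in genes}
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
        cutoffs = (698.0, 2348.0)
    else:
        try:
            assignments = dict(scenario["assignments"])
        except (KeyError, TypeError) as exc:
            raise ValueError("scenario mapping must provide 'assignments'") from exc
        unknown = set(assignments.values()) - {"highly", "moderately", "unlikely", "null"}
        if unknown:
            raise ValueError(f"unknown categories in scenario: {sorted(unknown)}")
        missing = [g for g in genes if g not in assignments]
        if missing:
            raise ValueError(f"scenario assigns no category to: {missing[:5]}")
        cutoffs = tuple(scenario.get("expression_cutoffs", (698.0, 2348.0)))

    ann_rows, region_rows, coloc_rows, expr_rows = [], [], [], []
    proxy_rows, peak_rows, contact_rows, truth_rows = [], [], [], []
    tpm_rows = {}

    tile = 1_000_000
    gene_len = 20_000
    for gi, gene in enumerate(genes):
        base = gi * tile + 100_000
        gstart, gend = base, base + gene_len
        chrom = "1"
        ann_rows.append((gene, chrom, gstart, gend, "+"))

        cat = assignments[gene]
        if cat == "null":
            # all-null: evidence contributes nothing; region score comes from
            # the annotation alone (single gene in its tile).
            s_region, s_loc, s_eqtl, s_expr, s_capc = 2, 0, 0, 0, 0
        else:
            choices = _CATEGORY_COMPONENTS[cat]
            s_region, s_loc, s_eqtl, s_expr, s_capc = choices[
                rng.integers(0, len(choices))
            ]

        # --- region geometry: lead position and CRV interval ------------
        if s_loc == 1:
            lead = (gstart + gend) // 2          # intronic
        else:
            lead = gend + 50_000                  # > 10 kb away -> outside
        if s_region == 2:
            rstart, rend = gstart - 1_000, gend + 1_000
        elif s_region == 1:
            # region also covers a filler gene downstream
            filler = f"{gene}_nbr"
            fstart, fend = gend + 30_000, gend + 30_000 + gene_len
            ann_rows.append((filler, chrom, fstart, fend, "-"))
            rstart, rend = gstart - 1_000, fend + 1_000
        else:
            rstart, rend = lead + 200_000, lead + 210_000  # gene desert
        region_rows.append((f"sig_{gene}", gene, chrom, lead, rstart, rend))

        # --- colocalization posteriors ----------------------------------
        # decompose s_eqtl = base (0/0.5/1 from non-testis count) + testis bonus
        if s_eqtl in (1.5, 2.0):
            testis_hit = True
            base_score = s_eqtl - 1.0
        else:
            testis_hit = False
            base_score = s_eqtl
        n_sig_nontestis = {0.0: 0, 0.5: 1, 1.0: 2}[float(base_score)]
        nontestis = [t for t in _TISSUES if t != "testis"]
        sig_tissues = list(rng.choice(nontestis, size=n_sig_nontestis, replace=False))
        for tissue in _TISSUES:
            if tissue in sig_tissues or (tissue == "testis" and testis_hit):
                pp = _significant_pp(rng)
            else:
                pp = _NULL_PP
            coloc_rows.append((gene, tissue, *pp))

        # --- fetal germ-cell expression ----------------------------------
        lo_c, hi_c = cutoffs
        if s_expr == 0:
            val = rng.uniform(10, lo_c * 0.9)
        elif s_expr == 0.5:
            val = rng.uniform(lo_c * 1.1, hi_c * 0.95)
        else:
            val = rng.uniform(hi_c * 1.1, hi_c * 3)
        expr_rows.append((gene, float(val)))

        # --- ATAC peaks + promoter contacts ------------------------------
        n_conn_lines = {0.0: 0, 0.5: 1, 1.0: 2}[float(s_capc)]
        snp_pos = lead if s_loc == 1 else gstart - 2_000
        proxy_rows.append((f"sig_{gene}", chrom, snp_pos))
        prom_start, prom_end = gstart - 1_000, gstart + 1_000
        # contact loop (NT2-D1 Capture-C): distal fragment around the proxy SNP
        contact_rows.append(
            ("NT2-D1", chrom, snp_pos - 200, snp_pos + 200, gene)
        )
        for line in _CELL_LINES[:n_conn_lines]:
            peak_rows.append((line, chrom, snp_pos - 100, snp_pos + 100))
            peak_rows.append((line, chrom, prom_start, prom_end))
        # decoy peaks elsewhere for lines without a connection
        for line in _CELL_LINES[n_conn_lines:]:
            peak_rows.append((line, chrom, base + 500_000, base + 500_400))

        # --- tissue TPM profile ------------------------------------------
        kind = rng.integers(0, 3)
        others = rng.uniform(0.5, 3.0, size=len(_TISSUES) - 1)
        if kind == 0:      # testis-enriched
            testis_tpm = 5.0 * others.max() * rng.uniform(1.2, 2.0)
        elif kind == 1:    # testis-enhanced
            testis_tpm = 5.0 * others.mean() * rng.uniform(1.05, 1.2)
            if testis_tpm >= 5.0 * others.max():
                testis_tpm = 4.0 * others.max()
        else:
            testis_tpm = rng.uniform(0.5, 3.0)
        profile = {"testis": float(max(testis_tpm, 0.0))}
        for t, v in zip([t for t in _TISSUES if t != "testis"], others):
            profile[t] = float(v)
        tpm_rows[gene] = profile

        truth_rows.append(
            (gene, cat, s_region, s_loc, s_eqtl, s_expr, s_capc,
             float(s_region + s_loc + s_eqtl + s_expr + s_capc))
        )

    tables = EvidenceTables(
        annotation=pd.DataFrame(
            ann_rows, columns=["gene", "chrom", "start", "end", "strand"]
        ),
        regions=pd.DataFrame(
            region_rows,
            columns=["signal_id", "gene", "chrom", "lead_pos", "region_start", "region_end"],
        ),
        coloc=pd.DataFrame(
            coloc_rows, columns=["gene", "tissue", "pp0", "pp1", "pp2", "pp3", "pp4"]
        ),
        fetal_expression=pd.DataFrame(expr_rows, columns=["gene", "value"]),
        expression_cutoffs=(float(cutoffs[0]), float(cutoffs[1])),
        proxies=pd.DataFrame(proxy_rows, columns=["signal_id", "chrom", "pos"]),
        peaks=pd.DataFrame(peak_rows, columns=["cell_line", "chrom", "start", "end"]),
        contacts=pd.DataFrame(
            contact_rows, columns=["cell_line", "chrom", "start", "end", "promoter_gene"]
        ),
        tpm=pd.DataFrame(tpm_rows).T[list(_TISSUES)],
        truth=pd.DataFrame(
            truth_rows,
            columns=["gene", "category", "s_region", "s_location", "s_eqtl",
                     "s_expr", "s_capc", "total"],
        ),
    )
    pp_sum = tables.coloc[["pp0", "pp1", "pp2", "pp3", "pp4"]].sum(axis=1)
    assert np.allclose(pp_sum, 1.0, atol=1e-9)
    return tables
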