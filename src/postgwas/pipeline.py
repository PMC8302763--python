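"""End-to-end orchestration: simulate -> QC -> associate -> meta-analyse ->
define loci -> heritability -> PRS -> adjudicate -> report.

A run is driven by a single :class:`RunConfig` (YAML/JSON serialisable,
lossless round-trip) and a master seed; every stage writes deterministic
artifact names under the output directory and contributes record counts to
the final :class:`RunReport`, which conserves counts (in = out + dropped)
across each stage boundary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .adjudicate import (
    ColocPosterior,
    GeneEvidence,
    adjudicate as adjudicate_gene,
    capture_c_connections,
)
from . import io as pio
from .assoc import assoc_scan, genomic_inflation
from .cojo import cojo_select
from .herit import LAMBDA_BROTHER, LAMBDA_FATHER, snp_heritability, total_heritability
from .ld import LDReference, classify_signal_location, count_region_genes, define_crv_set
from .meta import align_alleles, meta_scan
from .prs import PRSModel, percentile_or, prs_score
from .qc import QCThresholds, pca_genotypes, sample_qc, variant_qc
from .simulate import (
    CohortMatrix,
    DiseaseModel,
    PanelSpec,
    genotypes_from_panel,
    simulate_cohort,
    simulate_evidence,
    simulate_panel,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "replicate_table1", "StageFailure"]


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips through YAML losslessly."""

    seed: int = 0
    out_dir: str = "postgwas_run"
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "simulate": True, "qc": True, "assoc": True, "meta": True,
            "loci": True, "heritability": True, "prs": True, "adjudicate": False,
        }
    )
    panel: dict[str, Any] = field(
        default_factory=lambda: {
            "n_haplotypes": 4000, "n_variants": 300, "block_size": 20,
            "within_block_rho": 0.7, "allele_freq_range": [0.05, 0.95],
        }
    )
    disease: dict[str, Any] = field(
        default_factory=lambda: {"prevalence": 0.005, "causal": {}}
    )
    cohort: dict[str, Any] = field(
        default_factory=lambda: {
            "n_cases": 500, "n_controls": 500, "n_studies": 3, "missing_rate": 0.0,
        }
    )
    thresholds: dict[str, Any] = field(
        default_factory=lambda: {
            "gws_p": 5e-8, "het_p": 1e-3, "crv_r2": 0.80,
            "cojo_p": 5e-8, "cojo_collinearity": 0.9, "n_pcs": 3,
        }
    )
    prs: dict[str, Any] = field(
        default_factory=lambda: {"baseline_risk": 0.005}
    )
    heritability: dict[str, Any] = field(
        default_factory=lambda: {"lambdas": [LAMBDA_FATHER, LAMBDA_BROTHER]}
    )
    evidence: dict[str, Any] | None = None
    qc: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                cur = getattr(base, f.name)
                if isinstance(cur, dict) and isinstance(d[f.name], dict):
                    merged = dict(cur)
                    merged.update(d[f.name])
                    kwargs[f.name] = merged
                else:
                    kwargs[f.name] = d[f.name]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunReport:
    """Per-stage bookkeeping plus headline numbers."""

    seed: int
    version: str
    stage_counts: dict[str, dict[str, Any]] = field(default_factory=dict)
    headline: dict[str, Any] = field(default_factory=dict)

    def record(self, stage: str, n_in: int, n_out: int, reasons: dict[str, int] | None = None) -> None:
        dropped = n_in - n_out
        self.stage_counts[stage] = {
            "in": n_in, "out": n_out, "dropped": dropped,
            "reasons": dict(sorted((reasons or {}).items())),
        }
        if reasons is not None and sum(reasons.values()) != dropped:
            raise StageFailure(stage, "reason tallies do not conserve record counts")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "version": self.version,
            "stage_counts": self.stage_counts,
            "headline": self.headline,
        }


def _qc_subset(m: CohortMatrix, keep_samples: np.ndarray, keep_variants: np.ndarray) -> CohortMatrix:
    return CohortMatrix(
        dosage=m.dosage[np.ix_(keep_samples, keep_variants)],
        phenotype=m.phenotype[keep_samples],
        covariates=m.covariates.iloc[keep_samples],
        variants=m.variants.iloc[keep_variants].reset_index(drop=True),
        study_id=m.study_id,
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages and write artifacts under out_dir.

    Reruns with the same config and seed reproduce identical reports and
    tabular artifacts.  A stage failure raises :class:`StageFailure` naming
    the stage; artifacts from completed stages stay on disk.
    """
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, version=__version__)
    stages = config.stages

    cohorts: list[CohortMatrix] = []
    panel = None
    if stages.get("simulate"):
        spec = PanelSpec(seed=config.seed, **{
            k: tuple(v) if k == "allele_freq_range" else v
            for k, v in config.panel.items()
        })
        panel = simulate_panel(spec)
        model = DiseaseModel(
            causal_effects=config.disease.get("causal", {}),
            k=config.disease.get("prevalence", 0.005),
        )
        cohorts, truth = simulate_cohort(
            panel, model,
            n_cases=config.cohort["n_cases"],
            n_controls=config.cohort["n_controls"],
            n_studies=config.cohort["n_studies"],
            seed=config.seed,
            missing_rate=config.cohort.get("missing_rate", 0.0),
        )
        (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
        report.record(
            "simulate",
            n_in=sum(c.n_samples for c in cohorts),
            n_out=sum(c.n_samples for c in cohorts),
        )

    if stages.get("qc") and cohorts:
        th = QCThresholds(**config.qc) if config.qc else QCThresholds()
        n_in_s = sum(c.n_samples for c in cohorts)
        n_in_v = sum(c.n_variants for c in cohorts)
        v_reasons: dict[str, int] = {}
        s_reasons: dict[str, int] = {}
        cleaned = []
        for c in cohorts:
            vrep = variant_qc(c, th)
            srep = sample_qc(c, th)
            for r in vrep.loc[~vrep["kept"], "reason"]:
                v_reasons[r] = v_reasons.get(r, 0) + 1
            for r in srep.loc[~srep["kept"], "reason"]:
                s_reasons[r] = s_reasons.get(r, 0) + 1
            cleaned.append(
                _qc_subset(c, srep["kept"].to_numpy(), vrep["kept"].to_numpy())
            )
        cohorts = cleaned
        report.record("qc_samples", n_in_s, sum(c.n_samples for c in cohorts), s_reasons)
        report.record("qc_variants", n_in_v, sum(c.n_variants for c in cohorts), v_reasons)

    summaries: list[pd.DataFrame] = []
    if stages.get("assoc") and cohorts:
        n_pcs = int(config.thresholds.get("n_pcs", 3))
        for c in cohorts:
            pcs = pca_genotypes(c, k=n_pcs)
            cov = pd.DataFrame(
                pcs, columns=[f"PC{i+1}" for i in range(pcs.shape[1])],
                index=c.covariates.index,
            )
            s = assoc_scan(c, covariates=cov)
            pio.write_summary(s, out / f"assoc_{c.study_id}.tsv")
            summaries.append(s)
        report.record(
            "assoc",
            n_in=sum(len(s) for s in summaries),
            n_out=sum(len(s) for s in summaries),
        )

    meta_df = pd.DataFrame()
    if stages.get("meta") and summaries:
        usable = [s[s["FLAG"] == ""].drop(columns=["FLAG"]) for s in summaries]
        aligned, drops = align_alleles(usable)
        meta_df = meta_scan(aligned)
        het_removed = int(meta_df["HET_FAIL"].sum())
        pio.write_summary(meta_df, out / "meta.tsv")
        lam_gc = (
            genomic_inflation(meta_df["P"].to_numpy())
            if len(meta_df) >= 100 else float("nan")
        )
        n_sig = int(meta_df["SIGNIFICANT"].sum())
        n_union = len(set().union(*(set(s["SNP"]) for s in usable))) if usable else 0
        report.record(
            "meta",
            n_in=n_union,
            n_out=len(meta_df) - het_removed,
            reasons={"allele_alignment": len(drops), "heterogeneity": het_removed},
        )
        report.headline["lambda_gc"] = lam_gc
        report.headline["n_significant"] = n_sig
        qq = meta_df.sort_values("P")[["SNP", "P", "NEGLOG10P"]].copy()
        qq["EXPECTED_NEGLOG10P"] = -np.log10(
            (np.arange(1, len(qq) + 1) - 0.5) / len(qq)
        )
        qq.to_csv(out / "qq.tsv", sep="\t", index=False)

    loci_rows = []
    if stages.get("loci") and len(meta_df) and panel is not None:
        ld_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 991]))
        ref_geno = genotypes_from_panel(panel, min(5000, 4 * panel.n_haplotypes), ld_rng)
        ref = LDReference(ref_geno, panel.variants)
        sig = meta_df[meta_df["SIGNIFICANT"]].sort_values("P")
        used: set[str] = set()
        crv_frames = []
        for row in sig.itertuples(index=False):
            if row.SNP in used:
                continue
            locus = define_crv_set(
                row.SNP, ref, r2_threshold=config.thresholds.get("crv_r2", 0.80)
            )
            used.update(locus.crvs["id"])
            region = meta_df[
                (meta_df["CHR"].astype(str) == locus.chrom)
                & meta_df["POS"].between(row.POS - 1_000_000, row.POS + 1_000_000)
                & ~meta_df["HET_FAIL"]
            ]
            sel = cojo_select(
                region, ref,
                p_threshold=config.thresholds.get("cojo_p", 5e-8),
                collinearity_cap=config.thresholds.get("cojo_collinearity", 0.9),
            )
            loci_rows.append(
                (row.SNP, locus.chrom, row.POS, locus.n_crvs,
                 locus.region_start, locus.region_end,
                 len(sel.selected), ";".join(sel.selected))
            )
            c = locus.crvs.copy()
            c.insert(0, "lead", row.SNP)
            crv_frames.append(c)
        loci_df = pd.DataFrame(
            loci_rows,
            columns=["lead", "chrom", "pos", "n_crvs", "region_start",
                     "region_end", "n_independent", "independent_snps"],
        )
        loci_df.to_csv(out / "loci.tsv", sep="\t", index=False)
        if crv_frames:
            pd.concat(crv_frames).to_csv(out / "crvs.tsv", sep="\t", index=False)
        report.record("loci", n_in=len(sig), n_out=len(loci_df))
        report.headline["n_loci"] = len(loci_df)

    if stages.get("heritability") and len(meta_df):
        lams = config.heritability.get("lambdas", [LAMBDA_FATHER, LAMBDA_BROTHER])
        sig = meta_df[meta_df["SIGNIFICANT"]]
        h_rows = []
        for row in sig.itertuples(index=False):
            for lam in lams:
                h = snp_heritability(row.BETA, row.FREQ1, lam)
                h_rows.append((row.SNP, lam, h))
        h_df = pd.DataFrame(h_rows, columns=["SNP", "lambda", "h"])
        h_df.to_csv(out / "heritability.tsv", sep="\t", index=False)
        for lam in lams:
            report.headline[f"total_h_lambda{lam:g}"] = float(
                h_df.loc[h_df["lambda"] == lam, "h"].sum()
            )
        report.record("heritability", n_in=len(sig), n_out=len(sig))

    if stages.get("prs") and len(meta_df) and cohorts:
        sig = meta_df[meta_df["SIGNIFICANT"]]
        if len(sig):
            weights = sig[["SNP", "A1", "BETA"]].copy()
            model = PRSModel(
                weights=weights,
                baseline_risk=config.prs.get("baseline_risk", 0.005),
            )
            scores = np.concatenate([prs_score(c, model) for c in cohorts])
            status = np.concatenate([c.phenotype for c in cohorts])
            try:
                rep = percentile_or(
                    scores, status, baseline_risk=model.baseline_risk
                )
            except ValueError as exc:
                # few significant loci make the score too discrete for
                # percentile strata; report the skip rather than fail the run
                report.headline["prs_skipped"] = str(exc)
                rep = None
            if rep is not None:
                rep.bins.to_csv(out / "prs_bins.tsv", sep="\t", index=False)
                (out / "prs_report.json").write_text(
                    json.dumps(
                        {
                            "auc": rep.auc,
                            "reference": list(rep.reference),
                            "baseline_risk": rep.baseline_risk,
                            "top_bin_or": float(rep.bins.iloc[-1]["odds_ratio"]),
                        },
                        indent=1, sort_keys=True,
                    )
                )
                report.headline["prs_auc"] = rep.auc
                report.headline["prs_top_bin_or"] = float(rep.bins.iloc[-1]["odds_ratio"])
                report.record("prs", n_in=len(scores), n_out=len(scores))

    if stages.get("adjudicate") and config.evidence:
        genes = list(config.evidence["genes"])
        tables = simulate_evidence(
            genes, config.evidence.get("scenario", "all-null"),
            seed=config.seed,
        )
        scored = score_evidence_tables(tables)
        scored.to_csv(out / "adjudication.tsv", sep="\t", index=False)
        counts = scored["category"].value_counts().to_dict()
        report.headline["gene_categories"] = {
            k: int(counts.get(k, 0)) for k in ("highly", "moderately", "unlikely")
        }
        report.record("adjudicate", n_in=len(genes), n_out=len(scored))

    (out / "report.json").write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True, default=float)
    )
    return report


def score_evidence_tables(tables) -> pd.DataFrame:
    """Adjudicate every target gene in a set of evidence tables.

    Recomputes each component from the raw tables — region gene counts from
    the annotation, signal location from lead positions, eQTL scores from
    the colocalization posteriors, expression scores from the configured
    cutoffs, and connection counts from peaks, loops and proxies.
    """
    from .ld import Locus

    promoters = tables.annotation[["gene", "chrom", "start", "end"]].copy()
    promoters["end"] = promoters["start"] + 1000
    promoters["start"] = promoters["start"] - 1000

    conn = capture_c_connections(
        tables.proxies, tables.peaks, tables.contacts, promoters
    )
    coloc_by_gene: dict[str, list[ColocPosterior]] = {}
    for r in tables.coloc.itertuples(index=False):
        coloc_by_gene.setdefault(r.gene, []).append(
            ColocPosterior(
                gene=r.gene, tissue=r.tissue, is_testis=(r.tissue == "testis"),
                pp0=r.pp0, pp1=r.pp1, pp2=r.pp2, pp3=r.pp3, pp4=r.pp4,
            )
        )
    expr = tables.fetal_expression.set_index("gene")["value"]

    rows = []
    for r in tables.regions.itertuples(index=False):
        locus = Locus(
            lead=r.signal_id, crvs=pd.DataFrame(), chrom=str(r.chrom),
            region_start=int(r.region_start), region_end=int(r.region_end),
        )
        n_genes, _ = count_region_genes(locus, tables.annotation)
        gene_row = tables.annotation.set_index("gene").loc[r.gene]
        loc_class = classify_signal_location(int(r.lead_pos), gene_row)
        ev = GeneEvidence(
            gene=r.gene,
            n_genes_in_region=n_genes,
            location_class=loc_class,
            posteriors=coloc_by_gene.get(r.gene, []),
            fetal_expression=float(expr.get(r.gene, np.nan))
            if r.gene in expr.index else None,
            connection_count=int(conn.get(r.gene, 0)),
        )
        score = adjudicate_gene(ev, expression_cutoffs=tables.expression_cutoffs)
        rows.append(
            (r.gene, score.s_region, score.s_location, score.s_eqtl,
             score.s_expr, score.s_capc, score.total, score.category,
             ",".join(score.missing))
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "s_region", "s_location", "s_eqtl", "s_expr",
                 "s_capc", "total", "category", "flags"],
    )


def replicate_table1(
    fixture_path: str | Path | None = None,
    lambdas: tuple[float, ...] = (LAMBDA_FATHER, LAMBDA_BROTHER),
) -> dict:
    """Heritability explained by the packaged 22-locus susceptibility table.

    Converts each locus's odds ratio to beta = ln(OR) and sums the per-SNP
    heritability shares at each familial relative risk.  Totals are
    reported both as proportions (3 decimals) and percentages (1 decimal).
    """
    if fixture_path is None:
        loci = pio.load_table1_loci()
    else:
        loci = pd.read_csv(fixture_path, sep="\t", dtype={"chrom": str})
    for col in ("odds_ratio", "a1_freq", "rsid"):
        if col not in loci.columns:
            raise ValueError(f"loci fixture missing column {col!r}")
    out: dict[str, Any] = {"n_loci": int(len(loci)), "per_locus": {}, "totals": {}}
    for lam in lambdas:
        total, skipped = total_heritability(loci, lam)
        out["totals"][f"lambda{lam:g}"] = round(total, 3)
        out["totals"][f"lambda{lam:g}_percent"] = round(100.0 * total, 1)
        out["per_locus"][f"lambda{lam:g}"] = {
            str(r["rsid"]): snp_heritability(
                float(np.log(r["odds_ratio"])), float(r["a1_freq"]), lam
            )
            for _, r in loci.iterrows()
            if not (pd.isna(r["odds_ratio"]) or pd.isna(r["a1_freq"]))
        }
        out["skipped"] = skipped
    return out
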