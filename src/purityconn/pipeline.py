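"""End-to-end orchestration: simulate/read -> signatures -> connectivity ->
purity associations -> HIF stratification -> covariate models -> reports.

Stages communicate only through serialized artifacts in the output
directory, so any stage can be rerun or replaced independently. A manifest
records the seed, thresholds and completed stages. One global seed is
expanded into per-stage substreams keyed by stage name, so a stage's
randomness does not depend on the order in which stages run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import io as pio
from . import models as pmodels
from . import purity as ppurity
from . import signatures as psig
from . import stratify as pstrat
from . import discordant as pdisc
from .synth import DrugScreen, SynthConfig, ScreenConfig, generate_cohort, generate_drug_screen

log = logging.getLogger("purityconn")

STAGES = ("simulate", "signatures", "connectivity", "purity", "stratify", "models", "discordant")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Global run configuration: inputs, thresholds and sizes.

    With no input paths the cohort is simulated from ``synth``. Thresholds
    carry the analysis constants: CPM filter 0.5, signature FDR 1%, >=10
    signature genes per score, significance 0.05, purity split at 80% and
    tertile cutpoints (60, 72).
    """

    synth: SynthConfig = field(default_factory=SynthConfig)
    counts_path: str | None = None
    metadata_path: str | None = None
    ref_drugs: tuple[str, str] = ("HIFI-A", "HIFI-B")
    cpm_threshold: float = 0.5
    fdr_threshold: float = 0.01
    min_genes: int = 10
    alpha: float = 0.05
    purity_split_pct: float = 80.0
    tertile_cutpoints: tuple[float, float] = (60.0, 72.0)
    n_perm: int = 1000
    stability_B: int = 1000
    pvalue_B: int = 10000
    cv_k: int = 10
    cv_repeats: int = 100
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> None:
        if len(self.ref_drugs) != 2:
            raise ValueError("exactly two reference HIF drugs are required")
        if not 0 < self.fdr_threshold < 1 or not 0 < self.alpha < 1:
            raise ValueError("fdr_threshold and alpha must be in (0, 1)")
        if self.cpm_threshold < 0 or self.min_genes < 0:
            raise ValueError("cpm_threshold and min_genes must be non-negative")
        if not 0 <= self.purity_split_pct <= 100:
            raise ValueError("purity_split_pct must be within [0, 100]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_raw = raw.pop("synth", {})
        screen_raw = synth_raw.pop("screen", {}) if isinstance(synth_raw, dict) else {}
        synth = SynthConfig(**synth_raw, screen=ScreenConfig(**screen_raw))
        for key in ("ref_drugs", "tertile_cutpoints"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(synth=synth, **raw)
        cfg.validate()
        return cfg


def _stage_seed(seed: int, stage: str) -> int:
    return (int(seed) * 9176 + zlib.crc32(stage.encode())) % (2**31)


# ---------------------------------------------------------------------------
# Stage implementations (artifact in, artifact out)
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, outdir: Path) -> None:
    synth = dataclasses.replace(config.synth, seed=_stage_seed(config.seed, "simulate"))
    matrix, metadata, truth = generate_cohort(synth)
    screen = generate_drug_screen(synth, truth)
    pio.write_count_matrix(matrix, outdir / "counts.tsv")
    pio.write_metadata(metadata, outdir / "metadata.tsv")
    screen.meta.to_csv(outdir / "screen_meta.tsv", sep="\t", index=False)
    pd.DataFrame(screen.expression, columns=screen.gene_ids).to_csv(
        outdir / "screen_expression.tsv", sep="\t", index=False)
    truth_json = {
        "gene_modules": truth.gene_modules.to_dict(),
        "samples": truth.samples.reset_index().to_dict(orient="records"),
        "drugs": truth.drugs.reset_index().to_dict(orient="records"),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth_json, default=str))


def _load_inputs(config: RunConfig, outdir: Path):
    if config.counts_path:
        matrix = pio.read_count_matrix(config.counts_path)
        metadata = pio.read_metadata(config.metadata_path)
    else:
        matrix = pio.read_count_matrix(outdir / "counts.tsv")
        metadata = pio.read_metadata(outdir / "metadata.tsv")
    return matrix, metadata


def _load_screen(outdir: Path) -> DrugScreen:
    meta = pd.read_csv(outdir / "screen_meta.tsv", sep="\t")
    expr = pd.read_csv(outdir / "screen_expression.tsv", sep="\t")
    return DrugScreen(meta=meta, expression=expr.to_numpy(), gene_ids=list(expr.columns))


def stage_signatures(config: RunConfig, outdir: Path) -> None:
    matrix, metadata = _load_inputs(config, outdir)
    tumour_ids = [m.sample_id for m in metadata if m.role == "tumour" and m.qc_pass]
    normal_ids = [m.sample_id for m in metadata if m.role == "normal"]
    sigs = psig.cohort_signatures(
        matrix, tumour_ids, normal_ids,
        fdr_threshold=config.fdr_threshold, cpm_threshold=config.cpm_threshold)
    write_signatures(sigs, outdir / "signatures.tsv")
    screen = _load_screen(outdir)
    drug_sigs = psig.all_drug_signatures(screen)
    rows = []
    for drug_id, ds in drug_sigs.items():
        for rank, gene in enumerate(ds.ranking, start=1):
            rows.append({"drug_id": drug_id, "gene_id": gene,
                         "t": ds.stats.loc[gene, "t"], "rank": rank})
    pd.DataFrame(rows).to_csv(outdir / "drug_rankings.tsv", sep="\t", index=False)


def write_signatures(sigs: dict[str, psig.TumourSignature], path: Path) -> None:
    rows = []
    for sid, sig in sigs.items():
        rows.extend({"sample_id": sid, "gene_id": g, "direction": "up"} for g in sig.up_genes)
        rows.extend({"sample_id": sid, "gene_id": g, "direction": "down"} for g in sig.down_genes)
    pd.DataFrame(rows, columns=["sample_id", "gene_id", "direction"]).to_csv(
        path, sep="\t", index=False)


def read_signatures(path: Path, sample_ids: list[str]) -> dict[str, psig.TumourSignature]:
    df = pd.read_csv(path, sep="\t")
    sigs = {}
    for sid in sample_ids:
        sub = df[df["sample_id"] == sid]
        sigs[sid] = psig.TumourSignature(
            sample_id=sid,
            up_genes=list(sub.loc[sub["direction"] == "up", "gene_id"]),
            down_genes=list(sub.loc[sub["direction"] == "down", "gene_id"]),
            stats=pd.DataFrame(),
        )
    return sigs


def read_drug_signatures(path: Path) -> dict[str, psig.DrugSignature]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for drug_id, sub in df.groupby("drug_id"):
        sub = sub.sort_values("rank")
        stats = sub.set_index("gene_id")[["t"]].assign(slope=np.nan)
        out[str(drug_id)] = psig.DrugSignature(
            drug_id=str(drug_id), stats=stats, ranking=list(sub["gene_id"]))
    return out


def stage_connectivity(config: RunConfig, outdir: Path) -> None:
    _, metadata = _load_inputs(config, outdir)
    tumour_ids = [m.sample_id for m in metadata if m.role == "tumour" and m.qc_pass]
    sigs = read_signatures(outdir / "signatures.tsv", tumour_ids)
    drug_sigs = read_drug_signatures(outdir / "drug_rankings.tsv")
    results = conn.score_cohort(
        sigs, drug_sigs, min_genes=config.min_genes, n_perm=config.n_perm,
        seed=_stage_seed(config.seed, "connectivity"))
    results.to_csv(outdir / "connectivity.tsv", sep="\t", index=False)


def _purity_series(metadata: list[pio.SampleMetadata]) -> pd.Series:
    return pd.Series(
        {m.sample_id: np.nan if m.purity_pct is None else m.purity_pct
         for m in metadata if m.role == "tumour"}, name="purity_pct")


def stage_purity(config: RunConfig, outdir: Path) -> None:
    matrix, metadata = _load_inputs(config, outdir)
    purity = _purity_series(metadata)
    results = pd.read_csv(outdir / "connectivity.tsv", sep="\t")
    assoc_rows = []
    for drug_id, sub in results.groupby("drug_id"):
        try:
            a = ppurity.correlate_connectivity_purity(sub, purity, config.purity_split_pct)
            assoc_rows.append(vars(a))
        except ppurity.AnalysisError as exc:
            assoc_rows.append({"drug_id": drug_id, "error": str(exc)})
    pd.DataFrame(assoc_rows).to_csv(outdir / "purity_associations.tsv", sep="\t", index=False)

    ppurity.purity_tertile_comparison(results, purity, config.tertile_cutpoints).to_csv(
        outdir / "purity_tertiles.tsv", sep="\t", index=False)

    tumour_ids = [m.sample_id for m in metadata if m.role == "tumour" and m.qc_pass]
    sigs = read_signatures(outdir / "signatures.tsv", tumour_ids)
    cpm = psig.compute_cpm(matrix)
    log_expr = np.log2(cpm[tumour_ids] + 1.0)
    classes = ppurity.classify_signature_genes(sigs, log_expr, purity, alpha=config.alpha)
    pd.DataFrame([vars(c) for c in classes.values()]).to_csv(
        outdir / "gene_purity_classes.tsv", sep="\t", index=False)
    filtered = {sid: ppurity.filter_signature_purity(sig, classes) for sid, sig in sigs.items()}
    write_signatures(filtered, outdir / "signatures_filtered.tsv")


def stage_stratify(config: RunConfig, outdir: Path) -> None:
    _, metadata = _load_inputs(config, outdir)
    purity = _purity_series(metadata)
    results = pd.read_csv(outdir / "connectivity.tsv", sep="\t")
    ref1, ref2 = config.ref_drugs
    labels, excluded = pstrat.stratify_by_hif(results, ref1, ref2)
    lf = pstrat.labels_frame(labels)
    lf.to_csv(outdir / "hif_labels.tsv", sep="\t")
    (outdir / "hif_excluded.json").write_text(json.dumps(sorted(excluded)))
    assoc = pstrat.stratified_purity_association(results, purity, labels)
    rows = []
    for (drug_id, stratum), a in assoc.items():
        row = {"drug_id": drug_id, "stratum": stratum}
        row.update(vars(a) if a is not None else {"spearman_rho": np.nan})
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "stratified_associations.tsv", sep="\t", index=False)
    pstrat.stratified_rate_comparison(results, labels, config.alpha).to_csv(
        outdir / "stratified_rates.tsv", sep="\t", index=False)


_CONN_FIXED = ["purity_pct", "vhl_status", "stage", "mrna_subtype",
               "loss_3p", "gain_5q", "loss_14q", "p53_alterations"]
_CONN_RANDOM = ["batch_id", "plate_id", "ship_date", "tissue_source_site"]
_PURITY_FIXED = ["vhl_status", "stage", "mrna_subtype",
                 "loss_3p", "gain_5q", "loss_14q", "p53_alterations"]
_PURITY_RANDOM = ["batch_id", "tissue_source_site"]


def stage_models(config: RunConfig, outdir: Path) -> None:
    _, metadata = _load_inputs(config, outdir)
    meta_df = pio.metadata_frame(metadata)
    results = pd.read_csv(outdir / "connectivity.tsv", sep="\t")
    ref1, ref2 = config.ref_drugs
    mean_ref = pstrat.mean_reference_score(results, ref1, ref2).dropna()
    seed = _stage_seed(config.seed, "models")
    report = {}
    for outcome_name, outcome, fixed, random in (
        ("mean_ref_connectivity", mean_ref, _CONN_FIXED, _CONN_RANDOM),
        ("purity_pct", meta_df["purity_pct"], _PURITY_FIXED, _PURITY_RANDOM),
    ):
        data = pmodels.model_frame(meta_df, outcome, outcome_name) if \
            outcome_name != "purity_pct" else meta_df[meta_df["role"] == "tumour"].copy()
        fixed = pmodels.usable_terms(data, outcome_name, fixed)
        random = [t for t in random if t in data.columns and data[t].nunique() >= 2]
        screen_tbl = pmodels.univariate_screen(data, outcome_name, fixed)
        full = pmodels.fit_lmm(data, outcome_name, fixed, random)
        reduced = pmodels.backward_eliminate(data, outcome_name, fixed, alpha=config.alpha)
        stability = pmodels.bootstrap_stability(
            data, outcome_name, fixed, B=config.stability_B,
            alpha=config.alpha, seed=seed)
        final_terms = [t for t in fixed if stability.kept.get(t, False)]
        final = pmodels.fit_lmm(data, outcome_name, final_terms) if final_terms \
            else reduced
        boot = pmodels.bootstrap_pvalues(
            data, outcome_name, final.fixed_terms, B=config.pvalue_B, seed=seed + 1) \
            if final.fixed_terms else None
        cv = pmodels.repeated_kfold_cv(
            data, outcome_name, final.fixed_terms, k=config.cv_k,
            repeats=config.cv_repeats, seed=seed + 2) if final.fixed_terms else None
        report[outcome_name] = {
            "univariate_screen": screen_tbl.to_dict(orient="records"),
            "full_model": _fit_json(full),
            "reduced_model": _fit_json(reduced),
            "stability": {
                "frequency": stability.frequency.to_dict(),
                "kept": {k: bool(v) for k, v in stability.kept.items()},
                "n_resamples": stability.n_resamples,
                "n_skipped": stability.n_skipped,
            },
            "final_model": _fit_json(final),
            "bootstrap_p": boot["display"].to_dict() if boot is not None else {},
            "cv": {
                "mean_oof_r2": float(cv.oof_r2.mean()),
                "in_sample_r2": cv.in_sample_r2,
                "repeats": len(cv.oof_r2),
            } if cv is not None else {},
        }
    (outdir / "models.json").write_text(json.dumps(report, indent=2, default=float))


def _fit_json(fit: pmodels.ModelFit) -> dict:
    return {
        "fixed_terms": fit.fixed_terms,
        "random_terms": fit.random_terms,
        "coef": fit.coef.to_dict(),
        "asymptotic_p": fit.asymptotic_p.to_dict(),
        "term_p": fit.term_p.to_dict(),
        "random_var": fit.random_var,
        "r_squared": fit.r_squared,
        "n_used": fit.n_used,
        "converged": fit.converged,
    }


def stage_discordant(config: RunConfig, outdir: Path) -> None:
    (outdir / "discordant_report.json").write_text(json.dumps(pdisc.replication_report(), indent=2))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "signatures": stage_signatures,
    "connectivity": stage_connectivity,
    "purity": stage_purity,
    "stratify": stage_stratify,
    "models": stage_models,
    "discordant": stage_discordant,
}


def run_stage(stage: str, config: RunConfig, outdir: Path) -> float:
    t0 = time.monotonic()
    try:
        _STAGE_FUNCS[stage](config, outdir)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    dt = time.monotonic() - t0
    log.info("stage %s completed in %.1fs", stage, dt)
    return dt


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order and write a manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "thresholds": {
            "cpm": config.cpm_threshold, "fdr": config.fdr_threshold,
            "min_genes": config.min_genes, "alpha": config.alpha,
            "purity_split_pct": config.purity_split_pct,
            "tertile_cutpoints": list(config.tertile_cutpoints),
        },
        "ref_drugs": list(config.ref_drugs),
        "stages": [],
    }
    for stage in stages:
        dt = run_stage(stage, config, outdir)
        manifest["stages"].append({
            "name": stage, "seconds": round(dt, 3),
            "seed": _stage_seed(config.seed, stage),
        })
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
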