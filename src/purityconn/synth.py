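"""Seeded generator of a TCGA-like bulk ccRCC cohort and a LINCS-like
perturbation screen with known ground truth.

The cohort model encodes the biology the analysis is designed to probe:

* each tumour draws arm-level copy-number calls at the frequencies observed
  in the real cohort (3p loss 87.3%, 5q gain 58.7%, 14q loss 41.1%);
* HIF-pathway activation is latent and caused by 3p loss or, when 3p is
  intact, by a VHL mutation/methylation hit; its *strength* varies between
  activated tumours (activation is graded, mirroring "probability of HIF
  activation" rather than a clean on/off state);
* HIF-activated tumours are more vascular and therefore less pure: the mean
  purity deficit scales with activation strength;
* the HIF module has an induced and a repressed half (the pathway both
  up- and down-regulates targets); the stroma expresses the same vascular
  program at a reduced level, so part of the apparent HIF signal in an
  impure bulk sample comes from non-cancerous cells;
* the stromal module likewise has two halves: stroma-enriched genes that
  rise in impure bulk samples and epithelial genes the stroma lacks, which
  fall with admixture;
* measured bulk expression is a purity-weighted mixture of the tumour-cell
  profile (HIF module scaled by activation strength, plus per-sample
  p53-pathway genes shifted in proportion to the alteration count) and a
  stromal profile (stromal module elevated); normals are stroma-free
  baseline tissue;
* counts are negative binomial with shared dispersion and per-sample
  library sizes.

The drug screen programs each drug's per-gene concentration slope on its
target module — a reversal drug down-regulates the module's induced genes
and up-regulates its repressed genes — plus cell-line, duration and batch
nuisance structure and Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleMetadata


class ConfigError(ValueError):
    """Degenerate or inconsistent generator configuration."""


@dataclass
class ScreenConfig:
    """Perturbation-screen shape and effect sizes."""

    n_drugs: int = 4
    cell_lines: int = 3
    concentrations: tuple[float, ...] = (0.5, 1.0, 2.0)
    durations: tuple[str, ...] = ("6h", "24h")
    batches: int = 2
    reversal_strength: float = 1.0
    noise_sd: float = 0.3


@dataclass
class SynthConfig:
    """Cohort generator configuration.

    Defaults mirror the real study's conditions where those are known: the
    cohort size (538 tumours vs 72 normals), the arm-level alteration
    frequencies (3p loss 87.3%, 5q gain 58.7%, 14q loss 41.1%) and a purity
    distribution centred in the low 70s with a floor of 30%.

    ``purity_hif_shift_pct`` is the purity deficit at full activation
    strength; with strengths drawn from ``hif_strength_range`` the average
    deficit of activated versus non-activated tumours is about -10 points,
    bracketed by the fitted 3p-loss purity coefficient (-4.2, conditional
    on mRNA subtype, whose m3 level alone carries -12.5) and the 17-point
    median purity gap of the discordant high-purity samples.
    """

    n_genes: int = 2000
    n_tumour: int = 538
    n_normal: int = 72
    module_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"hif": 100, "stromal": 70, "p53": 400}
    )
    p_loss3p: float = 0.873
    p_gain5q: float = 0.587
    p_loss14q: float = 0.411
    p_vhl_hit_given_3p_intact: float = 0.4
    hif_effect_log2fc: float = 2.0
    hif_strength_range: tuple[float, float] = (0.4, 1.0)
    stroma_hif_log2fc: float = 1.4
    stromal_effect_log2fc: float = 3.0
    p53_effect_log2fc: float = 2.0
    purity_base_pct: float = 72.0
    purity_hif_shift_pct: float = -15.0
    purity_sd_pct: float = 10.0
    p53_rate: float = 2.5
    p53_per_alteration_de_genes: int = 15
    nb_dispersion: float = 0.1
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_loss3p", "p_gain5q", "p_loss14q", "p_vhl_hit_given_3p_intact"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} is not a probability")
        sizes = dict(self.module_sizes)
        if set(sizes) - {"hif", "stromal", "p53"}:
            raise ConfigError(f"unknown module names in {sorted(sizes)}")
        if any(s < 0 for s in sizes.values()):
            raise ConfigError("module sizes must be non-negative")
        if sum(sizes.values()) > self.n_genes:
            raise ConfigError(
                f"module sizes {sizes} overlap: sum exceeds n_genes={self.n_genes}"
            )
        if self.n_tumour < 2 or self.n_normal < 3:
            raise ConfigError("need at least 2 tumours and 3 normals")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        lo, hi = self.hif_strength_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ConfigError("hif_strength_range must satisfy 0 <= lo <= hi <= 1")
        if len(self.screen.concentrations) < 2:
            raise ConfigError("screen needs at least 2 concentrations per drug")


def desk_config(n_tumour: int = 300, n_normal: int = 40, seed: int = 0) -> SynthConfig:
    """A reduced-size configuration (1,200 genes) with the same module
    geometry and effect sizes as the defaults, used for worked examples and
    simulation studies where the full cohort would be unnecessarily slow."""
    return SynthConfig(
        n_genes=1200, n_tumour=n_tumour, n_normal=n_normal,
        module_sizes={"hif": 60, "stromal": 40, "p53": 240}, seed=seed,
    )


@dataclass
class GroundTruth:
    """Simulation truth record aligned with the emitted artifacts."""

    gene_modules: pd.Series        # gene_id -> {hif, stromal, p53, null}
    gene_sign: pd.Series           # module gene -> +1 (induced/up) or -1 (repressed)
    baseline_log2: pd.Series       # gene_id -> baseline log2 tissue mean
    samples: pd.DataFrame          # tumour sample_id -> hif_active, hif_strength, ...
    p53_genes: dict[str, list[str]]  # tumour sample_id -> shifted p53 genes
    drugs: pd.DataFrame            # drug_id -> target_module, effect (signed slope)


@dataclass
class DrugScreen:
    """Perturbation-screen profiles: covariates plus an expression matrix
    (profiles x genes, log2-like scale)."""

    meta: pd.DataFrame             # profile_id, drug_id, concentration, cell_line, duration, batch
    expression: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if self.expression.shape != (len(self.meta), len(self.gene_ids)):
            raise ConfigError("screen expression shape does not match meta/genes")
        per_drug = self.meta.groupby("drug_id")["concentration"].nunique()
        if (per_drug < 2).any():
            bad = per_drug[per_drug < 2].index.tolist()
            raise ConfigError(f"drugs with <2 concentrations: {bad}")
        if self.meta["cell_line"].nunique() < 2:
            raise ConfigError("screen needs at least 2 cell lines overall")


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(stream,))
    )


def _assign_modules(config: SynthConfig) -> tuple[pd.Series, list[str]]:
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    labels = np.array(["null"] * config.n_genes, dtype=object)
    start = 0
    for name in ("hif", "stromal", "p53"):
        size = dict(config.module_sizes).get(name, 0)
        labels[start:start + size] = name
        start += size
    return pd.Series(labels, index=gene_ids, name="module"), gene_ids


def _gene_signs(modules: pd.Series) -> pd.Series:
    """Within-module direction, alternating +1/-1 halves per module.

    hif: induced (+1) versus repressed (-1) pathway targets. stromal:
    stroma-enriched genes (+1, e.g. endothelial/immune markers) versus
    epithelial genes the stroma lacks (-1), so admixture moves the two
    halves of the bulk profile in opposite directions. p53: gained positive
    versus deleted negative regulators.
    """
    sign = pd.Series(0, index=modules.index, dtype=int)
    for name in ("hif", "p53", "stromal"):
        idx = modules.index[modules == name]
        sign[idx] = [1 if i % 2 == 0 else -1 for i in range(len(idx))]
    return sign


def _profiles(
    config: SynthConfig, modules: pd.Series, sign: pd.Series, baseline: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    """(stromal profile, hif-module shift direction vector), linear-ready."""
    base = baseline.to_numpy()
    mod = modules.to_numpy()
    s = sign.to_numpy().astype(float)
    stroma = base.copy()
    stroma[mod == "stromal"] += config.stromal_effect_log2fc * s[mod == "stromal"]
    stroma[mod == "hif"] += config.stroma_hif_log2fc * s[mod == "hif"]
    hif_shift = np.where(mod == "hif", config.hif_effect_log2fc * s, 0.0)
    return stroma, hif_shift


def expected_bulk_mean(
    config: SynthConfig,
    truth: GroundTruth,
    hif_strength: float,
    purity_pct: float,
    p53_genes: tuple[str, ...] = (),
) -> pd.Series:
    """Linear-scale expected bulk expression for a hypothetical tumour.

    Exposes the generator's mixture mean so the mixture identity (stromal
    genes decrease and tumour-only genes increase with purity) can be
    checked without Monte Carlo.
    """
    stroma, hif_shift = _profiles(config, truth.gene_modules, truth.gene_sign,
                                  truth.baseline_log2)
    tumour = truth.baseline_log2.to_numpy() + hif_strength * hif_shift
    tumour = pd.Series(tumour, index=truth.baseline_log2.index)
    for g in p53_genes:
        tumour[g] += config.p53_effect_log2fc * truth.gene_sign[g]
    w = purity_pct / 100.0
    return w * 2.0 ** tumour + (1.0 - w) * 2.0 ** pd.Series(
        stroma, index=truth.baseline_log2.index)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # var = mu + dispersion * mu^2  (gamma-Poisson mixture)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def generate_cohort(
    config: SynthConfig,
) -> tuple[CountMatrix, list[SampleMetadata], GroundTruth]:
    """Generate counts, metadata and ground truth for one cohort."""
    config.validate()
    rng = _rng(config, 0)
    modules, gene_ids = _assign_modules(config)
    sign = _gene_signs(modules)
    baseline = pd.Series(rng.uniform(3.0, 9.0, config.n_genes), index=gene_ids)
    stroma, hif_shift = _profiles(config, modules, sign, baseline)
    base = baseline.to_numpy()
    p53_idx = np.flatnonzero((modules == "p53").to_numpy())
    p53_sign_arr = sign.to_numpy()[p53_idx].astype(float)

    tumour_ids = [f"T{i:04d}" for i in range(config.n_tumour)]
    normal_ids = [f"N{i:04d}" for i in range(config.n_normal)]

    # --- sample-level covariates -------------------------------------------
    loss_3p = rng.random(config.n_tumour) < config.p_loss3p
    vhl_hit = np.where(
        loss_3p, False, rng.random(config.n_tumour) < config.p_vhl_hit_given_3p_intact
    )
    hif_active = loss_3p | vhl_hit
    s_lo, s_hi = config.hif_strength_range
    hif_strength = np.where(
        hif_active, rng.uniform(s_lo, s_hi, config.n_tumour), 0.0
    )
    purity = np.clip(
        config.purity_base_pct
        + config.purity_hif_shift_pct * hif_strength
        + rng.normal(0.0, config.purity_sd_pct, config.n_tumour),
        30.0, 100.0,
    )
    gain_5q = rng.random(config.n_tumour) < config.p_gain5q
    loss_14q = rng.random(config.n_tumour) < config.p_loss14q
    p53_counts = np.minimum(rng.poisson(config.p53_rate, config.n_tumour), 15)

    # VHL status label: a hit manifests as methylation or mutation; samples
    # without mutation/methylation data get the explicit missing category
    # (kept in the models, Table-1 style).
    vhl_label = np.where(
        vhl_hit | (loss_3p & (rng.random(config.n_tumour) < 0.3)),
        rng.choice(
            ["methylation", "moderate_mutation", "high_mutation"], config.n_tumour
        ),
        "none",
    ).astype(object)
    vhl_label[rng.random(config.n_tumour) < 0.376] = "missing"
    stage = rng.choice(
        ["I", "II", "III", "IV"], config.n_tumour,
        p=[0.497 / 0.994, 0.109 / 0.994, 0.236 / 0.994, 0.152 / 0.994],
    ).astype(object)
    stage[rng.random(config.n_tumour) < 0.006] = "missing"
    subtype = rng.choice(
        ["m1", "m2", "m3", "m4", "missing"], config.n_tumour,
        p=[0.274, 0.169, 0.179, 0.163, 0.215],
    ).astype(object)
    copy_number_missing = rng.random(config.n_tumour) < 0.015
    batch_id = rng.choice([f"batch{i:02d}" for i in range(15)], config.n_tumour)
    plate_id = rng.choice([f"plate{i:02d}" for i in range(18)], config.n_tumour)
    ship_date = rng.choice([f"2011-{m:02d}-01" for m in range(1, 13)], config.n_tumour)
    tss = rng.choice([f"TSS{i:02d}" for i in range(20)], config.n_tumour)

    # --- expression --------------------------------------------------------
    counts = np.zeros((config.n_genes, config.n_tumour + config.n_normal), dtype=np.int64)
    lib_lo, lib_hi = config.library_size_range
    sample_p53_genes: dict[str, list[str]] = {}
    k = config.p53_per_alteration_de_genes
    stroma_lin = 2.0 ** stroma
    for i, sid in enumerate(tumour_ids):
        tum = base + hif_strength[i] * hif_shift
        n_shift = min(int(p53_counts[i]) * k, len(p53_idx))
        if n_shift:
            chosen = rng.choice(len(p53_idx), n_shift, replace=False)
            tum = tum.copy()
            tum[p53_idx[chosen]] += config.p53_effect_log2fc * p53_sign_arr[chosen]
            sample_p53_genes[sid] = [gene_ids[j] for j in p53_idx[chosen]]
        else:
            sample_p53_genes[sid] = []
        w = purity[i] / 100.0
        mean = w * 2.0 ** tum + (1.0 - w) * stroma_lin
        lib = rng.integers(lib_lo, lib_hi + 1)
        counts[:, i] = _nb_counts(rng, lib * mean / mean.sum(), config.nb_dispersion)
    normal_mean = 2.0 ** base
    for j in range(config.n_normal):
        lib = rng.integers(lib_lo, lib_hi + 1)
        mu = lib * normal_mean / normal_mean.sum()
        counts[:, config.n_tumour + j] = _nb_counts(rng, mu, config.nb_dispersion)

    matrix = CountMatrix(gene_ids, tumour_ids + normal_ids, counts)

    metadata = []
    for i, sid in enumerate(tumour_ids):
        cn_missing = bool(copy_number_missing[i])
        metadata.append(SampleMetadata(
            sample_id=sid, role="tumour", purity_pct=float(purity[i]), qc_pass=True,
            vhl_status=str(vhl_label[i]), stage=str(stage[i]),
            mrna_subtype=str(subtype[i]),
            loss_3p="missing" if cn_missing else ("yes" if loss_3p[i] else "no"),
            gain_5q="missing" if cn_missing else ("yes" if gain_5q[i] else "no"),
            loss_14q="missing" if cn_missing else ("yes" if loss_14q[i] else "no"),
            p53_alterations=None if cn_missing else int(p53_counts[i]),
            batch_id=str(batch_id[i]), plate_id=str(plate_id[i]),
            ship_date=str(ship_date[i]), tissue_source_site=str(tss[i]),
        ))
    for sid in normal_ids:
        metadata.append(SampleMetadata(sample_id=sid, role="normal"))

    samples = pd.DataFrame({
        "hif_active": hif_active, "hif_strength": hif_strength,
        "purity_pct": purity,
        "loss_3p": loss_3p, "vhl_hit": vhl_hit.astype(bool),
        "gain_5q": gain_5q, "loss_14q": loss_14q,
        "p53_alterations": p53_counts,
    }, index=pd.Index(tumour_ids, name="sample_id"))

    truth = GroundTruth(
        gene_modules=modules, gene_sign=sign, baseline_log2=baseline,
        samples=samples, p53_genes=sample_p53_genes, drugs=_drug_table(config),
    )
    return matrix, metadata, truth


def _drug_table(config: SynthConfig) -> pd.DataFrame:
    """Drug roster: two HIF-reversing reference drugs, one stromal-reversing
    drug, and nulls for the remainder."""
    strength = config.screen.reversal_strength
    rows = [
        ("HIFI-A", "hif", -strength),
        ("HIFI-B", "hif", -strength),
        ("STROMA-R", "stromal", -strength),
        ("NULL-1", "null", 0.0),
    ]
    for extra in range(4, config.screen.n_drugs):
        rows.append((f"NULL-{extra - 2}", "null", 0.0))
    rows = rows[: max(config.screen.n_drugs, 3)]
    return pd.DataFrame(rows, columns=["drug_id", "target_module", "effect"]).set_index("drug_id")


def generate_drug_screen(config: SynthConfig, truth: GroundTruth) -> DrugScreen:
    """Generate the perturbation screen implied by the drug roster.

    Per gene, expression is baseline + cell-line intercept + duration and
    batch offsets + concentration x programmed slope + Gaussian noise. A
    reversal drug's slope is its signed effect times the module gene's
    direction (it pushes induced genes down and repressed genes up); other
    genes have slope zero. Batches are assigned at random so that omitting
    the batch term from a downstream model produces a realized-design-
    dependent bias rather than none.
    """
    config.validate()
    rng = _rng(config, 1)
    sc = config.screen
    gene_ids = list(truth.baseline_log2.index)
    n_genes = len(gene_ids)
    baseline = truth.baseline_log2.to_numpy()
    mod = truth.gene_modules.to_numpy()
    sign = truth.gene_sign.to_numpy().astype(float)
    cell_lines = [f"CL{i}" for i in range(sc.cell_lines)]
    batches = [f"b{i}" for i in range(sc.batches)]
    cl_intercepts = rng.normal(0.0, 0.2, (sc.cell_lines, n_genes))
    dur_offsets = rng.normal(0.0, 0.1, (len(sc.durations), n_genes))
    batch_offsets = rng.normal(0.0, 0.3, (sc.batches, n_genes))

    rows = []
    exprs = []
    pid = 0
    for drug_id, drug in truth.drugs.iterrows():
        slope = np.where(mod == drug["target_module"], drug["effect"] * sign, 0.0)
        for ic, cl in enumerate(cell_lines):
            for conc in sc.concentrations:
                for idur, dur in enumerate(sc.durations):
                    ib = int(rng.integers(0, sc.batches))
                    expr = (
                        baseline
                        + cl_intercepts[ic]
                        + dur_offsets[idur]
                        + batch_offsets[ib]
                        + conc * slope
                        + rng.normal(0.0, sc.noise_sd, n_genes)
                    )
                    rows.append({
                        "profile_id": f"P{pid:05d}", "drug_id": drug_id,
                        "concentration": conc, "cell_line": cl,
                        "duration": dur, "batch": batches[ib],
                    })
                    exprs.append(expr)
                    pid += 1
    meta = pd.DataFrame(rows)
    return DrugScreen(meta=meta, expression=np.vstack(exprs), gene_ids=gene_ids)
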