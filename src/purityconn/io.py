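"""Tabular I/O for the pipeline: count matrices, sample metadata and the
packaged discordant-methylation reference table.

All text formats are tab-separated UTF-8 with '.' as the decimal separator
and an empty cell denoting a missing value, so that read -> write -> read is
an identity. Count matrices are also supported as MatrixMarket (.mtx) with
plain-text gene/sample id sidecar files.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import io as io_module
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class VocabularyError(FormatError):
    """A categorical value is outside the controlled vocabulary."""


class RangeError(FormatError):
    """A numeric value is outside its permitted range."""


class IntegrityError(RuntimeError):
    """Packaged fixture does not match its recorded checksum."""


# Controlled vocabularies (Table-1 style categories; "missing" is an
# explicit category for the variables that keep missing samples).
VHL_STATUS = ("none", "methylation", "moderate_mutation", "high_mutation", "missing")
STAGES = ("I", "II", "III", "IV", "missing")
MRNA_SUBTYPES = ("m1", "m2", "m3", "m4", "missing")
ARM_CALLS = ("yes", "no", "missing")
ROLES = ("tumour", "normal")
METHYLATION_CLUSTERS = ("papillary", "chromophobe")
REEVAL_CATEGORIES = ("ccRCC", "unconventional-ccRCC", "non-ccRCC")

_DISCORDANT_SHA256 = "a2de6729e8714a845cd74d8810da8d95a3369ee80e7a903684ee70fe2d5958c3"


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Non-negative integer read counts, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        n_genes, n_samples = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.sample_ids) != n_samples:
            raise FormatError("id lists do not match the matrix shape")
        if n_genes < 1 or n_samples < 2:
            raise FormatError("need at least 1 gene and 2 samples")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise FormatError(f"duplicate {name} id: {dup!r}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_count_matrix(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a genes x samples count matrix from TSV or MatrixMarket.

    The TSV dialect has a header row of sample ids and the gene id in the
    first column. MatrixMarket input expects ``<stem>.rows.txt`` and
    ``<stem>.cols.txt`` sidecars listing gene and sample ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
        if df.index.name is None and df.shape[1] == 0:
            raise FormatError(f"{path}: malformed header")
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric entry ({exc})") from exc
        if np.isnan(values).any():
            row = df.index[np.argwhere(np.isnan(values))[0][0]]
            raise FormatError(f"{path}: non-numeric or empty entry in row {row!r}")
        return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)
    if format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = _read_id_sidecar(path.with_suffix("").with_suffix(".rows.txt"))
        samples = _read_id_sidecar(path.with_suffix("").with_suffix(".cols.txt"))
        return CountMatrix(genes, samples, np.asarray(mat))
    raise ValueError(f"unknown format {format!r}")


def _read_id_sidecar(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing id sidecar {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def write_count_matrix(matrix: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        matrix.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix.counts))
        base = path.with_suffix("")
        base.with_suffix(".rows.txt").write_text("\n".join(matrix.gene_ids) + "\n")
        base.with_suffix(".cols.txt").write_text("\n".join(matrix.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    """Per-sample purity, genomic and clinical covariates, batch labels.

    ``vhl_status`` and ``mrna_subtype`` keep missingness as an explicit
    category; for ``stage``, the arm calls and ``p53_alterations`` a missing
    value marks the sample for complete-case exclusion from the covariate
    models (:attr:`excluded_from_models`).
    """

    sample_id: str
    role: str = "tumour"
    purity_pct: float | None = None
    qc_pass: bool = True
    vhl_status: str = "missing"
    stage: str = "missing"
    mrna_subtype: str = "missing"
    loss_3p: str = "missing"
    gain_5q: str = "missing"
    loss_14q: str = "missing"
    p53_alterations: int | None = None
    batch_id: str = ""
    plate_id: str = ""
    ship_date: str = ""
    tissue_source_site: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise VocabularyError(f"unknown role {self.role!r}")
        if self.purity_pct is not None:
            # fractions are accepted on input and converted to percent
            if 0.0 <= self.purity_pct <= 1.0:
                self.purity_pct = self.purity_pct * 100.0
            if not 0.0 <= self.purity_pct <= 100.0:
                raise RangeError(
                    f"sample {self.sample_id!r}: purity {self.purity_pct} outside [0, 100]"
                )
        for attr, vocab in (
            ("vhl_status", VHL_STATUS),
            ("stage", STAGES),
            ("mrna_subtype", MRNA_SUBTYPES),
            ("loss_3p", ARM_CALLS),
            ("gain_5q", ARM_CALLS),
            ("loss_14q", ARM_CALLS),
        ):
            value = getattr(self, attr)
            if value not in vocab:
                raise VocabularyError(
                    f"sample {self.sample_id!r}: {attr} value {value!r} not in {vocab}"
                )
        if self.p53_alterations is not None and not 0 <= self.p53_alterations <= 15:
            raise RangeError(
                f"sample {self.sample_id!r}: p53_alterations {self.p53_alterations} "
                "outside [0, 15]"
            )

    @property
    def excluded_from_models(self) -> bool:
        """True when a complete-case variable is missing (tumour samples)."""
        if self.role != "tumour":
            return True
        return (
            self.stage == "missing"
            or "missing" in (self.loss_3p, self.gain_5q, self.loss_14q)
            or self.p53_alterations is None
            or self.purity_pct is None
        )


_META_COLUMNS = [
    "sample_id", "role", "purity_pct", "qc_pass", "vhl_status", "stage",
    "mrna_subtype", "loss_3p", "gain_5q", "loss_14q", "p53_alterations",
    "batch_id", "plate_id", "ship_date", "tissue_source_site",
]


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read one :class:`SampleMetadata` per TSV row.

    Empty cells map to the explicit ``missing`` category (vhl_status,
    mrna_subtype, stage, arm calls) or to ``None`` (purity, p53 count).
    Unknown category strings are rejected.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing 'sample_id' column")
    out = []
    for _, row in df.iterrows():
        def get(col: str, default: str = "") -> str:
            return row[col].strip() if col in row else default

        purity = get("purity_pct")
        p53 = get("p53_alterations")
        out.append(
            SampleMetadata(
                sample_id=get("sample_id"),
                role=get("role") or "tumour",
                purity_pct=float(purity) if purity else None,
                qc_pass=(get("qc_pass") or "true").lower() in ("true", "1", "yes"),
                vhl_status=get("vhl_status") or "missing",
                stage=get("stage") or "missing",
                mrna_subtype=get("mrna_subtype") or "missing",
                loss_3p=get("loss_3p") or "missing",
                gain_5q=get("gain_5q") or "missing",
                loss_14q=get("loss_14q") or "missing",
                p53_alterations=int(p53) if p53 else None,
                batch_id=get("batch_id"),
                plate_id=get("plate_id"),
                ship_date=get("ship_date"),
                tissue_source_site=get("tissue_source_site"),
            )
        )
    return out


def write_metadata(metadata: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = []
    for m in metadata:
        row = {c: getattr(m, c) for c in _META_COLUMNS}
        row["purity_pct"] = "" if m.purity_pct is None else repr(float(m.purity_pct))
        row["p53_alterations"] = "" if m.p53_alterations is None else m.p53_alterations
        row["qc_pass"] = "true" if m.qc_pass else "false"
        for cat in ("vhl_status", "stage", "mrna_subtype", "loss_3p", "gain_5q", "loss_14q"):
            if row[cat] == "missing":
                row[cat] = ""
        rows.append(row)
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(Path(path), sep="\t", index=False)


def metadata_frame(metadata: Iterable[SampleMetadata]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by sample id (missing -> NaN for the
    complete-case variables, kept as the 'missing' category otherwise)."""
    rows = []
    for m in metadata:
        rows.append({
            "sample_id": m.sample_id,
            "role": m.role,
            "purity_pct": np.nan if m.purity_pct is None else m.purity_pct,
            "qc_pass": m.qc_pass,
            "vhl_status": m.vhl_status,
            "stage": np.nan if m.stage == "missing" else m.stage,
            "mrna_subtype": m.mrna_subtype,
            "loss_3p": np.nan if m.loss_3p == "missing" else m.loss_3p,
            "gain_5q": np.nan if m.gain_5q == "missing" else m.gain_5q,
            "loss_14q": np.nan if m.loss_14q == "missing" else m.loss_14q,
            "p53_alterations": np.nan if m.p53_alterations is None else m.p53_alterations,
            "batch_id": m.batch_id,
            "plate_id": m.plate_id,
            "ship_date": m.ship_date,
            "tissue_source_site": m.tissue_source_site,
        })
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Metadata normalisation rules
# ---------------------------------------------------------------------------

def call_vhl_methylation(beta: float) -> bool:
    """Call VHL methylated when the cg15267345 beta value strictly exceeds 0.2."""
    if not 0.0 <= beta <= 1.0:
        raise RangeError(f"beta value {beta} outside [0, 1]")
    return beta > 0.2


def average_duplicates(
    values: Iterable[tuple[str, float]],
) -> list[tuple[str, float]]:
    """Collapse duplicate sample measurements to their arithmetic mean.

    Order of first appearance is preserved. Intended for numeric variables
    only; categorical duplicates that disagree must be resolved upstream.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    order: list[str] = []
    for prefix, value in values:
        if prefix not in sums:
            sums[prefix] = 0.0
            counts[prefix] = 0
            order.append(prefix)
        sums[prefix] += float(value)
        counts[prefix] += 1
    return [(p, sums[p] / counts[p]) for p in order]


def resolve_categorical_duplicates(
    values: Iterable[tuple[str, str]],
) -> list[tuple[str, str]]:
    """Collapse duplicate categorical measurements; disagreement is an error."""
    seen: dict[str, str] = {}
    order: list[str] = []
    for prefix, value in values:
        if prefix in seen:
            if seen[prefix] != value:
                raise FormatError(
                    f"conflicting duplicate values for {prefix!r}: "
                    f"{seen[prefix]!r} vs {value!r}"
                )
        else:
            seen[prefix] = value
            order.append(prefix)
    return [(p, seen[p]) for p in order]


# ---------------------------------------------------------------------------
# Packaged discordant-methylation reference table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscordantSampleRecord:
    """One discordant-methylation ccRCC sample: cluster assignment,
    histopathological re-evaluation, purity and mean reference-inhibitor
    connectivity score."""

    sample_prefix: str
    methylation_cluster: str
    reeval: str
    purity_pct: float
    mean_conn_px12_cay: float
    vhl_status: str
    mrna_subtype: str
    loss_3p: str


def load_discordant_samples() -> list[DiscordantSampleRecord]:
    """Load the packaged 24-sample discordant-methylation table.

    The file's SHA-256 is checked against the value recorded at packaging
    time; a mismatch raises :class:`IntegrityError`.
    """
    resource = importlib.resources.files("purityconn").joinpath("data/discordant_samples.tsv")
    raw = resource.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _DISCORDANT_SHA256:
        raise IntegrityError(
            f"discordant-sample table checksum mismatch: {digest} != {_DISCORDANT_SHA256}"
        )
    df = pd.read_csv(io_module.StringIO(raw.decode("utf-8")), sep="\t")
    records = []
    for _, row in df.iterrows():
        rec = DiscordantSampleRecord(
            sample_prefix=str(row["sample_prefix"]),
            methylation_cluster=str(row["methylation_cluster"]),
            reeval=str(row["reeval"]),
            purity_pct=float(row["purity_pct"]),
            mean_conn_px12_cay=float(row["mean_conn_px12_cay"]),
            vhl_status=str(row["vhl_status"]),
            mrna_subtype=str(row["mrna_subtype"]),
            loss_3p=str(row["loss_3p"]),
        )
        if rec.methylation_cluster not in METHYLATION_CLUSTERS:
            raise VocabularyError(f"bad methylation cluster {rec.methylation_cluster!r}")
        if rec.reeval not in REEVAL_CATEGORIES:
            raise VocabularyError(f"bad re-evaluation category {rec.reeval!r}")
        if rec.vhl_status not in VHL_STATUS:
            raise VocabularyError(f"bad VHL status {rec.vhl_status!r}")
        if rec.mrna_subtype not in MRNA_SUBTYPES:
            raise VocabularyError(f"bad mRNA subtype {rec.mrna_subtype!r}")
        if rec.loss_3p not in ARM_CALLS:
            raise VocabularyError(f"bad 3p call {rec.loss_3p!r}")
        records.append(rec)
    if len(records) != 24:
        raise IntegrityError(f"expected 24 records, found {len(records)}")
    return records
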