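"""Tumour-sample and drug signatures.

A tumour signature is the set of genes differentially expressed in one
tumour sample relative to the pooled normal-tissue reference: genes are
kept when their mean CPM in the normal pool is at least 0.5, tested with a
z-statistic on log2(CPM + 1) against the normal pool (SD floored at 0.1 and
inflated by sqrt(1 + 1/n_normal) for the single observation), and admitted
at Benjamini-Hochberg FDR strictly below 1%.

A drug signature is the full ranking of the gene universe by the
t-statistic of the concentration slope in an ordinary least squares fit of
screen expression on concentration with cell line, exposure duration and
batch as categorical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix
from .synth import DrugScreen

SD_FLOOR = 0.1


class SignatureError(ValueError):
    pass


@dataclass
class TumourSignature:
    """Up/down differentially expressed gene sets for one tumour sample."""

    sample_id: str
    up_genes: list[str]
    down_genes: list[str]
    stats: pd.DataFrame  # index gene_id: log2fc, z, p, fdr (kept genes only)

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise SignatureError("up and down sets overlap")

    @property
    def size(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


@dataclass
class DrugSignature:
    """Per-gene concentration-slope t-statistics and the induced ranking."""

    drug_id: str
    stats: pd.DataFrame   # index gene_id: slope, t
    ranking: list[str]    # all universe genes, descending t (top = most up)

    def __post_init__(self) -> None:
        if sorted(self.ranking) != sorted(self.stats.index):
            raise SignatureError("ranking is not a permutation of the universe")


def compute_cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million, genes x samples."""
    totals = counts.counts.sum(axis=0)
    if (totals == 0).any():
        bad = [counts.sample_ids[i] for i in np.flatnonzero(totals == 0)]
        raise SignatureError(f"zero library size for samples {bad}")
    cpm = counts.counts * 1e6 / totals
    return pd.DataFrame(cpm, index=counts.gene_ids, columns=counts.sample_ids)


def filter_low_expression(
    cpm: pd.DataFrame,
    reference_samples: list[str],
    threshold: float = 0.5,
) -> list[str]:
    """Genes whose mean CPM over the reference pool is >= threshold."""
    if not reference_samples:
        raise SignatureError("reference sample set is empty")
    missing = [s for s in reference_samples if s not in cpm.columns]
    if missing:
        raise SignatureError(f"unknown reference samples {missing}")
    means = cpm[list(reference_samples)].mean(axis=1)
    return list(means.index[means >= threshold])


def tumour_signature(
    sample_id: str,
    counts: CountMatrix,
    normal_ids: list[str],
    fdr_threshold: float = 0.01,
    cpm_threshold: float = 0.5,
) -> TumourSignature:
    """Differential expression of one tumour sample versus the normal pool."""
    cpm = compute_cpm(counts)
    return tumour_signature_from_cpm(
        sample_id, cpm, normal_ids, fdr_threshold=fdr_threshold,
        cpm_threshold=cpm_threshold,
    )


def tumour_signature_from_cpm(
    sample_id: str,
    cpm: pd.DataFrame,
    normal_ids: list[str],
    fdr_threshold: float = 0.01,
    cpm_threshold: float = 0.5,
) -> TumourSignature:
    """As :func:`tumour_signature` but on a precomputed CPM matrix, so one
    CPM computation can serve a whole cohort."""
    normal_ids = list(normal_ids)
    if len(normal_ids) < 3:
        raise SignatureError("need at least 3 normal reference samples")
    if sample_id in normal_ids:
        raise SignatureError(f"sample {sample_id!r} is part of the normal pool")
    if sample_id not in cpm.columns:
        raise SignatureError(f"unknown sample {sample_id!r}")
    kept = filter_low_expression(cpm, normal_ids, cpm_threshold)
    log_norm = np.log2(cpm.loc[kept, normal_ids] + 1.0)
    mu = log_norm.mean(axis=1)
    sd = log_norm.std(axis=1, ddof=1).clip(lower=SD_FLOOR)
    x = np.log2(cpm.loc[kept, sample_id] + 1.0)
    z = (x - mu) / (sd * np.sqrt(1.0 + 1.0 / len(normal_ids)))
    p = 2.0 * stats.norm.sf(np.abs(z))
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame({"log2fc": x - mu, "z": z, "p": p, "fdr": fdr}, index=kept)
    sig = table[table["fdr"] < fdr_threshold]
    return TumourSignature(
        sample_id=sample_id,
        up_genes=list(sig.index[sig["z"] > 0]),
        down_genes=list(sig.index[sig["z"] < 0]),
        stats=table,
    )


def cohort_signatures(
    counts: CountMatrix,
    tumour_ids: list[str],
    normal_ids: list[str],
    fdr_threshold: float = 0.01,
    cpm_threshold: float = 0.5,
) -> dict[str, TumourSignature]:
    """Per-sample signatures for every listed tumour sample."""
    cpm = compute_cpm(counts)
    return {
        sid: tumour_signature_from_cpm(
            sid, cpm, normal_ids, fdr_threshold=fdr_threshold,
            cpm_threshold=cpm_threshold,
        )
        for sid in tumour_ids
    }


def drug_signature(screen: DrugScreen, drug_id: str) -> DrugSignature:
    """OLS concentration-slope t-statistics for one drug, all genes at once.

    The design is concentration (linear) plus dummy-coded cell line,
    duration and batch; nuisance factors with a single observed level are
    dropped. A rank-deficient design raises an error naming the aliased
    term.
    """
    meta = screen.meta[screen.meta["drug_id"] == drug_id]
    if meta.empty:
        raise SignatureError(f"drug {drug_id!r} absent from screen")
    if meta["concentration"].nunique() < 2:
        raise SignatureError(f"drug {drug_id!r} has fewer than 2 concentrations")
    y = screen.expression[meta.index.to_numpy()]

    columns = [np.ones(len(meta)), meta["concentration"].to_numpy(dtype=float)]
    names = ["intercept", "concentration"]
    for term in ("cell_line", "duration", "batch"):
        levels = sorted(meta[term].unique())
        for level in levels[1:]:  # first level is the reference
            columns.append((meta[term] == level).to_numpy(dtype=float))
            names.append(f"{term}[{level}]")
    X = np.column_stack(columns)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        aliased = names[int(np.argmin(np.abs(np.diag(r))))]
        raise SignatureError(f"rank-deficient screen design: term {aliased!r} is aliased")

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(meta) - X.shape[1]
    if df <= 0:
        raise SignatureError("no residual degrees of freedom in screen design")
    sigma2 = (resid ** 2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    c = xtx_inv[1, 1]
    slope = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / np.sqrt(sigma2 * c)
    t = np.where(np.isfinite(t), t, 0.0)

    table = pd.DataFrame({"slope": slope, "t": t}, index=screen.gene_ids)
    # descending t; ties broken by gene id for determinism
    idx = np.lexsort((np.asarray(table.index), -table["t"].to_numpy()))
    return DrugSignature(
        drug_id=drug_id, stats=table, ranking=[table.index[i] for i in idx]
    )


def all_drug_signatures(screen: DrugScreen) -> dict[str, DrugSignature]:
    return {d: drug_signature(screen, d) for d in screen.meta["drug_id"].unique()}
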