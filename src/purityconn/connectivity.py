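"""Bidirectional Kolmogorov-Smirnov connectivity scoring.

A tumour signature's up and down gene sets are located in a drug-induced
gene ranking (most up-regulated by the drug first). Each set gets the
classic unweighted running-sum enrichment statistic; the connectivity score
is (ES_up - ES_down) / 2, set to exactly zero when both enrichment scores
are nonzero with the same sign (the drug moves both halves of the signature
the same way, which is neither mimicry nor reversal). A negative score
means the drug is expected to (partially) reverse the tumour signature.

Scores are undefined when fewer than ``min_genes`` signature genes are
present in the drug universe. Significance comes from a permutation null:
random disjoint up/down sets of the same sizes drawn from the universe.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signatures import DrugSignature, TumourSignature


class ConnectivityError(ValueError):
    pass


@dataclass
class ConnectivityResult:
    sample_id: str
    drug_id: str
    score: float | None
    perm_p: float | None
    n_up: int
    n_down: int
    n_perm: int = 0

    @property
    def defined(self) -> bool:
        return self.score is not None


def _ks_stat(positions_1based: np.ndarray, n_total: int) -> float:
    """Signed KS running-sum extremum for one gene set.

    ``positions_1based`` must be the sorted 1-based ranks of the set genes.
    With j = 1..n, the statistic is a = max(j/n - V_j/N) against
    b = max(V_j/N - (j-1)/n); returns a when a >= b else -b.
    """
    v = np.asarray(positions_1based, dtype=float)
    n = v.size
    j = np.arange(1, n + 1, dtype=float)
    a = np.max(j / n - v / n_total)
    b = np.max(v / n_total - (j - 1) / n)
    return float(a) if a >= b else float(-b)


def _ks_batch(positions: np.ndarray, n_total: int) -> np.ndarray:
    """Row-wise :func:`_ks_stat` for a (B, n) matrix of sorted 1-based ranks."""
    v = np.asarray(positions, dtype=float)
    n = v.shape[1]
    j = np.arange(1, n + 1, dtype=float)
    a = np.max(j / n - v / n_total, axis=1)
    b = np.max(v / n_total - (j - 1) / n, axis=1)
    return np.where(a >= b, a, -b)


def ks_enrichment(ranking: list[str], gene_set) -> float:
    """Bidirectional KS enrichment of ``gene_set`` within ``ranking``."""
    gene_set = list(gene_set)
    if not 1 <= len(gene_set) <= len(ranking):
        raise ConnectivityError(
            f"gene set size {len(gene_set)} invalid for ranking of {len(ranking)}"
        )
    pos = {g: i for i, g in enumerate(ranking)}
    try:
        v = np.sort([pos[g] + 1 for g in gene_set])
    except KeyError as exc:
        raise ConnectivityError(f"gene {exc.args[0]!r} absent from ranking") from exc
    if len(set(gene_set)) != len(gene_set):
        raise ConnectivityError("gene set contains duplicates")
    return _ks_stat(v, len(ranking))


def _combine(es_up: float, es_down: float) -> float:
    if es_up * es_down > 0:  # both nonzero, same sign
        return 0.0
    return (es_up - es_down) / 2.0


def connectivity_score(
    signature: TumourSignature,
    drug: DrugSignature,
    min_genes: int = 10,
) -> ConnectivityResult:
    """Score one tumour signature against one drug ranking."""
    universe = set(drug.ranking)
    up = [g for g in signature.up_genes if g in universe]
    down = [g for g in signature.down_genes if g in universe]
    n_up, n_down = len(up), len(down)
    if n_up + n_down < min_genes:
        return ConnectivityResult(signature.sample_id, drug.drug_id, None, None, n_up, n_down)
    es_up = ks_enrichment(drug.ranking, up) if up else 0.0
    es_down = ks_enrichment(drug.ranking, down) if down else 0.0
    return ConnectivityResult(
        signature.sample_id, drug.drug_id, _combine(es_up, es_down), None, n_up, n_down
    )


def permutation_pvalue(
    sizes: tuple[int, int],
    drug: DrugSignature,
    observed: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p for an observed score: random disjoint up/down sets of
    the given sizes, p = (1 + #{|s_perm| >= |observed|}) / (n_perm + 1)."""
    if observed is None:
        raise ConnectivityError("observed score is undefined")
    n_up, n_down = sizes
    n_total = len(drug.ranking)
    if n_up + n_down > n_total:
        raise ConnectivityError("set sizes exceed the drug universe")
    perm_scores = _permutation_scores(n_up, n_down, n_total, n_perm, seed)
    exceed = int(np.sum(np.abs(perm_scores) >= abs(observed)))
    return (1 + exceed) / (n_perm + 1)


def _permutation_scores(
    n_up: int, n_down: int, n_total: int, n_perm: int, seed: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    # each row of ranks is a random draw of n_up + n_down distinct 1-based ranks
    ranks = np.argsort(rng.random((n_perm, n_total)), axis=1)[:, : n_up + n_down] + 1
    es_up = _ks_batch(np.sort(ranks[:, :n_up], axis=1), n_total) if n_up else np.zeros(n_perm)
    es_down = (
        _ks_batch(np.sort(ranks[:, n_up:], axis=1), n_total) if n_down else np.zeros(n_perm)
    )
    same_sign = es_up * es_down > 0
    return np.where(same_sign, 0.0, (es_up - es_down) / 2.0)


def _subseed(seed: int, sample_id: str, drug_id: str) -> int:
    return (int(seed) * 1_000_003 + zlib.crc32(f"{sample_id}|{drug_id}".encode())) % (2**31)


def score_cohort(
    signatures: dict[str, TumourSignature],
    drugs: dict[str, DrugSignature],
    min_genes: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
    compute_p: bool = True,
) -> pd.DataFrame:
    """Score every (sample, drug) pair; one row each, NaN when undefined."""
    rows = []
    for drug_id, drug in drugs.items():
        for sample_id, sig in signatures.items():
            res = connectivity_score(sig, drug, min_genes=min_genes)
            perm_p = np.nan
            if res.defined and compute_p:
                perm_p = permutation_pvalue(
                    (res.n_up, res.n_down), drug, res.score,
                    n_perm=n_perm, seed=_subseed(seed, sample_id, drug_id),
                )
            rows.append({
                "sample_id": sample_id, "drug_id": drug_id,
                "score": np.nan if res.score is None else res.score,
                "perm_p": perm_p, "n_up": res.n_up, "n_down": res.n_down,
                "n_perm": n_perm if (res.defined and compute_p) else 0,
            })
    return pd.DataFrame(rows)
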