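"""Tumour-purity confounding analyses.

Associates per-drug connectivity scores with estimated tumour purity
(Spearman, Pearson-regression and a high/low purity split), classifies
signature genes by purity sensitivity, filters signatures, and computes and
compares negative-enrichment rates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import TumourSignature

PURITY_SPLIT_PCT = 80.0
TERTILE_CUTPOINTS = (60.0, 72.0)


class AnalysisError(ValueError):
    pass


@dataclass
class PurityAssociation:
    drug_id: str
    spearman_rho: float | None
    spearman_p: float | None
    pearson_p: float | None
    wilcoxon_split_p: float | None
    n: int


@dataclass
class PurityGeneClass:
    gene_id: str
    direction: str           # up | down
    label: str               # more_de | less_de | insensitive
    rho: float
    p: float


# ---------------------------------------------------------------------------
# Rank statistics helpers
# ---------------------------------------------------------------------------

def spearman_test(x, y) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Uses the tie-corrected t-approximation for n >= 10 and exact enumeration
    of all rank permutations below that, so toy examples are reproducible to
    full precision.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise AnalysisError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    if n >= 10:
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    perms = np.array(list(itertools.permutations(ry)))
    rho_null = _pearson_rows(rx, perms)
    p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    return rho, p


def _pearson_rows(x: np.ndarray, rows: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    rc = rows - rows.mean(axis=1, keepdims=True)
    num = rc @ xc
    den = np.sqrt((xc ** 2).sum() * (rc ** 2).sum(axis=1))
    return num / den


def wilcoxon_ranksum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p, tie-corrected normal approximation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise AnalysisError("empty group in rank-sum test")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0  # every observation tied: no evidence either way
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             use_continuity=False, method="asymptotic")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def correlate_connectivity_purity(
    results: pd.DataFrame,
    purity: pd.Series,
    split_pct: float = PURITY_SPLIT_PCT,
) -> PurityAssociation:
    """Associate one drug's connectivity scores with estimated purity.

    ``results`` holds one drug's rows (sample_id, score); undefined scores
    are dropped. The high-purity group in the split test is strictly above
    ``split_pct``; ties at the boundary go to the low group.
    """
    drug_ids = results["drug_id"].unique() if "drug_id" in results else ["?"]
    if len(drug_ids) != 1:
        raise AnalysisError(f"expected one drug, got {list(drug_ids)}")
    df = results.dropna(subset=["score"]).set_index("sample_id")
    df = df.join(purity.rename("purity_pct"), how="inner").dropna(subset=["purity_pct"])
    n = len(df)
    if n < 3:
        raise AnalysisError(f"fewer than 3 scored samples with purity (n={n})")
    rho, sp = spearman_test(df["purity_pct"], df["score"])
    if np.isnan(rho):
        rho = sp = None
        pearson_p = None
    else:
        _, pearson_p = stats.pearsonr(df["purity_pct"], df["score"])
        pearson_p = float(pearson_p)
    high = df.loc[df["purity_pct"] > split_pct, "score"]
    low = df.loc[df["purity_pct"] <= split_pct, "score"]
    wilcoxon_p = wilcoxon_ranksum(high, low) if len(high) and len(low) else None
    return PurityAssociation(
        drug_id=str(drug_ids[0]), spearman_rho=rho, spearman_p=sp,
        pearson_p=pearson_p, wilcoxon_split_p=wilcoxon_p, n=n,
    )


def classify_gene_purity_sensitivity(
    expr: pd.Series,
    purity: pd.Series,
    direction: str,
    alpha: float = 0.05,
) -> PurityGeneClass:
    """Classify a signature gene by how its expression tracks purity.

    An up-regulated gene whose expression rises with purity (or a
    down-regulated gene whose expression falls with purity) is *more*
    differentially expressed in purer samples (`more_de`); a significant
    correlation of the opposite sign makes it `less_de`; otherwise the gene
    is purity-`insensitive`.
    """
    if direction not in ("up", "down"):
        raise AnalysisError(f"direction must be 'up' or 'down', got {direction!r}")
    aligned = pd.concat([expr.rename("expr"), purity.rename("purity")], axis=1).dropna()
    rho, p = spearman_test(aligned["purity"], aligned["expr"])
    if np.isnan(rho) or p >= alpha:
        label = "insensitive"
    else:
        expected_sign = 1.0 if direction == "up" else -1.0
        label = "more_de" if rho * expected_sign > 0 else "less_de"
    return PurityGeneClass(
        gene_id=str(expr.name), direction=direction, label=label,
        rho=float(rho) if not np.isnan(rho) else np.nan, p=p,
    )


def classify_signature_genes(
    signatures: dict[str, TumourSignature],
    log_expr: pd.DataFrame,
    purity: pd.Series,
    alpha: float = 0.05,
) -> dict[tuple[str, str], PurityGeneClass]:
    """Classify every (gene, direction) pair appearing in any signature.

    ``log_expr`` is log2(CPM + 1), genes x tumour samples; the correlation
    runs over the tumour samples with known purity. A gene may appear as
    'up' in some samples and 'down' in others; each direction is classified
    once.
    """
    pairs = set()
    for sig in signatures.values():
        pairs.update((g, "up") for g in sig.up_genes)
        pairs.update((g, "down") for g in sig.down_genes)
    samples = [s for s in log_expr.columns if s in purity.index and not np.isnan(purity[s])]
    out = {}
    for gene, direction in sorted(pairs):
        out[(gene, direction)] = classify_gene_purity_sensitivity(
            log_expr.loc[gene, samples], purity[samples], direction, alpha=alpha
        )
    return out


def filter_signature_purity(
    signature: TumourSignature,
    classes: dict[tuple[str, str], PurityGeneClass],
) -> TumourSignature:
    """Drop genes that become less differentially expressed with purity."""
    def keep(gene: str, direction: str) -> bool:
        key = (gene, direction)
        if key not in classes:
            raise AnalysisError(f"no purity class for signature gene {key}")
        return classes[key].label != "less_de"

    return replace(
        signature,
        up_genes=[g for g in signature.up_genes if keep(g, "up")],
        down_genes=[g for g in signature.down_genes if keep(g, "down")],
    )


def negative_enrichment_rate(results: pd.DataFrame, alpha: float = 0.05) -> float:
    """Fraction of scored samples that significantly reverse the signature
    (score < 0 and permutation p < alpha); undefined scores are excluded."""
    df = results.dropna(subset=["score"])
    if df.empty:
        raise AnalysisError("no defined connectivity results")
    neg_sig = (df["score"] < 0) & (df["perm_p"] < alpha)
    return float(neg_sig.mean())


def negative_enrichment_counts(results: pd.DataFrame, alpha: float = 0.05) -> tuple[int, int]:
    """(negative-and-significant, other) counts over defined scores."""
    df = results.dropna(subset=["score"])
    neg_sig = int(((df["score"] < 0) & (df["perm_p"] < alpha)).sum())
    return neg_sig, len(df) - neg_sig


def compare_rates_chisq(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 count table."""
    table = np.array([counts_a, counts_b], dtype=float)
    if (table < 0).any():
        raise AnalysisError("negative counts")
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        raise AnalysisError("chi-square undefined: zero margin")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def purity_tertile(purity_pct: float, cutpoints: tuple[float, float] = TERTILE_CUTPOINTS) -> str:
    """Assign a purity value to its cohort tertile (low < c1 <= mid <= c2 < high)."""
    lo, hi = cutpoints
    if purity_pct < lo:
        return "low"
    if purity_pct > hi:
        return "high"
    return "mid"


def purity_tertile_comparison(
    results: pd.DataFrame,
    purity: pd.Series,
    cutpoints: tuple[float, float] = TERTILE_CUTPOINTS,
) -> pd.DataFrame:
    """Rank-sum comparison of connectivity scores between adjacent purity
    tertiles, per drug."""
    df = results.dropna(subset=["score"]).copy()
    df["purity_pct"] = df["sample_id"].map(purity)
    df = df.dropna(subset=["purity_pct"])
    df["tertile"] = [purity_tertile(p, cutpoints) for p in df["purity_pct"]]
    rows = []
    for drug_id, sub in df.groupby("drug_id"):
        groups = {t: sub.loc[sub["tertile"] == t, "score"].to_numpy()
                  for t in ("low", "mid", "high")}
        for a, b in (("low", "mid"), ("mid", "high")):
            if groups[a].size == 0 or groups[b].size == 0:
                raise AnalysisError(f"empty {a if groups[a].size == 0 else b} tertile "
                                    f"for drug {drug_id!r}")
            rows.append({
                "drug_id": drug_id, "comparison": f"{a}_vs_{b}",
                "n_a": groups[a].size, "n_b": groups[b].size,
                "p": wilcoxon_ranksum(groups[a], groups[b]),
            })
    return pd.DataFrame(rows)
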