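"""Statistics over the packaged discordant-methylation sample table.

These recompute, from the packaged 24-record fixture, the headline
comparisons for ccRCC samples whose methylomes clustered with papillary or
chromophobe RCC: how many sit above 80% estimated purity, how many retain
chromosome 3p, and whether the samples still regarded as (unconventional)
ccRCC on histopathological re-evaluation score lower with the reference
HIF inhibitors than those re-classified as non-ccRCC.
"""

from __future__ import annotations

import numpy as np

from .io import DiscordantSampleRecord, load_discordant_samples
from .purity import AnalysisError, wilcoxon_ranksum


def count_high_purity(records: list[DiscordantSampleRecord], threshold_pct: float = 80.0) -> int:
    """Number of records with estimated purity strictly above the threshold."""
    return sum(1 for r in records if r.purity_pct > threshold_pct)


def fraction_no_3p_loss(records: list[DiscordantSampleRecord]) -> tuple[int, int]:
    """(count with no 3p loss, count with a non-missing 3p call)."""
    calls = [r.loss_3p for r in records if r.loss_3p != "missing"]
    return sum(1 for c in calls if c == "no"), len(calls)


def reeval_group_comparison(records: list[DiscordantSampleRecord]) -> tuple[int, int, float]:
    """Compare mean reference-inhibitor scores between re-evaluation groups.

    Group A: still ccRCC or unconventional ccRCC on re-evaluation; group B:
    non-ccRCC. Returns (n_A, n_B, two-sided rank-sum p).
    """
    a = [r.mean_conn_px12_cay for r in records if r.reeval in ("ccRCC", "unconventional-ccRCC")]
    b = [r.mean_conn_px12_cay for r in records if r.reeval == "non-ccRCC"]
    if not a or not b:
        raise AnalysisError("empty re-evaluation group")
    return len(a), len(b), wilcoxon_ranksum(a, b)


def replication_report() -> dict:
    """All three fixture statistics as a JSON-ready dict."""
    records = load_discordant_samples()
    n_no, n_called = fraction_no_3p_loss(records)
    n_a, n_b, p = reeval_group_comparison(records)
    scores_a = [r.mean_conn_px12_cay for r in records
                if r.reeval in ("ccRCC", "unconventional-ccRCC")]
    scores_b = [r.mean_conn_px12_cay for r in records if r.reeval == "non-ccRCC"]
    return {
        "n_records": len(records),
        "n_purity_above_80": count_high_purity(records),
        "n_no_3p_loss": n_no,
        "n_3p_called": n_called,
        "reeval_n_ccrcc_like": n_a,
        "reeval_n_non_ccrcc": n_b,
        "reeval_median_ccrcc_like": float(np.median(scores_a)),
        "reeval_median_non_ccrcc": float(np.median(scores_b)),
        "reeval_wilcoxon_p": p,
    }
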