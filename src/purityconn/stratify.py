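"""Stratification of samples by probability of HIF-pathway activation.

A sample is deemed *more likely* HIF-activated when it produces a strictly
negative connectivity score with both reference HIF inhibitors, and *less
likely* otherwise (zero scores count as "otherwise"). The purity
associations and negative-enrichment comparisons are then rerun within each
stratum; in the confounded cohort the purity trend should vanish within the
more-likely stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .purity import (
    AnalysisError,
    PurityAssociation,
    compare_rates_chisq,
    correlate_connectivity_purity,
    negative_enrichment_counts,
    negative_enrichment_rate,
)

MORE_LIKELY = "more_likely"
LESS_LIKELY = "less_likely"


@dataclass
class StratumLabel:
    sample_id: str
    label: str
    score_ref1: float
    score_ref2: float


def _ref_scores(results: pd.DataFrame, ref_drug: str) -> pd.Series:
    sub = results[results["drug_id"] == ref_drug]
    if sub.empty:
        raise AnalysisError(f"reference drug {ref_drug!r} absent from results")
    return sub.set_index("sample_id")["score"]


def stratify_by_hif(
    results: pd.DataFrame,
    ref_drug_1: str,
    ref_drug_2: str,
) -> tuple[list[StratumLabel], list[str]]:
    """Label every sample scored with both reference drugs.

    Returns (labels, excluded) where ``excluded`` lists samples whose score
    with either reference drug is undefined.
    """
    s1 = _ref_scores(results, ref_drug_1)
    s2 = _ref_scores(results, ref_drug_2)
    samples = sorted(set(s1.index) | set(s2.index))
    labels, excluded = [], []
    for sid in samples:
        v1 = s1.get(sid, np.nan)
        v2 = s2.get(sid, np.nan)
        if np.isnan(v1) or np.isnan(v2):
            excluded.append(sid)
            continue
        label = MORE_LIKELY if (v1 < 0 and v2 < 0) else LESS_LIKELY
        labels.append(StratumLabel(sid, label, float(v1), float(v2)))
    return labels, excluded


def labels_frame(labels: list[StratumLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": l.sample_id, "label": l.label,
          "score_ref1": l.score_ref1, "score_ref2": l.score_ref2} for l in labels]
    ).set_index("sample_id")


def mean_reference_score(
    results: pd.DataFrame, ref_drug_1: str, ref_drug_2: str
) -> pd.Series:
    """Arithmetic mean of the two reference-drug scores per sample (the
    HIF-activation proxy used as a model outcome)."""
    s1 = _ref_scores(results, ref_drug_1)
    s2 = _ref_scores(results, ref_drug_2)
    return ((s1 + s2) / 2.0).rename("mean_ref_connectivity")


def stratified_purity_association(
    results: pd.DataFrame,
    purity: pd.Series,
    labels: list[StratumLabel],
) -> dict[tuple[str, str], PurityAssociation | None]:
    """Per-(drug, stratum) purity association; degenerate strata give None."""
    lf = labels_frame(labels)
    out: dict[tuple[str, str], PurityAssociation | None] = {}
    for drug_id, sub in results.groupby("drug_id"):
        for stratum in (MORE_LIKELY, LESS_LIKELY):
            members = lf.index[lf["label"] == stratum]
            rows = sub[sub["sample_id"].isin(members)]
            try:
                out[(str(drug_id), stratum)] = correlate_connectivity_purity(rows, purity)
            except AnalysisError:
                out[(str(drug_id), stratum)] = None
    return out


def stratified_rate_comparison(
    results: pd.DataFrame,
    labels: list[StratumLabel],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Negative-enrichment rate per stratum plus a chi-square on the raw
    counts, one row per drug."""
    lf = labels_frame(labels)
    more = lf.index[lf["label"] == MORE_LIKELY]
    less = lf.index[lf["label"] == LESS_LIKELY]
    if len(more) == 0 or len(less) == 0:
        raise AnalysisError("empty stratum")
    rows = []
    for drug_id, sub in results.groupby("drug_id"):
        sub_more = sub[sub["sample_id"].isin(more)]
        sub_less = sub[sub["sample_id"].isin(less)]
        rate_more = negative_enrichment_rate(sub_more, alpha)
        rate_less = negative_enrichment_rate(sub_less, alpha)
        counts_more = negative_enrichment_counts(sub_more, alpha)
        counts_less = negative_enrichment_counts(sub_less, alpha)
        try:
            chi2, p = compare_rates_chisq(counts_more, counts_less)
        except AnalysisError:
            chi2, p = np.nan, np.nan
        rows.append({
            "drug_id": drug_id, "rate_more": rate_more, "rate_less": rate_less,
            "chisq": chi2, "chisq_p": p,
            "n_more": sum(counts_more), "n_less": sum(counts_less),
        })
    return pd.DataFrame(rows)
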