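"""Covariate models for HIF activation and estimated tumour purity.

The HIF-activation proxy (mean reference-inhibitor connectivity score) and
estimated purity are modelled on genomic/clinical covariates with linear
mixed models: sequencing batch variables enter as random intercepts, the
covariates of interest as fixed effects. Model reduction is backward
elimination at P < 0.05 with multi-level categorical terms tested jointly;
selection stability and coefficient significance are assessed by resampling
the cohort with replacement, and generalisation by repeated k-fold
cross-validation.

Estimated tumour purity is never allowed as a predictor of itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .purity import spearman_test, wilcoxon_ranksum


class ModelError(ValueError):
    pass


# Preferred reference levels for dummy coding (most frequent / baseline
# category of the cohort).
_REFERENCE_LEVELS = {
    "vhl_status": "none",
    "stage": "I",
    "mrna_subtype": "m1",
    "loss_3p": "no",
    "gain_5q": "no",
    "loss_14q": "no",
}

P53_GROUP_BOUNDS = ((0, 0), (1, 3), (4, 15))


@dataclass
class ModelFit:
    outcome: str
    fixed_terms: list[str]
    random_terms: list[str]
    coef: pd.Series
    se: pd.Series
    asymptotic_p: pd.Series
    term_p: pd.Series
    random_var: dict[str, float]
    r_squared: float
    n_used: int
    converged: bool = True
    bootstrap_p: pd.Series | None = None


@dataclass
class StabilityReport:
    frequency: pd.Series          # per fixed term, selection frequency
    kept: pd.Series               # frequency >= 0.5
    n_resamples: int
    n_skipped: int                # degenerate resamples


@dataclass
class CVReport:
    oof_r2: np.ndarray            # per repeat, pooled out-of-fold R^2
    in_sample_r2: float
    n_degenerate_folds: int


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _is_categorical(series: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(series)


@dataclass
class _Design:
    y: np.ndarray
    X: np.ndarray
    names: list[str]
    term_cols: dict[str, list[int]]
    index: pd.Index


def build_design(data: pd.DataFrame, outcome: str, fixed_terms: list[str]) -> _Design:
    """Complete-case design matrix with intercept; categorical terms are
    dummy-coded against a fixed reference level."""
    cols = [outcome] + list(fixed_terms)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ModelError(f"variables absent from data: {missing}")
    df = data[cols].dropna()
    if df.empty:
        raise ModelError("no complete-case rows")
    y = df[outcome].to_numpy(dtype=float)
    names = ["intercept"]
    columns = [np.ones(len(df))]
    term_cols: dict[str, list[int]] = {}
    for term in fixed_terms:
        s = df[term]
        idx = []
        if _is_categorical(s):
            levels = sorted(s.astype(str).unique())
            ref = _REFERENCE_LEVELS.get(term)
            if ref in levels:
                levels = [ref] + [l for l in levels if l != ref]
            if len(levels) < 2:
                raise ModelError(f"term {term!r} has a single level")
            for level in levels[1:]:
                idx.append(len(names))
                names.append(f"{term}[{level}]")
                columns.append((s.astype(str) == level).to_numpy(dtype=float))
        else:
            idx.append(len(names))
            names.append(term)
            columns.append(s.to_numpy(dtype=float))
        term_cols[term] = idx
    return _Design(y=y, X=np.column_stack(columns), names=names,
                   term_cols=term_cols, index=df.index)


def usable_terms(data: pd.DataFrame, outcome: str, terms: list[str]) -> list[str]:
    """Terms with at least two observed values in the complete-case rows
    (degenerate single-level variables cannot enter a model)."""
    df = data[[outcome] + [t for t in terms if t in data.columns]].dropna()
    out = []
    for t in terms:
        if t in df.columns and df[t].astype(str).nunique() >= 2:
            out.append(t)
    return out


def model_frame(metadata: pd.DataFrame, outcome: pd.Series, outcome_name: str) -> pd.DataFrame:
    """Join an outcome onto tumour metadata.

    Rows failing QC or missing a complete-case variable (stage, arm calls,
    p53 count, purity) drop out later via :func:`build_design`; the
    vhl_status / mrna_subtype 'missing' category is retained as a level.
    """
    df = metadata[metadata["role"] == "tumour"].copy() if "role" in metadata else metadata.copy()
    if "qc_pass" in df:
        df = df[df["qc_pass"]]
    df[outcome_name] = outcome.reindex(df.index)
    return df.dropna(subset=[outcome_name])


# ---------------------------------------------------------------------------
# Fast OLS helpers (used standalone and inside the bootstrap loops)
# ---------------------------------------------------------------------------

def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _term_f_pvalues(
    y: np.ndarray, X: np.ndarray, term_cols: dict[str, list[int]]
) -> pd.Series:
    n, k = X.shape
    df_resid = n - k
    if df_resid <= 0:
        raise ModelError("no residual degrees of freedom")
    _, rss_full = _ols(y, X)
    out = {}
    for term, cols in term_cols.items():
        keep = [i for i in range(k) if i not in cols]
        _, rss_red = _ols(y, X[:, keep])
        q = len(cols)
        if rss_full <= 0:
            out[term] = 0.0
            continue
        f = (rss_red - rss_full) / q / (rss_full / df_resid)
        out[term] = float(stats.f.sf(max(f, 0.0), q, df_resid))
    return pd.Series(out)


def _eliminate_arrays(
    y: np.ndarray, X: np.ndarray, term_cols: dict[str, list[int]], alpha: float
) -> list[str]:
    """Backward elimination on a fixed design; returns retained terms."""
    cols = {t: list(c) for t, c in term_cols.items()}
    while cols:
        active = [0] + sorted(i for c in cols.values() for i in c)
        remap = {orig: j for j, orig in enumerate(active)}
        sub_cols = {t: [remap[i] for i in c] for t, c in cols.items()}
        pvals = _term_f_pvalues(y, X[:, active], sub_cols)
        worst = pvals.idxmax()
        if pvals[worst] < alpha:
            break
        del cols[worst]
    return list(cols)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _check_outcome_contract(outcome: str, fixed_terms: list[str]) -> None:
    if outcome in fixed_terms:
        raise ModelError(f"{outcome!r} cannot be used to predict itself")


def fit_lmm(
    data: pd.DataFrame,
    outcome: str,
    fixed_terms: list[str],
    random_terms: list[str] | None = None,
) -> ModelFit:
    """Fit a linear mixed model (or OLS when no random terms are given).

    Random terms become independent random intercepts (variance components)
    per batch variable. Fixed-effect p-values use the t distribution with
    residual degrees of freedom n - k_fixed; term-level p-values are joint
    F-type tests. R^2 is computed on the fixed-effects fitted values.
    """
    random_terms = list(random_terms or [])
    fixed_terms = list(fixed_terms)
    _check_outcome_contract(outcome, fixed_terms)
    design = build_design(data, outcome, fixed_terms)
    y, X = design.y, design.X
    n, k = X.shape
    df_resid = n - k
    if df_resid <= 0:
        raise ModelError("more parameters than observations")

    if not random_terms:
        beta, rss = _ols(y, X)
        tss = float(((y - y.mean()) ** 2).sum())
        sigma2 = rss / df_resid
        cov = sigma2 * np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
        term_p = _term_f_pvalues(y, X, design.term_cols)
        return ModelFit(
            outcome=outcome, fixed_terms=fixed_terms, random_terms=[],
            coef=pd.Series(beta, index=design.names),
            se=pd.Series(se, index=design.names),
            asymptotic_p=pd.Series(pvals, index=design.names),
            term_p=term_p, random_var={},
            r_squared=1.0 - rss / tss if tss > 0 else 0.0,
            n_used=n, converged=True,
        )

    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import VCSpec

    sub = data.loc[design.index]
    vc_names, vc_colnames, vc_mats = [], [], []
    for term in random_terms:
        if term not in sub.columns:
            raise ModelError(f"random term {term!r} absent from data")
        dummies = pd.get_dummies(sub[term].astype(str), dtype=float)
        vc_names.append(term)
        vc_colnames.append([list(dummies.columns)])
        vc_mats.append([dummies.to_numpy()])
    groups = np.zeros(n, dtype=int)  # one group: crossed random intercepts
    model = sm.MixedLM(
        y, X, groups=groups,
        exog_vc=VCSpec(vc_names, vc_colnames, vc_mats),
        exog_re=None,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True)
            converged = bool(res.converged)
        except np.linalg.LinAlgError:
            converged = False
            res = model.fit(method="powell")
    beta = np.asarray(res.fe_params)
    cov_fe = np.asarray(res.cov_params())[:k, :k]
    se = np.sqrt(np.diag(cov_fe))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    term_p = {}
    for term, cols in design.term_cols.items():
        b = beta[cols]
        C = cov_fe[np.ix_(cols, cols)]
        q = len(cols)
        try:
            w = float(b @ np.linalg.solve(C, b))
        except np.linalg.LinAlgError:
            w = 0.0
        term_p[term] = float(stats.f.sf(w / q, q, df_resid))
    fitted = X @ beta
    rss = float(((y - fitted) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return ModelFit(
        outcome=outcome, fixed_terms=fixed_terms, random_terms=random_terms,
        coef=pd.Series(beta, index=design.names),
        se=pd.Series(se, index=design.names),
        asymptotic_p=pd.Series(pvals, index=design.names),
        term_p=pd.Series(term_p),
        random_var={t: float(v) for t, v in zip(random_terms, np.asarray(res.vcomp))},
        r_squared=max(0.0, 1.0 - rss / tss) if tss > 0 else 0.0,
        n_used=n, converged=converged,
    )


def backward_eliminate(
    data: pd.DataFrame,
    outcome: str,
    fixed_terms: list[str],
    random_terms: list[str] | None = None,
    alpha: float = 0.05,
) -> ModelFit:
    """Drop the fixed term with the largest joint P >= alpha, refit, repeat.

    Random terms are never dropped. If every fixed term is eliminated the
    intercept-only model is returned.
    """
    random_terms = list(random_terms or [])
    terms = list(fixed_terms)
    _check_outcome_contract(outcome, terms)
    if not random_terms:
        design = build_design(data, outcome, terms)
        kept = _eliminate_arrays(design.y, design.X, design.term_cols, alpha)
        return fit_lmm(data, outcome, kept, random_terms=[]) if kept else _intercept_fit(
            data, outcome)
    while terms:
        fit = fit_lmm(data, outcome, terms, random_terms)
        worst = fit.term_p.idxmax()
        if fit.term_p[worst] < alpha:
            return fit
        terms = [t for t in terms if t != worst]
    return _intercept_fit(data, outcome, random_terms)


def _intercept_fit(
    data: pd.DataFrame, outcome: str, random_terms: list[str] | None = None
) -> ModelFit:
    y = data[outcome].dropna().to_numpy(dtype=float)
    return ModelFit(
        outcome=outcome, fixed_terms=[], random_terms=list(random_terms or []),
        coef=pd.Series({"intercept": float(y.mean())}),
        se=pd.Series({"intercept": float(y.std(ddof=1) / np.sqrt(len(y)))}),
        asymptotic_p=pd.Series({"intercept": np.nan}),
        term_p=pd.Series(dtype=float), random_var={},
        r_squared=0.0, n_used=len(y),
    )


# ---------------------------------------------------------------------------
# Univariate screen
# ---------------------------------------------------------------------------

def univariate_screen(
    data: pd.DataFrame,
    outcome: str,
    variables: list[str],
) -> pd.DataFrame:
    """Nonparametric per-variable association screen with Bonferroni
    adjustment: rank-sum for binary factors, Kruskal-Wallis for multi-level
    factors, Spearman for continuous variables."""
    rows = []
    for var in variables:
        sub = data[[outcome, var]].dropna()
        if sub.empty:
            rows.append({"variable": var, "test": "skipped", "raw_p": np.nan, "n": 0,
                         "note": "no complete cases"})
            continue
        y = sub[outcome].to_numpy(dtype=float)
        s = sub[var]
        if _is_categorical(s):
            groups = [y[(s == level).to_numpy()] for level in sorted(s.astype(str).unique())]
            if len(groups) < 2:
                rows.append({"variable": var, "test": "skipped", "raw_p": np.nan,
                             "n": len(sub), "note": "single level"})
                continue
            if len(groups) == 2:
                p = wilcoxon_ranksum(groups[0], groups[1])
                test = "wilcoxon"
            else:
                _, p = stats.kruskal(*groups)
                test = "kruskal"
        else:
            _, p = spearman_test(s.to_numpy(dtype=float), y)
            test = "spearman"
        rows.append({"variable": var, "test": test, "raw_p": float(p), "n": len(sub),
                     "note": ""})
    df = pd.DataFrame(rows)
    m = int((df["test"] != "skipped").sum())
    df["bonferroni_p"] = np.minimum(df["raw_p"] * m, 1.0)
    return df


# ---------------------------------------------------------------------------
# Bootstrap selection stability and P values
# ---------------------------------------------------------------------------

def _degenerate(X: np.ndarray, term_cols: dict[str, list[int]]) -> bool:
    cols = [i for c in term_cols.values() for i in c]
    return any(np.ptp(X[:, i]) == 0 for i in cols)


def bootstrap_stability(
    data: pd.DataFrame,
    outcome: str,
    fixed_terms: list[str],
    random_terms: list[str] | None = None,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> StabilityReport:
    """Backward elimination repeated on B row-resamples with replacement;
    a term is kept when retained in at least half of the resamples.

    Resamples in which a categorical level disappears (degenerate design)
    are skipped and counted.
    """
    _check_outcome_contract(outcome, list(fixed_terms))
    design = build_design(data, outcome, list(fixed_terms))
    rng = np.random.default_rng(seed)
    n = len(design.y)
    counts = {t: 0 for t in fixed_terms}
    skipped = 0
    used = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        Xb, yb = design.X[idx], design.y[idx]
        if _degenerate(Xb, design.term_cols):
            skipped += 1
            continue
        if random_terms:
            sub = data.loc[design.index[idx]].reset_index(drop=True)
            kept = list(backward_eliminate(
                sub, outcome, list(fixed_terms), random_terms, alpha).fixed_terms)
        else:
            kept = _eliminate_arrays(yb, Xb, design.term_cols, alpha)
        for t in kept:
            counts[t] += 1
        used += 1
    if used == 0:
        raise ModelError("all bootstrap resamples degenerate")
    freq = pd.Series({t: counts[t] / used for t in fixed_terms})
    return StabilityReport(frequency=freq, kept=freq >= 0.5,
                           n_resamples=used, n_skipped=skipped)


def bootstrap_pvalues(
    data: pd.DataFrame,
    outcome: str,
    fixed_terms: list[str],
    B: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-sided bootstrap P per coefficient of the final model.

    p = 2 * min(frac(b* <= 0), frac(b* >= 0)) over B row-resamples, floored
    at 1/B; coefficients whose resampled sign never crosses zero are
    reported as '<1/B' (display column), matching the convention of
    reporting e.g. '<1e-4' at B = 10,000.
    """
    _check_outcome_contract(outcome, list(fixed_terms))
    design = build_design(data, outcome, list(fixed_terms))
    rng = np.random.default_rng(seed)
    n = len(design.y)
    k = design.X.shape[1]
    betas = np.empty((B, k))
    used = np.zeros(B, dtype=bool)
    for b in range(B):
        idx = rng.integers(0, n, n)
        Xb, yb = design.X[idx], design.y[idx]
        if _degenerate(Xb, design.term_cols):
            continue
        betas[b], _ = _ols(yb, Xb)
        used[b] = True
    betas = betas[used]
    n_used = len(betas)
    if n_used == 0:
        raise ModelError("all bootstrap resamples degenerate")
    beta_hat, _ = _ols(design.y, design.X)
    rows = []
    for j, name in enumerate(design.names):
        le = float(np.mean(betas[:, j] <= 0.0))
        ge = float(np.mean(betas[:, j] >= 0.0))
        raw = 2.0 * min(le, ge)
        floored = raw <= 0.0
        p = min(max(raw, 1.0 / n_used), 1.0)
        rows.append({
            "coefficient": name, "estimate": float(beta_hat[j]),
            "bootstrap_p": p,
            "display": f"<{1.0 / n_used:g}" if floored else f"{p:g}",
        })
    return pd.DataFrame(rows).set_index("coefficient")


def repeated_kfold_cv(
    data: pd.DataFrame,
    outcome: str,
    fixed_terms: list[str],
    k: int = 10,
    repeats: int = 100,
    seed: int = 0,
) -> CVReport:
    """Repeated k-fold cross-validation of the fixed-effects model.

    Per repeat, rows are shuffled into k folds; the model is fitted on k-1
    folds (least squares; a categorical level unseen in training keeps a
    zero coefficient) and scored on the held-out fold. The pooled
    out-of-fold R^2 per repeat is returned next to the in-sample R^2.
    """
    _check_outcome_contract(outcome, list(fixed_terms))
    design = build_design(data, outcome, list(fixed_terms))
    y, X = design.y, design.X
    n = len(y)
    if n < 2 * k:
        raise ModelError(f"need at least {2 * k} rows for {k}-fold CV")
    rng = np.random.default_rng(seed)
    tss = float(((y - y.mean()) ** 2).sum())
    _, rss_in = _ols(y, X)
    oof = np.empty(repeats)
    degenerate_folds = 0
    for r in range(repeats):
        order = rng.permutation(n)
        folds = np.array_split(order, k)
        sse = 0.0
        for fold in folds:
            train = np.setdiff1d(order, fold, assume_unique=True)
            if _degenerate(X[train], design.term_cols):
                degenerate_folds += 1
            beta, _ = _ols(y[train], X[train])  # min-norm: unseen level -> 0
            pred = X[fold] @ beta
            sse += float(((y[fold] - pred) ** 2).sum())
        oof[r] = 1.0 - sse / tss
    return CVReport(oof_r2=oof, in_sample_r2=1.0 - rss_in / tss if tss > 0 else 0.0,
                    n_degenerate_folds=degenerate_folds)


# ---------------------------------------------------------------------------
# Signature size versus p53-pathway alterations
# ---------------------------------------------------------------------------

def p53_group(count: int, bounds=P53_GROUP_BOUNDS) -> str:
    for lo, hi in bounds:
        if lo <= count <= hi:
            return f"{lo}" if lo == hi else f"{lo}-{hi}"
    raise ModelError(f"p53 alteration count {count} outside configured groups")


def signature_size_vs_p53(
    sizes: pd.Series,
    p53_counts: pd.Series,
    bounds=P53_GROUP_BOUNDS,
) -> pd.DataFrame:
    """Rank-sum comparison of signature sizes across p53-alteration groups
    (0, 1-3, 4-15 alterations), all pairwise."""
    aligned = pd.concat(
        [sizes.rename("size"), p53_counts.rename("p53")], axis=1
    ).dropna()
    aligned["group"] = [p53_group(int(c), bounds) for c in aligned["p53"]]
    labels = [f"{lo}" if lo == hi else f"{lo}-{hi}" for lo, hi in bounds]
    groups = {lab: aligned.loc[aligned["group"] == lab, "size"].to_numpy()
              for lab in labels}
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            if groups[a].size == 0 or groups[b].size == 0:
                raise ModelError(f"empty p53 group {a if groups[a].size == 0 else b!r}")
            rows.append({
                "comparison": f"{a}_vs_{b}",
                "median_a": float(np.median(groups[a])),
                "median_b": float(np.median(groups[b])),
                "p": wilcoxon_ranksum(groups[a], groups[b]),
            })
    return pd.DataFrame(rows)
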