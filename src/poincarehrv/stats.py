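"""Statistical workflow over the extracted feature table.

Two stages, mirroring common practice in clinical HRV studies:

1. Per-feature univariate testing across NYHA classes with a
   normality-gated test choice — Lilliefors-corrected Kolmogorov-Smirnov on
   pooled within-group residuals decides between one-way ANOVA (with
   Bonferroni pairwise post-hoc) and Kruskal-Wallis (with Dunn's post-hoc,
   Bonferroni-adjusted); post-hoc tests run only after a significant omnibus
   test.
2. A binary low/high-risk multivariate logistic regression with three
   assumption checks: multicollinearity pruning at |r| > 0.7, influential
   point screening by Cook's distance and centered leverage, and an
   events-per-variable guard (smallest class / number of predictors > 10).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "UnivariateResult",
    "MLRConfig",
    "MLRResult",
    "EPVError",
    "SeparationError",
    "univariate_analysis",
    "mlr_fit",
]


class EPVError(RuntimeError):
    """Events-per-variable ratio too small to fit the model."""


class SeparationError(RuntimeError):
    """A feature perfectly separates the two classes."""


@dataclass(frozen=True)
class UnivariateResult:
    feature: str
    group_stats: dict          # label -> (mean, sd, n)
    normality_p: float | None
    test_used: str             # "ANOVA" | "Kruskal-Wallis" | "skipped-constant"
    omnibus_p: float | None
    posthoc: tuple | None      # ((label_i, label_j), adjusted_p), only if significant

    @property
    def significant(self) -> bool:
        return self.omnibus_p is not None and self.omnibus_p < 0.05


def _normality_p(values_by_group: list[np.ndarray], variant: str) -> float:
    """Normality of pooled within-group residuals (centered per group)."""
    resid = np.concatenate([g - g.mean() for g in values_by_group])
    if variant == "lilliefors":
        _, p = lilliefors(resid, dist="norm")
    elif variant == "ks":
        # plain KS against a normal with sample moments
        _, p = sps.kstest(resid, "norm", args=(resid.mean(), resid.std(ddof=1)))
    else:
        raise ValueError(f"unknown normality variant {variant!r}")
    return float(p)


def _anova_posthoc(groups, labels_order, alpha):
    """Bonferroni-adjusted pairwise t-tests using the pooled ANOVA MSE."""
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / (n_total - k)
    df = n_total - k
    pairs = list(itertools.combinations(range(k), 2))
    out = []
    for i, j in pairs:
        gi, gj = groups[i], groups[j]
        se = np.sqrt(mse * (1 / len(gi) + 1 / len(gj)))
        t = (gi.mean() - gj.mean()) / se
        p = 2 * sps.t.sf(abs(t), df) * len(pairs)
        out.append(((labels_order[i], labels_order[j]), float(min(p, 1.0))))
    return tuple(out)


def _dunn_posthoc(groups, labels_order, alpha):
    """Dunn's test on pooled ranks with tie correction, Bonferroni-adjusted."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term: sum(t^3 - t) / (12 (N - 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(range(len(groups)), 2))
    out = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2 * sps.norm.sf(abs(z)) * len(pairs)
        out.append(((labels_order[i], labels_order[j]), float(min(p, 1.0))))
    return tuple(out)


def univariate_analysis(
    table: pd.DataFrame,
    labels,
    alpha: float = 0.05,
    normality: str = "lilliefors",
    features: list[str] | None = None,
) -> list[UnivariateResult]:
    """Normality-gated omnibus test + conditional post-hoc, per feature.

    ``table`` holds one column per feature; ``labels`` assigns each row to a
    class (>= 2 classes, >= 3 rows each).  Constant features are flagged and
    skipped.  All p-values are two-sided; the post-hoc runs only when the
    omnibus p < ``alpha``.
    """
    labels = np.asarray(labels)
    features = list(features or table.columns)
    labels_order = list(pd.unique(labels))
    if len(labels_order) < 2:
        raise ValueError("univariate_analysis needs >= 2 classes")
    masks = [labels == lab for lab in labels_order]
    if min(m.sum() for m in masks) < 3:
        raise ValueError("every class needs >= 3 rows")
    if table[features].isna().any().any():
        raise ValueError("missing feature values are not allowed")

    results = []
    for feat in features:
        groups = [table.loc[m, feat].to_numpy(dtype=float) for m in masks]
        stats = {
            lab: (float(g.mean()), float(g.std(ddof=1)), int(g.size))
            for lab, g in zip(labels_order, groups)
        }
        if np.ptp(np.concatenate(groups)) == 0:
            results.append(UnivariateResult(feat, stats, None,
                                            "skipped-constant", None, None))
            continue
        norm_p = _normality_p(groups, normality)
        if norm_p > alpha:
            test_used = "ANOVA"
            _, omnibus_p = sps.f_oneway(*groups)
            posthoc_fn = _anova_posthoc
        else:
            test_used = "Kruskal-Wallis"
            _, omnibus_p = sps.kruskal(*groups)
            posthoc_fn = _dunn_posthoc
        posthoc = None
        if omnibus_p < alpha:
            posthoc = posthoc_fn(groups, labels_order, alpha)
        results.append(UnivariateResult(feat, stats, norm_p, test_used,
                                        float(omnibus_p), posthoc))
    return results


@dataclass(frozen=True)
class MLRConfig:
    """Thresholds of the assumption checks.

    Outlier screening removes rows with gross influence (Cook's distance
    above an absolute cutoff, classic D > 1) or extreme predictor profiles
    (unweighted centered leverage above ``mult * (k+1) / n``).  Trimming on
    covariate leverage selects on x only, so it does not bias the fitted
    odds ratios; an influence rule calibrated relative to n (such as 4/n)
    would delete several percent of perfectly clean observations and
    systematically steepen the slopes.
    """

    alpha: float = 0.05
    corr_threshold: float = 0.7
    cooks_cutoff: float = 1.0            # absolute Cook's distance cutoff
    leverage_multiplier: float = 2.0     # centered leverage cutoff = mult (k+1) / n
    epv_min: float = 10.0
    positive: str = "high"
    normality: str = "lilliefors"
    include: tuple | None = None         # explicit model, bypasses pruning


@dataclass(frozen=True)
class MLRResult:
    included: tuple
    excluded: dict                       # feature -> "collinear" | "not-selected"
    removed_outlier_ids: tuple
    or_table: pd.DataFrame               # index=feature; OR, ci_low, ci_high, p
    accuracy: float                      # in-sample, probability cutoff 0.5
    epv_ratio: float


def _univariate_label_p(x: np.ndarray, y: np.ndarray, normality: str,
                        alpha: float) -> float:
    """Association strength of one feature with the binary label (omnibus p)."""
    groups = [x[y == 0], x[y == 1]]
    if np.ptp(x) == 0:
        return 1.0
    if _normality_p(groups, normality) > alpha:
        _, p = sps.f_oneway(*groups)
    else:
        _, p = sps.kruskal(*groups)
    return float(p)


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    for feat in X.columns:
        x = X[feat].to_numpy(dtype=float)
        a, b = x[y == 0], x[y == 1]
        if a.max() < b.min() or b.max() < a.min():
            raise SeparationError(
                f"feature {feat!r} perfectly separates the classes"
            )


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    """ML logistic fit on internally standardised predictors.

    Newton iterations are unstable when features live on very different
    scales (areas in ms^2 next to percentages), so the design is z-scored
    for fitting; coefficients and Wald CIs are mapped back to per-unit
    scale by dividing by each feature's SD, to which Cook's distance,
    leverage, p-values and predictions are all invariant.
    """
    sds = X.std(ddof=1)
    if (sds == 0).any():
        bad = sds.index[sds == 0][0]
        raise ValueError(f"feature {bad!r} is constant; cannot enter the model")
    Z = (X - X.mean()) / sds
    design = sm.add_constant(Z.astype(float), has_constant="add")
    model = sm.Logit(y, design)
    with np.errstate(over="ignore", divide="ignore"):
        try:
            res = model.fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # Newton's Hessian goes singular under quasi-separation; BFGS
            # still reaches the (possibly extreme but finite) MLE
            res = model.fit(method="bfgs", disp=0, maxiter=1000)
        if not res.mle_retvals.get("converged", True):
            res = model.fit(method="bfgs", disp=0, maxiter=2000)
    if not res.mle_retvals.get("converged", True):
        raise SeparationError(
            "logistic fit did not converge (quasi-separated predictors?)"
        )
    return res, design, sds


def mlr_fit(
    table: pd.DataFrame,
    labels,
    config: MLRConfig | None = None,
    features: list[str] | None = None,
) -> MLRResult:
    """Multivariate logistic regression with the three assumption checks.

    Steps: (1) collinearity pruning — while any pair of offered features has
    |Pearson r| above the threshold, drop the member with the weaker
    univariate association with the label; (2) outlier screening on a
    provisional fit (gross Cook's distance or extreme centered leverage, see
    :class:`MLRConfig`), then one refit; (3) events-per-variable guard;
    (4) final maximum-likelihood fit reported as odds ratios with 95% Wald
    CIs, two-sided p-values and in-sample accuracy at cutoff 0.5.
    """
    config = config or MLRConfig()
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError("mlr_fit needs exactly 2 classes")
    if len(table) < 20:
        raise ValueError("mlr_fit needs >= 20 rows")
    y = (labels == config.positive).astype(int)
    if y.sum() in (0, len(y)):
        raise ValueError(f"positive class {config.positive!r} not found in labels")

    offered = list(features or table.columns)
    excluded: dict[str, str] = {}

    if config.include is not None:
        included = [f for f in offered if f in config.include]
        missing = set(config.include) - set(included)
        if missing:
            raise ValueError(f"include-list features not in table: {sorted(missing)}")
        excluded.update({f: "not-selected" for f in offered if f not in included})
    else:
        included = list(offered)
        assoc_p = {
            f: _univariate_label_p(table[f].to_numpy(dtype=float), y,
                                   config.normality, config.alpha)
            for f in included
        }
        while len(included) > 1:
            sub = table[included].astype(float)
            corr = sub.corr().abs().to_numpy()
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.argmax(corr), corr.shape)
            if corr[i, j] <= config.corr_threshold:
                break
            fi, fj = included[i], included[j]
            # drop the member with the weaker (larger-p) label association;
            # on an exact tie drop the later one in offered order
            drop = fi if assoc_p[fi] > assoc_p[fj] else fj
            included.remove(drop)
            excluded[drop] = "collinear"

    X = table[included].copy()
    _check_separation(X, y)

    # provisional fit -> influence screening -> single refit
    res0, design0, _ = _fit_logit(X, y)
    n = len(X)
    k = len(included)
    try:
        infl = res0.get_influence()
        cooks = np.asarray(infl.cooks_distance[0], dtype=float)
    except (ValueError, np.linalg.LinAlgError):
        # quasi-separated fits have no usable parameter covariance and
        # Cook's distance is ill-defined; screen on leverage alone
        cooks = np.zeros(n)
    Xc = X.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    leverage = np.einsum("ij,ji->i", Xc, np.linalg.solve(Xc.T @ Xc, Xc.T))
    out_mask = (cooks > config.cooks_cutoff) | (
        leverage > config.leverage_multiplier * (k + 1) / n
    )
    removed_ids = tuple(X.index[out_mask])
    X_fit, y_fit = X.loc[~out_mask], y[~out_mask]

    smallest = min((y_fit == 0).sum(), (y_fit == 1).sum())
    epv_ratio = float(smallest) / k
    if epv_ratio <= config.epv_min:
        raise EPVError(
            f"events-per-variable ratio {epv_ratio:.2f} <= {config.epv_min} "
            f"(smallest class {smallest}, {k} predictors); refusing to fit"
        )

    res, design, sds = _fit_logit(X_fit, y_fit)
    ci = res.conf_int(alpha=0.05)
    rows = []
    # exp overflow -> inf is the correct reading of an unbounded Wald CI
    with np.errstate(over="ignore"):
        for feat in included:
            scale = float(sds[feat])
            rows.append({
                "OR": float(np.exp(res.params[feat] / scale)),
                "ci_low": float(np.exp(ci.loc[feat, 0] / scale)),
                "ci_high": float(np.exp(ci.loc[feat, 1] / scale)),
                "p": float(res.pvalues[feat]),
            })
    or_table = pd.DataFrame(rows, index=pd.Index(included, name="feature"))
    pred = (res.predict(design) >= 0.5).astype(int)
    accuracy = float((pred == y_fit).mean())

    return MLRResult(
        included=tuple(included),
        excluded=excluded,
        removed_outlier_ids=removed_ids,
        or_table=or_table,
        accuracy=accuracy,
        epv_ratio=epv_ratio,
    )
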