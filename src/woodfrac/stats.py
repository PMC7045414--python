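"""Inference layer: species-random-effect mixed models with marginal and
conditional R2 and parametric-bootstrap p-values, ANOVA variance partitioning,
soil-class group tests, PCA, and stepwise backward AIC model selection.

R2_marginal is the share of total variance explained by the fixed effects
alone, sigma2_f / (sigma2_f + sigma2_b + sigma2_e), with sigma2_f the variance
of the fixed-effect linear predictor; R2_conditional adds the species random
intercept to the numerator. Bootstrap p-values compare the observed
likelihood-ratio statistic between nested models against its distribution
under responses simulated from the fitted reduced model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .lmm import LMMFit, RandomInterceptLMM
from .synthesis import FieldDataset

__all__ = [
    "MixedModelSpec",
    "MixedModelFit",
    "VariancePartition",
    "fit_mixed_model",
    "parametric_bootstrap_p",
    "variance_partition",
    "group_ttest",
    "pca_summary",
    "stepwise_backward_aic",
    "kruskal_within_species",
]

#: Responses the study log-transforms before modelling (vessel sizes, K_S).
LOG_RESPONSES = ("d_max_um", "dh_mean_um", "Ks_kg_m_MPa_s")


@dataclass(frozen=True)
class MixedModelSpec:
    """Random-intercept model: response ~ fixed predictors + (1 | species)."""

    response: str
    predictors: tuple[str, ...] = ()
    log_response: bool = False
    group: str = "species"

    def with_predictors(self, predictors) -> "MixedModelSpec":
        return replace(self, predictors=tuple(predictors))


@dataclass(frozen=True)
class MixedModelFit:
    spec: MixedModelSpec
    coefficients: dict[str, float]
    sigma2_fixed: float
    sigma2_random: float
    sigma2_residual: float
    r2_marginal: float
    r2_conditional: float
    aic_ml: float
    singular: bool
    _engine_fit: LMMFit = field(repr=False, compare=False, default=None)


def _design(data: pd.DataFrame, spec: MixedModelSpec):
    y = data[spec.response].to_numpy(dtype=float)
    if spec.log_response:
        if np.any(y <= 0):
            raise ValueError("log transform requires a positive response")
        y = np.log(y)
    X = np.column_stack(
        [np.ones(len(data))]
        + [data[p].to_numpy(dtype=float) for p in spec.predictors])
    groups = data[spec.group].to_numpy()
    return y, X, groups


def _frame(data) -> pd.DataFrame:
    return data.data if isinstance(data, FieldDataset) else data


def fit_mixed_model(data, spec: MixedModelSpec, reml: bool = True) -> MixedModelFit:
    """REML (default) fit of a species-random-intercept linear mixed model."""
    df = _frame(data)
    counts = df[spec.group].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 observations each")
    y, X, groups = _design(df, spec)
    engine = RandomInterceptLMM(X, groups)
    fit = engine.fit(y, reml=reml)
    if fit.singular:
        warnings.warn("singular fit: species variance estimated at zero",
                      stacklevel=2)
    aic_ml = fit.aic if not reml else engine.fit(y, reml=False).aic
    coef = {"(Intercept)": float(fit.beta[0])}
    coef.update({p: float(b) for p, b in zip(spec.predictors, fit.beta[1:])})
    return MixedModelFit(
        spec=spec, coefficients=coef, sigma2_fixed=fit.sigma2_f,
        sigma2_random=fit.sigma2_b, sigma2_residual=fit.sigma2_e,
        r2_marginal=fit.r2_marginal, r2_conditional=fit.r2_conditional,
        aic_ml=aic_ml, singular=fit.singular, _engine_fit=fit,
    )


def parametric_bootstrap_p(full: MixedModelSpec, reduced: MixedModelSpec,
                           data, reps: int = 999, seed: int = 0) -> float:
    """Bootstrap p-value for the nested comparison of two mixed models.

    Responses are simulated from the ML fit of the reduced model; both models
    are refitted by ML to each draw and the likelihood-ratio statistic
    compared with the observed one: p = (1 + #{LR* >= LR_obs}) / (reps + 1).
    """
    if not set(reduced.predictors) <= set(full.predictors):
        raise ValueError("reduced model must be nested in the full model")
    if reps < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    df = _frame(data)
    y, X_full, groups = _design(df, full)
    _, X_red, _ = _design(df, reduced)
    eng_full = RandomInterceptLMM(X_full, groups)
    eng_red = RandomInterceptLMM(X_red, groups)
    # observed and bootstrap statistics share one optimiser path so that
    # refinement error cancels in the comparison
    dev_full = eng_full.fit_many(y, reml=False)[0]
    dev_red = eng_red.fit_many(y, reml=False)[0]
    lr_obs = max(dev_red - dev_full, 0.0)
    red_fit = eng_red.fit(y, reml=False)

    rng = np.random.default_rng(seed)
    Y = eng_red.simulate(red_fit, reps, rng)
    dev_f = eng_full.fit_many(Y, reml=False)
    dev_r = eng_red.fit_many(Y, reml=False)
    lr_boot = np.maximum(dev_r - dev_f, 0.0)
    return float((1 + np.sum(lr_boot >= lr_obs)) / (reps + 1))


@dataclass(frozen=True)
class VariancePartition:
    """Percent of variance per effect, sigma2_effect / sigma2_total x 100.

    ``components`` holds the underlying absolute variance-component estimates
    (unbiased before the zero truncation); ratios of components *pooled over
    replicate datasets* recover a simulated share without the Jensen bias the
    per-dataset percentage ratio carries.
    """

    percent: dict[str, float]
    components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.percent.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"components sum to {total}, not 100")


def variance_partition(data, trait: str, group: str = "species") -> VariancePartition:
    """Species vs residual percent variance shares from one-way ANOVA.

    Variance components by the method of moments: sigma2_within = MS_within,
    sigma2_species = (MS_between - MS_within) / n0 with n0 the (near-)balanced
    group size, truncated at zero.
    """
    df = _frame(data)
    values = df[trait].to_numpy(dtype=float)
    codes, uniq = pd.factorize(df[group])
    k = len(uniq)
    if k < 2:
        raise ValueError("variance partition needs >= 2 species")
    n = len(values)
    means = np.array([values[codes == i].mean() for i in range(k)])
    sizes = np.array([(codes == i).sum() for i in range(k)], dtype=float)
    grand = values.mean()
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(np.sum((values - means[codes]) ** 2))
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k) if n > k else 0.0
    # effective group size for (possibly) unbalanced designs
    n0 = (n - np.sum(sizes**2) / n) / (k - 1)
    sigma2_species = max((ms_between - ms_within) / n0, 0.0)
    sigma2_resid = ms_within
    total = sigma2_species + sigma2_resid
    comps = {"species": sigma2_species, "residual": sigma2_resid}
    if total == 0:
        return VariancePartition({"species": 0.0, "residual": 100.0}, comps)
    return VariancePartition({
        "species": 100.0 * sigma2_species / total,
        "residual": 100.0 * sigma2_resid / total,
    }, comps)


def variance_partition_recovery(species_share: float, n_replicates: int = 200,
                                n_species: int = 16, n_individuals: int = 5,
                                seed: int = 0) -> float:
    """Recover a simulated species variance share (in %) by replicate ANOVA.

    Generates ``n_replicates`` datasets with the species and residual
    variances in the ratio ``species_share : 1 - species_share``, partitions
    each, and returns the share formed from the replicate-pooled variance
    components (the pooled ratio is free of the per-dataset ratio bias).
    """
    from .synthesis import TraitSpec, generate_field_dataset

    if not 0 <= species_share <= 1:
        raise ValueError("species_share must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    spec = {"trait": TraitSpec(0.0, species_share, 1.0 - species_share)}
    pooled = {"species": 0.0, "residual": 0.0}
    for _ in range(n_replicates):
        ds = generate_field_dataset(n_species, n_individuals, traits=spec,
                                    link=None,
                                    seed=int(rng.integers(2**31)))
        vp = variance_partition(ds, "trait")
        for key in pooled:
            pooled[key] += vp.components[key]
    total = pooled["species"] + pooled["residual"]
    return 100.0 * pooled["species"] / total


def group_ttest(values: pd.Series | np.ndarray, classes,
                convention: str = "low_minus_high"):
    """Welch two-sample t-test of per-species means, low vs high soil class.

    Returns (t, p). Under the default convention the statistic is positive
    when the low-soil mean exceeds the high-soil mean.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    low = values[classes == "low"]
    high = values[classes == "high"]
    if len(low) < 2 or len(high) < 2:
        raise ValueError("each soil class needs >= 2 species")
    if convention == "low_minus_high":
        a, b = low, high
    elif convention == "high_minus_low":
        a, b = high, low
    else:
        raise ValueError(f"unknown convention {convention!r}")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PCASummary:
    loadings: pd.DataFrame  # variables x components, orthonormal columns
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame


def pca_summary(data, variables: list[str]) -> PCASummary:
    """PCA of centred, unit-variance variables (they mix %, um, cm2 g-1...)."""
    df = _frame(data)
    if len(variables) < 2:
        raise ValueError("PCA needs >= 2 variables")
    M = df[list(variables)].to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValueError("complete cases required")
    sd = M.std(axis=0)
    if np.any(sd == 0):
        const = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"constant variable(s): {const}")
    Z = StandardScaler().fit_transform(M)
    pca = PCA()
    scores = pca.fit_transform(Z)
    comps = [f"PC{i + 1}" for i in range(pca.n_components_)]
    return PCASummary(
        loadings=pd.DataFrame(pca.components_.T, index=list(variables),
                              columns=comps),
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=pd.DataFrame(scores, columns=comps, index=df.index),
    )


def stepwise_backward_aic(data, full: MixedModelSpec) -> MixedModelFit:
    """Backward elimination by ML-based AIC over the fixed-effect terms.

    At each step the predictor whose removal lowers AIC the most is dropped;
    stops when no removal improves AIC. Returns the selected model refitted by
    REML (AIC comparisons themselves use maximum likelihood).
    """
    df = _frame(data)
    current = tuple(full.predictors)
    best_aic = fit_mixed_model(df, full.with_predictors(current)).aic_ml
    improved = True
    while improved and current:
        improved = False
        candidates = []
        for drop in current:
            trial = tuple(p for p in current if p != drop)
            aic = fit_mixed_model(df, full.with_predictors(trial)).aic_ml
            candidates.append((aic, trial))
        aic_min, trial_min = min(candidates, key=lambda t: t[0])
        if aic_min < best_aic:
            best_aic, current, improved = aic_min, trial_min, True
    return fit_mixed_model(df, full.with_predictors(current))


def kruskal_within_species(stem_values, twig_values):
    """Kruskal-Wallis rank test comparing stem vs twig samples of one species.

    All-tied data yield (0, 1) with a warning rather than an error.
    """
    stem = np.asarray(stem_values, dtype=float)
    twig = np.asarray(twig_values, dtype=float)
    if len(stem) < 2 or len(twig) < 2:
        raise ValueError("need >= 2 observations per organ")
    pooled = np.concatenate([stem, twig])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied; p = 1", stacklevel=2)
        return 0.0, 1.0
    res = sps.kruskal(stem, twig)
    return float(res.statistic), float(res.pvalue)
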