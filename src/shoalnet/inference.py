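"""Statistical battery: PCA, nested mixed models, repeatability, correlations.

The analysis asks three nested questions of each phenotype:

1. *Parallel divergence* — does the benthic/limnetic ecotype explain
   variation?  Linear mixed model with ecotype fixed and population,
   family-within-population (and, for behavior, group) random.
2. *Population-dependent divergence* — do populations differ regardless of
   ecotype?  Same structure with population as the fixed effect, followed
   by Tukey-adjusted pairwise contrasts of estimated marginal means.
3. *Consistency* — are individual differences repeatable across trials?
   Adjusted repeatability (intraclass correlation from a mixed model with
   population as fixed effect), with parametric-bootstrap confidence
   intervals and permutation p-values.

Fixed-effect significance uses Type III Wald chi-square tests under
sum-to-zero contrast coding.  Behaviors enter the PCA as per-fish means
across the two trials; latency to emerge is modelled separately with a
quasi-Poisson GLMM (log link, variance proportional to the mean) fitted by
penalized quasi-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA

from shoalnet._lmm import LMMFit, SingularFitError, VarianceComponentsLMM

BEHAVIORS = ("activity", "cohesion", "strength", "clustering")

# transformations applied before the repeatability fit, per behavior;
# clustering is left untransformed (approximately normal already)
DEFAULT_TRANSFORMS = {
    "activity": "log",
    "cohesion": "sqrt",
    "strength": "sqrt",
    "interaction_time": "sqrt",
    "clustering": "none",
}


class IncompleteDesignError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    """Model fit failed; the message carries the fit log."""


# ---------------------------------------------------------------------------
# behavior aggregation
# ---------------------------------------------------------------------------


def mean_across_trials(b, behaviors=BEHAVIORS) -> pd.DataFrame:
    """Per-fish mean of each behavior across the two trials.

    Accepts a BehaviorTable or its individual-level DataFrame; every fish
    must appear in both trials.  Metadata columns are carried through.
    """
    df = b.individual if hasattr(b, "individual") else b
    trials_per_fish = df.groupby("fish_id")["trial"].nunique()
    incomplete = trials_per_fish[trials_per_fish < 2]
    if len(incomplete):
        raise IncompleteDesignError(
            f"fish missing a trial: {list(incomplete.index)}"
        )
    meta_cols = [
        c
        for c in ("population", "ecotype", "family", "group_id", "standard_length")
        if c in df.columns
    ]
    agg = {c: "mean" for c in behaviors}
    agg.update({c: "first" for c in meta_cols})
    out = df.groupby("fish_id", as_index=False).agg(agg)
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Loadings, scores, and variance explained of a correlation-matrix PCA."""

    loadings: pd.DataFrame  # variables x components, unit-norm columns
    scores: pd.DataFrame  # observations x components
    variance_explained: np.ndarray  # proportions, sums to 1 over all PCs
    scaled: bool

    def top(self, k: int = 2) -> float:
        """Total proportion of variance in the first k components."""
        return float(self.variance_explained[:k].sum())


def run_pca(table: pd.DataFrame, scale: bool = True) -> PCAResult:
    """Principal component analysis of an observations x variables table.

    By default the analysis is on the correlation matrix (center and scale
    each column), appropriate when variables live on incommensurate scales
    (cm, seconds, dimensionless).  Components are ordered by decreasing
    variance and each is sign-flipped so its largest-magnitude loading is
    positive, fixing the inherent sign ambiguity.
    """
    X = table.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables")
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values")
    sd = X.std(axis=0, ddof=1)
    if scale:
        if np.any(sd == 0):
            bad = [c for c, s in zip(table.columns, sd) if s == 0]
            raise ValueError(f"constant column(s) under scaling: {bad}")
        X = (X - X.mean(axis=0)) / sd
    pca = _SKPCA(n_components=min(X.shape))
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # columns are unit-norm PC directions
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip
    pcs = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=table.columns, columns=pcs),
        scores=pd.DataFrame(scores, index=table.index, columns=pcs),
        variance_explained=pca.explained_variance_ratio_.copy(),
        scaled=scale,
    )


# ---------------------------------------------------------------------------
# fixed-effect coding and mixed models
# ---------------------------------------------------------------------------


def _sum_coded(labels):
    """Sum-to-zero (deviation) coding: columns for all levels but the last."""
    labels = np.asarray(labels)
    levels = sorted(pd.unique(labels).tolist())
    L = len(levels)
    X = np.zeros((len(labels), L - 1))
    last = levels[-1]
    for j, lev in enumerate(levels[:-1]):
        X[labels == lev, j] = 1.0
    X[labels == last, :] = -1.0
    return X, levels


@dataclass
class MixedModelResult:
    """Mixed-model fit summary with Type III Wald tests."""

    response: str
    fixed_effects: pd.Series
    wald: pd.DataFrame  # columns: term, chi2, df, p
    variance_components: dict
    converged: bool
    degenerate: bool = False
    dispersion: float | None = None  # quasi-likelihood models only
    n: int = 0
    _term_info: dict = field(default_factory=dict, repr=False)
    _fit: LMMFit | None = field(default=None, repr=False)

    def wald_for(self, term: str) -> tuple[float, int, float]:
        row = self.wald[self.wald["term"] == term]
        if row.empty:
            raise KeyError(f"no Wald row for term {term!r}")
        r = row.iloc[0]
        return float(r["chi2"]), int(r["df"]), float(r["p"])


def _assemble_design(data: pd.DataFrame, fixed: str):
    X_term, levels = _sum_coded(data[fixed].to_numpy())
    X = np.column_stack([np.ones(len(data)), X_term])
    names = ["Intercept"] + [f"{fixed}[S.{lev}]" for lev in levels[:-1]]
    cols = list(range(1, X.shape[1]))
    return X, names, {"levels": levels, "cols": cols}


def _random_spec(data: pd.DataFrame, names) -> dict:
    return {name: data[name].to_numpy() for name in names}


def _fit_lmm(
    data: pd.DataFrame, response: str, fixed: str, random: list, label=None
) -> MixedModelResult:
    y = data[response].to_numpy(dtype=float)
    label = label or response
    X, names, term_info = _assemble_design(data, fixed)
    if np.ptp(y) == 0:
        wald = pd.DataFrame(
            [{"term": fixed, "chi2": 0.0, "df": len(term_info["cols"]), "p": 1.0}]
        )
        return MixedModelResult(
            response=label,
            fixed_effects=pd.Series(
                np.r_[y[0], np.zeros(X.shape[1] - 1)], index=names
            ),
            wald=wald,
            variance_components={name: 0.0 for name in random + ["residual"]},
            converged=True,
            degenerate=True,
            n=len(y),
            _term_info={fixed: term_info},
        )
    model = VarianceComponentsLMM(
        X, _random_spec(data, random), fixed_names=names
    )
    fit = model.fit(y)
    if not fit.converged:
        raise ConvergenceError(
            f"REML did not converge for {label} ~ {fixed} + ({'+'.join(random)}); "
            f"variance components at exit: {fit.sigma2}"
        )
    chi2, df = fit.wald_chi2(term_info["cols"])
    wald = pd.DataFrame(
        [
            {
                "term": fixed,
                "chi2": chi2,
                "df": df,
                "p": float(stats.chi2.sf(chi2, df)),
            }
        ]
    )
    return MixedModelResult(
        response=label,
        fixed_effects=pd.Series(fit.beta, index=names),
        wald=wald,
        variance_components=dict(fit.sigma2),
        converged=True,
        n=len(y),
        _term_info={fixed: term_info},
        _fit=fit,
    )


def fit_ecotype_model(
    data: pd.DataFrame, response: str, include_group: bool | None = None
) -> MixedModelResult:
    """Ecotype (benthic vs limnetic) fixed; population and family random.

    For behavioral responses measured on fish assayed in groups, a group
    random intercept is added (default: whenever a ``group_id`` column is
    present).  The ecotype Wald test has 1 df and is the test of parallel
    divergence.
    """
    if include_group is None:
        include_group = "group_id" in data.columns
    random = ["population", "family"] + (["group_id"] if include_group else [])
    return _fit_lmm(data, response, "ecotype", random)


def fit_population_model(
    data: pd.DataFrame, response: str, include_group: bool | None = None
) -> MixedModelResult:
    """Population fixed (7 df at the 8-population design); family (and group) random."""
    if include_group is None:
        include_group = "group_id" in data.columns
    random = ["family"] + (["group_id"] if include_group else [])
    return _fit_lmm(data, response, "population", random)


# ---------------------------------------------------------------------------
# post-hoc estimated marginal means
# ---------------------------------------------------------------------------


def _emm_contrast(term_info, level, p):
    e = np.zeros(p)
    e[0] = 1.0
    levels, cols = term_info["levels"], term_info["cols"]
    if level == levels[-1]:
        e[cols] = -1.0
    else:
        e[cols[levels.index(level)]] = 1.0
    return e


def compact_letters(levels, sig_pairs) -> dict:
    """Compact letter display: levels sharing a letter are not significantly
    different (insert-and-absorb algorithm)."""
    groups = [set(levels)]
    for i, j in sig_pairs:
        new = []
        for g in groups:
            if i in g and j in g:
                new.extend([g - {i}, g - {j}])
            else:
                new.append(g)
        groups = []
        for g in new:
            if g and not any(g < h or (g == h and g in groups) for h in new if h is not g):
                if g not in groups:
                    groups.append(g)
    groups.sort(key=lambda g: sorted(levels.index(x) for x in g))
    letters = {lev: "" for lev in levels}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for lev in g:
            letters[lev] += letter
    return letters


def posthoc_pairwise(
    result: MixedModelResult, term: str, alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise contrasts of estimated marginal means with Tukey adjustment.

    The Tukey (studentized-range) adjustment controls the familywise error
    over all k(k-1)/2 comparisons; residual degrees of freedom approximate
    the denominator df.  A compact letter display column summarizes the
    significant separations.
    """
    if term not in result._term_info:
        raise KeyError(f"model has no fixed term {term!r}")
    info = result._term_info[term]
    levels = info["levels"]
    k = len(levels)
    if k < 2:
        raise ValueError("post-hoc contrasts need a factor with >= 2 levels")
    fit = result._fit
    if fit is None:
        raise ValueError("degenerate model: no contrasts available")
    p = len(fit.beta)
    df_resid = max(fit.resid_df, 2)
    emms = {lev: _emm_contrast(info, lev, p) for lev in levels}
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            c = emms[levels[a]] - emms[levels[b]]
            est = float(c @ fit.beta)
            se = float(np.sqrt(c @ fit.cov_beta @ c))
            if se == 0:
                t, p_unadj, p_tukey = 0.0, 1.0, 1.0
            else:
                t = est / se
                p_unadj = float(2 * stats.t.sf(abs(t), df_resid))
                q = abs(t) * np.sqrt(2.0)
                p_tukey = float(
                    np.clip(stats.studentized_range.sf(q, k, df_resid), 0, 1)
                )
            rows.append(
                {
                    "level_1": levels[a],
                    "level_2": levels[b],
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "p_unadjusted": p_unadj,
                    "p_tukey": p_tukey,
                }
            )
    table = pd.DataFrame(rows)
    sig = [
        (r["level_1"], r["level_2"])
        for _, r in table.iterrows()
        if r["p_tukey"] < alpha
    ]
    letters = compact_letters(levels, sig)
    table.attrs["letters"] = letters
    table.attrs["emmeans"] = {
        lev: float(emms[lev] @ fit.beta) for lev in levels
    }
    return table


# ---------------------------------------------------------------------------
# quasi-Poisson GLMM for latency to emerge
# ---------------------------------------------------------------------------


def fit_latency_model(
    data: pd.DataFrame,
    response: str = "latency",
    fixed: str = "ecotype",
    max_iter: int = 100,
    tol: float = 1e-6,
) -> MixedModelResult:
    """Quasi-Poisson GLMM (log link, Var = phi * mu) by penalized quasi-likelihood.

    Latencies are integer seconds in [0, 600]; fish that never emerged are
    scored 600 (treated as an observed ceiling value, not censored).  Random
    intercepts: population and family for the ecotype model, family for the
    population model.  The PQL loop alternates a linearized (working-
    response) weighted LMM with an update of the linear predictor, and the
    dispersion phi is the residual variance of the working model (equivalent
    to a Pearson chi-square / df moment estimator on the data scale).
    """
    y = data[response].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError("latencies must be nonnegative")
    if np.ptp(y) == 0:
        X, names, term_info = _assemble_design(data, fixed)
        wald = pd.DataFrame(
            [{"term": fixed, "chi2": 0.0, "df": len(term_info["cols"]), "p": 1.0}]
        )
        return MixedModelResult(
            response=response,
            fixed_effects=pd.Series(
                np.r_[np.log(max(y[0], 1e-12)), np.zeros(X.shape[1] - 1)],
                index=names,
            ),
            wald=wald,
            variance_components={},
            converged=True,
            degenerate=True,
            dispersion=0.0,
            n=len(y),
            _term_info={fixed: term_info},
        )
    random = ["population", "family"] if fixed == "ecotype" else ["family"]
    X, names, term_info = _assemble_design(data, fixed)
    factors = _random_spec(data, random)

    # initialize from a fixed-effects-only Poisson GLM working fit
    eta = np.log(np.clip(y, 0.5, None))
    beta = np.linalg.lstsq(X, eta, rcond=None)[0]
    eta = X @ beta
    u = {name: np.zeros(len(np.unique(f))) for name, f in factors.items()}
    codes = {
        name: np.unique(f, return_inverse=True)[1] for name, f in factors.items()
    }
    fit = None
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -30, 30))
        z = eta + (y - mu) / mu
        model = VarianceComponentsLMM(X, factors, weights=mu, fixed_names=names)
        fit = model.fit(z)
        ranef = model.ranef(fit)
        eta_new = X @ fit.beta
        for name in factors:
            eta_new = eta_new + ranef[name][codes[name]]
        if np.max(np.abs(eta_new - eta)) < tol:
            eta = eta_new
            break
        eta = eta_new
    else:
        raise ConvergenceError(
            f"PQL did not converge in {max_iter} iterations for {response} ~ {fixed}"
        )
    phi = fit.sigma2["residual"]  # working-scale residual variance = dispersion
    chi2, df = fit.wald_chi2(term_info["cols"])
    wald = pd.DataFrame(
        [{"term": fixed, "chi2": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df))}]
    )
    vc = {k: v for k, v in fit.sigma2.items() if k != "residual"}
    return MixedModelResult(
        response=response,
        fixed_effects=pd.Series(fit.beta, index=names),
        wald=wald,
        variance_components=vc,
        converged=True,
        dispersion=float(phi),
        n=len(y),
        _term_info={fixed: term_info},
        _fit=fit,
    )


# ---------------------------------------------------------------------------
# adjusted repeatability
# ---------------------------------------------------------------------------


@dataclass
class RepeatabilityResult:
    """Adjusted repeatability with bootstrap CI and resampling p-values."""

    label: str
    R: float
    ci_low: float
    ci_high: float
    p_boot: float
    p_perm: float
    n_boot: int
    n_perm: int
    variance_components: dict
    transform: str = "none"


def _apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return values
    if transform == "log":
        if np.any(values <= 0):
            raise ValueError("log transform requires positive values")
        return np.log(values)
    if transform == "sqrt":
        if np.any(values < 0):
            raise ValueError("sqrt transform requires nonnegative values")
        return np.sqrt(values)
    raise ValueError(f"unknown transform {transform!r}")


def _repeatability_from_fit(fit: LMMFit, id_name: str) -> float:
    va = fit.sigma2[id_name]
    ve = fit.sigma2["residual"]
    return va / (va + ve) if (va + ve) > 0 else 0.0


def adjusted_repeatability(
    data: pd.DataFrame,
    value: str,
    id_col: str = "fish_id",
    fixed: str = "population",
    transform: str = "none",
    n_boot: int = 1000,
    n_perm: int = 1000,
    rng=None,
    label: str | None = None,
    compute_p: bool = True,
) -> RepeatabilityResult:
    """Adjusted repeatability R = sigma2_ID / (sigma2_ID + sigma2_residual).

    Fits a linear mixed model with the (optionally transformed) behavior as
    response, ``fixed`` as a fixed effect and ``id_col`` as a random
    intercept, so R is the intraclass correlation net of the adjusted
    factor.  The 95% CI comes from a parametric bootstrap (simulate from
    the fitted model, refit, percentile bounds); ``p_boot`` from a
    parametric bootstrap under the no-individual-variance null; ``p_perm``
    from permuting individual identities across observations within levels
    of the fixed factor, comparing the between/within F-ratio of the
    adjusted residuals (a continuous statistic, so the null p-value
    distribution is uniform instead of piling up at 1 whenever the REML
    variance estimate sits on the zero boundary).  For pair-level
    interaction times, pass the pair identifier as ``id_col``.  ``compute_p=False`` skips both p-value
    resampling schemes (the CI bootstrap still runs), which halves the cost
    in calibration studies that only need interval coverage.
    """
    if n_boot < 1 or n_perm < 1:
        raise ValueError("n_boot and n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    counts = data.groupby(id_col)[value].size()
    if (counts < 2).all():
        raise ValueError("repeatability needs >= 2 observations for some individuals")
    y = _apply_transform(data[value].to_numpy(dtype=float), transform)
    X, names, _ = _assemble_design(data, fixed)
    ids = data[id_col].to_numpy()
    model = VarianceComponentsLMM(X, {id_col: ids}, fixed_names=names)
    fit = model.fit(y)
    R = _repeatability_from_fit(fit, id_col)

    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = _repeatability_from_fit(model.fit(model.simulate(fit, rng)), id_col)
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])

    if not compute_p:
        return RepeatabilityResult(
            label=label or value,
            R=float(R),
            ci_low=float(ci_low),
            ci_high=float(ci_high),
            p_boot=float("nan"),
            p_perm=float("nan"),
            n_boot=n_boot,
            n_perm=0,
            variance_components={
                "individual": fit.sigma2[id_col],
                "residual": fit.sigma2["residual"],
            },
            transform=transform,
        )

    # null bootstrap: same total variance, none of it between individuals
    null_fit = LMMFit(
        beta=fit.beta,
        cov_beta=fit.cov_beta,
        sigma2={id_col: 0.0, "residual": fit.sigma2[id_col] + fit.sigma2["residual"]},
        loglik_reml=np.nan,
        converged=True,
        n=fit.n,
        p=fit.p,
        fixed_names=fit.fixed_names,
    )
    null_R = np.empty(n_boot)
    for b in range(n_boot):
        null_R[b] = _repeatability_from_fit(
            model.fit(model.simulate(null_fit, rng)), id_col
        )
    p_boot = (1.0 + np.sum(null_R >= R)) / (n_boot + 1.0)

    # Permutation test on the one-way ANOVA F-ratio of the fixed-effect-
    # adjusted residuals.  The F statistic is a continuous, monotone proxy
    # for the ICC with no boundary truncation, so its permutation p-value
    # is uniform under the null; comparing the REML R-hat itself would pile
    # probability mass at p = 1 whenever the variance estimate hits zero.
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    _, id_codes = np.unique(ids, return_inverse=True)
    fixed_labels = data[fixed].to_numpy()
    pop_groups = [
        np.flatnonzero(fixed_labels == lev) for lev in pd.unique(fixed_labels)
    ]

    def _anova_f(codes):
        counts = np.bincount(codes)
        sums = np.bincount(codes, weights=resid)
        nz = counts > 0
        ssb = float(np.sum(sums[nz] ** 2 / counts[nz])) - resid.sum() ** 2 / len(resid)
        sst = float(resid @ resid) - resid.sum() ** 2 / len(resid)
        ssw = sst - ssb
        dfb = int(nz.sum()) - 1
        dfw = len(resid) - int(nz.sum())
        if dfb <= 0 or dfw <= 0 or ssw <= 0:
            return np.inf
        return (ssb / dfb) / (ssw / dfw)

    f_obs = _anova_f(id_codes)
    f_perm = np.empty(n_perm)
    for b in range(n_perm):
        perm_codes = id_codes.copy()
        for sel in pop_groups:
            perm_codes[sel] = perm_codes[rng.permutation(sel)]
        f_perm[b] = _anova_f(perm_codes)
    p_perm = (1.0 + np.sum(f_perm >= f_obs)) / (n_perm + 1.0)

    return RepeatabilityResult(
        label=label or value,
        R=float(R),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_boot=float(p_boot),
        p_perm=float(p_perm),
        n_boot=n_boot,
        n_perm=n_perm,
        variance_components={
            "individual": fit.sigma2[id_col],
            "residual": fit.sigma2["residual"],
        },
        transform=transform,
    )


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


@dataclass
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    p: float
    n: int


def spearman(x, y, n_boot: int = 1000, rng=None) -> SpearmanResult:
    """Spearman rank correlation with a bootstrap percentile 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    rng = np.random.default_rng(rng)
    n = len(x)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
            boots[b] = np.nan
            continue
        boots[b] = stats.spearmanr(x[idx], y[idx]).statistic
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return SpearmanResult(
        rho=float(rho), ci_low=float(lo), ci_high=float(hi), p=float(p), n=n
    )
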