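"""Count GLMs for species richness with diagnostics, selection and contrasts.

Per-sample species richness is a count response; the workflow mirrors the
standard ecological modelling path:

1. fit a Poisson log-linear model;
2. diagnose overdispersion via the Pearson dispersion statistic
   (sum of squared Pearson residuals over residual df) and a parametric
   bootstrap of that statistic;
3. if overdispersed, refit as negative binomial (NB2, dispersion theta
   estimated by maximum likelihood) and/or quasi-Poisson;
4. screen collinearity with generalized variance inflation factors
   (Fox-Monette), using the adjusted value GVIF^(1/(2*Df)) against a
   threshold of 2.2 (equivalent to VIF < 5 for single-df terms);
5. reduce the model by backward AIC selection respecting marginality;
6. compare factor levels through estimated marginal means with
   Tukey (studentized-range) adjusted pairwise contrasts.

Model fitting itself is delegated to statsmodels; this module owns the
design-matrix construction (treatment coding with configurable reference
levels, "factor(level)" / "a:b" column naming), the diagnostics, the
selection logic and the report format.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelSpec",
    "DesignInfo",
    "RichnessModelFit",
    "GvifReport",
    "build_design",
    "fit_count_glm",
    "pearson_dispersion",
    "dispersion_bootstrap_test",
    "gvif",
    "backward_aic",
    "posthoc_pairwise",
    "nonparametric_suite",
]

FAMILIES = ("poisson", "negative_binomial", "quasipoisson")


@dataclass(frozen=True)
class ModelSpec:
    """Symbolic model: response, additive terms, family, reference levels.

    Terms are variable names or colon-separated interactions ("year:sediment").
    Marginality is enforced: an interaction may only appear when both parent
    main effects are present.  Reference levels default to the first level in
    alphabetical order.
    """

    response: str
    terms: tuple[str, ...]
    family: str = "poisson"
    references: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        mains = {t for t in self.terms if ":" not in t}
        for t in self.terms:
            if ":" in t:
                parents = t.split(":")
                missing = [p for p in parents if p not in mains]
                if missing:
                    raise ValueError(
                        f"interaction {t!r} lacks main effect(s) {missing} (marginality)"
                    )

    def drop(self, term: str) -> "ModelSpec":
        return replace(self, terms=tuple(t for t in self.terms if t != term))

    @property
    def droppable(self) -> list[str]:
        """Terms removable without violating marginality."""
        interactions = [t for t in self.terms if ":" in t]
        protected = {p for t in interactions for p in t.split(":")}
        return [t for t in self.terms if ":" in t or t not in protected]


@dataclass
class DesignInfo:
    """Frozen encoding of a model's design matrix, reusable on new data."""

    terms: tuple[str, ...]
    factor_levels: dict[str, list[str]]  # reference level first
    numeric_vars: list[str]
    columns: list[str]
    term_columns: dict[str, list[str]]

    def _var_columns(self, var: str, df: pd.DataFrame) -> dict[str, np.ndarray]:
        """Coded columns for a single variable (indicator set or the raw column)."""
        if var in self.factor_levels:
            levels = self.factor_levels[var]
            vals = df[var].astype(str)
            unknown = set(vals) - set(levels)
            if unknown:
                raise ValueError(f"unseen level(s) {sorted(unknown)} for factor {var!r}")
            return {
                f"{var}({lvl})": (vals == lvl).to_numpy(dtype=float)
                for lvl in levels[1:]
            }
        return {var: df[var].to_numpy(dtype=float)}

    def encode(self, df: pd.DataFrame) -> pd.DataFrame:
        """Design matrix (with intercept) for ``df``, aligned to ``columns``."""
        cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(df))}
        for term in self.terms:
            parts = term.split(":")
            coded = [self._var_columns(v, df) for v in parts]
            for combo in itertools.product(*(c.items() for c in coded)):
                name = ":".join(n for n, _ in combo)
                val = np.prod([v for _, v in combo], axis=0)
                cols[name] = val
        X = pd.DataFrame(cols, index=df.index)
        return X[self.columns]


def build_design(
    spec: ModelSpec, data: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series, DesignInfo, int]:
    """Treatment-coded design matrix and response for ``spec`` on ``data``.

    Rows with missing values in any used column are dropped (their count is
    returned).  Factors are string/categorical columns; each contributes
    indicator columns against its reference level.  Interactions are element
    -wise products of the parents' coded columns, named "a:b".
    """
    variables = sorted({v for t in spec.terms for v in t.split(":")})
    used = [spec.response] + variables
    missing_cols = [c for c in used if c not in data.columns]
    if missing_cols:
        raise ValueError(f"data lacks column(s) {missing_cols}")
    complete = data[used].dropna()
    n_dropped = len(data) - len(complete)

    factor_levels: dict[str, list[str]] = {}
    numeric_vars: list[str] = []
    for v in variables:
        col = complete[v]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"factor {v!r} has a single observed level")
            ref = spec.references.get(v, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not observed for {v!r}")
            factor_levels[v] = [ref] + [l for l in levels if l != ref]
        else:
            numeric_vars.append(v)

    info = DesignInfo(
        terms=spec.terms,
        factor_levels=factor_levels,
        numeric_vars=numeric_vars,
        columns=[],
        term_columns={},
    )
    # first pass to discover column names per term
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(complete))}
    term_columns: dict[str, list[str]] = {}
    for term in spec.terms:
        parts = term.split(":")
        coded = [info._var_columns(v, complete) for v in parts]
        names = []
        for combo in itertools.product(*(c.items() for c in coded)):
            name = ":".join(n for n, _ in combo)
            cols[name] = np.prod([v for _, v in combo], axis=0)
            names.append(name)
        term_columns[term] = names
    info.columns = list(cols)
    info.term_columns = term_columns
    X = pd.DataFrame(cols, index=complete.index)
    y = complete[spec.response]
    return X, y, info, n_dropped


@dataclass
class RichnessModelFit:
    """A fitted count GLM with its diagnostics and provenance."""

    spec: ModelSpec
    table: pd.DataFrame  # coef, se, statistic, p per term-level
    family: str
    theta: float | None  # NB dispersion (variance = mu + mu^2/theta)
    phi: float | None  # quasi-Poisson Pearson scale
    aic: float | None
    null_deviance: float
    deviance: float
    df_null: int
    df_resid: int
    converged: bool
    design: DesignInfo
    X: pd.DataFrame
    y: pd.Series
    result: object  # statsmodels GLMResults

    @property
    def fitted_mu(self) -> np.ndarray:
        return np.asarray(self.result.fittedvalues)

    @property
    def cov_params(self) -> pd.DataFrame:
        return self.result.cov_params()


def _check_design(X: pd.DataFrame, y: pd.Series) -> None:
    yv = y.to_numpy()
    if np.any(yv < 0) or np.any(yv != np.floor(yv)):
        raise ValueError("response must be non-negative integers")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name aliased columns via QR pivoting
        _, r = np.linalg.qr(X.to_numpy())
        diag = np.abs(np.diag(r))
        aliased = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient (aliased: {aliased})")


def fit_count_glm(
    X: pd.DataFrame,
    y: pd.Series,
    family: str = "poisson",
    spec: ModelSpec | None = None,
    design: DesignInfo | None = None,
) -> RichnessModelFit:
    """Maximum-likelihood log-link count GLM.

    Poisson and negative binomial are likelihood fits (NB estimates theta
    jointly by ML; AIC counts theta as a parameter, as in glm.nb).
    Quasi-Poisson is a Poisson fit with the Pearson moment estimate of the
    scale phi inflating the standard errors; it has no AIC.
    """
    _check_design(X, y)
    theta = phi = aic = None
    if family == "negative_binomial":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mle = sm.NegativeBinomial(y, X, loglike_method="nb2").fit(
                disp=0, maxiter=200, method="bfgs"
            )
            alpha = float(np.clip(mle.params[-1], 1e-8, 1e8))
            theta = 1.0 / alpha
            res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        aic = float(-2 * res.llf + 2 * (X.shape[1] + 1))
        converged = bool(mle.mle_retvals.get("converged", True)) and res.converged
    else:
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        converged = res.converged
        if family == "quasipoisson":
            phi = float(res.pearson_chi2 / res.df_resid)
        else:
            aic = float(res.aic)
    if not converged:
        raise RuntimeError(f"{family} GLM did not converge")

    se = np.asarray(res.bse)
    if family == "quasipoisson":
        se = se * np.sqrt(phi)
    coef = np.asarray(res.params)
    stat = coef / se
    pvals = 2 * stats.norm.sf(np.abs(stat))
    table = pd.DataFrame(
        {"coef": coef, "se": se, "statistic": stat, "p": pvals},
        index=X.columns,
    )
    return RichnessModelFit(
        spec=spec if spec is not None else ModelSpec("y", ()),
        table=table,
        family=family,
        theta=theta,
        phi=phi,
        aic=aic,
        null_deviance=float(res.null_deviance),
        deviance=float(res.deviance),
        df_null=int(len(y) - 1),
        df_resid=int(res.df_resid),
        converged=converged,
        design=design
        if design is not None
        else DesignInfo((), {}, [], list(X.columns), {}),
        X=X,
        y=y,
        result=res,
    )


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> RichnessModelFit:
    """Convenience wrapper: build the design from ``spec`` and fit."""
    X, y, info, _ = build_design(spec, data)
    return fit_count_glm(X, y, spec.family, spec=spec, design=info)


def pearson_dispersion(fit: RichnessModelFit) -> float:
    """Sum of squared Pearson residuals over residual df (~1 if equidispersed)."""
    resid = np.asarray(fit.result.resid_pearson)
    return float(np.sum(resid**2) / fit.df_resid)


def _simulate_response(fit: RichnessModelFit, rng: np.random.Generator) -> np.ndarray:
    mu = fit.fitted_mu
    if fit.family == "negative_binomial" and fit.theta is not None:
        lam = rng.gamma(shape=fit.theta, scale=mu / fit.theta)
        return rng.poisson(lam)
    return rng.poisson(mu)


def dispersion_bootstrap_test(
    fit: RichnessModelFit, n_sim: int = 200, rng: np.random.Generator | int = 0
) -> float:
    """Parametric-bootstrap p-value for overdispersion.

    Simulates ``n_sim`` response vectors from the fitted model, refits, and
    returns the fraction of simulated Pearson dispersion statistics at least
    as large as the observed one (add-one corrected).  Small p means the
    observed dispersion is inconsistent with the fitted family.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    observed = pearson_dispersion(fit)
    if fit.family not in ("poisson", "negative_binomial"):
        raise ValueError("bootstrap test requires a likelihood family")
    exceed = 0
    for _ in range(n_sim):
        y_sim = pd.Series(_simulate_response(fit, rng), index=fit.y.index)
        sim_fit = fit_count_glm(fit.X, y_sim, fit.family)
        if pearson_dispersion(sim_fit) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_sim)


@dataclass
class GvifReport:
    """Generalized variance inflation per model term."""

    table: pd.DataFrame  # gvif, df, adjusted, passed
    threshold: float

    @property
    def all_passed(self) -> bool:
        return bool(self.table["passed"].all())


def gvif(
    X: pd.DataFrame,
    term_columns: dict[str, list[str]],
    threshold: float = 2.2,
) -> GvifReport:
    """Fox-Monette generalized VIF from the predictor correlation matrix.

    For each term, GVIF = det(R11) det(R22) / det(R) with the correlation
    matrix R of all non-intercept predictors partitioned into the term's
    columns (R11) and the rest (R22).  The adjusted value GVIF^(1/(2*Df))
    is compared against ``threshold`` (default 2.2, the analogue of
    VIF < 5); it is invariant to linear rescaling of numeric predictors.
    """
    terms = {t: cols for t, cols in term_columns.items()}
    if len(terms) < 2:
        raise ValueError("GVIF needs at least two terms")
    all_cols = [c for cols in terms.values() for c in cols]
    Z = X[all_cols].to_numpy(dtype=float)
    Z = Z - Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    if np.any(sd == 0):
        degenerate = [all_cols[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"constant predictor column(s): {degenerate}")
    R = np.corrcoef(Z, rowvar=False)
    det_R = np.linalg.det(R)
    if det_R < 1e-12:
        raise ValueError("singular predictor correlation matrix (exact collinearity)")
    rows = []
    idx = {c: i for i, c in enumerate(all_cols)}
    for term, cols in terms.items():
        i1 = [idx[c] for c in cols]
        i2 = [idx[c] for c in all_cols if c not in cols]
        g = (
            np.linalg.det(R[np.ix_(i1, i1)])
            * np.linalg.det(R[np.ix_(i2, i2)])
            / det_R
        )
        df = len(cols)
        adj = g ** (1.0 / (2.0 * df))
        rows.append(
            {"term": term, "gvif": g, "df": df, "adjusted": adj, "passed": adj < threshold}
        )
    return GvifReport(table=pd.DataFrame(rows).set_index("term"), threshold=threshold)


def backward_aic(
    spec: ModelSpec, data: pd.DataFrame, verbose: bool = False
) -> tuple[ModelSpec, RichnessModelFit, list[tuple[str, float]]]:
    """Backward AIC selection under marginality.

    Repeatedly removes the single term whose removal most lowers the AIC
    (ties broken by term name order); main effects are never dropped while
    one of their interactions survives.  Returns the reduced spec, its fit
    and the (dropped term, AIC) path; AIC is non-increasing along the path.
    """
    if spec.family == "quasipoisson":
        raise ValueError("AIC selection requires a likelihood family")
    current = spec
    fit = fit_model(current, data)
    path: list[tuple[str, float]] = [("<initial>", fit.aic)]
    while True:
        candidates = []
        for term in sorted(current.droppable):
            trial = current.drop(term)
            if not trial.terms:
                continue
            trial_fit = fit_model(trial, data)
            candidates.append((trial_fit.aic, term, trial, trial_fit))
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1]))
        best_aic, term, trial, trial_fit = candidates[0]
        if best_aic < fit.aic:
            current, fit = trial, trial_fit
            path.append((term, best_aic))
            if verbose:
                print(f"dropped {term}: AIC {best_aic:.2f}")
        else:
            break
    return current, fit, path


def posthoc_pairwise(
    fit: RichnessModelFit, factor: str, adjust: str = "tukey"
) -> pd.DataFrame:
    """Tukey-adjusted pairwise contrasts of estimated marginal means.

    Marginal means are computed on the link (log) scale by averaging the
    linear predictor over an equally weighted reference grid of the other
    factors, with numeric covariates at their observed means.  ``factor``
    may be a single factor or a colon-joined pair ("season:sediment"),
    whose joint levels are then compared.  Adjustment: "tukey"
    (studentized-range on the z statistics) or "holm".
    """
    parts = factor.split(":")
    for p in parts:
        if p not in fit.design.factor_levels:
            raise ValueError(f"{p!r} is not a factor in the fitted model")

    grid_vars = list(fit.design.factor_levels)
    level_sets = [fit.design.factor_levels[v] for v in grid_vars]
    # numeric covariates enter the grid at their observed means (their raw
    # values survive in the design matrix as single columns)
    numeric_means = {
        v: float(fit.X[v].mean()) for v in fit.design.numeric_vars if v in fit.X
    }

    rows = []
    for combo in itertools.product(*level_sets):
        row = dict(zip(grid_vars, combo))
        row.update(numeric_means)
        rows.append(row)
    grid = pd.DataFrame(rows)
    encoded = fit.design.encode(grid)

    if len(parts) == 1:
        labels = fit.design.factor_levels[parts[0]]
        groups = {lvl: grid[parts[0]] == lvl for lvl in labels}
    else:
        labels = [
            ":".join(c)
            for c in itertools.product(*(fit.design.factor_levels[p] for p in parts))
        ]
        groups = {
            lab: np.logical_and.reduce(
                [grid[p] == lvl for p, lvl in zip(parts, lab.split(":"))]
            )
            for lab in labels
        }

    beta = fit.table["coef"].to_numpy()
    cov = np.asarray(fit.cov_params)
    L = {lab: encoded[np.asarray(mask)].mean(axis=0).to_numpy() for lab, mask in groups.items()}

    k = len(labels)
    out = []
    for a, b in itertools.combinations(labels, 2):
        l = L[a] - L[b]
        est = float(l @ beta)
        se = float(np.sqrt(l @ cov @ l))
        z = est / se
        out.append({"contrast": f"{a} - {b}", "estimate": est, "se": se, "statistic": z})
    res = pd.DataFrame(out)
    if adjust == "tukey":
        q = np.abs(res["statistic"]) * np.sqrt(2.0)
        res["p_adj"] = stats.studentized_range.sf(q, k, 1e6)
    elif adjust == "holm":
        raw = 2 * stats.norm.sf(np.abs(res["statistic"]))
        res["p_adj"] = _holm(raw)
    else:
        raise ValueError("adjust must be 'tukey' or 'holm'")
    return res


def _holm(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def nonparametric_suite(values: pd.Series, groups: pd.Series) -> dict:
    """Distribution-free group comparison of richness.

    Returns Shapiro-Wilk normality tests per group, the Kruskal-Wallis
    omnibus test, and all pairwise two-sided Mann-Whitney tests with Holm
    adjustment.  The pairwise tests use the normal approximation without
    continuity correction, so with two groups the Mann-Whitney p-value
    coincides with the Kruskal-Wallis chi-square p-value on tie-free data.
    Groups with fewer than two observations are excluded (with a warning
    entry in the report).
    """
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    sizes = df.groupby("group")["value"].count()
    excluded = sizes[sizes < 2].index.tolist()
    kept = sizes[sizes >= 2].index.tolist()
    if len(kept) < 2:
        raise ValueError("need at least two groups with >= 2 observations")
    df = df[df["group"].isin(kept)]

    shapiro_rows = []
    for g in kept:
        vals = df.loc[df["group"] == g, "value"].to_numpy(dtype=float)
        if len(vals) >= 3 and np.ptp(vals) > 0:
            w, p = stats.shapiro(vals)
        else:
            w, p = np.nan, np.nan
        shapiro_rows.append({"group": g, "n": len(vals), "W": w, "p": p})

    samples = [df.loc[df["group"] == g, "value"].to_numpy(dtype=float) for g in kept]
    H, kw_p = stats.kruskal(*samples)

    pair_rows = []
    for (ga, va), (gb, vb) in itertools.combinations(zip(kept, samples), 2):
        u, p = stats.mannwhitneyu(
            va, vb, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        pair_rows.append({"group_a": ga, "group_b": gb, "U": u, "p_raw": p})
    pairs = pd.DataFrame(pair_rows)
    if len(pairs):
        pairs["p_holm"] = _holm(pairs["p_raw"].to_numpy())

    return {
        "shapiro": pd.DataFrame(shapiro_rows),
        "kruskal": {"H": float(H), "p": float(kw_p), "groups": kept},
        "pairwise": pairs,
        "excluded_groups": excluded,
    }
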