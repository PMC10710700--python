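"""Binomial mixed-model workflow: screening, thinning, GLMM, model averaging.

The modelling layer reproduces a standard movement-ecology workflow:

* predictors are standardized (mean 0, SD 1) so coefficients are comparable;
* collinear predictors (|Pearson r| >= 0.6) are screened, dropping the
  lower-priority member of each offending pair;
* 1 Hz behavioural series are thinned to one record per 30 s (response at
  the block's first fix, covariates block-averaged) to tame residual
  autocorrelation;
* a binomial logit GLMM with a per-individual random intercept is fitted by
  maximizing the exact marginal likelihood via Gauss-Hermite quadrature
  (a random-intercept-only model has a one-dimensional integral per
  individual, so quadrature is both fast and accurate; Laplace is the
  special case of one node);
* all fixed-effect subsets that respect marginality are ranked by AIC or
  AICc and the models within 2 of the best are averaged with Akaike
  weights (full, zero-substituting averaging by default);
* predictive accuracy is 10-fold cross-validated proportion-correct at a
  0.5 probability cutoff, and variance explained follows the
  variance-partition (latent-scale) R2 for logit models:
  R2_marginal = var_fixed / (var_fixed + var_RE + pi^2/3), with the random
  intercept variance joining the numerator for R2_conditional.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats as sps
from statsmodels.tools import numdiff

DEFAULT_PRIORITY = ("tailwind", "delta_T", "sidewind", "precip", "cloud")

__all__ = [
    "standardize",
    "collinearity_screen",
    "thin_30s",
    "orthogonal_poly",
    "ModelSpec",
    "GLMMResult",
    "fit_glmm",
    "fit_model",
    "dredge_average",
    "kfold_accuracy",
    "nakagawa_r2",
    "compare_metrics",
    "chi_square_counts",
]


# ---------------------------------------------------------------------------
# Table preparation
# ---------------------------------------------------------------------------


def standardize(table: pd.DataFrame, columns) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale columns to mean 0, SD 1 (SD with n-1); returns (table, scaling).

    The scaling frame records each column's original mean and SD for
    back-transformation.  A constant column cannot be standardized and
    raises ``ValueError``.
    """
    out = table.copy()
    recs = []
    for c in columns:
        x = out[c].astype(float)
        mu, sd = x.mean(), x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {c!r} has zero variance; cannot standardize")
        out[c] = (x - mu) / sd
        recs.append({"column": c, "mean": mu, "sd": sd})
    return out, pd.DataFrame(recs).set_index("column")


def collinearity_screen(
    table: pd.DataFrame, columns, r_max: float = 0.6, priority=DEFAULT_PRIORITY
):
    """Drop the lower-priority member of each highly correlated pair.

    Pairs with |Pearson r| >= ``r_max`` are resolved iteratively, worst pair
    first.  Priority follows the given order; columns not listed rank after
    all listed ones, in table order.  Returns (retained, report) where the
    report lists each dropped column with the offending partner and r.
    """
    columns = list(columns)

    def rank(c):
        return priority.index(c) if c in priority else len(priority) + columns.index(c)

    retained = list(columns)
    report = []
    while True:
        corr = table[retained].corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        if np.abs(corr[i, j]) < r_max:
            break
        a, b = retained[i], retained[j]
        drop = a if rank(a) > rank(b) else b
        keep = b if drop == a else a
        report.append({"dropped": drop, "kept": keep, "r": float(corr[i, j])})
        retained.remove(drop)
        if len(retained) < 2:
            break
    return retained, pd.DataFrame(report, columns=["dropped", "kept", "r"])


def thin_30s(
    fixes: pd.DataFrame,
    block_s: int = 30,
    response_col: str = "behavior",
    covariate_cols=("tailwind", "sidewind", "delta_T", "cloud", "precip"),
    burst_col: str = "burst_id",
) -> pd.DataFrame:
    """One record per non-overlapping 30 s block of a 1 Hz burst.

    The response is taken at the block's first fix; covariates are block
    means.  Incomplete trailing blocks are dropped.
    """
    covariate_cols = [c for c in covariate_cols if c in fixes.columns]
    rows = []
    for (bird, burst), g in fixes.groupby(["bird_id", burst_col], sort=True):
        g = g.sort_values("timestamp").reset_index(drop=True)
        n_blocks = len(g) // block_s
        for k in range(n_blocks):
            block = g.iloc[k * block_s : (k + 1) * block_s]
            rec = {
                "bird_id": bird,
                burst_col: burst,
                "timestamp": block["timestamp"].iloc[0],
                response_col: block[response_col].iloc[0],
            }
            for c in covariate_cols:
                rec[c] = block[c].mean()
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model terms and design matrices
# ---------------------------------------------------------------------------

_POLY_RE = re.compile(r"^poly\((\w+),\s*(\d+)\)$")


def orthogonal_poly(x, degree: int) -> np.ndarray:
    """Orthogonal polynomial basis of a covariate (R ``poly()`` convention).

    Columns are mutually orthogonal, orthogonal to the intercept, and scaled
    to unit sum of squares; the linear column correlates positively with x.
    A raw basis is available via :func:`raw_poly`.
    """
    x = np.asarray(x, dtype=float)
    V = np.vander(x - x.mean(), degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    Z = Q[:, 1:]
    for j in range(Z.shape[1]):
        lead = np.corrcoef(Z[:, j], x ** (j + 1))[0, 1]
        if lead < 0:
            Z[:, j] = -Z[:, j]
    return Z


def raw_poly(x, degree: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.column_stack([x ** (d + 1) for d in range(degree)])


@dataclass(frozen=True)
class _Term:
    name: str
    kind: str  # main | poly | interaction
    variables: tuple
    degree: int = 1

    @property
    def columns(self):
        if self.kind == "poly":
            return tuple(f"{self.name}{d + 1}" for d in range(self.degree))
        return (self.name,)


def _parse_term(name: str) -> _Term:
    m = _POLY_RE.match(name)
    if m:
        return _Term(name, "poly", (m.group(1),), int(m.group(2)))
    if ":" in name:
        a, b = name.split(":")
        return _Term(name, "interaction", (a.strip(), b.strip()))
    return _Term(name, "main", (name,))


def _term_columns(term: _Term, table: pd.DataFrame, poly_basis: str = "orthogonal"):
    if term.kind == "main":
        return {term.name: table[term.name].to_numpy(dtype=float)}
    if term.kind == "poly":
        basis = orthogonal_poly if poly_basis == "orthogonal" else raw_poly
        Z = basis(table[term.variables[0]].to_numpy(dtype=float), term.degree)
        return {c: Z[:, j] for j, c in enumerate(term.columns)}
    a, b = term.variables
    return {term.name: table[a].to_numpy(dtype=float) * table[b].to_numpy(dtype=float)}


@dataclass
class ModelSpec:
    """One GLMM family: response, fixed terms, random intercept, criterion.

    Term syntax: plain column names, ``poly(col,2)`` for an orthogonal
    quadratic (kept as a unit by the subset generator) and ``a:b`` for an
    interaction (included only when both mains are, respecting marginality).
    """

    response: str
    terms: list
    group: str | None = "bird_id"
    criterion: str = "AIC"
    poly_basis: str = "orthogonal"

    def parsed(self):
        terms = [_parse_term(t) for t in self.terms]
        names = [t.name for t in terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate model terms")
        return terms

    def design(self, table, subset=None):
        """(y, X) for a subset of term names (default: all terms)."""
        terms = self.parsed()
        if subset is not None:
            terms = [t for t in terms if t.name in set(subset)]
        cols = {}
        for t in terms:
            cols.update(_term_columns(t, table, self.poly_basis))
        X = pd.DataFrame(cols, index=table.index)
        y = table[self.response].to_numpy(dtype=int)
        return y, X


# ---------------------------------------------------------------------------
# The binomial random-intercept GLMM
# ---------------------------------------------------------------------------


@dataclass
class GLMMResult:
    params: pd.Series
    bse: pd.Series
    loglik: float
    n: int
    k_params: int
    sigma_re: float
    converged: bool
    method: str = "glmm-ghq"

    @property
    def zvalues(self):
        return self.params / self.bse

    @property
    def pvalues(self):
        return pd.Series(2 * sps.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    @property
    def aic(self):
        return 2 * self.k_params - 2 * self.loglik

    @property
    def aicc(self):
        k = self.k_params
        denom = self.n - k - 1
        if denom <= 0:
            return np.inf
        return self.aic + 2 * k * (k + 1) / denom

    def criterion(self, which="AIC"):
        return self.aic if which.upper() == "AIC" else self.aicc

    def predict_marginal(self, X: pd.DataFrame):
        """P(y=1) for new data at random effect 0 (new-individual prediction)."""
        Xd = np.column_stack([np.ones(len(X)), X[[c for c in self.params.index if c != "(Intercept)"]]])
        return special.expit(Xd @ self.params.to_numpy())


def _group_codes(groups):
    codes, _ = pd.factorize(np.asarray(groups))
    return codes


def _make_nll(y, Xd, codes, n_quad):
    """Marginal negative log-likelihood via Gauss-Hermite quadrature."""
    order = np.argsort(codes, kind="stable")
    y_s = y[order].astype(float)
    X_s = Xd[order]
    c_s = codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(c_s) > 0])
    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_quad)
    nodes = gh_x * np.sqrt(2.0)  # N(0,1) quadrature points
    logw = np.log(gh_w) - 0.5 * np.log(np.pi)
    p = Xd.shape[1]

    def nll(theta):
        beta = theta[:p]
        sigma = np.exp(theta[p])
        eta = X_s @ beta
        lp = eta[:, None] + sigma * nodes[None, :]
        ll = y_s[:, None] * lp - np.logaddexp(0.0, lp)  # (n, K)
        S = np.add.reduceat(ll, starts, axis=0)  # (G, K)
        return -float(special.logsumexp(S + logw[None, :], axis=1).sum())

    return nll


def fit_glmm(
    y,
    X: pd.DataFrame,
    groups=None,
    n_quad: int = 25,
    start_log_sigma: float = np.log(0.5),
) -> GLMMResult:
    """Binomial logit fit; random intercept per group when ``groups`` given.

    The mixed model maximizes the exact marginal likelihood, integrating
    the per-group intercept with ``n_quad``-point Gauss-Hermite quadrature.
    Standard errors come from the numerically differentiated observed
    information.  Without ``groups`` this is an ordinary logistic
    regression (fitted through statsmodels GLM).
    """
    y = np.asarray(y, dtype=int)
    names = ["(Intercept)", *X.columns]
    Xd = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])

    glm = sm.GLM(y, Xd, family=sm.families.Binomial()).fit()
    if groups is None:
        return GLMMResult(
            params=pd.Series(glm.params, index=names),
            bse=pd.Series(glm.bse, index=names),
            loglik=float(glm.llf),
            n=len(y),
            k_params=Xd.shape[1],
            sigma_re=0.0,
            converged=bool(glm.converged),
            method="glm",
        )

    codes = _group_codes(groups)
    if np.unique(codes).size < 2:
        raise ValueError("random intercept needs at least 2 groups")
    nll = _make_nll(y, Xd, codes, n_quad)
    p = Xd.shape[1]
    theta0 = np.r_[glm.params, start_log_sigma]
    opt = optimize.minimize(nll, theta0, method="BFGS", options={"gtol": 1e-6, "maxiter": 500})
    theta = opt.x

    H = numdiff.approx_hess1(theta, nll)
    converged = bool(opt.success)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov)[:p])
        if not np.all(np.isfinite(se)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        d = np.abs(np.diag(cov)[:p])
        se = np.sqrt(d)
        converged = False

    return GLMMResult(
        params=pd.Series(theta[:p], index=names),
        bse=pd.Series(se, index=names),
        loglik=-float(opt.fun),
        n=len(y),
        k_params=p + 1,
        sigma_re=float(np.exp(theta[p])),
        converged=converged,
    )


def fit_model(spec: ModelSpec, table: pd.DataFrame, subset=None) -> GLMMResult:
    """Fit one (sub)model of a spec on a prepared (standardized) table."""
    y, X = spec.design(table, subset)
    groups = table[spec.group] if spec.group else None
    return fit_glmm(y, X, groups)


# ---------------------------------------------------------------------------
# All-subsets averaging (dredge)
# ---------------------------------------------------------------------------


def _admissible_subsets(terms):
    names = [t.name for t in terms]
    providers = {}
    for t in terms:
        if t.kind in ("main", "poly"):
            providers[t.variables[0]] = t.name
    subsets = []
    for r in range(len(names) + 1):
        for combo in itertools.combinations(names, r):
            ok = True
            for t in terms:
                if t.kind == "interaction" and t.name in combo:
                    for v in t.variables:
                        if providers.get(v) not in combo:
                            ok = False
            if ok:
                subsets.append(tuple(combo))
    return subsets


@dataclass
class ModelResult:
    """Averaged fixed effects for one model family (plus fit diagnostics)."""

    table: pd.DataFrame  # estimate, se, z, p per design column
    n_models_averaged: int
    model_table: pd.DataFrame  # every admissible subset with criterion, delta, weight
    best_terms: tuple
    r2_marginal: float
    r2_conditional: float
    predictive_accuracy: float = np.nan
    averaging: str = "full"

    def to_json_dict(self):
        return {
            "coefficients": self.table.reset_index().rename(columns={"index": "predictor"}).to_dict("records"),
            "n_models_averaged": self.n_models_averaged,
            "best_terms": list(self.best_terms),
            "R2_marginal": self.r2_marginal,
            "R2_conditional": self.r2_conditional,
            "predictive_accuracy": self.predictive_accuracy,
        }


def dredge_average(
    spec: ModelSpec,
    table: pd.DataFrame,
    delta: float = 2.0,
    averaging: str = "full",
    kfold: int = 0,
    kfold_seed: int = 0,
) -> ModelResult:
    """Fit all marginality-respecting fixed-term subsets and average the best.

    Models within ``delta`` of the lowest criterion are averaged with Akaike
    weights.  ``averaging="full"`` substitutes zero for a term absent from a
    model (shrinking weakly supported effects); ``"conditional"`` averages
    only over the models containing the term.  Unconditional standard errors
    follow the usual model-averaging formula
    ``sum_m w_m * sqrt(se_m^2 + (b_m - b_avg)^2)``.

    Set ``kfold`` to also cross-validate the best model's accuracy.
    """
    terms = spec.parsed()
    subsets = _admissible_subsets(terms)
    fits = {}
    rows = []
    for sub in subsets:
        res = fit_model(spec, table, sub)
        if not np.all(np.isfinite(res.bse)):
            continue  # non-convergent fit: excluded from ranking/averaging
        fits[sub] = res
        rows.append({"terms": sub, "k": res.k_params, "criterion": res.criterion(spec.criterion)})
    if not fits:
        raise RuntimeError("no model in the set converged")
    model_table = pd.DataFrame(rows).sort_values("criterion").reset_index(drop=True)
    best_crit = model_table["criterion"].iloc[0]
    model_table["delta"] = model_table["criterion"] - best_crit
    in_set = model_table["delta"] < delta
    w = np.exp(-model_table.loc[in_set, "delta"].to_numpy() / 2.0)
    w = w / w.sum()
    model_table["weight"] = 0.0
    model_table.loc[in_set, "weight"] = w

    _, X_full = spec.design(table)
    columns = ["(Intercept)", *X_full.columns]
    est = pd.Series(0.0, index=columns)
    avg_rows = {c: [] for c in columns}  # (weight, b, se) triples
    for _, mrow in model_table[in_set].iterrows():
        res = fits[mrow["terms"]]
        for c in columns:
            b = float(res.params.get(c, 0.0))
            s = float(res.bse.get(c, 0.0))
            present = c in res.params.index
            avg_rows[c].append((mrow["weight"], b, s, present))

    out = []
    for c in columns:
        triples = avg_rows[c]
        if averaging == "conditional":
            wsum = sum(wt for wt, _, _, pres in triples if pres)
            if wsum == 0:
                out.append({"estimate": 0.0, "se": np.nan})
                continue
            b_avg = sum(wt * b for wt, b, _, pres in triples if pres) / wsum
            se = sum(wt * np.sqrt(s**2 + (b - b_avg) ** 2) for wt, b, s, pres in triples if pres) / wsum
        else:
            b_avg = sum(wt * b for wt, b, _, _ in triples)
            se = sum(wt * np.sqrt(s**2 + (b - b_avg) ** 2) for wt, b, s, _ in triples)
        out.append({"estimate": b_avg, "se": se})
    coef = pd.DataFrame(out, index=columns)
    coef["z"] = coef["estimate"] / coef["se"]
    coef["p"] = 2 * sps.norm.sf(np.abs(coef["z"]))

    best_terms = model_table["terms"].iloc[0]
    best_fit = fits[best_terms]
    r2m, r2c = nakagawa_r2(best_fit, spec.design(table, best_terms)[1])
    acc = np.nan
    if kfold:
        acc = kfold_accuracy(spec, table, k=kfold, seed=kfold_seed, subset=best_terms)
    return ModelResult(
        table=coef,
        n_models_averaged=int(in_set.sum()),
        model_table=model_table,
        best_terms=best_terms,
        r2_marginal=r2m,
        r2_conditional=r2c,
        predictive_accuracy=acc,
        averaging=averaging,
    )


# ---------------------------------------------------------------------------
# Model quality
# ---------------------------------------------------------------------------


def nakagawa_r2(result: GLMMResult, X: pd.DataFrame):
    """(R2_marginal, R2_conditional) on the latent logit scale.

    var_fixed is the sample variance of the fixed-effect linear predictor;
    the logit link contributes pi^2/3 of residual latent variance.
    """
    cols = [c for c in result.params.index if c != "(Intercept)"]
    Xd = np.column_stack([np.ones(len(X)), X[cols].to_numpy(dtype=float)]) if cols else np.ones((len(X), 1))
    eta = Xd @ result.params.to_numpy()
    var_f = float(np.var(eta))
    var_re = result.sigma_re**2
    denom = var_f + var_re + np.pi**2 / 3.0
    return var_f / denom, (var_f + var_re) / denom


def kfold_accuracy(
    spec: ModelSpec, table: pd.DataFrame, k: int = 10, seed: int = 0, subset=None, cutoff: float = 0.5
) -> float:
    """k-fold cross-validated proportion correct at a probability cutoff.

    Rows are stratified by the response so every fold sees both classes;
    held-out rows are predicted at random effect 0.
    """
    rng = np.random.default_rng(seed)
    y = table[spec.response].to_numpy(dtype=int)
    fold = np.empty(len(table), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % k
    accs = []
    for f in range(k):
        train = table[fold != f]
        test = table[fold == f]
        if test.empty or train[spec.response].nunique() < 2:
            continue
        res = fit_model(spec, train, subset)
        _, X_test = spec.design(test, subset)
        pred = (res.predict_marginal(X_test) >= cutoff).astype(int)
        accs.append(np.mean(pred == test[spec.response].to_numpy(dtype=int)))
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


def compare_metrics(group_a, group_b) -> dict:
    """Shapiro-Wilk normality per group + two-sided Mann-Whitney U.

    The Mann-Whitney test is the primary comparison (the flight metrics are
    generally non-normal); Shapiro-Wilk documents why.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    sw_a = sps.shapiro(a) if a.size >= 3 else (np.nan, np.nan)
    sw_b = sps.shapiro(b) if b.size >= 3 else (np.nan, np.nan)
    mw = sps.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "shapiro_a": (float(sw_a[0]), float(sw_a[1])),
        "shapiro_b": (float(sw_b[0]), float(sw_b[1])),
        "mannwhitney_U": float(mw.statistic),
        "mannwhitney_p": float(mw.pvalue),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


def chi_square_counts(table) -> dict:
    """Classic (uncorrected) chi-square test on a contingency table."""
    res = sps.chi2_contingency(np.asarray(table), correction=False)
    return {"chi2": float(res.statistic), "p": float(res.pvalue), "dof": int(res.dof)}
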