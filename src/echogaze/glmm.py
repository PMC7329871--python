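"""Mixed-effect models for the behavioural analyses.

The battery mirrors the study's statistical design: every model carries
a bat-ID random intercept; responses are either Gaussian (maximum
flight speed) or Poisson counts with a log link (pulse counts, delta
pulse direction); fixed effects are cells of condition x flight-number
(x section) or a standardised speed covariate, with interactions.

Model objects follow the statsmodels idiom: construct from a tidy
DataFrame, call :meth:`fit`, get a results object with coefficient
table, Wald type-II tests, estimated marginal means with Tukey-adjusted
pairwise contrasts, AICc, Nakagawa R2, overdispersion and a seeded
parametric bootstrap against a null model.

The Gaussian LMM delegates to statsmodels ``MixedLM`` (ML, so that
likelihoods are comparable across fixed-effect structures).  The
Poisson GLMM is fitted by maximum likelihood with an adaptive
Gauss-Hermite quadrature over the random intercept (the same scheme
lme4's ``glmer`` uses), since no ML Poisson GLMM is available in the
scientific Python stack.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

DEFAULT_FACTORS = ("condition", "flight_number", "section")


class ConvergenceWarningError(RuntimeError):
    """Optimiser failed to converge."""


# ---------------------------------------------------------------------------
# design matrices


class Design:
    """Treatment-coded design matrix with named term blocks.

    ``terms`` are strings such as ``"condition"``, ``"flight_number"``,
    ``"speed_z"`` or ``"condition:flight_number"``.  Variables listed in
    ``factors`` are coded as treatment dummies against their first
    (sorted) level; other variables enter numerically.
    """

    def __init__(self, data: pd.DataFrame, terms, factors=DEFAULT_FACTORS):
        self.terms = [tuple(t.split(":")) for t in terms]
        self.factors = set(factors) & {v for t in self.terms for v in t}
        self.levels = {v: sorted(pd.unique(data[v])) for v in self.factors}
        self.numeric_means = {
            v: float(np.mean(data[v]))
            for t in self.terms for v in t if v not in self.factors}
        self.column_names = ["Intercept"]
        self.term_slices = {"Intercept": [0]}
        col = 1
        for t in self.terms:
            name = ":".join(t)
            cols = []
            for combo in self._level_combos(t):
                label = name + "[" + ",".join(str(c) for c in combo if c is not None) + "]" \
                    if any(c is not None for c in combo) else name
                self.column_names.append(label)
                cols.append(col)
                col += 1
            self.term_slices[name] = cols
        self.n_columns = col

    def _level_combos(self, term):
        """Non-reference level combinations for one term."""
        opts = []
        for v in term:
            if v in self.factors:
                opts.append(self.levels[v][1:])  # drop reference level
            else:
                opts.append([None])  # numeric: single column
        return list(itertools.product(*opts))

    def matrix(self, data: pd.DataFrame) -> np.ndarray:
        n = len(data)
        X = np.zeros((n, self.n_columns))
        X[:, 0] = 1.0
        col = 1
        for t in self.terms:
            for combo in self._level_combos(t):
                x = np.ones(n)
                for v, lev in zip(t, combo):
                    if v in self.factors:
                        x = x * (np.asarray(data[v]) == lev)
                    else:
                        x = x * np.asarray(data[v], dtype=float)
                X[:, col] = x
                col += 1
        return X

    def reference_grid(self, groupby) -> pd.DataFrame:
        """All factor-level combinations, numeric covariates at their mean."""
        groupby = [groupby] if isinstance(groupby, str) else list(groupby)
        grid_vars = [v for v in self.levels] + list(self.numeric_means)
        rows = []
        factor_vars = list(self.levels)
        for combo in itertools.product(*[self.levels[v] for v in factor_vars]):
            row = dict(zip(factor_vars, combo))
            row.update(self.numeric_means)
            rows.append(row)
        grid = pd.DataFrame(rows) if rows else pd.DataFrame([self.numeric_means])
        missing = [g for g in groupby if g not in grid.columns]
        if missing:
            raise ValueError(f"grouping variables not in model: {missing}")
        return grid


# ---------------------------------------------------------------------------
# model base


class _MixedModelBase:
    """Shared construction and simulation for the two families."""

    family: str = ""

    def __init__(self, endog, data: pd.DataFrame, terms, groups,
                 factors=DEFAULT_FACTORS):
        self.data = data.reset_index(drop=True)
        if isinstance(endog, str):
            self.endog_name = endog
            self.endog = np.asarray(self.data[endog], dtype=float)
        else:
            self.endog_name = "y"
            self.endog = np.asarray(endog, dtype=float)
        self.design = Design(self.data, terms, factors)
        self.exog = self.design.matrix(self.data)
        group_vals = np.asarray(self.data[groups])
        self.group_name = groups
        self.group_labels, self.group_idx = np.unique(group_vals, return_inverse=True)
        self.n_groups = len(self.group_labels)
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups for a random intercept")
        self.n_obs = len(self.endog)
        self.terms = terms

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, terms,
                       groups: str = "bat_id", factors=DEFAULT_FACTORS):
        return cls(response, data, terms, groups, factors=factors)

    def refit_with_response(self, y):
        """Same design, new response (parametric-bootstrap refits)."""
        new = object.__new__(type(self))
        new.__dict__.update(self.__dict__)
        new.endog = np.asarray(y, dtype=float)
        return new


# ---------------------------------------------------------------------------
# Poisson GLMM (log link, single random intercept, adaptive Gauss-Hermite ML)


class PoissonGLMM(_MixedModelBase):
    family = "poisson"

    def __init__(self, endog, data, terms, groups, factors=DEFAULT_FACTORS,
                 n_quad: int = 15):
        super().__init__(endog, data, terms, groups, factors)
        if np.any(self.endog < 0) or np.any(self.endog != np.round(self.endog)):
            raise ValueError("Poisson response must be non-negative integers")
        z, w = np.polynomial.hermite.hermgauss(n_quad)
        self._gh_z, self._gh_logw = z, np.log(w)
        self._ll_const = -float(np.sum(gammaln(self.endog + 1.0)))

    # -- likelihood ---------------------------------------------------

    def _posterior_modes(self, eta0, sigma2):
        """Per-group modes of the random-intercept posterior (Newton)."""
        y_sum = np.bincount(self.group_idx, weights=self.endog,
                            minlength=self.n_groups)
        u = np.zeros(self.n_groups)
        for _ in range(50):
            mu = np.exp(np.clip(eta0 + u[self.group_idx], -50, 50))
            mu_sum = np.bincount(self.group_idx, weights=mu, minlength=self.n_groups)
            g1 = y_sum - mu_sum - u / sigma2
            g2 = -mu_sum - 1.0 / sigma2
            step = g1 / g2
            u = u - np.clip(step, -5.0, 5.0)
            if np.max(np.abs(step)) < 1e-9:
                break
        mu = np.exp(np.clip(eta0 + u[self.group_idx], -50, 50))
        mu_sum = np.bincount(self.group_idx, weights=mu, minlength=self.n_groups)
        return u, mu_sum + 1.0 / sigma2  # mode, negative curvature

    def loglike(self, params) -> float:
        beta, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
        sigma2 = sigma ** 2
        eta0 = self.exog @ beta
        u_hat, neg_curv = self._posterior_modes(eta0, sigma2)
        tau = 1.0 / np.sqrt(neg_curv)
        # adaptive nodes: (n_groups, n_quad)
        nodes = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * self._gh_z[None, :]
        eta = np.clip(eta0[:, None] + nodes[self.group_idx, :], -50, 50)
        contrib = self.endog[:, None] * eta - np.exp(eta)
        gsum = np.zeros((self.n_groups, nodes.shape[1]))
        np.add.at(gsum, self.group_idx, contrib)
        h = gsum - nodes ** 2 / (2.0 * sigma2)
        lse_in = h + (self._gh_logw + self._gh_z ** 2)[None, :]
        hmax = lse_in.max(axis=1, keepdims=True)
        log_int = (hmax[:, 0] + np.log(np.sum(np.exp(lse_in - hmax), axis=1))
                   + 0.5 * np.log(2.0) + np.log(tau))
        ll = np.sum(log_int) - self.n_groups * (0.5 * np.log(2 * np.pi) + np.log(sigma))
        return float(ll + self._ll_const)

    # -- fitting ------------------------------------------------------

    def _start_params(self):
        """Pooled Poisson GLM Newton iterations for starting betas."""
        X, y = self.exog, self.endog
        beta = np.zeros(X.shape[1])
        beta[0] = np.log(max(y.mean(), 0.1))
        for _ in range(8):
            mu = np.exp(np.clip(X @ beta, -30, 30))
            W = mu
            XtWX = X.T @ (X * W[:, None]) + 1e-8 * np.eye(X.shape[1])
            score = X.T @ (y - mu)
            try:
                beta = beta + np.linalg.solve(XtWX, score)
            except np.linalg.LinAlgError:
                break
        return np.concatenate([beta, [np.log(0.2)]])

    def fit(self, start_params=None, gtol: float = 1e-6,
            compute_cov: bool = True) -> "MixedModelResults":
        x0 = self._start_params() if start_params is None else np.asarray(start_params)
        neg = lambda p: -self.loglike(p)
        bounds = [(None, None)] * (len(x0) - 1) + [(np.log(1e-4), np.log(10.0))]
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-11,
                                         "gtol": gtol})
        params = res.x
        cov = (_numeric_cov(self.loglike, params) if compute_cov
               else np.zeros((len(params), len(params))))
        sigma_u = float(np.exp(params[-1]))
        return MixedModelResults(
            model=self, fe_params=params[:-1], cov_fe=cov[:-1, :-1],
            sigma_u=sigma_u, scale=None, llf=float(-res.fun),
            converged=bool(res.success), raw_params=params)

    def simulate(self, fe_params, sigma_u, rng) -> np.ndarray:
        u = rng.normal(0.0, sigma_u, size=self.n_groups)
        mu = np.exp(np.clip(self.exog @ fe_params + u[self.group_idx], -30, 30))
        return rng.poisson(mu).astype(float)


# ---------------------------------------------------------------------------
# Gaussian LMM via statsmodels MixedLM


class LinearMM(_MixedModelBase):
    family = "gaussian"

    def fit(self, **kwargs) -> "MixedModelResults":
        import warnings
        from statsmodels.regression.mixed_linear_model import MixedLM
        mod = MixedLM(self.endog, self.exog, groups=self.group_idx)
        res = None
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "bfgs", "powell"):
                try:
                    res = mod.fit(reml=False, method=method, maxiter=500)
                    break
                except (np.linalg.LinAlgError, ValueError):
                    continue
        if res is None:
            return self._fit_boundary()
        sigma_u = float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0)))
        return MixedModelResults(
            model=self, fe_params=np.asarray(res.fe_params),
            cov_fe=np.asarray(res.cov_params())[:self.exog.shape[1], :self.exog.shape[1]],
            sigma_u=sigma_u, scale=float(np.sqrt(res.scale)),
            llf=float(res.llf), converged=bool(res.converged),
            raw_params=None, _sm_results=res)

    def _fit_boundary(self) -> "MixedModelResults":
        """ML fit at the sigma_u = 0 boundary (plain regression)."""
        X, y = self.exog, self.endog
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        n = self.n_obs
        s2 = float(resid @ resid) / n
        llf = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
        cov = s2 * np.linalg.pinv(X.T @ X)
        return MixedModelResults(model=self, fe_params=beta, cov_fe=cov,
                                 sigma_u=0.0, scale=float(np.sqrt(s2)),
                                 llf=float(llf), converged=True,
                                 raw_params=None)

    def simulate(self, fe_params, sigma_u, rng, scale=1.0) -> np.ndarray:
        u = rng.normal(0.0, sigma_u, size=self.n_groups)
        return (self.exog @ fe_params + u[self.group_idx]
                + rng.normal(0.0, scale, size=self.n_obs))


def _numeric_cov(loglike, params, eps: float = 1e-4) -> np.ndarray:
    """Covariance from a central-difference Hessian of the loglik."""
    k = len(params)
    H = np.zeros((k, k))
    f0 = loglike(params)
    steps = eps * np.maximum(np.abs(params), 1.0)
    for i in range(k):
        for j in range(i, k):
            pi, pj = steps[i], steps[j]
            if i == j:
                fp = loglike(params + _e(k, i, pi))
                fm = loglike(params - _e(k, i, pi))
                H[i, i] = (fp - 2 * f0 + fm) / pi ** 2
            else:
                fpp = loglike(params + _e(k, i, pi) + _e(k, j, pj))
                fpm = loglike(params + _e(k, i, pi) - _e(k, j, pj))
                fmp = loglike(params - _e(k, i, pi) + _e(k, j, pj))
                fmm = loglike(params - _e(k, i, pi) - _e(k, j, pj))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * pi * pj)
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-H)
    return cov


def _e(k, i, step):
    v = np.zeros(k)
    v[i] = step
    return v


# ---------------------------------------------------------------------------
# results


@dataclass
class MixedModelResults:
    """Coefficients, diagnostics and post-hoc machinery of one fit."""

    model: _MixedModelBase
    fe_params: np.ndarray
    cov_fe: np.ndarray
    sigma_u: float
    scale: float | None   # residual SD (gaussian only)
    llf: float
    converged: bool
    raw_params: np.ndarray | None = None
    _sm_results: object = None

    # -- basics -------------------------------------------------------

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.cov_fe), 0.0))

    @property
    def n_params(self) -> int:
        """Fixed effects + random-intercept SD (+ residual SD)."""
        extra = 2 if self.model.family == "gaussian" else 1
        return len(self.fe_params) + extra

    @property
    def df_resid(self) -> float:
        return self.model.n_obs - len(self.fe_params) - 1

    @property
    def singular(self) -> bool:
        return self.sigma_u < 1e-3

    def aicc(self) -> float:
        k, n = self.n_params, self.model.n_obs
        pen = 2.0 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf
        return -2.0 * self.llf + 2.0 * k + pen

    def fitted_linpred(self) -> np.ndarray:
        return self.model.exog @ self.fe_params

    # -- marginal means ----------------------------------------------

    def _emm_matrix(self, groupby):
        groupby = [groupby] if isinstance(groupby, str) else list(groupby)
        grid = self.model.design.reference_grid(groupby)
        Xg = self.model.design.matrix(grid)
        labels, rows = [], []
        for combo, sub in grid.groupby(groupby, sort=True):
            combo = combo if isinstance(combo, tuple) else (combo,)
            labels.append(combo)
            rows.append(Xg[sub.index.to_numpy()].mean(axis=0))
        return groupby, labels, np.asarray(rows)

    def marginal_means(self, groupby, level: float = 0.95) -> pd.DataFrame:
        """Estimated marginal means on the response scale with CIs.

        Cell predictions are averaged over the levels of the other
        factors on the link scale (equal weights), then back-transformed
        -- the emmeans convention.
        """
        groupby_l, labels, L = self._emm_matrix(groupby)
        eta = L @ self.fe_params
        se = np.sqrt(np.einsum("ij,jk,ik->i", L, self.cov_fe, L))
        crit = self._crit(level)
        lo, hi = eta - crit * se, eta + crit * se
        if self.model.family == "poisson":
            eta, lo, hi = np.exp(eta), np.exp(lo), np.exp(hi)
        out = pd.DataFrame(labels, columns=groupby_l)
        out["emmean"], out["se_link"] = eta, se
        out["ci_lower"], out["ci_upper"] = lo, hi
        return out

    def _crit(self, level):
        # EMM uncertainty is dominated by the between-bat variance, so
        # CIs use a t quantile with between-group degrees of freedom
        alpha = 1.0 - level
        return stats.t.ppf(1 - alpha / 2, max(self.model.n_groups - 1, 1))

    def pairwise_contrasts(self, groupby, adjust: str = "tukey") -> pd.DataFrame:
        """All pairwise cell contrasts on the link scale.

        ``adjust`` is ``"tukey"`` (studentized-range) or
        ``"bonferroni"`` -- the study reports both styles; ``"none"``
        disables adjustment.
        """
        groupby_l, labels, L = self._emm_matrix(groupby)
        k = len(labels)
        rows = []
        df = self.df_resid if self.model.family == "gaussian" else 1e6
        n_pairs = k * (k - 1) // 2
        for i in range(k):
            for j in range(i + 1, k):
                c = L[i] - L[j]
                est = float(c @ self.fe_params)
                se = float(np.sqrt(c @ self.cov_fe @ c))
                z = est / se if se > 0 else np.nan
                if adjust == "tukey":
                    p = float(stats.studentized_range.sf(abs(z) * np.sqrt(2.0), k, df))
                elif adjust == "bonferroni":
                    p = float(min(2 * stats.t.sf(abs(z), df) * n_pairs, 1.0))
                else:
                    p = float(2 * stats.t.sf(abs(z), df))
                rows.append({
                    "contrast": " - ".join(["/".join(map(str, lab))
                                            for lab in (labels[i], labels[j])]),
                    "estimate": est, "se": se, "z_ratio": z, "p_value": p})
        return pd.DataFrame(rows)

    # -- term tests ---------------------------------------------------

    def wald_type2(self) -> pd.DataFrame:
        """Type-II Wald chi-square test per fixed term.

        Each term is tested in the model containing every term that
        does not include it (marginality respected), via the Wald
        statistic of its coefficient block.
        """
        rows = []
        for term in self.model.terms:
            tset = set(term.split(":"))
            peers = [t for t in self.model.terms
                     if t != term and not tset < set(t.split(":"))]
            sub = type(self.model)(self.model.endog, self.model.data,
                                   peers + [term], self.model.group_name,
                                   factors=tuple(self.model.design.factors))
            subres = sub.fit()
            cols = sub.design.term_slices[term]
            b = subres.fe_params[cols]
            V = subres.cov_fe[np.ix_(cols, cols)]
            try:
                chi2 = float(b @ np.linalg.solve(V, b))
            except np.linalg.LinAlgError:
                chi2 = np.nan
            dof = len(cols)
            rows.append({"term": term, "chi2": chi2, "df": dof,
                         "p_value": float(stats.chi2.sf(chi2, dof))})
        return pd.DataFrame(rows)

    # -- diagnostics --------------------------------------------------

    def overdispersion(self) -> float:
        """Pearson chi-square / residual df, with conditional means."""
        if self.model.family != "poisson":
            raise ValueError("overdispersion check applies to Poisson fits")
        eta0 = self.fitted_linpred()
        u, _ = self.model._posterior_modes(eta0, max(self.sigma_u, 1e-6) ** 2)
        mu = np.exp(eta0 + u[self.model.group_idx])
        pearson = np.sum((self.model.endog - mu) ** 2 / mu)
        return float(pearson / max(self.df_resid, 1))

    def r2_nakagawa(self) -> tuple[float, float]:
        """(marginal, conditional) R2 by latent-scale variance partition."""
        var_f = float(np.var(self.fitted_linpred()))
        var_u = self.sigma_u ** 2
        if self.model.family == "gaussian":
            var_e = self.scale ** 2
        else:
            lam = float(np.mean(np.exp(self.fitted_linpred() + var_u / 2)))
            var_e = float(np.log1p(1.0 / lam))  # lognormal approximation
        denom = var_f + var_u + var_e
        return var_f / denom, (var_f + var_u) / denom

    # -- summary ------------------------------------------------------

    def summary(self) -> str:
        names = self.model.design.column_names
        lines = [
            f"{type(self.model).__name__} ({self.model.family}), "
            f"response: {self.model.endog_name}",
            f"n_obs = {self.model.n_obs}, groups({self.model.group_name}) = "
            f"{self.model.n_groups}",
            f"logLik = {self.llf:.3f}   AICc = {self.aicc():.2f}   "
            f"sigma_u = {self.sigma_u:.4f}"
            + (f"   sigma_resid = {self.scale:.4f}" if self.scale else ""),
            "-" * 64,
            f"{'coef':<34}{'estimate':>10}{'se':>10}{'z':>8}",
        ]
        for name, b, se in zip(names, self.fe_params, self.bse):
            z = b / se if se > 0 else np.nan
            lines.append(f"{name:<34}{b:>10.4f}{se:>10.4f}{z:>8.2f}")
        if self.model.family == "poisson":
            lines.append("-" * 64)
            lines.append(f"overdispersion = {self.overdispersion():.3f}")
        r2m, r2c = self.r2_nakagawa()
        lines.append(f"R2 marginal = {r2m:.3f}   R2 conditional = {r2c:.3f}")
        if self.singular:
            lines.append("note: random-intercept variance is near zero (singular)")
        if not self.converged:
            lines.append("WARNING: optimiser did not converge")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model battery helpers


def fit_mixed_model(data: pd.DataFrame, response: str, terms, groups="bat_id",
                    family: str = "poisson",
                    factors=DEFAULT_FACTORS) -> MixedModelResults:
    """One-call fit of a mixed model with a bat-ID random intercept."""
    cls = PoissonGLMM if family == "poisson" else LinearMM
    return cls.from_dataframe(data, response, terms, groups, factors=factors).fit()


def collinearity_screen(x, y, threshold: float = 0.5) -> dict:
    """Pearson correlation screen between two covariates.

    Returns rho, t, df, p and whether |rho| > threshold, in which case
    the caller should split the model into single-covariate variants.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation (constant covariate)")
    rho, p = stats.pearsonr(x, y)
    df = len(x) - 2
    t = rho * np.sqrt(df / max(1.0 - rho ** 2, 1e-12))
    return {"rho": float(rho), "t": float(t), "df": int(df), "p_value": float(p),
            "split": bool(abs(rho) > threshold), "threshold": threshold}


def model_selection_aicc(results, names=None) -> pd.DataFrame:
    """AICc ranking of candidate fits on the same data."""
    ys = [tuple(np.asarray(r.model.endog)) for r in results]
    if len(set(ys)) != 1:
        raise ValueError("models must be fitted to identical data")
    names = names or [f"model{i}" for i in range(len(results))]
    tab = pd.DataFrame({
        "model": names,
        "aicc": [r.aicc() for r in results],
        "llf": [r.llf for r in results],
        "k": [r.n_params for r in results],
    }).sort_values("aicc").reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].iloc[0]
    tab["best"] = tab["delta_aicc"] == 0.0
    return tab


def parametric_bootstrap_null(full: MixedModelResults, null: MixedModelResults,
                              n_sim: int = 1000, rng=None) -> dict:
    """Parametric bootstrap LRT of a full model against a nested null.

    Responses are simulated from the fitted null; both models are
    refitted to each draw and the observed likelihood-ratio statistic
    is ranked among the simulated ones.  p = (1 + #{T* >= T}) /
    (n_ok + 1), the add-one continuity convention.  Non-converged
    refits are dropped and counted.
    """
    if rng is None:
        raise ValueError("pass a seeded numpy Generator")
    t_obs = max(2.0 * (full.llf - null.llf), 0.0)
    exceed = n_ok = n_fail = 0
    warm_full = full.raw_params
    warm_null = null.raw_params
    for _ in range(n_sim):
        kwargs = {"scale": null.scale} if null.model.family == "gaussian" else {}
        y = null.model.simulate(null.fe_params, null.sigma_u, rng, **kwargs)
        try:
            fast = {"compute_cov": False, "gtol": 1e-5}
            rf = full.model.refit_with_response(y).fit(
                **({"start_params": warm_full, **fast}
                   if warm_full is not None else {}))
            rn = null.model.refit_with_response(y).fit(
                **({"start_params": warm_null, **fast}
                   if warm_null is not None else {}))
        except Exception:
            n_fail += 1
            continue
        if not (rf.converged and rn.converged):
            n_fail += 1
            continue
        n_ok += 1
        if 2.0 * (rf.llf - rn.llf) >= t_obs - 1e-9:
            exceed += 1
    p = (1.0 + exceed) / (n_ok + 1.0) if n_ok else np.nan
    return {"stat": t_obs, "p_value": float(p), "n_sim": n_sim,
            "n_converged": n_ok, "n_failed": n_fail}


def simulate_poisson_glmm(data: pd.DataFrame, terms, beta, sigma_u,
                          groups: str = "bat_id", rng=None,
                          factors=DEFAULT_FACTORS) -> np.ndarray:
    """Draw a Poisson GLMM response on a design frame (for recovery tests)."""
    shell = data.assign(__y__=0)
    mod = PoissonGLMM("__y__", shell, terms, groups, factors=factors)
    return mod.simulate(np.asarray(beta, dtype=float), sigma_u, rng)
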