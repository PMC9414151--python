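"""GLMM fitting and AICc multi-model inference with model averaging.

Four response types are modelled on the individual-season-year table:

* occurrence area (km^2) and mean maximum daily displacement (km):
  log-normal, i.e. a Gaussian mixed model on the natural-log response with a
  random intercept per individual (fit through statsmodels MixedLM, ML);
* number of AFSs visited: Poisson / log link, individual random intercept,
  fit by maximum likelihood with adaptive Gauss-Hermite quadrature;
* probability of being at any AFS: binomial (fixes inside, fixes outside) /
  logit link, individual random intercept plus an observation-level random
  effect (OLRE) absorbing extra-binomial variance; nested adaptive
  quadrature (outer: individual; inner: OLRE).

Inference follows the information-theoretic recipe: all 2^p subsets of the
global fixed terms are fitted, ranked by AICc, and the candidate set
(delta AICc <= 6) is model-averaged.  Averaged coefficients use natural
(conditional) averaging by default, unconditional SEs use the revised
weighted-mean-of-roots formula, and each term's relative variable
importance (RVI) is the summed candidate weight of models containing it.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit, gammaln

log = logging.getLogger(__name__)

FAMILIES = ("lognormal", "poisson", "binomial")

#: Treatment coding: term -> (column, reference level, non-reference levels).
FACTOR_TERMS = {
    "age_class": ("age_class", "adult", ["juvenile"]),
    "origin": ("origin", "captive-released", ["wild-caught"]),
    "season": ("season", "autumn", ["spring", "summer", "winter"]),
    "sex": ("sex", "female", ["male"]),
}
CONTINUOUS_TERMS = ("fixes_per_day",)


class SingularDesignError(ValueError):
    """The design matrix is rank deficient."""


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response family plus a subset of fixed terms."""

    response: str
    family: str
    fixed_terms: tuple[str, ...]
    olre: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial":
            if not self.olre:
                raise ValueError("binomial models require the observation-level random effect")
            if "fixes_per_day" in self.fixed_terms:
                raise ValueError(
                    "fixes_per_day is excluded from the binomial model: the proportion "
                    "response already conditions on sampling effort"
                )


@dataclass
class FitResult:
    """A fitted mixed model: coefficients, SEs, variance components, logLik."""

    spec: ModelSpec
    params: pd.Series
    se: pd.Series
    vc: dict
    loglik: float
    k: int
    n: int
    converged: bool


@dataclass
class AveragedEstimate:
    """Model-averaged fixed effect with unconditional SE, CI and RVI."""

    term: str
    level: str
    estimate: float
    unc_se: float
    ci_low: float
    ci_high: float
    rvi: float


def _term_columns(term: str, data: pd.DataFrame) -> dict[str, np.ndarray]:
    """Dummy/numeric columns for one model term (treatment coding)."""
    if term in FACTOR_TERMS:
        col, ref, levels = FACTOR_TERMS[term]
        vals = data[col].astype(str)
        known = {ref, *levels}
        bad = set(vals.unique()) - known
        if bad:
            raise ValueError(f"unknown level(s) {sorted(bad)} for factor {term!r}")
        # only levels observed in the data enter the design; if the canonical
        # reference is absent the first observed level takes its place
        present = [lv for lv in [ref, *levels] if (vals == lv).any()]
        return {f"{term}[{lv}]": (vals == lv).to_numpy(float) for lv in present[1:]}
    if term == "year":
        years = sorted(data["year_label"].unique())
        ref = years[0]
        return {f"year[{y}]": (data["year_label"] == y).to_numpy(float) for y in years[1:]}
    if term in CONTINUOUS_TERMS:
        return {term: data[term].to_numpy(float)}
    raise ValueError(f"unknown model term {term!r}")


def build_design(data: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    """Design matrix with intercept for the given fixed terms."""
    cols = {"Intercept": np.ones(len(data))}
    for term in terms:
        cols.update(_term_columns(term, data))
    X = pd.DataFrame(cols, index=data.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X.iloc[:, : j + 1].to_numpy()) <= np.linalg.matrix_rank(
                X.iloc[:, :j].to_numpy()
            ):
                raise SingularDesignError(f"aliased design column: {X.columns[j]!r}")
        raise SingularDesignError("rank-deficient design")
    return X


def term_of_column(col: str) -> str:
    """Model term owning a design column ('season[spring]' -> 'season')."""
    return col.split("[")[0]


# ---------------------------------------------------------------------------
# collinearity diagnostics


def vif(design: pd.DataFrame, terms: tuple[str, ...] | None = None) -> pd.Series:
    """(Generalised) variance inflation factors per model term.

    Single-column terms give the classic 1/(1-R^2); multi-level factors give
    the generalised VIF det(R11) det(R22) / det(R) on the correlation matrix
    of the non-intercept columns.
    """
    X = design.drop(columns=["Intercept"], errors="ignore")
    if X.shape[1] < 2:
        return pd.Series({term_of_column(c): 1.0 for c in X.columns})
    Z = X.to_numpy(float)
    Z = Z - Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    if np.any(sd == 0):
        dead = X.columns[np.flatnonzero(sd == 0)[0]]
        raise SingularDesignError(f"constant (aliased) design column: {dead!r}")
    R = np.corrcoef(Z, rowvar=False)
    det_R = np.linalg.det(R)
    if det_R < 1e-12:
        raise SingularDesignError("near-singular correlation matrix among predictors")
    groups: dict[str, list[int]] = {}
    for j, c in enumerate(X.columns):
        groups.setdefault(term_of_column(c), []).append(j)
    out = {}
    for term, idx in groups.items():
        other = [j for j in range(X.shape[1]) if j not in idx]
        r11 = np.linalg.det(R[np.ix_(idx, idx)])
        r22 = np.linalg.det(R[np.ix_(other, other)]) if other else 1.0
        out[term] = float(r11 * r22 / det_R)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# likelihood machinery


def _gh_nodes(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Probabilists' Gauss-Hermite nodes/weights normalised against N(0,1)."""
    z, w = hermegauss(k)
    return z, w / math.sqrt(2.0 * math.pi)


def _numerical_hessian(fun, theta, step=1e-4):
    p = len(theta)
    H = np.zeros((p, p))
    h = step * (1.0 + np.abs(theta))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            f_pp = fun(theta + ei + ej)
            f_pm = fun(theta + ei - ej)
            f_mp = fun(theta - ei + ej)
            f_mm = fun(theta - ei - ej)
            H[i, j] = H[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * h[i] * h[j])
    return H


def _fit_lognormal(spec: ModelSpec, data: pd.DataFrame, X: pd.DataFrame) -> FitResult:
    """Gaussian mixed model (ML) on the log response via statsmodels MixedLM."""
    y = np.log(data[spec.response].to_numpy(float))
    if not np.all(np.isfinite(y)):
        raise ValueError(f"log response {spec.response!r} must be positive and finite")
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X.to_numpy(), groups=data["individual_id"].to_numpy())
        for method in ("lbfgs", "powell", "nm"):
            try:
                res = model.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if res.converged and np.all(np.isfinite(np.asarray(res.bse_fe))):
                break
    if res is None:
        raise RuntimeError("linear mixed model failed with every optimiser")
    params = pd.Series(res.fe_params, index=X.columns)
    se = pd.Series(np.asarray(res.bse_fe), index=X.columns)
    k = X.shape[1] + 2  # fixed effects + RE variance + residual variance
    return FitResult(
        spec=spec,
        params=params,
        se=se,
        vc={"individual": float(np.asarray(res.cov_re)[0, 0]), "residual": float(res.scale)},
        loglik=float(res.llf),
        k=k,
        n=len(y),
        converged=bool(res.converged),
    )


def _poisson_group_stats(X, y, groups):
    codes, uniq = pd.factorize(groups)
    return codes, len(uniq)


def _fit_poisson(spec: ModelSpec, data: pd.DataFrame, X: pd.DataFrame, n_quad=15) -> FitResult:
    """Poisson GLMM (log link, individual random intercept) by adaptive GH quadrature.

    With a log link the group likelihood depends on the random effect only
    through sum(y) and sum(exp(x beta)), so mode finding and quadrature are
    closed-form per group and cheap.
    """
    y = data[spec.response].to_numpy(float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("Poisson response must be non-negative integers")
    Xm = X.to_numpy(float)
    codes, G = _poisson_group_stats(Xm, y, data["individual_id"].to_numpy())
    z, w = _gh_nodes(n_quad)
    log_y_fact = gammaln(y + 1.0).sum()
    A = np.bincount(codes, weights=y, minlength=G)  # sum of counts per group

    def nll(theta):
        beta, log_tau = theta[:-1], theta[-1]
        tau2 = math.exp(2.0 * log_tau)
        eta = Xm @ beta
        S = np.bincount(codes, weights=np.exp(np.clip(eta, -30, 30)), minlength=G)
        yx = float(y @ eta)
        # Newton for the conditional mode per group: h(u) = A u - e^u S - u^2/(2 tau2)
        u = np.zeros(G)
        for _ in range(50):
            eu = np.exp(u)
            g1 = A - eu * S - u / tau2
            g2 = -eu * S - 1.0 / tau2
            du = -g1 / g2
            du = np.clip(du, -5, 5)
            u += du
            if np.max(np.abs(du)) < 1e-10:
                break
        sig = 1.0 / np.sqrt(np.exp(u) * S + 1.0 / tau2)
        # adaptive GH: log integral of exp(h(u)) phi-free form
        uu = u[:, None] + sig[:, None] * z[None, :]
        h = A[:, None] * uu - np.exp(uu) * S[:, None] - uu**2 / (2 * tau2)
        hmax = h.max(axis=1, keepdims=True)
        integ = np.log((w[None, :] * np.exp(h - hmax + z[None, :] ** 2 / 2.0)).sum(axis=1))
        log_int = (hmax[:, 0] + integ + np.log(sig) + 0.5 * math.log(2 * math.pi))
        ll = yx - log_y_fact + log_int.sum() - G * (0.5 * math.log(2 * math.pi * tau2))
        return -ll

    init_beta = _glm_start(Xm, y, "poisson")
    theta0 = np.concatenate([init_beta, [math.log(0.3)]])
    res = minimize(nll, theta0, method="BFGS", options={"gtol": 1e-6, "maxiter": 500})
    se_full, ok = _se_from_hessian(_numerical_hessian(nll, res.x), n_fixed=X.shape[1])
    params = pd.Series(res.x[:-1], index=X.columns)
    se = pd.Series(se_full[: X.shape[1]], index=X.columns)
    return FitResult(
        spec=spec,
        params=params,
        se=se,
        vc={"individual": math.exp(2.0 * res.x[-1])},
        loglik=-float(res.fun),
        k=X.shape[1] + 1,
        n=len(y),
        converged=_optimiser_ok(res) and ok,
    )


def _fit_binomial_olre(
    spec: ModelSpec, data: pd.DataFrame, X: pd.DataFrame, n_outer=11, n_inner=11
) -> FitResult:
    """Binomial GLMM (logit link) with individual intercept + OLRE.

    Marginal likelihood is a nested integral: the OLRE integral per
    observation (plain GH against its own scale omega) inside an adaptive GH
    integral per individual.
    """
    succ = data["n_fixes_inside"].to_numpy(float)
    tot = data["n_fixes_total"].to_numpy(float)
    if np.any(succ > tot):
        raise ValueError("successes exceed trials")
    Xm = X.to_numpy(float)
    codes, G = _poisson_group_stats(Xm, succ, data["individual_id"].to_numpy())
    z_in, w_in = _gh_nodes(n_inner)
    z_out, w_out = _gh_nodes(n_outer)
    log_binom = gammaln(tot + 1) - gammaln(succ + 1) - gammaln(tot - succ + 1)

    def _log_g(eta_u, omega, derivs=False):
        """log of the OLRE-integrated observation likelihood (adaptive).

        The integrand log Binom(y | eta_u + e) - e^2/(2 omega^2) can be far
        sharper than omega when trial counts are large, so the quadrature is
        centred per observation at the conditional mode with curvature
        scaling.  With ``derivs`` also returns the first and second
        derivatives with respect to the shared linear-predictor shift:
        d1 = E[c], d2 = E[c^2 + c'] - E[c]^2 under the posterior node
        weights, where c = y - n p and c' = -n p (1 - p).
        """
        om2 = omega * omega
        e0 = np.zeros_like(eta_u)
        for _ in range(25):
            p = expit(eta_u + e0)
            g = succ - tot * p - e0 / om2
            hcur = -tot * p * (1.0 - p) - 1.0 / om2
            de = np.clip(-g / hcur, -3.0, 3.0)
            e0 += de
            if np.max(np.abs(de)) < 1e-12:
                break
        sig_e = 1.0 / np.sqrt(-hcur)
        v = (eta_u + e0)[:, None] + sig_e[:, None] * z_in[None, :]
        ee = e0[:, None] + sig_e[:, None] * z_in[None, :]
        cexp = succ[:, None] * v - tot[:, None] * np.logaddexp(0.0, v) - ee**2 / (2 * om2)
        m = cexp.max(axis=1, keepdims=True)
        f = w_in[None, :] * np.exp(cexp - m + z_in[None, :] ** 2 / 2.0)
        sf = f.sum(axis=1)
        # log of integral over e, minus the N(0, omega^2) normaliser
        lg = (
            m[:, 0]
            + np.log(sf)
            + np.log(sig_e)
            + 0.5 * math.log(2 * math.pi)
            - 0.5 * math.log(2 * math.pi * om2)
            + log_binom
        )
        if not derivs:
            return lg, None, None
        p = expit(v)
        c = succ[:, None] - tot[:, None] * p
        cp = -tot[:, None] * p * (1.0 - p)
        d1 = (f * c).sum(axis=1) / sf
        d2 = (f * (c * c + cp)).sum(axis=1) / sf - d1 * d1
        return lg, d1, d2

    def _h(u, eta, tau2, omega, derivs=False):
        lg, d1, d2 = _log_g(eta + u[codes], omega, derivs)
        h = np.bincount(codes, weights=lg, minlength=G) - u**2 / (2 * tau2)
        if not derivs:
            return h, None, None
        g = np.bincount(codes, weights=d1, minlength=G) - u / tau2
        c = np.bincount(codes, weights=d2, minlength=G) - 1.0 / tau2
        return h, g, c

    def nll(theta):
        beta, log_tau, log_om = theta[:-2], theta[-2], theta[-1]
        tau2 = math.exp(2.0 * log_tau)
        omega = math.exp(log_om)
        eta = Xm @ beta
        u = np.zeros(G)
        curv = np.full(G, -1.0 / tau2)
        for _ in range(60):
            _, g, c = _h(u, eta, tau2, omega, derivs=True)
            curv = np.minimum(c, -1e-10 - 1.0 / tau2)
            du = np.clip(-g / curv, -4, 4)
            u += du
            if np.max(np.abs(du)) < 1e-11:
                break
        sig = 1.0 / np.sqrt(-curv)
        hk = np.empty((G, len(z_out)))
        for kq, zq in enumerate(z_out):
            hk[:, kq], _, _ = _h(u + sig * zq, eta, tau2, omega)
        hmax = hk.max(axis=1, keepdims=True)
        integ = np.log((w_out[None, :] * np.exp(hk - hmax + z_out[None, :] ** 2 / 2.0)).sum(axis=1))
        log_int = hmax[:, 0] + integ + np.log(sig) + 0.5 * math.log(2 * math.pi)
        ll = log_int.sum() - G * 0.5 * math.log(2 * math.pi * tau2)
        return -ll

    init_beta = _glm_start(Xm, np.column_stack([succ, tot - succ]), "binomial")
    theta0 = np.concatenate([init_beta, [math.log(0.7), math.log(0.7)]])
    res = minimize(
        nll, theta0, method="BFGS", options={"gtol": 1e-5, "maxiter": 300, "eps": 1e-6}
    )
    se_full, ok = _se_from_hessian(_numerical_hessian(nll, res.x), n_fixed=X.shape[1])
    params = pd.Series(res.x[:-2], index=X.columns)
    se = pd.Series(se_full[: X.shape[1]], index=X.columns)
    return FitResult(
        spec=spec,
        params=params,
        se=se,
        vc={"individual": math.exp(2.0 * res.x[-2]), "olre": math.exp(2.0 * res.x[-1])},
        loglik=-float(res.fun),
        k=X.shape[1] + 2,
        n=len(succ),
        converged=_optimiser_ok(res) and ok,
    )


def _glm_start(X, y, family: str) -> np.ndarray:
    """Fixed-effect starting values from an ordinary GLM fit."""
    fam = sm.families.Poisson() if family == "poisson" else sm.families.Binomial()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.asarray(sm.GLM(y, X, family=fam).fit().params)
    except Exception:  # fall back to a flat start
        return np.zeros(X.shape[1])


def _optimiser_ok(res) -> bool:
    """Accept BFGS results that stall on 'precision loss' with a tiny gradient.

    Variance components on the boundary (tau -> 0) flatten the likelihood in
    that direction, which trips the line search even though the fit is fine.
    """
    if res.success:
        return True
    jac = getattr(res, "jac", None)
    return jac is not None and float(np.max(np.abs(jac))) < 2e-3


def _se_from_hessian(H, n_fixed: int | None = None) -> tuple[np.ndarray, bool]:
    """SEs from the observed information; falls back to the fixed-effect block.

    When a variance component sits on the boundary the full Hessian is
    singular; the fixed-effect sub-block still carries the usable curvature.
    """
    p = H.shape[0]
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.all(d > 0):
            return np.sqrt(d), True
    except np.linalg.LinAlgError:
        pass
    if n_fixed is not None and n_fixed < p:
        try:
            cov = np.linalg.inv(H[:n_fixed, :n_fixed])
            d = np.diag(cov)
            if np.all(d > 0):
                out = np.full(p, np.nan)
                out[:n_fixed] = np.sqrt(d)
                return out, True
        except np.linalg.LinAlgError:
            pass
    return np.full(p, np.nan), False


def fit_glmm(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit one mixed model by maximum likelihood; see module docstring."""
    X = build_design(data, spec.fixed_terms)
    if spec.family == "lognormal":
        return _fit_lognormal(spec, data, X)
    if spec.family == "poisson":
        return _fit_poisson(spec, data, X)
    return _fit_binomial_olre(spec, data, X)


# ---------------------------------------------------------------------------
# information-theoretic model set


def aicc(fit: FitResult) -> float:
    """AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1)."""
    n, k = fit.n, fit.k
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n}, k={k}")
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def enumerate_subsets(global_spec: ModelSpec) -> list[ModelSpec]:
    """All 2^p fixed-term subsets of the global model (factors as whole terms)."""
    terms = global_spec.fixed_terms
    specs = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            specs.append(
                ModelSpec(
                    response=global_spec.response,
                    family=global_spec.family,
                    fixed_terms=combo,
                    olre=global_spec.olre,
                )
            )
    return specs


def fit_all_subsets(global_spec: ModelSpec, data: pd.DataFrame) -> list[FitResult]:
    """Fit every subset model; non-converged fits are dropped with a logged count."""
    fits, dropped = [], 0
    for spec in enumerate_subsets(global_spec):
        try:
            fit = fit_glmm(spec, data)
        except Exception as exc:  # keep the battery alive, record the loss
            log.warning("model %s failed: %s", spec.fixed_terms, exc)
            dropped += 1
            continue
        if fit.converged and fit.n - fit.k - 1 > 0:
            fits.append(fit)
        else:
            dropped += 1
    if dropped:
        log.warning(
            "%d of %d subset models dropped (non-convergence/failure)",
            dropped,
            2 ** len(global_spec.fixed_terms),
        )
    if not fits:
        raise RuntimeError("no subset model converged")
    return fits


def model_set_table(fits: list[FitResult]) -> pd.DataFrame:
    """Ranked model set: Df, logLik, AICc, delta AICc and Akaike weight."""
    rows = pd.DataFrame(
        {
            "terms": [" + ".join(f.spec.fixed_terms) or "(intercept)" for f in fits],
            "Df": [f.k for f in fits],
            "logLik": [f.loglik for f in fits],
            "AICc": [aicc(f) for f in fits],
        }
    )
    rows["delta_AICc"] = rows["AICc"] - rows["AICc"].min()
    rel = np.exp(-0.5 * rows["delta_AICc"])
    rows["weight"] = rel / rel.sum()
    return rows.sort_values("AICc").reset_index(drop=True)


def model_average(
    fits: list[FitResult],
    delta_max: float = 6.0,
    mode: str = "conditional",
    se_formula: str = "revised",
) -> list[AveragedEstimate]:
    """Average fixed effects over the candidate set (delta AICc <= delta_max).

    ``mode='conditional'`` (natural averaging) averages a coefficient over
    the candidate models that contain its term, renormalising the weights
    within that subset; ``mode='full'`` substitutes zero where the term is
    absent.  ``se_formula='revised'`` uses the weighted mean of per-model
    root terms sqrt(var_i + (b_i - bbar)^2); ``'original'`` uses the square
    root of the weighted variance sum.  RVI is the summed candidate weight
    of models containing the term (not renormalised).
    """
    if mode not in ("conditional", "full"):
        raise ValueError("mode must be 'conditional' or 'full'")
    if se_formula not in ("revised", "original"):
        raise ValueError("se_formula must be 'revised' or 'original'")
    aiccs = np.array([aicc(f) for f in fits])
    delta = aiccs - aiccs.min()
    cand_idx = np.flatnonzero(delta <= delta_max)
    cand = [fits[i] for i in cand_idx]
    w = np.exp(-0.5 * delta[cand_idx])
    w = w / w.sum()

    columns: list[str] = []
    for f in cand:
        for c in f.params.index:
            if c not in columns:
                columns.append(c)

    out = []
    for col in columns:
        term = term_of_column(col)
        has = np.array([col in f.params.index for f in cand])
        rvi = float(w[has].sum())
        if mode == "conditional":
            wc = w[has] / w[has].sum()
            b = np.array([f.params[col] for f, h in zip(cand, has) if h])
            v = np.array([f.se[col] ** 2 for f, h in zip(cand, has) if h])
        else:
            wc = w
            b = np.array([f.params.get(col, 0.0) for f in cand])
            v = np.array([f.se.get(col, 0.0) ** 2 for f in cand])
        bbar = float(wc @ b)
        if se_formula == "revised":
            unc_se = float(wc @ np.sqrt(v + (b - bbar) ** 2))
        else:
            unc_se = float(math.sqrt(wc @ (v + (b - bbar) ** 2)))
        level = col[col.index("[") + 1 : -1] if "[" in col else col
        out.append(
            AveragedEstimate(
                term=term,
                level=level,
                estimate=bbar,
                unc_se=unc_se,
                ci_low=bbar - 1.96 * unc_se,
                ci_high=bbar + 1.96 * unc_se,
                rvi=rvi if term != "Intercept" else float("nan"),
            )
        )
    return out


def averaged_table(estimates: list[AveragedEstimate], family: str) -> pd.DataFrame:
    """Averaged estimates with back-transformed columns.

    Log-scale families get percent-change back-transforms; the logit family
    gets probabilities (non-intercept rows added onto the intercept, i.e.
    the level's predicted probability at reference settings).
    """
    rows = []
    intercept = next((e.estimate for e in estimates if e.term == "Intercept"), 0.0)
    for e in estimates:
        row = {
            "term": e.term,
            "level": e.level,
            "estimate": e.estimate,
            "unc_se": e.unc_se,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "rvi": e.rvi,
        }
        if family in ("lognormal", "poisson"):
            row["bt_estimate"] = backtransform_percent(e.estimate)
            row["bt_ci_low"] = backtransform_percent(e.ci_low)
            row["bt_ci_high"] = backtransform_percent(e.ci_high)
        else:
            shift = 0.0 if e.term == "Intercept" else intercept
            row["bt_estimate"] = backtransform_prob(shift + e.estimate)
            row["bt_ci_low"] = backtransform_prob(shift + e.ci_low)
            row["bt_ci_high"] = backtransform_prob(shift + e.ci_high)
        rows.append(row)
    return pd.DataFrame(rows)


def backtransform_percent(beta: float) -> float:
    """Percent change implied by a log-scale coefficient: 100 (e^beta - 1)."""
    return 100.0 * (math.exp(beta) - 1.0)


def backtransform_prob(eta: float) -> float:
    """Probability implied by a logit-scale linear predictor."""
    return float(expit(eta))
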