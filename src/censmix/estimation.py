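"""Maximum-likelihood estimation of the censored mixture model.

The model: person i belongs to latent segment s with probability pi_s; in
trial t their intention Z follows the multiple-inflated negative binomial
of :mod:`censmix.outcome` with mean softplus(eta_its), where
eta_its = alpha_s + x_tilde' beta_tilde_s + x_star' beta_star.  A trial
contributes the pmf at the observed count when uncensored and the survival
probability P(Z >= y) when a loss card ended the round at card y.  The
mechanics factor (the Omega kernel) is parameter-free — censoring is
exogenous — so it is excluded from the objective by default.

Parameters are optimized on an unconstrained transformed scale:

* segment intercepts via cumulative squares, alpha_s = sum_{r<=s}
  alpha_tilde_r^2, which orders the segments and removes label switching;
* inflation weights phi and segment shares pi via multinomial logits
  (tau, sigma) with the last category as reference;
* dispersion via log delta;
* regression coefficients on the sum-to-zero orthonormal basis built by
  :mod:`censmix.design` (or used directly for plain numeric columns).

Optimization uses a quasi-Newton search with a strict relative-improvement
stopping rule, followed by a single Newton step on a central-difference
Hessian to push the gradient toward zero; the same Hessian provides
observed-information standard errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp, softmax

from .design import CovariateSchema, EncodedDesign, encode
from .game import GameConfig, omega
from .outcome import InflationSpec, inflated_pmf_matrix, inv_link, survival_matrix

__all__ = [
    "ModelParams",
    "ParamSpace",
    "ModelSpec",
    "FitResult",
    "transform",
    "untransform",
    "person_loglik",
    "total_loglik",
    "start_values",
    "fit",
    "standard_errors",
    "bic",
    "posterior_probs",
    "select_segments",
]

logger = logging.getLogger(__name__)

_TINY = 1e-300


@dataclass
class ModelParams:
    """Natural-scale parameters of the censored mixture model."""

    alpha: np.ndarray  # (S,) nondecreasing segment intercepts
    beta: np.ndarray  # (p,) common coefficients on reduced design columns
    delta: float
    phi: np.ndarray  # (4,)
    pi: np.ndarray  # (S,)
    beta_seg: np.ndarray | None = None  # (S, q) segment-specific block
    inflation: InflationSpec = field(default_factory=InflationSpec)

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float)) if np.size(self.beta) else np.zeros(0)
        self.phi = np.asarray(self.phi, dtype=float)
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        if self.beta_seg is not None:
            self.beta_seg = np.asarray(self.beta_seg, dtype=float)
            if self.beta_seg.ndim != 2 or self.beta_seg.shape[0] != self.n_segments:
                raise ValueError("beta_seg must have shape (S, q)")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if np.any(np.diff(self.alpha) < 0):
            raise ValueError("alpha must be nondecreasing")
        for name, w in (("phi", self.phi), ("pi", self.pi)):
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        if self.phi.shape != (4,):
            raise ValueError("phi must have length 4")
        if self.pi.shape != self.alpha.shape:
            raise ValueError("pi and alpha must share length S")

    @property
    def n_segments(self) -> int:
        return len(self.alpha)


@dataclass(frozen=True)
class ParamSpace:
    """Dimensions of the transformed parameter vector."""

    n_segments: int
    n_common: int
    n_seg_specific: int = 0

    @property
    def size(self) -> int:
        S, p, q = self.n_segments, self.n_common, self.n_seg_specific
        return S + p + S * q + 1 + 3 + (S - 1)

    def labels(self, colnames: list[str] | None = None) -> list[str]:
        S, p, q = self.n_segments, self.n_common, self.n_seg_specific
        cols = colnames or [f"x{j + 1}" for j in range(p + q)]
        lab = [f"alpha_tilde_{s + 1}" for s in range(S)]
        lab += [f"beta_{c}" for c in cols[:p]]
        for s in range(S):
            lab += [f"beta_{c}_s{s + 1}" for c in cols[p:]]
        lab += ["log_delta", "tau_1", "tau_2", "tau_3"]
        lab += [f"sigma_{s + 1}" for s in range(S - 1)]
        return lab


def transform(params: ModelParams) -> np.ndarray:
    """Map natural parameters to the unconstrained optimization space."""
    inc = np.diff(np.concatenate(([0.0], params.alpha)))
    if params.alpha[0] < 0 or np.any(inc < 0):
        raise ValueError("alpha must be nonnegative and nondecreasing")
    if np.any(params.phi <= 0) or np.any(params.pi <= 0):
        raise ValueError("phi and pi must be interior (strictly positive)")
    alpha_tilde = np.sqrt(inc)
    tau = np.log(params.phi[:3] / params.phi[3])
    sigma = np.log(params.pi[:-1] / params.pi[-1])
    parts = [alpha_tilde, params.beta]
    if params.beta_seg is not None:
        parts.append(params.beta_seg.ravel())
    parts += [[np.log(params.delta)], tau, sigma]
    return np.concatenate([np.atleast_1d(np.asarray(x, dtype=float)) for x in parts])


def untransform(
    vector: np.ndarray,
    space: ParamSpace,
    inflation: InflationSpec | None = None,
) -> ModelParams:
    """Inverse of :func:`transform`."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (space.size,):
        raise ValueError(f"expected vector of length {space.size}")
    S, p, q = space.n_segments, space.n_common, space.n_seg_specific
    i = 0
    alpha = np.cumsum(vector[i : i + S] ** 2)
    i += S
    beta = vector[i : i + p]
    i += p
    beta_seg = vector[i : i + S * q].reshape(S, q) if q else None
    i += S * q
    delta = float(np.exp(vector[i]))
    i += 1
    phi = softmax(np.concatenate([vector[i : i + 3], [0.0]]))
    i += 3
    pi = softmax(np.concatenate([vector[i : i + S - 1], [0.0]]))
    return ModelParams(
        alpha=alpha, beta=beta, delta=delta, phi=phi, pi=pi,
        beta_seg=beta_seg,
        inflation=inflation or InflationSpec(),
    )


@dataclass
class ModelSpec:
    """Data and design bound together for likelihood evaluation.

    Trials are sorted by person; design rows are deduplicated so each
    objective evaluation touches only the distinct (covariate, segment)
    combinations.
    """

    y: np.ndarray
    censored: np.ndarray
    person_index: np.ndarray  # 0..N-1 codes, sorted ascending
    person_ids: np.ndarray
    X_common: np.ndarray
    X_seg: np.ndarray
    space: ParamSpace
    inflation: InflationSpec
    colnames: list[str]
    log_omega: float  # constant mechanics term, sum over trials

    def __post_init__(self) -> None:
        starts = np.flatnonzero(
            np.diff(self.person_index, prepend=self.person_index[0] - 1)
        )
        self._starts = starts
        Xall = np.hstack([self.X_common, self.X_seg])
        uniq, codes = np.unique(Xall, axis=0, return_inverse=True)
        self._U_common = uniq[:, : self.X_common.shape[1]]
        self._U_seg = uniq[:, self.X_common.shape[1] :]
        self._codes = codes
        self._unc = self.censored == 0

    @property
    def n_persons(self) -> int:
        return len(self._starts)

    @property
    def n_trials(self) -> int:
        return len(self.y)

    def person_segment_loglik(self, params: ModelParams) -> np.ndarray:
        """(N, S) matrix of log prod_t Theta for each person and segment."""
        S = params.n_segments
        eta = params.alpha[None, :] + (self._U_common @ params.beta)[:, None]
        if params.beta_seg is not None and params.beta_seg.size:
            eta = eta + self._U_seg @ params.beta_seg.T
        mu = inv_link(eta)  # (U, S)
        pmf = inflated_pmf_matrix(mu, params.delta, params.phi, self.inflation)
        surv = survival_matrix(pmf)
        th_unc = pmf[self._codes, :, self.y]  # (n, S)
        th_cen = surv[self._codes, :, self.y]
        th = np.where(self._unc[:, None], th_unc, th_cen)
        bad = th <= 0
        if np.any(bad):
            logger.debug(
                "zero-probability observations for %d trial/segment pairs",
                int(bad.sum()),
            )
        logth = np.log(np.maximum(th, _TINY))
        logth[bad] = -np.inf
        with np.errstate(invalid="ignore"):
            out = np.add.reduceat(logth, self._starts, axis=0)
        out[np.isnan(out)] = -np.inf
        return out

    def total_loglik(self, params: ModelParams, include_omega: bool = False) -> float:
        ll = self.person_segment_loglik(params)
        with np.errstate(divide="ignore"):
            logpi = np.log(params.pi)
        value = float(np.sum(logsumexp(ll + logpi[None, :], axis=1)))
        if include_omega:
            value += self.log_omega
        return value

    def objective(self, vector: np.ndarray, include_omega: bool = False) -> float:
        params = untransform(vector, self.space, self.inflation)
        value = self.total_loglik(params, include_omega)
        return -value if np.isfinite(value) else 1e12


_REQUIRED = ("person_id", "trial", "gain", "loss", "n_loss", "y", "censored")


def build_model(
    data: pd.DataFrame,
    n_segments: int,
    schema: CovariateSchema | None = None,
    design: EncodedDesign | None = None,
    inflation: InflationSpec | None = None,
) -> tuple[ModelSpec, EncodedDesign | None]:
    """Validate the trial table, encode covariates, and assemble a ModelSpec."""
    for col in _REQUIRED:
        if col not in data.columns:
            raise ValueError(f"trial table is missing column {col!r}")
    if len(data) == 0:
        raise ValueError("empty trial table")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    inflation = inflation or InflationSpec()

    df = data.sort_values(["person_id", "trial"], kind="mergesort").reset_index(drop=True)
    y = df["y"].to_numpy(dtype=int)
    c = df["censored"].to_numpy(dtype=int)
    if np.any((y < 0) | (y > inflation.cap)):
        raise ValueError(f"y must lie in [0, {inflation.cap}]")
    if np.any((c != 0) & (c != 1)):
        raise ValueError("censored must be 0 or 1")
    if np.any((c == 1) & (y < 1)):
        raise ValueError("censored trials require y >= 1")

    ids, codes = np.unique(df["person_id"].to_numpy(), return_inverse=True)

    if design is None and schema is not None:
        design = encode(schema, df)
    if design is not None:
        Xc = design.X[:, design.common_cols]
        Xs = design.X[:, design.seg_cols]
        colnames = [design.colnames[j] for j in design.common_cols] + [
            design.colnames[j] for j in design.seg_cols
        ]
    else:
        Xc = np.zeros((len(df), 0))
        Xs = np.zeros((len(df), 0))
        colnames = []

    log_omega = 0.0
    cfg_cache: dict[tuple, float] = {}
    gains = df["gain"].to_numpy()
    losses = df["loss"].to_numpy()
    nlosses = df["n_loss"].to_numpy(dtype=int)
    for yi, ci, gi, li, mi in zip(y, c, gains, losses, nlosses):
        key = (yi, ci, mi)
        if key not in cfg_cache:
            cfg = GameConfig(gain=gi, loss=li, n_loss=mi, n_cards=inflation.cap)
            cfg_cache[key] = float(
                np.log(max(omega(yi, ci, yi if ci == 0 else inflation.cap, cfg), _TINY))
            )
        log_omega += cfg_cache[key]

    space = ParamSpace(
        n_segments=n_segments,
        n_common=Xc.shape[1],
        n_seg_specific=Xs.shape[1],
    )
    model = ModelSpec(
        y=y, censored=c, person_index=codes, person_ids=ids,
        X_common=Xc, X_seg=Xs, space=space, inflation=inflation,
        colnames=colnames, log_omega=log_omega,
    )
    return model, design


def person_loglik(params: ModelParams, model: ModelSpec, segment: int) -> np.ndarray:
    """log prod_t Theta per person, for one segment (0-based)."""
    return model.person_segment_loglik(params)[:, segment]


def total_loglik(
    params: ModelParams, model: ModelSpec, include_omega: bool = False
) -> float:
    """Mixture log likelihood sum_i log sum_s pi_s exp(loglik_is)."""
    return model.total_loglik(params, include_omega)


def start_values(model: ModelSpec, n_segments: int | None = None) -> np.ndarray:
    """Educated-guess start values on the transformed scale.

    Intercepts start equally spaced over the interior of the support;
    inflation weights start from the observed excess mass at the inflated
    outcomes (observed proportion minus the linear interpolation of the
    flanking non-inflated outcomes, floored at 1e-3).
    """
    S = n_segments or model.space.n_segments
    cap = model.inflation.cap
    alpha0 = np.array([(s + 1) * cap / (S + 1) for s in range(S)])
    alpha_tilde = np.sqrt(np.diff(np.concatenate(([0.0], alpha0))))

    unc = model.y[model.censored == 0]
    if unc.size:
        prop = np.bincount(unc, minlength=cap + 1).astype(float)
        prop /= prop.sum()
    else:
        prop = np.full(cap + 1, 1.0 / (cap + 1))
    inflated = {model.inflation.zero} | set(model.inflation.attract_set) | {
        model.inflation.top
    }

    def baseline(k: int) -> float:
        lo = next((j for j in range(k - 1, -1, -1) if j not in inflated), None)
        hi = next((j for j in range(k + 1, cap) if j not in inflated), None)
        if lo is None and hi is None:
            return 0.0
        if lo is None:
            return prop[hi]
        if hi is None:
            return prop[lo]
        w = (k - lo) / (hi - lo)
        return (1 - w) * prop[lo] + w * prop[hi]

    def excess(ks) -> float:
        return max(sum(prop[k] - baseline(k) for k in ks), 1e-3)

    phi = np.array(
        [
            excess([model.inflation.zero]),
            excess(model.inflation.attract_set),
            excess([model.inflation.top]),
            0.0,
        ]
    )
    phi[3] = max(1.0 - phi[:3].sum(), 0.25)
    phi /= phi.sum()
    tau = np.log(phi[:3] / phi[3])

    p, q = model.space.n_common, model.space.n_seg_specific
    return np.concatenate(
        [alpha_tilde, np.zeros(p + S * q), [0.0], tau, np.zeros(S - 1)]
    )


def _num_gradient(f, x, rel_step=1e-6):
    g = np.empty_like(x)
    for i in range(len(x)):
        h = rel_step * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g


def _num_hessian(f, x, rel_step=1e-4):
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += 2 * h[i]
                xm[i] -= 2 * h[i]
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / (4 * h[i] ** 2)
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += h[[i, j]]
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                xmm[[i, j]] -= h[[i, j]]
                H[i, j] = H[j, i] = (
                    f(xpp) - f(xpm) - f(xmp) + f(xmm)
                ) / (4 * h[i] * h[j])
    return H


@dataclass
class FitResult:
    """Estimates, uncertainty, and diagnostics of one fitted model."""

    params: ModelParams
    theta_t: np.ndarray  # transformed-space estimates
    cov_t: np.ndarray | None  # transformed-space covariance
    labels_t: list[str]
    loglik: float
    bic: float
    n_free: int
    n_persons: int
    n_trials: int
    converged: bool
    n_iter: int
    grad_norm: float
    posterior: np.ndarray  # (N, S)
    person_ids: np.ndarray
    space: ParamSpace
    design: EncodedDesign | None = None
    scalers: dict | None = None
    report: dict[str, tuple[float, float]] | None = None
    warnings_: list[str] = field(default_factory=list)

    def se(self, label: str) -> float:
        i = self.labels_t.index(label)
        if self.cov_t is None:
            return float("nan")
        v = self.cov_t[i, i]
        return float(np.sqrt(v)) if v > 0 else float("nan")

    def estimate(self, label: str) -> float:
        return float(self.theta_t[self.labels_t.index(label)])


def bic(loglik: float, n_free: int, n_persons: int) -> float:
    """Bayesian information criterion with persons as independent units."""
    return -2.0 * loglik + n_free * np.log(n_persons)


def fit(
    data: pd.DataFrame,
    n_segments: int,
    schema: CovariateSchema | None = None,
    *,
    start: np.ndarray | ModelParams | None = None,
    include_omega: bool = False,
    max_iter: int = 500,
    warm_start: int | None = None,
    compute_se: bool = True,
    inflation: InflationSpec | None = None,
    seed: int | None = None,
) -> FitResult:
    """Fit the censored mixture model by maximum likelihood.

    ``start`` may be a transformed-space vector or natural ModelParams;
    otherwise educated-guess start values are used, optionally refined by a
    warm-start fit on a random subsample of ``warm_start`` persons.
    Convergence follows the strict relative rule: the search stops once the
    log-likelihood improvement falls below 1e-10 (|logL| + 1e-10); one
    Newton-Raphson step on a numerically approximated Hessian then pushes
    the gradient toward zero (kept only if it does not reduce the
    log-likelihood by more than 1e-6).
    """
    model, design = build_model(data, n_segments, schema, inflation=inflation)
    wlist: list[str] = []

    if start is None:
        x0 = start_values(model)
        if warm_start and model.n_persons > warm_start:
            rng = np.random.default_rng(seed)
            keep = rng.choice(model.person_ids, size=warm_start, replace=False)
            sub = data[data["person_id"].isin(keep)]
            warm = fit(
                sub, n_segments, schema,
                start=x0, include_omega=include_omega,
                max_iter=max_iter, compute_se=False, inflation=inflation,
            )
            x0 = warm.theta_t
    elif isinstance(start, ModelParams):
        x0 = transform(start)
    else:
        x0 = np.asarray(start, dtype=float)
        if x0.shape != (model.space.size,):
            raise ValueError(
                f"start vector must have length {model.space.size}"
            )

    fun = lambda v: model.objective(v, include_omega)
    res = optimize.minimize(
        fun, x0, method="L-BFGS-B",
        options={"ftol": 1e-10, "gtol": 1e-7, "maxiter": max_iter,
                 "maxfun": 50 * max_iter},
    )
    x = res.x
    f_opt = fun(x)

    # Newton polish on a central-difference Hessian
    H = _num_hessian(fun, x)
    g = _num_gradient(fun, x)
    try:
        step = np.linalg.solve(H, -g)
        x_new = x + step
        f_new = fun(x_new)
        if np.isfinite(f_new) and f_new <= f_opt + 1e-6:
            if not np.allclose(x_new, x):
                x, f_opt = x_new, f_new
                H = _num_hessian(fun, x)
                g = _num_gradient(fun, x)
    except np.linalg.LinAlgError:
        wlist.append("singular Hessian: Newton polish skipped")
    grad_norm = float(np.linalg.norm(g))

    params = untransform(x, model.space, model.inflation)
    if np.any(params.pi < 1e-4):
        wlist.append(
            "segment share near the boundary (pi_s < 1e-4); solution may be degenerate"
        )
        warnings.warn(wlist[-1], RuntimeWarning, stacklevel=2)

    cov_t = None
    if compute_se:
        try:
            cov_t = np.linalg.inv(H)
            if np.any(np.diag(cov_t) <= 0):
                wlist.append("observed information not positive definite; some SEs missing")
        except np.linalg.LinAlgError:
            wlist.append("singular Hessian: standard errors reported as missing")
            warnings.warn(wlist[-1], RuntimeWarning, stacklevel=2)

    loglik = model.total_loglik(params, include_omega=False)
    post = _posterior(params, model)
    n_free = model.space.size

    result = FitResult(
        params=params,
        theta_t=x,
        cov_t=cov_t,
        labels_t=model.space.labels(model.colnames),
        loglik=loglik,
        bic=bic(loglik, n_free, model.n_persons),
        n_free=n_free,
        n_persons=model.n_persons,
        n_trials=model.n_trials,
        converged=bool(res.success),
        n_iter=int(res.nit),
        grad_norm=grad_norm,
        posterior=post,
        person_ids=model.person_ids,
        space=model.space,
        design=design,
        scalers=design.scalers if design is not None else None,
        warnings_=wlist,
    )
    if compute_se:
        result.report = standard_errors(result)
    return result


def standard_errors(fit_result: FitResult) -> dict[str, tuple[float, float]]:
    """Delta-method estimates and SEs on the reported scale.

    Reported parameters: segment intercepts alpha_s, shares pi_s, inflation
    weights phi_m, dispersion delta, and per-level (constrained) regression
    coefficients.
    """
    space = fit_result.space
    design = fit_result.design
    inflation = fit_result.params.inflation
    S, p, q = space.n_segments, space.n_common, space.n_seg_specific

    if design is not None:
        rep_common = np.nonzero(
            np.any(design.report_matrix[:, design.common_cols] != 0, axis=1)
        )[0]
        rep_seg = np.nonzero(
            np.any(design.report_matrix[:, design.seg_cols] != 0, axis=1)
        )[0]

    def reported(vec: np.ndarray) -> np.ndarray:
        pr = untransform(vec, space, inflation)
        parts = [pr.alpha, pr.pi, pr.phi, [pr.delta]]
        if design is not None:
            beta_red = np.zeros(design.n_columns)
            beta_red[design.common_cols] = pr.beta
            parts.append((design.report_matrix @ beta_red)[rep_common])
            for s in range(S) if q else ():
                bs = np.zeros(design.n_columns)
                bs[design.seg_cols] = pr.beta_seg[s]
                parts.append((design.report_matrix @ bs)[rep_seg])
        else:
            parts.append(pr.beta)
        return np.concatenate([np.atleast_1d(np.asarray(v, float)) for v in parts])

    names = [f"alpha_{s + 1}" for s in range(S)]
    names += [f"pi_{s + 1}" for s in range(S)]
    names += [f"phi_{m + 1}" for m in range(4)]
    names += ["delta"]
    if design is not None:
        names += [design.report_names[i] for i in rep_common]
        for s in range(S) if q else ():
            names += [f"{design.report_names[i]}_s{s + 1}" for i in rep_seg]
    else:
        names += [lab for lab in fit_result.labels_t if lab.startswith("beta_")]

    est = reported(fit_result.theta_t)
    if fit_result.cov_t is None:
        ses = np.full_like(est, np.nan)
    else:
        J = np.empty((len(est), len(fit_result.theta_t)))
        for i in range(len(fit_result.theta_t)):
            h = 1e-6 * (1.0 + abs(fit_result.theta_t[i]))
            xp, xm = fit_result.theta_t.copy(), fit_result.theta_t.copy()
            xp[i] += h
            xm[i] -= h
            J[:, i] = (reported(xp) - reported(xm)) / (2 * h)
        var = np.einsum("ij,jk,ik->i", J, fit_result.cov_t, J)
        ses = np.sqrt(np.where(var > 0, var, np.nan))
    return {nm: (float(e), float(s)) for nm, e, s in zip(names, est, ses)}


def _posterior(params: ModelParams, model: ModelSpec) -> np.ndarray:
    ll = model.person_segment_loglik(params)
    with np.errstate(divide="ignore"):
        logw = ll + np.log(params.pi)[None, :]
    logw -= logsumexp(logw, axis=1, keepdims=True)
    return np.exp(logw)


def posterior_probs(fit_result: FitResult) -> np.ndarray:
    """Posterior segment membership probabilities, rows summing to one."""
    return fit_result.posterior


@dataclass
class SegmentSelection:
    chosen: int
    diagnostics: pd.DataFrame


def select_segments(
    fits: list[FitResult],
    min_share: float = 0.05,
    min_intercept_gap: float = 1.0,
) -> SegmentSelection:
    """Pick the number of segments by the three-criterion rule.

    Walking over fits in ascending S, a model is accepted while (a) its BIC
    improves on the previously accepted model, (b) every segment holds at
    least ``min_share`` of the sample, and (c) adjacent intercepts differ by
    at least ``min_intercept_gap`` cards.  The last accepted S is returned
    together with per-model diagnostics.
    """
    if not fits:
        raise ValueError("select_segments requires at least one fit")
    fits = sorted(fits, key=lambda f: f.params.n_segments)
    rows = []
    chosen = fits[0].params.n_segments
    best_bic = np.inf
    accepted = True
    for f in fits:
        S = f.params.n_segments
        share_ok = bool(np.all(f.params.pi >= min_share))
        gaps = np.diff(f.params.alpha)
        gap_ok = bool(S == 1 or np.all(gaps >= min_intercept_gap))
        bic_ok = f.bic < best_bic
        ok = share_ok and gap_ok and bic_ok and accepted
        rows.append(
            {
                "S": S, "bic": f.bic, "min_share": float(f.params.pi.min()),
                "min_gap": float(gaps.min()) if S > 1 else np.nan,
                "share_ok": share_ok, "gap_ok": gap_ok, "bic_ok": bic_ok,
                "accepted": ok,
            }
        )
        if ok:
            chosen = S
            best_bic = f.bic
        else:
            accepted = False  # stop accepting larger models after a violation
    return SegmentSelection(chosen=chosen, diagnostics=pd.DataFrame(rows))
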