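"""Model-fit assessment.

Point predictions (mixture expectations of the intention), RMSE/MAD on
uncensored trials, censoring-corrected predicted joint distributions of
(outcome, censor flag), goodness-of-fit summaries (chi-square, Pearson
correlation of probability vectors, Hellinger distance), outcome category
profiles, and posterior-weighted segment profiles of external scores with a
Wald test for segment differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import ModelParams
from .game import GameConfig, hazard_vector, survival_vector
from .outcome import InflationSpec, inflated_pmf_matrix, inv_link

__all__ = [
    "expected_cards",
    "fit_metrics",
    "mixture_pmf",
    "predicted_joint_distribution",
    "GofResult",
    "gof",
    "category_profile",
    "SegmentProfile",
    "segment_profile",
]


def mixture_pmf(
    params: ModelParams,
    x_common: np.ndarray | None = None,
    x_seg: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Mixture distribution of the intention Z over {0, ..., cap} at one
    covariate row, weighted by ``weights`` (prior pi by default)."""
    w = params.pi if weights is None else np.asarray(weights, dtype=float)
    xc = np.zeros(len(params.beta)) if x_common is None else np.asarray(x_common, float)
    eta = params.alpha + xc @ params.beta
    if params.beta_seg is not None and params.beta_seg.size:
        xs = (
            np.zeros(params.beta_seg.shape[1])
            if x_seg is None
            else np.asarray(x_seg, float)
        )
        eta = eta + params.beta_seg @ xs
    pmf = inflated_pmf_matrix(
        inv_link(eta), params.delta, params.phi, params.inflation
    )
    return w @ pmf


def expected_cards(
    params: ModelParams,
    x_common: np.ndarray | None = None,
    x_seg: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Expected intention sum_l l * P(Z = l), mixed over segments with prior
    weights (unseen persons) or a posterior row (in-sample)."""
    pmf = mixture_pmf(params, x_common, x_seg, weights)
    return float(pmf @ np.arange(len(pmf)))


def fit_metrics(observed, predicted) -> tuple[float, float]:
    """RMSE and MAD of the residuals (uncensored trials only; filter before
    calling)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size == 0:
        raise ValueError("no observations left after filtering")
    resid = observed - predicted
    return float(np.sqrt(np.mean(resid**2))), float(np.mean(np.abs(resid)))


def predicted_joint_distribution(
    z_pmf: np.ndarray, config: GameConfig
) -> pd.DataFrame:
    """Joint distribution P(Y = k, C = c) implied by an intention pmf.

    Multiplies the intention distribution with the mechanics kernel:
    uncensored mass z_pmf[k] * survival(k); censored mass at card k is the
    first-loss probability times P(Z >= k).  Rows sum to one over (k, c).
    """
    z_pmf = np.asarray(z_pmf, dtype=float)
    n = config.n_cards
    if z_pmf.shape != (n + 1,):
        raise ValueError(f"z_pmf must have length {n + 1}")
    surv = survival_vector(config)
    haz = hazard_vector(config)
    p_unc = z_pmf * surv
    tail = np.concatenate([np.cumsum(z_pmf[::-1])[::-1], [0.0]])
    p_cen = np.zeros(n + 1)
    p_cen[1:] = surv[:-1] * haz * tail[1 : n + 1]
    return pd.DataFrame(
        {"k": np.arange(n + 1), "uncensored": p_unc, "censored": p_cen}
    )


@dataclass(frozen=True)
class GofResult:
    chi2: float
    df: int
    pvalue: float
    pearson_r: float
    hellinger: float


def _pool(obs: np.ndarray, pred: np.ndarray, n: int, threshold: float):
    """Pool adjacent cells whose expected count n*pred falls below the
    threshold, sweeping left to right (the last cell absorbs leftovers)."""
    o_cells, p_cells = [], []
    o_acc = p_acc = 0.0
    for o, p in zip(obs, pred):
        o_acc += o
        p_acc += p
        if n * p_acc >= threshold:
            o_cells.append(o_acc)
            p_cells.append(p_acc)
            o_acc = p_acc = 0.0
    if p_acc > 0 or o_acc > 0:
        if p_cells:
            o_cells[-1] += o_acc
            p_cells[-1] += p_acc
        else:
            o_cells, p_cells = [o_acc], [p_acc]
    return np.array(o_cells), np.array(p_cells)


def gof(
    observed_pmf: np.ndarray,
    predicted_pmf: np.ndarray,
    n: int,
    pool_threshold: float = 5.0,
) -> GofResult:
    """Chi-square GOF (with small-expected-cell pooling), Pearson correlation
    of the probability vectors, and the Hellinger distance."""
    obs = np.asarray(observed_pmf, dtype=float)
    pred = np.asarray(predicted_pmf, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("distributions must share a support")
    o_cells, p_cells = _pool(obs, pred, n, pool_threshold)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = n * (o_cells - p_cells) ** 2 / p_cells
    chi2 = float(np.nansum(terms))
    df = max(len(o_cells) - 1, 1)
    if len(obs) > 2 and np.ptp(obs) > 0 and np.ptp(pred) > 0:
        r = float(stats.pearsonr(obs, pred).statistic)
    else:
        r = 1.0 if np.allclose(obs, pred) else float("nan")
    hell = float(np.linalg.norm(np.sqrt(obs) - np.sqrt(pred)) / np.sqrt(2))
    return GofResult(
        chi2=chi2, df=df, pvalue=float(stats.chi2.sf(chi2, df)),
        pearson_r=r, hellinger=hell,
    )


def category_profile(
    outcomes, spec: InflationSpec | None = None
) -> np.ndarray:
    """Proportions of a person's uncensored outcomes over the four outcome
    categories: zero, the attractive set, the next-to-last card, and all
    outcomes.  An outcome in one of the first three categories splits its
    weight equally between that category and the catch-all category."""
    spec = spec or InflationSpec()
    outcomes = np.asarray(outcomes, dtype=int)
    if outcomes.size == 0:
        raise ValueError("category_profile requires at least one outcome")
    attract = set(spec.attract_set)
    w = np.zeros(4)
    for k in outcomes:
        if k == spec.zero:
            w[0] += 0.5
            w[3] += 0.5
        elif k in attract:
            w[1] += 0.5
            w[3] += 0.5
        elif k == spec.top:
            w[2] += 0.5
            w[3] += 0.5
        else:
            w[3] += 1.0
    return w / w.sum()


@dataclass
class SegmentProfile:
    """Posterior-weighted z-score means per segment with a Wald test of the
    hypothesis that all segment means coincide."""

    means: pd.DataFrame  # variables x segments
    wald: pd.DataFrame  # per variable: statistic, df, pvalue
    effective_n: np.ndarray


def segment_profile(
    posterior: np.ndarray, scores: pd.DataFrame
) -> SegmentProfile:
    """Weighted segment means of external scores and Wald tests.

    Scores are z-scored over the included persons, so the posterior-weighted
    overall mean of each variable is zero.  Each weighted segment mean gets
    a variance from its weighted variance and effective sample size
    (sum w)^2 / sum w^2; the Wald statistic (df = S - 1) compares the means
    against their precision-weighted common value.
    """
    W = np.asarray(posterior, dtype=float)
    if W.ndim != 2 or len(scores) != W.shape[0]:
        raise ValueError("posterior must be (N, S) matching the score table")
    if not np.allclose(W.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to one")
    S = W.shape[1]
    wsum = W.sum(axis=0)
    n_eff = wsum**2 / (W**2).sum(axis=0)
    keep = n_eff >= 2
    if not np.all(keep):
        warnings.warn(
            f"{int((~keep).sum())} segment(s) with effective size < 2 excluded",
            RuntimeWarning,
            stacklevel=2,
        )

    means = {}
    wald_rows = []
    for col in scores.columns:
        x = scores[col].to_numpy(dtype=float)
        z = (x - x.mean()) / x.std(ddof=1)
        m = (W * z[:, None]).sum(axis=0) / wsum
        v_within = (W * (z[:, None] - m) ** 2).sum(axis=0) / wsum
        var_mean = v_within / n_eff
        means[col] = m
        mk, vk = m[keep], var_mean[keep]
        common = np.sum(mk / vk) / np.sum(1.0 / vk)
        stat = float(np.sum((mk - common) ** 2 / vk))
        df = int(keep.sum()) - 1
        wald_rows.append(
            {
                "variable": col,
                "statistic": stat,
                "df": df,
                "pvalue": float(stats.chi2.sf(stat, df)) if df > 0 else np.nan,
            }
        )
    return SegmentProfile(
        means=pd.DataFrame(means, index=[f"s{j + 1}" for j in range(S)]).T,
        wald=pd.DataFrame(wald_rows).set_index("variable"),
        effective_n=n_eff,
    )
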