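"""Distribution of the latent intention Z.

The base distribution is a negative binomial with mean mu and dispersion
delta (variance mu + mu^2/delta), obtained from a linear predictor eta
through the softplus inverse link log(exp(eta) + 1).  On top of the base
distribution sits a *multiple inflation*: extra probability mass phi_1 on
zero (risk-averse non-players), phi_2 spread evenly over a set A of
attractive counts (multiples of four plus ten, matching geometric card
patterns), and phi_3 on the next-to-last card; phi_4 scales the smooth base
distribution.  Mass of the unbounded base distribution beyond the deck is
folded into the top of the support, so the pmf lives on {0, ..., cap} and
sums to one exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "InflationSpec",
    "OutcomeParams",
    "inv_link",
    "nb_pmf",
    "nb_logpmf",
    "inflated_pmf_matrix",
    "survival_matrix",
    "inflated_pmf",
    "inflated_survival",
    "theta",
]


@dataclass(frozen=True)
class InflationSpec:
    """Which outcomes receive extra mass.

    ``attract_set`` holds the phi_2 outcomes (weight phi_2/|A| each);
    ``zero`` and ``top`` are the phi_1 and phi_3 singletons.  ``cap`` is the
    deck size: the largest representable intention, carrying the folded tail
    of the base distribution.
    """

    attract_set: tuple[int, ...] = (4, 8, 10, 12, 16, 20, 24)
    zero: int = 0
    top: int = 31
    cap: int = 32

    def __post_init__(self) -> None:
        sets = {self.zero, self.top} | set(self.attract_set)
        if len(sets) != 2 + len(self.attract_set):
            raise ValueError("inflated outcome sets must be disjoint")
        if not all(0 <= v < self.cap for v in sets):
            raise ValueError(f"inflated outcomes must lie in [0, {self.cap})")


@dataclass(frozen=True)
class OutcomeParams:
    """Parameters of one intention distribution: base mean and dispersion
    plus the four inflation weights."""

    mu: float
    delta: float
    phi: tuple[float, float, float, float]
    spec: InflationSpec = field(default_factory=InflationSpec)

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        phi = np.asarray(self.phi, dtype=float)
        if phi.shape != (4,) or np.any(phi < 0) or np.any(phi > 1):
            raise ValueError("phi must be four weights in [0, 1]")
        if abs(phi.sum() - 1.0) > 1e-8:
            raise ValueError(f"phi must sum to 1, got {phi.sum()!r}")


def inv_link(eta):
    """Softplus inverse link log(exp(eta) + 1).

    Strictly positive for any real eta and within 0.007 of the identity for
    eta >= 5, so coefficients read on the cards scale.  Computed
    overflow-safely via logaddexp.
    """
    return np.logaddexp(0.0, eta)


def _nb_p(mu, delta):
    return delta / (delta + mu)


def nb_logpmf(z, mu, delta):
    """Log pmf of the negative binomial with mean ``mu``, dispersion ``delta``."""
    mu = np.asarray(mu, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(mu <= 0) or np.any(delta <= 0):
        raise ValueError("mu and delta must be > 0")
    return stats.nbinom.logpmf(z, delta, _nb_p(mu, delta))


def nb_pmf(z, mu, delta):
    """Negative binomial pmf Gamma(delta+z)/(Gamma(delta) z!) *
    (delta/(delta+mu))^delta (mu/(mu+delta))^z, computed in log space."""
    return np.exp(nb_logpmf(z, mu, delta))


def inflated_pmf_matrix(mu, delta, phi, spec: InflationSpec | None = None) -> np.ndarray:
    """Inflated pmf over {0, ..., cap} for an array of means.

    ``mu`` may have any shape; the result gains a trailing axis of length
    cap + 1.  The base negative binomial is evaluated in log space; the mass
    it places beyond cap - 1 is folded onto cap (scaled by phi_4, with no
    inflation there), which makes each row sum to one exactly.
    """
    if spec is None:
        spec = InflationSpec()
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    p = _nb_p(mu, delta)[..., None]
    support = np.arange(spec.cap)
    base = np.exp(stats.nbinom.logpmf(support, delta, p))
    tail = stats.nbinom.sf(spec.cap - 1, delta, p[..., 0])

    out = np.empty(mu.shape + (spec.cap + 1,))
    out[..., : spec.cap] = phi[3] * base
    out[..., spec.cap] = phi[3] * tail
    out[..., spec.zero] += phi[0]
    for a in spec.attract_set:
        out[..., a] += phi[1] / len(spec.attract_set)
    out[..., spec.top] += phi[2]
    return out


def survival_matrix(pmf: np.ndarray) -> np.ndarray:
    """P(Z >= k) for k = 0 .. cap, from a pmf with the support on the last
    axis.  Computed as a reverse cumulative sum, so it is nonnegative and
    nonincreasing by construction."""
    return np.cumsum(pmf[..., ::-1], axis=-1)[..., ::-1]


def _params_pmf(params: OutcomeParams) -> np.ndarray:
    return inflated_pmf_matrix(
        np.array(params.mu), params.delta, params.phi, params.spec
    )


def inflated_pmf(value: int, params: OutcomeParams) -> float:
    """P(Z = value) under the multiple-inflated, tail-folded distribution."""
    if not 0 <= value <= params.spec.cap:
        raise ValueError(
            f"value must be in [0, {params.spec.cap}], got {value}"
        )
    return float(_params_pmf(params)[value])


def inflated_survival(k: int, params: OutcomeParams) -> float:
    """P(Z >= k); defined for k in [0, cap + 1] with the conventions
    survival(0) = 1 and survival(cap + 1) = 0."""
    cap = params.spec.cap
    if not 0 <= k <= cap + 1:
        raise ValueError(f"k must be in [0, {cap + 1}], got {k}")
    if k == 0:
        return 1.0
    if k == cap + 1:
        return 0.0
    return float(survival_matrix(_params_pmf(params))[k])


def theta(y: int, c: int, params: OutcomeParams) -> float:
    """The parameter-dependent likelihood factor of one trial.

    Uncensored (c = 0): the pmf at the observed count.  Censored (c = 1):
    the survival probability P(Z >= y) — the participant intended at least
    the card at which the loss occurred.
    """
    if c not in (0, 1):
        raise ValueError(f"censor flag must be 0 or 1, got {c}")
    if c == 0:
        return inflated_pmf(y, params)
    if y < 1:
        raise ValueError("a censored trial requires y >= 1")
    return inflated_survival(y, params)
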