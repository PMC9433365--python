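"""Columbia Card Task game mechanics.

The CCT presents a deck of ``n_cards`` face-down cards of which ``n_loss``
are loss cards, placed uniformly at random.  Turning a win card earns
``gain`` points; turning a loss card subtracts ``loss`` points and ends the
round (the trial is *censored*).  The participant's latent intention Z is
the number of cards they would turn over absent censoring.

Everything in this module is parameter-free: the probabilities of each
observable (outcome, censor-flag) pair given an intention are determined
solely by the deck composition.

Conventions
-----------
Card indices ``k`` are 1-based (the k-th card turned).  Intentions and
observed counts are 0-based counts in ``{0, ..., n_cards}``.  For a
censored trial the observed outcome ``y`` records the index of the card at
which the loss occurred, so the number of win cards collected is ``y - 1``.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "GameConfig",
    "CANONICAL_SETTINGS",
    "censor_hazard",
    "survival_prob",
    "hazard_vector",
    "survival_vector",
    "omega",
    "omega_table",
    "trial_score",
    "ev_of_intention",
    "ev_optimal",
    "ev_table",
]


@dataclass(frozen=True)
class GameConfig:
    """One CCT game setting: payoffs and deck composition."""

    gain: float
    loss: float
    n_loss: int
    n_cards: int = 32

    def __post_init__(self) -> None:
        if self.n_cards < 1:
            raise ValueError(f"n_cards must be >= 1, got {self.n_cards}")
        if not 0 <= self.n_loss <= self.n_cards:
            raise ValueError(
                f"n_loss must be in [0, {self.n_cards}], got {self.n_loss}"
            )
        if self.gain < 0 or self.loss < 0:
            raise ValueError("gain and loss amounts must be nonnegative")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "GameConfig":
        return cls(**json.loads(text))


#: The eight canonical CCT settings: gain in {10, 30} x loss in {250, 750}
#: x number of loss cards in {1, 3}.
CANONICAL_SETTINGS: tuple[GameConfig, ...] = tuple(
    GameConfig(gain=g, loss=l, n_loss=m)
    for g, l, m in itertools.product((10, 30), (250, 750), (1, 3))
)


def censor_hazard(k: int, config: GameConfig) -> float:
    """Probability that the k-th card turned is a loss card, given that the
    first k-1 cards were win cards.

    With ``n_loss`` loss cards placed uniformly among ``n_cards`` positions
    this is the hypergeometric first-loss hazard n_loss / (n_cards - k + 1),
    clipped to [0, 1].
    """
    if not 1 <= k <= config.n_cards:
        raise IndexError(
            f"card index k must be in [1, {config.n_cards}], got {k}"
        )
    return min(1.0, config.n_loss / (config.n_cards - k + 1))


def survival_prob(k: int, config: GameConfig) -> float:
    """Probability that the first ``k`` cards turned are all win cards.

    Equals prod_{i=1..k} (1 - p_i); computed in closed form as the
    hypergeometric probability C(n_cards - k, n_loss) / C(n_cards, n_loss).
    """
    if not 0 <= k <= config.n_cards:
        raise IndexError(
            f"k must be in [0, {config.n_cards}], got {k}"
        )
    n, m = config.n_cards, config.n_loss
    if n - k < m:
        return 0.0
    return math.comb(n - k, m) / math.comb(n, m)


def hazard_vector(config: GameConfig) -> np.ndarray:
    """Hazards p_1 .. p_{n_cards} as an array (index 0 holds p_1)."""
    return np.array(
        [censor_hazard(k, config) for k in range(1, config.n_cards + 1)]
    )


def survival_vector(config: GameConfig) -> np.ndarray:
    """Survival probabilities for k = 0 .. n_cards."""
    return np.array(
        [survival_prob(k, config) for k in range(config.n_cards + 1)]
    )


def omega(k: int, c: int, intention: int, config: GameConfig) -> float:
    """The fixed outcome-probability kernel.

    Returns P(Y = k, C = c | Z = intention): for an uncensored trial the
    probability of surviving k cards (only possible when intention == k);
    for a censored trial the probability of surviving k-1 cards and hitting
    a loss card at card k (constant in the intention for intention >= k).
    """
    if c not in (0, 1):
        raise ValueError(f"censor flag must be 0 or 1, got {c}")
    n = config.n_cards
    if not 0 <= k <= n or not 0 <= intention <= n:
        raise IndexError(f"k and intention must be in [0, {n}]")
    if c == 0:
        return survival_prob(k, config) if intention == k else 0.0
    if k < 1 or intention < k:
        return 0.0
    return survival_prob(k - 1, config) * censor_hazard(k, config)


def omega_table(config: GameConfig) -> np.ndarray:
    """Full kernel as an array of shape (n_cards+1, n_cards+1, 2) indexed
    by (observed k, intention, censor flag)."""
    n = config.n_cards
    out = np.zeros((n + 1, n + 1, 2))
    for k in range(n + 1):
        for intent in range(n + 1):
            for c in (0, 1):
                out[k, intent, c] = omega(k, c, intent, config)
    return out


def trial_score(n_wins: int, hit_loss: bool, config: GameConfig) -> float:
    """Total points of a round: win cards times gain, minus the loss amount
    if a loss card ended the round."""
    if n_wins < 0:
        raise ValueError("n_wins must be nonnegative")
    return n_wins * config.gain - config.loss * bool(hit_loss)


def ev_of_intention(intention: int, config: GameConfig) -> float:
    """Expected points of intending to turn over ``intention`` cards.

    Gains collected before a loss card are kept, so the round ending at the
    j-th card scores (j-1)*gain - loss.
    """
    if not 0 <= intention <= config.n_cards:
        raise IndexError(
            f"intention must be in [0, {config.n_cards}], got {intention}"
        )
    ev = survival_prob(intention, config) * intention * config.gain
    for j in range(1, intention + 1):
        p_stop = survival_prob(j - 1, config) * censor_hazard(j, config)
        ev += p_stop * ((j - 1) * config.gain - config.loss)
    return ev


def ev_optimal(config: GameConfig, tol: float = 1e-9) -> tuple[int, ...]:
    """All intentions maximizing the expected value, ascending.

    Exact ties occur for some settings (the marginal expected value of one
    more card can be exactly zero); every intention within ``tol`` of the
    maximum is returned.  The smallest maximizer is a convenient scalar
    summary: ``ev_optimal(cfg)[0]``.
    """
    evs = np.array(
        [ev_of_intention(l, config) for l in range(config.n_cards + 1)]
    )
    best = evs.max()
    return tuple(int(l) for l in np.nonzero(evs >= best - tol * (1 + abs(best)))[0])


def ev_table(configs: tuple[GameConfig, ...] = CANONICAL_SETTINGS) -> "list[dict]":
    """EV-optimal strategy per game setting (rows for the 2x2x2 design)."""
    rows = []
    for cfg in configs:
        opt = ev_optimal(cfg)
        rows.append(
            {
                "gain": cfg.gain,
                "loss": cfg.loss,
                "n_loss": cfg.n_loss,
                "optimal": opt[0],
                "all_optimal": ",".join(str(v) for v in opt),
                "ev": ev_of_intention(opt[0], cfg),
            }
        )
    return rows
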