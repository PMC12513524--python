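"""Synthetic lipid panels and rater matrices.

The generator emulates the two kinds of input the scoring tool and the
agreement module consume:

* pre/post lipid panel pairs — a pre value is drawn uniformly within a
  sampled NCEP category interval (the unbounded top interval is truncated
  at twice its lower bound for sampling only); the post value is the pre
  value times a per-marker multiplicative effect times lognormal noise;
* raters x items score matrices — each rater reproduces the true score but
  mis-scores by +/-1 with a configurable error probability, emulating the
  three-observer reliability study design (24 interventions, 3 observers).

Everything is reproducible from a single integer seed.  The generator is
deliberately transparent rather than physiological: markers are sampled
independently (no TC = LDL + HDL + TG/2.2 constraint, no correlation
structure) and within-category values are uniform, not lognormal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .agreement import RatingsMatrix
from .domain import CATEGORY_LADDER, Category, LipidPanel, Marker, Unit
from .errors import ConfigError

__all__ = [
    "SimulationConfig",
    "simulate_panels",
    "simulate_ratings",
    "category_interval",
]

# mmol/L sampling intervals per (marker, category); the top interval of each
# ladder is truncated at 2x its lower bound, and the open lower end of a
# bottom interval is floored slightly above zero so sampled values stay
# valid measurements.
_VALUE_FLOOR = 0.05


def category_interval(marker: Marker, category: Category) -> tuple[float, float]:
    """mmol/L interval that ``categorize`` maps back to ``category``."""
    from .domain import _UPPER_CUTS, _HDL_NORMAL_CUT  # noqa: PLC2701

    if marker is Marker.HDL_C:
        cut = _HDL_NORMAL_CUT[Unit.MMOL_PER_L]
        if category is Category.NORMAL:
            return (cut, 2 * cut)
        return (_VALUE_FLOOR, cut)
    cuts = _UPPER_CUTS[(marker, Unit.MMOL_PER_L)]
    ladder = CATEGORY_LADDER[marker]
    rank = ladder.index(category)
    bounds = (_VALUE_FLOOR, *cuts, 2 * cuts[-1])
    return (bounds[rank], bounds[rank + 1])


def _uniform_probs(marker: Marker) -> tuple[float, ...]:
    k = len(CATEGORY_LADDER[marker])
    return tuple(1.0 / k for _ in range(k))


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world for the panel/rating generator.

    Defaults mirror the reliability study design this tool was validated
    with: 24 scored interventions, priors spanning every NCEP category
    uniformly, a null intervention (effect 1.0), mild biological noise
    (sd 0.05 on the log scale) and a 5% per-component rater error rate.
    """

    n_subjects: int = 24
    seed: int = 0
    pre_category_probs: Mapping[Marker, Sequence[float]] = field(
        default_factory=lambda: {m: _uniform_probs(m) for m in Marker}
    )
    effect: Mapping[Marker, float] = field(
        default_factory=lambda: {m: 1.0 for m in Marker}
    )
    noise_sd: float = 0.05
    rater_error_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.rater_error_rate <= 1.0:
            raise ConfigError(
                f"rater_error_rate must be in [0, 1], got {self.rater_error_rate}"
            )
        probs = {m: _uniform_probs(m) for m in Marker}
        for m, p in dict(self.pre_category_probs).items():
            m = Marker(m)
            p = tuple(float(x) for x in p)
            if len(p) != len(CATEGORY_LADDER[m]):
                raise ConfigError(
                    f"{m.value} needs {len(CATEGORY_LADDER[m])} category "
                    f"probabilities, got {len(p)}"
                )
            if any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
                raise ConfigError(
                    f"{m.value} category probabilities must be non-negative "
                    f"and sum to 1, got {p}"
                )
            probs[m] = p
        object.__setattr__(self, "pre_category_probs", probs)
        effects = {m: 1.0 for m in Marker}
        for m, e in dict(self.effect).items():
            m = Marker(m)
            e = float(e)
            if e <= 0:
                raise ConfigError(f"effect for {m.value} must be > 0, got {e}")
            effects[m] = e
        object.__setattr__(self, "effect", effects)


def simulate_panels(
    config: SimulationConfig,
) -> list[tuple[LipidPanel, LipidPanel]]:
    """Draw ``n_subjects`` pre/post panel pairs in mmol/L.

    ``post = pre * effect * exp(N(0, noise_sd))`` per marker; effect 1.0
    with zero noise therefore reproduces the pre panel exactly.
    """
    rng = np.random.default_rng(config.seed)
    pairs = []
    for _ in range(config.n_subjects):
        pre_values: dict[Marker, float] = {}
        post_values: dict[Marker, float] = {}
        for marker in Marker:
            ladder = CATEGORY_LADDER[marker]
            probs = config.pre_category_probs[marker]
            cat = ladder[rng.choice(len(ladder), p=probs)]
            low, high = category_interval(marker, cat)
            pre = float(rng.uniform(low, high))
            noise = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd else 0.0
            post = pre * config.effect[marker] * float(np.exp(noise))
            pre_values[marker] = pre
            post_values[marker] = post
        pairs.append(
            (
                LipidPanel(pre_values, Unit.MMOL_PER_L),
                LipidPanel(post_values, Unit.MMOL_PER_L),
            )
        )
    return pairs


def simulate_ratings(
    true_scores: Sequence[int],
    m_raters: int = 3,
    rater_error_rate: float = 0.05,
    seed: int = 0,
    clip: tuple[int, int] = (-14, 18),
) -> RatingsMatrix:
    """Simulate ``m_raters`` observers independently scoring the same items.

    Each cell equals the item's true score, perturbed by +/-1 (random sign)
    with probability ``rater_error_rate``, then clipped to the legal score
    range (the complete-panel total range by default).
    """
    if m_raters < 2:
        raise ConfigError(f"need >= 2 raters, got {m_raters}")
    if not 0.0 <= rater_error_rate <= 1.0:
        raise ConfigError(f"rater_error_rate must be in [0, 1], got {rater_error_rate}")
    truth = np.asarray(true_scores, dtype=int)
    if truth.ndim != 1 or truth.shape[0] < 2:
        raise ConfigError("true_scores must be a 1-D sequence of >= 2 integers")
    rng = np.random.default_rng(seed)
    n = truth.shape[0]
    errs = rng.random((n, m_raters)) < rater_error_rate
    signs = rng.choice([-1, 1], size=(n, m_raters))
    scores = truth[:, None] + errs * signs
    scores = np.clip(scores, clip[0], clip[1])
    return RatingsMatrix(
        scores=scores.astype(int),
        raters=tuple(f"observer{j+1}" for j in range(m_raters)),
    )
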