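"""Count normalisation and Poisson noise realisations.

Noiseless simulated projections are scaled to a clinically realistic total
count level (set by the administered activity and collimator) and then
replaced pixel-wise by Poisson deviates, once per acquisition realisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import rng_for
from .errors import ConfigurationError, NormalisationError
from .projector import ProjectionSet

#: Clinical total counts over all projections, keyed by (collimator, MBq).
COUNT_TOTALS = {
    ("LEGP", 25): 1.23e6,
    ("LEGP", 125): 6.14e6,
    ("LEHR", 25): 0.73e6,
    ("LEHR", 125): 3.64e6,
}


@dataclass(frozen=True)
class NoiseConfig:
    target_total_counts: float
    n_realisations: int = 40
    base_seed: int = 0

    def __post_init__(self):
        if self.target_total_counts <= 0:
            raise ConfigurationError("target_total_counts must be positive")
        if self.n_realisations < 1:
            raise ConfigurationError("n_realisations must be >= 1")


def target_counts(collimator: str, activity_mbq: int) -> float:
    try:
        return COUNT_TOTALS[(collimator, activity_mbq)]
    except KeyError:
        raise ConfigurationError(
            f"no count total configured for ({collimator}, {activity_mbq} MBq)"
        ) from None


def normalize_counts(projections: ProjectionSet, target_total: float) -> ProjectionSet:
    """Scale projections so their total equals ``target_total`` exactly."""
    s = projections.counts.sum()
    if s <= 0:
        raise NormalisationError("cannot normalise all-zero projections")
    return projections.copy_with(projections.counts * (target_total / s))


def poisson_realize(projections: ProjectionSet, seed) -> ProjectionSet:
    """One noisy acquisition: independent Poisson deviates per pixel."""
    if np.any(projections.counts < 0):
        raise ConfigurationError("Poisson means must be non-negative")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(projections.counts).astype(np.float64)
    return projections.copy_with(noisy)


def make_realizations(projections: ProjectionSet, config: NoiseConfig,
                      stream: str = "") -> list[ProjectionSet]:
    """Scale to the target total and draw ``n_realisations`` noisy copies.

    Realisation seeds are derived from (base_seed, stream, index) so each
    (design, realisation) pair is reproducible in isolation.
    """
    scaled = normalize_counts(projections, config.target_total_counts)
    return [
        poisson_realize(scaled, rng_for(config.base_seed, stream, i))
        for i in range(config.n_realisations)
    ]
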