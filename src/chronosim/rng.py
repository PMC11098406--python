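"""Reproducible named random substreams.

Every stochastic component draws from its own substream keyed by
(master seed, stream name, wave), so toggling one component never perturbs
another, and all draws are generated as person-id-ordered arrays, making
results invariant to person iteration/storage order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "stream_factory", "person_uniform", "person_normal"]


def substream(master_seed: int, name: str, wave: int = 0) -> np.random.Generator:
    """Generator for the named substream at the given wave."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) % (2**31), key, int(wave)]))


def person_uniform(rng: np.random.Generator, pop) -> np.ndarray:
    """Uniform(0,1) per person, indexed by stable uid.

    Draws are generated over the original cohort's id span and selected by
    uid, so a person receives the same variate regardless of where they are
    stored (iteration/storage-order invariance)."""
    return rng.random(pop.uid_span)[pop.uid]


def person_normal(rng: np.random.Generator, pop, mean: float = 0.0, sd: float = 1.0) -> np.ndarray:
    """Normal(mean, sd) per person, indexed by stable uid."""
    return mean + sd * rng.standard_normal(pop.uid_span)[pop.uid]


def stream_factory(master_seed: int, wave: int = 0):
    """Returns ``rng_for(name)`` binding the master seed and wave."""
    def rng_for(name: str) -> np.random.Generator:
        return substream(master_seed, name, wave)

    return rng_for
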