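"""Deterministic, named random substreams.

A single integer seed drives every stochastic component.  Each component
draws from its own substream, keyed by a stable name, so regenerating one
artifact (e.g. pollutant fields) never perturbs another (e.g. individuals).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream `name` of `seed`.

    The stream key is ``[seed, crc32(name)]`` fed to `numpy.random.SeedSequence`,
    which is stable across platforms and numpy versions that keep the
    Philox/SeedSequence contract.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
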