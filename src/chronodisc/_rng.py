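"""Seed-substream helpers.

One global integer seed fans out into named, order-independent substreams so
that adding or removing a participant (or disabling a pipeline stage) never
perturbs the random numbers any other participant or stage receives.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "participant_stream"]


def _key_to_int(key: object) -> int:
    """Map an arbitrary hashable label to a stable 32-bit integer."""
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys`` under ``seed``.

    The same (seed, keys) always yields the same stream; distinct key tuples
    yield statistically independent streams.
    """
    entropy = (int(seed),) + tuple(_key_to_int(k) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def participant_stream(seed: int, participant: object, stage: str) -> np.random.Generator:
    """Per-participant, per-stage substream keyed by the participant id."""
    return substream(seed, stage, participant)
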