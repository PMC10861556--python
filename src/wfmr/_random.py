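"""Seed management.

A single user-facing integer seed is expanded into independent per-stage
streams by combining it with a stable 32-bit hash of the stage name inside a
:class:`numpy.random.SeedSequence`.  Stages are therefore individually
reproducible: re-running one stage with the same global seed gives the same
draws regardless of which other stages ran before it.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed_sequence", "stage_rng", "spawn_rngs"]


def _stage_key(stage: str) -> int:
    return zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF


def stage_seed_sequence(seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic child seed sequence for a named pipeline stage."""
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(_stage_key(stage),))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for a named stage, independent of other stages."""
    return np.random.default_rng(stage_seed_sequence(seed, stage))


def spawn_rngs(seed: int, stage: str, n: int) -> list[np.random.Generator]:
    """``n`` independent generators (e.g. one per simulation replicate).

    The i-th generator depends only on ``(seed, stage, i)``, so results are
    invariant to how replicates are scheduled across workers.
    """
    children = stage_seed_sequence(seed, stage).spawn(n)
    return [np.random.default_rng(c) for c in children]
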