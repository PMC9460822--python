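"""Deterministic fan-out of one global seed into independent per-stage streams.

Every stage derives its generator as ``default_rng(SeedSequence((seed, crc32(stage))))``,
so re-running a single stage with the pipeline seed reproduces exactly what the
full pipeline run produced for that stage.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "stage_rng"]


def child_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Seed sequence for a named stage, derived stably from the global seed."""
    return np.random.SeedSequence((int(seed), zlib.crc32(stage.encode("utf-8"))))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Fresh generator for a named stage."""
    return np.random.default_rng(child_seed(seed, stage))
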