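"""Deterministic per-stage random streams derived from one master seed."""

from __future__ import annotations

import zlib

import numpy as np


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """A reproducible generator for one pipeline stage.

    One master seed covers a whole run; each stage draws from an
    independent stream keyed by its name, so adding a stage never
    perturbs the randomness of another.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key]))
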