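"""Deterministic per-stage seed derivation.

Every stochastic stage draws from a Generator obtained through
:func:`stage_rng` so a single master seed reproduces a whole run while
stages stay independent: changing the surrogate seed cannot perturb the
synthetic cortex, and vice versa.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed", "stage_rng"]


def stage_seed(master: int, stage: str) -> int:
    """Derive a 31-bit stage seed from a master seed and a stage name.

    The schedule is a CRC32 of the stage name mixed with the master seed
    through :class:`numpy.random.SeedSequence`, so it is stable across
    runs, platforms and numpy versions.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(master), tag])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def stage_rng(master: int, stage: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for one named stage."""
    return np.random.default_rng(stage_seed(master, stage))
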