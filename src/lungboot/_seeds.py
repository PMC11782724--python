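"""Deterministic sub-seeding.

Every source of randomness in the package derives its generator from a master
integer seed plus an integer path describing *where* in the computation the
stream is used, via :class:`numpy.random.SeedSequence` spawn keys.  Two streams
with different paths are statistically independent; the same (seed, path)
always yields the same stream.

Stream constants (first path element):

====================  ====
phantom fields           0
respiratory series       1
cardiac series           2
scan-set depths          3
bootstrap iterations     4
CI re-computations       5
Monte-Carlo truth        6
====================  ====
"""

from __future__ import annotations

import numpy as np

STREAM_PHANTOM = 0
STREAM_RESP = 1
STREAM_CARD = 2
STREAM_DEPTHS = 3
STREAM_BOOT = 4
STREAM_CI = 5
STREAM_MC = 6


def seed_sequence(seed: int, *path: int) -> np.random.SeedSequence:
    """SeedSequence for master ``seed`` at integer ``path``."""
    return np.random.SeedSequence(
        entropy=int(seed), spawn_key=tuple(int(p) for p in path)
    )


def rng_for(seed: int, *path: int) -> np.random.Generator:
    """PCG64 generator for master ``seed`` at integer ``path``."""
    return np.random.default_rng(seed_sequence(seed, *path))


def child_seed(seed: int, *path: int) -> int:
    """A derived integer seed (< 2**31) usable as a new master seed."""
    return int(seed_sequence(seed, *path).generate_state(1, np.uint32)[0] % 2**31)
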