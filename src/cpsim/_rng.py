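"""Deterministic named random substreams.

Every stochastic stage of a run draws from its own generator derived from
the master seed plus a tuple of string/int tags, so adding or reordering
stages never perturbs the draws of other stages and a run is
bit-reproducible from its master seed alone.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(master_seed: int, *tags: object) -> np.random.Generator:
    """Return a generator for the substream identified by ``tags``.

    Tags are hashed with CRC32 (stable across platforms and Python
    versions, unlike ``hash``) and fed to a ``SeedSequence`` together with
    the master seed.
    """
    keys = [zlib.crc32(str(t).encode("utf8")) for t in tags]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0xFFFFFFFF, *keys]))


def spawn_seed(master_seed: int, *tags: object) -> int:
    """Derive a 32-bit integer seed for APIs that take plain seeds."""
    keys = [zlib.crc32(str(t).encode("utf8")) for t in tags]
    ss = np.random.SeedSequence([int(master_seed) & 0xFFFFFFFF, *keys])
    return int(ss.generate_state(1)[0])
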