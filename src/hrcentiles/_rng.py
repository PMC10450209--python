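"""Seed-substream derivation.

Every stochastic stage of the pipeline draws from its own generator, derived
from the single master seed plus a stable string label.  Because the
substream depends only on (seed, label), adding or reordering stages never
perturbs the draws of another stage.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for stage ``label`` under master ``seed``.

    The label is folded into the seed sequence via its CRC-32, which is
    stable across platforms and Python versions (unlike ``hash``).
    """
    tag = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
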