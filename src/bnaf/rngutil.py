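"""Named, reproducible random substreams derived from one global seed."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _label_int(label) -> int:
    if isinstance(label, (int, np.integer)):
        return int(label) & 0xFFFFFFFF
    digest = hashlib.sha256(str(label).encode()).digest()
    return int.from_bytes(digest[:4], "big")


def substream(seed: int, *labels) -> np.random.Generator:
    """Generator for the substream named by ``labels`` under a global ``seed``.

    Streams with different labels are statistically independent; identical
    (seed, labels) always reproduce the same stream.
    """
    entropy = [int(seed)] + [_label_int(x) for x in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))
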