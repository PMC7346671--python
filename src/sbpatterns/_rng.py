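"""Named, reproducible random substreams derived from a single root seed."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    Each (seed, name) pair yields an independent, reproducible stream, so the
    cohort generator, k-means restarts and imputation jitter can be re-run in
    isolation without perturbing one another.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
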