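"""Shared helpers: seed plumbing and numerically safe statistics."""
from __future__ import annotations

import warnings
import zlib

import numpy as np

__all__ = ["child_rng", "child_seed", "pearson"]


def _tag_int(tag: str) -> int:
    return zlib.crc32(tag.encode("utf-8"))


def child_seed(seed: int, *tags: str) -> np.random.SeedSequence:
    """Derive a named child seed from one integer master seed.

    Every stochastic stage of the pipeline draws its generator from the master
    seed plus a stable string tag, so stages are reproducible independently of
    execution order.
    """
    return np.random.SeedSequence([int(seed)] + [_tag_int(t) for t in tags])


def child_rng(seed: int, *tags: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *tags))


def pearson(a: np.ndarray, b: np.ndarray, warn: bool = True) -> float:
    """Pearson correlation with a defined value for degenerate input.

    A zero-variance vector has no correlation; downstream scoring treats that
    fold/trial conservatively, so the value is defined as 0 (with a warning)
    instead of NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("pearson: shape mismatch")
    a = a - a.mean()
    b = b - b.mean()
    na = np.sqrt(a @ a)
    nb = np.sqrt(b @ b)
    if na == 0.0 or nb == 0.0:
        if warn:
            warnings.warn("zero-variance input to pearson; correlation set to 0")
        return 0.0
    return float(np.clip((a @ b) / (na * nb), -1.0, 1.0))
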