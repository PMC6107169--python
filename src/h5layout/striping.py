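"""Lustre-style file striping model.

A striped file is cut into fixed-size stripes placed round-robin over
``stripe_count`` object storage targets (OSTs), starting from a first
OST the filesystem picks at random for load balancing.  The model maps
byte offsets to OSTs, enumerates a file's stripes, applies the standard
stripe-count rules of thumb, and quantifies how many OSTs a byte range
(for example one chunk) touches — the quantity chunk/stripe alignment
is meant to reduce.

Stripe sizes here are binary (1 MB stripe = 2**20 B, the Lustre
convention consistent with the required 64 KiB multiple); dataset sizes
reported elsewhere in the package use decimal MB/GB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StripingConfig",
    "StripeMap",
    "ost_for_offset",
    "stripes_of_file",
    "recommended_stripe_count",
    "osts_touched_by_range",
    "random_first_ost",
]

STRIPE_GRANULE = 65536  # stripe size must be a multiple of 64 KiB
_DECIMAL_GB = 10**9


@dataclass(frozen=True)
class StripingConfig:
    """Stripe size S (bytes), stripe count c, and the starting OST."""

    stripe_size: int = 2**20
    stripe_count: int = 4
    first_ost: int = 0
    total_osts: int = 48

    def __post_init__(self) -> None:
        if self.stripe_size < STRIPE_GRANULE or self.stripe_size % STRIPE_GRANULE:
            raise ValueError(
                f"stripe_size must be a positive multiple of {STRIPE_GRANULE} B"
            )
        if not 1 <= self.stripe_count <= self.total_osts:
            raise ValueError("stripe_count must be in [1, total_osts]")
        if not 0 <= self.first_ost < self.total_osts:
            raise ValueError("first_ost must be in [0, total_osts)")

    def ost_of_stripe(self, stripe_index: int) -> int:
        return (self.first_ost + stripe_index % self.stripe_count) % self.total_osts


@dataclass(frozen=True)
class StripeMap:
    """Ordered (stripe_index, ost_id, byte_size) triples for one file."""

    stripes: tuple[tuple[int, int, int], ...]
    file_size: int


def random_first_ost(cfg_total_osts: int, rng: np.random.Generator) -> int:
    """Seeded stand-in for the filesystem's random first-OST choice."""
    return int(rng.integers(0, cfg_total_osts))


def ost_for_offset(offset: int, cfg: StripingConfig) -> int:
    """OST holding the stripe that contains ``offset``."""
    if offset < 0:
        raise ValueError("offset must be >= 0")
    return cfg.ost_of_stripe(offset // cfg.stripe_size)


def stripes_of_file(file_size: int, cfg: StripingConfig) -> StripeMap:
    """Enumerate the stripes of a file; the last stripe may be short."""
    if file_size < 1:
        raise ValueError("file_size must be >= 1")
    n = -(-file_size // cfg.stripe_size)
    stripes = []
    for i in range(n):
        size = cfg.stripe_size if i < n - 1 else file_size - cfg.stripe_size * (n - 1)
        stripes.append((i, cfg.ost_of_stripe(i), size))
    return StripeMap(stripes=tuple(stripes), file_size=file_size)


def recommended_stripe_count(file_size_bytes: int) -> tuple[int, int]:
    """Rule-of-thumb stripe-count range: 1 stripe per 4 GB up to 1 per GB.

    GB is decimal (10**9 B); for the ~5.21 GB benchmark dataset this
    gives the range (2, 6).
    """
    if file_size_bytes < 1:
        raise ValueError("file_size_bytes must be >= 1")
    low = max(1, -(-file_size_bytes // (4 * _DECIMAL_GB)))
    high = max(low, -(-file_size_bytes // _DECIMAL_GB))
    return low, high


def osts_touched_by_range(start_offset: int, length: int, cfg: StripingConfig) -> int:
    """Distinct OSTs holding stripes overlapped by a byte range."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if start_offset < 0:
        raise ValueError("start_offset must be >= 0")
    first = start_offset // cfg.stripe_size
    last = (start_offset + length - 1) // cfg.stripe_size
    # OST assignment is periodic in the stripe index with period c.
    span = min(last - first + 1, cfg.stripe_count)
    return len({cfg.ost_of_stripe(i) for i in range(first, first + span)})
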