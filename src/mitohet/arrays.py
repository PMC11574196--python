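"""Elementary moves on mitochondrial genome arrays.

A cell's mitochondrial network is represented as a single unbranched
array of mtDNA copies, one symbol per copy, with two variants denoted
0 and 1.  Order along the array is meaningful: copies sitting in the
same stretch of the tubular network tend to be partitioned together,
which is why division takes a contiguous block rather than a random
subset.  Three moves act on such arrays:

* relaxed replication — molecules are picked uniformly at random (the
  same molecule may replicate repeatedly, a Pólya-urn scheme) and the
  new copy is inserted next to its template, until the array is back at
  the target copy number;
* fission–fusion shuffling — the array is cut into ``nspl`` contiguous
  fragments at random internal boundaries and the fragments re-fuse in
  random order (never reversed);
* division — a fixed-size block of ``ndau`` copies splits off one end
  and founds the daughter cell.

All functions are pure: they return new arrays and draw randomness only
from the :class:`numpy.random.Generator` passed in.
"""

from __future__ import annotations

import logging
from typing import Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

ArrayLike = Union[str, Sequence[int], np.ndarray]

FOUNDER_PATTERNS = ("mixed", "semi_mixed", "non_mixed")


def as_array(alleles: ArrayLike) -> np.ndarray:
    """Coerce a string like ``"0101"`` or an integer sequence to a uint8 array.

    Raises ``ValueError`` on empty input or symbols outside {0, 1}.
    """
    if isinstance(alleles, str):
        arr = np.frombuffer(alleles.encode("ascii"), dtype=np.uint8) - ord("0")
    else:
        arr = np.asarray(alleles, dtype=np.uint8)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("allele array must be a non-empty 1-D sequence")
    if not np.all((arr == 0) | (arr == 1)):
        raise ValueError("alleles must be 0 or 1")
    return arr.copy()


def to_string(array: np.ndarray) -> str:
    """Render an allele array as a compact 0/1 string (for logs and tests)."""
    return "".join("01"[int(a)] for a in array)


def _split_sizes(total: int, m: int, large_first: bool) -> list[int]:
    base, rem = divmod(total, m)
    large = [base + 1] * rem
    small = [base] * (m - rem)
    return large + small if large_first else small + large


def init_founder(
    n_copies: int,
    pattern: ArrayLike = "mixed",
    fraction1: float = 0.5,
) -> np.ndarray:
    """Build the founder (zygote) array.

    ``pattern`` is one of the named layouts or an explicit allele
    sequence.  With ``k = round(n_copies * fraction1)`` copies of
    variant 1:

    * ``mixed`` — maximally interleaved, e.g. ``0101...`` at 50 %;
    * ``semi_mixed`` — short alternating runs, e.g. ``0011100011``;
    * ``non_mixed`` — two homogeneous blocks, e.g. ``0000011111``.

    A mixed founder with zero copies of either variant is permitted but
    logged as degenerate (segregation is then trivially complete).
    """
    if isinstance(pattern, str) and pattern not in FOUNDER_PATTERNS:
        # treat any other string as an explicit allele sequence
        return as_array(pattern)
    if not isinstance(pattern, str):
        return as_array(pattern)
    if n_copies < 2:
        raise ValueError("founder needs at least 2 copies")
    if not 0.0 <= fraction1 <= 1.0:
        raise ValueError("fraction1 must lie in [0, 1]")
    k = int(round(n_copies * fraction1))
    if pattern == "mixed":
        if k == 0 or k == n_copies:
            logger.warning(
                "degenerate mixed founder: %d of %d copies are variant 1", k, n_copies
            )
        # variant 1 at positions where the running quota round(i*k/n) advances
        idx = np.arange(n_copies)
        arr = (((idx + 1) * k) // n_copies - (idx * k) // n_copies).astype(np.uint8)
        return arr
    if pattern == "non_mixed":
        return np.concatenate(
            [np.zeros(n_copies - k, dtype=np.uint8), np.ones(k, dtype=np.uint8)]
        )
    # semi_mixed: alternating 0-runs and 1-runs, run lengths as even as possible,
    # shorter 0-runs leading and longer 1-runs leading so that n=10 at 50 %
    # reproduces 0011100011
    m = max(2, round(n_copies / 5))
    zero_sizes = _split_sizes(n_copies - k, m, large_first=False)
    one_sizes = _split_sizes(k, m, large_first=True)
    parts: list[np.ndarray] = []
    for z, o in zip(zero_sizes, one_sizes):
        parts.append(np.zeros(z, dtype=np.uint8))
        parts.append(np.ones(o, dtype=np.uint8))
    return np.concatenate(parts)


def replicate_to_capacity(
    array: np.ndarray, target_n: int, rng: np.random.Generator
) -> np.ndarray:
    """Relaxed replication back to ``target_n`` copies.

    Each step picks one existing molecule uniformly at random (with
    replacement across steps — a molecule may template several rounds)
    and inserts an identical copy immediately to its right.  There is
    no degradation, so an array above capacity is an error.
    """
    n = len(array)
    if n > target_n:
        raise ValueError(f"array of {n} copies exceeds target {target_n}; the model has no mtDNA depletion")
    if n == target_n:
        return np.asarray(array, dtype=np.uint8).copy()
    out = list(array)
    while len(out) < target_n:
        i = int(rng.integers(len(out)))
        out.insert(i + 1, out[i])
    return np.array(out, dtype=np.uint8)


def shuffle(array: np.ndarray, nspl: int, rng: np.random.Generator) -> np.ndarray:
    """Fission–fusion shuffling: cut into ``nspl`` fragments, re-fuse randomly.

    The ``nspl - 1`` cut points are distinct internal boundaries drawn
    uniformly at random; fragments are concatenated in a uniformly
    random order and never reversed.  ``nspl = 1`` is the identity.
    """
    n = len(array)
    if not 1 <= nspl <= n:
        raise ValueError(f"nspl={nspl} must lie in [1, {n}]")
    arr = np.asarray(array, dtype=np.uint8)
    if nspl == 1:
        return arr.copy()
    cuts = np.sort(rng.choice(np.arange(1, n), size=nspl - 1, replace=False))
    fragments = np.split(arr, cuts)
    order = rng.permutation(nspl)
    return np.concatenate([fragments[i] for i in order])


def divide(array: np.ndarray, ndau: int) -> tuple[np.ndarray, np.ndarray]:
    """Split off the daughter's block of ``ndau`` copies.

    The daughter receives the shorter part, capped at half the copy
    number; by convention it takes the left end (shuffling has already
    randomised fragment order, so a random-end choice would be
    distributionally equivalent).  Returns ``(mother, daughter)``.
    """
    n = len(array)
    if ndau < 1:
        raise ValueError("daughter must receive at least one copy")
    if ndau > n // 2:
        raise ValueError(
            f"ndau={ndau} exceeds the cap of half the copy number (floor({n}/2) = {n // 2})"
        )
    arr = np.asarray(array, dtype=np.uint8)
    return arr[ndau:].copy(), arr[:ndau].copy()


def allele_fraction(array: np.ndarray) -> float:
    """Fraction of variant-1 copies — the true heteroplasmy of the cell."""
    arr = np.asarray(array)
    if arr.size == 0:
        raise ValueError("empty array has no allele fraction")
    return float(arr.sum() / arr.size)
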