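"""Zeckendorf (Fibonacci) integer codec.

Every positive integer has a unique representation as a sum of distinct,
pairwise non-consecutive Fibonacci numbers (Zeckendorf's theorem).  For
8-bit image intensities the usable basis is the 12 distinct Fibonacci
values not exceeding 255::

    {1, 2, 3, 5, 8, 13, 21, 34, 55, 89, 144, 233}

so every intensity maps to a sparse term set, e.g. 183 -> (144, 34, 5) and
255 -> (233, 21, 1).  The duplicated leading 1 of the mathematical sequence
(f(0) = f(1) = 1) appears once: the codec operates on the *set* of distinct
values, which is the object the coding transforms manipulate.

The greedy largest-first construction implemented here provably yields the
non-adjacent representation and is also the representation with the fewest
terms among all Fibonacci subset sums of the same integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

__all__ = [
    "FibonacciBasis",
    "ZDecomposition",
    "fibonacci_basis",
    "zeckendorf",
    "reconstruct",
    "is_valid_zeckendorf",
    "enumerate_representations",
]


@dataclass(frozen=True)
class FibonacciBasis:
    """Ordered distinct Fibonacci values usable to code integers up to a cap.

    Attributes
    ----------
    values : tuple of int
        Ascending distinct Fibonacci numbers, starting 1, 2, 3, 5, ...
    max_value : int
        The intensity ceiling; the next Fibonacci number would exceed it.
    """

    values: tuple[int, ...]
    max_value: int

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def index(self, value: int) -> int:
        """Position of ``value`` in the basis; raises ValueError if absent."""
        return self.values.index(value)


@dataclass(frozen=True)
class ZDecomposition:
    """The unique non-adjacent Fibonacci term set of one integer.

    ``terms`` is stored descending, matching the conventional printed tuple
    form, e.g. (233, 21, 1) for 255.  ``terms`` is empty iff ``source == 0``.
    """

    terms: tuple[int, ...]
    source: int

    def __iter__(self):
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)


@lru_cache(maxsize=None)
def fibonacci_basis(max_value: int) -> FibonacciBasis:
    """Build the distinct-value Fibonacci basis capped at ``max_value``.

    Parameters
    ----------
    max_value : int
        Positive intensity ceiling, e.g. 255 for 8-bit images.

    Returns
    -------
    FibonacciBasis
        Ascending distinct values; for ``max_value=255`` exactly 12 elements.

    Raises
    ------
    ValueError
        If ``max_value`` is not a positive integer.
    """
    if not isinstance(max_value, (int,)) or isinstance(max_value, bool):
        raise ValueError(f"max_value must be an integer, got {max_value!r}")
    if max_value < 1:
        raise ValueError(f"max_value must be >= 1, got {max_value}")
    values = []
    a, b = 1, 2  # distinct-value sequence: 1, 2, 3, 5, 8, ...
    while a <= max_value:
        values.append(a)
        a, b = b, a + b
    return FibonacciBasis(values=tuple(values), max_value=max_value)


def zeckendorf(n: int, basis: FibonacciBasis | None = None) -> ZDecomposition:
    """Greedy largest-first Zeckendorf decomposition of ``n``.

    Repeatedly subtracts the largest basis value not exceeding the
    remainder; the result is the unique representation whose term set
    contains no two adjacent basis positions.  ``zeckendorf(0)`` is the
    empty decomposition.

    Raises
    ------
    ValueError
        If ``n`` is negative or exceeds the sum of the basis.
    """
    if basis is None:
        basis = fibonacci_basis(255)
    if n < 0:
        raise ValueError(f"n must be nonnegative, got {n}")
    if n > sum(basis.values):
        raise ValueError(
            f"{n} is not representable within a basis capped at {basis.max_value}"
        )
    terms = []
    remainder = n
    for value in reversed(basis.values):
        if value <= remainder:
            terms.append(value)
            remainder -= value
            if remainder == 0:
                break
    if remainder != 0:  # cannot happen for a valid Fibonacci basis
        raise ValueError(f"{n} is not representable in basis {basis.values}")
    return ZDecomposition(terms=tuple(terms), source=n)


def reconstruct(d: ZDecomposition) -> int:
    """Sum of the decomposition's terms; inverse of :func:`zeckendorf`."""
    return sum(d.terms)


def is_valid_zeckendorf(terms, basis: FibonacciBasis | None = None) -> bool:
    """True iff ``terms`` are distinct basis members with no two adjacent.

    Adjacency is adjacency of *positions* in the distinct-value basis, so
    {2, 1} and {5, 3} both fail (consecutive Fibonacci numbers), while
    {233, 21, 1} passes.
    """
    if basis is None:
        basis = fibonacci_basis(255)
    terms = list(terms)
    if len(set(terms)) != len(terms):
        return False
    try:
        positions = sorted(basis.index(t) for t in terms)
    except ValueError:
        return False
    return all(b - a >= 2 for a, b in zip(positions, positions[1:]))


def enumerate_representations(
    n: int, basis: FibonacciBasis | None = None
) -> list[tuple[int, ...]]:
    """All Fibonacci subset sums equal to ``n``, as descending tuples.

    Brute-force enumeration over every subset of the basis (4096 subsets
    for the 8-bit basis); serves as the uniqueness/minimality oracle for
    the greedy construction.  The result is sorted lexicographically on
    the descending tuples; ``n=0`` yields ``[()]``.
    """
    if basis is None:
        basis = fibonacci_basis(255)
    if n < 0 or n > sum(basis.values):
        raise ValueError(f"{n} is outside the basis range")
    return list(_subsets_by_sum(basis).get(n, []))


@lru_cache(maxsize=None)
def _subsets_by_sum(basis: FibonacciBasis) -> dict[int, tuple[tuple[int, ...], ...]]:
    """One pass over all 2^|basis| subsets, bucketed by their sum."""
    values = basis.values
    buckets: dict[int, list[tuple[int, ...]]] = {}
    for mask in range(1 << len(values)):
        subset = tuple(
            values[i] for i in range(len(values) - 1, -1, -1) if mask >> i & 1
        )
        buckets.setdefault(sum(subset), []).append(subset)
    return {total: tuple(sorted(subs)) for total, subs in buckets.items()}
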