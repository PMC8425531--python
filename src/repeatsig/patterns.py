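"""Small shared primitives for repeat patterns.

A tandem-repeat pattern is only defined up to cyclic rotation (a run of
``GTGAGTGA...`` can equally be read as a run of ``TGAG...``).  Everything
downstream therefore works with the lexicographically smallest rotation as
the canonical form.
"""

from __future__ import annotations

from functools import lru_cache

import edlib

ALPHABET = "ACGT"


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance between two nucleotide strings."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return _cached_edit(a, b) if len(a) <= 32 and len(b) <= 32 else _edlib(a, b)


def _edlib(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


@lru_cache(maxsize=1 << 18)
def _cached_edit(a: str, b: str) -> int:
    return _edlib(a, b)


def rotations(pattern: str) -> list[str]:
    return [pattern[i:] + pattern[:i] for i in range(len(pattern))]


def canonical_rotation(pattern: str) -> str:
    """Lexicographically smallest cyclic rotation of ``pattern``."""
    if not pattern:
        raise ValueError("empty pattern")
    return min(rotations(pattern))


def rotation_distance(s: str, pattern: str) -> int:
    """Minimal edit distance from ``s`` to any rotation of ``pattern``."""
    return min(edit_distance(s, r) for r in set(rotations(pattern)))


def primitive_period(pattern: str) -> str:
    """Shortest substring whose tandem repetition equals ``pattern``.

    ``ACAC`` has primitive period ``AC``; a primitive pattern returns itself.
    """
    n = len(pattern)
    for p in range(1, n):
        if n % p == 0 and pattern[:p] * (n // p) == pattern:
            return pattern[:p]
    return pattern
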