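"""Duplication-history estimation: the mutation index (m, d).

A tandem repeat region is modelled as the product of a history that starts
from a root pattern and applies two kinds of events: single-block tandem
duplications (one existing block is copied and the copy inserted
immediately to its right) and point mutations (substitution, insertion or
deletion of one nucleotide).  A mutation applied before a duplication
propagates into the copy.  The *error number* m of a region is the minimal
total number of point mutations over all histories generating it; the
*copy number* d is the number of pattern-length blocks.  The pair (m, d)
is the region's mutation index.

Two estimators are provided:

``estimate_index_exact``
    true minimum over all histories, by a budgeted reverse search
    (feasible only for small regions; guarded);

``estimate_index``
    polynomial-time greedy reverse contraction of the block partition,
    an upper bound on the exact minimum that matches it on the vast
    majority of small instances.
"""

from __future__ import annotations

import heapq
import itertools
import re
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

import edlib

from .catalog import RepeatRegion
from .patterns import (
    ALPHABET,
    canonical_rotation,
    edit_distance,
    primitive_period,
    rotation_distance,
    rotations,
)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

#: tractability guard for the exhaustive search
EXACT_MAX_LENGTH = 24
EXACT_MAX_PATTERN = 4


class SizeLimitError(ValueError):
    """Input too large for the exact history search; use estimate_index."""


@dataclass(frozen=True)
class MutationIndex:
    """The pair (m, d): minimal point-mutation count and copy number."""

    m: int
    d: int

    def __post_init__(self) -> None:
        if self.m < 0 or self.d < 1:
            raise ValueError("require m >= 0 and d >= 1")


@dataclass
class BlockPartition:
    """Pattern-period blocks of a repeat region.

    ``blocks`` concatenate to the region sequence; ``phase`` is the
    rotation of the pattern the region was cut against; ``distances``
    holds each block's edit distance to that phase.
    """

    blocks: list[str]
    pattern: str
    phase: str
    distances: list[int]

    @property
    def d(self) -> int:
        return len(self.blocks)


def partition_blocks(region_sequence: str, pattern: str) -> BlockPartition:
    """Partition a region into pattern-period blocks.

    The region is aligned against cyclic repetitions of the pattern
    (choosing the repetition count with minimal edit distance, ties toward
    the count closest to region length / pattern length) and cut wherever
    the optimal alignment path completes one full pattern copy.
    """
    if not pattern:
        raise ValueError("empty pattern")
    if len(region_sequence) < len(pattern):
        raise ValueError("region shorter than pattern")
    _, _, k, phase = _rank_phases(region_sequence, pattern)[0]
    p = len(pattern)
    L = len(region_sequence)
    cigar = edlib.align(region_sequence, phase * k, mode="NW", task="path")["cigar"]
    cuts = _copy_boundaries(cigar, p, k)
    blocks = [region_sequence[a:b] for a, b in zip([0] + cuts, cuts + [L]) if b > a]
    if not blocks:  # degenerate: whole region deleted against one copy
        blocks = [region_sequence]
    return BlockPartition(
        blocks=blocks,
        pattern=pattern,
        phase=phase,
        distances=[edit_distance(b, phase) for b in blocks],
    )


@lru_cache(maxsize=1 << 14)
def _rank_phases(
    region_sequence: str, pattern: str, rotate: bool = True
) -> tuple[tuple[int, int, int, str], ...]:
    """All (distance, |kp-L|, k, rotation) keys, best first.

    A tandem pattern is defined only up to rotation and the best copy
    count is ambiguous when indels shift block lengths, so both are
    scanned; ties resolve toward the count closest to L/p, then the
    smaller count, then the lexicographically smaller rotation.
    """
    p = len(pattern)
    L = len(region_sequence)
    k0 = max(1, round(L / p))
    keys = []
    phases = sorted(set(rotations(pattern))) if rotate else [pattern]
    for rot in phases:
        for k in range(max(1, k0 - 3), k0 + 4):
            dist = edlib.align(region_sequence, rot * k, mode="NW", task="distance")[
                "editDistance"
            ]
            keys.append((dist, abs(k * p - L), k, rot))
    keys.sort()
    return tuple(keys)


def _partition_for(
    region_sequence: str, key: tuple[int, int, int, str], attach_left: bool = False
) -> list[str]:
    _, _, k, phase = key
    p = len(phase)
    cigar = edlib.align(region_sequence, phase * k, mode="NW", task="path")["cigar"]
    cuts = _copy_boundaries(cigar, p, k, attach_left)
    L = len(region_sequence)
    blocks = [region_sequence[a:b] for a, b in zip([0] + cuts, cuts + [L]) if b > a]
    return blocks or [region_sequence]


def _copy_boundaries(cigar: str, p: int, k: int, attach_left: bool = False) -> list[int]:
    """Query positions where the alignment path crosses pattern-copy starts.

    An insertion sitting exactly on a copy boundary may belong to either
    neighbouring copy; ``attach_left`` assigns it to the preceding copy
    (cut after the inserted bases) instead of the following one.
    """
    cuts: list[int] = []
    q = t = 0
    pending = False  # reached a boundary; cut position may move past I ops
    targets = {j * p for j in range(1, k)}

    def flush() -> None:
        nonlocal pending
        if pending:
            cuts.append(q)
            pending = False

    def boundary() -> None:
        nonlocal pending
        if attach_left:
            pending = True
        else:
            cuts.append(q)

    for count, op in _CIGAR_RE.findall(cigar):
        n = int(count)
        if op in "=XM":
            for _ in range(n):
                flush()
                q += 1
                t += 1
                if t in targets:
                    boundary()
        elif op == "I":  # consumes query only
            q += n
        else:  # 'D' consumes target only
            for _ in range(n):
                flush()
                t += 1
                if t in targets:
                    boundary()
    flush()
    return sorted(set(cuts))


def _mode_block(region_sequence: str, p: int) -> str:
    """Most frequent naive p-block; consensus fallback for the exact search."""
    blocks = [region_sequence[i : i + p] for i in range(0, len(region_sequence) - p + 1, p)]
    blocks = [b for b in blocks if len(b) == p]
    counts: dict[str, int] = {}
    for i, b in enumerate(blocks):
        counts[b] = counts.get(b, 0) + 1
    return min(counts, key=lambda b: (-counts[b], blocks.index(b)))


# ---------------------------------------------------------------------------
# greedy estimator
# ---------------------------------------------------------------------------

def estimate_index(region: RepeatRegion) -> MutationIndex:
    """Upper-bound estimate of the mutation index in polynomial time.

    Several feasible histories are constructed and the cheapest kept:

    * greedy reverse contraction of the block partition — repeatedly
      merge the adjacent pair with minimal edit distance (rightmost pair
      on ties), add that distance to m, delete the member farther from
      the pattern (right member on ties), finally add the surviving
      block's distance to the nearest pattern rotation;
    * the same contraction against near-optimal alternative phases and
      against period-(p±1) consensus strings — an indel in the root
      propagates into every copy and shifts the true period, and a root
      of the wrong length costs one extra indel per unit of length
      difference;
    * a "star" history: duplicate a consensus block, then edit each
      block individually (cost = sum of block-to-consensus distances).

    Every candidate corresponds to a replayable history, so the minimum
    remains an upper bound on the exact m.  d is the block count of the
    best-fitting partition at the pattern's own period.
    """
    seq = region.region_sequence
    pattern = region.pattern
    p = len(pattern)
    L = len(seq)
    keys = _rank_phases(seq, pattern)
    d = len(_partition_for(seq, keys[0]))

    # a perfect repeat of some rotation needs no events at all
    if keys[0][0] == 0 and L % p == 0:
        return MutationIndex(m=0, d=d)

    def evaluate(blocks: list[str], period: str, extra: list[str]) -> int:
        variants = list(dict.fromkeys([period, pattern] + extra))
        cand = _interval_contract(blocks, variants, p)
        if cand is None:  # too many distinct runs: greedy fallback
            cand = min(
                abs(len(anchor) - p)
                + min(
                    _greedy_contract(blocks, anchor, prefer_right=True),
                    _greedy_contract(blocks, anchor, prefer_right=False),
                )
                for anchor in {period, pattern}
            )
        return cand

    # stage one: partitions at the pattern's own period
    tried: set[tuple[str, int]] = set()
    candidates: list[tuple[list[str], str]] = []
    for key in keys[:12]:
        if key[0] <= keys[0][0] + 2 and (key[3], key[2]) not in tried:
            tried.add((key[3], key[2]))
            candidates.append((_partition_for(seq, key), key[3]))
            candidates.append((_partition_for(seq, key, attach_left=True), key[3]))
    scored = [(evaluate(b, per, []), b, per) for b, per in candidates]
    m = min(s for s, _, _ in scored)
    if m <= 1:  # not perfect, so one mutation is already minimal
        return MutationIndex(m=m, d=d)

    # stage two: an indel in the root propagates into every copy, shifting
    # the true period; sampled substrings, phase consensus and excised
    # sub-period runs recover it
    extras: list[tuple[list[str], str]] = []
    seen: set[str] = set()
    for p2 in range(max(1, p - 2), min(12, p + 2) + 1):
        if p2 > L:
            continue
        for period in (seq[:p2], seq[L - p2 :], _period_consensus(seq, p2)):
            if period in seen:
                continue
            seen.add(period)
            key = _rank_phases(seq, period, rotate=False)[0]
            extras.append((_partition_for(seq, key), period))
            extras.append((_partition_for(seq, key, attach_left=True), period))
    run_extras = _run_excised_partitions(seq, pattern)
    # evidence-based run units take pool precedence over sampled substrings
    pool = list(dict.fromkeys(
        [per for _, per in run_extras] + [per for _, per in extras]
    ))[:8]
    extras.extend(run_extras)
    # segmentation against the whole candidate vocabulary at once: cut the
    # region wherever that minimizes total block-to-vocabulary distance
    vocab = list(dict.fromkeys(list(set(rotations(pattern))) + pool))
    extras.append((_vocab_partition(seq, vocab), pattern))
    def compress_sig(blocks: list[str]) -> tuple[str, ...]:
        return tuple(b for i, b in enumerate(blocks) if i == 0 or b != blocks[i - 1])

    evaluated: set[tuple] = {(compress_sig(b), per) for _, b, per in scored}
    for b, per in extras:
        sig = (compress_sig(b), per)
        if sig in evaluated:
            continue
        evaluated.add(sig)
        scored.append((evaluate(b, per, pool), b, per))
    scored.sort(key=lambda t: t[0])
    m = scored[0][0]
    if m > 1:
        # hill-climb the cut points of every leading partition: boundary
        # edits make the optimal cut placement ambiguous by a base or two
        leader_sigs: set[tuple[str, ...]] = set()
        leaders = []
        for t in scored:
            if t[0] > m + 1:
                continue
            sig = tuple(
                b for i, b in enumerate(t[1]) if i == 0 or b != t[1][i - 1]
            )
            if sig in leader_sigs:
                continue
            leader_sigs.add(sig)
            leaders.append(t)
            if len(leaders) == 6:
                break
        for s, blocks, period in leaders:
            m = min(m, _refine_boundaries(blocks, [period, pattern] + pool, p, m))
    return MutationIndex(m=max(m, 1), d=d)


def _refine_boundaries(
    blocks: list[str], variants: list[str], p: int, current: int
) -> int:
    best = current
    blocks = list(blocks)
    for _ in range(3):
        improved = False
        for bi in range(len(blocks) - 1):
            a, b = blocks[bi], blocks[bi + 1]
            if a == b:
                continue  # boundaries inside a uniform run are immaterial
            moves: list[list[str]] = []
            for shift in (-2, -1, 1, 2):
                if shift < 0 and len(a) > -shift:
                    moves.append([a[:shift], a[shift:] + b])
                elif shift > 0 and len(b) > shift:
                    moves.append([a + b[:shift], b[shift:]])
            if len(a) + len(b) <= 2 * len(max(variants, key=len)):
                moves.append([a + b])  # fuse into one (possibly variant) block
            for pair in moves:
                cand_blocks = blocks[:bi] + pair + blocks[bi + 2 :]
                cand = _interval_contract(cand_blocks, variants, p)
                if cand is not None and cand < best:
                    best, blocks, improved = cand, cand_blocks, True
                    break
            if improved:
                break
        if not improved:
            break
    return best


def _interval_contract(
    blocks: list[str], extra_variants: list[str], p: int
) -> int | None:
    """Optimal merge-order cost over a finite variant set.

    Adjacent equal blocks collapse free (reverse duplication); reducing an
    interval to one block of variant v costs the cheapest combination of
    per-block edits, splits and whole-interval re-edits.  Editing between
    variants obeys the triangle inequality, so one relaxation round
    suffices.  Returns None when the run-compressed interval is too long
    (callers fall back to the greedy chain).
    """
    comp = [b for i, b in enumerate(blocks) if i == 0 or b != blocks[i - 1]]
    n = len(comp)
    if n > 10:
        return None
    variants = list(dict.fromkeys(comp + extra_variants))[:16]
    nv = len(variants)
    index = {v: i for i, v in enumerate(variants)}
    D = np.empty((nv, nv), dtype=np.int64)
    for ui, u in enumerate(variants):
        for vi in range(ui, nv):
            D[ui, vi] = D[vi, ui] = edit_distance(u, variants[vi])
    # C[i, j, v]: cost to reduce comp[i..j] to a single block equal to v
    C = np.zeros((n, n, nv), dtype=np.int64)
    for i, b in enumerate(comp):
        C[i, i] = D[index[b]]
    for span in range(2, n + 1):
        for i in range(n - span + 1):
            j = i + span - 1
            base = C[i, i:j] + C[i + 1 : j + 1, j]
            base = base.min(axis=0)
            C[i, j] = (base[:, None] + D).min(axis=0)
    root_cost = np.array([abs(len(v) - p) for v in variants], dtype=np.int64)
    return int((C[0, n - 1] + root_cost).min())


def _vocab_partition(seq: str, vocab: list[str]) -> list[str]:
    """Cut seq into blocks minimizing total edit distance to the nearest
    vocabulary unit; block lengths stay within ±2 of some unit length."""
    L = len(seq)
    lens = sorted(
        {len(v) + dl for v in vocab for dl in (-2, -1, 0, 1, 2) if len(v) + dl >= 1}
    )
    INF = float("inf")
    F = [INF] * (L + 1)
    F[0] = 0.0
    back = [0] * (L + 1)
    for i in range(1, L + 1):
        for ln in lens:
            if ln > i:
                break
            blk = seq[i - ln : i]
            c = F[i - ln] + min(edit_distance(blk, v) for v in vocab)
            if c < F[i]:
                F[i] = c
                back[i] = ln
    blocks = []
    i = L
    while i > 0:
        ln = back[i]
        blocks.append(seq[i - ln : i])
        i -= ln
    return blocks[::-1]


def _run_excised_partitions(
    seq: str, pattern: str
) -> list[tuple[list[str], str]]:
    """Partitions that excise the longest exact tandem run of a shifted
    period, with remainders partitioned at the pattern's own period.

    A single early indel that propagates through later duplications
    leaves a long perfect run of a (p±1)-length unit embedded in the
    region; cutting it out as whole unit copies exposes the cheap
    history.
    """
    p = len(pattern)
    L = len(seq)
    out: list[tuple[list[str], str]] = []
    pattern_rots = set(rotations(pattern))

    def pattern_blocks(segment: str) -> list[str]:
        if len(segment) >= p:
            return _partition_for(segment, _rank_phases(segment, pattern)[0])
        return [segment] if segment else []

    def pattern_periodic(unit: str) -> bool:
        # a run of CCC under pattern C is the repeat itself, not a variant
        return primitive_period(unit) in pattern_rots

    for p2 in range(max(1, p - 2), min(12, p + 2) + 1):
        # maximal exact runs, left to right, non-overlapping
        runs: list[tuple[int, int]] = []
        i = 0
        while i + 2 * p2 <= L:
            if seq[i : i + p2] != seq[i + p2 : i + 2 * p2]:
                i += 1
                continue
            j = i + 2 * p2
            while j < L and seq[j] == seq[j - p2]:
                j += 1
            if not pattern_periodic(seq[i : i + p2]):
                runs.append((i, j))
            i = j
        if not runs:
            continue
        blocks: list[str] = []
        longest_unit = ""
        prev_end = 0
        for a, b in runs:
            # shift the run start so the gap before it holds whole pattern
            # copies — only when the shift leaves the unit unchanged
            shift = (p - (a - prev_end) % p) % p
            if (
                a + shift + 2 * p2 <= b
                and seq[a : a + p2] == seq[a + shift : a + shift + p2]
            ):
                a += shift
            unit = seq[a : a + p2]
            n_copies = (b - a) // p2
            blocks.extend(pattern_blocks(seq[prev_end:a]))
            blocks.extend([unit] * n_copies)
            prev_end = a + n_copies * p2
            if n_copies * p2 > len(longest_unit) * 2:
                longest_unit = unit
        blocks.extend(pattern_blocks(seq[prev_end:]))
        out.append((blocks, longest_unit or seq[runs[0][0] : runs[0][0] + p2]))

    # cross-period joint excision: propagated variants of different lengths
    # (a CT-run and a CCT-run from the same CTC pattern) excised together
    all_runs: list[tuple[int, int, int, str]] = []  # (length, start, end, unit)
    for p2 in range(max(1, p - 2), min(12, p + 2) + 1):
        i = 0
        while i + 2 * p2 <= L:
            if seq[i : i + p2] != seq[i + p2 : i + 2 * p2]:
                i += 1
                continue
            j = i + 2 * p2
            while j < L and seq[j] == seq[j - p2]:
                j += 1
            unit = seq[i : i + p2]
            if not pattern_periodic(unit):
                # prefer the phase closest to the pattern
                best_t = min(
                    (t for t in range(p2) if i + t + 2 * p2 <= j),
                    key=lambda t: rotation_distance(seq[i + t : i + t + p2], pattern),
                )
                all_runs.append((j - (i + best_t), i + best_t, j, seq[i + best_t : i + best_t + p2]))
            i = j
    if len(all_runs) > 1:
        all_runs.sort(reverse=True)
        chosen: list[tuple[int, int, str]] = []
        for _, a, b, unit in all_runs:
            p2 = len(unit)
            # trim an overlapping run to its first in-phase position after
            # the already-chosen runs
            for a2, b2, _ in sorted(chosen):
                if a < b2 and b > a2 and a < a2:
                    b = min(b, a2)
                elif a < b2 and b > a2:
                    a += -((a - b2) // p2) * p2  # ceil to phase
            if b - a >= 2 * p2 and all(b <= a2 or a >= b2 for a2, b2, _ in chosen):
                chosen.append((a, b, seq[a : a + p2]))
        chosen.sort()
        blocks = []
        prev_end = 0
        main_unit = all_runs[0][3]
        for a, b, unit in chosen:
            n_copies = (b - a) // len(unit)
            blocks.extend(pattern_blocks(seq[prev_end:a]))
            blocks.extend([unit] * n_copies)
            prev_end = a + n_copies * len(unit)
        blocks.extend(pattern_blocks(seq[prev_end:]))
        out.append((blocks, main_unit))

    # phase-switch partitions: an indel propagating through part of the
    # region rotates the phase midway, so the two halves are cut against
    # the units of the two longest runs, switching at the second run's start
    if len(all_runs) > 1:
        top = sorted(all_runs, reverse=True)[:3]
        for _, a1, b1, u1 in top:
            for _, a2, b2, u2 in top:
                if u1 == u2 or b1 > a2:
                    continue
                blocks = []
                for segment, unit in ((seq[:a2], u1), (seq[a2:], u2)):
                    if len(segment) >= len(unit):
                        blocks.extend(
                            _partition_for(
                                segment,
                                _rank_phases(segment, unit, rotate=False)[0],
                            )
                        )
                    elif segment:
                        blocks.append(segment)
                out.append((blocks, u1))

    # phase-aware single-run excisions: a run found at its earliest start
    # may be phased wrongly (a GTT-run first seeded as TGT), so the phases
    # whose unit lies closest to the pattern are tried as well
    for p2 in range(max(1, p - 2), min(12, p + 2) + 1):
        runs2: list[tuple[int, int, int]] = []
        for i in range(L - 2 * p2 + 1):
            if seq[i : i + p2] != seq[i + p2 : i + 2 * p2]:
                continue
            if i > 0 and seq[i - 1] == seq[i - 1 + p2]:
                continue  # same run seen from i-1
            j = i + 2 * p2
            while j < L and seq[j] == seq[j - p2]:
                j += 1
            runs2.append((j - i, i, j))
        runs2.sort(reverse=True)
        runs2 = [r for r in runs2 if not pattern_periodic(seq[r[1] : r[1] + p2])]
        for _, a0, b in runs2[:2]:
            phases: list[tuple[int, int, str]] = []
            for t in range(p2):
                a = a0 + t
                if a + 2 * p2 > b:
                    break
                unit = seq[a : a + p2]
                phases.append((rotation_distance(unit, pattern), t, unit))
            seen_units: set[str] = set()
            for _, t, unit in sorted(phases)[:3]:
                if unit in seen_units or pattern_periodic(unit):
                    continue
                seen_units.add(unit)
                a = a0 + t
                n_copies = (b - a) // p2
                # the copy at either run edge may belong to the flanking
                # segment's phase instead: try handing one copy over
                for lead, trail in ((0, 0), (1, 0), (0, 1)):
                    n = n_copies - lead - trail
                    if n < 2:
                        continue
                    start = a + lead * p2
                    blocks = pattern_blocks(seq[:start])
                    blocks.extend([unit] * n)
                    blocks.extend(pattern_blocks(seq[start + n * p2 :]))
                    out.append((blocks, unit))
    return out


def _period_consensus(seq: str, p: int) -> str:
    """Column-majority consensus of the naive period-p phases of seq."""
    cols = []
    for j in range(p):
        counts: dict[str, int] = {}
        for k in range(j, len(seq), p):
            counts[seq[k]] = counts.get(seq[k], 0) + 1
        cols.append(min(counts, key=lambda b: (-counts[b], b)))
    return "".join(cols)


def _greedy_contract(blocks: list[str], pattern: str, prefer_right: bool = True) -> int:
    blocks = list(blocks)
    m = 0
    while len(blocks) > 1:
        dists = [edit_distance(blocks[i], blocks[i + 1]) for i in range(len(blocks) - 1)]
        lo = min(dists)
        if prefer_right:
            i = len(dists) - 1 - dists[::-1].index(lo)
        else:
            i = dists.index(lo)
        m += lo
        left_far = edit_distance(blocks[i], pattern)
        right_far = edit_distance(blocks[i + 1], pattern)
        del blocks[i + 1 if right_far >= left_far else i]
    return m + rotation_distance(blocks[0], pattern)


# ---------------------------------------------------------------------------
# exact search
# ---------------------------------------------------------------------------

def estimate_index_exact(region_sequence: str, pattern_length: int) -> MutationIndex:
    """Exact minimal mutation count over all histories (small regions only).

    The search runs backwards from the observed region: un-duplication
    merges equal adjacent blocks at no cost; un-mutation applies a single
    edit (cost 1) restricted to edits that bring a block strictly closer
    to another block — any optimal history can be reordered so that every
    reversed mutation is of this form.  Iterative deepening on the
    mutation budget, capped by the greedy estimate, gives the minimum.
    """
    p = pattern_length
    if not 1 <= p <= EXACT_MAX_PATTERN or len(region_sequence) > EXACT_MAX_LENGTH:
        raise SizeLimitError(
            f"exact search limited to regions <= {EXACT_MAX_LENGTH} nt with pattern "
            f"length <= {EXACT_MAX_PATTERN}; use estimate_index"
        )
    if len(region_sequence) < p:
        raise ValueError("region shorter than pattern")
    pattern = _mode_block(region_sequence, p)
    part = partition_blocks(region_sequence, pattern)
    upper = _greedy_contract(part.blocks, pattern)
    for budget in range(upper + 1):
        if _feasible(region_sequence, p, budget):
            return MutationIndex(m=budget, d=part.d)
    return MutationIndex(m=upper, d=part.d)


def _compositions(
    total: int, lo: int, hi: int, limit: int | None = None
) -> list[tuple[int, ...]] | None:
    """Compositions of ``total`` into parts in [lo, hi]; None over limit."""
    out: list[tuple[int, ...]] = []

    def rec(rem: int, acc: list[int]) -> bool:
        if limit is not None and len(out) > limit:
            return False
        if rem == 0:
            if acc:
                out.append(tuple(acc))
            return True
        for part in range(lo, min(hi, rem) + 1):
            acc.append(part)
            ok = rec(rem - part, acc)
            acc.pop()
            if not ok:
                return False
        return True

    return out if rec(total, []) else None


def _merge_closure(blocks: tuple[str, ...]) -> tuple[str, ...]:
    out = list(blocks)
    i = 0
    while i < len(out) - 1:
        if out[i] == out[i + 1]:
            del out[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    return tuple(out)


def _single_edits(s: str) -> set[str]:
    edits: set[str] = set()
    for i in range(len(s)):
        for b in ALPHABET:
            if b != s[i]:
                edits.add(s[:i] + b + s[i + 1 :])
        if len(s) > 1:
            edits.add(s[:i] + s[i + 1 :])
    for i in range(len(s) + 1):
        for b in ALPHABET:
            edits.add(s[:i] + b + s[i:])
    edits.discard(s)
    return edits


def _lower_bound(state: tuple[str, ...], p: int) -> int:
    """Admissible bound on remaining mutations.

    Before two block lineages merge, their contents stay at least their
    current edit distance apart, and every edit separating them is a
    distinct event — so the largest adjacent-pair distance cannot exceed
    the remaining budget.  A lone block still needs |len - p| indels.
    """
    if len(state) == 1:
        return abs(len(state[0]) - p)
    return max(
        edit_distance(state[i], state[i + 1]) for i in range(len(state) - 1)
    )


def _feasible(seq: str, p: int, budget: int, max_nodes: int | None = None) -> bool:
    """Whether some history with ≤ budget mutations generates seq.

    ``max_nodes`` caps the number of expanded states; on hitting the cap
    the search conservatively reports infeasible.
    """
    comps = _compositions(
        len(seq), max(1, p - budget), p + budget, limit=max_nodes
    )
    if comps is None:
        return False
    start_states = {_merge_closure(tuple(_split(seq, comp))) for comp in comps}
    expanded = 0
    best: dict[tuple[str, ...], int] = {}
    heap: list[tuple[int, int, int, tuple[str, ...]]] = []
    counter = itertools.count()
    for st in start_states:
        h = _lower_bound(st, p)
        if h > budget:
            continue
        best[st] = 0
        heapq.heappush(heap, (h, 0, next(counter), st))
    while heap:
        _, cost, _, state = heapq.heappop(heap)
        if cost > best.get(state, budget + 1):
            continue
        if len(state) == 1 and cost + abs(len(state[0]) - p) <= budget:
            return True
        if cost >= budget:
            continue
        expanded += 1
        if max_nodes is not None and expanded > max_nodes:
            return False
        for i, blk in enumerate(state):
            base = {o: edit_distance(blk, o) for o in set(state) if o != blk}
            if not base:
                continue
            for cand in _single_edits(blk):
                if not any(edit_distance(cand, o) < dist for o, dist in base.items()):
                    continue
                nxt = _merge_closure(state[:i] + (cand,) + state[i + 1 :])
                ncost = cost + 1
                if ncost + _lower_bound(nxt, p) > budget:
                    continue
                if ncost < best.get(nxt, budget + 1):
                    best[nxt] = ncost
                    heapq.heappush(
                        heap, (ncost + _lower_bound(nxt, p), ncost, next(counter), nxt)
                    )
    return False


def _split(seq: str, comp: tuple[int, ...]) -> list[str]:
    out = []
    pos = 0
    for ln in comp:
        out.append(seq[pos : pos + ln])
        pos += ln
    return out


# ---------------------------------------------------------------------------
# profile export
# ---------------------------------------------------------------------------

def build_profile_table(regions: list[RepeatRegion]) -> pd.DataFrame:
    """Per-region mutation indices as a tidy table (one sample's profile)."""
    rows = []
    for r in regions:
        idx = estimate_index(r)
        rows.append(
            {
                "region_id": r.region_id,
                "seq_id": r.seq_id,
                "start": r.start,
                "end": r.end,
                "pattern": canonical_rotation(r.pattern),
                "m": idx.m,
                "d": idx.d,
            }
        )
    return pd.DataFrame(
        rows, columns=["region_id", "seq_id", "start", "end", "pattern", "m", "d"]
    )


def write_profile(regions: list[RepeatRegion], path) -> None:
    build_profile_table(regions).to_csv(path, sep="\t", index=False)
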