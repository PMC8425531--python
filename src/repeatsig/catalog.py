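"""Tandem-repeat detection and catalog IO.

Finds microsatellite regions — consecutive repetitions of a short pattern
(period ≤ 10) — in nucleotide sequences, and interoperates with Tandem
Repeat Finder (TRF) ``.dat`` tables.  The built-in detector is k-mer
seeded: a doubled pattern occurrence seeds a candidate, which is extended
outward while a sliding identity criterion holds, then trimmed to a whole
number of pattern copies and scored against its column-majority consensus.

Only regions with period ≤ 10 and copy number ≤ 100 (hence length
< 1000 nt) are considered; larger structures are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .patterns import canonical_rotation, primitive_period

logger = logging.getLogger(__name__)

_CATALOG_COLUMNS = ["seq_id", "start", "end", "pattern", "copy_count", "region_sequence"]


class TRFParseError(ValueError):
    """Raised for a malformed line in a TRF data table."""


@dataclass(frozen=True)
class DetectorParams:
    """Tuning knobs of the tandem-repeat detector.

    match_weight / mismatch_weight score a region against its consensus
    (a position agreeing with the consensus earns +match_weight, a
    disagreement costs -mismatch_weight); regions scoring below
    ``min_score`` are not reported.  ``min_identity`` is the running
    identity a candidate extension must maintain.
    """

    max_pattern_length: int = 10
    max_copy_number: int = 100
    min_copy_number: float = 2.0
    max_region_length: int = 1000
    match_weight: int = 2
    mismatch_weight: int = 7
    min_score: int = 14
    min_identity: float = 0.75

    def validate(self) -> None:
        if self.max_pattern_length < 1 or self.max_pattern_length > 10:
            raise ValueError("max_pattern_length must be in [1, 10]")
        if self.max_copy_number < 2 or self.max_region_length < 2:
            raise ValueError("copy/length limits must be >= 2")
        if self.max_pattern_length * self.max_copy_number < self.max_region_length:
            # region length is bounded by p * copies; limits must agree
            raise ValueError("max_region_length inconsistent with pattern/copy limits")
        if not (self.match_weight > 0 and self.mismatch_weight > 0 and self.min_score > 0):
            raise ValueError("score weights must be positive")
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass
class RepeatRegion:
    """A detected tandem repeat: ``[start, end)`` on ``seq_id``.

    ``copy_count`` is the copy number as reported by detection — an
    integer number of whole copies from the built-in detector, possibly
    fractional when imported from TRF.
    """

    seq_id: str
    start: int
    end: int
    pattern: str
    copy_count: float
    region_sequence: str
    score: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if not 1 <= len(self.pattern) <= 10:
            raise ValueError(f"pattern length {len(self.pattern)} outside [1, 10]")
        if self.end - self.start >= 1000:
            raise ValueError("region length must be < 1000")
        if self.copy_count > 100:
            raise ValueError("copy_count must be <= 100")
        if len(self.region_sequence) != self.end - self.start:
            raise ValueError("region_sequence length does not match coordinates")

    @property
    def region_id(self) -> str:
        return f"{self.seq_id}:{self.start}-{self.end}"


def _consensus(window: str, p: int) -> str:
    """Column-majority consensus over the pattern-length blocks of window."""
    cols: list[str] = []
    for j in range(p):
        counts: dict[str, int] = {}
        for k in range(j, len(window), p):
            counts[window[k]] = counts.get(window[k], 0) + 1
        # ties broken alphabetically for determinism
        cols.append(min(counts, key=lambda b: (-counts[b], b)))
    return "".join(cols)


def _score_window(window: str, cons: str, params: DetectorParams) -> int:
    p = len(cons)
    matches = sum(1 for k, ch in enumerate(window) if ch == cons[k % p])
    mismatches = len(window) - matches
    return params.match_weight * matches - params.mismatch_weight * mismatches


def _extend(seq: str, i: int, p: int, params: DetectorParams) -> tuple[int, int]:
    """Maximal per-position periodic extension of the seed at [i, i+2p)."""
    n = len(seq)
    # right: compare seq[k] with seq[k-p]
    k = i + 2 * p
    comparisons = p  # the seed itself contributes p matching comparisons
    mismatches = 0
    last_match = k
    while k < n and seq[k] != "N":
        if seq[k] == seq[k - p]:
            comparisons += 1
            k += 1
            last_match = k
        else:
            if (mismatches + 1) > (1 - params.min_identity) * (comparisons + 1):
                break
            mismatches += 1
            comparisons += 1
            k += 1
    right = last_match
    # left: compare seq[j] with seq[j+p]
    j = i - 1
    comparisons = p
    mismatches = 0
    first_match = i
    while j >= 0 and seq[j] != "N":
        if seq[j] == seq[j + p]:
            comparisons += 1
            first_match = j
            j -= 1
        else:
            if (mismatches + 1) > (1 - params.min_identity) * (comparisons + 1):
                break
            mismatches += 1
            comparisons += 1
            j -= 1
    return first_match, right


def detect_repeats(
    sequence: str, seq_id: str = "seq", params: DetectorParams | None = None
) -> list[RepeatRegion]:
    """Detect tandem repeat regions in ``sequence``.

    Returns non-overlapping regions sorted by start coordinate.  Each
    region spans a whole number of pattern copies; overlapping candidates
    are resolved in favour of the longer region, then the shorter period,
    then the leftmost start.
    """
    params = params or DetectorParams()
    params.validate()
    seq = sequence.upper()
    n = len(seq)
    candidates: list[RepeatRegion] = []

    for p in range(1, params.max_pattern_length + 1):
        i = 0
        while i + 2 * p <= n:
            window = seq[i : i + 2 * p]
            if "N" in window:
                i += 1
                continue
            if seq[i : i + p] != seq[i + p : i + 2 * p]:
                i += 1
                continue
            lo, hi = _extend(seq, i, p, params)
            region = _best_whole_copy_region(seq, lo, hi, p, params, seq_id)
            if region is not None:
                candidates.append(region)
            i = hi  # any further seed inside [i, hi) extends to the same interval
    return _resolve_overlaps(candidates)


def _best_copy_window(
    copies: list[str], params: DetectorParams, min_len: int, max_len: int
) -> tuple[int, int, int] | None:
    """Maximum-score contiguous run of whole copies (length in [min, max]).

    Per-copy scores against the column-majority consensus; returns
    (score, first_copy, last_copy_exclusive) or None.  Trims noisy flank
    copies picked up when the raw extension overshoots into non-repeat
    sequence.
    """
    cons = _consensus("".join(copies), len(copies[0]))
    scores = [_score_window(c, cons, params) for c in copies]
    n = len(scores)
    prefix = [0] * (n + 1)
    for i, s in enumerate(scores):
        prefix[i + 1] = prefix[i] + s
    best: tuple[int, int, int] | None = None
    for end in range(min_len, n + 1):
        j_lo = max(0, end - max_len)
        j_hi = end - min_len
        j = min(range(j_lo, j_hi + 1), key=lambda x: (prefix[x], x))
        cand = (prefix[end] - prefix[j], j, end)
        if best is None or (cand[0], cand[2] - cand[1], -cand[1]) > (
            best[0], best[2] - best[1], -best[1]
        ):
            best = cand
    return best


def _best_whole_copy_region(
    seq: str, lo: int, hi: int, p: int, params: DetectorParams, seq_id: str
) -> RepeatRegion | None:
    min_copies = max(2, int(params.min_copy_number))
    if (hi - lo) // p < min_copies:
        return None
    max_copies = min(params.max_copy_number, (params.max_region_length - 1) // p)
    best: tuple[int, int, int, int] | None = None  # (score, n_copies, -start, start)
    for off in range(min(p, (hi - lo) - min_copies * p + 1)):
        n_copies = (hi - lo - off) // p
        if n_copies < min_copies:
            break
        copies = [
            seq[lo + off + c * p : lo + off + (c + 1) * p] for c in range(n_copies)
        ]
        win = _best_copy_window(copies, params, min_copies, max_copies)
        if win is None:
            continue
        score, c0, c1 = win
        start = lo + off + c0 * p
        cand = (score, c1 - c0, -start, start)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    score, n_copies, _, start = best
    length = n_copies * p
    window = seq[start : start + length]
    # refine: consensus of the selected window, rescored
    cons = _consensus(window, p)
    score = _score_window(window, cons, params)
    if score < params.min_score:
        return None
    prim = primitive_period(cons)
    if len(prim) < p:
        # consensus is itself periodic: report the primitive period
        p = len(prim)
        cons = prim
        n_copies = length // p
    return RepeatRegion(
        seq_id=seq_id,
        start=start,
        end=start + length,
        pattern=canonical_rotation(cons),
        copy_count=float(n_copies),
        region_sequence=window,
        score=float(score),
    )


def _resolve_overlaps(candidates: list[RepeatRegion]) -> list[RepeatRegion]:
    chosen: list[RepeatRegion] = []
    for cand in sorted(
        candidates, key=lambda r: (-(r.end - r.start), len(r.pattern), r.start)
    ):
        if all(
            cand.end <= kept.start or cand.start >= kept.end or cand.seq_id != kept.seq_id
            for kept in chosen
        ):
            chosen.append(cand)
    chosen.sort(key=lambda r: (r.seq_id, r.start))
    # drop exact duplicates arising from distinct periods collapsing to one
    deduped: list[RepeatRegion] = []
    for r in chosen:
        if not deduped or (r.seq_id, r.start, r.end) != (
            deduped[-1].seq_id,
            deduped[-1].start,
            deduped[-1].end,
        ):
            deduped.append(r)
    return deduped


_TRF_SKIP_PREFIXES = (
    "Tandem Repeats Finder",
    "Gary Benson",
    "Program written",
    "Version",
    "Sequence:",
    "Parameters:",
)


def read_trf_table(path) -> list[RepeatRegion]:
    """Read a Tandem Repeat Finder ``.dat`` data table.

    TRF reports 1-based inclusive coordinates and fractional copy numbers;
    coordinates are converted to 0-based half-open.  Records violating the
    catalog limits (period > 10, copies > 100, length >= 1000) are dropped
    and the drop count is logged.
    """
    regions: list[RepeatRegion] = []
    dropped = 0
    seq_id = "seq"
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("@"):
                seq_id = line[1:].split()[0]
                continue
            if any(line.startswith(pref) for pref in _TRF_SKIP_PREFIXES):
                if line.startswith("Sequence:"):
                    seq_id = line.split(":", 1)[1].strip().split()[0]
                continue
            fields = line.split()
            if len(fields) < 15:
                raise TRFParseError(f"line {lineno}: expected 15 fields, got {len(fields)}")
            try:
                start1 = int(fields[0])
                end1 = int(fields[1])
                period = int(fields[2])
                copies = float(fields[3])
                pattern = fields[13]
                region_seq = fields[14]
            except ValueError as exc:
                raise TRFParseError(f"line {lineno}: {exc}") from exc
            start, end = start1 - 1, end1
            if period > 10 or copies > 100 or end - start >= 1000 or len(pattern) > 10:
                dropped += 1
                continue
            if len(region_seq) != end - start:
                raise TRFParseError(
                    f"line {lineno}: sequence length {len(region_seq)} does not match "
                    f"coordinates [{start}, {end})"
                )
            regions.append(
                RepeatRegion(
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    pattern=canonical_rotation(pattern),
                    copy_count=copies,
                    region_sequence=region_seq,
                )
            )
    if dropped:
        logger.info("read_trf_table: dropped %d record(s) outside catalog limits", dropped)
    return regions


def write_catalog(regions: list[RepeatRegion], path) -> None:
    """Write a catalog as TSV (header + one row per region)."""
    df = pd.DataFrame(
        [
            {
                "seq_id": r.seq_id,
                "start": r.start,
                "end": r.end,
                "pattern": r.pattern,
                "copy_count": r.copy_count,
                "region_sequence": r.region_sequence,
            }
            for r in regions
        ],
        columns=_CATALOG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_catalog(path) -> list[RepeatRegion]:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"seq_id": str, "pattern": str, "region_sequence": str},
    )
    return [
        RepeatRegion(
            seq_id=row.seq_id,
            start=int(row.start),
            end=int(row.end),
            pattern=row.pattern,
            copy_count=float(row.copy_count),
            region_sequence=row.region_sequence,
        )
        for row in df.itertuples(index=False)
    ]
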