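"""Alignment of mutation profiles against a reference profile.

A sample's mutation profile — the coordinate-ordered list of
(pattern, m, d) entries over its repeat regions — rarely has the same
regions as another sample's: regions drop out, and patterns drift.  To
give every sample a fixed-width feature vector, each profile is aligned
against the reference profile by a global dynamic program whose pairing
cost is the normalized edit distance between patterns (Levenshtein
distance divided by mean pattern length) and whose cost for leaving an
entry unpaired ("missing pattern") is a flat 0.4.  Query entries with no
reference counterpart are omitted; unmatched reference slots are filled
with (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .patterns import canonical_rotation, edit_distance

_EPS = 1e-9


@dataclass(frozen=True)
class AlignParams:
    """gap_cost: cost of pairing a pattern with '–'; match_threshold: the
    normalized distance below which two patterns count as the same."""

    gap_cost: float = 0.4
    match_threshold: float = 0.4

    def validate(self) -> None:
        if not (0 < self.gap_cost <= 1 and 0 < self.match_threshold <= 1):
            raise ValueError("gap_cost and match_threshold must be in (0, 1]")


@dataclass(frozen=True)
class ProfileEntry:
    seq_id: str
    start: int
    end: int
    pattern: str
    m: int
    d: int

    @property
    def region_id(self) -> str:
        return f"{self.seq_id}:{self.start}-{self.end}"


@dataclass
class MutationProfile:
    """One sample's ordered (region, pattern, m, d) entries."""

    sample_id: str
    entries: list[ProfileEntry]
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: (e.seq_id, e.start))
        for e in self.entries:
            if e.m < 0 or e.d < 1:
                raise ValueError(f"invalid (m, d) in entry {e.region_id}")

    @classmethod
    def from_table(
        cls, table: pd.DataFrame, sample_id: str, class_label: str | None = None
    ) -> "MutationProfile":
        entries = [
            ProfileEntry(
                seq_id=str(row.seq_id),
                start=int(row.start),
                end=int(row.end),
                pattern=canonical_rotation(str(row.pattern)),
                m=int(row.m),
                d=int(row.d),
            )
            for row in table.itertuples(index=False)
        ]
        return cls(sample_id=sample_id, entries=entries, class_label=class_label)


def normalized_edit_distance(a: str, b: str) -> float:
    """Levenshtein distance divided by the mean of the two lengths.

    Symmetric, zero iff the strings are equal, at most 2.  Missing
    patterns are handled by the alignment gap cost, not here.
    """
    if not a or not b:
        raise ValueError("patterns must be non-empty")
    return edit_distance(a, b) / ((len(a) + len(b)) / 2)


@dataclass
class AlignmentResult:
    """``pairs[k]`` is the query entry matched to reference entry k, or
    None for a gap; ``cost`` includes gap charges for omitted query-only
    entries."""

    pairs: list[ProfileEntry | None]
    cost: float
    n_gaps: int


def align_profiles(
    query: MutationProfile,
    reference: MutationProfile,
    params: AlignParams | None = None,
) -> AlignmentResult:
    """Globally align a query profile to the reference profile.

    Alignment is monotone and performed independently per seq_id; the
    total cost is the sum of pairing costs plus ``gap_cost`` per unpaired
    entry on either side.  Cost ties are broken toward fewer gaps and a
    deterministic backtrack order.
    """
    params = params or AlignParams()
    params.validate()
    ref_seq_ids = []
    for e in reference.entries:
        if e.seq_id not in ref_seq_ids:
            ref_seq_ids.append(e.seq_id)
    query_by_seq: dict[str, list[ProfileEntry]] = {}
    for e in query.entries:
        query_by_seq.setdefault(e.seq_id, []).append(e)
    # single-contig profiles (one sequence per sample) have no seq_id in
    # common with the reference contig: align the two entry streams directly
    if (
        len(ref_seq_ids) == 1
        and len(query_by_seq) <= 1
        and not set(query_by_seq) & set(ref_seq_ids)
    ):
        query_by_seq = {ref_seq_ids[0]: query.entries}

    pairs: list[ProfileEntry | None] = []
    cost = 0.0
    n_gaps = 0
    for sid in ref_seq_ids:
        ref_entries = [e for e in reference.entries if e.seq_id == sid]
        q_entries = query_by_seq.get(sid, [])
        p, c, g = _align_block(q_entries, ref_entries, params)
        pairs.extend(p)
        cost += c
        n_gaps += g
    # query entries on seq_ids absent from the reference are all omitted
    for sid, entries in query_by_seq.items():
        if sid not in ref_seq_ids:
            cost += params.gap_cost * len(entries)
            n_gaps += len(entries)
    return AlignmentResult(pairs=pairs, cost=cost, n_gaps=n_gaps)


def _align_block(
    q: list[ProfileEntry], r: list[ProfileEntry], params: AlignParams
) -> tuple[list[ProfileEntry | None], float, int]:
    n, m = len(q), len(r)
    gap = params.gap_cost
    ned_cache: dict[tuple[str, str], float] = {}

    def ned(a: str, b: str) -> float:
        key = (a, b)
        if key not in ned_cache:
            ned_cache[key] = normalized_edit_distance(a, b)
        return ned_cache[key]

    # DP over (cost, gaps); ties toward fewer gaps, backtrack prefers
    # pairing, then a reference gap, then a query gap
    cost = np.empty((n + 1, m + 1))
    gaps = np.empty((n + 1, m + 1), dtype=int)
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 ref-gap, 2 query-gap
    for i in range(n + 1):
        cost[i, 0] = gap * i
        gaps[i, 0] = i
        move[i, 0] = 2
    for j in range(m + 1):
        cost[0, j] = gap * j
        gaps[0, j] = j
        move[0, j] = 1
    move[0, 0] = -1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            options = (
                (cost[i - 1, j - 1] + ned(q[i - 1].pattern, r[j - 1].pattern),
                 gaps[i - 1, j - 1], 0),
                (cost[i, j - 1] + gap, gaps[i, j - 1] + 1, 1),
                (cost[i - 1, j] + gap, gaps[i - 1, j] + 1, 2),
            )
            best = options[0]
            for opt in options[1:]:
                if opt[0] < best[0] - _EPS or (
                    abs(opt[0] - best[0]) <= _EPS and opt[1] < best[1]
                ):
                    best = opt
            cost[i, j], gaps[i, j], move[i, j] = best
    # backtrack
    pairs: list[ProfileEntry | None] = [None] * m
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 0:
            pairs[j - 1] = q[i - 1]
            i, j = i - 1, j - 1
        elif mv == 1:
            j -= 1
        else:
            i -= 1
    return pairs, float(cost[n, m]), int(gaps[n, m])


@dataclass
class AlignedMatrix:
    """samples × (2R) feature matrix: columns interleave m and d per
    reference region; unmatched slots carry (0, 0)."""

    reference_regions: list[str]
    values: pd.DataFrame  # index sample_id, columns <region>_m, <region>_d
    labels: pd.Series | None = None

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        df = self.values.copy()
        if self.labels is not None:
            df.insert(0, "class", self.labels)
        df.to_csv(path, sep="\t", index_label="sample_id")

    def to_mtx(self, prefix) -> None:
        """Sparse export for large region sets: ``<prefix>.mtx`` plus
        row (sample) and column (feature) name files."""
        from pathlib import Path

        from scipy import io as sio
        from scipy import sparse

        prefix = Path(prefix)
        sio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(self.values.to_numpy()))
        prefix.with_suffix(".rows.txt").write_text("\n".join(self.values.index) + "\n")
        prefix.with_suffix(".cols.txt").write_text("\n".join(self.values.columns) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "AlignedMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        labels = None
        if "class" in df.columns:
            labels = df.pop("class")
        regions = [c[:-2] for c in df.columns[::2]]
        return cls(reference_regions=regions, values=df, labels=labels)


def build_matrix(
    profiles: list[MutationProfile],
    reference: MutationProfile,
    params: AlignParams | None = None,
) -> AlignedMatrix:
    """Align every profile to the reference and stack the (m, d) rows."""
    if not reference.entries:
        raise ValueError("reference profile is empty")
    params = params or AlignParams()
    region_ids = [e.region_id for e in reference.entries]
    columns: list[str] = []
    for rid in region_ids:
        columns.extend([f"{rid}_m", f"{rid}_d"])
    rows = np.zeros((len(profiles), 2 * len(region_ids)))
    labels = {}
    sample_ids = []
    for si, prof in enumerate(profiles):
        res = align_profiles(prof, reference, params)
        for k, entry in enumerate(res.pairs):
            if entry is not None:
                rows[si, 2 * k] = entry.m
                rows[si, 2 * k + 1] = entry.d
        sample_ids.append(prof.sample_id)
        labels[prof.sample_id] = prof.class_label
    values = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"),
                          columns=columns)
    label_series = pd.Series(labels, name="class").reindex(sample_ids)
    if label_series.isna().all():
        label_series = None
    return AlignedMatrix(reference_regions=region_ids, values=values,
                         labels=label_series)


class ProfileAligner:
    """Transformer-style wrapper: fit on the reference profile, transform
    a list of profiles into an AlignedMatrix."""

    def __init__(self, gap_cost: float = 0.4, match_threshold: float = 0.4):
        self.gap_cost = gap_cost
        self.match_threshold = match_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"gap_cost": self.gap_cost, "match_threshold": self.match_threshold}

    def set_params(self, **params) -> "ProfileAligner":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    @property
    def _align_params(self) -> AlignParams:
        return AlignParams(gap_cost=self.gap_cost, match_threshold=self.match_threshold)

    def fit(self, reference: MutationProfile) -> "ProfileAligner":
        if not reference.entries:
            raise ValueError("reference profile is empty")
        self.reference_ = reference
        return self

    def transform(self, profiles: list[MutationProfile]) -> AlignedMatrix:
        if not hasattr(self, "reference_"):
            raise RuntimeError("ProfileAligner is not fitted")
        return build_matrix(profiles, self.reference_, self._align_params)

    def fit_transform(
        self, reference: MutationProfile, profiles: list[MutationProfile]
    ) -> AlignedMatrix:
        return self.fit(reference).transform(profiles)
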