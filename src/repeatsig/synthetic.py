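"""Synthetic cohort generator with ground-truth duplication histories.

Emulates a multi-class cohort of per-sample sequences in which tandem
repeat regions evolve by an explicit event process: single-block tandem
duplications (a block is copied and inserted immediately to its right)
interleaved with point mutations (substitution, insertion, deletion), so
that a mutation applied before a duplication propagates into the copy.
Class structure is planted as additive shifts of the expected mutation
and/or duplication counts in a designated subset of regions for one
"signature" class, mirroring the situation where single repeat regions
separate one tumour type from the rest.

Every generated region carries its full history, so downstream detection,
history estimation, alignment and classification are testable against
known truth.  Regions are separated by non-repetitive spacers
(rejection-sampled until the detector finds nothing in them) so planted
boundaries are unambiguous.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import DetectorParams, detect_repeats
from .patterns import ALPHABET, canonical_rotation, primitive_period

#: cohort class sizes emulating a multi-cancer blood-derived WXS study
DEFAULT_CLASS_SIZES = (344, 153, 396, 393, 440, 513, 411, 432, 316, 190, 255)


@dataclass(frozen=True)
class Event:
    """One history event.

    ``kind`` is ``duplication``, ``substitution``, ``insertion`` or
    ``deletion``.  For duplications ``index`` is the block ordinal; for
    mutations it is the sequence position at application time.  ``detail``
    is the replacement/inserted base where applicable.
    """

    kind: str
    index: int
    detail: str = ""

    @property
    def block_index(self) -> int:
        """Alias: for duplications ``index`` is the block ordinal."""
        return self.index


@dataclass
class DuplicationHistory:
    root_pattern: str
    events: list[Event]
    final_sequence: str

    @property
    def witness_mutations(self) -> int:
        return sum(1 for e in self.events if e.kind != "duplication")

    @property
    def final_block_count(self) -> int:
        return 1 + sum(1 for e in self.events if e.kind == "duplication")


def replay(root_pattern: str, events: list[Event]) -> str:
    """Re-execute a history's events from its root; returns the sequence."""
    blocks = [root_pattern]
    for ev in events:
        if ev.kind == "duplication":
            blocks.insert(ev.index + 1, blocks[ev.index])
            continue
        pos = ev.index
        for bi, blk in enumerate(blocks):
            limit = len(blk) if ev.kind != "insertion" else len(blk) + 1
            if pos < limit or (ev.kind == "insertion" and bi == len(blocks) - 1):
                if ev.kind == "substitution":
                    blocks[bi] = blk[:pos] + ev.detail + blk[pos + 1 :]
                elif ev.kind == "deletion":
                    blocks[bi] = blk[:pos] + blk[pos + 1 :]
                else:
                    blocks[bi] = blk[:pos] + ev.detail + blk[pos:]
                break
            pos -= len(blk)
    return "".join(blocks)


def simulate_history(
    pattern: str, n_duplications: int, n_mutations: int, rng_seed: int
) -> DuplicationHistory:
    """Simulate one region's history with the given event counts.

    Duplications and mutations are interleaved uniformly at random, so a
    mutated block may later be duplicated (the mutation propagating into
    the copy) or mutations may strike after all duplications.
    """
    if not pattern:
        raise ValueError("empty pattern")
    if n_duplications < 0 or n_mutations < 0:
        raise ValueError("event counts must be >= 0")
    rng = np.random.default_rng(rng_seed)
    order = ["D"] * n_duplications + ["M"] * n_mutations
    rng.shuffle(order)
    blocks = [pattern]
    events: list[Event] = []
    for tag in order:
        if tag == "D":
            bi = int(rng.integers(len(blocks)))
            events.append(Event("duplication", bi))
            blocks.insert(bi + 1, blocks[bi])
            continue
        events.append(_random_mutation(blocks, rng))
    return DuplicationHistory(
        root_pattern=pattern, events=events, final_sequence="".join(blocks)
    )


def _random_mutation(blocks: list[str], rng: np.random.Generator) -> Event:
    total = sum(len(b) for b in blocks)
    kinds = ["substitution", "insertion", "deletion"]
    while True:
        kind = kinds[int(rng.integers(3))]
        if kind == "insertion":
            pos = int(rng.integers(total + 1))
            base = ALPHABET[int(rng.integers(4))]
            ev = Event(kind, pos, base)
        else:
            pos = int(rng.integers(total))
            # locate the block that owns pos
            bpos, bi = pos, 0
            while bpos >= len(blocks[bi]):
                bpos -= len(blocks[bi])
                bi += 1
            if kind == "deletion":
                if len(blocks[bi]) == 1:
                    continue  # never empty a block
                ev = Event(kind, pos)
            else:
                current = blocks[bi][bpos]
                base = rng.choice([b for b in ALPHABET if b != current])
                ev = Event(kind, pos, str(base))
        # apply in place
        if kind == "insertion":
            p2, bi = ev.index, 0
            while bi < len(blocks) - 1 and p2 > len(blocks[bi]):
                p2 -= len(blocks[bi])
                bi += 1
            blocks[bi] = blocks[bi][:p2] + ev.detail + blocks[bi][p2:]
        elif kind == "deletion":
            p2, bi = ev.index, 0
            while p2 >= len(blocks[bi]):
                p2 -= len(blocks[bi])
                bi += 1
            blocks[bi] = blocks[bi][:p2] + blocks[bi][p2 + 1 :]
        else:
            p2, bi = ev.index, 0
            while p2 >= len(blocks[bi]):
                p2 -= len(blocks[bi])
                bi += 1
            blocks[bi] = blocks[bi][:p2] + ev.detail + blocks[bi][p2 + 1 :]
        return ev


@dataclass
class CohortSpec:
    """Generative parameters for a synthetic cohort.

    Rates are per region: ``base_mutation_rate`` and
    ``base_duplication_count`` are Poisson expectations for point
    mutations and duplications; ``m_shift``/``d_shift`` are added to those
    expectations in ``signal_regions`` for ``effect_class`` only.
    """

    n_classes: int = 11
    samples_per_class: tuple[int, ...] = DEFAULT_CLASS_SIZES
    n_regions: int = 100
    pattern_length_range: tuple[int, int] = (1, 10)
    copy_range: tuple[int, int] = (2, 100)
    base_mutation_rate: float = 1.0
    base_duplication_count: float = 9.0
    signal_regions: frozenset[int] = field(default_factory=lambda: frozenset(range(10)))
    effect_class: int = 10
    m_shift: float = 3.0
    d_shift: float = 0.0
    dropout_rate: float = 0.05
    pattern_noise_rate: float = 0.02
    spacer_length: int = 35
    seed: int = 0

    def validate(self) -> None:
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class must have n_classes entries")
        if not all(n >= 1 for n in self.samples_per_class):
            raise ValueError("class sizes must be >= 1")
        if not self.signal_regions <= set(range(self.n_regions)):
            raise ValueError("signal_regions must be region ordinals < n_regions")
        if not 0 <= self.effect_class < self.n_classes:
            raise ValueError("effect_class out of range")
        for rate in (self.base_mutation_rate, self.base_duplication_count,
                     self.m_shift, self.d_shift):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        for prob in (self.dropout_rate, self.pattern_noise_rate):
            if not 0 <= prob <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if not 1 <= self.pattern_length_range[0] <= self.pattern_length_range[1] <= 10:
            raise ValueError("pattern lengths must be within [1, 10]")
        if self.spacer_length < 30:
            raise ValueError("spacers must be >= 30 nt")

    @property
    def class_labels(self) -> list[str]:
        return [f"class_{i + 1:02d}" for i in range(self.n_classes)]

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["samples_per_class"] = list(self.samples_per_class)
        data["pattern_length_range"] = list(self.pattern_length_range)
        data["copy_range"] = list(self.copy_range)
        data["signal_regions"] = sorted(self.signal_regions)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["samples_per_class"] = tuple(data["samples_per_class"])
        data["pattern_length_range"] = tuple(data["pattern_length_range"])
        data["copy_range"] = tuple(data["copy_range"])
        data["signal_regions"] = frozenset(data["signal_regions"])
        return cls(**data)


@dataclass
class Cohort:
    spec: CohortSpec
    samples: dict[str, str]          # sample_id -> sequence
    reference: str                   # zero-mutation ancestor sequence
    labels: pd.DataFrame             # sample_id, class
    ground_truth: pd.DataFrame       # sample_id, region, present, witness_m, true_d, ...
    region_patterns: list[str]
    histories: dict[tuple[str, int], DuplicationHistory]

    def to_records(self) -> list[SeqRecord]:
        return [SeqRecord(Seq(s), id=sid, description="") for sid, s in self.samples.items()]


def _random_pattern(rng: np.random.Generator, lo: int, hi: int) -> str:
    while True:
        p = int(rng.integers(lo, hi + 1))
        pat = "".join(ALPHABET[int(b)] for b in rng.integers(0, 4, size=p))
        if primitive_period(pat) == pat:
            return pat


def _pattern_variant(pattern: str, rng: np.random.Generator) -> str:
    """A 1-edit variant of a pattern, kept within length limits [1, 10]."""
    choices = ["substitution"]
    if len(pattern) > 1:
        choices.append("deletion")
    if len(pattern) < 10:
        choices.append("insertion")
    kind = choices[int(rng.integers(len(choices)))]
    i = int(rng.integers(len(pattern)))
    if kind == "substitution":
        base = str(rng.choice([b for b in ALPHABET if b != pattern[i]]))
        return pattern[:i] + base + pattern[i + 1 :]
    if kind == "deletion":
        return pattern[:i] + pattern[i + 1 :]
    base = ALPHABET[int(rng.integers(4))]
    return pattern[:i] + base + pattern[i:]


def _spacer(
    rng: np.random.Generator,
    length: int,
    params: DetectorParams,
    forbidden_first: str = "",
    forbidden_last: str = "",
) -> str:
    """Random non-repetitive spacer.

    Rejected until the detector finds nothing in it and its boundary
    characters cannot extend an adjacent region's periodicity
    (``forbidden_first`` / ``forbidden_last``).
    """
    while True:
        s = "".join(ALPHABET[int(b)] for b in rng.integers(0, 4, size=length))
        if s[0] in forbidden_first or s[-1] in forbidden_last:
            continue
        if not detect_repeats(s, "spacer", params):
            return s


def generate_cohort(spec: CohortSpec, keep_histories: bool = True) -> Cohort:
    """Generate a cohort per ``spec``; deterministic for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    det = DetectorParams()
    patterns = [
        _random_pattern(rng, *spec.pattern_length_range) for _ in range(spec.n_regions)
    ]
    # spacer r sits before region r; boundary bases must not extend the
    # periodicity of either neighbouring region
    spacers = []
    for r in range(spec.n_regions + 1):
        # right extension of region r-1 tests spacer[0] against pattern[0];
        # left extension of region r tests spacer[-1] against pattern[-1]
        prev_first = patterns[r - 1][0] if r > 0 else ""
        next_last = patterns[r][-1] if r < spec.n_regions else ""
        spacers.append(
            _spacer(rng, spec.spacer_length, det,
                    forbidden_first=prev_first, forbidden_last=next_last)
        )

    max_dups = spec.copy_range[1] - 1
    samples: dict[str, str] = {}
    labels_rows = []
    truth_rows = []
    histories: dict[tuple[str, int], DuplicationHistory] = {}

    for ci, (label, n_samples) in enumerate(
        zip(spec.class_labels, spec.samples_per_class)
    ):
        mut_rate = np.full(spec.n_regions, spec.base_mutation_rate)
        dup_rate = np.full(spec.n_regions, spec.base_duplication_count)
        if ci == spec.effect_class:
            for r in spec.signal_regions:
                mut_rate[r] += spec.m_shift
                dup_rate[r] += spec.d_shift
        for si in range(n_samples):
            sample_id = f"{label}_s{si + 1:04d}"
            labels_rows.append({"sample_id": sample_id, "class": label})
            parts = []
            pos = 0
            for r in range(spec.n_regions):
                parts.append(spacers[r])
                pos += len(spacers[r])
                present = bool(rng.random() >= spec.dropout_rate)
                if not present:
                    truth_rows.append(
                        {
                            "sample_id": sample_id,
                            "region": r,
                            "class": label,
                            "present": False,
                            "pattern": canonical_rotation(patterns[r]),
                            "witness_m": -1,
                            "true_d": -1,
                            "start": -1,
                            "end": -1,
                        }
                    )
                    continue
                root = patterns[r]
                if rng.random() < spec.pattern_noise_rate:
                    root = _pattern_variant(root, rng)
                n_dup = int(np.clip(rng.poisson(dup_rate[r]), 1, max_dups))
                n_mut = int(rng.poisson(mut_rate[r]))
                hist = simulate_history(root, n_dup, n_mut, int(rng.integers(2**31)))
                if keep_histories:
                    histories[(sample_id, r)] = hist
                seq = hist.final_sequence
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "region": r,
                        "class": label,
                        "present": True,
                        "pattern": canonical_rotation(root),
                        "witness_m": hist.witness_mutations,
                        "true_d": hist.final_block_count,
                        "start": pos,
                        "end": pos + len(seq),
                    }
                )
                parts.append(seq)
                pos += len(seq)
            parts.append(spacers[-1])
            samples[sample_id] = "".join(parts)

    ref_copies = max(2, int(round(spec.base_duplication_count)) + 1)
    ref_parts = []
    for r in range(spec.n_regions):
        ref_parts.append(spacers[r])
        ref_parts.append(patterns[r] * ref_copies)
    ref_parts.append(spacers[-1])

    return Cohort(
        spec=spec,
        samples=samples,
        reference="".join(ref_parts),
        labels=pd.DataFrame(labels_rows, columns=["sample_id", "class"]),
        ground_truth=pd.DataFrame(
            truth_rows,
            columns=[
                "sample_id", "region", "class", "present", "pattern",
                "witness_m", "true_d", "start", "end",
            ],
        ),
        region_patterns=patterns,
        histories=histories,
    )


def write_cohort(cohort: Cohort, outdir) -> dict[str, Path]:
    """Write FASTA/TSV artefacts; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": outdir / "samples.fasta",
        "reference": outdir / "reference.fasta",
        "labels": outdir / "labels.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
        "spec": outdir / "cohort_spec.yaml",
    }
    SeqIO.write(cohort.to_records(), paths["samples"], "fasta")
    SeqIO.write(
        [SeqRecord(Seq(cohort.reference), id="reference", description="")],
        paths["reference"],
        "fasta",
    )
    cohort.labels.to_csv(paths["labels"], sep="\t", index=False)
    cohort.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    cohort.spec.to_yaml(paths["spec"])
    return paths
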