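"""Domain types and coordinate conventions shared by every pipeline stage.

All internal coordinates are 0-based, half-open.  Two formats keep their
native conventions at the I/O boundary only: AGP records are 1-based
inclusive, and label-map positions are 1-based base pairs (CMAP style).

Sequences are uppercase DNA over ``{A, C, G, T, N}``.  ``N`` is the only
ambiguity code accepted; other IUPAC codes are rejected unless the caller
asks for coercion to ``N``.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

_VALID_SEQ = re.compile(r"[ACGTN]+\Z")
_IUPAC_AMBIG = set("RYSWKMBDHV")

#: provenance block: (source_id, start, end, strand) in source coordinates
SourceInterval = tuple[str, int, int, str]


class MapweaverError(ValueError):
    """Base error for invalid inputs or violated preconditions."""


@dataclass
class SequenceRecord:
    """A named DNA sequence with optional provenance back to its source.

    ``source_intervals`` tile ``[0, len(seq))`` in record coordinates order:
    block ``i`` describes where the ``i``-th chunk of this sequence came
    from, as ``(source_id, start, end, strand)`` in *source* coordinates.
    """

    id: str
    seq: str
    source_intervals: list[SourceInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)

    def validate(self) -> None:
        if not self.seq:
            raise MapweaverError(f"record {self.id!r}: empty sequence")
        if not _VALID_SEQ.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise MapweaverError(
                f"record {self.id!r}: invalid characters {bad}; only A/C/G/T/N allowed"
            )
        if self.source_intervals:
            total = sum(e - s for _, s, e, _ in self.source_intervals)
            if total != len(self.seq):
                raise MapweaverError(
                    f"record {self.id!r}: provenance blocks cover {total} bp, "
                    f"sequence is {len(self.seq)} bp"
                )


@dataclass(frozen=True)
class NGapInterval:
    """A run of Ns, 0-based half-open; ``kind`` records how the gap arose."""

    start: int
    end: int
    kind: str = "unknown"  # {estimated, overlap13N, unknown}

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise MapweaverError(f"gap end {self.end} <= start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LabelMap:
    """Ordered label positions on one molecule or contig (CMAP role).

    Positions are 1-based base pairs, strictly increasing, within
    ``[1, length_bp]``.  ``source`` distinguishes in-silico digests of
    sequence from (simulated) optical consensus maps.
    """

    id: str
    length_bp: float
    labels: list[float]
    source: str = "sequence_digest"  # {sequence_digest, optical}

    def __post_init__(self) -> None:
        self.labels = [float(x) for x in self.labels]
        if self.length_bp <= 0:
            raise MapweaverError(f"map {self.id!r}: non-positive length")
        prev = 0.0
        for x in self.labels:
            if x <= prev:
                raise MapweaverError(
                    f"map {self.id!r}: labels not strictly increasing at {x}"
                )
            prev = x
        if self.labels and self.labels[-1] > self.length_bp:
            raise MapweaverError(
                f"map {self.id!r}: label {self.labels[-1]} beyond length {self.length_bp}"
            )

    @property
    def n_labels(self) -> int:
        return len(self.labels)


@dataclass
class MapAlignment:
    """A monotone pairing of query and reference label indices.

    ``pairs`` are (query_label_idx, ref_label_idx), strictly increasing in
    the reference index and — for orientation ``+`` — in the query index;
    for ``-`` the query indices are strictly decreasing.  Spans are bp
    intervals covered by the outermost paired labels, in each map's own
    coordinates.
    """

    query_id: str
    ref_id: str
    orientation: str  # {+, -}
    pairs: list[tuple[int, int]]
    score: float
    confidence: float
    query_span: tuple[float, float]
    ref_span: tuple[float, float]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class FeatureInterval:
    """Half-open genomic interval with a class label and optional score."""

    seq_id: str
    start: int
    end: int
    label: str
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise MapweaverError(
                f"feature {self.label} on {self.seq_id}: end {self.end} <= start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AssemblyMetrics:
    n50: int
    n90: int
    max_len: int
    total_len: int
    gap_len: int
    n_contigs: int


@dataclass
class AGPRecord:
    """One AGP v2.1 row; coordinates 1-based inclusive.

    Component type ``W`` places a contig sub-range; ``N``/``U`` are gap rows
    whose provenance kind travels in the gap-type column.
    """

    object_id: str
    object_start: int
    object_end: int
    part_number: int
    component_type: str  # {W, N, U}
    component_id: str | None = None
    component_start: int | None = None
    component_end: int | None = None
    orientation: str = "+"
    gap_length: int | None = None
    gap_kind: str | None = None  # {estimated, overlap13N, scaffold, ...}

    @property
    def is_gap(self) -> bool:
        return self.component_type in ("N", "U")


_N_RUN = {}


def find_n_gaps(record: SequenceRecord, min_excluded_run: int = 10) -> list[NGapInterval]:
    """Maximal N-runs strictly longer than ``min_excluded_run``, sorted.

    The default threshold of 10 means an 11-N run is the shortest reported
    gap, matching the convention that assembly gap length counts only runs
    of more than 10 Ns.
    """
    if min_excluded_run < 0:
        raise MapweaverError("min_excluded_run must be >= 0")
    pat = _N_RUN.get(min_excluded_run)
    if pat is None:
        pat = _N_RUN[min_excluded_run] = re.compile("N{%d,}" % (min_excluded_run + 1))
    return [
        NGapInterval(m.start(), m.end())
        for m in pat.finditer(record.seq)
    ]


def total_gap_length(records: Iterable[SequenceRecord], min_excluded_run: int = 10) -> int:
    return sum(
        g.length for rec in records for g in find_n_gaps(rec, min_excluded_run)
    )


def assembly_metrics(records: Sequence[SequenceRecord]) -> AssemblyMetrics:
    """Contiguity metrics over a contig set.

    N50 is the smallest contig length L such that contigs of length >= L sum
    to at least half the assembly; N90 is the analogue at 90%.  Gap length
    counts N-runs longer than 10.  All values are exact integer bp.
    """
    if not records:
        raise MapweaverError("assembly_metrics: empty record list")
    lengths = sorted((len(r) for r in records), reverse=True)
    total = sum(lengths)
    n50 = n90 = lengths[-1]
    acc = 0
    got50 = got90 = False
    for ln in lengths:
        acc += ln
        if not got50 and acc * 2 >= total:
            n50, got50 = ln, True
        if not got90 and acc * 10 >= 9 * total:
            n90, got90 = ln, True
            break
    return AssemblyMetrics(
        n50=n50,
        n90=n90,
        max_len=lengths[0],
        total_len=total,
        gap_len=total_gap_length(records),
        n_contigs=len(lengths),
    )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
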