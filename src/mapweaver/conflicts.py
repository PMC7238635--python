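"""Map-versus-sequence conflict detection and chimeric-contig cutting.

A chimeric contig joins two loci that do not belong together; aligned to
an optical map it shows an alignment that stops mid-contig with plenty of
unaligned labels and sequence left on *both* sides of the terminus.  We
emit such termini as conflicts, score how many independent maps span the
junction contiguously, and cut the sequence (never the map — the maps are
the anchor) where support falls below a threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LabelMap, MapAlignment, MapweaverError, SequenceRecord


@dataclass
class Conflict:
    contig_id: str
    junction_bp: int
    map_id: str
    overhang_labels_contig: int
    overhang_labels_map: int
    support_score: float = -1.0  # unscored

    def key(self) -> tuple[str, int]:
        return (self.contig_id, self.junction_bp)


def detect_conflicts(alignments: list[MapAlignment],
                     digests: dict[str, LabelMap],
                     maps: dict[str, LabelMap],
                     min_overhang_labels: int = 5,
                     min_overhang_bp: int = 50_000) -> list[Conflict]:
    """Emit a conflict wherever an alignment terminates with at least
    ``min_overhang_labels`` unaligned labels *and* ``min_overhang_bp``
    unaligned bp beyond the terminus on both the contig and the map.

    The junction is placed at the contig position of the terminal paired
    label — the last evidence-bearing coordinate.  Only the best-scoring
    alignment per (contig, map) pair is examined: secondary local
    alignments are not conflict evidence.
    """
    best: dict[tuple[str, str], MapAlignment] = {}
    for aln in alignments:
        key = (aln.query_id, aln.ref_id)
        if key not in best or aln.score > best[key].score:
            best[key] = aln
    out: list[Conflict] = []
    for aln in best.values():
        dig = digests.get(aln.query_id)
        ref = maps.get(aln.ref_id)
        if dig is None or ref is None:
            continue
        q = dig.labels
        r = ref.labels
        q_idx = [p[0] for p in aln.pairs]
        r_idx = [p[1] for p in aln.pairs]
        # contig-side terminals in contig coordinates
        q_first, q_last = min(q_idx), max(q_idx)
        r_first, r_last = min(r_idx), max(r_idx)
        # how the contig's low-coordinate side maps onto the ref depends on
        # orientation: for '+', contig start pairs with ref r_first; for '-',
        # contig start pairs with ref r_last.
        for side in ("low", "high"):
            if side == "low":
                c_labels = q_first
                c_bp = q[q_first] - 1.0
                junction = int(round(q[q_first]))
            else:
                c_labels = dig.n_labels - 1 - q_last
                c_bp = dig.length_bp - q[q_last]
                junction = int(round(q[q_last]))
            map_low = (side == "low") == (aln.orientation == "+")
            if map_low:
                m_labels = r_first
                m_bp = r[r_first] - 1.0
            else:
                m_labels = ref.n_labels - 1 - r_last
                m_bp = ref.length_bp - r[r_last]
            if (c_labels >= min_overhang_labels and c_bp >= min_overhang_bp
                    and m_labels >= min_overhang_labels and m_bp >= min_overhang_bp):
                out.append(Conflict(
                    contig_id=aln.query_id, junction_bp=junction,
                    map_id=aln.ref_id,
                    overhang_labels_contig=int(c_labels),
                    overhang_labels_map=int(m_labels)))
    return out


def score_junction_support(conflict: Conflict,
                           alignments: list[MapAlignment],
                           digests: dict[str, LabelMap],
                           window_labels: int = 3) -> float:
    """Support = 100 x (fraction of window-spanning maps that align
    contiguously through a +/- ``window_labels`` window around the junction).

    A map's alignment *spans* the window if its paired query labels reach
    both sides of the window; it is *contiguous* if every contig label
    inside the window is paired.  No spanning maps means zero support.
    """
    dig = digests[conflict.contig_id]
    labels = np.asarray(dig.labels)
    jidx = int(np.argmin(np.abs(labels - conflict.junction_bp)))
    lo = max(0, jidx - window_labels)
    hi = min(dig.n_labels - 1, jidx + window_labels)
    window = set(range(lo, hi + 1))
    spanning = 0
    contiguous = 0
    per_map_best: dict[str, MapAlignment] = {}
    for aln in alignments:
        if aln.query_id != conflict.contig_id:
            continue
        prev = per_map_best.get(aln.ref_id)
        if prev is None or aln.score > prev.score:
            per_map_best[aln.ref_id] = aln
    for aln in per_map_best.values():
        q_idx = sorted(p[0] for p in aln.pairs)
        if q_idx[0] <= lo and q_idx[-1] >= hi:
            spanning += 1
            if window <= set(q_idx):
                contiguous += 1
    if spanning == 0:
        return 0.0
    return 100.0 * contiguous / spanning


@dataclass
class CutRecord:
    fragment_id: str
    source_id: str
    start: int
    end: int
    flagged_short: bool


def cut_contigs(contigs: list[SequenceRecord],
                conflicts: list[Conflict],
                support_cut: float = 35.0,
                min_fragment: int = 20_000,
                dedup_radius: int = 10_000) -> tuple[list[SequenceRecord], list[CutRecord]]:
    """Split contigs at unsupported junctions.

    Junctions with support below ``support_cut`` cut the sequence at
    ``junction_bp``; junctions within ``dedup_radius`` of each other (the
    same break seen from replicate maps or both chromosomes' maps) merge
    into one cut.  Fragments are suffixed ``.1``, ``.2``, ... in
    coordinate order, keep provenance back to the source contig, and are
    flagged (never dropped) when shorter than ``min_fragment``.
    """
    cuts_by_contig: dict[str, list[int]] = {}
    for c in conflicts:
        if 0 <= c.support_score < support_cut:
            cuts_by_contig.setdefault(c.contig_id, []).append(c.junction_bp)
    out: list[SequenceRecord] = []
    ledger: list[CutRecord] = []
    for rec in contigs:
        raw = sorted(set(cuts_by_contig.get(rec.id, [])))
        cuts = []
        for pos in raw:
            if cuts and pos - cuts[-1] <= dedup_radius:
                continue
            cuts.append(pos)
        if not cuts:
            # identity provenance so stage-to-stage liftover can chain
            out.append(SequenceRecord(rec.id, rec.seq,
                                      [(rec.id, 0, len(rec), "+")]))
            ledger.append(CutRecord(rec.id, rec.id, 0, len(rec), False))
            continue
        for pos in cuts:
            if not (0 < pos < len(rec)):
                raise MapweaverError(
                    f"cut position {pos} outside contig {rec.id!r} (len {len(rec)})")
        bounds = [0] + cuts + [len(rec)]
        for i, (s, e) in enumerate(zip(bounds, bounds[1:]), start=1):
            frag = SequenceRecord(f"{rec.id}.{i}", rec.seq[s:e],
                                  source_intervals=[(rec.id, s, e, "+")])
            out.append(frag)
            ledger.append(CutRecord(frag.id, rec.id, s, e, (e - s) < min_fragment))
    return out, ledger
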