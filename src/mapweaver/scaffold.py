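"""Map-guided adjacency, hybrid scaffolding with gap sizing, and 13N
overlap-junction resolution.

Hybrid scaffolding orders and orients conflict-free contigs along optical
maps.  Positive inter-contig gaps become N runs of the map-estimated size
(minimum 100); junctions whose placements overlap on the map get exactly
13 Ns — the conventional marker for an identified-but-unmerged overlap —
and are revisited by sequence-level merging afterwards.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AGPRecord,
    LabelMap,
    MapAlignment,
    SequenceRecord,
    reverse_complement,
)


@dataclass
class Placement:
    contig_id: str
    orientation: str
    start: float  # projected contig span on the map, bp
    end: float
    confidence: float

    @property
    def span(self) -> float:
        return self.end - self.start


@dataclass
class ScaffoldGap:
    after_index: int  # gap follows this placement index
    kind: str  # {estimated, overlap13N}
    size: int


@dataclass
class ScaffoldPlan:
    scaffold_id: str
    map_id: str
    placements: list[Placement]
    gaps: list[ScaffoldGap] = field(default_factory=list)


def project_placement(aln: MapAlignment, digest: LabelMap, ref: LabelMap) -> Placement:
    """Full-contig interval on the map implied by an alignment: the ref
    span extended by the contig's unaligned tails."""
    q = np.asarray(digest.labels)
    q_idx = [p[0] for p in aln.pairs]
    q_lo, q_hi = min(q_idx), max(q_idx)
    head = q[q_lo] - 1.0  # unaligned contig bp before first paired label
    tail = digest.length_bp - q[q_hi]
    r_lo, r_hi = aln.ref_span
    if aln.orientation == "+":
        start, end = r_lo - head, r_hi + tail
    else:
        start, end = r_lo - tail, r_hi + head
    return Placement(aln.query_id, aln.orientation, float(start), float(end),
                     aln.confidence)


def best_placements(alignments: list[MapAlignment],
                    digests: dict[str, LabelMap],
                    maps: dict[str, LabelMap],
                    ambiguity_margin: float = 1e-9
                    ) -> tuple[dict[str, dict[str, Placement]], set[str]]:
    """Best placement per (contig, map).

    A contig with two equally-scoring placements at *distinct loci on the
    same map* (the repeat-induced case) is flagged ambiguous and left
    unplaced.  Equal scores on different maps are expected — replicate
    consensus maps cover the same locus — and are resolved later by
    greedy map selection.
    """
    per_contig: dict[str, list[tuple[float, str, Placement]]] = {}
    for aln in alignments:
        dig = digests.get(aln.query_id)
        ref = maps.get(aln.ref_id)
        if dig is None or ref is None:
            continue
        pl = project_placement(aln, dig, ref)
        per_contig.setdefault(aln.query_id, []).append((aln.score, aln.ref_id, pl))
    placements: dict[str, dict[str, Placement]] = {}
    ambiguous: set[str] = set()
    for cid, cands in per_contig.items():
        cands.sort(key=lambda t: -t[0])
        best_by_map: dict[str, Placement] = {}
        for score, ref_id, pl in cands:
            if ref_id not in best_by_map:
                best_by_map[ref_id] = pl
        by_map_all: dict[str, list[tuple[float, Placement]]] = {}
        for score, ref_id, pl in cands:
            by_map_all.setdefault(ref_id, []).append((score, pl))
        for ref_id, lst in by_map_all.items():
            if len(lst) < 2:
                continue
            (s0, p0), (s1, p1) = lst[0], lst[1]
            distinct = abs(p0.start - p1.start) > p0.span * 0.5
            if distinct and abs(s0 - s1) <= ambiguity_margin * max(abs(s0), 1.0):
                ambiguous.add(cid)
        placements[cid] = best_by_map
    return placements, ambiguous


def map_guided_adjacency(contigs: dict[str, SequenceRecord],
                         maps: dict[str, LabelMap],
                         alignments: list[MapAlignment],
                         digests: dict[str, LabelMap],
                         min_detectable_overlap_bp: int = 200_000
                         ) -> list[tuple[tuple[str, str], float, bool]]:
    """Gaps between consecutive contigs on each map.

    Returns ``((left_id, right_id), estimated_gap_bp, merge_now)`` where
    ``merge_now`` marks overlaps large enough (>= the detectability floor)
    to hand straight to sequence-level merging; smaller overlaps wait for
    hybrid scaffolding.
    """
    placements, ambiguous = best_placements(alignments, digests, maps)
    by_map: dict[str, list[Placement]] = {}
    for cid, per_map in placements.items():
        if cid in ambiguous or not per_map:
            continue
        best = max(per_map.values(), key=lambda p: p.confidence)
        best_map = next(m for m, p in per_map.items() if p is best)
        by_map.setdefault(best_map, []).append(best)
    out = []
    for map_id, pls in by_map.items():
        pls.sort(key=lambda p: p.start)
        for a, b in zip(pls, pls[1:]):
            gap = b.start - a.end
            merge_now = gap < 0 and -gap >= min_detectable_overlap_bp
            out.append(((a.contig_id, b.contig_id), float(gap), merge_now))
    return out


def hybrid_scaffold(contigs: list[SequenceRecord],
                    maps: dict[str, LabelMap],
                    alignments: list[MapAlignment],
                    digests: dict[str, LabelMap],
                    min_gap: int = 100
                    ) -> tuple[list[ScaffoldPlan], list[SequenceRecord], list[str]]:
    """Order and orient contigs along optical maps.

    Maps are chosen greedily by total newly-anchored contig span, so
    near-duplicate (replicate) maps do not fragment a chromosome across
    scaffolds.  Returns (plans, scaffold sequences, leftover contig ids —
    unplaced or ambiguous).
    """
    by_id = {c.id: c for c in contigs}
    placements, ambiguous = best_placements(alignments, digests, maps)
    unassigned = {c.id for c in contigs}
    leftovers = sorted(cid for cid in unassigned if cid in ambiguous
                       or not placements.get(cid))
    assignable = unassigned - set(leftovers)
    chosen: list[tuple[str, list[Placement]]] = []
    while assignable:
        best_map, best_gain, best_pls = None, 0.0, None
        for map_id in maps:
            pls = []
            gain = 0.0
            for cid in assignable:
                pl = placements.get(cid, {}).get(map_id)
                if pl is not None:
                    pls.append(pl)
                    gain += pl.span
            if gain > best_gain:
                best_map, best_gain, best_pls = map_id, gain, pls
        if best_map is None:
            break
        chosen.append((best_map, best_pls))
        assignable -= {p.contig_id for p in best_pls}
    leftovers.extend(sorted(assignable))

    plans: list[ScaffoldPlan] = []
    seqs: list[SequenceRecord] = []
    for n, (map_id, pls) in enumerate(sorted(chosen, key=lambda t: t[0]), start=1):
        pls.sort(key=lambda p: p.start)
        plan = ScaffoldPlan(f"scaffold_{n:03d}", map_id, pls)
        for i in range(len(pls) - 1):
            gap = pls[i + 1].start - pls[i].end
            if gap > 0:
                plan.gaps.append(ScaffoldGap(i, "estimated", max(int(round(gap)), min_gap)))
            else:
                plan.gaps.append(ScaffoldGap(i, "overlap13N", 13))
        plans.append(plan)
        seqs.append(build_scaffold_sequence(plan, by_id))
    return plans, seqs, leftovers


def build_scaffold_sequence(plan: ScaffoldPlan,
                            by_id: dict[str, SequenceRecord]) -> SequenceRecord:
    gaps = {g.after_index: g for g in plan.gaps}
    parts: list[str] = []
    blocks = []
    for i, pl in enumerate(plan.placements):
        rec = by_id[pl.contig_id]
        seq = rec.seq if pl.orientation == "+" else reverse_complement(rec.seq)
        parts.append(seq)
        blocks.append((pl.contig_id, 0, len(rec), pl.orientation))
        if i in gaps:
            parts.append("N" * gaps[i].size)
            blocks.append((f"gap:{gaps[i].kind}", 0, gaps[i].size, "+"))
    return SequenceRecord(plan.scaffold_id, "".join(parts), source_intervals=blocks)


def plan_to_agp(plan: ScaffoldPlan, by_id: dict[str, SequenceRecord]) -> list[AGPRecord]:
    rows: list[AGPRecord] = []
    gaps = {g.after_index: g for g in plan.gaps}
    pos = 1
    part = 1
    for i, pl in enumerate(plan.placements):
        ln = len(by_id[pl.contig_id])
        rows.append(AGPRecord(plan.scaffold_id, pos, pos + ln - 1, part, "W",
                              component_id=pl.contig_id, component_start=1,
                              component_end=ln, orientation=pl.orientation))
        pos += ln
        part += 1
        if i in gaps:
            g = gaps[i]
            rows.append(AGPRecord(plan.scaffold_id, pos, pos + g.size - 1, part, "N",
                                  gap_length=g.size, gap_kind=g.kind))
            pos += g.size
            part += 1
    return rows


def resolve_13N_overlaps(plans: list[ScaffoldPlan],
                         contigs: list[SequenceRecord],
                         overlap_params: dict | None = None,
                         skip_junctions: set[tuple[str, int]] | None = None
                         ) -> tuple[list[ScaffoldPlan], list[SequenceRecord],
                                    list[SequenceRecord], int, int]:
    """Attempt sequence-level merging across every overlap13N junction.

    On success the two flanking contigs become one merged contig and the
    gap disappears from the plan; on failure (no confident dovetail — e.g.
    flanks sharing only a diverged repeat) the 13 Ns stay.  Junctions in
    ``skip_junctions`` — regions configured unmergeable, the NOR analogue —
    are never attempted.  Returns (plans, scaffold sequences, updated
    contig list, n_resolved, n_retained).
    """
    from .overlap import find_sequence_overlaps, merge_overlapping

    overlap_params = dict(overlap_params or {})
    skip_junctions = skip_junctions or set()
    by_id = {c.id: c for c in contigs}
    n_resolved = n_retained = 0
    new_plans: list[ScaffoldPlan] = []
    seqs: list[SequenceRecord] = []
    for plan in plans:
        placements = list(plan.placements)
        gaps = sorted(plan.gaps, key=lambda g: g.after_index)
        changed = True
        while changed:
            changed = False
            for gi, gap in enumerate(gaps):
                if gap.kind != "overlap13N":
                    continue
                if (plan.scaffold_id, gap.after_index) in skip_junctions:
                    continue
                left = placements[gap.after_index]
                right = placements[gap.after_index + 1]
                l_rec = by_id[left.contig_id]
                r_rec = by_id[right.contig_id]
                l_seq = (l_rec.seq if left.orientation == "+"
                         else reverse_complement(l_rec.seq))
                r_seq = (r_rec.seq if right.orientation == "+"
                         else reverse_complement(r_rec.seq))
                lo = SequenceRecord(f"{left.contig_id}|{left.orientation}", l_seq,
                                    [(left.contig_id, 0, len(l_rec), left.orientation)])
                ro = SequenceRecord(f"{right.contig_id}|{right.orientation}", r_seq,
                                    [(right.contig_id, 0, len(r_rec), right.orientation)])
                ovs = find_sequence_overlaps([lo], [ro], **overlap_params)
                dts = [o for o in ovs if o.kind == "dovetail" and o.orientation == "+"
                       and o.a_interval[1] >= len(lo) - overlap_params.get("max_overhang", 500)]
                if not dts:
                    n_retained += 1
                    continue
                merged, ledger = merge_overlapping([lo, ro], dts)
                if len(merged) != 1:
                    n_retained += 1
                    continue
                m = merged[0]
                m.id = f"{left.contig_id}+{right.contig_id}"
                # remap provenance through the oriented wrappers
                m.source_intervals = _unwrap_blocks(m.source_intervals,
                                                    {lo.id: lo, ro.id: ro})
                by_id[m.id] = m
                new_pl = Placement(m.id, "+", left.start, right.end,
                                   min(left.confidence, right.confidence))
                placements[gap.after_index:gap.after_index + 2] = [new_pl]
                gaps.pop(gi)
                for g in gaps:
                    if g.after_index > gap.after_index:
                        g.after_index -= 1
                n_resolved += 1
                changed = True
                break
        new_plan = ScaffoldPlan(plan.scaffold_id, plan.map_id, placements, gaps)
        new_plans.append(new_plan)
        seqs.append(build_scaffold_sequence(new_plan, by_id))
    return new_plans, seqs, list(by_id.values()), n_resolved, n_retained


def _unwrap_blocks(blocks, wrappers):
    out = []
    for sid, s, e, strand in blocks:
        w = wrappers.get(sid)
        if w is None:
            out.append((sid, s, e, strand))
            continue
        inner_id, _, _, inner_strand = w.source_intervals[0]
        L = len(w)
        if inner_strand == "+":
            out.append((inner_id, s, e, strand))
        else:
            flip = "-" if strand == "+" else "+"
            out.append((inner_id, L - e, L - s, flip))
    return out
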