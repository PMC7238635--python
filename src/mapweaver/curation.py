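"""Insertion/deletion discrepancy calling against rescaled maps, and
patching of the primary assembly with concordant alternate-assembly
sequence.

A discrepancy is an adjacent matched-label pair whose contig span and map
span disagree by more than ``min_size`` bp: the contig carries an
insertion when its span is the larger one, otherwise a deletion (the
classic signature of a collapsed tandem array).  Only homozygous calls —
all maps covering the locus agree — are treated as true assembly errors
and patched from the alternate assembly, and only when the alternate
contig is itself concordant with the map across the same label interval.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import LabelMap, MapAlignment, MapweaverError, SequenceRecord


@dataclass
class DiscrepancyCall:
    contig_id: str
    kind: str  # {insertion, deletion}
    contig_interval: tuple[int, int]  # bp on contig, 0-based half-open
    map_interval: tuple[float, float]  # bp on map
    map_id: str
    size: int
    confidence: float
    zygosity: str = "unknown"  # {homozygous, heterozygous, unknown}


def _transition_scores(qpos, rpos, sizing_sd_coeff: float) -> np.ndarray:
    from .optical import MATCH_BONUS

    qlen = np.abs(np.diff(qpos))
    rlen = np.diff(rpos)
    mean = 0.5 * (qlen + rlen)
    delta = qlen - rlen
    with np.errstate(divide="ignore", invalid="ignore"):
        pen = np.where(mean > 0, delta * delta / (sizing_sd_coeff ** 2 * mean), np.inf)
    return MATCH_BONUS - pen


def call_discrepancies(alignment: MapAlignment, query: LabelMap, ref: LabelMap,
                       min_size: int = 1000, min_confidence: float = 0.1,
                       sizing_sd_coeff: float = 3.0, max_window: int = 8,
                       noise_z: float = 4.0) -> list[DiscrepancyCall]:
    """Size discrepancies between a contig digest and a (rescaled) map.

    A discrepancy is a step change in the cumulative contig-minus-map
    drift along the alignment.  Scanning windows of up to ``max_window``
    transitions catches steps the aligner smeared across skipped labels;
    a single-transition span difference is the ``max_window=1`` special
    case.  A step must exceed both ``min_size`` and a sizing-noise floor
    of ``noise_z`` standard deviations for the window's span (sd =
    sizing_sd_coeff * sqrt(span)).  Confidence is the mean of the
    flanking transitions' match scores normalised to [0, 1]; calls below
    ``min_confidence`` are suppressed.  Zygosity is left ``unknown`` here
    and adjudicated across maps by :func:`adjudicate_zygosity`.
    """
    from .optical import MATCH_BONUS

    q = np.asarray(query.labels, dtype=np.float64)
    r = np.asarray(ref.labels, dtype=np.float64)
    qi = np.array([p[0] for p in alignment.pairs])
    ri = np.array([p[1] for p in alignment.pairs])
    qpos = q[qi]
    rpos = r[ri]
    n = qpos.size
    if n < 2:
        return []
    qspan = np.abs(np.diff(qpos))
    rspan = np.diff(rpos)
    trans = _transition_scores(qpos, rpos, sizing_sd_coeff)
    # cumulative drift at each matched pair
    drift = np.concatenate([[0.0], np.cumsum(qspan - rspan)])
    calls: list[DiscrepancyCall] = []
    blocked = np.zeros(n - 1, dtype=bool)  # transitions already inside a call
    while True:
        best = None  # (margin, t, w, step)
        for t in range(n - 1):
            if blocked[t]:
                continue
            for w in range(1, min(max_window, n - 1 - t) + 1):
                if blocked[t:t + w].any():
                    break
                step = drift[t + w] - drift[t]
                span = max(abs(qpos[t + w] - qpos[t]), rpos[t + w] - rpos[t], 1.0)
                floor = max(min_size, noise_z * sizing_sd_coeff * math.sqrt(span))
                margin = abs(step) - floor
                if margin > 0 and (best is None or margin > best[0]):
                    best = (margin, t, w, step)
        if best is None:
            break
        _, t, w, step = best
        blocked[t:t + w] = True
        flank = []
        if t - 1 >= 0:
            flank.append(trans[t - 1])
        if t + w < trans.size:
            flank.append(trans[t + w])
        conf = (float(np.clip(np.mean(flank) / MATCH_BONUS, 0.0, 1.0))
                if flank else 0.0)
        if conf < min_confidence:
            continue
        c_lo, c_hi = sorted((qpos[t], qpos[t + w]))
        calls.append(DiscrepancyCall(
            contig_id=alignment.query_id,
            kind="insertion" if step > 0 else "deletion",
            contig_interval=(int(c_lo) - 1, int(c_hi)),
            map_interval=(float(rpos[t]), float(rpos[t + w])),
            map_id=alignment.ref_id,
            size=int(round(abs(step))),
            confidence=conf,
        ))
    calls.sort(key=lambda c: c.contig_interval)
    return calls


def merge_adjacent_calls(calls: list[DiscrepancyCall],
                         max_gap: int = 0) -> list[DiscrepancyCall]:
    """Merge same-kind calls on one contig whose contig intervals touch or
    lie within ``max_gap`` bp (discrepancies split across label intervals)."""
    out: list[DiscrepancyCall] = []
    for call in sorted(calls, key=lambda c: (c.contig_id, c.map_id, c.contig_interval)):
        prev = out[-1] if out else None
        if (prev and prev.contig_id == call.contig_id and prev.map_id == call.map_id
                and prev.kind == call.kind
                and call.contig_interval[0] - prev.contig_interval[1] <= max_gap):
            out[-1] = replace(
                prev,
                contig_interval=(prev.contig_interval[0], call.contig_interval[1]),
                map_interval=(prev.map_interval[0], call.map_interval[1]),
                size=prev.size + call.size,
                confidence=min(prev.confidence, call.confidence),
            )
        else:
            out.append(call)
    return out


def adjudicate_zygosity(calls: list[DiscrepancyCall],
                        covering_maps: dict[tuple[str, int, int], int],
                        size_tol: float = 0.5) -> list[DiscrepancyCall]:
    """Set zygosity by cross-map agreement.

    ``covering_maps`` gives, per call key (contig, interval), the number of
    maps whose alignment covers the locus.  A call seen in every covering
    map (same kind, sizes within ``size_tol`` relative tolerance) is
    homozygous; seen in some but not all, heterozygous; with fewer than two
    covering maps, unknown (conservative: never patched).
    """
    grouped: dict[tuple, list[DiscrepancyCall]] = {}
    for c in calls:
        placed = False
        for key, grp in grouped.items():
            ref = grp[0]
            if (ref.contig_id == c.contig_id and ref.kind == c.kind
                    and _intervals_close(ref.contig_interval, c.contig_interval)
                    and abs(ref.size - c.size) <= size_tol * max(ref.size, c.size)):
                grp.append(c)
                placed = True
                break
        if not placed:
            grouped[(c.contig_id, c.kind, c.contig_interval)] = [c]
    out: list[DiscrepancyCall] = []
    for grp in grouped.values():
        rep = max(grp, key=lambda c: c.confidence)
        n_cover = covering_maps.get(
            (rep.contig_id, rep.contig_interval[0], rep.contig_interval[1]),
            len({c.map_id for c in grp}))
        n_agree = len({c.map_id for c in grp})
        if n_cover < 2:
            zyg = "unknown"
        elif n_agree >= n_cover:
            zyg = "homozygous"
        else:
            zyg = "heterozygous"
        out.append(replace(rep, zygosity=zyg))
    return out


def _intervals_close(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """Same locus if the contig intervals overlap (boundaries jitter by a
    few label intervals between maps)."""
    return a[0] < b[1] and b[0] < a[1]


def _snap_junction(recipient: str, r_pos: int, donor: str, d_pos: int,
                   k: int = 20, radius: int = 500) -> tuple[int, int]:
    """Shift a splice boundary to the nearest exact shared k-mer within
    ``radius`` bp, to avoid junction artifacts; fall back to the label
    positions themselves."""
    r_lo = max(0, r_pos - radius)
    r_hi = min(len(recipient), r_pos + radius + k)
    d_lo = max(0, d_pos - radius)
    d_hi = min(len(donor), d_pos + radius + k)
    window = donor[d_lo:d_hi]
    donor_kmers: dict[str, int] = {}
    for i in range(len(window) - k + 1):
        km = window[i:i + k]
        if "N" not in km:
            donor_kmers.setdefault(km, d_lo + i)
    best: tuple[int, int, int] | None = None
    for i in range(r_lo, r_hi - k + 1):
        km = recipient[i:i + k]
        j = donor_kmers.get(km)
        if j is None:
            continue
        dist = abs(i - r_pos) + abs(j - d_pos)
        if best is None or dist < best[0]:
            best = (dist, i, j)
    if best is None:
        return r_pos, d_pos
    return best[1], best[2]


def patch_with_alternate(primary_contig: SequenceRecord,
                         call: DiscrepancyCall,
                         alternate_contigs: dict[str, SequenceRecord],
                         alt_alignments: list[MapAlignment],
                         alt_digests: dict[str, LabelMap],
                         maps: dict[str, LabelMap],
                         min_size: int = 1000,
                         sizing_sd_coeff: float = 3.0,
                         noise_z: float = 4.0) -> tuple[SequenceRecord, str]:
    """Replace the discrepant inter-label segment with the alternate
    assembly's segment, if a concordant donor exists.

    The donor must align to the call's map across the call's label
    interval with no discrepancy of its own (every covered transition's
    span difference <= ``min_size``).  Boundaries snap to matched label
    positions, then to the nearest exact 20-mer shared by donor and
    recipient within 500 bp.  Returns (record, note); the record is
    unchanged when no concordant donor is found or the call is not
    homozygous.
    """
    c_lo, c_hi = call.contig_interval
    if not (0 <= c_lo < c_hi <= len(primary_contig)):
        raise MapweaverError(
            f"call interval {call.contig_interval} outside contig {primary_contig.id!r}")
    if call.zygosity != "homozygous":
        return primary_contig, f"not patched: zygosity {call.zygosity}"
    m_lo, m_hi = call.map_interval
    for aln in alt_alignments:
        if aln.ref_id != call.map_id:
            continue
        dig = alt_digests.get(aln.query_id)
        donor_rec = alternate_contigs.get(aln.query_id)
        if dig is None or donor_rec is None:
            continue
        q = np.asarray(dig.labels)
        r = np.asarray(maps[aln.ref_id].labels)
        qpos = q[[p[0] for p in aln.pairs]]
        rpos = r[[p[1] for p in aln.pairs]]
        if not (rpos.min() <= m_lo and rpos.max() >= m_hi):
            continue  # does not cover the locus
        # concordance: no discrepancy of its own across the call's map
        # interval — per-transition and cumulative drift both stay under
        # the sizing-noise-aware floor
        concordant = True
        drift = 0.0
        first_r = None
        for t in range(len(rpos) - 1):
            if rpos[t + 1] <= m_lo or rpos[t] >= m_hi:
                continue
            if first_r is None:
                first_r = rpos[t]
            span_t = max(rpos[t + 1] - rpos[t], 1.0)
            span_c = max(rpos[t + 1] - first_r, 1.0)
            d = abs(qpos[t + 1] - qpos[t]) - (rpos[t + 1] - rpos[t])
            drift += d
            floor_t = max(min_size, noise_z * sizing_sd_coeff * math.sqrt(span_t))
            floor_c = max(min_size, noise_z * sizing_sd_coeff * math.sqrt(span_c))
            if abs(d) > floor_t or abs(drift) > floor_c:
                concordant = False
                break
        if not concordant:
            continue
        # donor segment between the labels nearest the call's map interval
        d_lo_i = int(np.argmin(np.abs(rpos - m_lo)))
        d_hi_i = int(np.argmin(np.abs(rpos - m_hi)))
        d_a, d_b = sorted((qpos[d_lo_i], qpos[d_hi_i]))
        d_a, d_b = int(d_a) - 1, int(d_b)
        donor_seq = donor_rec.seq
        if aln.orientation == "-":
            from .core import reverse_complement

            donor_seq = reverse_complement(donor_seq)
            d_a, d_b = len(donor_seq) - d_b, len(donor_seq) - d_a
        left_r, left_d = _snap_junction(primary_contig.seq, c_lo, donor_seq, d_a)
        right_r, right_d = _snap_junction(primary_contig.seq, c_hi, donor_seq, d_b)
        if right_r <= left_r or right_d <= left_d:
            continue
        patched_seq = (primary_contig.seq[:left_r]
                       + donor_seq[left_d:right_d]
                       + primary_contig.seq[right_r:])
        if aln.orientation == "-":
            donor_block = (donor_rec.id, len(donor_seq) - right_d,
                           len(donor_seq) - left_d, "-")
        else:
            donor_block = (donor_rec.id, left_d, right_d, "+")
        blocks = [
            (primary_contig.id, 0, left_r, "+"),
            donor_block,
            (primary_contig.id, right_r, len(primary_contig), "+"),
        ]
        patched = SequenceRecord(primary_contig.id, patched_seq,
                                 source_intervals=[b for b in blocks if b[2] > b[1]])
        return patched, (f"patched from {donor_rec.id} "
                         f"[{left_d},{right_d}) into [{left_r},{right_r})")
    return primary_contig, "no concordant donor"
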