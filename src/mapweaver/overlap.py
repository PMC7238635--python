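"""Sequence overlap detection between two contig sets and unbranched-path
(unitig) merging.

Overlaps are found by sampled exact k-mer anchors, restricted to a
dominant diagonal band (collinear chain), and classified as dovetail,
containment or internal.  Identity is estimated as the chained-anchor
coverage of the overlap span, which is exact for identical sequences and
drops steeply with divergence — a deliberately conservative estimator
suited to polished contigs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MapweaverError, SequenceRecord, reverse_complement
from .kmers import kmer_keys


@dataclass
class SequenceOverlap:
    a_id: str
    b_id: str
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]  # on b's forward strand
    orientation: str  # orientation of b relative to a
    identity: float
    kind: str  # {dovetail, containment, internal}
    # exact shared-anchor splice points (a_pos, b_pos on b forward strand, k)
    first_anchor: tuple[int, int]
    last_anchor: tuple[int, int]
    k: int

    def swapped(self) -> "SequenceOverlap":
        kind = self.kind
        return SequenceOverlap(
            self.b_id, self.a_id, self.b_interval, self.a_interval,
            self.orientation, self.identity, kind,
            (self.first_anchor[1], self.first_anchor[0]),
            (self.last_anchor[1], self.last_anchor[0]), self.k)


def _indexed_keys(records: list[SequenceRecord], k: int, window: int):
    """Hash-mod sampled k-mer keys over a record set: (h1, h2, rec_idx, pos).

    A k-mer is kept when its hash is 0 mod ``window``; unlike fixed-stride
    sampling this keeps the same k-mers regardless of each contig's frame,
    so shared k-mers are found at any relative offset.
    """
    h1s, h2s, ridx, poss = [], [], [], []
    mod = np.uint64(max(window, 1))
    for i, rec in enumerate(records):
        if len(rec) < k:
            continue
        h1, h2, valid = kmer_keys(rec.seq, k)
        sel = np.flatnonzero(valid & (h1 % mod == 0))
        if sel.size == 0:
            continue
        h1s.append(h1[sel])
        h2s.append(h2[sel])
        ridx.append(np.full(sel.size, i, dtype=np.int32))
        poss.append(sel)
    if not h1s:
        empty = np.empty(0, dtype=np.uint64)
        return empty, empty, np.empty(0, np.int32), np.empty(0, np.int64)
    return (np.concatenate(h1s), np.concatenate(h2s),
            np.concatenate(ridx), np.concatenate(poss))


def _mixed(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return a1 ^ (a2 * np.uint64(0x9E3779B97F4A7C15))


def _key_counts(keys: np.ndarray) -> np.ndarray:
    """Occurrences of each entry's key within its own (sorted-agnostic) table."""
    order = np.argsort(keys, kind="stable")
    s = keys[order]
    new = np.empty(s.size, dtype=bool)
    new[0] = True
    new[1:] = s[1:] != s[:-1]
    group = np.cumsum(new) - 1
    counts = np.bincount(group)[group]
    out = np.empty(keys.size, dtype=np.int64)
    out[order] = counts
    return out


def _match_keys(a_keys, b_keys, max_hits: int):
    """Join two sampled key tables on their 128-bit key (folded to one
    mixed 64-bit word); fully vectorised.

    Keys occurring more than ``max_hits`` times in either table are
    dropped as repeats.
    """
    a1, a2, ar, ap = a_keys
    b1, b2, br, bp = b_keys
    if a1.size == 0 or b1.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    ka = _mixed(a1, a2)
    kb = _mixed(b1, b2)
    keep_a = np.flatnonzero(_key_counts(ka) <= max_hits)
    keep_b = np.flatnonzero(_key_counts(kb) <= max_hits)
    ka, kb = ka[keep_a], kb[keep_b]
    order = np.argsort(ka, kind="stable")
    kas = ka[order]
    lo = np.searchsorted(kas, kb, side="left")
    hi = np.searchsorted(kas, kb, side="right")
    cnt = hi - lo
    sel = np.flatnonzero(cnt > 0)
    if sel.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    cnt_sel = cnt[sel]
    total = int(cnt_sel.sum())
    offsets = np.cumsum(cnt_sel) - cnt_sel
    ranges = np.arange(total) - np.repeat(offsets, cnt_sel)
    a_sorted_pos = np.repeat(lo[sel], cnt_sel) + ranges
    out_a = keep_a[order[a_sorted_pos]]
    out_b = keep_b[np.repeat(sel, cnt_sel)]
    return out_a, out_b


def _chain(a_pos: np.ndarray, b_pos: np.ndarray, k: int,
           band: int = 5000) -> tuple[np.ndarray, np.ndarray] | None:
    """Keep anchors on the dominant diagonal (within ``band`` bp) and make
    them strictly co-monotone."""
    diag = a_pos - b_pos
    # dominant diagonal via histogram mode
    lo, hi = diag.min(), diag.max()
    if hi - lo <= band:
        sel = np.ones(diag.size, dtype=bool)
    else:
        bins = np.arange(lo, hi + band, band // 2 or 1)
        which = np.digitize(diag, bins)
        counts = np.bincount(which)
        mode = counts.argmax()
        center = bins[min(mode, bins.size - 1)]
        sel = np.abs(diag - center) <= band
    a_sel, b_sel = a_pos[sel], b_pos[sel]
    if a_sel.size == 0:
        return None
    order = np.argsort(a_sel, kind="stable")
    a_sel, b_sel = a_sel[order], b_sel[order]
    # one-pass monotone filter on b (anchors are already near one diagonal)
    keep = np.empty(b_sel.size, dtype=bool)
    last = -np.inf
    bl = b_sel.tolist()
    for i, v in enumerate(bl):
        if v > last:
            keep[i] = True
            last = v
        else:
            keep[i] = False
    return a_sel[keep], b_sel[keep]


def _lis(arr: np.ndarray) -> np.ndarray:
    """Indices of a longest strictly increasing subsequence (patience)."""
    import bisect

    tails: list[int] = []  # values
    tails_idx: list[int] = []
    parent = np.full(arr.size, -1, dtype=np.int64)
    for i, v in enumerate(arr.tolist()):
        j = bisect.bisect_left(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    out = []
    cur = tails_idx[-1]
    while cur >= 0:
        out.append(cur)
        cur = parent[cur]
    return np.array(out[::-1], dtype=np.int64)


def _coverage(a_pos: np.ndarray, k: int) -> int:
    """Union length of [pos, pos+k) intervals over sorted positions."""
    if a_pos.size == 0:
        return 0
    gaps = np.diff(a_pos)
    return int(np.minimum(gaps, k).sum() + k)


def _classify(a_len: int, b_len: int, a_iv, b_iv, max_overhang: int,
              orientation: str) -> str:
    a_left = a_iv[0] <= max_overhang
    a_right = a_len - a_iv[1] <= max_overhang
    b_left = b_iv[0] <= max_overhang
    b_right = b_len - b_iv[1] <= max_overhang
    if (a_left and a_right) or (b_left and b_right):
        return "containment"
    if orientation == "-":
        # b's forward-strand right end faces a's right end
        b_left, b_right = b_right, b_left
    if (a_right and b_left) or (a_left and b_right):
        return "dovetail"
    return "internal"


def find_sequence_overlaps(set_a: list[SequenceRecord],
                           set_b: list[SequenceRecord],
                           k: int = 21,
                           min_overlap: int = 5000,
                           min_identity: float = 0.9,
                           max_overhang: int = 500,
                           sample_window: int = 4,
                           max_kmer_hits: int = 100) -> list[SequenceOverlap]:
    """Pairwise overlaps between two contig sets (both orientations).

    Returns one record per (a, b) pair per orientation at most — the best
    diagonal chain — classified as dovetail/containment/internal.  The
    relation is symmetric: ``overlap(a, b)`` is reported from a's
    perspective; :meth:`SequenceOverlap.swapped` gives b's.
    """
    if k < 15:
        raise MapweaverError("k must be >= 15")
    a_keys = _indexed_keys(set_a, k, sample_window)
    out: list[SequenceOverlap] = []
    min_anchors = max(4, min_overlap // (4 * sample_window))
    for orientation in ("+", "-"):
        if orientation == "+":
            b_recs = set_b
        else:
            b_recs = [SequenceRecord(r.id, reverse_complement(r.seq)) for r in set_b]
        b_keys = _indexed_keys(b_recs, k, sample_window)
        ia, ib = _match_keys(a_keys, b_keys, max_kmer_hits)
        if ia.size == 0:
            continue
        ar, ap = a_keys[2][ia], a_keys[3][ia]
        br, bp = b_keys[2][ib], b_keys[3][ib]
        pair_key = ar.astype(np.int64) * len(set_b) + br
        order = np.argsort(pair_key, kind="stable")
        pair_sorted = pair_key[order]
        bounds = np.flatnonzero(np.diff(pair_sorted)) + 1
        for seg in np.split(order, bounds):
            if seg.size < min_anchors:
                continue
            a_i, b_i = int(ar[seg[0]]), int(br[seg[0]])
            if set_a[a_i].id == set_b[b_i].id:
                continue  # self
            chained = _chain(ap[seg], bp[seg], k)
            if chained is None:
                continue
            ca, cb = chained
            if ca.size < min_anchors:
                continue
            a_iv = (int(ca[0]), int(ca[-1]) + k)
            span = a_iv[1] - a_iv[0]
            if span < min_overlap:
                continue
            identity = min(1.0, _coverage(ca, k) / span)
            if identity < min_identity:
                continue
            b_len = len(set_b[b_i])
            if orientation == "+":
                b_iv = (int(cb[0]), int(cb[-1]) + k)
                first = (int(ca[0]), int(cb[0]))
                last = (int(ca[-1]), int(cb[-1]))
            else:
                # cb are positions on reverse-complemented b
                b_iv = (b_len - (int(cb[-1]) + k), b_len - int(cb[0]))
                first = (int(ca[0]), int(cb[0]))
                last = (int(ca[-1]), int(cb[-1]))
            kind = _classify(len(set_a[a_i]), b_len, a_iv, b_iv, max_overhang,
                             orientation)
            out.append(SequenceOverlap(
                a_id=set_a[a_i].id, b_id=set_b[b_i].id,
                a_interval=a_iv, b_interval=b_iv, orientation=orientation,
                identity=identity, kind=kind,
                first_anchor=first, last_anchor=last, k=k))
    # keep best overlap per (a, b, orientation)
    best: dict[tuple, SequenceOverlap] = {}
    for ov in out:
        key = (ov.a_id, ov.b_id, ov.orientation)
        prev = best.get(key)
        if prev is None or (ov.a_interval[1] - ov.a_interval[0]
                            > prev.a_interval[1] - prev.a_interval[0]):
            best[key] = ov
    return list(best.values())




@dataclass
class MergeRecord:
    unitig_id: str
    parts: list[tuple[str, str]]  # (contig_id, orientation within unitig)
    overlap_bases_removed: int
    note: str = ""


@dataclass
class _Edge:
    """Directed junction: leave ``cur`` via ``cur_end``, enter ``nxt`` via
    ``nxt_end``.  Anchor positions are k-mer starts on each contig's native
    forward strand; ``first``/``last`` are ordered by the stored overlap's
    a-coordinate."""

    cur: str
    cur_end: str  # {L, R}
    nxt: str
    nxt_end: str
    anchors: list[tuple[int, int]]  # [(p_cur, p_nxt) first, (p_cur, p_nxt) last]
    k: int


def _native_anchor(pos: int, length: int, k: int, flipped: bool) -> int:
    return length - pos - k if flipped else pos


def merge_overlapping(contigs: list[SequenceRecord],
                      overlaps: list[SequenceOverlap],
                      primary_ids: set[str] | None = None
                      ) -> tuple[list[SequenceRecord], list[MergeRecord]]:
    """Merge dovetail-overlapping contigs along maximal unbranched paths.

    A contig end carrying more than one dovetail is a branch: no merge
    happens through it.  At each junction the sequences are spliced at an
    exact shared-anchor k-mer; when exactly one side belongs to
    ``primary_ids`` the splice retains the primary contig's bases across
    the overlap (backbone-plus-patcher donor policy).  Contigs contained
    in another contig are absorbed.  A cyclic unbranched path is recorded
    as ``circular unitig`` and emitted unmerged.
    """
    primary_ids = primary_ids or set()
    by_id = {c.id: c for c in contigs}
    contained: set[str] = set()
    for ov in overlaps:
        if ov.kind != "containment" or ov.a_id not in by_id or ov.b_id not in by_id:
            continue
        a_len, b_len = len(by_id[ov.a_id]), len(by_id[ov.b_id])
        span_a = ov.a_interval[1] - ov.a_interval[0]
        span_b = ov.b_interval[1] - ov.b_interval[0]
        if span_b >= 0.9 * b_len and b_len <= a_len:
            contained.add(ov.b_id)
        elif span_a >= 0.9 * a_len and a_len < b_len:
            contained.add(ov.a_id)

    # build directed edges keyed by (contig_id, end)
    raw_edges: dict[tuple[str, str], list[_Edge]] = {}
    for ov in overlaps:
        if ov.kind != "dovetail":
            continue
        if ov.a_id in contained or ov.b_id in contained:
            continue
        if ov.a_id not in by_id or ov.b_id not in by_id:
            continue
        a_len = len(by_id[ov.a_id])
        b_len = len(by_id[ov.b_id])
        a_right = (a_len - ov.a_interval[1]) <= ov.a_interval[0]
        a_end = "R" if a_right else "L"
        if ov.orientation == "+":
            b_end = "L" if a_right else "R"
        else:
            b_end = "R" if a_right else "L"
        flipped = ov.orientation == "-"
        anchors = [
            (ov.first_anchor[0], _native_anchor(ov.first_anchor[1], b_len, ov.k, flipped)),
            (ov.last_anchor[0], _native_anchor(ov.last_anchor[1], b_len, ov.k, flipped)),
        ]
        fwd = _Edge(ov.a_id, a_end, ov.b_id, b_end, anchors, ov.k)
        rev = _Edge(ov.b_id, b_end, ov.a_id, a_end,
                    [(p_b, p_a) for p_a, p_b in anchors], ov.k)
        raw_edges.setdefault((fwd.cur, fwd.cur_end), []).append(fwd)
        raw_edges.setdefault((rev.cur, rev.cur_end), []).append(rev)

    branched = {key for key, lst in raw_edges.items()
                if len({(e.nxt, e.nxt_end) for e in lst}) > 1}
    edges: dict[tuple[str, str], _Edge] = {}
    for key, lst in raw_edges.items():
        if key in branched:
            continue
        e = lst[0]
        if (e.nxt, e.nxt_end) in branched:
            continue
        edges[key] = e

    out: list[SequenceRecord] = []
    ledger: list[MergeRecord] = []
    done: set[str] = set()
    unitig_n = 0

    def degree(cid: str) -> int:
        return sum(1 for e in ("L", "R") if (cid, e) in edges)

    for rec in contigs:
        if rec.id in done or rec.id in contained:
            continue
        deg = degree(rec.id)
        if deg == 0:
            done.add(rec.id)
            out.append(rec)
            continue
        if deg == 2:
            continue  # interior; handled from a terminal (or cycle pass below)
        path = _walk_path(rec.id, edges)
        unitig_n += 1
        merged, removed, parts = _merge_path(path, by_id, primary_ids)
        merged.id = f"unitig_{unitig_n:03d}"
        done.update(cid for cid, _ in parts)
        out.append(merged)
        ledger.append(MergeRecord(merged.id, parts, removed))
    # anything left with degree 2 is part of a cycle
    for rec in contigs:
        if rec.id in done or rec.id in contained:
            continue
        comp = _cycle_members(rec.id, edges)
        for cid in comp:
            done.add(cid)
            out.append(by_id[cid])
        ledger.append(MergeRecord("", [(c, "+") for c in comp], 0,
                                  "circular unitig: emitted unmerged"))
    for cid in sorted(contained):
        if cid in by_id:
            ledger.append(MergeRecord("", [(cid, "+")], len(by_id[cid]),
                                      "contained: absorbed"))
    return out, ledger


def _walk_path(terminal: str, edges: dict[tuple[str, str], "_Edge"]):
    """Ordered [(contig_id, orientation, edge_to_next | None)] starting at a
    terminal contig (degree 1)."""
    start_end = "R" if (terminal, "R") in edges else "L"
    orient = "+" if start_end == "R" else "-"
    path = []
    cid = terminal
    while True:
        out_end = "R" if orient == "+" else "L"
        edge = edges.get((cid, out_end))
        path.append((cid, orient, edge))
        if edge is None:
            break
        cid = edge.nxt
        orient = "+" if edge.nxt_end == "L" else "-"
    return path


def _cycle_members(start: str, edges: dict) -> list[str]:
    members = [start]
    prev, cur = None, start
    while True:
        nxt = None
        for e in ("L", "R"):
            edge = edges.get((cur, e))
            if edge is not None and edge.nxt != prev:
                nxt = edge.nxt
                break
        if nxt is None or nxt == start:
            break
        members.append(nxt)
        prev, cur = cur, nxt
        if len(members) > len(edges) + 1:
            break
    return members


def _merge_path(path, by_id, primary_ids):
    """Splice a walked path into one sequence; returns (record, bases
    removed at junctions, [(contig_id, orientation)])."""
    seq_parts: list[str] = []
    blocks: list[tuple[str, int, int, str]] = []
    parts: list[tuple[str, str]] = []
    removed = 0
    resume = 0  # oriented start within current contig
    for cid, orient, edge in path:
        rec = by_id[cid]
        L = len(rec)
        oriented = rec.seq if orient == "+" else reverse_complement(rec.seq)
        parts.append((cid, orient))
        if edge is None:
            cut = L
            nxt_resume = 0
        else:
            nxt_id = edge.nxt
            nxt_rec = by_id[nxt_id]
            nL = len(nxt_rec)
            nxt_orient = "+" if edge.nxt_end == "L" else "-"
            # pick splice anchor per donor policy: keep the primary side's
            # bases across the overlap
            cur_primary = cid in primary_ids
            nxt_primary = nxt_id in primary_ids
            cands = []
            for p_cur, p_nxt in edge.anchors:
                cur_cut = p_cur + edge.k if orient == "+" else L - p_cur
                n_res = p_nxt + edge.k if nxt_orient == "+" else nL - p_nxt
                cands.append((cur_cut, n_res))
            if cur_primary and not nxt_primary:
                cut, nxt_resume = max(cands, key=lambda t: t[0])
            elif nxt_primary and not cur_primary:
                cut, nxt_resume = min(cands, key=lambda t: t[1])
            else:
                cut, nxt_resume = max(cands, key=lambda t: t[0])
        piece_start = min(resume, cut)
        seq_parts.append(oriented[piece_start:cut])
        if cut > piece_start:
            if orient == "+":
                blocks.append((cid, piece_start, cut, "+"))
            else:
                blocks.append((cid, L - cut, L - piece_start, "-"))
        if edge is not None:
            removed += (L - cut) + nxt_resume
        resume = nxt_resume if edge is not None else 0
        if edge is None:
            break
    seq = "".join(seq_parts)
    # canonical orientation: the lexicographically smaller terminal contig
    # id leads, so unitigs are independent of traversal direction
    if parts and parts[-1][0] < parts[0][0]:
        seq = reverse_complement(seq)
        parts = [(cid, "-" if o == "+" else "+") for cid, o in reversed(parts)]
        blocks = [(src, s0, e0, "-" if st == "+" else "+")
                  for src, s0, e0, st in reversed(blocks)]
    merged = SequenceRecord("unitig", seq, source_intervals=blocks)
    return merged, removed, parts
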