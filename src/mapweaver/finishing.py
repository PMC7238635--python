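"""Iterative long-read gap filling, telomere extension, marker filtering,
genetic-map scaffold ordering, and pseudomolecule emission.

Read anchoring is internal and alignment-free: reads and scaffolds are
both sampled with the same hash-mod k-mer rule (a k-mer is kept when its
hash is 0 mod the sampling modulus), so exact shared k-mers are found
regardless of relative offset.  "Uniquely mapped" means a read's anchors
form a single cluster against globally unique scaffold k-mers — a
deliberate stand-in for aligner MAPQ.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AGPRecord,
    MapweaverError,
    SequenceRecord,
    find_n_gaps,
    reverse_complement,
)
from .kmers import kmer_keys

_MOD = 32  # hash-mod sampling modulus


def _mod_sampled(seq: str, k: int):
    """(h1, h2, pos) for k-mers passing the hash-mod sampling rule."""
    h1, h2, valid = kmer_keys(seq, k)
    keep = valid & (h1 % np.uint64(_MOD) == 0)
    pos = np.flatnonzero(keep)
    return h1[pos], h2[pos], pos


class ScaffoldAnchorIndex:
    """Hash-mod sampled k-mer index over a scaffold set, restricted to
    k-mers occurring exactly once (globally unique anchors)."""

    def __init__(self, scaffolds: list[SequenceRecord], k: int = 21):
        self.k = k
        self.ids = [s.id for s in scaffolds]
        h1s, h2s, sidx, poss = [], [], [], []
        for i, s in enumerate(scaffolds):
            if len(s) < k:
                continue
            h1, h2, pos = _mod_sampled(s.seq, k)
            h1s.append(h1)
            h2s.append(h2)
            sidx.append(np.full(pos.size, i, dtype=np.int32))
            poss.append(pos)
        if not h1s:
            raise MapweaverError("no scaffold long enough to index")
        h1 = np.concatenate(h1s)
        h2 = np.concatenate(h2s)
        sidx = np.concatenate(sidx)
        pos = np.concatenate(poss)
        order = np.lexsort((h2, h1))
        h1, h2, sidx, pos = h1[order], h2[order], sidx[order], pos[order]
        new = np.empty(h1.size, dtype=bool)
        new[0] = True
        new[1:] = (h1[1:] != h1[:-1]) | (h2[1:] != h2[:-1])
        group = np.cumsum(new) - 1
        counts = np.bincount(group)
        uniq = counts[group] == 1
        self.h1, self.h2 = h1[uniq], h2[uniq]
        self.sidx, self.pos = sidx[uniq], pos[uniq]

    def match(self, h1: np.ndarray, h2: np.ndarray, qpos: np.ndarray):
        """Match query keys; returns (q_pos, scaffold_idx, s_pos)."""
        if h1.size == 0:
            return (np.empty(0, np.int64),) * 3
        loc = np.searchsorted(self.h1, h1)
        loc = np.clip(loc, 0, self.h1.size - 1)
        hit = (self.h1[loc] == h1) & (self.h2[loc] == h2)
        return qpos[hit], self.sidx[loc[hit]].astype(np.int64), self.pos[loc[hit]]


@dataclass
class ReadAnchors:
    """One read's unique-anchor matches against the scaffold index, per
    strand, grouped into diagonal clusters."""

    read_id: str
    clusters: list[dict]  # {scaffold, strand, q, s (arrays), matched_bases}


def anchor_reads(reads: list[SequenceRecord], index: ScaffoldAnchorIndex,
                 min_matches: int = 3, cluster_slack: int = 2000,
                 key_cache: dict | None = None) -> list[ReadAnchors]:
    """Anchor every read against the scaffold index.

    ``key_cache`` (read_id, strand) -> (h1, h2, pos) memoises the read-side
    hashing, which dominates the cost when anchoring is repeated across
    gap-fill iterations and telomere extension.
    """
    k = index.k
    out = []
    for read in reads:
        if len(read) < k:
            continue
        clusters = []
        for strand in ("+", "-"):
            ck = (read.id, strand)
            if key_cache is not None and ck in key_cache:
                h1, h2, pos = key_cache[ck]
            else:
                seq = read.seq if strand == "+" else reverse_complement(read.seq)
                h1, h2, pos = _mod_sampled(seq, k)
                if key_cache is not None:
                    key_cache[ck] = (h1, h2, pos)
            q, sidx, spos = index.match(h1, h2, pos)
            if q.size < min_matches:
                continue
            # cluster by (scaffold, diagonal)
            diag = spos - q
            order = np.lexsort((diag, sidx))
            q, sidx, spos, diag = q[order], sidx[order], spos[order], diag[order]
            brk = np.flatnonzero((np.diff(sidx) != 0)
                                 | (np.abs(np.diff(diag)) > cluster_slack)) + 1
            for seg in np.split(np.arange(q.size), brk):
                if seg.size < min_matches:
                    continue
                clusters.append({
                    "scaffold": int(sidx[seg[0]]), "strand": strand,
                    "q": q[seg], "s": spos[seg],
                    "matched_bases": int(seg.size) * min(_MOD, k),
                })
        if clusters:
            out.append(ReadAnchors(read.id, clusters))
    return out


@dataclass
class GapFillReport:
    scaffold_id: str
    gap: tuple[int, int]
    action: str  # {closed, shrunk, unchanged}
    read_id: str = ""
    delta_n: int = 0  # N bases removed
    added_bases: int = 0  # non-N bases added


def fill_gaps(scaffolds: list[SequenceRecord], reads: list[SequenceRecord],
              n_iter: int = 3, anchor_len: int = 250,
              max_gap_delta: float = 2.0, k: int = 21,
              flank: int = 2000, min_residual: int = 13,
              max_extension: int = 5000,
              key_cache: dict | None = None
              ) -> tuple[list[SequenceRecord], list[GapFillReport]]:
    """Iterative gap filling by reads anchored to the gap flanks.

    A read anchored to both flanks (>= ``anchor_len`` estimated matched bp
    per flank, globally unique anchors) patches the gap with its interior
    when the implied span is within a factor ``max_gap_delta`` of the
    estimated gap size.  Reads anchored to one flank only shrink the gap
    by their extension, never closing it outright: at least
    ``min_residual`` Ns remain without a spanning read.
    """
    scaffolds = [SequenceRecord(s.id, s.seq, list(s.source_intervals))
                 for s in scaffolds]
    reports: list[GapFillReport] = []
    for _ in range(n_iter):
        index = ScaffoldAnchorIndex(scaffolds, k)
        anchors = anchor_reads(reads, index, key_cache=key_cache)
        by_read = {a.read_id: a for a in anchors}
        reads_by_id = {r.id: r for r in reads}
        changed = False
        for si, scaf in enumerate(scaffolds):
            gaps = find_n_gaps(scaf)
            if not gaps:
                continue
            edits = []  # (start, end, replacement, report)
            for gap in gaps:
                est = gap.length
                lf_lo = max(0, gap.start - flank)
                rf_hi = min(len(scaf), gap.end + flank)
                best = None  # (read_id, l_cut_s, l_cut_r, r_cut_s, r_cut_r, seq)
                best_left = None  # (ext_len, read_id, splice_s, tail_seq)
                best_right = None
                for ra in anchors:
                    for cl in ra.clusters:
                        if cl["scaffold"] != si:
                            continue
                        q, s = cl["q"], cl["s"]
                        in_l = (s >= lf_lo) & (s < gap.start - k + 1)
                        in_r = (s >= gap.end) & (s < rf_hi)
                        lm = int(in_l.sum()) * min(_MOD, k)
                        rm = int(in_r.sum()) * min(_MOD, k)
                        read = reads_by_id[ra.read_id]
                        seq = (read.seq if cl["strand"] == "+"
                               else reverse_complement(read.seq))
                        if lm >= anchor_len and rm >= anchor_len:
                            li = np.flatnonzero(in_l).max()
                            ri = np.flatnonzero(in_r).min()
                            # read span between the two splice anchors vs the
                            # scaffold's expectation (flank remainders + gap)
                            span = int(q[ri] - (q[li] + k))
                            expect = (gap.start - (int(s[li]) + k)) + est \
                                + (int(s[ri]) - gap.end)
                            lo_ok = span >= expect / max_gap_delta - 200
                            hi_ok = span <= expect * max_gap_delta + 200
                            if span >= 0 and lo_ok and hi_ok:
                                cand = (ra.read_id, int(s[li]) + k, int(q[li]) + k,
                                        int(s[ri]), int(q[ri]), seq)
                                if best is None or len(seq) > len(best[5]):
                                    best = cand
                        elif lm >= anchor_len:
                            li = np.flatnonzero(in_l).max()
                            ext = len(seq) - (int(q[li]) + k)
                            avail = gap.start - (int(s[li]) + k)
                            ext_into_gap = ext - avail
                            if ext_into_gap > 50:
                                cand = (ext_into_gap, ra.read_id, int(s[li]) + k,
                                        seq[int(q[li]) + k:])
                                if best_left is None or cand[0] > best_left[0]:
                                    best_left = cand
                        elif rm >= anchor_len:
                            ri = np.flatnonzero(in_r).min()
                            ext = int(q[ri])
                            avail = int(s[ri]) - gap.end
                            ext_into_gap = ext - avail
                            if ext_into_gap > 50:
                                cand = (ext_into_gap, ra.read_id, int(s[ri]),
                                        seq[:int(q[ri])])
                                if best_right is None or cand[0] > best_right[0]:
                                    best_right = cand
                if best is not None:
                    rid, s_l, r_l, s_r, r_r, seq = best
                    replacement = seq[r_l:r_r]
                    rep = GapFillReport(scaf.id, (gap.start, gap.end), "closed",
                                        rid, delta_n=est,
                                        added_bases=len(replacement)
                                        - ((gap.start - s_l) + (s_r - gap.end)))
                    edits.append((s_l, s_r, replacement, rep))
                    continue
                new_start, new_end = gap.start, gap.end
                left_seq = right_seq = ""
                rid = ""
                if best_left is not None:
                    ext, rid_l, splice_s, tail = best_left
                    keep = min(len(tail), (gap.start - splice_s)
                               + min(gap.length - min_residual, max_extension))
                    left_seq = tail[:keep]
                    rid = rid_l
                    lstart = splice_s
                else:
                    lstart = gap.start
                if best_right is not None:
                    ext, rid_r, splice_s, head = best_right
                    room = min(gap.length - max(0, len(left_seq)
                                                - (gap.start - lstart))
                               - min_residual, max_extension)
                    keep = min(len(head), (splice_s - gap.end) + max(0, room))
                    right_seq = head[-keep:] if keep > 0 else ""
                    rid = (rid + "," + rid_r).strip(",")
                    rend = splice_s
                else:
                    rend = gap.end
                if left_seq or right_seq:
                    n_kept = (rend - lstart) - len(left_seq) - len(right_seq)
                    if n_kept < min_residual:
                        n_kept = min_residual
                    replacement = left_seq + "N" * n_kept + right_seq
                    delta = gap.length - n_kept
                    rep = GapFillReport(scaf.id, (gap.start, gap.end), "shrunk",
                                        rid, delta_n=delta,
                                        added_bases=len(left_seq) + len(right_seq)
                                        - ((gap.start - lstart) + (rend - gap.end)))
                    edits.append((lstart, rend, replacement, rep))
                else:
                    reports.append(GapFillReport(scaf.id, (gap.start, gap.end),
                                                 "unchanged"))
            if edits:
                changed = True
                new_seq = scaf.seq
                for s_l, s_r, replacement, rep in sorted(edits, reverse=True):
                    new_seq = new_seq[:s_l] + replacement + new_seq[s_r:]
                    reports.append(rep)
                scaffolds[si] = SequenceRecord(scaf.id, new_seq,
                                               scaf.source_intervals)
        if not changed:
            break
    return scaffolds, reports


def terminal_tract_length(seq: str, unit: str, end: str,
                          min_frac: float = 0.9) -> int:
    """Terminal tandem-tract length of ``unit``, over all phases.

    A terminal window qualifies while its per-base unit identity stays at
    or above ``min_frac``; the reported tract length is the number of
    *matching* bases inside the longest qualifying window, so random
    flanking sequence (which matches the unit ~25% of the time) cannot
    inflate a short tract past a length floor.

    ``end`` is '5' (prefix, unit read as its reverse complement — the
    C-rich CCCTAAA strand for telomeres) or '3' (suffix, TTTAGGG)."""
    u = unit if end == "3" else reverse_complement(unit)
    p = len(u)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    if end == "3":
        arr = arr[::-1]
        u = u[::-1]
    uarr = np.frombuffer(u.encode(), dtype=np.uint8)
    n = arr.size
    best = 0
    lengths = np.arange(1, n + 1)
    for phase in range(p):
        tiled = uarr[(np.arange(n) + phase) % p]
        match = (arr == tiled).astype(np.int64).cumsum()
        ok = np.flatnonzero(match >= min_frac * lengths)
        if ok.size:
            best = max(best, int(match[ok.max()]))
    return best


@dataclass
class TelomereReport:
    scaffold_id: str
    end: str  # {5, 3}
    read_id: str
    added_bases: int


def extend_telomeres(scaffolds: list[SequenceRecord],
                     reads: list[SequenceRecord],
                     min_tract: int = 1000, unit: str = "TTTAGGG",
                     anchor_len: int = 250, k: int = 21,
                     terminal_window: int = 30_000,
                     key_cache: dict | None = None
                     ) -> tuple[list[SequenceRecord], list[TelomereReport]]:
    """Extend scaffold ends with the longest uniquely anchored read
    carrying a terminal telomere tract of >= ``min_tract`` bp.

    Tract orientation must be telomere-consistent: CCCTAAA at 5' ends,
    TTTAGGG at 3' ends (in scaffold-forward coordinates).  Reads anchoring
    at more than one locus are excluded; interiors are never touched.
    """
    scaffolds = [SequenceRecord(s.id, s.seq, list(s.source_intervals))
                 for s in scaffolds]
    index = ScaffoldAnchorIndex(scaffolds, k)
    anchors = anchor_reads(reads, index, key_cache=key_cache)
    reads_by_id = {r.id: r for r in reads}
    reports: list[TelomereReport] = []
    # candidates[(scaffold_idx, end)] = (read_len, read_id, splice_s, segment)
    candidates: dict[tuple[int, str], tuple] = {}
    for ra in anchors:
        big = [c for c in ra.clusters if c["matched_bases"] >= anchor_len]
        if len(big) != 1:
            continue  # not uniquely mapped
        cl = big[0]
        si = cl["scaffold"]
        scaf = scaffolds[si]
        read = reads_by_id[ra.read_id]
        seq = read.seq if cl["strand"] == "+" else reverse_complement(read.seq)
        q, s = cl["q"], cl["s"]
        near5 = s < terminal_window
        near3 = s >= len(scaf) - terminal_window
        if near3.any():
            idx = int(np.flatnonzero(near3).max())
            ext = (len(seq) - (int(q[idx]) + k)) - (len(scaf) - (int(s[idx]) + k))
            if ext > 0:
                segment = seq[int(q[idx]) + k:]
                if terminal_tract_length(segment, unit, "3") >= min_tract:
                    key = (si, "3")
                    cand = (len(read), ra.read_id, int(s[idx]) + k, segment)
                    if key not in candidates or cand[0] > candidates[key][0]:
                        candidates[key] = cand
        if near5.any():
            idx = int(np.flatnonzero(near5).min())
            ext = int(q[idx]) - int(s[idx])
            if ext > 0:
                segment = seq[:int(q[idx])]
                if terminal_tract_length(segment, unit, "5") >= min_tract:
                    key = (si, "5")
                    cand = (len(read), ra.read_id, int(s[idx]), segment)
                    if key not in candidates or cand[0] > candidates[key][0]:
                        candidates[key] = cand
    for (si, end), (_, rid, splice, segment) in sorted(candidates.items()):
        scaf = scaffolds[si]
        if end == "3":
            new_seq = scaf.seq[:splice] + segment
            added = len(new_seq) - len(scaf)
        else:
            new_seq = segment + scaf.seq[splice:]
            added = len(new_seq) - len(scaf)
        if added <= 0:
            continue
        scaffolds[si] = SequenceRecord(scaf.id, new_seq, scaf.source_intervals)
        reports.append(TelomereReport(scaf.id, end, rid, added))
    return scaffolds, reports


def filter_markers(markers: pd.DataFrame, min_per_scaffold: int = 21,
                   cap: int = 100, min_mapq: int = 31) -> pd.DataFrame:
    """Marker filtering for pseudomolecule construction.

    Keeps uniquely mapped markers with mapq >= ``min_mapq`` (i.e. strictly
    greater than 30 at the default), drops scaffolds with fewer than
    ``min_per_scaffold`` survivors (strictly more than 20 at the default),
    and caps each scaffold at ``cap`` markers chosen evenly spaced by
    physical position (first and last always kept)."""
    df = markers[(markers["unique"].astype(bool)) & (markers["mapq"] >= min_mapq)]
    kept = []
    for sid, grp in df.groupby("scaffold_id", sort=True):
        if len(grp) < min_per_scaffold:
            continue
        grp = grp.sort_values("physical_bp", kind="mergesort")
        if len(grp) > cap:
            idx = np.unique(np.round(np.linspace(0, len(grp) - 1, cap)).astype(int))
            grp = grp.iloc[idx]
        kept.append(grp)
    if not kept:
        return df.iloc[0:0]
    return pd.concat(kept, ignore_index=True)


def _rank(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=np.int64)
    ranks[order] = np.arange(values.size)
    return ranks


def _arrangement_objective(arrangement: list[tuple[str, str]],
                           per_source: dict) -> float:
    """Weighted sum over sources of |Spearman rho| between genetic rank and
    assembled physical rank (ordinal ranks; deterministic tie-break)."""
    total = 0.0
    signed_total = 0.0
    for src, (weight, per_scaf) in per_source.items():
        g_ranks = []
        for sid, orient in arrangement:
            entry = per_scaf.get(sid)
            if entry is None:
                continue
            g = entry["granks"]
            g_ranks.append(g if orient == "+" else g[::-1])
        if not g_ranks:
            continue
        g = np.concatenate(g_ranks)
        n = g.size
        if n < 2:
            continue
        d = np.arange(n) - g
        rho = 1.0 - 6.0 * float((d * d).sum()) / (n * (n * n - 1))
        total += weight * abs(rho)
        signed_total += weight * rho
    return total, signed_total


def order_orient(markers: pd.DataFrame,
                 weights: dict[str, float] | None = None,
                 exhaustive_max: int = 8,
                 seed: int = 0) -> dict[str, list[tuple[str, str]]]:
    """Order and orient scaffolds within each linkage group to maximise the
    weighted |Spearman| rank concordance between genetic and physical order.

    Groups of up to ``exhaustive_max`` scaffolds are solved by exhaustive
    search over orders x orientations; larger groups by greedy insertion
    followed by 2-opt segment reversals and single flips to a local
    optimum.  The arrangement's global direction is canonicalised so the
    signed concordance is non-negative.  Deterministic given the input.
    """
    if "source" not in markers.columns:
        markers = markers.assign(source="default")
    if markers.empty:
        raise MapweaverError("order_orient: empty marker table")
    weights = weights or {}
    out: dict[str, list[tuple[str, str]]] = {}
    for lg, grp in markers.groupby("linkage_group", sort=True):
        scaffolds = sorted(grp["scaffold_id"].unique())
        per_source: dict[str, tuple[float, dict]] = {}
        for src, sgrp in grp.groupby("source", sort=True):
            sgrp = sgrp.sort_values(["scaffold_id", "physical_bp"], kind="mergesort")
            granks_all = _rank(sgrp["genetic_pos"].to_numpy())
            per_scaf = {}
            for sid in scaffolds:
                mask = (sgrp["scaffold_id"] == sid).to_numpy()
                if mask.any():
                    per_scaf[sid] = {"granks": granks_all[mask]}
            per_source[src] = (weights.get(src, 1.0), per_scaf)
        if len(scaffolds) <= exhaustive_max:
            best = _exhaustive(scaffolds, per_source)
        else:
            best = _heuristic(scaffolds, per_source)
        obj, signed = _arrangement_objective(best, per_source)
        if signed < 0:
            best = [(sid, "-" if o == "+" else "+") for sid, o in reversed(best)]
        out[str(lg)] = best
    return out


def _exhaustive(scaffolds, per_source):
    """Exact search over orders x orientations.

    Uses the decomposition sum((offset + w - g)^2) = A + 2*offset*B +
    m*offset^2 per (scaffold, orientation, source), so every orientation
    vector of a permutation is scored with vectorised arithmetic.
    """
    from itertools import permutations

    n = len(scaffolds)
    srcs = list(per_source)
    stats = {}  # (src, sid) -> (A+, B+, A-, B-, m)
    n_tot = {}
    for src in srcs:
        _, per_scaf = per_source[src]
        tot = 0
        for sid in scaffolds:
            e = per_scaf.get(sid)
            if e is None:
                stats[(src, sid)] = (0.0, 0.0, 0.0, 0.0, 0)
                continue
            g = e["granks"].astype(np.float64)
            m = g.size
            w = np.arange(m, dtype=np.float64)
            dp = w - g
            dm = (m - 1 - w) - g
            stats[(src, sid)] = (float((dp * dp).sum()), float(dp.sum()),
                                 float((dm * dm).sum()), float(dm.sum()), m)
            tot += m
        n_tot[src] = tot
    masks = np.arange(1 << n)
    bits = [(masks >> i) & 1 for i in range(n)]
    best_perm, best_mask, best_obj = None, 0, -np.inf
    for perm in permutations(scaffolds):
        obj = np.zeros(1 << n)
        for src in srcs:
            weight, _ = per_source[src]
            ntot = n_tot[src]
            if ntot < 2:
                continue
            D = np.zeros(1 << n)
            off = 0
            for slot, sid in enumerate(perm):
                Ap, Bp, Am, Bm, m = stats[(src, sid)]
                if m == 0:
                    continue
                dplus = Ap + 2.0 * off * Bp + m * off * off
                dminus = Am + 2.0 * off * Bm + m * off * off
                D += np.where(bits[slot] == 1, dminus, dplus)
                off += m
            rho = 1.0 - 6.0 * D / (ntot * (ntot * ntot - 1))
            obj += weight * np.abs(rho)
        mi = int(obj.argmax())
        if obj[mi] > best_obj + 1e-12:
            best_obj = float(obj[mi])
            best_perm, best_mask = perm, mi
    return [(sid, "-" if (best_mask >> i) & 1 else "+")
            for i, sid in enumerate(best_perm)]


def _heuristic(scaffolds, per_source):
    # greedy insertion in order of median genetic position
    med = {}
    for sid in scaffolds:
        vals = []
        for _, (_, per_scaf) in per_source.items():
            e = per_scaf.get(sid)
            if e is not None:
                vals.extend(e["granks"].tolist())
        med[sid] = float(np.median(vals)) if vals else 0.0
    order = sorted(scaffolds, key=lambda s: (med[s], s))
    arr: list[tuple[str, str]] = []
    for sid in order:
        best, best_obj = None, -1.0
        for pos in range(len(arr) + 1):
            for o in "+-":
                cand = arr[:pos] + [(sid, o)] + arr[pos:]
                obj, _ = _arrangement_objective(cand, per_source)
                if obj > best_obj + 1e-12:
                    best_obj, best = obj, cand
        arr = best
    improved = True
    cur_obj, _ = _arrangement_objective(arr, per_source)
    while improved:
        improved = False
        n = len(arr)
        for i in range(n):
            for j in range(i + 1, n + 1):
                seg = [(s, "-" if o == "+" else "+") for s, o in reversed(arr[i:j])]
                cand = arr[:i] + seg + arr[j:]
                obj, _ = _arrangement_objective(cand, per_source)
                if obj > cur_obj + 1e-12:
                    arr, cur_obj, improved = cand, obj, True
        for i in range(n):
            s, o = arr[i]
            cand = arr[:i] + [(s, "-" if o == "+" else "+")] + arr[i + 1:]
            obj, _ = _arrangement_objective(cand, per_source)
            if obj > cur_obj + 1e-12:
                arr, cur_obj, improved = cand, obj, True
    return arr


def emit_pseudomolecules(ordering: dict[str, list[tuple[str, str]]],
                         scaffolds: list[SequenceRecord],
                         inter_gap: int = 100,
                         name_prefix: str = "chr"
                         ) -> tuple[list[SequenceRecord], list[AGPRecord]]:
    """Concatenate ordered, oriented scaffolds into pseudomolecules with
    ``inter_gap`` Ns between neighbours; AGP gap kind is ``scaffold``.
    AGP plus the scaffold sequences reconstruct the FASTA exactly."""
    if not ordering or all(not v for v in ordering.values()):
        raise MapweaverError("emit_pseudomolecules: empty ordering")
    by_id = {s.id: s for s in scaffolds}
    records: list[SequenceRecord] = []
    agp: list[AGPRecord] = []
    for lg in sorted(ordering):
        arrangement = ordering[lg]
        if not arrangement:
            raise MapweaverError(f"emit_pseudomolecules: empty group {lg!r}")
        name = f"{name_prefix}{lg}"
        parts = []
        blocks = []
        pos = 1
        pn = 1
        for i, (sid, orient) in enumerate(arrangement):
            rec = by_id[sid]
            seq = rec.seq if orient == "+" else reverse_complement(rec.seq)
            parts.append(seq)
            blocks.append((sid, 0, len(rec), orient))
            agp.append(AGPRecord(name, pos, pos + len(rec) - 1, pn, "W",
                                 component_id=sid, component_start=1,
                                 component_end=len(rec), orientation=orient))
            pos += len(rec)
            pn += 1
            if i < len(arrangement) - 1:
                parts.append("N" * inter_gap)
                blocks.append(("gap:scaffold", 0, inter_gap, "+"))
                agp.append(AGPRecord(name, pos, pos + inter_gap - 1, pn, "U",
                                     gap_length=inter_gap, gap_kind="scaffold"))
                pos += inter_gap
                pn += 1
        records.append(SequenceRecord(name, "".join(parts), blocks))
    return records, agp


def reconstruct_from_agp(agp: list[AGPRecord],
                         components: dict[str, SequenceRecord]) -> list[SequenceRecord]:
    """Rebuild object sequences from AGP rows plus component sequences."""
    by_obj: dict[str, list[AGPRecord]] = {}
    for r in agp:
        by_obj.setdefault(r.object_id, []).append(r)
    out = []
    for obj in by_obj:
        rows = sorted(by_obj[obj], key=lambda r: r.part_number)
        parts = []
        for r in rows:
            if r.is_gap:
                parts.append("N" * r.gap_length)
            else:
                seq = components[r.component_id].seq[r.component_start - 1:r.component_end]
                if r.orientation == "-":
                    seq = reverse_complement(seq)
                parts.append(seq)
        out.append(SequenceRecord(obj, "".join(parts)))
    return out
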