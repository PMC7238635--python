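"""Satellite-array, centromere, mappability, enrichment and co-occurrence
analyses.

Definitions follow the conventions of maize repeat biology: knobs are
repeat clusters of at least 500 kb that are at least 10% knob180/TR-1
consensus with no more than 100 kb between repeat units (subtelomeric
knob180 arrays excluded); CentC arrays are the 100-kb analogue; the
effective genome size is the fraction of unique 150-mers; functional
centromeres are broad ChIP enrichment islands with score above 250 and
fold change above 4 at 5-kb bins.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

import edlib

from .core import FeatureInterval, MapweaverError, SequenceRecord, reverse_complement
from .kmers import kmer_keys, unique_kmer_fraction


@dataclass
class RepeatHit:
    """A block of consecutive monomer units of one repeat family."""

    seq_id: str
    start: int
    end: int
    family: str
    identity: float  # mean unit identity
    units: int
    strand: str = "+"


@dataclass
class RepeatArray:
    seq_id: str
    start: int
    end: int
    family: str
    density: float  # repeat bp / span
    units: int

    @property
    def span(self) -> int:
        return self.end - self.start


def _seed_regions(genome_seq: str, consensus: str, seed_k: int = 12,
                  merge_gap: int = 2000) -> list[tuple[int, int]]:
    """Candidate regions sharing an exact seed k-mer with the consensus
    (either strand), merged."""
    cons_keys = set()
    for s in (consensus, reverse_complement(consensus)):
        if len(s) < seed_k:
            continue
        h1, h2, valid = kmer_keys(s, seed_k)
        for a, b in zip(h1[valid].tolist(), h2[valid].tolist()):
            cons_keys.add((a, b))
    if not cons_keys or len(genome_seq) < seed_k:
        return []
    h1, h2, valid = kmer_keys(genome_seq, seed_k)
    # membership via sorted arrays
    ck = np.array(sorted(cons_keys), dtype=np.uint64)
    ck1, ck2 = ck[:, 0], ck[:, 1]
    order = np.lexsort((ck2, ck1))
    ck1, ck2 = ck1[order], ck2[order]
    loc = np.searchsorted(ck1, h1)
    hits = np.zeros(h1.size, dtype=bool)
    inb = loc < ck1.size
    cand = np.flatnonzero(inb & valid)
    # scan forward over equal-h1 runs
    for i in cand:
        j = loc[i]
        while j < ck1.size and ck1[j] == h1[i]:
            if ck2[j] == h2[i]:
                hits[i] = True
                break
            j += 1
    pos = np.flatnonzero(hits)
    if pos.size == 0:
        return []
    regions = []
    start = prev = int(pos[0])
    for p in pos[1:].tolist():
        if p - prev > merge_gap:
            regions.append((start, prev + seed_k))
            start = p
        prev = p
    regions.append((start, prev + seed_k))
    return regions


def scan_repeat_monomers(genome: list[SequenceRecord],
                         consensus: SequenceRecord,
                         min_identity: float = 0.7,
                         family: str | None = None) -> list[RepeatHit]:
    """Non-overlapping monomer units of a consensus across a genome.

    Seed k-mers locate candidate regions; within each region the consensus
    is tiled greedily by infix (local) alignment, accepting units at
    >= ``min_identity``.  Adjacent units (gap below one monomer length)
    merge into hit blocks carrying unit counts and mean identity.
    """
    if len(consensus) < 50:
        raise MapweaverError("consensus must be >= 50 bp")
    family = family or consensus.id
    L = len(consensus)
    out: list[RepeatHit] = []
    for rec in genome:
        for r_start, r_end in _seed_regions(rec.seq, consensus.seq):
            lo = max(0, r_start - L)
            hi = min(len(rec), r_end + L)
            units: list[tuple[int, int, float, str]] = []
            pos = lo

            def best_in(window: str):
                best = None
                for strand, cons in (("+", consensus.seq),
                                     ("-", reverse_complement(consensus.seq))):
                    res = edlib.align(cons, window, mode="HW", task="locations")
                    if res["editDistance"] < 0:
                        continue
                    ident = 1.0 - res["editDistance"] / L
                    if best is None or ident > best[0]:
                        locs = res["locations"][0]
                        best = (ident, locs[0], locs[1] + 1, strand)
                return best

            while pos < hi - L // 2:
                window = rec.seq[pos:min(hi, pos + int(1.7 * L))]
                if len(window) < L // 2:
                    break
                best = best_in(window)
                if best is not None and best[1] > 0.6 * L:
                    # the window's best copy is the *next* unit; give the
                    # skipped prefix its own chance before jumping ahead
                    prefix = rec.seq[pos:pos + best[1] + 20]
                    pbest = best_in(prefix)
                    if pbest is not None and pbest[0] >= min_identity:
                        best = pbest
                if best is not None and best[0] >= min_identity:
                    ident, w_lo, w_hi, strand = best
                    units.append((pos + w_lo, pos + w_hi, ident, strand))
                    pos = pos + w_hi
                else:
                    pos += max(L // 2, 25)
            # merge consecutive units into blocks
            i = 0
            while i < len(units):
                j = i
                while (j + 1 < len(units)
                       and units[j + 1][0] - units[j][1] < L):
                    j += 1
                block = units[i:j + 1]
                out.append(RepeatHit(
                    rec.id, block[0][0], block[-1][1], family,
                    identity=float(np.mean([u[2] for u in block])),
                    units=len(block),
                    strand=block[0][3]))
                i = j + 1
    out.sort(key=lambda h: (h.seq_id, h.start))
    return out


def call_repeat_arrays(hits: list[RepeatHit], family_class: str,
                       knob_span: int = 500_000, centc_span: int = 100_000,
                       min_density: float = 0.10, max_spacing: int = 100_000,
                       subtelomeric_windows: list[FeatureInterval] | None = None
                       ) -> list[RepeatArray]:
    """Cluster monomer hit blocks into arrays and apply class thresholds.

    Single-linkage clustering joins blocks separated by at most
    ``max_spacing``.  A cluster qualifies when its span reaches the class
    minimum (500 kb for knobs, 100 kb for CentC) *and* its repeat density
    reaches ``min_density``.  Knob calls overlapping a configured
    subtelomeric window are dropped (subtelomeric knob180 arrays are not
    knobs).
    """
    if family_class not in ("knob", "centc"):
        raise MapweaverError("family_class must be 'knob' or 'centc'")
    min_span = knob_span if family_class == "knob" else centc_span
    subtel = subtelomeric_windows or []
    arrays: list[RepeatArray] = []
    by_seq: dict[str, list[RepeatHit]] = {}
    for h in sorted(hits, key=lambda h: (h.seq_id, h.start)):
        by_seq.setdefault(h.seq_id, []).append(h)
    for seq_id, hs in by_seq.items():
        cluster: list[RepeatHit] = []
        for h in hs + [None]:
            if h is not None and (not cluster or h.start - cluster[-1].end <= max_spacing):
                cluster.append(h)
                continue
            if cluster:
                start, end = cluster[0].start, cluster[-1].end
                span = end - start
                repeat_bp = sum(c.end - c.start for c in cluster)
                density = repeat_bp / span
                units = sum(c.units for c in cluster)
                ok = span >= min_span and density >= min_density
                if ok and family_class == "knob":
                    for w in subtel:
                        if w.seq_id == seq_id and start < w.end and end > w.start:
                            ok = False
                            break
                if ok:
                    arrays.append(RepeatArray(seq_id, start, end,
                                              cluster[0].family, density, units))
            cluster = [h] if h is not None else []
    return arrays


def effective_genome_fraction(genome: list[SequenceRecord], k: int = 150) -> float:
    """Fraction of k-mer positions whose canonical (strand-folded), N-free
    k-mer occurs exactly once genome-wide."""
    seqs = [r.seq for r in genome if len(r) >= k]
    if not seqs:
        raise MapweaverError(f"all sequences shorter than k={k}")
    return unique_kmer_fraction(seqs, k)


def _bin_track(track: np.ndarray, bin_size: int) -> np.ndarray:
    n_bins = math.ceil(track.size / bin_size)
    padded = np.zeros(n_bins * bin_size, dtype=np.float64)
    padded[:track.size] = track
    return padded.reshape(n_bins, bin_size).sum(axis=1)


def call_cenh3_domains(chip_cov: dict[str, np.ndarray],
                       input_cov: dict[str, np.ndarray],
                       bin_size: int = 5000, gap_bins: int = 0,
                       min_score: float = 250.0, min_fc: float = 4.0,
                       effective_fraction: float = 1.0,
                       bin_p: float = 0.01) -> list[FeatureInterval]:
    """Broad ChIP enrichment islands (CENH3 centromere calling).

    Per bin, a Poisson upper-tail -log10 p of the ChIP signal given an
    input-scaled background; the background floor is the genome-average
    ChIP rate divided by the effective (unique) genome fraction, so
    repeat-driven mappability loss does not create spurious enrichment.
    Significant bins (p < ``bin_p``) merge across at most ``gap_bins``
    non-significant bins; an island's score is the sum of its bin scores.
    Kept islands need score > ``min_score`` and a depth-normalised
    ChIP/input fold change > ``min_fc``.
    """
    from scipy.stats import poisson

    chip_total = sum(float(t.sum()) for t in chip_cov.values())
    input_total = sum(float(t.sum()) for t in input_cov.values())
    if input_total <= 0:
        raise MapweaverError("zero-depth input track")
    genome_len = sum(t.size for t in chip_cov.values())
    lam_floor = chip_total * bin_size / (genome_len * max(effective_fraction, 1e-9))
    ratio = chip_total / input_total
    islands: list[FeatureInterval] = []
    for seq_id, chip in chip_cov.items():
        inp = input_cov[seq_id]
        cb = _bin_track(chip, bin_size)
        ib = _bin_track(inp, bin_size)
        lam = np.maximum(ib * ratio, lam_floor)
        # counts normalised per-bp coverage sums; treat as Poisson intensity
        logp = np.maximum(poisson.logsf(np.round(cb) - 1, lam), -2.3e6)
        score = -logp / math.log(10)  # capped at 1e6 per bin
        sig = np.exp(logp) < bin_p
        # merge significant bins across <= gap_bins gaps
        i = 0
        n = sig.size
        while i < n:
            if not sig[i]:
                i += 1
                continue
            j = i
            last_sig = i
            while j + 1 < n:
                if sig[j + 1]:
                    j += 1
                    last_sig = j
                elif j + 1 - last_sig <= gap_bins and any(
                        sig[j + 1:j + 2 + gap_bins]):
                    j += 1
                else:
                    break
            lo_bin, hi_bin = i, last_sig
            island_score = float(score[lo_bin:hi_bin + 1].sum())
            chip_sum = float(cb[lo_bin:hi_bin + 1].sum())
            inp_sum = float(ib[lo_bin:hi_bin + 1].sum())
            denom = inp_sum * ratio
            if denom <= 0:
                denom = lam_floor * (hi_bin - lo_bin + 1)
            fc = chip_sum / denom if denom > 0 else math.inf
            if island_score > min_score and fc > min_fc:
                islands.append(FeatureInterval(
                    seq_id, lo_bin * bin_size,
                    min((hi_bin + 1) * bin_size, chip.size),
                    "CENH3_island", score=island_score))
            i = hi_bin + 1
    return islands


def mappability_classes(self_coverage: dict[str, np.ndarray],
                        low: int = 2, high: int = 101,
                        merge_gap: int = 1000
                        ) -> tuple[list[FeatureInterval], list[FeatureInterval]]:
    """Split the genome into uniquely and non-uniquely mappable intervals.

    Positions with self-alignment depth <= ``low`` or >= ``high`` are
    non-unique; non-unique runs within ``merge_gap`` bp merge into
    islands; the complement is unique.
    """
    unique_iv: list[FeatureInterval] = []
    nonunique_iv: list[FeatureInterval] = []
    for seq_id, depth in self_coverage.items():
        bad = (depth <= low) | (depth >= high)
        runs = _runs(bad)
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] <= merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        prev = 0
        for s, e in merged:
            nonunique_iv.append(FeatureInterval(seq_id, s, e, "non_unique"))
            if s > prev:
                unique_iv.append(FeatureInterval(seq_id, prev, s, "unique"))
            prev = e
        if prev < depth.size:
            unique_iv.append(FeatureInterval(seq_id, prev, depth.size, "unique"))
    return unique_iv, nonunique_iv


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def low_coverage_regions(depth: dict[str, np.ndarray],
                         min_reads: int) -> list[FeatureInterval]:
    """Maximal runs with read depth strictly below ``min_reads``."""
    out = []
    for seq_id, track in depth.items():
        for s, e in _runs(track < min_reads):
            out.append(FeatureInterval(seq_id, s, e, f"lt{min_reads}"))
    return out


def rpkm_enrichment(chip_counts: dict[str, float], input_counts: dict[str, float],
                    feature_lengths: dict[str, int],
                    chip_total: float, input_total: float
                    ) -> dict[str, float | None]:
    """Per-feature ratio of ChIP RPKM to input RPKM.

    RPKM = reads per kb of feature per million mapped reads, so the ratio
    is exactly depth-normalised: scaling either track's depth leaves it
    unchanged.  Features with zero input reads report ``None`` rather than
    infinity.
    """
    if chip_total <= 0 or input_total <= 0:
        raise MapweaverError("total mapped counts must be positive")
    out: dict[str, float | None] = {}
    for feat, ln in feature_lengths.items():
        c = chip_counts.get(feat, 0.0)
        i = input_counts.get(feat, 0.0)
        if i <= 0:
            out[feat] = None
            continue
        rpkm_c = c / (ln / 1000.0) / (chip_total / 1e6)
        rpkm_i = i / (ln / 1000.0) / (input_total / 1e6)
        out[feat] = rpkm_c / rpkm_i
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float | None, float]:
    """Two-sided Fisher's exact test on [[a, b], [c, d]].

    Small tables (N <= 2000) use exact integer-binomial tail summation —
    every table with the same margins and probability not exceeding the
    observed one contributes, compared in exact arithmetic.  Larger tables
    defer to scipy.  The odds ratio is the sample ratio ad/bc, ``None``
    when undefined (zero denominator).
    """
    n = a + b + c + d
    odds: float | None
    if b * c == 0:
        odds = None if a * d == 0 else math.inf
    else:
        odds = (a * d) / (b * c)
    if n == 0:
        return odds, 1.0
    if n > 2000:
        from scipy.stats import fisher_exact

        return odds, float(fisher_exact([[a, b], [c, d]])[1])
    r1, r2 = a + b, c + d
    c1 = a + c
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    num = 0
    tot = 0
    for x in range(lo, hi + 1):
        w = math.comb(r1, x) * math.comb(r2, c1 - x)
        tot += w
        if w <= obs:
            num += w
    return odds, float(Fraction(num, tot))


def interval_cooccurrence_fisher(set_a: list[FeatureInterval],
                                 set_b: list[FeatureInterval],
                                 genome_lengths: dict[str, int],
                                 flank: int = 500_000
                                 ) -> tuple[float | None, float]:
    """Association between two interval sets over genome bp.

    Set A intervals are expanded by ``flank`` on both sides (clipped to
    the sequence), then every genome bp is classified in/out of expanded-A
    x in/out of B; a two-sided Fisher's exact test on the 2x2 bp table
    gives the p-value, and the sample odds ratio is reported (``None``
    when a zero cell makes it undefined/unbounded).
    """
    masks_a = {sid: np.zeros(ln, dtype=bool) for sid, ln in genome_lengths.items()}
    masks_b = {sid: np.zeros(ln, dtype=bool) for sid, ln in genome_lengths.items()}
    for iv in set_a:
        if iv.seq_id not in masks_a:
            raise MapweaverError(f"interval on unknown sequence {iv.seq_id!r}")
        ln = genome_lengths[iv.seq_id]
        masks_a[iv.seq_id][max(0, iv.start - flank):min(ln, iv.end + flank)] = True
    for iv in set_b:
        if iv.seq_id not in masks_b:
            raise MapweaverError(f"interval on unknown sequence {iv.seq_id!r}")
        masks_b[iv.seq_id][iv.start:iv.end] = True
    a = b = c = d = 0
    for sid in genome_lengths:
        ma, mb = masks_a[sid], masks_b[sid]
        a += int((ma & mb).sum())
        b += int((ma & ~mb).sum())
        c += int((~ma & mb).sum())
        d += int((~ma & ~mb).sum())
    return fisher_exact_2x2(a, b, c, d)


def repeat_composition(arrays: list[RepeatArray],
                       annotations: list[FeatureInterval]
                       ) -> dict[tuple[str, int, int], dict[str, float]]:
    """Per-array fraction of span covered by each annotation family.

    Overlapping annotations of one family are flattened (each bp counted
    once per family), so a family's fraction never exceeds 1.
    """
    by_seq: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for ann in annotations:
        by_seq.setdefault(ann.seq_id, {}).setdefault(ann.label, []).append(
            (ann.start, ann.end))
    out: dict[tuple[str, int, int], dict[str, float]] = {}
    for arr in arrays:
        fams: dict[str, float] = {}
        for fam, ivs in by_seq.get(arr.seq_id, {}).items():
            clipped = [(max(s, arr.start), min(e, arr.end)) for s, e in ivs]
            clipped = [(s, e) for s, e in clipped if e > s]
            if not clipped:
                continue
            clipped.sort()
            covered = 0
            cur_s, cur_e = clipped[0]
            for s, e in clipped[1:]:
                if s > cur_e:
                    covered += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            covered += cur_e - cur_s
            fams[fam] = covered / arr.span
        out[(arr.seq_id, arr.start, arr.end)] = fams
    return out
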