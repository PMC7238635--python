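"""Synthetic-data generator: a truth-annotated repeat-rich genome and every
derived input the pipeline consumes.

The genome emulates a maize-like chromosome architecture at desk scale:
telomere tracts (TTTAGGG) at both ends, subtelomeric repeat blocks, one
CentC (156-bp monomer) centromeric array per chromosome, knob180 (180 bp)
and TR-1 (~360 bp) knob arrays, all interspersed with labelled
retroelement-like insertions, a unique single-copy background, and one
heterozygous region with a separately emitted alternate haplotype.  Array
spans are scaled down ~100x from their megabase-scale real counterparts so
the whole bundle runs in minutes while preserving the threshold topology
(which arrays break which assembly profile).

Two assembly profiles reproduce the characteristic long-read failure
modes: the accurate-short profile breaks inside arrays longer than its
threshold, collapses designated tandem arrays and plants chimeric joins;
the long-noisy profile breaks only above a larger threshold and carries
more base errors.  Optical maps get sqrt-length sizing noise, missed and
false labels.  Everything is byte-reproducible from (config, seed).
"""
from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import FeatureInterval, MapweaverError, SequenceRecord, reverse_complement
from .optical import insilico_digest

MONOMER_LENGTHS = {
    "CentC": 156,
    "knob180": 180,
    "TR-1": 360,
    "telomere": 7,
    "rDNA-5S": 341,
    "rDNA-45S": 9349,
    "subtelomere": 502,
}

TE_FAMILIES = {
    "CinfulZeon-like": 5200,
    "CRM-like": 4600,
    "Gypsy-like": 6100,
    "Opie-like": 4100,
    "Prem1-like": 5500,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, n: int, forbid: str = "CTTAAG") -> str:
    seq = _BASES[rng.integers(0, 4, n)].tobytes().decode()
    # keep synthetic consensus sequences label-free so satellite arrays are
    # label-poor, as real satellite DNA typically is for a given motif
    while forbid and forbid in seq:
        seq = seq.replace(forbid, forbid[:3] + "C" + forbid[4:], 1)
    return seq


_CONSENSUS_CACHE: dict[str, str] = {}


def consensus_monomer(family: str) -> str:
    """Deterministic consensus for a repeat family.

    TR-1 is the bundled real consensus; telomere is TTTAGGG; other
    families are synthetic sequences generated once from the family name.
    """
    if family in _CONSENSUS_CACHE:
        return _CONSENSUS_CACHE[family]
    if family == "telomere":
        seq = "TTTAGGG"
    elif family == "TR-1":
        data = (importlib.resources.files("mapweaver") / "data" / "tr1_consensus.fasta")
        lines = data.read_text().splitlines()
        seq = "".join(l.strip() for l in lines if not l.startswith(">")).upper()
    else:
        n = MONOMER_LENGTHS.get(family) or TE_FAMILIES.get(family)
        if n is None:
            raise MapweaverError(f"unknown repeat family {family!r}")
        rng = np.random.default_rng([hash_name(family), 7])
        seq = _random_dna(rng, n)
    _CONSENSUS_CACHE[family] = seq
    return seq


def hash_name(name: str) -> int:
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2 ** 31)
    return h


@dataclass
class ArrayPlacement:
    family: str
    start: int
    span: int
    divergence: float = 0.08
    te_rate: float = 0.0  # probability of a TE insert after each unit
    collapse_frac: float = 0.0  # fraction the accurate profile collapses
    rc: bool = False  # build from the monomer's reverse complement
    # (the 5' chromosome end carries the C-rich telomere strand, CCCTAAA)

    @property
    def end(self) -> int:
        return self.start + self.span


@dataclass
class ChromPlan:
    name: str
    length: int
    arrays: list[ArrayPlacement] = field(default_factory=list)
    het_region: tuple[int, int] | None = None
    random_breaks_a: list[int] = field(default_factory=list)
    random_breaks_b: list[int] = field(default_factory=list)


@dataclass
class ProfileConfig:
    name: str
    break_over: int  # arrays longer than this break the profile
    edge_keep: int = 5000  # array bp retained at each side of a break
    end_trim: int = 2500  # chromosome-end bp the assembly misses
    sub_rate: float = 1e-4
    indel_rate: float = 0.0
    break_at_het: bool = False
    rc_every: int = 0  # reverse-complement every n-th contig (0 = never)


@dataclass
class ReadProfile:
    n50: float
    sigma: float = 0.55
    sub_rate: float = 0.01
    indel_rate: float = 0.0
    depth: float = 8.0
    min_len: int = 1000
    max_len: int = 60_000


@dataclass
class MapConfig:
    motif: str = "CTTAAG"
    min_label_spacing: int = 800
    sizing_sd_coeff: float = 3.0
    miss_rate: float = 0.05
    false_per_100kb: float = 0.5
    n_replicates: int = 2
    min_map_len: int = 150_000
    breaks: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class ChipConfig:
    fold: float = 8.0
    depth: float = 30.0
    read_len: int = 150


@dataclass
class MarkerConfig:
    per_group: int = 60
    noise_sd: float = 0.4  # cM
    frac_nonunique: float = 0.10
    frac_lowmapq: float = 0.05
    cm_per_mb: float = 4.0


@dataclass
class SimConfig:
    chromosomes: list[ChromPlan]
    profile_a: ProfileConfig
    profile_b: ProfileConfig
    maps: MapConfig = field(default_factory=MapConfig)
    reads_a: ReadProfile = field(default_factory=lambda: ReadProfile(n50=22_300,
                                                                     sub_rate=0.01,
                                                                     indel_rate=0.002))
    reads_b: ReadProfile = field(default_factory=lambda: ReadProfile(n50=29_311,
                                                                     sigma=0.6,
                                                                     sub_rate=0.02,
                                                                     indel_rate=0.01))
    chip: ChipConfig = field(default_factory=ChipConfig)
    markers: MarkerConfig = field(default_factory=MarkerConfig)
    # chimeric joins: ((chrom, array_idx, 'left'), (chrom, array_idx, 'right'))
    chimera_joins: list[tuple] = field(default_factory=list)
    cenh3_flank: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if self.profile_a.break_over >= self.profile_b.break_over:
            raise MapweaverError("profile A threshold must be below profile B's")
        for plan in self.chromosomes:
            for arr in plan.arrays:
                if arr.end > plan.length:
                    raise MapweaverError(
                        f"array {arr.family} overflows chromosome {plan.name}")


def default_config(seed: int = 0) -> SimConfig:
    """The default desk-scale bundle: 3 x 5 Mb chromosomes; two solvable
    chromosomes, one with an array exceeding both break thresholds (so it
    must retain a gap), two planted chimeras, one collapsed array, one
    heterozygous break."""
    tel = 4000
    sub = 10_000
    mk = lambda name, arrays, het=None, rba=(), rbb=(): ChromPlan(
        name, 5_000_000,
        arrays=[ArrayPlacement("telomere", 0, tel, 0.01, rc=True),
                ArrayPlacement("subtelomere", tel, sub, 0.05)]
        + arrays
        + [ArrayPlacement("subtelomere", 5_000_000 - tel - sub, sub, 0.05),
           ArrayPlacement("telomere", 5_000_000 - tel, tel, 0.01)],
        het_region=het, random_breaks_a=list(rba), random_breaks_b=list(rbb))
    chroms = [
        mk("chrA", [
            ArrayPlacement("knob180", 1_200_000, 25_000, 0.08, te_rate=0.06),
            ArrayPlacement("CentC", 2_500_000, 12_000, 0.08, te_rate=0.05,
                           collapse_frac=0.5),
            ArrayPlacement("TR-1", 3_600_000, 20_000, 0.08, te_rate=0.06),
        ], rba=[700_000, 2_000_000, 4_400_000], rbb=[400_000, 1_700_000,
                                                     3_000_000, 4_100_000]),
        mk("chrB", [
            ArrayPlacement("knob180", 1_500_000, 30_000, 0.08, te_rate=0.06),
            ArrayPlacement("CentC", 2_400_000, 12_000, 0.08, te_rate=0.05),
        ], het=(3_300_000, 3_500_000),
            rba=[800_000, 2_900_000, 4_300_000],
            rbb=[500_000, 1_900_000, 2_650_000, 3_900_000]),
        mk("chrC", [
            ArrayPlacement("knob180", 1_800_000, 100_000, 0.08, te_rate=0.04),
            ArrayPlacement("CentC", 2_600_000, 12_000, 0.08, te_rate=0.05),
            ArrayPlacement("TR-1", 3_900_000, 12_000, 0.08, te_rate=0.06),
        ], rba=[900_000, 3_200_000, 4_500_000], rbb=[600_000, 1_400_000,
                                                     3_500_000, 4_400_000]),
    ]
    return SimConfig(
        chromosomes=chroms,
        profile_a=ProfileConfig("pb", break_over=15_000, end_trim=2500,
                                sub_rate=1e-4, break_at_het=True),
        profile_b=ProfileConfig("ont", break_over=40_000, end_trim=2000,
                                sub_rate=5e-4, indel_rate=2e-4, rc_every=3),
        chimera_joins=[
            (("chrA", "knob180", 0, "left"), ("chrB", "knob180", 0, "right")),
            (("chrB", "knob180", 0, "left"), ("chrA", "TR-1", 0, "right")),
        ],
        seed=seed,
    )


@dataclass
class SimTruth:
    features: list[FeatureInterval]  # repeats, TE inserts, telomeres
    arrays: pd.DataFrame  # chrom,start,end,family,units,repeat_bp
    centromeres: list[FeatureInterval]  # CENH3 domains
    het: tuple[str, int, int] | None
    het_alt: SequenceRecord | None
    chrom_lengths: dict[str, int]


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n_mut = rng.binomial(arr.size, rate)
    if n_mut == 0:
        return seq
    pos = rng.choice(arr.size, size=n_mut, replace=False)
    shift = rng.integers(1, 4, size=n_mut)
    code = np.zeros(256, dtype=np.uint8)
    for i, c in enumerate(b"ACGT"):
        code[c] = i
    cur = code[arr[pos]]
    arr[pos] = _BASES[(cur + shift) % 4]
    return arr.tobytes().decode()


def _apply_errors(rng: np.random.Generator, seq: str, sub_rate: float,
                  indel_rate: float) -> str:
    seq = _mutate(rng, seq, sub_rate)
    if indel_rate <= 0:
        return seq
    n = len(seq)
    n_ind = rng.binomial(n, indel_rate)
    if n_ind == 0:
        return seq
    pos = np.sort(rng.choice(n, size=n_ind, replace=False))
    kinds = rng.integers(0, 2, size=n_ind)  # 0 del, 1 ins
    ins_bases = _BASES[rng.integers(0, 4, size=n_ind)]
    parts = []
    prev = 0
    for p, kd, ib in zip(pos.tolist(), kinds.tolist(), ins_bases.tolist()):
        parts.append(seq[prev:p])
        if kd == 0:  # deletion: drop the base at p
            prev = p + 1
        else:  # insertion before p
            parts.append(chr(ib))
            prev = p
    parts.append(seq[prev:])
    return "".join(parts)


def _build_array(rng: np.random.Generator, placement: ArrayPlacement,
                 chrom: str) -> tuple[str, list[FeatureInterval], int]:
    """Tandem monomer array with optional TE-like interruptions; returns
    (sequence of exactly placement.span bp, features, unit count)."""
    cons = consensus_monomer(placement.family)
    if placement.rc:
        cons = reverse_complement(cons)
    te_names = list(TE_FAMILIES)
    parts: list[str] = []
    feats: list[FeatureInterval] = []
    pos = placement.start
    units = 0
    run_start = pos
    while pos - placement.start < placement.span:
        remaining = placement.span - (pos - placement.start)
        unit = _mutate(rng, cons, placement.divergence)
        if len(unit) > remaining:
            unit = unit[:remaining]
        parts.append(unit)
        pos += len(unit)
        units += 1
        if (placement.te_rate > 0 and rng.random() < placement.te_rate
                and placement.span - (pos - placement.start) > 8000):
            if pos > run_start:
                feats.append(FeatureInterval(chrom, run_start, pos, placement.family))
            fam = te_names[int(rng.integers(0, len(te_names)))]
            te = _mutate(rng, consensus_monomer(fam), 0.02)
            room = placement.span - (pos - placement.start) - 2000
            te = te[:max(0, min(len(te), room))]
            if te:
                parts.append(te)
                feats.append(FeatureInterval(chrom, pos, pos + len(te), fam))
                pos += len(te)
            run_start = pos
    if pos > run_start:
        feats.append(FeatureInterval(chrom, run_start, pos, placement.family))
    seq = "".join(parts)
    assert len(seq) == placement.span
    return seq, feats, units


def simulate_genome(config: SimConfig) -> tuple[list[SequenceRecord], SimTruth]:
    """Build the truth genome and its annotation tables (deterministic per
    config.seed)."""
    config.validate()
    records: list[SequenceRecord] = []
    features: list[FeatureInterval] = []
    array_rows = []
    centromeres: list[FeatureInterval] = []
    het = None
    het_alt = None
    chrom_lengths = {}
    for ci, plan in enumerate(config.chromosomes):
        rng = np.random.default_rng([config.seed, 101, ci])
        arrays = sorted(plan.arrays, key=lambda a: a.start)
        for a, b in zip(arrays, arrays[1:]):
            if a.end > b.start:
                raise MapweaverError(
                    f"overlapping arrays {a.family}/{b.family} on {plan.name}")
        parts: list[str] = []
        cursor = 0
        for arr in arrays:
            if arr.start > cursor:
                parts.append(_random_dna(rng, arr.start - cursor, forbid=""))
            seq, feats, units = _build_array(rng, arr, plan.name)
            parts.append(seq)
            features.extend(feats)
            repeat_bp = sum(f.length for f in feats if f.label == arr.family)
            array_rows.append({"chrom": plan.name, "start": arr.start,
                               "end": arr.end, "family": arr.family,
                               "units": units, "repeat_bp": repeat_bp,
                               "collapse_frac": arr.collapse_frac})
            if arr.family == "CentC":
                lo = max(0, arr.start - config.cenh3_flank)
                hi = min(plan.length, arr.end + config.cenh3_flank)
                centromeres.append(FeatureInterval(plan.name, lo, hi, "centromere"))
            cursor = arr.end
        if cursor < plan.length:
            parts.append(_random_dna(rng, plan.length - cursor, forbid=""))
        seq = "".join(parts)
        assert len(seq) == plan.length
        records.append(SequenceRecord(plan.name, seq,
                                      [(plan.name, 0, plan.length, "+")]))
        chrom_lengths[plan.name] = plan.length
        if plan.het_region is not None:
            s, e = plan.het_region
            het = (plan.name, s, e)
            alt_rng = np.random.default_rng([config.seed, 102, ci])
            alt = _mutate(alt_rng, seq[s:e], 0.01)
            # one 20 kb deletion in the alternate haplotype
            mid = (e - s) // 2
            alt = alt[:mid] + alt[mid + 20_000:]
            het_alt = SequenceRecord(f"{plan.name}_alt", alt,
                                     [(plan.name, s, e, "+")])
            features.append(FeatureInterval(plan.name, s, e, "heterozygous"))
    truth = SimTruth(features=features,
                     arrays=pd.DataFrame(array_rows),
                     centromeres=centromeres,
                     het=het, het_alt=het_alt,
                     chrom_lengths=chrom_lengths)
    return records, truth


@dataclass
class PlantedEvent:
    profile: str
    contig_id: str
    event: str  # {chimera, collapse, array_break, het_break, random_break}
    pos_contig: int
    chrom: str
    pos_chrom: int
    size: int = 0


def simulate_assemblies(genome: list[SequenceRecord], truth: SimTruth,
                        config: SimConfig
                        ) -> tuple[list[SequenceRecord], list[SequenceRecord],
                                   pd.DataFrame]:
    """Derive the two contig sets with planted breaks, collapses and
    chimeras; every planted event is returned in the truth ledger."""
    by_chrom = {r.id: r for r in genome}
    plans = {p.name: p for p in config.chromosomes}
    sets = []
    all_events: list[PlantedEvent] = []
    for pi, prof in enumerate((config.profile_a, config.profile_b)):
        rng = np.random.default_rng([config.seed, 201 + pi])
        # segments per chromosome: (chrom, start, end) with deleted array
        # interiors between segments
        segments: dict[tuple[str, str, int, str], dict] = {}
        seg_list = []
        for plan in config.chromosomes:
            chrom = plan.name
            arrays = sorted([a for a in plan.arrays], key=lambda a: a.start)
            breaks = []  # (del_start, del_end, tag)
            arr_count: dict[str, int] = {}
            for arr in arrays:
                idx = arr_count.get(arr.family, 0)
                arr_count[arr.family] = idx + 1
                if arr.span > prof.break_over:
                    breaks.append((arr.start + prof.edge_keep,
                                   arr.end - prof.edge_keep,
                                   ("array", arr.family, idx)))
            if prof.break_at_het and plan.het_region is not None:
                mid = (plan.het_region[0] + plan.het_region[1]) // 2
                breaks.append((mid, mid, ("het", "", 0)))
            rb = (plan.random_breaks_a if pi == 0 else plan.random_breaks_b)
            for pos in rb:
                breaks.append((pos, pos, ("random", "", 0)))
            breaks.sort()
            cursor = prof.end_trim
            chrom_end = plan.length - prof.end_trim
            bounds = breaks + [(chrom_end, chrom_end, ("end", "", 0))]
            for del_s, del_e, tag in bounds:
                if del_s > cursor:
                    seg = {"chrom": chrom, "start": cursor, "end": del_s,
                           "right_tag": tag}
                    seg_list.append(seg)
                cursor = max(cursor, del_e)
        # chimera construction (accurate profile only)
        contigs: list[SequenceRecord] = []
        events: list[PlantedEvent] = []
        used = [False] * len(seg_list)

        def find_segment(chrom, family, idx, side):
            for i, seg in enumerate(seg_list):
                if seg["chrom"] != chrom or used[i]:
                    continue
                plan = plans[chrom]
                target = None
                arr_count: dict[str, int] = {}
                for arr in sorted(plan.arrays, key=lambda a: a.start):
                    j = arr_count.get(arr.family, 0)
                    arr_count[arr.family] = j + 1
                    if arr.family == family and j == idx:
                        target = arr
                if target is None:
                    raise MapweaverError(f"no array {family}[{idx}] on {chrom}")
                if side == "left" and abs(seg["end"] - (target.start
                                                        + config.profile_a.edge_keep)) < 2:
                    return i
                if side == "right" and abs(seg["start"] - (target.end
                                                           - config.profile_a.edge_keep)) < 2:
                    return i
            raise MapweaverError(f"no segment flanking {family}[{idx}] {side} on {chrom}")

        n = 0
        if pi == 0:
            for (left_spec, right_spec) in config.chimera_joins:
                li = find_segment(*left_spec)
                ri = find_segment(*right_spec)
                ls, rs = seg_list[li], seg_list[ri]
                used[li] = used[ri] = True
                n += 1
                cid = f"{prof.name}_{n:03d}"
                seq = (by_chrom[ls["chrom"]].seq[ls["start"]:ls["end"]]
                       + by_chrom[rs["chrom"]].seq[rs["start"]:rs["end"]])
                rec = SequenceRecord(cid, seq, [
                    (ls["chrom"], ls["start"], ls["end"], "+"),
                    (rs["chrom"], rs["start"], rs["end"], "+")])
                contigs.append(rec)
                events.append(PlantedEvent(prof.name, cid, "chimera",
                                           ls["end"] - ls["start"],
                                           ls["chrom"], ls["end"]))
        for i, seg in enumerate(seg_list):
            if used[i]:
                continue
            n += 1
            cid = f"{prof.name}_{n:03d}"
            seq = by_chrom[seg["chrom"]].seq[seg["start"]:seg["end"]]
            rec = SequenceRecord(cid, seq,
                                 [(seg["chrom"], seg["start"], seg["end"], "+")])
            contigs.append(rec)
        # collapses (accurate profile): delete the central fraction of the
        # designated arrays inside whatever contig contains them
        if pi == 0:
            for row in truth.arrays.itertuples():
                if row.collapse_frac <= 0:
                    continue
                cut = int(row.collapse_frac * (row.end - row.start))
                mid = (row.start + row.end) // 2
                del_s, del_e = mid - cut // 2, mid + cut - cut // 2
                for j, rec in enumerate(contigs):
                    blocks = rec.source_intervals
                    if len(blocks) != 1:
                        continue
                    chrom, s, e, strand = blocks[0]
                    if chrom == row.chrom and s < del_s and del_e < e:
                        seq = rec.seq[:del_s - s] + rec.seq[del_e - s:]
                        contigs[j] = SequenceRecord(rec.id, seq, [
                            (chrom, s, del_s, "+"), (chrom, del_e, e, "+")])
                        events.append(PlantedEvent(prof.name, rec.id, "collapse",
                                                   del_s - s, chrom, del_s,
                                                   size=cut))
                        break
        # base errors and optional reverse-complementing
        final = []
        for j, rec in enumerate(contigs):
            seq = _apply_errors(rng, rec.seq, prof.sub_rate, prof.indel_rate)
            blocks = rec.source_intervals
            if prof.rc_every and (j + 1) % prof.rc_every == 0:
                seq = reverse_complement(seq)
                blocks = [(c, s, e, "-" if st == "+" else "+")
                          for c, s, e, st in reversed(blocks)]
            final.append(SequenceRecord(rec.id, seq, blocks))
        sets.append(final)
        all_events.extend(events)
    ledger = pd.DataFrame([e.__dict__ for e in all_events])
    return sets[0], sets[1], ledger


def simulate_optical_maps(genome: list[SequenceRecord], config: SimConfig
                          ) -> tuple[list, dict[str, tuple[str, int]]]:
    """Consensus-map analogues: truth digest labels with sizing noise,
    missed and false labels; returns (maps, map_id -> (chrom, offset))."""
    from .core import LabelMap

    mc = config.maps
    maps = []
    origins: dict[str, tuple[str, int]] = {}
    for ci, rec in enumerate(genome):
        digest = insilico_digest(rec, mc.motif, mc.min_label_spacing)
        base = np.asarray(digest.labels)
        brks = sorted(pos for chrom, pos in mc.breaks if chrom == rec.id)
        pieces = []
        lo = 0
        for b in brks + [len(rec)]:
            pieces.append((lo, b))
            lo = b
        for ri in range(mc.n_replicates):
            rng = np.random.default_rng([config.seed, 301, ci, ri])
            for (p_lo, p_hi) in pieces:
                if p_hi - p_lo < mc.min_map_len:
                    continue
                sel = base[(base > p_lo) & (base <= p_hi)] - p_lo
                if sel.size == 0:
                    continue
                intervals = np.diff(np.concatenate([[0.0], sel]))
                noise = rng.normal(0.0, mc.sizing_sd_coeff
                                   * np.sqrt(np.maximum(intervals, 1.0)))
                noisy = np.cumsum(intervals + noise)
                keep = rng.random(noisy.size) >= mc.miss_rate
                labels = noisy[keep]
                length = (p_hi - p_lo) + float(noise.sum())
                n_false = rng.poisson(mc.false_per_100kb * (p_hi - p_lo) / 1e5)
                if n_false:
                    falses = rng.uniform(1.0, max(length - 1.0, 2.0), n_false)
                    labels = np.concatenate([labels, falses])
                labels = np.unique(np.clip(labels, 1.0, max(length, 2.0)))
                # enforce strict monotonicity after clipping
                labels = labels[np.concatenate([[True], np.diff(labels) > 1e-6])]
                mid = f"map_{rec.id}_r{ri + 1}" + (f"_p{p_lo}" if brks else "")
                maps.append(LabelMap(mid, max(length, float(labels[-1])),
                                     labels.tolist(), source="optical"))
                origins[mid] = (rec.id, p_lo)
    return maps, origins


def _lognormal_lengths(rng, n, profile: ReadProfile) -> np.ndarray:
    # base-weighted median of a lognormal is exp(mu + sigma^2): tune mu so
    # the emitted read-set N50 lands on the profile target
    mu = math.log(profile.n50) - profile.sigma ** 2
    ln = rng.lognormal(mu, profile.sigma, n)
    return np.clip(ln, profile.min_len, profile.max_len).astype(np.int64)


def simulate_reads(genome: list[SequenceRecord], profile: ReadProfile,
                   config: SimConfig, salt: int = 0,
                   depth: float | None = None) -> list[SequenceRecord]:
    """Uniformly positioned reads with lognormal lengths tuned to the
    profile's N50, per-profile substitution/indel errors, and truth source
    intervals; read starts may fall off the ends so coverage is uniform
    right up to the chromosome termini."""
    depth = profile.depth if depth is None else depth
    reads: list[SequenceRecord] = []
    mean_len = math.exp(math.log(profile.n50) - profile.sigma ** 2
                        + profile.sigma ** 2 / 2.0)
    for ci, rec in enumerate(genome):
        rng = np.random.default_rng([config.seed, 401 + salt, ci])
        L = len(rec)
        n_reads = int(round(depth * L / mean_len))
        lens = _lognormal_lengths(rng, n_reads, profile)
        starts = rng.integers(-lens + 200, L - 200, size=n_reads)
        strands = rng.integers(0, 2, size=n_reads)
        for i in range(n_reads):
            s = max(0, int(starts[i]))
            e = min(L, int(starts[i]) + int(lens[i]))
            if e - s < profile.min_len:
                continue
            seq = rec.seq[s:e]
            seq = _apply_errors(rng, seq, profile.sub_rate, profile.indel_rate)
            strand = "+" if strands[i] == 0 else "-"
            if strand == "-":
                seq = reverse_complement(seq)
            reads.append(SequenceRecord(f"rd{salt}_{rec.id}_{i}", seq,
                                        [(rec.id, s, e, strand)]))
    return reads


def simulate_chip(genome: list[SequenceRecord],
                  centromeres: list[FeatureInterval],
                  config: SimConfig
                  ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-bp ChIP and input coverage: input uniform Poisson, ChIP with the
    sampling rate multiplied by ``fold`` inside centromere truth."""
    cc = config.chip
    if cc.depth <= 0:
        raise MapweaverError("chip depth must be positive")
    chip: dict[str, np.ndarray] = {}
    inp: dict[str, np.ndarray] = {}
    for ci, rec in enumerate(genome):
        rng = np.random.default_rng([config.seed, 501, ci])
        L = len(rec)
        n = int(cc.depth * L / cc.read_len)
        weights = np.ones(L)
        for iv in centromeres:
            if iv.seq_id == rec.id:
                weights[iv.start:iv.end] = cc.fold
        for kind in ("input", "chip"):
            w = np.ones(L) if kind == "input" else weights
            p = w / w.sum()
            starts = rng.choice(L, size=n, p=p)
            delta = np.zeros(L + cc.read_len + 1)
            np.add.at(delta, starts, 1)
            np.add.at(delta, starts + cc.read_len, -1)
            cov = np.cumsum(delta)[:L]
            (inp if kind == "input" else chip)[rec.id] = cov
    return chip, inp


def simulate_markers(truth: SimTruth, config: SimConfig,
                     scaffold_ids: dict[str, str] | None = None) -> pd.DataFrame:
    """Markers with monotone-plus-noise genetic positions, two sources of
    equal size, and configured fractions of non-unique / low-mapq rows."""
    mc = config.markers
    if mc.per_group < 2:
        raise MapweaverError("per_group must be >= 2")
    rows = []
    for ci, (chrom, L) in enumerate(sorted(truth.chrom_lengths.items())):
        rng = np.random.default_rng([config.seed, 601, ci])
        pos = np.sort(rng.integers(0, L, size=mc.per_group))
        genetic = pos / 1e6 * mc.cm_per_mb + rng.normal(0, mc.noise_sd,
                                                        mc.per_group)
        nonuniq = rng.random(mc.per_group) < mc.frac_nonunique
        lowq = rng.random(mc.per_group) < mc.frac_lowmapq
        src = np.where(np.arange(mc.per_group) % 2 == 0, "anchors", "ibm")
        for i in range(mc.per_group):
            rows.append({
                "marker_id": f"mk_{chrom}_{i}",
                "scaffold_id": scaffold_ids.get(chrom, chrom) if scaffold_ids else chrom,
                "physical_bp": int(pos[i]),
                "linkage_group": chrom,
                "genetic_pos": float(genetic[i]),
                "mapq": 20 if lowq[i] else 60,
                "unique": not nonuniq[i],
                "source": src[i],
            })
    return pd.DataFrame(rows)
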