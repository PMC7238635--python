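"""End-to-end driver: conflict cutting, error curation, contig merging,
hybrid scaffolding, 13N resolution, finishing, pseudomolecule emission —
plus coordinate liftover through the provenance chain and validation
against simulator truth.

Steps run strictly in order; each stage's contig set keeps provenance
blocks back to the previous stage, so intervals can be lifted from any
input assembly to the final coordinates.  Non-N bases are conserved
through cutting, merging and scaffolding; curation and finishing itemise
every base they add or remove.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conflicts import cut_contigs, detect_conflicts, score_junction_support
from .core import (
    LabelMap,
    MapAlignment,
    MapweaverError,
    SequenceRecord,
    assembly_metrics,
    find_n_gaps,
    total_gap_length,
)
from .curation import (
    adjudicate_zygosity,
    call_discrepancies,
    merge_adjacent_calls,
    patch_with_alternate,
)
from .finishing import (
    emit_pseudomolecules,
    extend_telomeres,
    fill_gaps,
    filter_markers,
    order_orient,
)
from .optical import AlignParams, align_label_maps, fit_stretch, insilico_digest, rescale_map
from .overlap import find_sequence_overlaps, merge_overlapping
from .scaffold import (
    hybrid_scaffold,
    plan_to_agp,
    resolve_13N_overlaps,
)


@dataclass
class PipelineConfig:
    """Every pipeline threshold as a named knob (desk-scale defaults)."""

    motif: str = "CTTAAG"
    min_label_spacing: int = 800
    align: AlignParams = field(default_factory=AlignParams)
    # step 1: conflicts
    min_overhang_labels: int = 4
    min_overhang_bp: int = 12_000
    support_window_labels: int = 3
    support_cut: float = 35.0
    min_fragment: int = 20_000
    # step 2: discrepancies
    discrepancy_min_size: int = 1000
    discrepancy_min_confidence: float = 0.1
    # step 3: overlaps
    overlap_k: int = 21
    min_overlap: int = 5000
    min_identity: float = 0.9
    max_overhang: int = 2500
    min_detectable_overlap_bp: int = 50_000
    rerun_conflicts_after_merge: bool = True
    # step 4: scaffolding
    min_gap: int = 100
    unmergeable_junctions: set = field(default_factory=set)
    # finishing
    gap_fill_iterations: int = 3
    anchor_len: int = 250
    max_gap_delta: float = 2.0
    telomere_unit: str = "TTTAGGG"
    telomere_min_tract: int = 1000
    inter_scaffold_gap: int = 100
    marker_min_per_scaffold: int = 21
    marker_cap: int = 100
    marker_min_mapq: int = 31
    seed: int = 0


@dataclass
class PipelineInputs:
    contigs_a: list[SequenceRecord]
    contigs_b: list[SequenceRecord]
    maps: list[LabelMap]
    reads: list[SequenceRecord] | None = None
    markers: pd.DataFrame | None = None
    map_origins: dict[str, tuple[str, int]] | None = None  # map -> (group, offset)


@dataclass
class PipelineReport:
    conflicts_found: int = 0
    conflicts_cut: int = 0
    discrepancies_called: int = 0
    discrepancies_patched: int = 0
    patch_bases_added: int = 0
    patch_bases_removed: int = 0
    overlaps_found: int = 0
    unitigs_merged: int = 0
    overlap_bases_removed: int = 0
    scaffolds_built: int = 0
    junctions_13n: int = 0
    junctions_13n_resolved: int = 0
    gaps_filled: int = 0
    gaps_shrunk: int = 0
    fill_bases_added: int = 0
    fill_n_removed: int = 0
    telomeres_extended: int = 0
    telomere_bases_added: int = 0
    cut_junctions: list = field(default_factory=list)  # (contig_id, junction_bp)
    metrics_before: dict = field(default_factory=dict)
    metrics_after: dict = field(default_factory=dict)
    non_n_deltas: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class PipelineResult:
    pseudomolecules: list[SequenceRecord]
    scaffolds: list[SequenceRecord]
    agp: list
    report: PipelineReport
    stages: dict[str, list[SequenceRecord]]  # provenance chain, in order
    leftovers: list[SequenceRecord]


def _non_n(records: list[SequenceRecord]) -> int:
    return sum(len(r) - r.seq.count("N") for r in records)


def _interval_grams(labels, bucket: int = 800):
    d = np.diff(np.asarray(labels))
    q = (d // bucket).astype(np.int64)
    return set(zip(q[:-1].tolist(), q[1:].tolist()))


def align_all(digests: dict[str, LabelMap], maps: dict[str, LabelMap],
              params: AlignParams, prefilter: bool = True,
              min_shared_grams: int = 4) -> list[MapAlignment]:
    """Align every digest against every map, with a quantised interval
    2-gram prefilter to skip hopeless pairs cheaply."""
    map_grams = {}
    if prefilter:
        for mid, m in maps.items():
            g = _interval_grams(m.labels)
            # add neighbour buckets for sizing-noise tolerance
            expanded = set()
            for x, y in g:
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        expanded.add((x + dx, y + dy))
            map_grams[mid] = expanded
    out: list[MapAlignment] = []
    for dig in digests.values():
        dg = _interval_grams(dig.labels) if prefilter else None
        for mid, m in maps.items():
            if prefilter and dg is not None:
                if len(dg & map_grams[mid]) < min_shared_grams:
                    continue
            out.extend(align_label_maps(dig, m, params))
    return out


def digest_all(records: list[SequenceRecord], cfg: PipelineConfig) -> dict[str, LabelMap]:
    return {r.id: insilico_digest(r, cfg.motif, cfg.min_label_spacing)
            for r in records}


def _conflict_stage(contigs, digests, maps, alignments, cfg: PipelineConfig):
    conflicts = detect_conflicts(alignments, digests, maps,
                                 cfg.min_overhang_labels, cfg.min_overhang_bp)
    for c in conflicts:
        c.support_score = score_junction_support(
            c, alignments, digests, cfg.support_window_labels)
    cut, ledger = cut_contigs(contigs, conflicts, cfg.support_cut, cfg.min_fragment)
    n_cut = sum(1 for c in conflicts if 0 <= c.support_score < cfg.support_cut)
    return cut, conflicts, n_cut


def _rescale_maps(maps: dict[str, LabelMap], digests: dict[str, LabelMap],
                  alignments: list[MapAlignment]) -> dict[str, LabelMap]:
    """One stretch fit per map from its best contig alignments (median)."""
    factors: dict[str, list[float]] = {}
    for aln in alignments:
        if aln.n_pairs < 10:
            continue
        try:
            f = fit_stretch(aln, digests[aln.query_id], maps[aln.ref_id])
        except (KeyError, MapweaverError):
            continue
        factors.setdefault(aln.ref_id, []).append(1.0 / f)
    out = {}
    for mid, m in maps.items():
        fs = factors.get(mid)
        out[mid] = rescale_map(m, float(np.median(fs))) if fs else m
    return out


def run_pipeline(cfg: PipelineConfig, inputs: PipelineInputs,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute steps 1-4 plus finishing in order; returns the final
    assembly, AGP, report and the stage chain for liftover."""
    if not inputs.maps:
        raise MapweaverError("optical maps are required before step 1")
    if not inputs.contigs_a:
        raise MapweaverError("primary contig set required")
    report = PipelineReport()
    stages: dict[str, list[SequenceRecord]] = {}
    maps = {m.id: m for m in inputs.maps}
    contigs_a = inputs.contigs_a
    contigs_b = inputs.contigs_b
    stages["input_a"] = contigs_a
    stages["input_b"] = contigs_b
    report.metrics_before = assembly_metrics(contigs_a + contigs_b).__dict__

    # --- step 1: conflict resolution (both assemblies) -------------------
    n_before = _non_n(contigs_a) + _non_n(contigs_b)
    dig_a = digest_all(contigs_a, cfg)
    dig_b = digest_all(contigs_b, cfg)
    aln_a = align_all(dig_a, maps, cfg.align)
    aln_b = align_all(dig_b, maps, cfg.align)
    contigs_a, confl_a, cut_a = _conflict_stage(contigs_a, dig_a, maps, aln_a, cfg)
    contigs_b, confl_b, cut_b = _conflict_stage(contigs_b, dig_b, maps, aln_b, cfg)
    report.conflicts_found = len(confl_a) + len(confl_b)
    report.conflicts_cut = cut_a + cut_b
    report.cut_junctions = [(c.contig_id, c.junction_bp)
                            for c in confl_a + confl_b
                            if 0 <= c.support_score < cfg.support_cut]
    stages["step1_a"] = contigs_a
    stages["step1_b"] = contigs_b
    report.non_n_deltas["step1"] = (_non_n(contigs_a) + _non_n(contigs_b)) - n_before

    # --- step 2: error curation (patch A from B) -------------------------
    dig_a = digest_all(contigs_a, cfg)
    dig_b = digest_all(contigs_b, cfg)
    aln_a = align_all(dig_a, maps, cfg.align)
    maps = _rescale_maps(maps, dig_a, aln_a)
    aln_a = align_all(dig_a, maps, cfg.align)
    aln_b = align_all(dig_b, maps, cfg.align)
    best_a: dict[tuple[str, str], MapAlignment] = {}
    for aln in aln_a:
        key = (aln.query_id, aln.ref_id)
        if key not in best_a or aln.score > best_a[key].score:
            best_a[key] = aln
    calls = []
    coverage: dict[tuple[str, int, int], set] = {}
    for aln in best_a.values():
        cs = call_discrepancies(aln, dig_a[aln.query_id], maps[aln.ref_id],
                                cfg.discrepancy_min_size,
                                cfg.discrepancy_min_confidence,
                                cfg.align.sizing_sd_coeff)
        calls.extend(merge_adjacent_calls(cs))
    # covering maps per call locus
    cover_counts: dict[tuple[str, int, int], int] = {}
    for c in calls:
        n_cov = 0
        for aln in best_a.values():
            if aln.query_id != c.contig_id:
                continue
            q = np.asarray(dig_a[c.contig_id].labels)
            qi = [p[0] for p in aln.pairs]
            lo, hi = q[min(qi)], q[max(qi)]
            if lo <= c.contig_interval[0] and hi >= c.contig_interval[1]:
                n_cov += 1
        cover_counts[(c.contig_id, *c.contig_interval)] = n_cov
    adjudicated = adjudicate_zygosity(calls, cover_counts)
    report.discrepancies_called = len(adjudicated)
    by_id_b = {r.id: r for r in contigs_b}
    new_a = []
    patched_ids = {}
    for rec in contigs_a:
        rec_calls = [c for c in adjudicated if c.contig_id == rec.id
                     and c.zygosity == "homozygous"]
        cur = rec
        for c in sorted(rec_calls, key=lambda c: -c.contig_interval[0]):
            before = len(cur)
            cur, note = patch_with_alternate(
                cur, c, by_id_b, aln_b, dig_b, maps, cfg.discrepancy_min_size,
                cfg.align.sizing_sd_coeff)
            if note.startswith("patched"):
                report.discrepancies_patched += 1
                delta = len(cur) - before
                if delta >= 0:
                    report.patch_bases_added += delta
                else:
                    report.patch_bases_removed += -delta
        new_a.append(cur)
        patched_ids[rec.id] = cur
    contigs_a = new_a
    stages["step2_a"] = contigs_a

    # --- step 3: contig merging ------------------------------------------
    overlaps = find_sequence_overlaps(
        contigs_a, contigs_b, cfg.overlap_k, cfg.min_overlap,
        cfg.min_identity, cfg.max_overhang)
    report.overlaps_found = len(overlaps)
    n_before = _non_n(contigs_a) + _non_n(contigs_b)
    merged, merge_ledger = merge_overlapping(
        contigs_a + contigs_b, overlaps, primary_ids={r.id for r in contigs_a})
    report.unitigs_merged = sum(1 for m in merge_ledger
                                if m.unitig_id and len(m.parts) > 1)
    report.overlap_bases_removed = sum(m.overlap_bases_removed
                                       for m in merge_ledger)
    stages["step3"] = merged
    report.non_n_deltas["step3"] = (_non_n(merged) - n_before
                                    + report.overlap_bases_removed)
    if cfg.rerun_conflicts_after_merge:
        dig_m = digest_all(merged, cfg)
        aln_m = align_all(dig_m, maps, cfg.align)
        merged, confl_m, cut_m = _conflict_stage(merged, dig_m, maps, aln_m, cfg)
        report.conflicts_found += len(confl_m)
        report.conflicts_cut += cut_m
        stages["step3_recut"] = merged

    # --- step 4: hybrid scaffolding + 13N resolution ---------------------
    dig_m = digest_all(merged, cfg)
    aln_m = align_all(dig_m, maps, cfg.align)
    n_before = _non_n(merged)
    plans, scaffold_seqs, leftover_ids = hybrid_scaffold(
        merged, maps, aln_m, dig_m, cfg.min_gap)
    report.junctions_13n = sum(1 for p in plans for g in p.gaps
                               if g.kind == "overlap13N")
    plans, scaffold_seqs, merged_after, n_res, n_ret = resolve_13N_overlaps(
        plans, merged,
        {"k": cfg.overlap_k, "min_overlap": cfg.min_overlap,
         "min_identity": cfg.min_identity, "max_overhang": cfg.max_overhang},
        cfg.unmergeable_junctions)
    report.junctions_13n_resolved = n_res
    report.scaffolds_built = len(plans)
    by_id_m = {r.id: r for r in merged_after}
    stages["step4_components"] = merged_after
    stages["step4"] = scaffold_seqs
    leftovers = [c for c in merged if c.id in set(leftover_ids)]
    report.non_n_deltas["step4"] = (_non_n(scaffold_seqs) + _non_n(leftovers)
                                    - n_before)
    agp = [row for p in plans for row in plan_to_agp(p, by_id_m)]

    # --- finishing: gap fill, telomeres, pseudomolecules ------------------
    scaffolds = scaffold_seqs
    if inputs.reads:
        read_key_cache: dict = {}
        scaffolds, fill_reports = fill_gaps(
            scaffolds, inputs.reads, cfg.gap_fill_iterations,
            cfg.anchor_len, cfg.max_gap_delta, key_cache=read_key_cache)
        report.gaps_filled = sum(1 for r in fill_reports if r.action == "closed")
        report.gaps_shrunk = sum(1 for r in fill_reports if r.action == "shrunk")
        report.fill_bases_added = sum(r.added_bases for r in fill_reports)
        report.fill_n_removed = sum(r.delta_n for r in fill_reports)
        scaffolds, tel_reports = extend_telomeres(
            scaffolds, inputs.reads, cfg.telomere_min_tract, cfg.telomere_unit,
            cfg.anchor_len, key_cache=read_key_cache)
        report.telomeres_extended = len(tel_reports)
        report.telomere_bases_added = sum(t.added_bases for t in tel_reports)
    stages["finishing"] = scaffolds

    pseudos = scaffolds
    if inputs.markers is not None and len(inputs.markers):
        markers = project_markers(inputs.markers, plans,
                                  inputs.map_origins or {}, scaffolds)
        filtered = filter_markers(markers, cfg.marker_min_per_scaffold,
                                  cfg.marker_cap, cfg.marker_min_mapq)
        if len(filtered):
            ordering = order_orient(filtered, seed=cfg.seed)
            placed = {sid for arr in ordering.values() for sid, _ in arr}
            pseudos, ps_agp = emit_pseudomolecules(
                ordering, scaffolds, cfg.inter_scaffold_gap, name_prefix="")
            agp = ps_agp
            leftovers = leftovers + [s for s in scaffolds if s.id not in placed]
    stages["final"] = pseudos

    report.metrics_after = assembly_metrics(pseudos).__dict__
    if outdir is not None:
        _dump(outdir, stages, agp, report, leftovers)
    return PipelineResult(pseudos, scaffolds, agp, report, stages, leftovers)


def project_markers(markers: pd.DataFrame, plans, map_origins,
                    scaffolds) -> pd.DataFrame:
    """Project truth-coordinate markers onto scaffolds through each
    scaffold's anchoring map (map origins give group + offset)."""
    scaffold_len = {s.id: len(s) for s in scaffolds}
    rows = []
    for plan in plans:
        origin = map_origins.get(plan.map_id)
        if origin is None:
            continue
        group, offset = origin
        if not plan.placements:
            continue
        start = min(p.start for p in plan.placements)
        sub = markers[markers["linkage_group"] == group]
        L = scaffold_len.get(plan.scaffold_id, None)
        if L is None:
            continue
        for row in sub.itertuples(index=False):
            pos = row.physical_bp - offset - start
            if 0 <= pos < L:
                d = row._asdict()
                d["scaffold_id"] = plan.scaffold_id
                d["physical_bp"] = int(pos)
                rows.append(d)
    return pd.DataFrame(rows)


def _dump(outdir, stages, agp, report, leftovers) -> None:
    from .io import write_agp, write_sequences

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, records in stages.items():
        if records:
            write_sequences(records, outdir / f"{name}.fasta")
    if agp:
        write_agp(agp, outdir / "final.agp")
    if leftovers:
        write_sequences(leftovers, outdir / "leftovers.fasta")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=str)


# --- liftover -------------------------------------------------------------

def liftover_intervals(intervals: list[tuple[str, int, int]],
                       stages: list[list[SequenceRecord]]
                       ) -> list[dict]:
    """Map intervals through a chain of stages via provenance blocks.

    ``stages[0]`` must contain the records the intervals refer to; each
    subsequent stage's records carry source_intervals naming the previous
    stage's ids.  Intervals landing in replaced sequence are flagged
    ``deleted-in-target`` rather than dropped; cut junctions split an
    interval into multiple lifted pieces; orientation flips are handled.
    """
    known = {r.id for r in stages[0]}
    for sid, _, _ in intervals:
        if sid not in known:
            raise MapweaverError(f"unknown source id {sid!r}")
    current = [{"seq_id": s, "start": a, "end": b, "status": "ok"}
               for s, a, b in intervals]
    for stage in stages[1:]:
        nxt: list[dict] = []
        for iv in current:
            if iv["status"] != "ok":
                nxt.append(iv)
                continue
            pieces = _lift_one(iv, stage)
            nxt.extend(pieces)
        current = nxt
    return current


def _lift_one(iv: dict, stage: list[SequenceRecord]) -> list[dict]:
    pieces = []
    for rec in stage:
        pos = 0
        for (src, s, e, strand) in rec.source_intervals:
            blk_len = e - s
            if src == iv["seq_id"]:
                lo = max(iv["start"], s)
                hi = min(iv["end"], e)
                if hi > lo:
                    if strand == "+":
                        ns, ne = pos + (lo - s), pos + (hi - s)
                    else:
                        ns, ne = pos + (e - hi), pos + (e - lo)
                    pieces.append({"seq_id": rec.id, "start": int(ns),
                                   "end": int(ne), "status": "ok"})
            pos += blk_len
    if not pieces:
        return [{**iv, "status": "deleted-in-target"}]
    return pieces


# --- validation -----------------------------------------------------------

def validate_against_truth(assembly: list[SequenceRecord],
                           truth_genome: list[SequenceRecord],
                           truth_arrays: pd.DataFrame | None = None,
                           sample_windows: int = 120,
                           window: int = 500,
                           seed: int = 0) -> dict:
    """Completeness, identity outside repeat arrays, and gap count.

    Completeness: fraction of sampled truth windows (outside arrays) found
    in the assembly by banded infix alignment (edit distance <= window/4).
    Identity: mean identity of the found windows.
    """
    import edlib

    rng = np.random.default_rng(seed)
    asm_seqs = [r.seq for r in assembly]
    found = 0
    idents = []
    total = 0
    for rec in truth_genome:
        mask = np.zeros(len(rec), dtype=bool)
        if truth_arrays is not None and len(truth_arrays):
            for row in truth_arrays.itertuples():
                if row.chrom == rec.id:
                    mask[row.start:row.end] = True
        n = max(1, sample_windows // max(1, len(truth_genome)))
        starts = rng.integers(0, len(rec) - window, size=n * 3)
        picked = [s for s in starts if not mask[s:s + window].any()][:n]
        for s in picked:
            total += 1
            w = rec.seq[s:s + window]
            best = None
            for seq in asm_seqs:
                res = edlib.align(w, seq, mode="HW", task="distance", k=window // 4)
                if res["editDistance"] >= 0:
                    ident = 1.0 - res["editDistance"] / window
                    best = ident if best is None else max(best, ident)
            if best is not None:
                found += 1
                idents.append(best)
    truth_len = sum(len(r) for r in truth_genome)
    return {
        "completeness": found / total if total else 0.0,
        "identity_outside_arrays": float(np.mean(idents)) if idents else 0.0,
        "gap_count": sum(len(find_n_gaps(r)) for r in assembly),
        "gap_bp": total_gap_length(assembly),
        "assembly_bp": sum(len(r) for r in assembly),
        "truth_bp": truth_len,
    }
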