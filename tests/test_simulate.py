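"""The synthetic-data generator: determinism, truth self-consistency, and
the planted error processes."""
import numpy as np
import pytest

from mapweaver.core import SequenceRecord
from mapweaver.optical import insilico_digest
from mapweaver.simulate import (
    ArrayPlacement,
    ChromPlan,
    MapConfig,
    ProfileConfig,
    ReadProfile,
    SimConfig,
    consensus_monomer,
    default_config,
    simulate_assemblies,
    simulate_chip,
    simulate_genome,
    simulate_markers,
    simulate_optical_maps,
    simulate_reads,
)

from conftest import mini_config


def test_monomer_lengths_match_biology():
    assert len(consensus_monomer("CentC")) == 156
    assert len(consensus_monomer("knob180")) == 180
    assert len(consensus_monomer("TR-1")) == 358  # printed consensus
    assert consensus_monomer("telomere") == "TTTAGGG"
    assert len(consensus_monomer("rDNA-5S")) == 341
    assert len(consensus_monomer("rDNA-45S")) == 9349


def test_genome_deterministic_per_seed():
    cfg = mini_config(seed=3)
    g1, t1 = simulate_genome(cfg)
    g2, t2 = simulate_genome(mini_config(seed=3))
    assert [r.seq for r in g1] == [r.seq for r in g2]
    assert t1.arrays.equals(t2.arrays)
    g3, _ = simulate_genome(mini_config(seed=4))
    assert g3[0].seq != g1[0].seq


def test_truth_arrays_rescanned_within_one_monomer(mini_bundle):
    """Cross-module consistency: re-scanning a truth array with the
    annotation scanner recovers its span to within one monomer."""
    from mapweaver.annotate import scan_repeat_monomers

    genome = {r.id: r for r in mini_bundle["genome"]}
    arrays = mini_bundle["truth"].arrays
    row = arrays[(arrays.family == "knob180") & (arrays.chrom == "m1")].iloc[0]
    lo = max(0, row.start - 5000)
    region = SequenceRecord("m1", genome["m1"].seq[lo:row.end + 5000])
    cons = SequenceRecord("knob180", consensus_monomer("knob180"))
    hits = scan_repeat_monomers([region], cons, min_identity=0.7)
    assert hits
    span_lo = min(h.start for h in hits) + lo
    span_hi = max(h.end for h in hits) + lo
    assert abs(span_lo - row.start) <= 180
    assert abs(span_hi - row.end) <= 180


def test_zero_interruption_array_is_pure_tandem():
    plan = ChromPlan("z", 100_000, arrays=[
        ArrayPlacement("CentC", 40_000, 10_000, divergence=0.0, te_rate=0.0)])
    cfg = SimConfig([plan], ProfileConfig("a", 15_000),
                    ProfileConfig("b", 40_000), seed=5)
    genome, truth = simulate_genome(cfg)
    cons = consensus_monomer("CentC")
    region = genome[0].seq[40_000:50_000]
    assert region == (cons * (10_000 // 156 + 1))[:10_000]
    feats = [f for f in truth.features if f.label == "CentC"]
    assert len(feats) == 1 and (feats[0].start, feats[0].end) == (40_000, 50_000)


def test_array_overflow_errors():
    plan = ChromPlan("z", 50_000, arrays=[
        ArrayPlacement("CentC", 45_000, 10_000)])
    cfg = SimConfig([plan], ProfileConfig("a", 15_000),
                    ProfileConfig("b", 40_000))
    with pytest.raises(Exception):
        simulate_genome(cfg)


# --- assemblies -----------------------------------------------------------

def test_planted_event_bookkeeping(mini_bundle):
    events = mini_bundle["events"]
    assert (events.event == "chimera").sum() == 2
    assert (events.event == "collapse").sum() == 1
    collapse = events[events.event == "collapse"].iloc[0]
    assert collapse["size"] == 6000  # half of the 12 kb designated array


def test_threshold_semantics_between_profiles(mini_bundle):
    """An array between the two break thresholds is broken in the
    accurate-short profile but intact in the long-noisy profile."""
    truth = mini_bundle["truth"]
    knob = truth.arrays[(truth.arrays.chrom == "m1")
                        & (truth.arrays.family == "knob180")].iloc[0]

    def covered_intact(contigs):
        for rec in contigs:
            for (src, s, e, strand) in rec.source_intervals:
                if src == "m1" and s <= knob.start and e >= knob.end:
                    return True
        return False

    assert not covered_intact(mini_bundle["a"])  # 20 kb > 15 kb: broken
    assert covered_intact(mini_bundle["b"])      # 20 kb < 40 kb: intact


def test_zero_event_config_tiles_the_genome_exactly():
    plan = ChromPlan("z", 200_000, arrays=[])
    cfg = SimConfig([plan],
                    ProfileConfig("a", 10**9, end_trim=0, sub_rate=0.0),
                    ProfileConfig("b", 2 * 10**9, end_trim=0, sub_rate=0.0,
                                  indel_rate=0.0),
                    seed=9)
    genome, truth = simulate_genome(cfg)
    a, b, events = simulate_assemblies(genome, truth, cfg)
    assert "".join(r.seq for r in a) == genome[0].seq
    assert "".join(r.seq for r in b) == genome[0].seq
    assert len(events) == 0 or not (events.event == "collapse").any()


# --- optical maps ---------------------------------------------------------

def test_zero_noise_maps_equal_digest():
    cfg = mini_config(seed=2)
    cfg.maps = MapConfig(sizing_sd_coeff=0.0, miss_rate=0.0,
                         false_per_100kb=0.0, n_replicates=1)
    genome, _ = simulate_genome(cfg)
    maps, origins = simulate_optical_maps(genome, cfg)
    dig = insilico_digest(genome[0], cfg.maps.motif, cfg.maps.min_label_spacing)
    m = [x for x in maps if origins[x.id][0] == genome[0].id][0]
    assert np.allclose(m.labels, dig.labels, atol=1e-6)


def test_miss_rate_matches_label_recall():
    cfg = mini_config(seed=2)
    cfg.maps = MapConfig(sizing_sd_coeff=0.0, miss_rate=0.1,
                         false_per_100kb=0.0, n_replicates=3)
    genome, _ = simulate_genome(cfg)
    maps, origins = simulate_optical_maps(genome, cfg)
    dig_counts = {r.id: insilico_digest(r, cfg.maps.motif,
                                        cfg.maps.min_label_spacing).n_labels
                  for r in genome}
    kept = sum(m.n_labels for m in maps)
    total = sum(dig_counts[origins[m.id][0]] for m in maps)
    recall = kept / total
    # binomial: 3 replicates x ~800 labels, sd ~ 0.006
    assert recall == pytest.approx(0.9, abs=0.02)


def test_maps_deterministic(mini_bundle):
    cfg = mini_bundle["cfg"]
    maps2, _ = simulate_optical_maps(mini_bundle["genome"], cfg)
    assert [(m.id, m.labels) for m in maps2] == \
        [(m.id, m.labels) for m in mini_bundle["maps"]]


# --- reads ----------------------------------------------------------------

def test_read_set_n50_and_depth():
    cfg = mini_config(seed=6)
    genome, _ = simulate_genome(cfg)
    profile = ReadProfile(n50=22_300, sub_rate=0.0, indel_rate=0.0, depth=20)
    reads = simulate_reads(genome, profile, cfg, salt=3, depth=20)
    lens = np.sort(np.array([len(r) for r in reads]))[::-1]
    cum = np.cumsum(lens)
    n50 = lens[np.searchsorted(cum, cum[-1] / 2)]
    assert abs(n50 - 22_300) / 22_300 < 0.10
    genome_bp = sum(len(r) for r in genome)
    assert abs(cum[-1] / genome_bp - 20) / 20 < 0.05


def test_error_free_reads_are_exact_substrings():
    cfg = mini_config(seed=6)
    genome, _ = simulate_genome(cfg)
    by_id = {r.id: r for r in genome}
    profile = ReadProfile(n50=8000, sub_rate=0.0, indel_rate=0.0, depth=0.5)
    reads = simulate_reads(genome, profile, cfg, salt=4)
    from mapweaver.core import reverse_complement

    assert reads
    for read in reads[:50]:
        (src, s, e, strand) = read.source_intervals[0]
        seq = by_id[src].seq[s:e]
        if strand == "-":
            seq = reverse_complement(seq)
        assert read.seq == seq


# --- ChIP -----------------------------------------------------------------

def test_chip_fold_enrichment_ratio():
    cfg = mini_config(seed=8)
    cfg.chip.fold = 10.0
    genome, truth = simulate_genome(cfg)
    chip, inp = simulate_chip(genome, truth.centromeres, cfg)
    cen = truth.centromeres[0]
    c = chip[cen.seq_id]
    inside = c[cen.start:cen.end].mean()
    outside = np.concatenate([c[:cen.start], c[cen.end:]]).mean()
    assert inside / outside == pytest.approx(10.0, rel=0.15)


def test_chip_fold_one_indistinguishable_from_input():
    from scipy.stats import ks_2samp

    cfg = mini_config(seed=8)
    cfg.chip.fold = 1.0
    genome, truth = simulate_genome(cfg)
    chip, inp = simulate_chip(genome, truth.centromeres, cfg)
    sid = genome[0].id
    # compare binned coverage distributions
    cb = chip[sid][:1_400_000].reshape(-1, 5000).sum(axis=1)
    ib = inp[sid][:1_400_000].reshape(-1, 5000).sum(axis=1)
    assert ks_2samp(cb, ib).pvalue > 0.01


def test_chip_zero_depth_errors():
    cfg = mini_config(seed=8)
    cfg.chip.depth = 0.0
    genome, truth = simulate_genome(cfg)
    with pytest.raises(Exception):
        simulate_chip(genome, truth.centromeres, cfg)


# --- markers --------------------------------------------------------------

def test_zero_noise_markers_are_monotone():
    cfg = mini_config(seed=9)
    cfg.markers.noise_sd = 0.0
    _, truth = simulate_genome(cfg)
    mk = simulate_markers(truth, cfg)
    for _, grp in mk.groupby("linkage_group"):
        grp = grp.sort_values("physical_bp")
        assert (np.diff(grp["genetic_pos"]) >= 0).all()


def test_nonunique_fraction_exercises_filters():
    from mapweaver.finishing import filter_markers

    cfg = mini_config(seed=9)
    cfg.markers.per_group = 300
    cfg.markers.frac_nonunique = 0.10
    cfg.markers.frac_lowmapq = 0.0
    _, truth = simulate_genome(cfg)
    mk = simulate_markers(truth, cfg)
    frac = 1.0 - mk["unique"].mean()
    assert frac == pytest.approx(0.10, abs=0.03)
    kept = filter_markers(mk, cap=10**9)
    assert len(kept) == int(mk["unique"].sum())


def test_markers_deterministic():
    cfg = mini_config(seed=9)
    _, truth = simulate_genome(cfg)
    m1 = simulate_markers(truth, cfg)
    m2 = simulate_markers(truth, cfg)
    assert m1.equals(m2)


def test_default_config_has_work_for_every_stage():
    """The default bundle plants, by design: two chimeras, one collapse,
    one heterozygous break, and one array exceeding both break
    thresholds."""
    cfg = default_config(seed=0)
    L_a = cfg.profile_a.break_over
    L_b = cfg.profile_b.break_over
    assert L_a < L_b
    assert len(cfg.chimera_joins) == 2
    collapses = [a for p in cfg.chromosomes for a in p.arrays
                 if a.collapse_frac > 0]
    assert len(collapses) == 1
    hets = [p for p in cfg.chromosomes if p.het_region]
    assert len(hets) == 1
    unsolvable = [a for p in cfg.chromosomes for a in p.arrays
                  if a.span > L_b]
    assert len(unsolvable) == 1
    solvable_chroms = [p for p in cfg.chromosomes
                       if all(a.span <= L_b for a in p.arrays)]
    assert len(solvable_chroms) == 2
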