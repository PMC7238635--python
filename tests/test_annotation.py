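"""Satellite scanning, array calling, k-mer uniqueness, enrichment-island
calling, mappability, coverage, Fisher co-occurrence and composition."""
import math
from fractions import Fraction

import numpy as np
import pytest

from mapweaver.annotate import (
    RepeatArray,
    RepeatHit,
    call_cenh3_domains,
    call_repeat_arrays,
    effective_genome_fraction,
    fisher_exact_2x2,
    interval_cooccurrence_fisher,
    low_coverage_regions,
    mappability_classes,
    repeat_composition,
    rpkm_enrichment,
    scan_repeat_monomers,
)
from mapweaver.core import FeatureInterval, MapweaverError, SequenceRecord
from mapweaver.simulate import consensus_monomer


def _dna(rng, n):
    return np.frombuffer(b"ACGT", dtype=np.uint8)[
        rng.integers(0, 4, n)].tobytes().decode()


# --- monomer scanning -----------------------------------------------------

def test_exact_tandem_units_counted():
    rng = np.random.default_rng(1)
    cons = SequenceRecord("mono", _dna(rng, 156))
    genome = [SequenceRecord("c", _dna(rng, 5000) + cons.seq * 10
                             + _dna(rng, 5000))]
    hits = scan_repeat_monomers(genome, cons)
    assert len(hits) == 1
    assert hits[0].units == 10
    assert hits[0].start == pytest.approx(5000, abs=160)
    assert hits[0].end == pytest.approx(5000 + 1560, abs=160)


def test_diverged_units_still_detected_at_07():
    rng = np.random.default_rng(2)
    cons = SequenceRecord("mono", _dna(rng, 156))
    units = []
    arr = np.frombuffer(cons.seq.encode(), np.uint8).copy()
    for _ in range(12):
        u = arr.copy()
        pos = rng.choice(156, size=31, replace=False)  # 20% divergence
        u[pos] = np.frombuffer(b"ACGT", np.uint8)[
            (np.searchsorted(np.frombuffer(b"ACGT", np.uint8), u[pos]) + 1) % 4]
        units.append(u.tobytes().decode())
    genome = [SequenceRecord("c", _dna(rng, 3000) + "".join(units)
                             + _dna(rng, 3000))]
    hits = scan_repeat_monomers(genome, cons, min_identity=0.7)
    assert sum(h.units for h in hits) == pytest.approx(12, abs=1)


def test_random_sequence_has_no_hits():
    rng = np.random.default_rng(3)
    cons = SequenceRecord("mono", _dna(rng, 156))
    genome = [SequenceRecord("c", _dna(rng, 100_000))]
    assert scan_repeat_monomers(genome, cons, min_identity=0.7) == []


def test_reverse_strand_units_found():
    from mapweaver.core import reverse_complement

    rng = np.random.default_rng(4)
    cons = SequenceRecord("mono", _dna(rng, 156))
    genome = [SequenceRecord("c", _dna(rng, 3000)
                             + reverse_complement(cons.seq * 8)
                             + _dna(rng, 3000))]
    hits = scan_repeat_monomers(genome, cons)
    assert sum(h.units for h in hits) == 8


def test_short_consensus_rejected():
    with pytest.raises(MapweaverError):
        scan_repeat_monomers([], SequenceRecord("m", "ACGT" * 10))


# --- array calling --------------------------------------------------------

def _hit(seq_id, start, end, family="knob180", units=None):
    return RepeatHit(seq_id, start, end, family, 0.9,
                     units or max(1, (end - start) // 180))


def test_knob_thresholds():
    # 600 kb cluster at 15% density -> knob
    hits = [_hit("c", i * 60_000, i * 60_000 + 9000) for i in range(10)]
    arrays = call_repeat_arrays(hits, "knob")
    assert len(arrays) == 1
    a = arrays[0]
    assert a.span >= 500_000 and a.density >= 0.10


def test_span_below_class_minimum_rejected_but_centc_class_passes():
    # 400 kb cluster at 40% density: not a knob (span), valid CentC-class
    hits = [_hit("c", i * 40_000, i * 40_000 + 16_000, "CentC")
            for i in range(10)]
    assert call_repeat_arrays(hits, "knob") == []
    assert len(call_repeat_arrays(hits, "centc")) == 1


def test_spacing_rule_splits_clusters():
    # two 300 kb clusters 150 kb apart: spacing > 100 kb keeps them apart,
    # and neither alone reaches the knob minimum
    left = [_hit("c", i * 60_000, i * 60_000 + 30_000) for i in range(5)]
    right = [_hit("c", 450_000 + i * 60_000, 450_000 + i * 60_000 + 30_000)
             for i in range(5)]
    assert call_repeat_arrays(left + right, "knob") == []
    # with a wider allowance they fuse into one qualifying knob
    assert len(call_repeat_arrays(left + right, "knob",
                                  max_spacing=200_000)) == 1


def test_density_sharp_at_10_percent():
    # nine blocks 66 kb apart; block length t sets the density of the
    # 528000+t cluster: t=5900 -> 0.0994 (fails), t=6000 -> 0.1011 (passes)
    for t, expect in ((5900, 0), (6000, 1)):
        hits = [_hit("c", i * 66_000, i * 66_000 + t) for i in range(9)]
        got = call_repeat_arrays(hits, "knob")
        assert len(got) == expect, t


def test_span_sharp_at_class_minimum():
    for end, expect in ((500_000, 1), (499_999, 0)):
        hits = [_hit("c", 0, 200_000), _hit("c", 300_000, end)]
        got = call_repeat_arrays(hits, "knob")
        assert len(got) == expect, end
    for end, expect in ((100_000, 1), (99_999, 0)):
        hits = [_hit("c", 0, 40_000, "CentC"), _hit("c", 60_000, end, "CentC")]
        got = call_repeat_arrays(hits, "centc")
        assert len(got) == expect, end


def test_subtelomeric_knobs_excluded():
    hits = [_hit("c", i * 60_000, i * 60_000 + 9000) for i in range(10)]
    windows = [FeatureInterval("c", 0, 200_000, "subtelomere_window")]
    assert call_repeat_arrays(hits, "knob", subtelomeric_windows=windows) == []
    other = [FeatureInterval("other", 0, 200_000, "subtelomere_window")]
    assert len(call_repeat_arrays(hits, "knob",
                                  subtelomeric_windows=other)) == 1


# --- effective genome fraction -------------------------------------------

def brute_force_unique_fraction(seqs, k):
    """Dictionary-count oracle over explicit canonical k-mer strings."""
    from mapweaver.core import reverse_complement

    counts = {}
    total = 0
    for s in seqs:
        for i in range(len(s) - k + 1):
            km = s[i:i + k]
            if "N" in km:
                continue
            can = min(km, reverse_complement(km))
            counts[can] = counts.get(can, 0) + 1
            total += 1
    if total == 0:
        raise ValueError("no valid k-mers")
    uniq = sum(c for c in counts.values() if c == 1)
    return uniq / total


def test_random_genome_nearly_all_unique():
    rng = np.random.default_rng(5)
    genome = [SequenceRecord("c", _dna(rng, 1_000_000))]
    assert effective_genome_fraction(genome, k=150) > 0.999


def test_duplicated_chromosome_fraction_zero():
    rng = np.random.default_rng(6)
    s = _dna(rng, 2000)
    genome = [SequenceRecord("c1", s), SequenceRecord("c2", s)]
    assert effective_genome_fraction(genome, k=150) == 0.0


def test_half_duplicated_matches_dictionary_oracle():
    rng = np.random.default_rng(7)
    u = _dna(rng, 3000)
    d = _dna(rng, 1500)
    seqs = [u + d + d]
    got = effective_genome_fraction([SequenceRecord("c", seqs[0])], k=31)
    want = brute_force_unique_fraction(seqs, 31)
    assert got == pytest.approx(want, abs=1e-12)


def test_all_sequences_too_short_error():
    with pytest.raises(MapweaverError):
        effective_genome_fraction([SequenceRecord("c", "ACGT")], k=150)


# --- CENH3 island calling -------------------------------------------------

def _tracks(rng, L=600_000, depth=30.0, read_len=150, fold_region=None,
            fold=1.0):
    n = int(depth * L / read_len)
    w = np.ones(L)
    if fold_region is not None:
        w[fold_region[0]:fold_region[1]] = fold
    chip_starts = rng.choice(L, size=n, p=w / w.sum())
    inp_starts = rng.choice(L, size=n)
    chip = np.zeros(L + read_len + 1)
    inp = np.zeros(L + read_len + 1)
    np.add.at(chip, chip_starts, 1)
    np.add.at(chip, chip_starts + read_len, -1)
    np.add.at(inp, inp_starts, 1)
    np.add.at(inp, inp_starts + read_len, -1)
    return ({"c": np.cumsum(chip)[:L]}, {"c": np.cumsum(inp)[:L]})


def test_planted_enrichment_recovered():
    rng = np.random.default_rng(8)
    chip, inp = _tracks(rng, fold_region=(200_000, 250_000), fold=10.0)
    islands = call_cenh3_domains(chip, inp, effective_fraction=1.0)
    assert len(islands) == 1
    isl = islands[0]
    assert isl.start <= 205_000 and isl.end >= 245_000  # +/- one bin
    assert isl.score > 250


def test_uniform_tracks_yield_no_islands():
    rng = np.random.default_rng(9)
    chip, inp = _tracks(rng)
    assert call_cenh3_domains(chip, inp, effective_fraction=1.0) == []


def test_threefold_excluded_by_fold_change_filter():
    rng = np.random.default_rng(10)
    chip, inp = _tracks(rng, fold_region=(200_000, 250_000), fold=3.0)
    islands = call_cenh3_domains(chip, inp, min_fc=4.0, effective_fraction=1.0)
    assert islands == []
    # the same signal passes once the fold filter allows it
    islands2 = call_cenh3_domains(chip, inp, min_fc=2.0, min_score=250,
                                  effective_fraction=1.0)
    assert len(islands2) == 1


def test_zero_depth_input_errors():
    with pytest.raises(MapweaverError):
        call_cenh3_domains({"c": np.ones(10_000)}, {"c": np.zeros(10_000)},
                           effective_fraction=1.0)


# --- mappability and coverage ---------------------------------------------

def test_mappability_examples():
    const = {"c": np.full(50_000, 30)}
    uniq, non = mappability_classes(const)
    assert non == [] and len(uniq) == 1 and uniq[0].length == 50_000

    low = {"c": np.ones(20_000, dtype=int)}
    uniq, non = mappability_classes(low)
    assert uniq == [] and non[0].length == 20_000

    # two non-unique runs 800 bp apart merge into one island (<= 1 kb rule)
    d = np.full(30_000, 30)
    d[1000:2000] = 1
    d[2800:3800] = 200
    uniq, non = mappability_classes({"c": d})
    assert len(non) == 1
    assert (non[0].start, non[0].end) == (1000, 3800)


def test_low_coverage_regions_and_nesting():
    d = np.full(10_000, 10)
    d[100:200] = 2
    d[5000:5400] = 1
    track = {"c": d}
    lt3 = low_coverage_regions(track, 3)
    lt2 = low_coverage_regions(track, 2)
    assert [(r.start, r.end) for r in lt3] == [(100, 200), (5000, 5400)]
    assert [(r.start, r.end) for r in lt2] == [(5000, 5400)]
    # monotonicity: the min-2 set is nested inside the min-3 set
    for r in lt2:
        assert any(q.start <= r.start and r.end <= q.end for q in lt3)
    whole = low_coverage_regions({"c": np.zeros(500, dtype=int)}, 3)
    assert [(r.start, r.end) for r in whole] == [(0, 500)]


def test_single_low_position():
    d = np.full(1000, 10)
    d[500] = 2
    assert [(r.start, r.end)
            for r in low_coverage_regions({"c": d}, 3)] == [(500, 501)]


# --- RPKM enrichment ------------------------------------------------------

def test_rpkm_identities():
    feats = {"f1": 1000, "f2": 4000}
    chip = {"f1": 100.0, "f2": 400.0}
    ratios = rpkm_enrichment(chip, chip, feats, 1e6, 1e6)
    assert ratios == {"f1": pytest.approx(1.0), "f2": pytest.approx(1.0)}
    # doubling ChIP depth everywhere leaves ratios unchanged
    chip2 = {k: 2 * v for k, v in chip.items()}
    ratios2 = rpkm_enrichment(chip2, chip, feats, 2e6, 1e6)
    assert ratios2["f1"] == pytest.approx(1.0)
    # 5x local enrichment at matched depth
    ratios3 = rpkm_enrichment({"f1": 500.0}, {"f1": 100.0}, {"f1": 1000},
                              1e6, 1e6)
    assert ratios3["f1"] == pytest.approx(5.0)


def test_rpkm_zero_input_reported_absent():
    out = rpkm_enrichment({"f": 10.0}, {"f": 0.0}, {"f": 1000}, 1e6, 1e6)
    assert out["f"] is None


# --- Fisher ---------------------------------------------------------------

def fisher_oracle(a, b, c, d):
    """Fractions-based enumeration over all tables with the same margins."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(c1, r1)
    obs = Fraction(math.comb(r1, a) * math.comb(r2, c1 - a))
    total = Fraction(0)
    tail = Fraction(0)
    for x in range(lo, hi + 1):
        w = Fraction(math.comb(r1, x) * math.comb(r2, c1 - x))
        total += w
        if w <= obs:
            tail += w
    return tail / total


def test_fisher_constructed_example():
    odds, p = fisher_exact_2x2(1, 9, 11, 3)
    assert p == pytest.approx(float(fisher_oracle(1, 9, 11, 3)), abs=1e-12)
    # the one-sided lower tail of this table is ~0.0013; the two-sided sum
    # of all equally-or-less-probable tables is ~0.00276
    assert p == pytest.approx(0.00276, abs=5e-5)
    assert odds == pytest.approx((1 * 3) / (9 * 11))


def test_fisher_matches_oracle_on_random_tables(rng):
    for _ in range(60):
        a, b, c, d = (int(x) for x in rng.integers(0, 26, 4))
        if a + b + c + d == 0:
            continue
        _, p = fisher_exact_2x2(a, b, c, d)
        assert p == pytest.approx(float(fisher_oracle(a, b, c, d)), abs=1e-12)


def test_fisher_agrees_with_scipy():
    from scipy.stats import fisher_exact as scipy_fisher

    rng = np.random.default_rng(17)
    for _ in range(20):
        a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
        if a + b + c + d == 0:
            continue
        _, p = fisher_exact_2x2(a, b, c, d)
        assert p == pytest.approx(scipy_fisher([[a, b], [c, d]])[1], abs=1e-9)


def test_interval_cooccurrence_degenerate_and_flank():
    lengths = {"c": 10_000}
    set_a = [FeatureInterval("c", 2000, 3000, "a")]
    # b exactly equals expanded a (flank 500): maximal association
    set_b = [FeatureInterval("c", 1500, 3500, "b")]
    odds, p = interval_cooccurrence_fisher(set_a, set_b, lengths, flank=500)
    assert odds is None or odds == math.inf  # off-diagonal zero cell
    assert p < 1e-200
    # disjoint b gives no association (p near 1 impossible to exceed)
    far_b = [FeatureInterval("c", 8000, 8100, "b")]
    _, p2 = interval_cooccurrence_fisher(set_a, far_b, lengths, flank=500)
    assert p2 < 1.0 or p2 == 1.0


def test_interval_fisher_unknown_sequence_errors():
    with pytest.raises(MapweaverError):
        interval_cooccurrence_fisher([FeatureInterval("zz", 0, 10, "x")], [],
                                     {"c": 100})


# --- composition ----------------------------------------------------------

def test_repeat_composition_flattening():
    arr = RepeatArray("c", 0, 10_000, "knob180", 0.5, 20)
    ann = [FeatureInterval("c", 0, 5000, "CinfulZeon-like"),
           FeatureInterval("c", 1000, 4000, "CinfulZeon-like"),  # nested
           FeatureInterval("c", 6000, 7000, "CRM-like")]
    comp = repeat_composition([arr], ann)
    fracs = comp[("c", 0, 10_000)]
    assert fracs["CinfulZeon-like"] == pytest.approx(0.5)
    assert fracs["CRM-like"] == pytest.approx(0.1)
    # one TE covering half an array, alone
    comp2 = repeat_composition([arr], [ann[0]])
    assert comp2[("c", 0, 10_000)]["CinfulZeon-like"] == pytest.approx(0.5)
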