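"""Gap filling, telomere extension, marker filtering, scaffold ordering
and pseudomolecule emission."""
import numpy as np
import pandas as pd
import pytest

from mapweaver.core import MapweaverError, SequenceRecord, find_n_gaps, reverse_complement
from mapweaver.finishing import (
    emit_pseudomolecules,
    extend_telomeres,
    fill_gaps,
    filter_markers,
    order_orient,
    reconstruct_from_agp,
    terminal_tract_length,
)


def _dna(rng, n):
    return np.frombuffer(b"ACGT", dtype=np.uint8)[
        rng.integers(0, 4, n)].tobytes().decode()


# --- gap filling ----------------------------------------------------------

@pytest.fixture(scope="module")
def gap_scene():
    rng = np.random.default_rng(10)
    truth = _dna(rng, 60_000)
    scaffold = SequenceRecord(
        "s", truth[:25_000] + "N" * 5000 + truth[30_000:])
    return {"truth": truth, "scaffold": scaffold, "rng": rng}


def test_spanning_read_closes_gap(gap_scene):
    truth = gap_scene["truth"]
    read = SequenceRecord("r1", truth[20_000:40_000])
    filled, reports = fill_gaps([gap_scene["scaffold"]], [read])
    assert [r.action for r in reports if r.action != "unchanged"] == ["closed"]
    assert find_n_gaps(filled[0]) == []
    assert filled[0].seq == truth


def test_reverse_strand_spanning_read_closes_gap(gap_scene):
    truth = gap_scene["truth"]
    read = SequenceRecord("r1", reverse_complement(truth[20_000:40_000]))
    filled, reports = fill_gaps([gap_scene["scaffold"]], [read])
    assert find_n_gaps(filled[0]) == []
    assert filled[0].seq == truth


def test_no_read_leaves_gap_unchanged(gap_scene):
    rng = np.random.default_rng(55)
    noise_read = SequenceRecord("r", _dna(rng, 15_000))
    filled, reports = fill_gaps([gap_scene["scaffold"]], [noise_read], n_iter=3)
    assert filled[0].seq == gap_scene["scaffold"].seq


def test_wildly_inconsistent_span_rejected(gap_scene):
    """A read whose flank-to-flank span is far off the estimated gap size
    does not patch it."""
    truth = gap_scene["truth"]
    # fabricate a read with 50 kb of foreign sequence between the flanks
    rng = np.random.default_rng(56)
    read = SequenceRecord(
        "r1", truth[20_000:25_000] + _dna(rng, 50_000) + truth[30_000:40_000])
    filled, reports = fill_gaps([gap_scene["scaffold"]], [read],
                                max_gap_delta=2.0)
    gaps = find_n_gaps(filled[0])
    assert len(gaps) == 1  # not closed by the inconsistent read


def test_single_flank_reads_shrink_but_never_close(gap_scene):
    truth = gap_scene["truth"]
    left = SequenceRecord("rl", truth[20_000:28_000])   # 3 kb into the gap
    right = SequenceRecord("rr", truth[27_500:40_000])
    filled, reports = fill_gaps([gap_scene["scaffold"]], [left, right],
                                n_iter=1, max_extension=5000)
    gaps = find_n_gaps(filled[0])
    assert len(gaps) == 1
    assert gaps[0].length < 5000  # shrunk
    assert gaps[0].length >= 13   # never fully closed without a spanning read
    total_n = sum(g.length for g in find_n_gaps(filled[0]))
    assert total_n < 5000


def test_gap_fill_never_increases_gap_length(mini_run):
    res = mini_run["res"]
    before = sum(g.length for s in res.stages["step4"] for g in find_n_gaps(s))
    after = sum(g.length for s in res.stages["finishing"]
                for g in find_n_gaps(s))
    assert after <= before


# --- telomere extension ---------------------------------------------------

@pytest.fixture(scope="module")
def telo_scene():
    rng = np.random.default_rng(20)
    unit = "TTTAGGG"
    chrom = (reverse_complement(unit) * 400 + _dna(rng, 50_000)
             + unit * 400)  # 2.8 kb telomere tracts both ends
    scaffold = SequenceRecord("s", chrom[2000:-2000])
    return {"chrom": chrom, "scaffold": scaffold, "rng": rng, "unit": unit}


def test_terminal_tract_lengths():
    unit = "TTTAGGG"
    seq = _dna(np.random.default_rng(3), 5000) + unit * 200
    assert terminal_tract_length(seq, unit, "3") >= 1395
    assert terminal_tract_length(seq, unit, "5") < 50
    rc_seq = reverse_complement(seq)
    assert terminal_tract_length(rc_seq, unit, "5") >= 1395


def test_telomere_read_extends_scaffold_end(telo_scene):
    chrom = telo_scene["chrom"]
    read = SequenceRecord("r1", chrom[-15_000:])  # includes 2.8 kb tract
    ext, reports = extend_telomeres([telo_scene["scaffold"]], [read])
    assert len(reports) == 1
    assert reports[0].end == "3"
    assert ext[0].seq.endswith(chrom[-50:])
    assert terminal_tract_length(ext[0].seq[-4000:], "TTTAGGG", "3") >= 1000


def test_five_prime_end_uses_c_rich_strand(telo_scene):
    chrom = telo_scene["chrom"]
    read = SequenceRecord("r1", chrom[:15_000])
    ext, reports = extend_telomeres([telo_scene["scaffold"]], [read])
    assert len(reports) == 1 and reports[0].end == "5"
    assert ext[0].seq.startswith(chrom[:50])


def test_short_tract_not_a_candidate(telo_scene):
    chrom = telo_scene["chrom"]
    # a read whose terminal tract is only ~0.9 kb
    read = SequenceRecord("r1", chrom[-12_200 - 900:len(chrom) - 1900])
    base = telo_scene["scaffold"]
    ext, reports = extend_telomeres([base], [read], min_tract=1000)
    assert reports == []
    ext2, reports2 = extend_telomeres([base], [read], min_tract=800)
    assert len(reports2) == 1  # same read passes a lower floor


def test_multi_locus_read_excluded(telo_scene):
    """A read anchoring at two loci is not uniquely mapped and never
    extends an end."""
    chrom = telo_scene["chrom"]
    rng = np.random.default_rng(30)
    interior = telo_scene["scaffold"].seq[20_000:30_000]
    two_locus = SequenceRecord("r1", chrom[-12_000:] + interior)
    ext, reports = extend_telomeres([telo_scene["scaffold"]], [two_locus])
    assert reports == []


def test_longest_candidate_wins(telo_scene):
    chrom = telo_scene["chrom"]
    short = SequenceRecord("r_short", chrom[-9000:])
    long = SequenceRecord("r_long", chrom[-15_000:])
    ext, reports = extend_telomeres([telo_scene["scaffold"]], [short, long])
    assert [r.read_id for r in reports] == ["r_long"]


def test_extension_touches_only_termini(telo_scene):
    chrom = telo_scene["chrom"]
    read = SequenceRecord("r1", chrom[-15_000:])
    base = telo_scene["scaffold"]
    ext, _ = extend_telomeres([base], [read])
    # interior untouched: the original scaffold is a prefix of the result
    assert ext[0].seq[:len(base)] == base.seq


# --- marker filtering -----------------------------------------------------

def _marker_df(rows):
    return pd.DataFrame(rows, columns=["marker_id", "scaffold_id",
                                       "physical_bp", "linkage_group",
                                       "genetic_pos", "mapq", "unique"])


def test_marker_filters_are_strict_at_the_boundary():
    rows = []
    for i in range(20):  # exactly 20 markers: excluded ("more than 20")
        rows.append((f"a{i}", "s20", i * 1000, "lg1", float(i), 60, True))
    for i in range(21):  # 21 markers: kept
        rows.append((f"b{i}", "s21", i * 1000, "lg1", float(i), 60, True))
    out = filter_markers(_marker_df(rows))
    assert set(out["scaffold_id"]) == {"s21"}


def test_mapq_threshold_strict():
    rows = [(f"m{i}", "s", i * 1000, "lg1", float(i), 31 if i % 2 else 30, True)
            for i in range(60)]
    out = filter_markers(_marker_df(rows))
    assert (out["mapq"] >= 31).all()
    assert len(out) == 30


def test_nonunique_markers_dropped():
    rows = [(f"m{i}", "s", i * 1000, "lg1", float(i), 60, i % 3 != 0)
            for i in range(90)]
    out = filter_markers(_marker_df(rows))
    assert len(out) == 60


def test_cap_keeps_100_evenly_spaced_with_ends():
    rows = [(f"m{i}", "s", i * 997, "lg1", float(i), 60, True)
            for i in range(250)]
    out = filter_markers(_marker_df(rows), cap=100)
    assert len(out) == 100
    phys = sorted(out["physical_bp"])
    assert phys[0] == 0 and phys[-1] == 249 * 997
    spacing = np.diff(phys)
    assert spacing.max() <= 3 * spacing.min()  # roughly even


# --- ordering and orientation --------------------------------------------

def _group_markers(arrangement, n_per=10, noise=0.0, rng=None):
    """Markers for scaffolds laid out in a known true order/orientation."""
    rows = []
    pos_cm = 0.0
    for sid, orient in arrangement:
        cms = np.arange(n_per) + pos_cm
        if orient == "-":
            phys = np.arange(n_per)[::-1] * 1000
        else:
            phys = np.arange(n_per) * 1000
        for i in range(n_per):
            g = float(cms[i])
            if rng is not None and noise:
                g += rng.normal(0, noise)
            rows.append({"marker_id": f"{sid}_{i}", "scaffold_id": sid,
                         "physical_bp": int(phys[i]), "linkage_group": "lg1",
                         "genetic_pos": g, "mapq": 60, "unique": True})
        pos_cm += n_per
    return pd.DataFrame(rows)


def test_three_scaffolds_true_order_recovered():
    truth = [("s1", "+"), ("s2", "-"), ("s3", "+")]
    markers = _group_markers(truth)
    out = order_orient(markers)
    assert out["lg1"] == truth


def test_single_scaffold_orientation_follows_marker_trend():
    up = _group_markers([("s1", "+")])
    down = _group_markers([("s1", "-")])
    assert order_orient(up)["lg1"] == [("s1", "+")]
    assert order_orient(down)["lg1"] == [("s1", "-")]


def test_heuristic_matches_exhaustive_on_small_groups():
    rng = np.random.default_rng(77)
    for trial in range(6):
        n = int(rng.integers(3, 7))
        truth = [(f"s{i}", "+-"[rng.integers(0, 2)]) for i in range(n)]
        markers = _group_markers(truth, n_per=8, noise=0.5, rng=rng)
        exact = order_orient(markers, exhaustive_max=8)
        heur = order_orient(markers, exhaustive_max=0)
        from mapweaver.finishing import _arrangement_objective

        # compare objective values (several arrangements can tie)
        def obj(arr):
            per_source = {}
            markers2 = markers.assign(source="default")
            import mapweaver.finishing as fin

            grp = markers2
            sgrp = grp.sort_values(["scaffold_id", "physical_bp"],
                                   kind="mergesort")
            granks = fin._rank(sgrp["genetic_pos"].to_numpy())
            per_scaf = {}
            for sid in sorted(grp["scaffold_id"].unique()):
                mask = (sgrp["scaffold_id"] == sid).to_numpy()
                per_scaf[sid] = {"granks": granks[mask]}
            return _arrangement_objective(arr, {"default": (1.0, per_scaf)})[0]

        assert obj(heur["lg1"]) == pytest.approx(obj(exact["lg1"]), abs=1e-9)


def test_empty_group_errors():
    with pytest.raises(MapweaverError):
        order_orient(_marker_df([]))


# --- pseudomolecules ------------------------------------------------------

def test_pseudomolecule_arithmetic_and_agp_round_trip():
    rng = np.random.default_rng(8)
    s1 = SequenceRecord("s1", _dna(rng, 10_000))
    s2 = SequenceRecord("s2", _dna(rng, 5_000))
    recs, agp = emit_pseudomolecules({"1": [("s1", "+"), ("s2", "-")]},
                                     [s1, s2], inter_gap=100)
    assert len(recs) == 1
    assert len(recs[0]) == 15_100
    rebuilt = reconstruct_from_agp(agp, {"s1": s1, "s2": s2})
    assert rebuilt[0].seq == recs[0].seq
    gap_rows = [r for r in agp if r.is_gap]
    assert len(gap_rows) == 1 and gap_rows[0].gap_kind == "scaffold"


def test_empty_ordering_errors():
    with pytest.raises(MapweaverError):
        emit_pseudomolecules({}, [])
    with pytest.raises(MapweaverError):
        emit_pseudomolecules({"1": []}, [])
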