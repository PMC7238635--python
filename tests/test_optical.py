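"""In-silico digestion and the label-map aligner, checked against an
independent brute-force enumeration of monotone pairings."""
import itertools
import math

import numpy as np
import pytest

from mapweaver.core import LabelMap, MapweaverError, SequenceRecord, reverse_complement
from mapweaver.optical import (
    MATCH_BONUS,
    AlignParams,
    align_label_maps,
    fit_stretch,
    insilico_digest,
    rescale_map,
)


# --- independent oracle ---------------------------------------------------

def brute_force_best(query: LabelMap, ref: LabelMap, params: AlignParams):
    """Best monotone pairing by exhaustive enumeration, scored with an
    independent implementation of the model: each pair earns the match
    bonus; each transition pays delta^2/(coeff^2*mean) plus the miss
    penalty per skipped label.  Tries both orientations."""
    best = (-math.inf, None, None)
    r = ref.labels
    for orientation in ("+", "-"):
        if orientation == "+":
            q = query.labels
        else:
            q = [query.length_bp + 1.0 - x for x in reversed(query.labels)]
        nq, nr = len(q), len(r)
        for m in range(params.min_pairs, min(nq, nr) + 1):
            for q_idx in itertools.combinations(range(nq), m):
                for r_idx in itertools.combinations(range(nr), m):
                    score = MATCH_BONUS
                    for t in range(1, m):
                        qlen = q[q_idx[t]] - q[q_idx[t - 1]]
                        rlen = r[r_idx[t]] - r[r_idx[t - 1]]
                        mean = 0.5 * (qlen + rlen)
                        delta = qlen - rlen
                        skips = (q_idx[t] - q_idx[t - 1] - 1
                                 + r_idx[t] - r_idx[t - 1] - 1)
                        score += (MATCH_BONUS
                                  - delta * delta
                                  / (params.sizing_sd_coeff ** 2 * mean)
                                  - params.miss_penalty * skips)
                    if score > best[0]:
                        best = (score, orientation, (q_idx, r_idx))
    return best


def random_map(rng, n_labels, mean_interval=5000.0):
    intervals = rng.uniform(0.3 * mean_interval, 2.0 * mean_interval, n_labels)
    labels = np.cumsum(intervals) + 500.0
    return LabelMap(f"m{rng.integers(1e9)}", float(labels[-1] + 500.0),
                    labels.tolist())


def exhaustive_params():
    # full-width band so the DP searches the same space the oracle does;
    # the confidence floor sits at the single-pair bonus: a local
    # alignment scoring no more than one isolated matched pair is not a
    # reportable alignment, for the DP and the oracle alike
    return AlignParams(sizing_sd_coeff=3.0, miss_penalty=3.0, min_pairs=2,
                       min_confidence=MATCH_BONUS / math.log(10.0) + 1e-9,
                       band_labels=10)


# --- digestion ------------------------------------------------------------

def test_digest_single_exact_match():
    lm = insilico_digest(SequenceRecord("x", "CTTAAG"), min_label_spacing=1)
    assert lm.labels == [1.0]


def test_digest_two_matches_linear_scan_oracle():
    seq = "CTTAAGCTTAAG"
    lm = insilico_digest(SequenceRecord("x", seq), min_label_spacing=1)
    # independent linear scan
    expected = [i + 1 for i in range(len(seq)) if seq[i:i + 6] == "CTTAAG"]
    assert lm.labels == [float(p) for p in expected] == [1.0, 7.0]


def test_digest_no_occurrences(rng):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
    seq = seq.replace("CTTAAG", "CTTACG")
    lm = insilico_digest(SequenceRecord("x", seq))
    assert lm.labels == []
    assert lm.length_bp == len(seq)


def test_digest_collapses_close_labels():
    seq = "CTTAAG" + "A" * 100 + "CTTAAG" + "A" * 2000 + "CTTAAG"
    lm = insilico_digest(SequenceRecord("x", seq), min_label_spacing=800)
    assert len(lm.labels) == 2
    assert lm.labels[0] == pytest.approx((1 + 107) / 2, abs=1)


def test_digest_n_runs_produce_no_labels():
    lm = insilico_digest(SequenceRecord("x", "CTTAAG" + "N" * 50 + "CTTAAG"),
                         min_label_spacing=1)
    assert lm.labels == [1.0, 57.0]


def test_digest_motif_validation():
    with pytest.raises(MapweaverError):
        insilico_digest(SequenceRecord("x", "ACGT"), motif="CTN")
    with pytest.raises(MapweaverError):
        insilico_digest(SequenceRecord("x", "ACGT"), motif="CTNAAG")


# --- aligner --------------------------------------------------------------

def test_self_alignment_pairs_everything():
    rng = np.random.default_rng(5)
    m = random_map(rng, 7)
    params = exhaustive_params()
    alns = align_label_maps(m, m, params)
    best = alns[0]
    assert best.orientation == "+"
    assert best.n_pairs == 7
    assert best.pairs == [(i, i) for i in range(7)]
    assert best.score == pytest.approx(7 * MATCH_BONUS)


def test_confidence_calibration_ten_perfect_pairs():
    """A perfect 10-pair alignment over ~10 kb intervals reaches
    confidence >= 20."""
    labels = (np.arange(10) * 10_000.0 + 5000.0).tolist()
    m = LabelMap("m", 100_000.0, labels)
    best = align_label_maps(m, m, exhaustive_params())[0]
    assert best.n_pairs == 10
    assert best.confidence >= 20


def test_alignment_with_deleted_labels_matches_brute_force():
    rng = np.random.default_rng(11)
    ref = random_map(rng, 7)
    kept = [0, 1, 2, 5, 6]  # labels 3 and 4 (0-based) deleted from query
    q_labels = [ref.labels[i] for i in kept]
    query = LabelMap("q", ref.length_bp, q_labels)
    params = exhaustive_params()
    best = align_label_maps(query, ref, params)[0]
    oracle_score, oracle_orient, (qi, ri) = brute_force_best(query, ref, params)
    assert best.score == pytest.approx(oracle_score, rel=1e-9)
    assert best.orientation == oracle_orient == "+"
    assert [p[1] for p in best.pairs] == list(ri) == kept
    # two ref-side labels skipped inside the alignment
    skips = sum(b - a - 1 for a, b in zip(kept, kept[1:]))
    assert skips == 2


def test_reversal_symmetry():
    rng = np.random.default_rng(21)
    ref = random_map(rng, 8)
    query = LabelMap("q", ref.length_bp, ref.labels)
    flipped = LabelMap("qr", ref.length_bp,
                       sorted(ref.length_bp + 1.0 - np.array(ref.labels)))
    params = exhaustive_params()
    fwd = align_label_maps(query, ref, params)[0]
    rev = align_label_maps(flipped, ref, params)[0]
    assert rev.score == pytest.approx(fwd.score, rel=1e-9)
    assert fwd.orientation == "+" and rev.orientation == "-"
    assert rev.n_pairs == fwd.n_pairs


def test_dp_matches_brute_force_on_random_instances():
    """A handful of random small instances here; the full 50-instance sweep
    runs in the acceptance suite."""
    rng = np.random.default_rng(42)
    params = exhaustive_params()
    for _ in range(8):
        nq = int(rng.integers(3, 7))
        nr = int(rng.integers(3, 7))
        q = random_map(rng, nq)
        r = random_map(rng, nr)
        alns = align_label_maps(q, r, params)
        oracle_score, _, _ = brute_force_best(q, r, params)
        if oracle_score > MATCH_BONUS:
            assert alns and alns[0].score == pytest.approx(oracle_score, rel=1e-9)
        else:
            assert not alns


def test_score_invariant_under_translation():
    rng = np.random.default_rng(31)
    q = random_map(rng, 8)
    r = random_map(rng, 8)
    params = exhaustive_params()
    a1 = align_label_maps(q, r, params)
    q2 = LabelMap(q.id, q.length_bp + 10_000, [x + 10_000 for x in q.labels])
    r2 = LabelMap(r.id, r.length_bp + 3_000, [x + 3_000 for x in r.labels])
    a2 = align_label_maps(q2, r2, params)
    assert len(a1) == len(a2)
    if a1:
        assert a2[0].score == pytest.approx(a1[0].score, rel=1e-9)


def test_too_few_labels_returns_empty():
    q = LabelMap("q", 1000, [100.0])
    r = LabelMap("r", 1000, [100.0, 500.0, 900.0])
    assert align_label_maps(q, r, AlignParams(min_pairs=2)) == []


# --- rescaling ------------------------------------------------------------

def test_fit_stretch_identity():
    rng = np.random.default_rng(3)
    m = random_map(rng, 10)
    aln = align_label_maps(m, m, exhaustive_params())[0]
    assert fit_stretch(aln, m, m) == pytest.approx(1.0)


def test_fit_stretch_uniform_scaling_closed_form():
    rng = np.random.default_rng(4)
    ref = random_map(rng, 10)
    query = LabelMap("q", ref.length_bp * 1.02,
                     [x * 1.02 for x in ref.labels])
    aln = align_label_maps(query, ref,
                           AlignParams(sizing_sd_coeff=30, min_pairs=2,
                                       min_confidence=0.1, band_labels=10))[0]
    s = fit_stretch(aln, query, ref)
    assert s == pytest.approx(1 / 1.02, abs=1e-9)
    # applying the factor minimises the summed squared interval deltas
    scaled = rescale_map(query, s)
    q = np.diff(np.array(scaled.labels))
    r = np.diff(np.array(ref.labels))
    base = np.sum((q - r) ** 2)
    for eps in (0.999, 1.001):
        q_eps = q * eps
        assert np.sum((q_eps - r) ** 2) >= base


def test_fit_stretch_needs_three_pairs():
    m = LabelMap("m", 10_000, [1000.0, 2000.0, 3000.0])
    aln = align_label_maps(m, m, AlignParams(min_pairs=2, min_confidence=0.1,
                                             band_labels=5))[0]
    aln.pairs = aln.pairs[:2]
    with pytest.raises(MapweaverError, match="insufficient pairs"):
        fit_stretch(aln, m, m)
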