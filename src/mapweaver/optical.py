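"""In-silico digestion and dynamic-programming label-map alignment.

The aligner scores a monotone pairing of query and reference labels.  Each
matched pair earns a fixed bonus ``MATCH_BONUS``; each transition between
consecutive matched pairs pays a sizing penalty

    delta^2 / (sizing_sd_coeff^2 * mean_interval)

where ``delta`` is the difference between the matched query and reference
interval lengths, plus ``miss_penalty`` per label skipped on either side.
This mirrors the standard optical-map error model in which interval sizing
error grows with the square root of interval length, so the penalty is the
squared z-score of the observed interval discrepancy.

The DP is local (alignments may start and end anywhere), tries both
orientations, and limits consecutive skips to ``band_labels`` per side for
speed; with ``band_labels >= n`` it searches the full monotone-pairing
space exactly.

Confidence is ``max(score, 0) / ln(10)`` — monotone in score, and scaled so
a perfect 10-pair alignment scores >= 20.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import LabelMap, MapAlignment, MapweaverError, SequenceRecord

MATCH_BONUS = 5.0

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap


@dataclass
class AlignParams:
    """Tunables for the label-map aligner.

    sizing_sd_coeff: sd of interval-length error = coeff * sqrt(interval bp).
    miss_penalty: cost per skipped (unmatched) label inside an alignment.
    min_pairs: minimum matched pairs for a reported alignment (>= 2).
    min_confidence: minimum reported confidence.
    band_labels: maximum consecutive skipped labels per side in the DP.
    """

    sizing_sd_coeff: float = 3.0
    miss_penalty: float = 3.0
    min_pairs: int = 8
    min_confidence: float = 20.0
    band_labels: int = 6

    def __post_init__(self) -> None:
        if min(self.sizing_sd_coeff, self.miss_penalty, self.min_confidence) < 0:
            raise MapweaverError("AlignParams fields must be positive")
        if self.min_pairs < 2:
            raise MapweaverError("min_pairs must be >= 2")
        if self.band_labels < 1:
            raise MapweaverError("band_labels must be >= 1")


def insilico_digest(record: SequenceRecord, motif: str = "CTTAAG",
                    min_label_spacing: int = 800) -> LabelMap:
    """Label map of motif occurrences in a sequence (1-based start positions).

    Both strands are scanned; for a palindromic motif such as the default
    CTTAAG (its own reverse complement) the reverse-strand scan adds
    nothing.  Occurrences closer than ``min_label_spacing`` are collapsed to
    the midpoint of the run, emulating optical resolution.  N runs carry no
    labels.
    """
    motif = motif.upper()
    if len(motif) < 4:
        raise MapweaverError("digest motif must be >= 4 bp")
    if set(motif) - set("ACGT"):
        raise MapweaverError(f"digest motif {motif!r} must be ACGT only")
    from .core import reverse_complement

    seq = record.seq
    positions: set[int] = set()
    for m in (motif, reverse_complement(motif)):
        start = seq.find(m)
        while start != -1:
            positions.add(start + 1)  # 1-based
            start = seq.find(m, start + 1)
        if m == motif and motif == reverse_complement(motif):
            break
    pos = sorted(positions)
    # collapse runs of labels closer than min_label_spacing to their midpoint
    collapsed: list[float] = []
    i = 0
    while i < len(pos):
        j = i
        while j + 1 < len(pos) and pos[j + 1] - pos[j] < min_label_spacing:
            j += 1
        collapsed.append(round((pos[i] + pos[j]) / 2.0))
        i = j + 1
    return LabelMap(record.id, float(len(seq)), collapsed, source="sequence_digest")


@njit(cache=True)
def _dp_kernel(q, r, coeff, miss, band, bonus):  # pragma: no cover - numba
    nq, nr = q.size, r.size
    S = np.empty((nq, nr), dtype=np.float64)
    BI = np.full((nq, nr), -1, dtype=np.int32)
    BJ = np.full((nq, nr), -1, dtype=np.int32)
    c2 = coeff * coeff
    for i in range(nq):
        for j in range(nr):
            best = bonus
            bi = -1
            bj = -1
            for di in range(1, band + 1):
                pi = i - di
                if pi < 0:
                    break
                qlen = q[i] - q[pi]
                for dj in range(1, band + 1):
                    pj = j - dj
                    if pj < 0:
                        break
                    rlen = r[j] - r[pj]
                    mean = 0.5 * (qlen + rlen)
                    if mean <= 0.0:
                        continue
                    delta = qlen - rlen
                    cand = (S[pi, pj] + bonus - delta * delta / (c2 * mean)
                            - miss * (di - 1 + dj - 1))
                    if cand > best:
                        best = cand
                        bi = pi
                        bj = pj
            S[i, j] = best
            BI[i, j] = bi
            BJ[i, j] = bj
    return S, BI, BJ


def _dp_python(q, r, coeff, miss, band, bonus):
    nq, nr = q.size, r.size
    S = np.empty((nq, nr))
    BI = np.full((nq, nr), -1, dtype=np.int32)
    BJ = np.full((nq, nr), -1, dtype=np.int32)
    c2 = coeff * coeff
    for i in range(nq):
        row = np.full(nr, bonus)
        bi = np.full(nr, -1, dtype=np.int32)
        bj = np.full(nr, -1, dtype=np.int32)
        for di in range(1, min(band, i) + 1):
            qlen = q[i] - q[i - di]
            for dj in range(1, band + 1):
                if dj > nr - 1:
                    break
                rlen = r[dj:] - r[:-dj]
                mean = 0.5 * (qlen + rlen)
                delta = qlen - rlen
                cand = (S[i - di, : nr - dj] + bonus - delta * delta / (c2 * mean)
                        - miss * (di - 1 + dj - 1))
                upd = cand > row[dj:]
                if upd.any():
                    row[dj:][upd] = cand[upd]
                    bi[dj:][upd] = i - di
                    idx = np.nonzero(upd)[0]
                    bj[dj:][upd] = idx
        S[i] = row
        BI[i] = bi
        BJ[i] = bj
    return S, BI, BJ


def _run_dp(q, r, params: AlignParams):
    if _HAVE_NUMBA:
        return _dp_kernel(q, r, params.sizing_sd_coeff, params.miss_penalty,
                          params.band_labels, MATCH_BONUS)
    return _dp_python(q, r, params.sizing_sd_coeff, params.miss_penalty,
                      params.band_labels, MATCH_BONUS)


def _extract(S, BI, BJ, min_pairs, min_score, max_alignments=10):
    """Greedy best-first extraction of non-conflicting local alignments."""
    nq, nr = S.shape
    used_q = np.zeros(nq, dtype=bool)
    used_r = np.zeros(nr, dtype=bool)
    flat = np.argsort(S, axis=None)[::-1]
    results = []
    for idx in flat:
        if len(results) >= max_alignments:
            break
        i, j = divmod(int(idx), nr)
        if S[i, j] < min_score:
            break
        if used_q[i] or used_r[j]:
            continue
        path = []
        ci, cj = i, j
        ok = True
        while ci >= 0:
            if used_q[ci] or used_r[cj]:
                ok = False
                break
            path.append((ci, cj))
            ci, cj = int(BI[ci, cj]), int(BJ[ci, cj])
            if cj < 0:
                break
        if not ok or len(path) < min_pairs:
            continue
        path.reverse()
        for pi, pj in path:
            used_q[pi] = True
            used_r[pj] = True
        results.append((float(S[i, j]), path))
    return results


def align_label_maps(query: LabelMap, ref: LabelMap,
                     params: AlignParams | None = None) -> list[MapAlignment]:
    """Local DP alignment of two label maps, both orientations, best-first.

    Maps with fewer than ``min_pairs`` labels yield an empty result.
    """
    params = params or AlignParams()
    if query.n_labels < params.min_pairs or ref.n_labels < params.min_pairs:
        return []
    r = np.asarray(ref.labels, dtype=np.float64)
    qf = np.asarray(query.labels, dtype=np.float64)
    ln10 = math.log(10.0)
    min_score = params.min_confidence * ln10
    out: list[MapAlignment] = []
    for orientation in ("+", "-"):
        if orientation == "+":
            q = qf
            idx_map = np.arange(qf.size)
        else:
            q = query.length_bp + 1.0 - qf[::-1]
            idx_map = np.arange(qf.size)[::-1]
        S, BI, BJ = _run_dp(q, r, params)
        for score, path in _extract(S, BI, BJ, params.min_pairs, min_score):
            pairs = [(int(idx_map[i]), int(j)) for i, j in path]
            q_idx = [p[0] for p in pairs]
            r_idx = [p[1] for p in pairs]
            qlo, qhi = min(q_idx), max(q_idx)
            out.append(MapAlignment(
                query_id=query.id, ref_id=ref.id, orientation=orientation,
                pairs=pairs, score=score, confidence=max(score, 0.0) / ln10,
                query_span=(qf[qlo] - 1.0, qf[qhi]),
                ref_span=(r[min(r_idx)] - 1.0, r[max(r_idx)]),
            ))
    out.sort(key=lambda a: -a.score)
    return out


def score_pairing(query: LabelMap, ref: LabelMap, pairs, orientation: str,
                  params: AlignParams) -> float:
    """Score an explicit monotone pairing under the aligner's model (used by
    tests as a shared scoring definition and by support scoring)."""
    q = np.asarray(query.labels, dtype=np.float64)
    if orientation == "-":
        qpos = query.length_bp + 1.0 - q
    else:
        qpos = q
    score = MATCH_BONUS
    c2 = params.sizing_sd_coeff ** 2
    for (qa, ra), (qb, rb) in zip(pairs, pairs[1:]):
        qlen = abs(qpos[qb] - qpos[qa])
        rlen = ref.labels[rb] - ref.labels[ra]
        mean = 0.5 * (qlen + rlen)
        delta = qlen - rlen
        skips = abs(qb - qa) - 1 + (rb - ra) - 1
        score += MATCH_BONUS - delta * delta / (c2 * mean) - params.miss_penalty * skips
    return float(score)


def fit_stretch(alignment: MapAlignment, query: LabelMap, ref: LabelMap) -> float:
    """Least-squares rescaling factor mapping query intervals onto ref
    intervals (regression through the origin).

    Multiplying the query map's positions by the returned slope minimises
    the summed squared matched-interval deltas.
    """
    if alignment.n_pairs < 3:
        raise MapweaverError("insufficient pairs for rescaling (need >= 3)")
    q = np.asarray(query.labels, dtype=np.float64)
    r = np.asarray(ref.labels, dtype=np.float64)
    if alignment.orientation == "-":
        qpos = query.length_bp + 1.0 - q
    else:
        qpos = q
    qi = np.array([p[0] for p in alignment.pairs])
    ri = np.array([p[1] for p in alignment.pairs])
    qlen = np.abs(np.diff(qpos[qi]))
    rlen = np.diff(r[ri])
    denom = float(np.sum(qlen * qlen))
    if denom == 0:
        raise MapweaverError("degenerate intervals in fit_stretch")
    return float(np.sum(qlen * rlen) / denom)


def rescale_map(m: LabelMap, factor: float) -> LabelMap:
    return LabelMap(m.id, m.length_bp * factor,
                    [x * factor for x in m.labels], m.source)
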