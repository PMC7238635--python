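"""Readers and writers for every on-disk format the pipeline touches.

FASTA (wrap 60) via Biopython; label maps as a CMAP-style TSV; alignments
as an XMAP-like TSV; AGP v2.1; BED3+; markers as plain CSV.  Every
reader/writer pair round-trips valid inputs exactly (floats to 1e-6).
"""
from __future__ import annotations

import csv
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .core import (
    AGPRecord,
    FeatureInterval,
    LabelMap,
    MapAlignment,
    MapweaverError,
    SequenceRecord,
)

_AMBIG = set("RYSWKMBDHVU")


def read_sequences(path, coerce_ambiguous: bool = False) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords, folding case to upper.

    IUPAC ambiguity codes other than N raise unless ``coerce_ambiguous``
    replaces them with N.  Empty records and duplicate ids are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise MapweaverError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise MapweaverError(f"empty record {rec.id!r} in {path}")
        bad = set(seq) - set("ACGTN")
        if bad:
            if coerce_ambiguous and bad <= _AMBIG:
                seq = "".join(c if c in "ACGTN" else "N" for c in seq)
            else:
                raise MapweaverError(
                    f"record {rec.id!r}: non-ACGTN characters {sorted(bad)} "
                    "(pass coerce_ambiguous=True to fold them to N)"
                )
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_sequences(records: Iterable[SequenceRecord], path, wrap: int = 60) -> None:
    bio = [BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


_CMAP_COLS = ["MapID", "MapLength", "NumLabels", "LabelID", "Channel", "Position", "Source"]


def write_label_maps(maps: Iterable[LabelMap], path) -> None:
    """CMAP-style TSV: one row per label plus a channel-0 terminal row."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_CMAP_COLS)
        for m in maps:
            for i, pos in enumerate(m.labels, start=1):
                w.writerow([m.id, f"{m.length_bp:.6f}", m.n_labels, i, 1, f"{pos:.6f}", m.source])
            w.writerow([m.id, f"{m.length_bp:.6f}", m.n_labels, m.n_labels + 1, 0,
                        f"{m.length_bp:.6f}", m.source])


def read_label_maps(path) -> list[LabelMap]:
    df = pd.read_csv(path, sep="\t")
    maps: list[LabelMap] = []
    for map_id, grp in df.groupby("MapID", sort=False):
        labels = grp.loc[grp["Channel"] == 1, "Position"].tolist()
        length = float(grp["MapLength"].iloc[0])
        source = str(grp["Source"].iloc[0])
        try:
            maps.append(LabelMap(str(map_id), length, labels, source))
        except MapweaverError as e:
            raise MapweaverError(f"map {map_id!r} in {path}: {e}") from e
    return maps


_XMAP_COLS = ["QueryID", "RefID", "Orientation", "QryStart", "QryEnd",
              "RefStart", "RefEnd", "Score", "Confidence", "Pairs"]


def write_alignments(alns: Iterable[MapAlignment], path) -> None:
    """XMAP-like TSV; the label pairing travels as a ``q:r;`` string."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_XMAP_COLS)
        for a in alns:
            pairs = ";".join(f"{q}:{r}" for q, r in a.pairs)
            w.writerow([a.query_id, a.ref_id, a.orientation,
                        f"{a.query_span[0]:.1f}", f"{a.query_span[1]:.1f}",
                        f"{a.ref_span[0]:.1f}", f"{a.ref_span[1]:.1f}",
                        f"{a.score:.6g}", f"{a.confidence:.6g}", pairs])


def read_alignments(path) -> list[MapAlignment]:
    df = pd.read_csv(path, sep="\t", dtype={"QueryID": str, "RefID": str})
    out = []
    for row in df.itertuples(index=False):
        pairs = [tuple(map(int, p.split(":"))) for p in str(row.Pairs).split(";") if p]
        out.append(MapAlignment(
            query_id=row.QueryID, ref_id=row.RefID, orientation=row.Orientation,
            pairs=pairs, score=float(row.Score), confidence=float(row.Confidence),
            query_span=(float(row.QryStart), float(row.QryEnd)),
            ref_span=(float(row.RefStart), float(row.RefEnd)),
        ))
    return out


def _validate_agp_tiling(records: Sequence[AGPRecord]) -> None:
    by_obj: dict[str, list[AGPRecord]] = {}
    for r in records:
        by_obj.setdefault(r.object_id, []).append(r)
    for obj, rows in by_obj.items():
        rows.sort(key=lambda r: r.part_number)
        expect = 1
        for r in rows:
            if r.object_start != expect:
                raise MapweaverError(
                    f"AGP object {obj!r}: part {r.part_number} starts at "
                    f"{r.object_start}, expected {expect} (non-contiguous tiling)"
                )
            span = r.object_end - r.object_start + 1
            if r.is_gap:
                if r.gap_length != span:
                    raise MapweaverError(
                        f"AGP object {obj!r}: gap length {r.gap_length} != span {span}")
            else:
                if r.component_start is None or r.component_end is None:
                    raise MapweaverError(f"AGP object {obj!r}: W row missing component range")
                if r.component_end - r.component_start + 1 != span:
                    raise MapweaverError(
                        f"AGP object {obj!r}: component span != object span at part {r.part_number}")
            expect = r.object_end + 1


def write_agp(records: Sequence[AGPRecord], path) -> None:
    _validate_agp_tiling(records)
    with open(path, "w", newline="") as fh:
        fh.write("##agp-version\t2.1\n")
        w = csv.writer(fh, delimiter="\t")
        for r in records:
            if r.is_gap:
                w.writerow([r.object_id, r.object_start, r.object_end, r.part_number,
                            r.component_type, r.gap_length, r.gap_kind or "scaffold",
                            "yes", "map"])
            else:
                w.writerow([r.object_id, r.object_start, r.object_end, r.part_number,
                            r.component_type, r.component_id, r.component_start,
                            r.component_end, r.orientation])


def read_agp(path) -> list[AGPRecord]:
    out: list[AGPRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            ctype = f[4]
            if ctype in ("N", "U"):
                out.append(AGPRecord(f[0], int(f[1]), int(f[2]), int(f[3]), ctype,
                                     gap_length=int(f[5]), gap_kind=f[6]))
            else:
                out.append(AGPRecord(f[0], int(f[1]), int(f[2]), int(f[3]), ctype,
                                     component_id=f[5], component_start=int(f[6]),
                                     component_end=int(f[7]), orientation=f[8]))
    _validate_agp_tiling(out)
    return out


def write_bed(features: Iterable[FeatureInterval], path) -> None:
    """BED3+ with label, score and strand; output sorted by (seq_id, start)."""
    feats = sorted(features, key=lambda f: (f.seq_id, f.start, f.end))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for f in feats:
            score = "." if f.score is None else f"{f.score:.6g}"
            w.writerow([f.seq_id, f.start, f.end, f.label, score, f.strand])


def read_bed(path) -> list[FeatureInterval]:
    out: list[FeatureInterval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            start, end = int(f[1]), int(f[2])
            if end <= start:
                raise MapweaverError(f"BED {path}: end {end} <= start {start}")
            label = f[3] if len(f) > 3 else "."
            score = None if len(f) <= 4 or f[4] == "." else float(f[4])
            strand = f[5] if len(f) > 5 else "."
            out.append(FeatureInterval(f[0], start, end, label, score, strand))
    return out


MARKER_COLUMNS = ["marker_id", "scaffold_id", "physical_bp", "linkage_group",
                  "genetic_pos", "mapq", "unique"]


def write_markers(markers: pd.DataFrame, path) -> None:
    markers.to_csv(path, index=False, columns=MARKER_COLUMNS)


def read_markers(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"scaffold_id": str, "linkage_group": str})
    missing = set(MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise MapweaverError(f"marker table {path} missing columns {sorted(missing)}")
    return df


def write_provenance(records: Iterable[SequenceRecord], path) -> None:
    """Provenance blocks as TSV (record_id, block_idx, source_id, start,
    end, strand) — the liftover chain's on-disk form."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["record_id", "block", "source_id", "start", "end", "strand"])
        for rec in records:
            for i, (src, s, e, st) in enumerate(rec.source_intervals):
                w.writerow([rec.id, i, src, s, e, st])


def read_provenance(path) -> dict[str, list]:
    out: dict[str, list] = {}
    df = pd.read_csv(path, sep="\t", dtype={"record_id": str, "source_id": str})
    for row in df.sort_values(["record_id", "block"]).itertuples(index=False):
        out.setdefault(row.record_id, []).append(
            (row.source_id, int(row.start), int(row.end), row.strand))
    return out
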