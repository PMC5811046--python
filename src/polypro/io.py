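"""Readers and writers for the pipeline's external formats.

FASTA (Biopython), aligned FASTA, Newick trees (dendropy), and typed TSV
tables for orthology, annotations, expression and motif results.  All
external coordinates are 1-based inclusive; sequence letters are
upper-cased on read; duplicate ids are rejected; output tables are sorted
by id so files are diffable across runs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Malformed input file."""


def read_fasta(path) -> dict[str, str]:
    """Protein records as an id -> sequence mapping.

    Headers of the form "strain|protein_id" keep the full string as the id.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(proteome: Mapping[str, str], path) -> None:
    recs = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sorted(proteome.items())]
    SeqIO.write(recs, str(path), "fasta")


def read_alignment(path) -> dict[str, str]:
    """Aligned FASTA; all rows must have equal length."""
    msa = read_fasta(path)
    if len({len(s) for s in msa.values()}) != 1:
        raise FormatError(f"{path}: alignment rows have unequal lengths")
    return msa


write_alignment = write_fasta


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def read_orthology(path) -> pd.DataFrame:
    """TSV with columns og_id, strain, protein_id (one row per membership)."""
    return _read_tsv(path, ["og_id", "strain", "protein_id"])


def read_annotation_tracks(path):
    """TSV with columns protein_id, kind, start, end (1-based inclusive).

    Returns {kind: AnnotationTrack}.
    """
    from .positional import AnnotationTrack

    df = _read_tsv(path, ["protein_id", "kind", "start", "end"])
    tracks = {}
    for kind, grp in df.groupby("kind"):
        intervals: dict[str, list[tuple[int, int]]] = {}
        for row in grp.sort_values(["protein_id", "start"]).itertuples():
            intervals.setdefault(row.protein_id, []).append((int(row.start), int(row.end)))
        tracks[kind] = AnnotationTrack(kind=str(kind), intervals=intervals).validate()
    return tracks


def write_annotation_tracks(tracks, path) -> None:
    rows = [
        {"protein_id": pid, "kind": track.kind, "start": s, "end": e}
        for track in tracks
        for pid, ivs in sorted(track.intervals.items())
        for s, e in ivs
    ]
    pd.DataFrame(rows, columns=["protein_id", "kind", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def read_expression(path) -> pd.DataFrame:
    """TSV with columns gene_id, abundance, transcription."""
    return _read_tsv(path, ["gene_id", "abundance", "transcription"])


def read_profiling(path) -> dict[str, float]:
    df = _read_tsv(path, ["gene_id", "asymmetry_score"])
    return dict(zip(df["gene_id"], df["asymmetry_score"].astype(float)))


def write_motif_table(table: pd.DataFrame, path) -> None:
    table.sort_values(["protein_id", "start"]).to_csv(path, sep="\t", index=False)


def read_motif_table(path) -> pd.DataFrame:
    return _read_tsv(path, ["protein_id", "start", "n", "strength"])


def write_results(out_dir, objects: Mapping[str, pd.DataFrame]) -> list[Path]:
    """Write each named DataFrame as <name>.tsv under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in sorted(objects.items()):
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written
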