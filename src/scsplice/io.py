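"""Readers and writers for the pipeline's interchange formats.

All tabular formats are plain tab-separated text: read-count tables
(exon_id, cell_id, inclusion_reads, exclusion_reads), per-cell CpG reports
(chrom, pos, value), bedGraph conservation tracks, and the filtered-exon
table.  Genomes are indexed FASTA (pyfaidx); annotation is GTF/GFF3 parsed
through gffutils.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .types import CassetteExon

COUNT_COLUMNS = ["exon_id", "cell_id", "inclusion_reads", "exclusion_reads"]
EXON_COLUMNS = [
    "exon_id", "gene_id", "chrom", "strand",
    "c1_start", "c1_end", "a_start", "a_end", "c2_start", "c2_end",
    "distance_to_tss", "distance_to_tts",
]


class AnnotationParseError(ValueError):
    pass


def open_genome(fasta_path: str) -> Fasta:
    """Open an indexed FASTA; the .fai index is built on first use."""
    return Fasta(str(fasta_path), sequence_always_upper=True)


def load_annotation_db(annotation_path: str) -> gffutils.FeatureDB:
    """Parse a GTF/GFF3 file into an in-memory gffutils database."""
    try:
        return gffutils.create_db(
            str(annotation_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise AnnotationParseError(f"failed to parse {annotation_path}: {exc}") from exc


def read_count_table(path: str) -> pd.DataFrame:
    """Read a read-count table; validates columns and non-negativity."""
    df = pd.read_csv(path, sep="\t", dtype={"exon_id": str, "cell_id": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table {path} lacks columns: {sorted(missing)}")
    if (df[["inclusion_reads", "exclusion_reads"]] < 0).any().any():
        raise ValueError("negative read counts in count table")
    return df[COUNT_COLUMNS]


def write_count_table(df: pd.DataFrame, path: str) -> None:
    df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_methylation_calls(path: str, cell_id: str | None = None) -> pd.DataFrame:
    """Read one cell's CpG report: chrom, pos (0-based C of the CpG), value.

    ``value`` may be a hard state in {0, 1} or a methylation probability in
    [0, 1]; binarization happens downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"chrom", "pos", "value"}
    if not need <= set(df.columns):
        raise ValueError(f"CpG report {path} needs columns {sorted(need)}")
    if ((df["value"] < 0) | (df["value"] > 1)).any():
        raise ValueError("methylation values outside [0, 1]")
    if cell_id is not None:
        df = df.assign(cell_id=cell_id)
    return df


def read_methylation_dir(directory: str) -> pd.DataFrame:
    """Read every ``<cell_id>.cpg.tsv`` report in a directory into one table."""
    frames = []
    for name in sorted(os.listdir(directory)):
        if name.endswith(".cpg.tsv"):
            cell = name[: -len(".cpg.tsv")]
            frames.append(read_methylation_calls(os.path.join(directory, name), cell))
    if not frames:
        raise FileNotFoundError(f"no *.cpg.tsv reports under {directory}")
    return pd.concat(frames, ignore_index=True)


def write_methylation_calls(df: pd.DataFrame, path: str) -> None:
    df[["chrom", "pos", "value"]].to_csv(path, sep="\t", index=False)


def read_conservation_bedgraph(path: str) -> Dict[str, "np.ndarray"]:
    """Read a bedGraph conservation track into dense per-chromosome arrays.

    Bases not covered by any record are NaN (missing is allowed).  Scores
    must lie in [0, 1].
    """
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "score"], dtype={"chrom": str},
    )
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise ValueError("conservation scores outside [0, 1]")
    track: Dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        arr = np.full(int(sub["end"].max()), np.nan)
        for start, end, score in sub[["start", "end", "score"]].itertuples(index=False):
            arr[int(start):int(end)] = score
        track[chrom] = arr
    return track


def write_conservation_bedgraph(track: Dict[str, "np.ndarray"], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, arr in track.items():
            # run-length encode consecutive equal scores
            start = 0
            for i in range(1, len(arr) + 1):
                if i == len(arr) or arr[i] != arr[start]:
                    if not np.isnan(arr[start]):
                        fh.write(f"{chrom}\t{start}\t{i}\t{arr[start]:.4f}\n")
                    start = i


def write_exon_table(exons: Iterable[CassetteExon], path: str) -> None:
    rows = [
        [e.exon_id, e.gene_id, e.chrom, e.strand,
         e.c1[0], e.c1[1], e.a[0], e.a[1], e.c2[0], e.c2[1],
         e.distance_to_tss, e.distance_to_tts]
        for e in exons
    ]
    pd.DataFrame(rows, columns=EXON_COLUMNS).to_csv(path, sep="\t", index=False)


def read_exon_table(path: str) -> List[CassetteExon]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "exon_id": str})
    exons = []
    for row in df.itertuples(index=False):
        exons.append(CassetteExon(
            exon_id=row.exon_id, gene_id=row.gene_id, chrom=row.chrom,
            strand=row.strand,
            c1=(int(row.c1_start), int(row.c1_end)),
            a=(int(row.a_start), int(row.a_end)),
            c2=(int(row.c2_start), int(row.c2_end)),
            distance_to_tss=int(row.distance_to_tss),
            distance_to_tts=int(row.distance_to_tts),
        ))
    return exons
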