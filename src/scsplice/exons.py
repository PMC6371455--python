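"""Cassette-exon candidate extraction, filtering, and cell QC.

A candidate is an internal exon A whose flanking exons C1/C2 are shared by at
least one transcript of the same gene that contains A and at least one that
skips it (C1 and C2 adjacent).  Filters re-implement the standard
cassette-exon criteria: autosomal location, no overlap with another
alternative exon, flanking introns longer than 100 bp, exon length within
50-450 bp, at least 500 bp from the nearest TSS/TTS, and canonical AG-GT
splice-site dinucleotides in transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from .io import load_annotation_db, open_genome
from .types import CassetteExon, CellQcStats, interval_len, intervals_overlap, reverse_complement

DEFAULT_MIN_INTRON = 100
DEFAULT_MIN_EXON = 50
DEFAULT_MAX_EXON = 450
DEFAULT_MIN_TSS_DIST = 500


def _transcript_exons(db, transcript) -> List[Tuple[int, int]]:
    """0-based half-open exon intervals of a transcript, genomic order."""
    exons = []
    for ex in db.children(transcript, featuretype="exon", order_by="start"):
        exons.append((ex.start - 1, ex.end))  # GTF is 1-based inclusive
    return exons


def read_cassette_exon_annotation(annotation_file: str, genome=None) -> List[CassetteExon]:
    """Extract cassette-exon candidates from a GTF/GFF3 annotation.

    For every transcript with >= 3 exons, each internal exon A (with
    transcript-adjacent neighbours C1, C2) becomes a candidate if another
    transcript of the same gene joins C1 directly to C2 (A skipped).
    Duplicates with identical C1/A/C2 coordinates are collapsed.
    """
    if isinstance(genome, str):
        genome = open_genome(genome)
    db = load_annotation_db(annotation_file)
    candidates: Dict[tuple, CassetteExon] = {}

    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype="transcript"))
        if len(transcripts) < 2:
            continue
        tx_exons = {t.id: _transcript_exons(db, t) for t in transcripts}
        gene_start = min(e[0] for exs in tx_exons.values() for e in exs)
        gene_end = max(e[1] for exs in tx_exons.values() for e in exs)
        strand = gene.strand
        # adjacency sets for skip evidence: pairs of consecutive exons
        junctions = {tid: set(zip(exs[:-1], exs[1:])) for tid, exs in tx_exons.items()}
        exon_sets = {tid: set(exs) for tid, exs in tx_exons.items()}

        for tid, exs in tx_exons.items():
            for i in range(1, len(exs) - 1):
                left, a, right = exs[i - 1], exs[i], exs[i + 1]
                skipped = any(
                    (left, right) in junctions[other] and a not in exon_sets[other]
                    for other in tx_exons if other != tid
                )
                if not skipped:
                    continue
                if strand == "+":
                    c1, c2 = left, right
                    dist_tss = a[0] - gene_start
                    dist_tts = gene_end - a[1]
                else:
                    c1, c2 = right, left
                    dist_tss = gene_end - a[1]
                    dist_tts = a[0] - gene_start
                key = (gene.seqid, strand, c1, a, c2)
                if key in candidates:
                    continue
                if genome is not None:
                    if gene.seqid not in genome:
                        raise KeyError(f"chromosome {gene.seqid} absent from genome")
                    if gene_end > len(genome[gene.seqid]):
                        raise ValueError(
                            f"exon beyond end of {gene.seqid} "
                            f"({gene_end} > {len(genome[gene.seqid])})"
                        )
                exon_id = f"{gene.seqid}:{a[0]}-{a[1]}:{strand}"
                candidates[key] = CassetteExon(
                    exon_id=exon_id, gene_id=gene.id, chrom=gene.seqid,
                    strand=strand, c1=c1, a=a, c2=c2,
                    distance_to_tss=dist_tss, distance_to_tts=dist_tts,
                )
    return list(candidates.values())


def _splice_dinucleotides(exon: CassetteExon, genome) -> Tuple[str, str]:
    """(acceptor, donor) dinucleotides flanking A, transcript-oriented.

    Acceptor: last 2 bp of intron I1 (expected AG); donor: first 2 bp of
    intron I2 (expected GT).
    """
    chrom = genome[exon.chrom]
    i1, i2 = exon.i1, exon.i2
    if exon.strand == "+":
        acceptor = str(chrom[i1[1] - 2:i1[1]])
        donor = str(chrom[i2[0]:i2[0] + 2])
    else:
        acceptor = reverse_complement(str(chrom[i1[0]:i1[0] + 2]))
        donor = reverse_complement(str(chrom[i2[1] - 2:i2[1]]))
    return acceptor.upper(), donor.upper()


def filter_cassette_exons(
    candidates: Sequence[CassetteExon],
    genome,
    chrom_whitelist: Iterable[str] | None = None,
    min_intron: int = DEFAULT_MIN_INTRON,
    min_exon: int = DEFAULT_MIN_EXON,
    max_exon: int = DEFAULT_MAX_EXON,
    min_tss_dist: int = DEFAULT_MIN_TSS_DIST,
) -> List[CassetteExon]:
    """Apply the cassette-exon filters; returns the retained candidates.

    ``chrom_whitelist`` restricts to the given chromosomes (e.g. autosomes);
    ``None`` admits every chromosome present in the genome.
    """
    if isinstance(genome, str):
        genome = open_genome(genome)
    whitelist = set(chrom_whitelist) if chrom_whitelist is not None else None

    retained = []
    for exon in candidates:
        if whitelist is not None and exon.chrom not in whitelist:
            continue
        if exon.chrom not in genome:
            raise KeyError(f"chromosome {exon.chrom} absent from genome")
        overlapped = any(
            other is not exon and other.chrom == exon.chrom
            and intervals_overlap(exon.a, other.a)
            for other in candidates
        )
        if overlapped:
            continue
        if interval_len(exon.i1) <= min_intron or interval_len(exon.i2) <= min_intron:
            continue
        if not (min_exon <= interval_len(exon.a) <= max_exon):
            continue
        if exon.distance_to_tss < min_tss_dist or exon.distance_to_tts < min_tss_dist:
            continue
        acceptor, donor = _splice_dinucleotides(exon, genome)
        if acceptor != "AG" or donor != "GT":
            continue
        retained.append(exon)
    return retained


# Expression QC thresholds: minimum endogenous counts, minimum genes with
# non-zero expression, maximum fraction of counts in the top-100 genes,
# maximum ERCC spike-in fraction, minimum mapping rate.
QC_RULES = (
    ("min_endogenous_counts", lambda s: s.endogenous_counts >= 50_000),
    ("min_genes_nonzero", lambda s: s.genes_nonzero >= 5_000),
    ("max_top100_fraction", lambda s: s.top100_fraction < 0.9),
    ("max_ercc_fraction", lambda s: s.ercc_fraction < 0.2),
    ("min_mapping_rate", lambda s: s.mapping_rate >= 0.4),
)


@dataclass(frozen=True)
class QcResult:
    cell_id: str
    passed: bool
    failed_rules: tuple


def qc_cells(stats: Dict[str, CellQcStats]) -> List[QcResult]:
    """Evaluate the five expression QC rules per cell."""
    results = []
    for cell_id, s in stats.items():
        if not isinstance(s, CellQcStats):
            raise TypeError(f"cell {cell_id}: expected CellQcStats, got {type(s)}")
        failed = tuple(name for name, rule in QC_RULES if not rule(s))
        results.append(QcResult(cell_id=cell_id, passed=not failed, failed_rules=failed))
    return results
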