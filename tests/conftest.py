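"""Shared fixtures: toy annotations/genomes and small simulated datasets."""

import numpy as np
import pytest

from scsplice.simulate import SimulationConfig, simulate_dataset

# ---------------------------------------------------------------------------
# Hand-built toy gene: one plus-strand gene whose middle exon is skipped.
#
# chr1 layout (0-based half-open):
#   E1 [700, 900)   E2 [1100, 1200)   E3 [1400, 1600)
# with AG planted at [1098, 1100) (acceptor before E2) and GT at
# [1200, 1202) (donor after E2).  Gene span [700, 1600); E2 is 500+ bp from
# neither end, so TSS/TTS distances are 400/400 (fails the 500 bp filter
# unless relaxed -- useful for boundary tests).

TOY_CHROM_LEN = 2400


def _toy_sequence(rng: np.random.Generator) -> str:
    bases = np.array(list("ACGT"))
    seq = list("".join(bases[rng.integers(0, 4, TOY_CHROM_LEN)]))
    seq[1098:1100] = "AG"
    seq[1200:1202] = "GT"
    return "".join(seq)


@pytest.fixture(scope="session")
def toy_genome_seq():
    return _toy_sequence(np.random.default_rng(1234))


@pytest.fixture(scope="session")
def toy_genome(toy_genome_seq):
    return {"chr1": toy_genome_seq}


def gtf_lines(chrom, gene, strand, transcripts):
    """transcripts: {tid: [(start0, end0), ...]} -> GTF text (1-based)."""
    all_ivs = [iv for ivs in transcripts.values() for iv in ivs]
    lo, hi = min(i[0] for i in all_ivs), max(i[1] for i in all_ivs)
    out = [f'{chrom}\ttest\tgene\t{lo + 1}\t{hi}\t.\t{strand}\t.\tgene_id "{gene}";']
    for tid, ivs in transcripts.items():
        t_lo, t_hi = min(i[0] for i in ivs), max(i[1] for i in ivs)
        out.append(f'{chrom}\ttest\ttranscript\t{t_lo + 1}\t{t_hi}\t.\t{strand}\t.\t'
                   f'gene_id "{gene}"; transcript_id "{tid}";')
        for s, e in sorted(ivs):
            out.append(f'{chrom}\ttest\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t'
                       f'gene_id "{gene}"; transcript_id "{tid}";')
    return "\n".join(out) + "\n"


E1, E2, E3 = (700, 900), (1100, 1200), (1400, 1600)


@pytest.fixture(scope="session")
def toy_gtf(tmp_path_factory):
    path = tmp_path_factory.mktemp("anno") / "toy.gtf"
    path.write_text(gtf_lines("chr1", "g1", "+", {
        "g1.t1": [E1, E2, E3],
        "g1.t2": [E1, E3],
    }))
    return str(path)


@pytest.fixture(scope="session")
def toy_fasta(tmp_path_factory, toy_genome_seq):
    path = tmp_path_factory.mktemp("fa") / "toy.fa"
    with open(path, "w") as fh:
        fh.write(">chr1\n")
        for i in range(0, len(toy_genome_seq), 60):
            fh.write(toy_genome_seq[i:i + 60] + "\n")
    return str(path)


# ---------------------------------------------------------------------------
# Small simulated datasets (module cost amortized across tests)

@pytest.fixture(scope="session")
def small_sim():
    """60 exons x 2x30 cells: enough for most integration-level checks."""
    return simulate_dataset(SimulationConfig(n_exons=60, n_cells=(30, 30), seed=11))


@pytest.fixture(scope="session")
def small_sim_files(tmp_path_factory):
    """A written-to-disk simulation for I/O round-trips and the pipeline."""
    out = tmp_path_factory.mktemp("simdata")
    ds = simulate_dataset(SimulationConfig(n_exons=40, n_cells=(25, 25), seed=21),
                          out_dir=str(out))
    return ds, str(out)
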