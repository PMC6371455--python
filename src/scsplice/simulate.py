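"""Synthetic scM&T-seq-like data with planted, recoverable structure.

The generator emits a toy genome, a matching GTF annotation, a conservation
track, per-cell CpG methylation calls, and per-cell inclusion/exclusion read
counts for two cell states, together with the full ground truth.  Design:

* every emitted cassette exon passes the candidate filters (AG-GT splice
  sites, intron/exon length bounds, TSS/TTS distance);
* each exon's mean PSI is a logistic function of a small set of its own
  sequence k-mer frequencies (the "active" genomic features), shifted per
  category (excluded/included exons sit near 0.05/0.95);
* per-exon read coverage follows a negative binomial, leaving many
  (exon, cell) pairs below the 5-read quantification floor;
* CpG sites are observed sparsely (default 30% of sites, matching the
  typical 20-40% coverage of single-cell bisulfite data);
* a configurable fraction of exons carries a monotone coupling between one
  context's per-cell methylation rate and that cell's inclusion probability;
* conservation over the alternative exon is elevated in proportion to the
  planted mean PSI, so conservation is an informative recoverable feature.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import features as feat
from . import io as sio
from .types import CONTEXT_KEYS, CassetteExon, reverse_complement

BASES = np.array(list("ACGT"))
REGIMES = ("excluded", "included", "overdispersed", "underdispersed",
           "multimodal", "gene", "cell")

# Active genomic features driving mean PSI: (context, k-mer) -> weight.
ACTIVE_GENOMIC_WEIGHTS = {
    ("A", "C"): 1.0, ("A", "G"): -1.0, ("A", "CG"): 1.5, ("A", "GC"): -1.0,
    ("I1_3p", "T"): 1.0, ("I1_3p", "CG"): -1.5,
    ("I2_5p", "A"): -1.0, ("I2_5p", "CG"): 1.5,
    ("C1", "TT"): 1.0, ("C2", "AA"): -1.0,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults emulate the experimental scale: ~80 cells per state, negative-
    binomial read coverage with substantial mass below 5 reads, 30% CpG
    observation rate, and a planted methylation-splicing coupling at 20% of
    loci with a strong logit-scale effect.
    """

    n_exons: int = 300
    n_cells: Tuple[int, int] = (80, 80)
    seed: int = 0
    coverage_mean: float = 10.0
    coverage_shape: float = 1.5
    meth_observation_rate: float = 0.3
    coupled_fraction: float = 0.2
    coupling_effect: float = 8.0
    # where couplings sit: concentrated on the alternative exon and the
    # flanking intron ends nearest to it, mirroring the observation that
    # methylation information in A and the downstream intron carries most of
    # the predictive signal
    coupling_context_weights: Dict[str, float] = field(default_factory=lambda: {
        "C1": 0.05, "I1_5p": 0.05, "I1_3p": 0.15, "A": 0.3,
        "I2_5p": 0.3, "I2_3p": 0.1, "C2": 0.05,
    })
    category_fractions: Dict[str, float] = field(default_factory=lambda: {
        "excluded": 0.2, "included": 0.2, "overdispersed": 0.15,
        "underdispersed": 0.15, "multimodal": 0.3,
    })
    genomic_scale: float = 1.0
    state_shift_fraction: float = 0.1
    state_shift_logit: float = 1.0
    # geometry (bp); intron range keeps intron-end contexts disjoint and the
    # alternative exon >= 500 bp from TSS/TTS
    c_exon_len: int = 200
    intron_range: Tuple[int, int] = (620, 900)
    alt_exon_range: Tuple[int, int] = (80, 250)
    flank_len: int = 550
    spacer: int = 120
    # methylation cell-to-cell spread (Beta concentration) and regime shapes
    meth_concentration: float = 2.5
    over_concentration: float = 0.8
    multimodal_concentration: float = 6.0
    chrom: str = "chr1"

    def __post_init__(self):
        for name in ("meth_observation_rate", "coupled_fraction",
                     "state_shift_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_exons <= 0 or any(n <= 0 for n in self.n_cells):
            raise ValueError("n_exons and n_cells must be positive")
        if self.coverage_mean <= 0 or self.coverage_shape <= 0:
            raise ValueError("coverage law parameters must be positive")
        if self.alt_exon_range[0] < 50 or self.alt_exon_range[1] > 450:
            raise ValueError("alt exon lengths must stay within the 50-450 filter")
        if self.intron_range[0] <= 100:
            raise ValueError("introns must exceed the 100 bp filter")
        if abs(sum(self.category_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")


@dataclass
class SimulatedDataset:
    """In-memory result of a simulation run (plus optional files on disk)."""

    config: SimulationConfig
    exons: list                    # CassetteExon, all passing the filters
    genome: Dict[str, str]
    conservation: Dict[str, np.ndarray]
    counts: Dict[str, pd.DataFrame]       # state -> long count table
    methylation: Dict[str, pd.DataFrame]  # state -> long call table
    truth: pd.DataFrame                   # per-exon ground truth
    cell_meth_rates: Dict[str, dict]      # state -> {(exon_id, ctx): cells array}

    @property
    def states(self):
        return tuple(self.counts)


def _coverage(rng, mean, shape, size):
    """Negative-binomial read coverage (gamma-Poisson; var = m + m^2/shape)."""
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p, size=size)


def coverage_below_floor_probability(mean: float, shape: float, floor: int = 5) -> float:
    """P(coverage < floor) under the negative-binomial coverage law."""
    from scipy.stats import nbinom
    p = shape / (shape + mean)
    return float(nbinom.cdf(floor - 1, shape, p))


def simulate_reads_for_exon(
    mean_psi: float,
    regime: str,
    n_cells: int,
    coverage,
    seed,
    logit_shift: Optional[np.ndarray] = None,
    over_concentration: float = 0.8,
    multimodal_concentration: float = 6.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-cell inclusion/exclusion read counts for one exon.

    ``coverage`` is either a fixed integer depth or a (mean, shape) tuple of
    the negative-binomial coverage law.  ``regime`` selects the per-cell
    inclusion-probability law:

    * ``gene``/``underdispersed``/``excluded``/``included`` — every cell uses
      p = mean_psi (binomial read sampling only);
    * ``cell`` — each cell commits to one isoform, Bernoulli(mean_psi);
    * ``overdispersed``/``multimodal`` — per-cell p ~ Beta with mean
      mean_psi and the given concentration (low concentrations are U-shaped,
      placing modes near 0 and 1).

    ``logit_shift`` (per-cell) models methylation coupling: it displaces each
    cell's inclusion probability on the logit scale.
    """
    if not 0.0 <= mean_psi <= 1.0:
        raise ValueError("mean_psi must lie in [0, 1]")
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(coverage, (int, np.integer)):
        if coverage <= 0:
            raise ValueError("coverage must be positive")
        n = np.full(n_cells, int(coverage))
    else:
        mean, shape = coverage
        if mean <= 0:
            raise ValueError("coverage mean must be positive")
        n = _coverage(rng, mean, shape, n_cells)

    if mean_psi in (0.0, 1.0):
        p_cell = np.full(n_cells, mean_psi)
    elif regime == "cell":
        p_cell = rng.binomial(1, mean_psi, n_cells).astype(float)
    elif regime in ("overdispersed", "multimodal"):
        conc = over_concentration if regime == "overdispersed" else multimodal_concentration
        p_cell = rng.beta(mean_psi * conc, (1.0 - mean_psi) * conc, n_cells)
    else:
        p_cell = np.full(n_cells, mean_psi)

    if logit_shift is not None and mean_psi not in (0.0, 1.0) and regime != "cell":
        eps = 1e-9
        p_cell = expit(logit(np.clip(p_cell, eps, 1 - eps)) + np.asarray(logit_shift))

    inclusion = rng.binomial(n, p_cell)
    return inclusion, n - inclusion


def simulate_methylation_profile(
    contexts,
    rates: Dict[str, float],
    observation_rate: float,
    seed,
    chrom_seq: Optional[str] = None,
) -> pd.DataFrame:
    """Sparse CpG calls for one cell over an exon's contexts.

    CpG sites are the cytosines of CG dinucleotides in each context (located
    on the plus strand; the dyad is palindromic so orientation does not
    change the site set).  Each site is observed independently with
    ``observation_rate``; the observed state is Bernoulli(context rate).
    """
    if not 0.0 <= observation_rate <= 1.0:
        raise ValueError("observation_rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for ctx in CONTEXT_KEYS:
        rate = rates[ctx]
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {ctx} outside [0, 1]")
        sites = _context_cpg_sites(contexts, ctx)
        observed = sites[rng.random(sites.size) < observation_rate]
        states = rng.binomial(1, rate, observed.size)
        for pos, st in zip(observed, states):
            rows.append((int(pos), int(st), ctx))
    return pd.DataFrame(rows, columns=["pos", "value", "context"])


def _context_cpg_sites(contexts, ctx: str) -> np.ndarray:
    """Plus-strand positions of CpG cytosines within one context."""
    seq = contexts[ctx]
    pos = contexts.positions[ctx]
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    oriented = pos[:-1][cg] if len(pos) > 1 else np.empty(0, np.int64)
    # plus-strand C of the dyad: oriented position itself on '+', position-1
    # of the oriented C (which sits on the G of the plus strand) on '-'
    if len(pos) > 1 and pos[0] > pos[-1]:  # minus strand: descending positions
        return np.sort(oriented - 1)
    return np.sort(oriented)


def _random_seq(rng, length: int, probs: np.ndarray) -> str:
    return "".join(BASES[rng.choice(4, size=length, p=probs)])


def _build_gene(rng, cfg: SimulationConfig, offset: int, idx: int):
    """Assemble one gene's plus-strand sequence and its CassetteExon."""
    strand = "+" if idx % 2 == 0 else "-"
    i1_len = int(rng.integers(*cfg.intron_range))
    i2_len = int(rng.integers(*cfg.intron_range))
    a_len = int(rng.integers(*cfg.alt_exon_range))
    comp = {part: rng.dirichlet(np.full(4, 6.0)) for part in
            ("flank5", "C1", "I1", "A", "I2", "C2", "flank3")}
    c1 = _random_seq(rng, cfg.c_exon_len, comp["C1"])
    i1 = _random_seq(rng, i1_len - 2, comp["I1"]) + "AG"
    a = _random_seq(rng, a_len, comp["A"])
    i2 = "GT" + _random_seq(rng, i2_len - 2, comp["I2"])
    c2 = _random_seq(rng, cfg.c_exon_len, comp["C2"])
    flank5 = _random_seq(rng, cfg.flank_len, comp["flank5"])
    flank3 = _random_seq(rng, cfg.flank_len, comp["flank3"])
    oriented = flank5 + c1 + i1 + a + i2 + c2 + flank3

    # oriented (transcript-space) intervals within the gene construct
    o_c1 = (cfg.flank_len, cfg.flank_len + cfg.c_exon_len)
    o_a = (o_c1[1] + i1_len, o_c1[1] + i1_len + a_len)
    o_c2 = (o_a[1] + i2_len, o_a[1] + i2_len + cfg.c_exon_len)
    length = len(oriented)

    if strand == "+":
        plus_seq = oriented
        g_c1, g_a, g_c2 = (
            tuple(offset + x for x in iv) for iv in (o_c1, o_a, o_c2)
        )
    else:
        plus_seq = reverse_complement(oriented)
        def flip(iv):
            return (offset + length - iv[1], offset + length - iv[0])
        g_c1, g_a, g_c2 = flip(o_c1), flip(o_a), flip(o_c2)

    exon = CassetteExon(
        exon_id=f"ex{idx:04d}", gene_id=f"gene{idx:04d}", chrom=cfg.chrom,
        strand=strand, c1=g_c1, a=g_a, c2=g_c2,
        distance_to_tss=cfg.c_exon_len + i1_len,
        distance_to_tts=cfg.c_exon_len + i2_len,
    )
    return plus_seq, exon


def _genomic_score(exon: CassetteExon, contexts) -> float:
    """The planted linear predictor over active k-mer features."""
    score = 0.0
    for (ctx, kmer), w in ACTIVE_GENOMIC_WEIGHTS.items():
        freqs = feat.kmer_frequencies(contexts[ctx], k_max=len(kmer))
        score += w * freqs[kmer]
    return score


def simulate_dataset(
    config: SimulationConfig,
    out_dir: Optional[str] = None,
) -> SimulatedDataset:
    """Generate the full two-state dataset; optionally write all files.

    Returns the in-memory dataset; when ``out_dir`` is given, additionally
    writes genome.fa, annotation.gtf, conservation.bedgraph, counts_<state>.tsv,
    truth.tsv and per-cell CpG reports under ``out_dir``/meth_<state>/.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    ss_genome, ss_truth, ss_reads, ss_meth, ss_cons = root.spawn(5)
    rng_genome = np.random.default_rng(ss_genome)

    # --- genome, annotation, exons -------------------------------------
    pieces, exons = [], []
    offset = 0
    for i in range(cfg.n_exons):
        pieces.append(_random_seq(rng_genome, cfg.spacer, np.full(4, 0.25)))
        offset += cfg.spacer
        plus_seq, exon = _build_gene(rng_genome, cfg, offset, i)
        pieces.append(plus_seq)
        offset += len(plus_seq)
        exons.append(exon)
    genome = {cfg.chrom: "".join(pieces)}

    contexts = {e.exon_id: feat.extract_contexts(e, genome) for e in exons}

    # --- planted regimes and mean PSI ----------------------------------
    rng_truth = np.random.default_rng(ss_truth)
    raw = np.array([_genomic_score(e, contexts[e.exon_id]) for e in exons])
    z = (raw - raw.mean()) / (raw.std() if raw.std() > 0 else 1.0)

    # mean PSI is sequence-determined: the lowest-scoring exons are the
    # excluded class, the highest-scoring the included class, and the
    # dispersion regimes are drawn at random among the intermediate exons
    counts_by_cat = {c: int(round(f * cfg.n_exons))
                     for c, f in cfg.category_fractions.items()}
    n_exc, n_inc = counts_by_cat.get("excluded", 0), counts_by_cat.get("included", 0)
    order = np.argsort(z, kind="stable")
    regimes = np.empty(cfg.n_exons, dtype=object)
    regimes[order[:n_exc]] = "excluded"
    if n_inc:
        regimes[order[cfg.n_exons - n_inc:]] = "included"
    middle = order[n_exc:cfg.n_exons - n_inc]
    middle_regimes = []
    for regime in ("overdispersed", "underdispersed", "multimodal"):
        middle_regimes.extend([regime] * counts_by_cat.get(regime, 0))
    middle_regimes = (middle_regimes + ["multimodal"] * len(middle))[:len(middle)]
    regimes[middle] = rng_truth.permutation(middle_regimes)

    mean_psi_a = np.empty(cfg.n_exons)
    for i, regime in enumerate(regimes):
        if regime == "excluded":
            mean_psi_a[i] = expit(logit(0.05) + 0.3 * z[i])
        elif regime == "included":
            mean_psi_a[i] = expit(logit(0.95) + 0.3 * z[i])
        else:
            mean_psi_a[i] = expit(cfg.genomic_scale * z[i])
    if len(middle):
        # re-centre the intermediate exons' scores so their mean PSI spans
        # the intermediate band rather than inheriting the truncated tails
        z_mid = z[middle]
        z_mid = (z_mid - z_mid.mean()) / (z_mid.std() or 1.0)
        mean_psi_a[middle] = expit(cfg.genomic_scale * z_mid)

    shifted = rng_truth.random(cfg.n_exons) < cfg.state_shift_fraction
    shift = np.where(rng_truth.random(cfg.n_exons) < 0.5, 1.0, -1.0)
    shift *= cfg.state_shift_logit * shifted
    mean_psi_b = expit(logit(np.clip(mean_psi_a, 1e-9, 1 - 1e-9)) + shift)

    # methylation-splicing coupling is planted only at intermediate-splicing
    # loci: an exon pinned near PSI 0 or 1 cannot respond measurably to a
    # methylation shift, so couplings there would be unfalsifiable
    intermediate_regime = ~np.isin(regimes, ["excluded", "included"])
    coupled = (rng_truth.random(cfg.n_exons) < cfg.coupled_fraction) \
        & intermediate_regime
    weights = np.array([cfg.coupling_context_weights.get(c, 0.0)
                        for c in CONTEXT_KEYS])
    coupled_ctx = rng_truth.choice(CONTEXT_KEYS, cfg.n_exons,
                                   p=weights / weights.sum())
    # effect direction is a property of the context, not the locus: exonic
    # methylation promotes inclusion, intronic methylation represses it, so
    # the global regression models can exploit a consistent direction
    coupled_sign = np.where(
        np.isin(coupled_ctx, ["C1", "A", "C2"]), 1.0, -1.0)
    ctx_mean_rate = rng_truth.uniform(0.2, 0.8, size=(cfg.n_exons, len(CONTEXT_KEYS)))

    truth = pd.DataFrame({
        "exon_id": [e.exon_id for e in exons],
        "regime": regimes,
        "mean_psi_A": mean_psi_a,
        "mean_psi_B": mean_psi_b,
        "coupled": coupled,
        "coupled_context": np.where(coupled, coupled_ctx, ""),
        "coupling_sign": np.where(coupled, coupled_sign, 0.0),
    }).set_index("exon_id")

    # --- per-state reads and methylation -------------------------------
    states = ("A", "B")
    counts: Dict[str, pd.DataFrame] = {}
    meth: Dict[str, pd.DataFrame] = {}
    cell_rates: Dict[str, dict] = {}
    reads_children = ss_reads.spawn(len(states))
    meth_children = ss_meth.spawn(len(states))

    for s_idx, state in enumerate(states):
        n_cells = cfg.n_cells[s_idx]
        cells = [f"{state}_c{j:03d}" for j in range(n_cells)]
        rng_reads = np.random.default_rng(reads_children[s_idx])
        rng_meth = np.random.default_rng(meth_children[s_idx])
        mean_psi = mean_psi_a if state == "A" else mean_psi_b

        incl_mat = np.empty((cfg.n_exons, n_cells), dtype=int)
        excl_mat = np.empty((cfg.n_exons, n_cells), dtype=int)
        meth_cells, meth_pos, meth_vals = [], [], []
        rates_by_key = {}
        conc = cfg.meth_concentration
        for i, exon in enumerate(exons):
            # per-cell true context methylation rates
            rates = rng_meth.beta(
                ctx_mean_rate[i][None, :] * conc,
                (1.0 - ctx_mean_rate[i][None, :]) * conc,
                size=(n_cells, len(CONTEXT_KEYS)),
            )
            for c_idx, ctx in enumerate(CONTEXT_KEYS):
                rates_by_key[(exon.exon_id, ctx)] = rates[:, c_idx]

            logit_shift = None
            read_regime = str(regimes[i])
            if coupled[i]:
                c_idx = CONTEXT_KEYS.index(coupled_ctx[i])
                logit_shift = coupled_sign[i] * cfg.coupling_effect * (
                    rates[:, c_idx] - ctx_mean_rate[i, c_idx]
                )
                # at a coupled locus the cross-cell splicing heterogeneity is
                # the methylation response itself: reads sample binomially
                # around the methylation-shifted per-cell rate
                read_regime = "gene"
            incl_mat[i], excl_mat[i] = simulate_reads_for_exon(
                float(mean_psi[i]), read_regime, n_cells,
                (cfg.coverage_mean, cfg.coverage_shape), rng_reads,
                logit_shift=logit_shift,
                over_concentration=cfg.over_concentration,
                multimodal_concentration=cfg.multimodal_concentration,
            )

            # sparse CpG calls: (cells x sites) observation and state draws
            ctx_obj = contexts[exon.exon_id]
            site_lists = [_context_cpg_sites(ctx_obj, ctx) for ctx in CONTEXT_KEYS]
            all_sites = np.concatenate(site_lists)
            if all_sites.size == 0:
                continue
            site_ctx = np.repeat(np.arange(len(CONTEXT_KEYS)),
                                 [s.size for s in site_lists])
            observed = rng_meth.random((n_cells, all_sites.size)) < cfg.meth_observation_rate
            states_mat = rng_meth.random((n_cells, all_sites.size)) < rates[:, site_ctx]
            cell_idx, site_idx = np.nonzero(observed)
            meth_cells.append(cell_idx)
            meth_pos.append(all_sites[site_idx])
            meth_vals.append(states_mat[cell_idx, site_idx].astype(float))

        counts[state] = pd.DataFrame({
            "exon_id": np.repeat([e.exon_id for e in exons], n_cells),
            "cell_id": np.tile(cells, cfg.n_exons),
            "inclusion_reads": incl_mat.ravel(),
            "exclusion_reads": excl_mat.ravel(),
        })
        if meth_cells:
            cell_arr = np.concatenate(meth_cells)
            meth[state] = pd.DataFrame({
                "cell_id": np.asarray(cells, dtype=object)[cell_arr],
                "chrom": cfg.chrom,
                "pos": np.concatenate(meth_pos),
                "value": np.concatenate(meth_vals),
            })
        else:
            meth[state] = pd.DataFrame(columns=["cell_id", "chrom", "pos", "value"])
        cell_rates[state] = rates_by_key

    # --- conservation ---------------------------------------------------
    rng_cons = np.random.default_rng(ss_cons)
    L = len(genome[cfg.chrom])
    coarse = rng_cons.uniform(0.05, 0.45, size=L // 50 + 2)
    base = np.interp(np.arange(L), np.arange(coarse.size) * 50, coarse)
    for i, exon in enumerate(exons):
        lift_a = 0.25 + 0.5 * mean_psi_a[i]
        for iv, lift in ((exon.c1, 0.3), (exon.c2, 0.3), (exon.a, lift_a)):
            base[iv[0]:iv[1]] += lift
    cons = {cfg.chrom: np.round(np.clip(base, 0.0, 1.0), 2)}

    ds = SimulatedDataset(
        config=cfg, exons=exons, genome=genome, conservation=cons,
        counts=counts, methylation=meth, truth=truth, cell_meth_rates=cell_rates,
    )
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def write_dataset(ds: SimulatedDataset, out_dir: str) -> None:
    """Write every pipeline input format for a simulated dataset."""
    os.makedirs(out_dir, exist_ok=True)
    cfg = ds.config

    with open(os.path.join(out_dir, "genome.fa"), "w") as fh:
        for chrom, seq in ds.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")

    with open(os.path.join(out_dir, "annotation.gtf"), "w") as fh:
        for exon in ds.exons:
            gid = exon.gene_id
            chrom, strand = exon.chrom, exon.strand
            span = exon.span
            def line(ftype, start, end, tid=None):
                attrs = f'gene_id "{gid}";'
                if tid:
                    attrs += f' transcript_id "{tid}";'
                return (f"{chrom}\tsim\t{ftype}\t{start + 1}\t{end}\t.\t"
                        f"{strand}\t.\t{attrs}\n")
            fh.write(line("gene", span[0], span[1]))
            for tid, exon_ivs in (
                (f"{gid}.incl", (exon.c1, exon.a, exon.c2)),
                (f"{gid}.skip", (exon.c1, exon.c2)),
            ):
                ivs = sorted(exon_ivs)
                fh.write(line("transcript", ivs[0][0], ivs[-1][1], tid))
                for iv in ivs:
                    fh.write(line("exon", iv[0], iv[1], tid))

    sio.write_conservation_bedgraph(
        ds.conservation, os.path.join(out_dir, "conservation.bedgraph"))

    for state, df in ds.counts.items():
        sio.write_count_table(df, os.path.join(out_dir, f"counts_{state}.tsv"))
    for state, df in ds.methylation.items():
        meth_dir = os.path.join(out_dir, f"meth_{state}")
        os.makedirs(meth_dir, exist_ok=True)
        for cell, sub in df.groupby("cell_id", sort=True):
            sio.write_methylation_calls(
                sub, os.path.join(meth_dir, f"{cell}.cpg.tsv"))

    ds.truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t")
    sio.write_exon_table(ds.exons, os.path.join(out_dir, "exons.tsv"))
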