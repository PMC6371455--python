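"""Genomic and methylation feature extraction over the seven exon contexts.

The genomic block has exactly 607 named features per cassette exon:

* 84 k-mer frequencies (k <= 3 over ACGT) plus 1 mean conservation score in
  each of the 7 contexts (C1, I1_5p, I1_3p, A, I2_5p, I2_3p, C2) -> 595;
* logarithmic and relative length of the 5 regions (C1, I1, A, I2, C2) -> 10;
* acceptor and donor splice-site strengths at the alternative exon's
  boundaries -> 2.

The methylation block has exactly 826 features: in each of the 7 contexts,
the 116 k-mers (k <= 3 over the extended alphabet {A, G, T, M, U}, where M/U
are methylated/unmethylated cytosines) that contain at least one M or U, plus
the methylation mean and variance across the context's CpG sites -> 7 x 118.

k-mer frequencies are counts of overlapping windows divided by the number of
valid windows of that length; windows containing a base outside the alphabet
(N, or an unannotated C in methylation space) are excluded from both
numerator and denominator.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .types import CONTEXT_KEYS, REGION_KEYS, CassetteExon, ExonContexts, reverse_complement

logger = logging.getLogger(__name__)

GENOMIC_ALPHABET = "ACGT"
METH_ALPHABET = "AGTMU"
INTRON_CONTEXT_BP = 300
METH_FILL_WINDOW = 900

N_GENOMIC_FEATURES = 607
N_METH_FEATURES = 826


# ---------------------------------------------------------------------------
# k-mer machinery

def kmer_names(alphabet: str, k_max: int = 3):
    """All k-mers for k = 1..k_max, ordered by k then lexicographically."""
    names = []
    for k in range(1, k_max + 1):
        names.extend("".join(t) for t in itertools.product(alphabet, repeat=k))
    return names


#: The methylation-aware k-mers: those containing at least one M or U.
MU_KMER_NAMES = [k for k in kmer_names(METH_ALPHABET) if ("M" in k or "U" in k)]
_MU_INDEX = np.array(
    [i for i, k in enumerate(kmer_names(METH_ALPHABET)) if ("M" in k or "U" in k)]
)


def _encode(seq: str, alphabet: str) -> np.ndarray:
    """Map a sequence to integer codes; characters outside the alphabet -> -1."""
    lut = np.full(256, -1, dtype=np.int16)
    for i, ch in enumerate(alphabet):
        lut[ord(ch)] = i
        lut[ord(ch.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_freqs_batch(codes: np.ndarray, n_letters: int, k_max: int = 3) -> np.ndarray:
    """Frequencies of all k-mers (k=1..k_max) for each row of a code matrix.

    ``codes`` is (n_rows, L) with -1 marking invalid bases.  Returns
    (n_rows, sum_k n_letters**k); each k-block is normalized by that row's
    count of valid windows (0 when no window is valid).
    """
    codes = np.atleast_2d(codes)
    n_rows, length = codes.shape
    blocks = []
    for k in range(1, k_max + 1):
        n_kmers = n_letters ** k
        if length < k:
            blocks.append(np.zeros((n_rows, n_kmers)))
            continue
        idx = np.zeros((n_rows, length - k + 1), dtype=np.int64)
        valid = np.ones((n_rows, length - k + 1), dtype=bool)
        for j in range(k):
            win = codes[:, j:length - k + 1 + j]
            valid &= win >= 0
            idx = idx * n_letters + np.maximum(win, 0)
        # offset each row into its own bin range, then one global bincount
        offset = idx + np.arange(n_rows)[:, None] * n_kmers
        counts = np.bincount(offset[valid], minlength=n_rows * n_kmers)
        counts = counts.reshape(n_rows, n_kmers).astype(float)
        denom = valid.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = np.where(denom > 0, counts / denom, 0.0)
        blocks.append(freqs)
    return np.hstack(blocks)


def kmer_frequencies(seq: str, k_max: int = 3, alphabet: str = GENOMIC_ALPHABET) -> pd.Series:
    """Overlapping k-mer frequencies of one sequence (k = 1..k_max)."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    codes = _encode(seq, alphabet)[None, :]
    freqs = _kmer_freqs_batch(codes, len(alphabet), k_max)[0]
    return pd.Series(freqs, index=kmer_names(alphabet, k_max))


# ---------------------------------------------------------------------------
# Context extraction

def extract_contexts(exon: CassetteExon, genome) -> ExonContexts:
    """Extract the seven transcript-oriented context sequences of an exon.

    Intron-end contexts keep at most 300 bp anchored at their own end; for
    short introns the 5' and 3' contexts overlap.  Genomic (plus-strand)
    positions of each oriented base are retained for methylation alignment.
    """
    chrom = genome[exon.chrom]
    chrom_len = len(chrom)

    def fetch(iv):
        if iv[0] < 0 or iv[1] > chrom_len:
            raise ValueError(f"{exon.exon_id}: interval {iv} outside {exon.chrom}")
        seq = str(chrom[iv[0]:iv[1]]).upper()
        pos = np.arange(iv[0], iv[1])
        if exon.strand == "-":
            seq = reverse_complement(seq)
            pos = pos[::-1]
        return seq, pos

    i1, i2 = exon.i1, exon.i2

    def intron_ends(iv):
        """(5' context interval, 3' context interval) in transcript space."""
        w = min(INTRON_CONTEXT_BP, iv[1] - iv[0])
        if exon.strand == "+":
            return (iv[0], iv[0] + w), (iv[1] - w, iv[1])
        return (iv[1] - w, iv[1]), (iv[0], iv[0] + w)

    i1_5p, i1_3p = intron_ends(i1)
    i2_5p, i2_3p = intron_ends(i2)
    intervals = {
        "C1": exon.c1, "I1_5p": i1_5p, "I1_3p": i1_3p, "A": exon.a,
        "I2_5p": i2_5p, "I2_3p": i2_3p, "C2": exon.c2,
    }
    ctx = ExonContexts(exon_id=exon.exon_id)
    for key, iv in intervals.items():
        seq, pos = fetch(iv)
        ctx.sequences[key] = seq
        ctx.positions[key] = pos
    return ctx


# ---------------------------------------------------------------------------
# Splice-site position weight matrices

@dataclass(frozen=True)
class SpliceSitePwm:
    """Log-odds PWM over ACGT; ``exonic`` bases of the window lie in the exon.

    ``probs`` is (width, 4); scores are sum of log2(p/0.25) per position,
    with out-of-alphabet bases contributing 0 (background).
    """

    probs: np.ndarray
    exonic: int  # number of window positions inside the exon

    def __post_init__(self):
        colsums = self.probs.sum(axis=1)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def score(self, site_seq: str) -> float:
        if len(site_seq) != self.width:
            raise ValueError(
                f"site window length {len(site_seq)} != PWM width {self.width}"
            )
        codes = _encode(site_seq, GENOMIC_ALPHABET)
        logodds = np.log2(self.probs / 0.25)
        return float(sum(
            logodds[i, c] for i, c in enumerate(codes) if c >= 0
        ))

    def consensus(self) -> str:
        return "".join(GENOMIC_ALPHABET[i] for i in self.probs.argmax(axis=1))


def load_pwm(path: str, exonic: int) -> SpliceSitePwm:
    """Load a PWM from a TSV of per-position A/C/G/T probabilities."""
    df = pd.read_csv(path, sep="\t")
    return SpliceSitePwm(probs=df[list("ACGT")].to_numpy(float), exonic=exonic)


def _pwm_from_consensus(consensus: str, exonic: int, strength: Sequence[float]) -> SpliceSitePwm:
    """Build a PWM giving each consensus base probability ``strength`` and
    spreading the remainder uniformly (a declared default motif model)."""
    probs = np.empty((len(consensus), 4))
    for i, (base, s) in enumerate(zip(consensus, strength)):
        if base == "N":
            probs[i] = 0.25
        else:
            probs[i] = (1.0 - s) / 3.0
            probs[i, GENOMIC_ALPHABET.index(base)] = s
    return SpliceSitePwm(probs=probs, exonic=exonic)


# Canonical U2-type splice motifs.  Donor window: 3 exonic + 6 intronic bases
# around the consensus (C/A)AG|GTAAGT; acceptor window: 13 intronic (pyrimidine
# tract + AG) + 2 exonic bases.  Consensus-position strengths approximate the
# information content of vertebrate splice sites; both PWMs are replaceable
# via load_pwm.
DEFAULT_DONOR_PWM = _pwm_from_consensus(
    "CAGGTAAGT", exonic=3,
    strength=[0.35, 0.60, 0.80, 0.97, 0.97, 0.60, 0.70, 0.80, 0.50],
)
DEFAULT_ACCEPTOR_PWM = _pwm_from_consensus(
    "TTTTTTTTTNCAGGN", exonic=2,
    strength=[0.45, 0.45, 0.45, 0.45, 0.45, 0.45, 0.45, 0.45, 0.45,
              0.25, 0.70, 0.97, 0.97, 0.50, 0.25],
)


def splice_site_strength(site_seq: str, pwm: SpliceSitePwm) -> float:
    """Sum of per-position log-odds of the site window against background."""
    return pwm.score(site_seq)


def _splice_site_windows(exon: CassetteExon, genome,
                         donor_pwm: SpliceSitePwm, acceptor_pwm: SpliceSitePwm):
    """Transcript-oriented acceptor (I1|A) and donor (A|I2) windows."""
    chrom = genome[exon.chrom]

    def oriented(start, end):
        seq = str(chrom[max(start, 0):end]).upper()
        if start < 0:
            seq = "N" * (-start) + seq
        if end > len(chrom):
            seq = seq + "N" * (end - len(chrom))
        return reverse_complement(seq) if exon.strand == "-" else seq

    a = exon.a
    d_ex, d_in = donor_pwm.exonic, donor_pwm.width - donor_pwm.exonic
    a_in, a_ex = acceptor_pwm.width - acceptor_pwm.exonic, acceptor_pwm.exonic
    if exon.strand == "+":
        acceptor = oriented(a[0] - a_in, a[0] + a_ex)
        donor = oriented(a[1] - d_ex, a[1] + d_in)
    else:
        acceptor = oriented(a[1] - a_ex, a[1] + a_in)
        donor = oriented(a[0] - d_in, a[0] + d_ex)
    return acceptor, donor


# ---------------------------------------------------------------------------
# Genomic feature vector (607)

def genomic_feature_names():
    names = []
    for ctx in CONTEXT_KEYS:
        names.extend(f"kmer_{ctx}_{k}" for k in kmer_names(GENOMIC_ALPHABET))
        names.append(f"cons_{ctx}")
    for region in REGION_KEYS:
        names.extend([f"log_len_{region}", f"rel_len_{region}"])
    names.extend(["acceptor_strength", "donor_strength"])
    assert len(names) == N_GENOMIC_FEATURES
    return names


def mean_conservation(positions: np.ndarray, track, chrom: str) -> float:
    """Mean of available per-base conservation scores; 0 when none."""
    if track is None or chrom not in track:
        return 0.0
    arr = track[chrom]
    pos = positions[(positions >= 0) & (positions < len(arr))]
    vals = arr[pos]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        logger.warning("no conservation scores available for %s context", chrom)
        return 0.0
    return float(vals.mean())


def genomic_features(
    exon: CassetteExon,
    contexts: ExonContexts,
    conservation=None,
    donor_pwm: SpliceSitePwm = DEFAULT_DONOR_PWM,
    acceptor_pwm: SpliceSitePwm = DEFAULT_ACCEPTOR_PWM,
    genome=None,
) -> pd.Series:
    """The 607-dimensional genomic feature vector of one cassette exon."""
    values = []
    for ctx in CONTEXT_KEYS:
        seq = contexts[ctx]
        codes = _encode(seq, GENOMIC_ALPHABET)[None, :]
        values.extend(_kmer_freqs_batch(codes, 4)[0])
        values.append(mean_conservation(contexts.positions[ctx], conservation, exon.chrom))
    span = exon.span[1] - exon.span[0]
    for region, length in exon.region_lengths.items():
        values.append(float(np.log(length)))
        values.append(length / span)
    if genome is not None:
        acc_seq, don_seq = _splice_site_windows(exon, genome, donor_pwm, acceptor_pwm)
        values.append(splice_site_strength(acc_seq, acceptor_pwm))
        values.append(splice_site_strength(don_seq, donor_pwm))
    else:
        # splice-site windows extend past the context sequences; without a
        # genome the scores default to the background score
        values.extend([0.0, 0.0])
    out = pd.Series(values, index=genomic_feature_names(), name=exon.exon_id)
    assert len(out) == N_GENOMIC_FEATURES
    return out


def genomic_feature_table(exons, genome, conservation=None, **kwargs) -> pd.DataFrame:
    """Genomic feature matrix (exon x 607) for a list of filtered exons."""
    rows = {}
    for exon in exons:
        ctx = extract_contexts(exon, genome)
        rows[exon.exon_id] = genomic_features(
            exon, ctx, conservation=conservation, genome=genome, **kwargs
        )
    return pd.DataFrame(rows).T.rename_axis("exon_id")


# ---------------------------------------------------------------------------
# Methylation handling

def binarize_methylation(probability):
    """Binarize methylation probabilities: <= 0.3 -> 0, > 0.7 -> 1, else NaN."""
    p = np.asarray(probability, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("methylation probability outside [0, 1]")
    out = np.full(p.shape, np.nan)
    out[p <= 0.3] = 0.0
    out[p > 0.7] = 1.0
    return out if out.ndim else float(out)


def _cytosine_call_states(
    c_positions: np.ndarray,
    call_positions: np.ndarray,
    call_states: np.ndarray,
    window: int = METH_FILL_WINDOW,
) -> np.ndarray:
    """State (0/1) of each cytosine: exact call, else nearest informed call
    within +-window genomic bp, else unmethylated (0).

    ``call_positions`` must be sorted and carry only informed (0/1) states.
    """
    if call_positions.size == 0:
        return np.zeros(c_positions.size)
    right = np.searchsorted(call_positions, c_positions)
    left = np.clip(right - 1, 0, call_positions.size - 1)
    right = np.clip(right, 0, call_positions.size - 1)
    d_left = np.abs(c_positions - call_positions[left])
    d_right = np.abs(call_positions[right] - c_positions)
    nearest = np.where(d_left <= d_right, left, right)
    dist = np.minimum(d_left, d_right)
    states = call_states[nearest].astype(float)
    states[dist > window] = 0.0
    return states


def methylation_annotate_sequence(
    seq: str,
    positions: np.ndarray,
    strand: str,
    call_positions: np.ndarray,
    call_states: np.ndarray,
    window: int = METH_FILL_WINDOW,
) -> str:
    """Rewrite every C of a transcript-oriented sequence as M or U.

    Calls are indexed by the plus-strand position of the CpG's cytosine; a C
    read on the minus strand therefore looks up position - 1 (the CpG dyad is
    palindromic).  Uninformed cytosines take the state of the nearest
    informed cytosine within ``window`` bp, defaulting to unmethylated.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    c_mask = (arr == ord("C")) | (arr == ord("c"))
    if not c_mask.any():
        return seq
    c_pos = positions[c_mask]
    lookup = c_pos if strand == "+" else c_pos - 1
    order = np.argsort(lookup)
    states_sorted = _cytosine_call_states(lookup[order], call_positions, call_states, window)
    states = np.empty_like(states_sorted)
    states[order] = states_sorted
    arr[c_mask] = np.where(states >= 0.5, ord("M"), ord("U"))
    return arr.tobytes().decode("ascii")


class MethylationIndex:
    """Sorted per-(cell, chrom) call positions/states for fast lookups.

    Accepts a long table (cell_id, chrom, pos, value); values are binarized
    and intermediate (missing) calls dropped from the information set.
    """

    def __init__(self, calls: pd.DataFrame):
        self._index: Dict[tuple, tuple] = {}
        states = binarize_methylation(calls["value"].to_numpy())
        keep = ~np.isnan(states)
        sub = calls.loc[keep, ["cell_id", "chrom", "pos"]].assign(state=states[keep])
        for (cell, chrom), grp in sub.groupby(["cell_id", "chrom"], sort=False):
            pos = grp["pos"].to_numpy(np.int64)
            order = np.argsort(pos)
            self._index[(cell, chrom)] = (pos[order], grp["state"].to_numpy()[order])
        self.cells = sorted(sub["cell_id"].unique())

    def get(self, cell_id: str, chrom: str):
        return self._index.get((cell_id, chrom), (np.empty(0, np.int64), np.empty(0)))


# ---------------------------------------------------------------------------
# Methylation feature vector (826)

def methylation_feature_names():
    names = []
    for ctx in CONTEXT_KEYS:
        names.extend(f"mkmer_{ctx}_{k}" for k in MU_KMER_NAMES)
        names.extend([f"meth_mean_{ctx}", f"meth_var_{ctx}"])
    assert len(names) == N_METH_FEATURES
    return names


def _context_meth_features(mu_seq: str) -> np.ndarray:
    """116 M/U k-mer frequencies + CpG methylation mean and variance."""
    codes = _encode(mu_seq, METH_ALPHABET)[None, :]
    freqs = _kmer_freqs_batch(codes, 5)[0][_MU_INDEX]
    arr = np.frombuffer(mu_seq.encode("ascii"), dtype=np.uint8)
    is_mu = (arr == ord("M")) | (arr == ord("U"))
    followed_by_g = np.zeros(arr.size, dtype=bool)
    followed_by_g[:-1] = arr[1:] == ord("G")
    cpg = is_mu & followed_by_g
    if cpg.any():
        states = (arr[cpg] == ord("M")).astype(float)
        mean, var = float(states.mean()), float(states.var())
    else:
        logger.warning("context without CpG sites; methylation mean/var set to 0")
        mean = var = 0.0
    return np.concatenate([freqs, [mean, var]])


_M_CODE = METH_ALPHABET.index("M")
_U_CODE = METH_ALPHABET.index("U")
_G_CODE = METH_ALPHABET.index("G")


def _context_meth_features_cells(
    seq: str,
    positions: np.ndarray,
    strand: str,
    meth_index: "MethylationIndex",
    chrom: str,
    cells: Sequence[str],
    window: int,
) -> np.ndarray:
    """Per-cell (cells x 118) methylation features of one context.

    Equivalent to annotating the sequence per cell and calling
    :func:`_context_meth_features`, but the cytosine states are assigned in
    one matrix and the k-mers counted in one batched pass.
    """
    base = _encode(seq, METH_ALPHABET)  # C and N both come back -1
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    c_mask = arr == ord("C")
    n_cells = len(cells)
    codes = np.tile(base, (n_cells, 1))
    if c_mask.any():
        c_pos = positions[c_mask]
        lookup = c_pos if strand == "+" else c_pos - 1
        order = np.argsort(lookup)
        lookup_sorted = lookup[order]
        states = np.empty((n_cells, lookup.size))
        for i, cell in enumerate(cells):
            pos, st = meth_index.get(cell, chrom)
            s_sorted = _cytosine_call_states(lookup_sorted, pos, st, window)
            states[i, order] = s_sorted
        codes[:, c_mask] = np.where(states >= 0.5, _M_CODE, _U_CODE)
    freqs = _kmer_freqs_batch(codes, 5)[:, _MU_INDEX]

    is_mu = (codes == _M_CODE) | (codes == _U_CODE)
    followed_by_g = np.zeros_like(is_mu)
    followed_by_g[:, :-1] = codes[:, 1:] == _G_CODE
    cpg = is_mu & followed_by_g
    n_cpg = cpg.sum(axis=1)
    is_m = (codes == _M_CODE) & cpg
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_cpg > 0, is_m.sum(axis=1) / n_cpg, 0.0)
    var = np.where(n_cpg > 0, mean * (1.0 - mean), 0.0)  # Bernoulli states
    return np.hstack([freqs, mean[:, None], var[:, None]])


def methylation_features(
    exon: CassetteExon,
    contexts: ExonContexts,
    meth_index: MethylationIndex,
    cells: Sequence[str] | None = None,
    mode: str = "cell",
    window: int = METH_FILL_WINDOW,
) -> pd.DataFrame | pd.Series:
    """The 826-dimensional methylation feature block for one exon.

    ``mode='cell'`` returns a cell x 826 frame; ``mode='mean'`` averages each
    coordinate across cells into a single Series.
    """
    if mode not in ("cell", "mean"):
        raise ValueError(f"mode must be 'cell' or 'mean', got {mode!r}")
    cells = list(cells) if cells is not None else meth_index.cells
    names = methylation_feature_names()
    blocks = [
        _context_meth_features_cells(
            contexts[ctx], contexts.positions[ctx], exon.strand,
            meth_index, exon.chrom, cells, window,
        )
        for ctx in CONTEXT_KEYS
    ]
    frame = pd.DataFrame(np.hstack(blocks),
                         index=pd.Index(cells, name="cell_id"), columns=names)
    if mode == "mean":
        return frame.mean(axis=0).rename(exon.exon_id)
    return frame


def methylation_feature_table(
    exons, genome, meth_index: MethylationIndex,
    cells: Sequence[str] | None = None, mode: str = "cell",
) -> pd.DataFrame:
    """Methylation feature matrix for many exons.

    ``mode='cell'`` -> rows indexed by (exon_id, cell_id); ``mode='mean'`` ->
    rows indexed by exon_id.
    """
    pieces = []
    for exon in exons:
        ctx = extract_contexts(exon, genome)
        block = methylation_features(exon, ctx, meth_index, cells=cells, mode=mode)
        if mode == "mean":
            pieces.append(block.to_frame().T.rename_axis("exon_id"))
        else:
            block = block.copy()
            block.index = pd.MultiIndex.from_product(
                [[exon.exon_id], block.index], names=["exon_id", "cell_id"]
            )
            pieces.append(block)
    return pd.concat(pieces)


def context_methylation_matrix(
    exons, genome, meth_index: MethylationIndex,
    cells: Sequence[str] | None = None,
    window: int = METH_FILL_WINDOW,
) -> pd.DataFrame:
    """Per-cell context methylation rate for every (exon, context).

    The rate is the mean filled M/U state over the context's CpG cytosines —
    the same quantity as the ``meth_mean_<ctx>`` feature — computed without
    the k-mer machinery.  Rows are a (exon_id, context) MultiIndex, columns
    are cells; NaN where a context has no CpG site.
    """
    cells = list(cells) if cells is not None else meth_index.cells
    rows, keys = [], []
    for exon in exons:
        ctx_obj = extract_contexts(exon, genome)
        for ctx in CONTEXT_KEYS:
            seq = ctx_obj[ctx]
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            is_c = arr == ord("C")
            followed_by_g = np.zeros(arr.size, dtype=bool)
            followed_by_g[:-1] = arr[1:] == ord("G")
            cpg_mask = is_c & followed_by_g
            if not cpg_mask.any():
                rows.append(np.full(len(cells), np.nan))
                keys.append((exon.exon_id, ctx))
                continue
            c_pos = ctx_obj.positions[ctx][cpg_mask]
            lookup = c_pos if exon.strand == "+" else c_pos - 1
            lookup = np.sort(lookup)
            vals = np.empty(len(cells))
            for i, cell in enumerate(cells):
                pos, states = meth_index.get(cell, exon.chrom)
                vals[i] = _cytosine_call_states(lookup, pos, states, window).mean()
            rows.append(vals)
            keys.append((exon.exon_id, ctx))
    return pd.DataFrame(
        rows, columns=pd.Index(cells, name="cell_id"),
        index=pd.MultiIndex.from_tuples(keys, names=["exon_id", "context"]),
    )


def feature_manifest() -> pd.DataFrame:
    """Feature name -> (block, family, context) manifest for both blocks."""
    rows = []
    for name in genomic_feature_names():
        if name.startswith("kmer_"):
            _, ctx, kmer = name.split("_", 2)
            rows.append((name, "genomic", "kmer", ctx))
        elif name.startswith("cons_"):
            rows.append((name, "genomic", "conservation", name.split("_", 1)[1]))
        elif name.startswith(("log_len_", "rel_len_")):
            rows.append((name, "genomic", "length", name.rsplit("_", 1)[1]))
        else:
            rows.append((name, "genomic", "splice_site", "A"))
    for name in methylation_feature_names():
        if name.startswith("mkmer_"):
            _, ctx, kmer = name.split("_", 2)
            rows.append((name, "methylation", "mu_kmer", ctx))
        else:
            rows.append((name, "methylation", "meth_summary", name.rsplit("_", 1)[1]))
    return pd.DataFrame(rows, columns=["feature", "block", "family", "context"])
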