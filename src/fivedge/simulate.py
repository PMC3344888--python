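"""In-silico 5'-tag library generation with known ground truth.

The generator emulates what the counting pipeline actually sees from a
5'-tag (CAGE/5'-SAGE-like) library made with EcoP15I digestion and SOLiD
sequencing:

* a toy genome of random scaffolds carrying non-overlapping gene models on
  both strands, written as FASTA + GFF3;
* per-gene true expression (TPM summing to 10^6 per sample) following a
  small bank of temporal patterns plus flat null genes;
* tags whose genomic 5' position is a mixture of a sharp peak at the
  annotated transcription start (weight ``tss_peak_weight``) and an
  exponentially decaying background over exonic positions (truncated
  transcripts, premature template switching);
* per-gene tag counts Poisson-distributed around depth x TPM / 10^6;
* reads emitted ANTISENSE to the transcript (sequencing runs from 25 bp
  inside the transcript back toward the cap) and encoded in color space
  with a uniform per-color error rate;
* optional suppression of tag positions in a window 3' of CTGCTG
  (reverse EcoP15I) sites, emulating restriction-site sequence bias.

Library-prep enzymology (adaptors, PCR, bead capture) is abstracted; only
its observable consequences are modeled. Every draw comes from a single
seeded generator, so outputs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .colorspace import ReadBatch, _BASE_LUT, reverse_complement
from .reference import write_fasta
from .regions import GeneModel, write_gff3

logger = logging.getLogger(__name__)

TAG_LENGTH = 25
ECOP15I_FORWARD = "CAGCAG"
ECOP15I_REVERSE = "CTGCTG"
# EcoP15I cleaves 25/27 nt downstream of its site, leaving a 2-nt 5' overhang
_CUT_NEAR, _CUT_FAR = 25, 27

DEFAULT_TSS_PEAK_WEIGHT = 0.6
DEFAULT_DECAY_SCALE_BP = 500.0
DEFAULT_COLOR_ERROR_RATE = 0.01
DEFAULT_REPLICATE_SD_LOG2 = 0.4


@dataclass
class ToyGenome:
    scaffolds: list[tuple[str, str]]
    seed: int

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.scaffolds}

    def sequence(self, name: str) -> str:
        for n, s in self.scaffolds:
            if n == name:
                return s
        raise KeyError(name)

    def write_fasta(self, path: str | Path) -> None:
        write_fasta(self.scaffolds, path)


@dataclass
class LibraryParams:
    """Observable library parameters: depth, tag length, error and bias."""

    depth: int
    tag_length: int = TAG_LENGTH
    color_error_rate: float = DEFAULT_COLOR_ERROR_RATE
    ecop15i_bias: tuple[float, int] | None = None  # (suppression factor, window bp)
    antisense_orientation: bool = True
    primer_base: str = "T"

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.color_error_rate < 0.25:
            raise ValueError("color_error_rate must be in [0, 0.25)")
        if self.ecop15i_bias is not None:
            factor, window = self.ecop15i_bias
            if factor < 1 or window < 1:
                raise ValueError("bias factor must be >= 1 and window >= 1 bp")


@dataclass
class SimTruth:
    """Ground truth: per-gene TPM per time point plus generator parameters."""

    tpm: pd.DataFrame             # genes x time points, sums to 1e6 per column
    labels: pd.Series             # pattern label per gene ('null' or 'p<k>')
    tss_peak_weight: pd.Series    # fraction of tags at the annotated TSS
    decay_scale: pd.Series        # bp scale of the exon-body background
    params: dict = field(default_factory=dict)

    @property
    def timepoints(self) -> list[str]:
        return list(self.tpm.columns)

    def write_tsv(self, path: str | Path) -> None:
        out = self.tpm.copy()
        out["pattern"] = self.labels
        with open(path, "w") as fh:
            fh.write("# true TPM per time point; per-column sums are 1e6\n")
            out.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# toy genome


def make_toy_genome(
    n_scaffolds: int,
    n_genes: int,
    mean_gene_len: int = 1500,
    mean_gap: int = 3000,
    seed: int = 0,
    fixed_gap: int | None = None,
    max_exons: int = 2,
    scaffold_length: int | None = None,
    min_scaffold_len: int = 10_000,
) -> tuple[ToyGenome, list[GeneModel]]:
    """Random genome with non-overlapping same-strand gene models.

    Gaps between consecutive genes are exponential around ``mean_gap``
    (spanning both sides of the 3 kb extension threshold) unless
    ``fixed_gap`` pins them. When ``scaffold_length`` is given, genes that
    do not fit raise instead of silently truncating.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    rng = np.random.default_rng(seed)
    per_scaffold = [n_genes // n_scaffolds] * n_scaffolds
    for i in range(n_genes % n_scaffolds):
        per_scaffold[i] += 1

    scaffolds: list[tuple[str, str]] = []
    models: list[GeneModel] = []
    strands = rng.choice(list("+-"), size=n_genes)
    if len(set(strands)) == 1:  # both strands must be represented
        strands[-1] = "+" if strands[0] == "-" else "-"
    g_idx = 0
    for si in range(n_scaffolds):
        name = f"scaffold_{si + 1}"
        pos = int(rng.integers(2200, 3200))
        for _ in range(per_scaffold[si]):
            glen = max(300, int(rng.gamma(4.0, mean_gene_len / 4.0)))
            start, end = pos, pos + glen
            gene_id = f"gene_{g_idx + 1:04d}"
            exons = _make_exons(start, end, int(rng.integers(1, max_exons + 1)), rng)
            models.append(
                GeneModel(gene_id, name, str(strands[g_idx]), start, end, exons)
            )
            gap = fixed_gap if fixed_gap is not None else max(
                200, int(rng.exponential(mean_gap))
            )
            pos = end + gap
            g_idx += 1
        length = max(min_scaffold_len, models[-1].end + int(rng.integers(2200, 3200)))
        if scaffold_length is not None:
            if models[-1].end + 100 > scaffold_length:
                raise ValueError(
                    f"{per_scaffold[si]} genes do not fit on a "
                    f"{scaffold_length} bp scaffold (need {models[-1].end + 100})"
                )
            length = scaffold_length
        seq = "".join(rng.choice(list("ACGT"), size=length))
        scaffolds.append((name, seq))
    return ToyGenome(scaffolds, seed), models


def _make_exons(
    start: int, end: int, n_exons: int, rng: np.random.Generator
) -> tuple[tuple[int, int], ...]:
    """Split [start, end) into exons separated by short introns."""
    span = end - start
    min_exon, min_intron = 100, 100
    while n_exons > 1 and span < n_exons * min_exon + (n_exons - 1) * (min_intron + 50):
        n_exons -= 1
    if n_exons == 1:
        return ((start, end),)
    introns = [int(rng.integers(min_intron, 301)) for _ in range(n_exons - 1)]
    exon_total = span - sum(introns)
    cuts = np.sort(rng.choice(np.arange(1, exon_total // min_exon), size=n_exons - 1,
                              replace=False)) * min_exon if exon_total // min_exon > n_exons else None
    if cuts is None:
        sizes = [exon_total // n_exons] * n_exons
        sizes[-1] += exon_total - sum(sizes)
    else:
        bounds = [0, *cuts.tolist(), exon_total]
        sizes = [b - a for a, b in zip(bounds[:-1], bounds[1:])]
    exons = []
    pos = start
    for k, size in enumerate(sizes):
        exons.append((pos, pos + size))
        pos += size + (introns[k] if k < len(introns) else 0)
    last_s, _ = exons[-1]
    exons[-1] = (last_s, end)
    return tuple(exons)


def write_sample_sheet(
    timepoints: Sequence[str], n_replicates: int, path: str | Path
) -> pd.DataFrame:
    rows = [
        {"sample": f"{t}_r{k + 1}", "timepoint": t, "replicate": k + 1}
        for t in timepoints
        for k in range(n_replicates)
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# expression truth


def _pattern_shapes(n_timepoints: int, n_patterns: int) -> np.ndarray:
    """Bank of smooth temporal shapes scaled to [0, 1] each."""
    if n_patterns > 9:
        raise ValueError("at most 9 patterns supported")
    tau = np.linspace(0.0, 1.0, n_timepoints)
    bank = [tau, 1.0 - tau]
    for center in (0.33, 0.66, 0.15, 0.85, 0.5):
        bank.append(np.exp(-((tau - center) ** 2) / (2 * 0.15**2)))
    bank.append(np.abs(np.sin(np.pi * tau)))          # symmetric bump
    bank.append(1.0 - np.abs(np.sin(np.pi * tau)))    # symmetric dip
    shapes = np.stack(bank[:n_patterns])
    lo = shapes.min(axis=1, keepdims=True)
    hi = shapes.max(axis=1, keepdims=True)
    return (shapes - lo) / (hi - lo)


def assign_expression_profiles(
    genes: Sequence[GeneModel],
    n_timepoints: int = 6,
    n_patterns: int = 3,
    fraction_null: float = 0.5,
    seed: int = 0,
    effect_fold: float = 4.0,
    tss_peak_weight: float = DEFAULT_TSS_PEAK_WEIGHT,
    decay_scale: float = DEFAULT_DECAY_SCALE_BP,
    base_log10_range: tuple[float, float] = (-0.5, 2.5),
) -> SimTruth:
    """Assign temporal expression patterns and true TPM values to genes.

    Non-null genes cycle through ``n_patterns`` shapes whose max/min ratio
    is ``effect_fold``; null genes are flat. True TPM is renormalized so
    each time point sums to 10^6.
    """
    if not 0 <= fraction_null <= 1:
        raise ValueError("fraction_null must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = [m.gene_id for m in genes]
    n = len(gene_ids)
    base = 10.0 ** rng.uniform(*base_log10_range, size=n)
    n_null = int(round(fraction_null * n))
    null_mask = np.zeros(n, dtype=bool)
    null_mask[rng.choice(n, size=n_null, replace=False)] = True

    shapes = _pattern_shapes(n_timepoints, n_patterns) if n_patterns else None
    labels = np.array(["null"] * n, dtype=object)
    log2_amp = np.log2(effect_fold)
    profile = np.ones((n, n_timepoints))
    non_null = np.flatnonzero(~null_mask)
    for j, gi in enumerate(non_null):
        k = j % n_patterns
        labels[gi] = f"p{k}"
        profile[gi] = 2.0 ** (log2_amp * shapes[k])
    tpm = base[:, None] * profile
    tpm = tpm / tpm.sum(axis=0, keepdims=True) * 1e6
    cols = [f"t{j}" for j in range(n_timepoints)]
    return SimTruth(
        tpm=pd.DataFrame(tpm, index=pd.Index(gene_ids, name="gene_id"), columns=cols),
        labels=pd.Series(labels, index=gene_ids, name="pattern"),
        tss_peak_weight=pd.Series(tss_peak_weight, index=gene_ids),
        decay_scale=pd.Series(decay_scale, index=gene_ids),
        params={
            "n_timepoints": n_timepoints,
            "n_patterns": n_patterns,
            "fraction_null": fraction_null,
            "effect_fold": effect_fold,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# EcoP15I digestion


@dataclass(frozen=True)
class DigestedTag:
    tag: str         # 25 bp, 3' of the recognition site in site orientation
    overhang: str    # 2 nt 5' overhang left by the staggered cut
    site_position: int  # top-strand 0-based start of the 6-mer site
    orientation: str    # '+' for CAGCAG, '-' for CTGCTG


def digest_ecop15i(sequence: str) -> list[DigestedTag]:
    """Cut a double-stranded cDNA at every EcoP15I site.

    The enzyme cleaves 25/27 nt downstream of its asymmetric site, so each
    productive site yields a 25 bp tag with a 2-nt 5' overhang taken 3' of
    the site in the site's own orientation. Sites with fewer than 27 nt of
    downstream sequence cannot be cut and are dropped with a warning. A
    sequence without any site returns an empty list (undigested molecule).
    """
    seq = sequence.upper()
    out: list[DigestedTag] = []
    for orientation, motif in (("+", ECOP15I_FORWARD), ("-", ECOP15I_REVERSE)):
        start = 0
        while True:
            s = seq.find(motif, start)
            if s < 0:
                break
            start = s + 1
            if orientation == "+":
                room = len(seq) - (s + 6)
                if room < _CUT_FAR:
                    logger.warning(
                        "EcoP15I site at %d dropped: only %d nt downstream "
                        "(need %d)", s, room, _CUT_FAR,
                    )
                    continue
                tag = seq[s + 6 : s + 6 + _CUT_NEAR]
                overhang = reverse_complement(
                    seq[s + 6 + _CUT_NEAR : s + 6 + _CUT_FAR]
                )
            else:
                room = s
                if room < _CUT_FAR:
                    logger.warning(
                        "EcoP15I site at %d dropped: only %d nt downstream "
                        "in site orientation (need %d)", s, room, _CUT_FAR,
                    )
                    continue
                tag = reverse_complement(seq[s - _CUT_NEAR : s])
                overhang = seq[s - _CUT_FAR : s - _CUT_NEAR]
            out.append(DigestedTag(tag, overhang, s, orientation))
    out.sort(key=lambda t: (t.site_position, t.orientation))
    return out


# ---------------------------------------------------------------------------
# tag simulation


@dataclass
class _GeneCandidates:
    """Precomputed candidate tag 5'-end positions for one gene."""

    genome_pos: np.ndarray       # genomic coordinate of the transcript 5' base
    offset: np.ndarray           # transcript distance from the TSS
    window_start: np.ndarray     # genomic window start of the 25 bp tag


def _gene_candidates(model: GeneModel, tag_length: int) -> _GeneCandidates:
    pos_list, off_list, win_list = [], [], []
    cum = 0
    exons = model.exons if model.strand == "+" else tuple(reversed(model.exons))
    for s, e in exons:
        exon_len = e - s
        n_valid = exon_len - tag_length + 1
        if n_valid > 0:
            if model.strand == "+":
                g = np.arange(s, s + n_valid)
                off = cum + (g - s)
                win = g
            else:
                g = np.arange(e - 1, e - 1 - n_valid, -1)
                off = cum + (e - 1 - g)
                win = g - (tag_length - 1)
            pos_list.append(g)
            off_list.append(off)
            win_list.append(win)
        cum += exon_len
    if not pos_list:
        raise ValueError(
            f"{model.gene_id}: no exon can hold a {tag_length} bp tag"
        )
    return _GeneCandidates(
        np.concatenate(pos_list),
        np.concatenate(off_list),
        np.concatenate(win_list),
    )


def _position_weights(
    cand: _GeneCandidates,
    peak_weight: float,
    decay_scale: float,
    suppression: np.ndarray | None,
    bias_factor: float,
) -> np.ndarray:
    w = np.exp(-cand.offset / decay_scale)
    at_tss = cand.offset == 0
    if w[~at_tss].sum() > 0:
        w[~at_tss] *= (1.0 - peak_weight) / w[~at_tss].sum()
    else:
        w[~at_tss] = 0.0
    w[at_tss] = peak_weight if np.any(at_tss) else 0.0
    if w.sum() <= 0:
        w = np.ones_like(w)
    if suppression is not None:
        w = w * np.where(suppression[cand.genome_pos], 1.0 / bias_factor, 1.0)
    return w / w.sum()


def _suppression_mask(seq: str, window_bp: int) -> np.ndarray:
    """Genomic positions suppressed by proximity to a reverse EcoP15I site.

    For a CTGCTG occurrence at top-strand start ``s`` the site's 3' flank in
    site orientation is the window [s - window_bp, s) on top-strand
    coordinates; tag 5' positions falling there are down-weighted.
    """
    mask = np.zeros(len(seq), dtype=bool)
    start = 0
    while True:
        s = seq.find(ECOP15I_REVERSE, start)
        if s < 0:
            break
        mask[max(0, s - window_bp) : s] = True
        start = s + 1
    return mask


def simulate_tags(
    genome: ToyGenome,
    gene_models: Sequence[GeneModel],
    truth: SimTruth,
    params: LibraryParams,
    sample_id: str,
    seed: int = 0,
    timepoint: str | None = None,
    n_low_information: int = 0,
) -> tuple[ReadBatch, pd.DataFrame]:
    """Draw one library for ``sample_id`` and return (reads, truth hits).

    ``timepoint`` selects the truth column (defaults to ``sample_id``).
    ``n_low_information`` appends that many all-zero-color reads, a fixture
    for exercising the low-information filter.
    """
    tp = timepoint or sample_id
    if tp not in truth.tpm.columns:
        raise ValueError(f"timepoint {tp!r} not in truth table")
    missing = [m.gene_id for m in gene_models if m.gene_id not in truth.tpm.index]
    if missing:
        raise ValueError(f"genes missing from truth: {missing[:3]}...")
    rng = np.random.default_rng(seed)
    tag_len = params.tag_length

    # per-scaffold base codes, color strings and window views
    codes = {
        name: _BASE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
        for name, seq in genome.scaffolds
    }
    refcolors = {name: (c[:-1] ^ c[1:]) for name, c in codes.items()}
    windows = {
        name: sliding_window_view(rc, tag_len - 1) for name, rc in refcolors.items()
    }
    suppression = None
    bias_factor = 1.0
    if params.ecop15i_bias is not None:
        bias_factor, window_bp = params.ecop15i_bias
        suppression = {
            name: _suppression_mask(seq, int(window_bp))
            for name, seq in genome.scaffolds
        }

    ids: list[str] = []
    color_blocks: list[np.ndarray] = []
    truth_rows: dict[str, list] = {
        "read_id": [], "scaffold": [], "position": [], "strand": [],
        "gene_id": [], "offset": [],
    }
    primer_code = "ACGT".index(params.primer_base)
    for m in gene_models:
        lam = params.depth * truth.tpm.at[m.gene_id, tp] / 1e6
        count = int(rng.poisson(lam))
        if count == 0:
            continue
        cand = _gene_candidates(m, tag_len)
        w = _position_weights(
            cand,
            float(truth.tss_peak_weight[m.gene_id]),
            float(truth.decay_scale[m.gene_id]),
            suppression[m.scaffold] if suppression is not None else None,
            bias_factor,
        )
        picks = rng.choice(cand.genome_pos.size, size=count, p=w)
        win = cand.window_start[picks]
        off = cand.offset[picks]

        internal = windows[m.scaffold][win]  # (count, tag_len-1) top-strand colors
        if (m.strand == "+") == params.antisense_orientation:
            # read is the reverse complement of the top-strand window:
            # reversed colors, first base = complement of the window's last base
            internal = internal[:, ::-1]
            first_code = 3 - codes[m.scaffold][win + tag_len - 1]
            mapped_strand = "-"
        else:
            first_code = codes[m.scaffold][win]
            mapped_strand = "+"
        colors = np.empty((count, tag_len), dtype=np.uint8)
        colors[:, 0] = primer_code ^ first_code
        colors[:, 1:] = internal

        base_idx = len(ids)
        gene_ids = [f"{sample_id}:{m.gene_id}:{base_idx + j}" for j in range(count)]
        ids.extend(gene_ids)
        color_blocks.append(colors)
        truth_rows["read_id"].extend(gene_ids)
        truth_rows["scaffold"].extend([m.scaffold] * count)
        truth_rows["position"].extend(win.tolist())
        truth_rows["strand"].extend([mapped_strand] * count)
        truth_rows["gene_id"].extend([m.gene_id] * count)
        truth_rows["offset"].extend(off.tolist())

    if color_blocks:
        colors = np.vstack(color_blocks)
    else:
        colors = np.empty((0, tag_len), dtype=np.uint8)
    if params.color_error_rate > 0 and colors.size:
        err = rng.random(colors.shape) < params.color_error_rate
        shift = rng.integers(1, 4, size=colors.shape, dtype=np.uint8)
        colors = np.where(err, (colors + shift) % 4, colors).astype(np.uint8)
    if n_low_information > 0:
        zero = np.zeros((n_low_information, tag_len), dtype=np.uint8)
        colors = np.vstack([colors, zero]) if colors.size else zero
        ids.extend(f"{sample_id}:lowinfo:{j}" for j in range(n_low_information))

    batch = ReadBatch(ids, params.primer_base, colors)
    truth_hits = pd.DataFrame(truth_rows)
    return batch, truth_hits


# ---------------------------------------------------------------------------
# expression-matrix simulation (for the time-course statistics)


def _step_shapes(n_timepoints: int, n_patterns: int) -> np.ndarray:
    """Block patterns: pattern k holds a contiguous run of time points at 1.

    The affected time points then sit at exactly ``effect_fold`` times the
    unaffected ones, so a "4-fold effect" means a genuine 4-fold change at
    those points (a ramp scaled to the same range would expose most time
    points to much less than the nominal fold change).
    """
    edges = np.linspace(0, n_timepoints, n_patterns + 1).astype(int)
    shapes = np.zeros((n_patterns, n_timepoints))
    for k in range(n_patterns):
        shapes[k, edges[k] : max(edges[k + 1], edges[k] + 1)] = 1.0
    return shapes


def simulate_expression_matrix(
    n_genes: int = 5000,
    n_timepoints: int = 6,
    n_replicates: int = 3,
    fraction_de: float = 0.1,
    effect_fold: float = 4.0,
    n_patterns: int = 3,
    pattern_style: str = "step",
    rep_sd_log2: float = DEFAULT_REPLICATE_SD_LOG2,
    base_log10_range: tuple[float, float] = (-0.5, 2.5),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """TPM matrix with replicate noise and planted differential expression.

    Replicate variation is log-normal: log2 observed TPM = log2 true TPM +
    N(0, ``rep_sd_log2``), emulating biological replicates of clonal
    material. Returns (tpm genes x samples, truth table, sample -> timepoint
    map). DE genes cycle through ``n_patterns`` temporal patterns with
    max/min fold change ``effect_fold``: distinct up-regulated time blocks
    (``pattern_style="step"``, the default) or the smooth shape bank
    (``"smooth"``).
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    base = 10.0 ** rng.uniform(*base_log10_range, size=n_genes)
    n_de = int(round(fraction_de * n_genes))
    de_mask = np.zeros(n_genes, dtype=bool)
    de_mask[rng.choice(n_genes, size=n_de, replace=False)] = True
    if pattern_style == "step":
        shapes = _step_shapes(n_timepoints, n_patterns)
    elif pattern_style == "smooth":
        shapes = _pattern_shapes(n_timepoints, n_patterns)
    else:
        raise ValueError(f"unknown pattern_style {pattern_style!r}")
    log2_amp = np.log2(effect_fold)

    labels = np.array(["null"] * n_genes, dtype=object)
    profile = np.ones((n_genes, n_timepoints))
    for j, gi in enumerate(np.flatnonzero(de_mask)):
        k = j % n_patterns
        labels[gi] = f"p{k}"
        profile[gi] = 2.0 ** (log2_amp * shapes[k])
    true_tpm = base[:, None] * profile

    samples, times = [], {}
    cols = []
    for t in range(n_timepoints):
        for r in range(n_replicates):
            name = f"t{t}_r{r + 1}"
            samples.append(name)
            times[name] = f"t{t}"
            noise = rng.normal(0.0, rep_sd_log2, size=n_genes)
            cols.append(true_tpm[:, t] * 2.0**noise)
    tpm = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(gene_ids, name="gene_id"),
        columns=samples,
    )
    truth = pd.DataFrame(
        {"de": de_mask, "pattern": labels},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return tpm, truth, times
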