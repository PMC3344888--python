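"""Quality-control analyses for 5'-tag libraries.

Covers the restriction-site bias profile around EcoP15I motifs, replicate
correlation, the transcript length vs TPM relationship, mapping statistics
and the Poisson stochastic error expected at a given expression level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counting import TagArray, compute_tpm
from .regions import GeneModel
from .simulate import ECOP15I_FORWARD, ECOP15I_REVERSE

logger = logging.getLogger(__name__)


@dataclass
class BiasProfile:
    """Cumulative tag weight at positions relative to a 6-mer motif.

    Offset 0 is the first base of the motif; negative offsets are genomic
    left of the site. Summed over all exact occurrences of the motif, both
    strands' tag weights combined.
    """

    motif: str
    offsets: np.ndarray     # -window .. +window
    weights: np.ndarray
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "weight": self.weights})

    def normalized(self) -> np.ndarray:
        mean = self.weights.mean()
        return self.weights / mean if mean > 0 else self.weights


def _find_motif(seq: str, motif: str) -> list[int]:
    out, start = [], 0
    while True:
        s = seq.find(motif, start)
        if s < 0:
            return out
        out.append(s)
        start = s + 1


def ecop15i_bias_profile(
    scaffolds: Sequence[tuple[str, str]],
    tags: TagArray,
    window_bp: int = 100,
    motifs: Sequence[str] = (ECOP15I_FORWARD, ECOP15I_REVERSE),
) -> dict[str, BiasProfile]:
    """Cumulative tag weights around every occurrence of each motif."""
    offsets = np.arange(-window_bp, window_bp + 1)
    profiles = {}
    for motif in motifs:
        acc = np.zeros(offsets.size)
        n_sites = 0
        for name, seq in scaffolds:
            total = tags.get(name, "+") + tags.get(name, "-")
            L = total.size
            for s in _find_motif(seq, motif):
                lo, hi = s - window_bp, s + window_bp + 1
                a, b = max(lo, 0), min(hi, L)
                acc[a - lo : acc.size - (hi - b)] += total[a:b]
                n_sites += 1
        if n_sites == 0:
            warnings.warn(f"no occurrences of motif {motif}; empty profile")
        profiles[motif] = BiasProfile(motif, offsets.copy(), acc, n_sites)
    return profiles


def estimate_suppression_factor(
    profile: BiasProfile,
    suppressed: tuple[int, int] = (-20, 0),
    flanks: Sequence[tuple[int, int]] = ((-100, -40), (40, 100)),
) -> float:
    """Ratio of mean flanking tag weight to mean weight in the window.

    ``suppressed`` and ``flanks`` are half-open offset intervals relative to
    the motif's first base. A value of ~3 means tags in the window are
    depleted threefold relative to the local background.
    """
    off = profile.offsets
    sup_mask = (off >= suppressed[0]) & (off < suppressed[1])
    flank_mask = np.zeros_like(sup_mask)
    for a, b in flanks:
        flank_mask |= (off >= a) & (off < b)
    sup_mean = profile.weights[sup_mask].mean()
    flank_mean = profile.weights[flank_mask].mean()
    if sup_mean <= 0:
        return float("inf")
    return float(flank_mean / sup_mean)


def profile_flatness_pvalue(profile: BiasProfile) -> float:
    """Chi-square test of the profile against a flat expectation."""
    w = profile.weights
    expected = np.full_like(w, w.mean())
    if expected[0] <= 0:
        return 1.0
    chi2 = ((w - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(chi2, w.size - 1))


def replicate_correlation(
    tpm: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    scale: str = "log10",
    min_tpm: float = 1.0,
) -> float:
    """Squared Pearson correlation between two samples' TPM values.

    Genes below ``min_tpm`` in either sample are excluded; with the default
    log10 scale the correlation is computed on log-transformed values,
    matching how replicate scatter is normally inspected.
    """
    a = tpm[sample_a]
    b = tpm[sample_b]
    keep = (a >= min_tpm) & (b >= min_tpm)
    if int(keep.sum()) < 3:
        raise ValueError("fewer than 3 genes pass the min_tpm filter")
    x, y = a[keep].to_numpy(), b[keep].to_numpy()
    if scale == "log10":
        x, y = np.log10(x), np.log10(y)
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def length_vs_tpm(
    gene_models: Sequence[GeneModel],
    tpm: pd.Series,
    bin_size_genes: int = 1000,
) -> pd.DataFrame:
    """Five-number TPM summaries for genes binned by summed exon length.

    Genes are sorted by exon length (gene_id as the deterministic
    tie-break) and chunked into bins of ``bin_size_genes``; a final partial
    bin is retained and flagged.
    """
    lengths = pd.Series(
        {m.gene_id: m.exon_length for m in gene_models}, name="exon_length"
    )
    df = pd.DataFrame({"exon_length": lengths, "tpm": tpm}).dropna()
    # deterministic order: length, then gene_id
    df = df.iloc[np.lexsort((df.index.to_numpy(), df["exon_length"].to_numpy()))]
    rows = []
    for b, start in enumerate(range(0, len(df), bin_size_genes)):
        chunk = df.iloc[start : start + bin_size_genes]
        q = chunk["tpm"].quantile([0, 0.25, 0.5, 0.75, 1.0])
        rows.append(
            {
                "bin": b,
                "n_genes": len(chunk),
                "partial": len(chunk) < bin_size_genes,
                "length_min": int(chunk["exon_length"].min()),
                "length_max": int(chunk["exon_length"].max()),
                "tpm_min": q[0],
                "tpm_q1": q[0.25],
                "tpm_median": q[0.5],
                "tpm_q3": q[0.75],
                "tpm_max": q[1.0],
            }
        )
    return pd.DataFrame(rows).set_index("bin")


def mapping_stats(
    total_reads: int,
    low_info_removed: int,
    mapped_reads: int,
    unique_reads: int,
) -> dict:
    """Percentages for the run manifest; NA where a denominator is zero."""
    mappable = total_reads - low_info_removed

    def pct(num, den):
        return 100.0 * num / den if den else None

    return {
        "total_reads": total_reads,
        "low_information_removed": low_info_removed,
        "mapped_reads": mapped_reads,
        "unique_reads": unique_reads,
        "pct_low_information": pct(low_info_removed, total_reads),
        "pct_mapped": pct(mapped_reads, mappable),
        "pct_unique_of_mapped": pct(unique_reads, mapped_reads),
    }


def stochastic_error_at_tpm(
    tpm: float,
    depth: int,
    n_replicates: int = 2000,
    seed: int = 0,
) -> float:
    """Relative stochastic error (SD/mean) of the TPM estimate at a depth.

    Monte-Carlo Poisson resampling: a gene at ``tpm`` sequenced to ``depth``
    mapped tags yields counts ~ Poisson(depth * tpm / 1e6); the error is the
    relative standard deviation of the recovered TPM estimates (analytically
    1/sqrt(lambda)).
    """
    if depth <= 0 or tpm < 0:
        raise ValueError("depth must be positive and tpm non-negative")
    rng = np.random.default_rng(seed)
    lam = depth * tpm / 1e6
    counts = rng.poisson(lam, size=n_replicates)
    est = compute_tpm(counts.astype(float), depth)
    mean = est.mean()
    if mean == 0:
        return float("nan")
    return float(est.std(ddof=1) / mean)
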