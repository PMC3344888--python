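"""Strand-resolved tag accumulation, region counting and TPM.

Every mapped read deposits a total weight of exactly 1.0 into a per-strand,
genome-length array of floats: 1.0 at its single best location, or 1/n at
each of its n least-mismatch locations when the hit is ambiguous. Summing
array cells over an interval therefore gives a (possibly fractional) tag
count, and dividing by the total mapped reads times 10^6 gives tags per
million (TPM). No transcript-length normalization is applied: one tag is
one observed 5' end, regardless of how long the mRNA is.

The cell a read is recorded in is, by default, the genomic position of the
transcript's 5'-most base. Tags are sequenced from the antisense strand of
the cDNA, so a transcript on strand s produces reads mapping to strand -s;
with the default ``antisense`` convention a gene is counted from tags mapped
to the opposite strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .mapping import MapHit, MapHits
from .reference import ConcatenatedReference
from .regions import ExtendedRegion

_STRANDS = ("+", "-")


@dataclass
class TagArray:
    """Fractional tag weights per (scaffold, strand) genomic position."""

    arrays: dict[tuple[str, str], np.ndarray]
    total_mapped: float = 0.0
    n_reads: int = 0

    @classmethod
    def zeros(cls, scaffold_lengths: Mapping[str, int]) -> "TagArray":
        arrays = {
            (name, strand): np.zeros(length, dtype=np.float64)
            for name, length in scaffold_lengths.items()
            for strand in _STRANDS
        }
        return cls(arrays)

    def get(self, scaffold: str, strand: str) -> np.ndarray:
        return self.arrays[(scaffold, strand)]

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {name: arr.size for (name, strand), arr in self.arrays.items()
                if strand == "+"}


def tag_record_position(
    window_start: int,
    mapped_strand: str,
    tag_length: int,
    convention: str = "transcript_five_prime",
) -> int:
    """Cell a hit is recorded in.

    ``transcript_five_prime``: sequencing runs from 25 bp inside the
    transcript back toward the cap, so the biological 5' end of the tag is
    the last sequenced base -- the window start for a minus-strand hit
    (transcript on +) and the window end for a plus-strand hit (transcript
    on -). ``window_start`` records the alignment start instead.
    """
    if convention == "window_start":
        return window_start
    if convention != "transcript_five_prime":
        raise ValueError(f"unknown position convention {convention!r}")
    return window_start if mapped_strand == "-" else window_start + tag_length - 1


def accumulate_tags(
    hits: "MapHits | Iterable[Sequence[MapHit]]",
    scaffold_lengths: Mapping[str, int],
    mode: str = "fractional",
    position_convention: str = "transcript_five_prime",
    tag_length: int = 25,
    reference: ConcatenatedReference | None = None,
) -> TagArray:
    """Accumulate mapped reads into a :class:`TagArray`.

    ``hits`` is either a :class:`MapHits` batch table (fast path; requires
    ``reference`` for coordinate translation) or an iterable of non-empty
    per-read hit lists. In ``fractional`` mode an n-way ambiguous read adds
    1/n at each least-mismatch location; in ``unique_only`` mode ambiguous
    reads are discarded entirely.
    """
    if mode not in ("fractional", "unique_only"):
        raise ValueError(f"unknown mode {mode!r}")
    tags = TagArray.zeros(scaffold_lengths)
    if isinstance(hits, MapHits):
        if reference is None:
            raise ValueError("a ConcatenatedReference is required for MapHits input")
        _accumulate_batch(tags, hits, reference, mode, position_convention)
    else:
        for read_hits in hits:
            if not read_hits:
                raise ValueError(
                    "empty hit list in stream; unmapped reads must be "
                    "filtered before accumulation"
                )
            best = min(h.mismatches for h in read_hits)
            top = [h for h in read_hits if h.mismatches == best]
            if mode == "unique_only" and len(top) > 1:
                continue
            w = 1.0 / len(top)
            for h in top:
                pos = tag_record_position(
                    h.position, h.strand, tag_length, position_convention
                )
                tags.get(h.scaffold, h.strand)[pos] += w
            tags.total_mapped += 1.0
            tags.n_reads += 1
    return tags


def _accumulate_batch(
    tags: TagArray,
    hits: MapHits,
    reference: ConcatenatedReference,
    mode: str,
    position_convention: str,
) -> None:
    if len(hits) == 0:
        return
    ri = hits.read_index
    # per-read least mismatch via segmented minimum (rows sorted by read)
    new_seg = np.diff(ri, prepend=ri[0] - 1) != 0
    starts = np.flatnonzero(new_seg)
    seg_min = np.minimum.reduceat(hits.mismatches, starts)
    seg_id = np.cumsum(new_seg) - 1
    is_best = hits.mismatches == seg_min[seg_id]
    n_best = np.add.reduceat(is_best.astype(np.int64), starts)
    if mode == "unique_only":
        keep_read = n_best == 1
        row_keep = is_best & keep_read[seg_id]
        weights = np.ones(int(row_keep.sum()))
        n_counted = int(keep_read.sum())
    else:
        row_keep = is_best
        weights = 1.0 / n_best[seg_id][row_keep]
        n_counted = int(starts.size)

    gpos = hits.gpos[row_keep]
    strand = hits.strand[row_keep]
    rec = np.where(
        strand == 1, gpos, gpos + hits.tag_length - 1
    ) if position_convention == "transcript_five_prime" else gpos
    if position_convention not in ("transcript_five_prime", "window_start"):
        raise ValueError(f"unknown position convention {position_convention!r}")

    # translate global -> (scaffold, local) vectorized via offset bins
    names = reference.names
    offs = np.array([reference.offsets[n] for n in names], dtype=np.int64)
    ends = offs + np.array([reference.lengths[n] for n in names], dtype=np.int64)
    scaf_idx = np.searchsorted(offs, rec, side="right") - 1
    if np.any(rec >= ends[scaf_idx]):
        raise ValueError("tag position falls inside a spacer region")
    local = rec - offs[scaf_idx]
    for si, name in enumerate(names):
        for sc, strand_char in ((0, "+"), (1, "-")):
            sel = (scaf_idx == si) & (strand == sc)
            if np.any(sel):
                np.add.at(tags.get(name, strand_char), local[sel], weights[sel])
    tags.total_mapped += float(weights.sum())
    tags.n_reads += n_counted


def count_region(
    tags: TagArray,
    region: ExtendedRegion,
    strand_convention: str = "antisense",
) -> float:
    """Sum tag weights over a region on the strand the convention implies."""
    if region.end > tags.get(region.scaffold, "+").size or region.start < 0:
        raise ValueError(f"{region.gene_id}: region out of array bounds")
    opposite = {"+": "-", "-": "+"}[region.strand]
    if strand_convention == "antisense":
        strands = [opposite]
    elif strand_convention == "sense":
        strands = [region.strand]
    elif strand_convention == "both":
        strands = ["+", "-"]
    else:
        raise ValueError(f"unknown strand convention {strand_convention!r}")
    return float(
        sum(tags.get(region.scaffold, s)[region.start : region.end].sum()
            for s in strands)
    )


def compute_tpm(counts: "pd.Series | np.ndarray | float", total_mapped: float):
    """Tags per million: count / total mapped reads * 10^6."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return counts / total_mapped * 1e6


def binned_track(
    tags: TagArray,
    scaffold: str,
    strand: str,
    start: int,
    end: int,
    n_bins: int,
) -> np.ndarray:
    """Bin sums over [start, end); conserves the region total exactly."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    span = end - start
    if span < 1:
        raise ValueError("empty range")
    n_bins = min(n_bins, span)  # at least one position per bin
    arr = tags.get(scaffold, strand)[start:end]
    edges = np.linspace(0, span, n_bins + 1).astype(np.int64)
    return np.add.reduceat(arr, edges[:-1])


@dataclass
class CountTable:
    """Genes x samples raw fractional counts and TPM."""

    counts: pd.DataFrame            # genes x samples, fractional tag counts
    total_mapped: dict[str, float]  # per-sample mapped-read totals

    @property
    def tpm(self) -> pd.DataFrame:
        totals = pd.Series(self.total_mapped)
        return self.counts / totals * 1e6

    def add_sample(
        self,
        sample: str,
        tags: TagArray,
        regions: Sequence[ExtendedRegion],
        strand_convention: str = "antisense",
    ) -> None:
        col = pd.Series(
            {r.gene_id: count_region(tags, r, strand_convention) for r in regions},
            name=sample,
        )
        self.counts[sample] = col
        self.total_mapped[sample] = tags.total_mapped

    @classmethod
    def empty(cls, gene_ids: Sequence[str]) -> "CountTable":
        return cls(pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")), {})

    def write_tsv(self, path: str | Path) -> None:
        tpm = self.tpm
        out = pd.concat(
            {"count": self.counts.round(6), "tpm": tpm.round(6)}, axis=1
        )
        out.columns = [f"{kind}:{sample}" for kind, sample in out.columns]
        with open(path, "w") as fh:
            fh.write("# fractional tag counts and TPM per extended gene region\n")
            out.to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        counts = df[[c for c in df.columns if c.startswith("count:")]]
        counts.columns = [c.split(":", 1)[1] for c in counts.columns]
        tpm = df[[c for c in df.columns if c.startswith("tpm:")]]
        tpm.columns = [c.split(":", 1)[1] for c in tpm.columns]
        return counts, tpm


def write_bedgraph(
    tags: TagArray, strand: str, path: str | Path, name: str = "tags"
) -> None:
    """Per-strand bedGraph (0-based half-open) of nonzero cells."""
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="{name}({strand})" '
            "description=\"fractional 5' tag weights, 0-based half-open\"\n"
        )
        for scaf in tags.scaffold_lengths:
            arr = tags.get(scaf, strand)
            nz = np.flatnonzero(arr)
            if nz.size == 0:
                continue
            # merge adjacent equal-valued cells into intervals
            breaks = np.flatnonzero(
                (np.diff(nz) != 1) | (np.diff(arr[nz]) != 0)
            )
            seg_starts = np.concatenate(([0], breaks + 1))
            seg_ends = np.concatenate((breaks, [nz.size - 1]))
            for a, b in zip(seg_starts, seg_ends):
                fh.write(f"{scaf}\t{nz[a]}\t{nz[b] + 1}\t{arr[nz[a]]:.6g}\n")


def run_manifest(
    total_reads: int,
    low_info_removed: int,
    mapped_reads: int,
    unique_reads: int,
    path: str | Path | None = None,
) -> dict:
    """Per-run read accounting, written as JSON when ``path`` is given."""
    mappable = total_reads - low_info_removed
    manifest = {
        "total_reads": total_reads,
        "low_information_removed": low_info_removed,
        "mapped_reads": mapped_reads,
        "unique_reads": unique_reads,
        "pct_low_information": _pct(low_info_removed, total_reads),
        "pct_mapped": _pct(mapped_reads, mappable),
        "pct_unique_of_mapped": _pct(unique_reads, mapped_reads),
    }
    if path is not None:
        Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _pct(num: int, den: int) -> float | None:
    return round(100.0 * num / den, 3) if den else None
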