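"""SOLiD di-base color-space encoding, decoding and the low-information filter.

Each color symbol 0-3 encodes the transition between two adjacent bases.
With the 2-bit base codes A=0, C=1, G=2, T=3 the color is simply the XOR of
the two codes, which reproduces the canonical 4x4 di-base matrix:
identical pair -> 0; A<->C, G<->T -> 1; A<->G, C<->T -> 2; A<->T, C<->G -> 3.
Because complementing a base flips both bits (A<->T, C<->G), colors are
complement-invariant: the reverse complement of a sequence has the reversed
color string. The mapper relies on that property for minus-strand search.

A read is the synthetic primer base followed by one color per sequenced
base; for 25 bp tags that is 25 colors, the first of which encodes the
primer-to-first-base transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# byte-level lookup tables for vectorized encoding
_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_CODE.items():
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i
_COLOR_LUT = np.full(256, 255, dtype=np.uint8)
for _c in "0123":
    _COLOR_LUT[ord(_c)] = int(_c)


@dataclass
class ColorRead:
    """A single SOLiD-style read: primer base plus a color string."""

    id: str
    primer_base: str
    colors: str
    quality: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if self.primer_base not in _BASE_CODE:
            raise ValueError(f"invalid primer base {self.primer_base!r}")
        bad = set(self.colors) - set("0123")
        if bad:
            raise ValueError(f"invalid color characters {sorted(bad)} in read {self.id}")

    @property
    def n_informative(self) -> int:
        """Number of non-'0' colors (a color 0 repeats the previous base)."""
        return sum(1 for c in self.colors if c != "0")

    def decode(self) -> str:
        return decode_colorspace(self.primer_base, self.colors)


@dataclass
class ReadBatch:
    """Column-oriented container for many reads of equal length.

    Used on the bulk path (simulation, mapping at library scale) where one
    Python object per read would dominate memory. ``colors`` holds one row
    per read with values 0-3.
    """

    ids: list[str]
    primer_base: str
    colors: np.ndarray  # (n_reads, read_length) uint8

    def __len__(self) -> int:
        return self.colors.shape[0]

    @property
    def read_length(self) -> int:
        return self.colors.shape[1]

    def color_strings(self) -> list[str]:
        lut = np.array([ord(c) for c in "0123"], dtype=np.uint8)
        return [bytes(lut[row]).decode() for row in self.colors]

    def to_reads(self) -> list[ColorRead]:
        return [
            ColorRead(i, self.primer_base, s)
            for i, s in zip(self.ids, self.color_strings())
        ]

    def subset(self, index: np.ndarray) -> "ReadBatch":
        ids = [self.ids[i] for i in np.atleast_1d(index)]
        return ReadBatch(ids, self.primer_base, self.colors[index])

    @classmethod
    def from_reads(cls, reads: Sequence[ColorRead]) -> "ReadBatch":
        if not reads:
            raise ValueError("empty read list")
        primer = reads[0].primer_base
        length = len(reads[0].colors)
        for r in reads:
            if r.primer_base != primer:
                raise ValueError("mixed primer bases in one batch")
            if len(r.colors) != length:
                raise ValueError("mixed read lengths in one batch")
        colors = np.empty((len(reads), length), dtype=np.uint8)
        for i, r in enumerate(reads):
            colors[i] = _COLOR_LUT[np.frombuffer(r.colors.encode(), dtype=np.uint8)]
        return cls([r.id for r in reads], primer, colors)


def encode_colorspace(sequence: str, primer_base: str) -> str:
    """Encode a DNA sequence into colors, prefixed by the primer transition."""
    if not sequence:
        raise ValueError("empty sequence")
    if primer_base not in _BASE_CODE:
        raise ValueError(f"invalid primer base {primer_base!r}")
    codes = _BASE_LUT[np.frombuffer(sequence.upper().encode(), dtype=np.uint8)]
    bad = np.flatnonzero(codes == 255)
    if bad.size:
        raise ValueError(
            f"non-ACGT character {sequence[bad[0]]!r} at position {int(bad[0])}"
        )
    prev = np.concatenate(([_BASE_CODE[primer_base]], codes[:-1])).astype(np.uint8)
    colors = prev ^ codes
    return "".join("0123"[c] for c in colors)


def decode_colorspace(primer_base: str, colors: str) -> str:
    """Invert :func:`encode_colorspace`."""
    if primer_base not in _BASE_CODE:
        raise ValueError(f"invalid primer base {primer_base!r}")
    code = _BASE_CODE[primer_base]
    out = []
    for i, c in enumerate(colors):
        if c not in "0123":
            raise ValueError(f"invalid color character {c!r} at position {i}")
        code ^= int(c)
        out.append(_BASES[code])
    return "".join(out)


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class FilterReport:
    total: int
    kept: int
    removed: int
    threshold: int

    @property
    def removed_fraction(self) -> float:
        return self.removed / self.total if self.total else 0.0


def filter_low_information(
    reads: "Sequence[ColorRead] | ReadBatch", threshold: int = 3
) -> tuple["list[ColorRead] | ReadBatch", "list[ColorRead] | ReadBatch", FilterReport]:
    """Remove reads with ``threshold`` or fewer non-0 colors.

    Near-monochrome reads carry almost no sequence information (long runs of
    color 0 arise from homopolymers) and produce spurious alignments, so they
    are dropped before mapping. Returns ``(kept, removed, report)``.
    """
    if isinstance(reads, ReadBatch):
        nonzero = (reads.colors != 0).sum(axis=1)
        keep = nonzero > threshold
        report = FilterReport(len(reads), int(keep.sum()), int((~keep).sum()), threshold)
        return (
            reads.subset(np.flatnonzero(keep)),
            reads.subset(np.flatnonzero(~keep)),
            report,
        )
    kept = [r for r in reads if r.n_informative > threshold]
    removed = [r for r in reads if r.n_informative <= threshold]
    return kept, removed, FilterReport(len(reads), len(kept), len(removed), threshold)


# ---------------------------------------------------------------------------
# csfasta I/O


def read_csfasta(path: str | Path) -> list[ColorRead]:
    """Parse a csfasta file: '>' header lines, then primer base + colors."""
    reads: list[ColorRead] = []
    current_id: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                current_id = line[1:].split()[0]
            else:
                if current_id is None:
                    raise ValueError(f"{path}:{lineno}: sequence line before header")
                reads.append(ColorRead(current_id, line[0], line[1:]))
                current_id = None
    return reads


def read_csfasta_batch(path: str | Path) -> ReadBatch:
    return ReadBatch.from_reads(read_csfasta(path))


def write_csfasta(
    reads: "Iterable[ColorRead] | ReadBatch", path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("# csfasta: primer base followed by di-base colors\n")
        if isinstance(reads, ReadBatch):
            primer = reads.primer_base
            for rid, colors in zip(reads.ids, reads.color_strings()):
                fh.write(f">{rid}\n{primer}{colors}\n")
        else:
            for r in reads:
                fh.write(f">{r.id}\n{r.primer_base}{r.colors}\n")
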