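"""Reference genome handling.

Scaffolds are concatenated into a single sequence with a 60-N spacer after
each segment, so a tag can never align across a scaffold boundary (N has no
valid color-space encoding). An offset map converts between global
(concatenated) and local (per-scaffold) coordinates; all coordinates are
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SPACER_N = 60


@dataclass
class ConcatenatedReference:
    """Single concatenated sequence plus an invertible scaffold offset map."""

    sequence: str
    names: list[str]
    offsets: dict[str, int]          # scaffold name -> global start
    lengths: dict[str, int]          # scaffold name -> scaffold length
    spacer: int = SPACER_N

    def __len__(self) -> int:
        return len(self.sequence)

    def to_global(self, scaffold: str, position: int) -> int:
        if not 0 <= position < self.lengths[scaffold]:
            raise ValueError(
                f"position {position} outside scaffold {scaffold!r} "
                f"[0, {self.lengths[scaffold]})"
            )
        return self.offsets[scaffold] + position

    def to_local(self, global_position: int) -> tuple[str, int]:
        if not 0 <= global_position < len(self.sequence):
            raise ValueError(f"global position {global_position} out of bounds")
        for name in self.names:
            start = self.offsets[name]
            if start <= global_position < start + self.lengths[name]:
                return name, global_position - start
        raise ValueError(
            f"global position {global_position} falls in a spacer region"
        )

    def scaffold_sequence(self, name: str) -> str:
        start = self.offsets[name]
        return self.sequence[start : start + self.lengths[name]]

    def iter_scaffolds(self) -> Iterator[tuple[str, str]]:
        for name in self.names:
            yield name, self.scaffold_sequence(name)


def concatenate_reference(
    scaffolds: "Iterable[tuple[str, str]] | str | Path",
    spacer: int = SPACER_N,
) -> ConcatenatedReference:
    """Concatenate scaffolds with ``spacer`` Ns after each segment.

    ``scaffolds`` is either an iterable of ``(name, sequence)`` pairs or a
    path to a FASTA file.
    """
    if isinstance(scaffolds, (str, Path)):
        scaffolds = read_fasta(scaffolds)

    parts: list[str] = []
    names: list[str] = []
    offsets: dict[str, int] = {}
    lengths: dict[str, int] = {}
    pos = 0
    for name, seq in scaffolds:
        if name in offsets:
            raise ValueError(f"duplicate scaffold name {name!r}")
        seq = str(seq).upper()
        names.append(name)
        offsets[name] = pos
        lengths[name] = len(seq)
        parts.append(seq)
        parts.append("N" * spacer)
        pos += len(seq) + spacer
    if not names:
        raise ValueError("no scaffolds given")
    return ConcatenatedReference(
        sequence="".join(parts),
        names=names,
        offsets=offsets,
        lengths=lengths,
        spacer=spacer,
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(scaffolds: Iterable[tuple[str, str]], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in scaffolds
    ]
    SeqIO.write(records, str(path), "fasta")
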