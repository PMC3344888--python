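"""Gene models and extended counting regions.

Because 5'-tag peaks usually fall upstream of annotated gene models (UTR
annotation is sparse), each gene is counted over a widened interval: up to
2 kb added on the 5' side and 1 kb on the 3' side, in transcription
orientation. When two same-strand neighbors are closer than the combined
caps allow, the intervening gap is divided 1:2 -- one part to the upstream
gene's 3' extension, two parts to the downstream gene's 5' extension -- so
the widened regions abut without overlapping. Opposite-strand neighbors are
ignored; counting is strand-resolved, so cross-strand overlap cannot
double-count.

All in-memory coordinates are 0-based half-open; GFF3 (1-based inclusive)
is converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

logger = logging.getLogger(__name__)

FIVE_EXT_BP = 2000
THREE_EXT_BP = 1000
GAP_THRESHOLD_BP = 3000


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    scaffold: str
    strand: str
    start: int  # 0-based half-open
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        exons = self.exons or ((self.start, self.end),)
        object.__setattr__(self, "exons", tuple(sorted(exons)))
        prev_end = self.start
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon outside gene bounds")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping or unsorted exons")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start (5'-most base)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class ExtendedRegion:
    gene_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    five_ext_bp: int
    three_ext_bp: int
    clipped_five: bool = False
    clipped_three: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def parse_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene (+ optional exon) features from GFF3 into 0-based models."""
    if not any(
        line.strip() and not line.startswith("#")
        for line in Path(path).read_text().splitlines()
    ):
        return []
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises several parse error types
        raise ValueError(f"failed to parse GFF3 {path}: {exc}") from exc

    models: list[GeneModel] = []
    seen: set[str] = set()
    for gene in db.features_of_type("gene"):
        gid = gene.id
        if gid in seen:
            raise ValueError(f"duplicate gene_id {gid!r}")
        seen.add(gid)
        if gene.end < gene.start:
            raise ValueError(f"{gid}: end < start in GFF3")
        exons = tuple(
            (child.start - 1, child.end)
            for child in db.children(gene, featuretype="exon", order_by="start")
        )
        models.append(
            GeneModel(
                gene_id=gid,
                scaffold=gene.seqid,
                strand=gene.strand,
                start=gene.start - 1,
                end=gene.end,
                exons=exons,
            )
        )
    models.sort(key=lambda m: (m.scaffold, m.start, m.gene_id))
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene and exon features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.scaffold, m.start, m.gene_id)):
            attrs = f"ID={m.gene_id}"
            fh.write(
                f"{m.scaffold}\tfivedge\tgene\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            for k, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.scaffold}\tfivedge\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.exon{k};Parent={m.gene_id}\n"
                )


def extend_gene_models(
    models: Sequence[GeneModel],
    scaffold_lengths: Mapping[str, int],
    five_ext: int = FIVE_EXT_BP,
    three_ext: int = THREE_EXT_BP,
    gap_threshold: int = GAP_THRESHOLD_BP,
) -> list[ExtendedRegion]:
    """Compute the extended counting region for every gene.

    For a same-strand gap ``d`` between neighboring gene models: if
    ``d > gap_threshold`` both genes take their full caps (``three_ext`` on
    the upstream gene's 3' side, ``five_ext`` on the downstream gene's 5'
    side); otherwise the gap is split 1:2, ``floor(d/3)`` to the 3' side and
    the remainder to the 5' side, so the shares sum exactly to ``d`` and the
    split is continuous with the capped case at ``d == three_ext + five_ext``.
    Extensions are clipped at scaffold boundaries.
    """
    regions: list[ExtendedRegion] = []
    by_group: dict[tuple[str, str], list[GeneModel]] = {}
    for m in models:
        if m.scaffold not in scaffold_lengths:
            raise ValueError(f"{m.gene_id}: unknown scaffold {m.scaffold!r}")
        if m.end > scaffold_lengths[m.scaffold]:
            raise ValueError(f"{m.gene_id}: gene extends past scaffold end")
        by_group.setdefault((m.scaffold, m.strand), []).append(m)

    for (scaffold, strand), group in sorted(by_group.items()):
        group = sorted(group, key=lambda m: m.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping same-strand genes {a.gene_id!r} and {b.gene_id!r} "
                    f"on {scaffold}{strand}"
                )
        scaffold_len = scaffold_lengths[scaffold]
        for i, m in enumerate(group):
            left_gap = m.start - (group[i - 1].end if i > 0 else None) if i > 0 else None
            right_gap = (group[i + 1].start - m.end) if i + 1 < len(group) else None
            # left/right extension in genomic orientation
            if strand == "+":
                left_cap, right_cap = five_ext, three_ext  # 5' is genomic left
            else:
                left_cap, right_cap = three_ext, five_ext
            left_amt = _side_extension(left_gap, left_cap, gap_threshold, strand, "left")
            right_amt = _side_extension(right_gap, right_cap, gap_threshold, strand, "right")

            start = m.start - left_amt
            end = m.end + right_amt
            clipped_left = start < 0
            clipped_right = end > scaffold_len
            start = max(start, 0)
            end = min(end, scaffold_len)
            left_got = m.start - start
            right_got = end - m.end
            if strand == "+":
                five_got, three_got = left_got, right_got
                clip5, clip3 = clipped_left, clipped_right
            else:
                five_got, three_got = right_got, left_got
                clip5, clip3 = clipped_right, clipped_left
            regions.append(
                ExtendedRegion(
                    gene_id=m.gene_id,
                    scaffold=scaffold,
                    strand=strand,
                    start=start,
                    end=end,
                    five_ext_bp=five_got,
                    three_ext_bp=three_got,
                    clipped_five=clip5,
                    clipped_three=clip3,
                )
            )
    regions.sort(key=lambda r: (r.scaffold, r.start, r.gene_id))
    return regions


def _side_extension(
    gap: int | None, cap: int, gap_threshold: int, strand: str, side: str
) -> int:
    """Extension on one genomic side of a gene.

    ``cap`` already encodes whether this side is the gene's 5' or 3' side.
    With a neighbor at distance ``gap``: above the threshold the full cap
    applies; at or below it the 1:2 split applies, where the gene whose 3'
    side faces the gap receives floor(gap/3) and the gene whose 5' side
    faces it receives the remainder.
    """
    if gap is None:
        return cap
    if gap > gap_threshold:
        return cap
    third = gap // 3
    # which transcription side of THIS gene faces the gap?
    five_faces_gap = (strand == "+" and side == "left") or (
        strand == "-" and side == "right"
    )
    return (gap - third) if five_faces_gap else third


def write_regions_bed(regions: Sequence[ExtendedRegion], path: str | Path) -> None:
    """Extended regions as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write('track name="extended_regions" description="0-based half-open"\n')
        for r in regions:
            fh.write(
                f"{r.scaffold}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n"
            )


def write_extension_audit(
    regions: Sequence[ExtendedRegion], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfive_ext_bp\tthree_ext_bp\tclipped_five\tclipped_three\n")
        for r in regions:
            fh.write(
                f"{r.gene_id}\t{r.five_ext_bp}\t{r.three_ext_bp}\t"
                f"{int(r.clipped_five)}\t{int(r.clipped_three)}\n"
            )
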