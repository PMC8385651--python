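"""Genomic intervals, gene annotations, and the poplar SDR gene set.

Coordinates are held internally as 0-based half-open intervals, the
convention of BED and of ordinary interval arithmetic.  GFF3 files and
published gene coordinates are 1-based inclusive and are converted at the
I/O boundary.

The sex-determining region (SDR) of the male *P. trichocarpa* "Stettler 14"
assembly spans Chr18:16,200,000-16,320,000.  The assembly places the SDR on
chromosome 18 although genetic mapping locates it on chromosome 19; the
chromosome name is treated as an opaque label and the quirk is recorded in
:data:`SDR_ASSEMBLY_NOTE` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

Strand = Literal["+", "-", "."]

SDR_ASSEMBLY_NOTE = (
    "SDR located on chromosome 18 in the Stettler 14 assembly; "
    "genetic mapping places it on chromosome 19."
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: Strand = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand: {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, pos0: int) -> bool:
        """True if the 0-based position falls inside the interval."""
        return self.start <= pos0 < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if not self.overlaps(other):
            return 0
        return min(self.end, other.end) - max(self.start, other.start)

    @classmethod
    def from_one_based(
        cls, chrom: str, start1: int, end1: int, strand: Strand = "."
    ) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (GFF3 / printed tables)."""
        return cls(chrom, start1 - 1, end1, strand)

    def to_one_based(self) -> tuple[int, int]:
        """Return (start, end) in 1-based inclusive convention."""
        return self.start + 1, self.end


@dataclass(frozen=True)
class GeneAnnotation:
    """A named gene span; the interval is opaque (UTR status unknown)."""

    gene_id: str
    symbol: str
    interval: GenomicInterval


#: The SDR scan window: Chr18:16,200,000-16,320,000, 120 kb.
SDR_REGION = GenomicInterval("Chr18", 16_200_000, 16_320_000)

#: Width of coverage bins used for the SDR scan (bp).
SDR_BIN_WIDTH = 200

# Published 1-based inclusive spans of the five SDR genes.
_SDR_GENE_TABLE = (
    ("PtStettler14.18G127900", "TCP", 16_275_593, 16_279_859, "-"),
    ("PtStettler14.18G127800", "CLC", 16_268_169, 16_272_894, "-"),
    ("PtStettler14.18G127700", "MET1", 16_249_745, 16_259_190, "-"),
    ("PtStettler14.18G127600", "NB-ARC", 16_226_313, 16_236_215, "-"),
    ("PtStettler14.18G127500", "unknown", 16_214_199, 16_215_600, "+"),
)


def build_sdr_genes() -> list[GeneAnnotation]:
    """The five annotated SDR genes of the Stettler 14 reference.

    TCP, CLC, MET1 and NB-ARC lie on the reverse strand; the unannotated
    fifth gene is on the forward strand.  Coordinates are converted from
    the published 1-based inclusive spans.
    """
    return [
        GeneAnnotation(
            gene_id,
            symbol,
            GenomicInterval.from_one_based("Chr18", s, e, strand),
        )
        for gene_id, symbol, s, e, strand in _SDR_GENE_TABLE
    ]


def bin_interval(region: GenomicInterval, width: int) -> list[GenomicInterval]:
    """Tile ``region`` with contiguous bins of ``width`` bp.

    The final bin is truncated when the region length is not a multiple of
    the width.  Bins inherit the region's chromosome and are unstranded.
    """
    if width < 1:
        raise ValueError(f"bin width must be >= 1, got {width}")
    return [
        GenomicInterval(region.chrom, s, min(s + width, region.end))
        for s in range(region.start, region.end, width)
    ]


def assign_gene(pos0: int, chrom: str, genes: Iterable[GeneAnnotation]) -> str | None:
    """Gene id covering the 0-based position, or None (genes assumed disjoint)."""
    for g in genes:
        if g.interval.chrom == chrom and g.interval.contains_point(pos0):
            return g.gene_id
    return None


class AnnotationParseError(ValueError):
    """Raised on a malformed annotation line; carries the line number."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def read_annotation(path: str | Path, fmt: str | None = None) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 (1-based) or 6-column BED (0-based).

    ``fmt`` is ``"gff3"`` or ``"bed"``; inferred from the suffix if omitted.
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() == ".bed" else "gff3"
    fmt = fmt.lower()
    if fmt not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation format: {fmt}")

    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    if len(fields) < 4:
                        raise ValueError("BED line needs >= 4 columns")
                    chrom, start, end, name = fields[:4]
                    strand = fields[5] if len(fields) >= 6 else "."
                    interval = GenomicInterval(chrom, int(start), int(end), strand)
                    gene_id = symbol = name
                else:
                    if len(fields) != 9:
                        raise ValueError("GFF3 line needs 9 columns")
                    chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields
                    if ftype != "gene":
                        continue
                    attr_map = dict(
                        kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                    )
                    gene_id = attr_map.get("ID", "")
                    if not gene_id:
                        raise ValueError("gene record lacks ID attribute")
                    symbol = attr_map.get("Name", gene_id)
                    interval = GenomicInterval.from_one_based(
                        chrom, int(start), int(end), strand if strand in "+-" else "."
                    )
            except (ValueError, IndexError) as exc:
                raise AnnotationParseError(path, lineno, str(exc)) from exc
            if gene_id in seen:
                raise AnnotationParseError(path, lineno, f"duplicate gene id {gene_id}")
            seen.add(gene_id)
            genes.append(GeneAnnotation(gene_id, symbol, interval))
    return genes


def write_annotation(
    genes: Iterable[GeneAnnotation], path: str | Path, fmt: str | None = None
) -> None:
    """Write annotations as GFF3 or BED6 (see :func:`read_annotation`)."""
    path = Path(path)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() == ".bed" else "gff3"
    fmt = fmt.lower()
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            for g in genes:
                s1, e1 = g.interval.to_one_based()
                fh.write(
                    f"{g.interval.chrom}\tsdrase\tgene\t{s1}\t{e1}\t.\t"
                    f"{g.interval.strand}\t.\tID={g.gene_id};Name={g.symbol}\n"
                )
        elif fmt == "bed":
            for g in genes:
                iv = g.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t.\t{iv.strand}\n"
                )
        else:
            raise ValueError(f"unknown annotation format: {fmt}")


def packaged_sdr_gff3() -> Path:
    """Path to the GFF3 copy of the SDR gene set shipped with the package."""
    return Path(resources.files("sdrase").joinpath("data/sdr_genes.gff3"))
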