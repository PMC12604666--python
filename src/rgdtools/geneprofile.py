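"""Gene-level variant-density profiling and track building.

A gene span is tiled into consecutive fixed-width windows (500 bp by
default) covering the entire gene; each window reports the number of
pathogenic catalog variants falling inside it. The per-window table supports
assay design (e.g. choosing a dPCR amplicon segment dense in known
pathogenic sites). A four-tier track model — chromosome context, gene span,
exon intervals, variant positions — backs genome-browser-style display and
BED export.

Coordinates are 1-based closed intervals internally; BED output uses the
conventional 0-based half-open representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .catalog import GeneModel, GenomicVariant

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_SEGMENT_WIDTH",
    "GeneModel",
    "SegmentProfile",
    "TrackSet",
    "segment_gene",
    "count_variants_per_segment",
    "build_tracks",
    "write_profile",
    "read_profile",
    "write_bed",
    "read_bed",
]

#: default window width in base pairs
DEFAULT_SEGMENT_WIDTH = 500


@dataclass(frozen=True)
class SegmentProfile:
    """Per-window pathogenic-variant counts tiling one gene span."""

    gene_symbol: str
    chrom: str
    width: int
    segments: tuple[tuple[int, int, int], ...]  # (start, end, n_variants)

    @property
    def total(self) -> int:
        return sum(n for _, _, n in self.segments)


@dataclass(frozen=True)
class TrackSet:
    """Four ordered display tiers for one gene.

    Tier 1 is the chromosome context (the enclosing range), tier 2 the gene
    span, tier 3 the exon intervals, tier 4 the variant positions. All
    coordinates of tiers 2-4 fall within tier 1.
    """

    gene_symbol: str
    chrom: str
    strand: str
    chromosome_range: tuple[int, int]
    gene_span: tuple[int, int]
    exons: tuple[tuple[int, int], ...]
    variants: tuple[int, ...]


def segment_gene(
    gene: GeneModel, width: int = DEFAULT_SEGMENT_WIDTH
) -> list[tuple[int, int]]:
    """Tile the gene span into consecutive ``width``-bp windows.

    Windows start at ``gene.start``; the last window is truncated at
    ``gene.end`` so that coverage is exact with no gaps or overlaps.
    """
    if width < 1:
        raise ValueError(f"segment width must be >= 1, got {width}")
    return [
        (s, min(s + width - 1, gene.end))
        for s in range(gene.start, gene.end + 1, width)
    ]


def count_variants_per_segment(
    segments: Sequence[tuple[int, int]],
    variants: Iterable[GenomicVariant],
    gene: GeneModel,
) -> SegmentProfile:
    """Count variants per window; each in-span variant lands in exactly one.

    Variants on a different chromosome are excluded with a warning; variants
    outside the gene span are ignored. Window intervals are closed, so a
    variant at a window's end position belongs to that window.
    """
    if not segments or segments[0][0] != gene.start or segments[-1][1] != gene.end:
        raise ValueError("segments do not tile the gene span")
    width = segments[0][1] - segments[0][0] + 1
    counts = [0] * len(segments)
    for v in variants:
        if v.chrom != gene.chrom:
            logger.warning(
                "variant %s on %s ignored for gene %s on %s",
                v, v.chrom, gene.symbol, gene.chrom,
            )
            continue
        if gene.start <= v.pos <= gene.end:
            counts[(v.pos - gene.start) // width] += 1
    return SegmentProfile(
        gene_symbol=gene.symbol,
        chrom=gene.chrom,
        width=width,
        segments=tuple(
            (s, e, n) for (s, e), n in zip(segments, counts)
        ),
    )


def build_tracks(gene: GeneModel, variants: Iterable[GenomicVariant]) -> TrackSet:
    """Assemble the four-tier display model for one gene.

    The chromosome-context tier is the union of the gene span and all
    same-chromosome variant positions, so tiers 2-4 always fit inside it.
    """
    positions = tuple(
        sorted(v.pos for v in variants if v.chrom == gene.chrom)
    )
    lo = min((gene.start, *positions))
    hi = max((gene.end, *positions))
    return TrackSet(
        gene_symbol=gene.symbol,
        chrom=gene.chrom,
        strand=gene.strand,
        chromosome_range=(lo, hi),
        gene_span=(gene.start, gene.end),
        exons=gene.exons,
        variants=positions,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = ["segment", "chrom", "start", "end", "count"]


def write_profile(profile: SegmentProfile, path) -> None:
    """Write the per-window count table as TSV."""
    rows = [
        {"segment": i + 1, "chrom": profile.chrom, "start": s, "end": e, "count": n}
        for i, (s, e, n) in enumerate(profile.segments)
    ]
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_profile(path, gene_symbol: str = ".") -> SegmentProfile:
    df = pd.read_csv(path, sep="\t")
    segments = tuple(
        (int(r.start), int(r.end), int(r.count)) for r in df.itertuples(index=False)
    )
    width = segments[0][1] - segments[0][0] + 1 if segments else 0
    chrom = str(df.chrom.iloc[0]) if len(df) else "chr1"
    return SegmentProfile(
        gene_symbol=gene_symbol, chrom=chrom, width=width, segments=segments
    )


def write_bed(obj: SegmentProfile | TrackSet, path) -> None:
    """Export a profile or track set as BED (0-based half-open intervals).

    A :class:`SegmentProfile` becomes one track with the window count in the
    score column; a :class:`TrackSet` becomes four tracks.
    """
    lines: list[str] = []
    if isinstance(obj, SegmentProfile):
        lines.append(f'track name="{obj.gene_symbol}_segments" useScore=1')
        for i, (s, e, n) in enumerate(obj.segments):
            lines.append(
                f"{obj.chrom}\t{s - 1}\t{e}\t{obj.gene_symbol}_seg{i + 1}\t{n}\t."
            )
    else:
        strand = obj.strand
        lines.append(f'track name="{obj.gene_symbol}_chromosome"')
        lo, hi = obj.chromosome_range
        lines.append(f"{obj.chrom}\t{lo - 1}\t{hi}\t{obj.chrom}\t0\t.")
        lines.append(f'track name="{obj.gene_symbol}_gene"')
        gs, ge = obj.gene_span
        lines.append(f"{obj.chrom}\t{gs - 1}\t{ge}\t{obj.gene_symbol}\t0\t{strand}")
        lines.append(f'track name="{obj.gene_symbol}_exons"')
        for i, (s, e) in enumerate(obj.exons):
            lines.append(
                f"{obj.chrom}\t{s - 1}\t{e}\t{obj.gene_symbol}_exon{i + 1}\t0\t{strand}"
            )
        lines.append(f'track name="{obj.gene_symbol}_variants"')
        for i, p in enumerate(obj.variants):
            lines.append(
                f"{obj.chrom}\t{p - 1}\t{p}\t{obj.gene_symbol}_var{i + 1}\t0\t{strand}"
            )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_bed(path) -> list[tuple[str, int, int, str, int]]:
    """Read BED intervals back as 1-based closed (chrom, start, end, name, score)."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line or line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else "."
        score = int(fields[4]) if len(fields) > 4 else 0
        out.append((chrom, start + 1, end, name, score))
    return out
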