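"""CpG-context and genic annotation of target regions.

The CpG-centric annotation partitions each chromosome, relative to its
CpG islands, into island / shore (0-2 kb flank) / shelf (2-4 kb flank) /
open sea, with N denoting the lower-coordinate and S the higher-coordinate
flank (Illumina manifest convention, strand-independent). The genic
annotator is a simplified single-transcript reimplementation of the usual
precedence-based scheme (CDS-exonic > UTR > ncRNA-exonic > intronic >
up/downstream > intergenic).
"""
from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .regions import GeneModel, GenomicInterval, TargetRegion

logger = logging.getLogger(__name__)

SHORE_BP = 2000
SHELF_BP = 2000
UPDOWNSTREAM_BP = 1000


class CpGContext(str, Enum):
    ISLAND = "ISLAND"
    N_SHORE = "N_SHORE"
    S_SHORE = "S_SHORE"
    N_SHELF = "N_SHELF"
    S_SHELF = "S_SHELF"
    OPEN_SEA = "OPEN_SEA"


#: priority tiers for region-level context assignment (highest first)
_CONTEXT_PRIORITY = [
    (CpGContext.ISLAND,),
    (CpGContext.N_SHORE, CpGContext.S_SHORE),
    (CpGContext.N_SHELF, CpGContext.S_SHELF),
    (CpGContext.OPEN_SEA,),
]


class GenicCategory(str, Enum):
    EXONIC = "EXONIC"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    NCRNA_EXONIC = "NCRNA_EXONIC"
    INTRONIC = "INTRONIC"
    NCRNA_INTRONIC = "NCRNA_INTRONIC"
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    INTERGENIC = "INTERGENIC"


#: overlap categories in decreasing precedence
_GENIC_PRECEDENCE = [
    GenicCategory.EXONIC,
    GenicCategory.UTR5,
    GenicCategory.UTR3,
    GenicCategory.NCRNA_EXONIC,
    GenicCategory.INTRONIC,
    GenicCategory.NCRNA_INTRONIC,
]


class CodingClass(str, Enum):
    CODING = "CODING"
    NONCODING = "NONCODING"


@dataclass(frozen=True)
class GenicAnnotation:
    category: GenicCategory
    nearest_gene: str | None
    distance: int | None  # bp; 0 when overlapping, None when no genes exist


ContextMap = dict[str, list[tuple[int, int, CpGContext]]]


def build_context_map(
    islands: list[GenomicInterval],
    chrom_lengths: dict[str, int],
    *,
    shore_bp: int = SHORE_BP,
    shelf_bp: int = SHELF_BP,
) -> ContextMap:
    """Partition every chromosome into CpG contexts around its islands.

    Flanks of adjacent islands may collide; each base then belongs to the
    nearer island's context (distance to the island edge; ties go to the
    lower-coordinate island). Returns, per chromosome, a sorted list of
    (start, end, context) tiles covering [0, length) exactly once.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_lengths}
    for isl in islands:
        if isl.chrom not in chrom_lengths:
            raise ValueError(f"island on unknown chromosome {isl.chrom}")
        if isl.end > chrom_lengths[isl.chrom]:
            raise ValueError(f"island {isl.chrom}:{isl.start}-{isl.end} exceeds chromosome")
        by_chrom[isl.chrom].append(isl)

    cmap: ContextMap = {}
    for chrom, length in chrom_lengths.items():
        isls = sorted(by_chrom[chrom], key=lambda i: i.start)
        for a, b in zip(isls, isls[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping islands on {chrom}: {a} / {b}")
        tiles: list[tuple[int, int, CpGContext]] = []
        if not isls:
            cmap[chrom] = [(0, length, CpGContext.OPEN_SEA)]
            continue
        # leading gap: N flank of the first island
        _add_flank_tiles(tiles, 0, isls[0].start, side="N", shore_bp=shore_bp, shelf_bp=shelf_bp)
        for i, isl in enumerate(isls):
            tiles.append((isl.start, isl.end, CpGContext.ISLAND))
            gap_end = isls[i + 1].start if i + 1 < len(isls) else length
            if i + 1 < len(isls):
                # split the inter-island gap at the nearest-island midpoint;
                # a tied base goes to the lower-coordinate island (S side)
                split = (isl.end + gap_end + 1) // 2
                _add_flank_tiles(tiles, isl.end, split, side="S", shore_bp=shore_bp, shelf_bp=shelf_bp)
                _add_flank_tiles(tiles, split, gap_end, side="N", shore_bp=shore_bp, shelf_bp=shelf_bp)
            else:
                _add_flank_tiles(tiles, isl.end, gap_end, side="S", shore_bp=shore_bp, shelf_bp=shelf_bp)
        cmap[chrom] = _merge_tiles([t for t in tiles if t[0] < t[1]])
    return cmap


def _add_flank_tiles(tiles, lo: int, hi: int, *, side: str, shore_bp: int, shelf_bp: int) -> None:
    """Fill [lo, hi) with shore/shelf/open-sea tiles anchored at the island edge.

    ``side="S"`` anchors at lo (island immediately to the left);
    ``side="N"`` anchors at hi (island immediately to the right).
    """
    if lo >= hi:
        return
    shore = CpGContext.S_SHORE if side == "S" else CpGContext.N_SHORE
    shelf = CpGContext.S_SHELF if side == "S" else CpGContext.N_SHELF
    if side == "S":
        a = min(hi, lo + shore_bp)
        b = min(hi, lo + shore_bp + shelf_bp)
        tiles.append((lo, a, shore))
        tiles.append((a, b, shelf))
        tiles.append((b, hi, CpGContext.OPEN_SEA))
    else:
        a = max(lo, hi - shore_bp)
        b = max(lo, hi - shore_bp - shelf_bp)
        tiles.append((a, hi, shore))
        tiles.append((b, a, shelf))
        tiles.append((lo, b, CpGContext.OPEN_SEA))


def _merge_tiles(tiles):
    tiles = sorted(tiles)
    merged = [tiles[0]]
    for s, e, c in tiles[1:]:
        ps, pe, pc = merged[-1]
        if c == pc and s == pe:
            merged[-1] = (ps, e, c)
        else:
            merged.append((s, e, c))
    return merged


def context_at(cmap: ContextMap, chrom: str, pos: int) -> CpGContext:
    """Context of a single base (bisect lookup into the tile partition)."""
    tiles = cmap[chrom]
    i = bisect.bisect_right(tiles, (pos, float("inf"))) - 1
    s, e, c = tiles[i]
    if not (s <= pos < e):
        raise ValueError(f"position {chrom}:{pos} outside context map")
    return c


def annotate_cpg_context(region: TargetRegion, cmap: ContextMap) -> CpGContext:
    """Assign one CpG context to a region that may straddle several tiles.

    Priority island > shore > shelf > open sea among overlapped contexts;
    within a tier the larger base overlap wins, ties N before S.
    """
    if region.chrom not in cmap:
        raise ValueError(f"region {region.region_id} on unknown chromosome {region.chrom}")
    overlaps: dict[CpGContext, int] = {}
    tiles = cmap[region.chrom]
    i = bisect.bisect_right(tiles, (region.start, float("inf"))) - 1
    i = max(i, 0)
    while i < len(tiles) and tiles[i][0] < region.end:
        s, e, c = tiles[i]
        ov = min(e, region.end) - max(s, region.start)
        if ov > 0:
            overlaps[c] = overlaps.get(c, 0) + ov
        i += 1
    for tier in _CONTEXT_PRIORITY:
        present = [c for c in tier if c in overlaps]
        if present:
            # larger overlap wins; tie -> N before S (tier order lists N first)
            return max(present, key=lambda c: (overlaps[c], -tier.index(c)))
    raise AssertionError("context map does not cover region")  # partition guarantee


def annotate_regions_cpg(regions: list[TargetRegion], cmap: ContextMap) -> pd.Series:
    return pd.Series(
        {r.region_id: annotate_cpg_context(r, cmap).value for r in regions},
        name="cpg_context",
    )


def _gene_overlap_category(region: TargetRegion, gene: GeneModel) -> GenicCategory | None:
    """Highest-precedence overlap category of region vs one gene, or None."""
    iv = region.interval
    if not iv.overlaps(gene.transcript):
        return None
    exon_ov = any(iv.overlaps(ex) for ex in gene.exons)
    if gene.coding:
        if any(iv.overlaps(c) for c in gene.cds):
            return GenicCategory.EXONIC
        if exon_ov:
            # exonic but outside CDS: UTR; side relative to the CDS span, strand-aware
            cds_lo = min(c.start for c in gene.cds)
            cds_hi = max(c.end for c in gene.cds)
            utr5 = utr3 = False
            for ex in gene.exons:
                if not iv.overlaps(ex):
                    continue
                lo = max(iv.start, ex.start)
                hi = min(iv.end, ex.end)
                if lo < cds_lo:
                    if gene.strand == "+":
                        utr5 = True
                    else:
                        utr3 = True
                if hi > cds_hi:
                    if gene.strand == "+":
                        utr3 = True
                    else:
                        utr5 = True
            if utr5:
                return GenicCategory.UTR5
            if utr3:
                return GenicCategory.UTR3
            return GenicCategory.EXONIC  # overlap confined to CDS gaps within an exon
        return GenicCategory.INTRONIC
    if exon_ov:
        return GenicCategory.NCRNA_EXONIC
    return GenicCategory.NCRNA_INTRONIC


def annotate_genic(region: TargetRegion, genes: list[GeneModel]) -> GenicAnnotation:
    """Simplified precedence-based genic annotation with nearest gene.

    Overlap with any interval of a category suffices; ties across genes are
    broken by smaller distance, then lexicographic gene_id. Up/downstream
    means within 1 kb of the transcript boundary, strand-aware.
    """
    chrom_genes = sorted(
        (g for g in genes if g.chrom == region.chrom), key=lambda g: g.gene_id
    )
    if not genes:
        logger.warning("genic annotation with empty gene set: all INTERGENIC, distance undefined")
        return GenicAnnotation(GenicCategory.INTERGENIC, None, None)
    if not chrom_genes:
        return GenicAnnotation(GenicCategory.INTERGENIC, None, None)

    best: tuple[int, int, str, GenicCategory] | None = None  # (prec_rank, dist, gene_id, cat)
    for g in chrom_genes:
        cat = _gene_overlap_category(region, g)
        if cat is not None:
            rank = _GENIC_PRECEDENCE.index(cat)
            cand = (rank, 0, g.gene_id, cat)
        else:
            d = region.interval.distance_to(g.transcript)
            if d <= UPDOWNSTREAM_BP:
                region_is_left = region.interval.end <= g.transcript.start
                if g.strand == "+":
                    cat = GenicCategory.UPSTREAM if region_is_left else GenicCategory.DOWNSTREAM
                else:
                    cat = GenicCategory.DOWNSTREAM if region_is_left else GenicCategory.UPSTREAM
                cand = (len(_GENIC_PRECEDENCE), d, g.gene_id, cat)
            else:
                cand = (len(_GENIC_PRECEDENCE) + 1, d, g.gene_id, GenicCategory.INTERGENIC)
        if best is None or (cand[0], cand[1], cand[2]) < (best[0], best[1], best[2]):
            best = cand
    rank, dist, gid, cat = best
    return GenicAnnotation(cat, gid, dist)


def annotate_regions_genic(regions: list[TargetRegion], genes: list[GeneModel]) -> pd.DataFrame:
    rows = {}
    for r in regions:
        ann = annotate_genic(r, genes)
        rows[r.region_id] = {
            "genic_category": ann.category.value,
            "nearest_gene": ann.nearest_gene,
            "distance": ann.distance,
            "coding_class": classify_coding(ann).value,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "region_id"
    return df


def classify_coding(annotation: GenicAnnotation) -> CodingClass:
    """CODING iff the region overlaps a CDS exon; everything else is noncoding."""
    return CodingClass.CODING if annotation.category == GenicCategory.EXONIC else CodingClass.NONCODING


def summarize_annotation(annotations: pd.Series) -> pd.DataFrame:
    """Counts and percentages per annotation category."""
    if len(annotations) == 0:
        raise ValueError("no annotations to summarize")
    counts = annotations.value_counts()
    out = pd.DataFrame({"count": counts, "percent": 100.0 * counts / counts.sum()})
    out.index.name = "category"
    logger.info("annotation summary:\n%s", out.to_string())
    return out
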