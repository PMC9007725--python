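"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (per-base scans, exhaustive
enumeration) kept separate from the package's interval arithmetic.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np

from capmeth.annotate import CpGContext, GenicCategory
from capmeth.regions import GeneModel, GenomicInterval, TargetRegion

SHORE, SHELF = 2000, 2000


def base_context(x: int, islands: list[GenomicInterval]) -> CpGContext:
    """Context of one base by explicit nearest-island distance."""
    best = None  # (distance, island_index, side)
    for i, isl in enumerate(islands):
        if isl.start <= x < isl.end:
            return CpGContext.ISLAND
        if x < isl.start:
            cand = (isl.start - x, i, "N")
        else:
            cand = (x - isl.end + 1, i, "S")
        if best is None or cand[0] < best[0] or (cand[0] == best[0] and cand[1] < best[1]):
            best = cand
    if best is None:
        return CpGContext.OPEN_SEA
    d, _, side = best
    if d <= SHORE:
        return CpGContext.N_SHORE if side == "N" else CpGContext.S_SHORE
    if d <= SHORE + SHELF:
        return CpGContext.N_SHELF if side == "N" else CpGContext.S_SHELF
    return CpGContext.OPEN_SEA


def region_context(region: TargetRegion, islands: list[GenomicInterval]) -> CpGContext:
    """Region context by per-base scan + the priority/overlap/tie rule."""
    counts: dict[CpGContext, int] = {}
    isls = [i for i in islands if i.chrom == region.chrom]
    for x in range(region.start, region.end):
        c = base_context(x, isls)
        counts[c] = counts.get(c, 0) + 1
    tiers = [
        [CpGContext.ISLAND],
        [CpGContext.N_SHORE, CpGContext.S_SHORE],
        [CpGContext.N_SHELF, CpGContext.S_SHELF],
        [CpGContext.OPEN_SEA],
    ]
    for tier in tiers:
        present = [c for c in tier if c in counts]
        if present:
            best = max(counts[c] for c in present)
            return [c for c in present if counts[c] == best][0]  # tier order: N first
    raise AssertionError


def gene_base_sets(gene: GeneModel, chrom_len: int):
    """Explicit per-base category masks for one gene."""
    sets: dict[GenicCategory, np.ndarray] = {}
    mask = np.zeros(chrom_len, dtype=bool)

    def fill(ivs):
        m = np.zeros(chrom_len, dtype=bool)
        for iv in ivs:
            m[iv.start : iv.end] = True
        return m

    tx = fill([gene.transcript])
    ex = fill(gene.exons)
    if gene.coding:
        cds = fill(gene.cds)
        cds_lo = min(c.start for c in gene.cds)
        cds_hi = max(c.end for c in gene.cds)
        left = np.zeros(chrom_len, dtype=bool)
        left[:cds_lo] = True
        right = np.zeros(chrom_len, dtype=bool)
        right[cds_hi:] = True
        utr_left = ex & ~cds & left
        utr_right = ex & ~cds & right
        sets[GenicCategory.EXONIC] = cds | (ex & ~cds & ~left & ~right)
        if gene.strand == "+":
            sets[GenicCategory.UTR5] = utr_left
            sets[GenicCategory.UTR3] = utr_right
        else:
            sets[GenicCategory.UTR5] = utr_right
            sets[GenicCategory.UTR3] = utr_left
        sets[GenicCategory.INTRONIC] = tx & ~ex
    else:
        sets[GenicCategory.NCRNA_EXONIC] = ex
        sets[GenicCategory.NCRNA_INTRONIC] = tx & ~ex
    return sets


PRECEDENCE = [
    GenicCategory.EXONIC,
    GenicCategory.UTR5,
    GenicCategory.UTR3,
    GenicCategory.NCRNA_EXONIC,
    GenicCategory.INTRONIC,
    GenicCategory.NCRNA_INTRONIC,
]


def region_genic(region: TargetRegion, genes: list[GeneModel], chrom_len: int,
                 window: int = 1000, sets_by_gene: dict | None = None):
    """(category, nearest_gene, distance) via per-base category scans.

    ``sets_by_gene`` may carry precomputed gene_base_sets to amortize the
    per-base mask construction across many regions.
    """
    candidates = []  # (precedence_rank, distance, gene_id, category)
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.chrom != region.chrom:
            continue
        if sets_by_gene is not None and g.gene_id in sets_by_gene:
            sets = sets_by_gene[g.gene_id]
        else:
            sets = gene_base_sets(g, chrom_len)
        overlap_cat = None
        for cat in PRECEDENCE:
            if cat in sets and sets[cat][region.start : region.end].any():
                overlap_cat = cat
                break
        if overlap_cat is not None:
            candidates.append((PRECEDENCE.index(overlap_cat), 0, g.gene_id, overlap_cat))
            continue
        if region.end <= g.transcript.start:
            d = g.transcript.start - region.end
            side = "left"
        elif region.start >= g.transcript.end:
            d = region.start - g.transcript.end
            side = "right"
        else:
            # overlaps transcript but no category base (cannot happen: tx is partitioned)
            raise AssertionError
        if d <= window:
            if g.strand == "+":
                cat = GenicCategory.UPSTREAM if side == "left" else GenicCategory.DOWNSTREAM
            else:
                cat = GenicCategory.DOWNSTREAM if side == "left" else GenicCategory.UPSTREAM
            candidates.append((len(PRECEDENCE), d, g.gene_id, cat))
        else:
            candidates.append((len(PRECEDENCE) + 1, d, g.gene_id, GenicCategory.INTERGENIC))
    if not candidates:
        return GenicCategory.INTERGENIC, None, None
    rank, d, gid, cat = min(candidates, key=lambda c: (c[0], c[1], c[2]))
    return cat, gid, d


def collapse_scan(cytosines, regions):
    """O(n*m) membership scan: dict (region_id, sample) -> (meth, total)."""
    out = {}
    for r in regions:
        for row in cytosines.itertuples(index=False):
            if row.chrom == r.chrom and r.start <= row.pos < r.end:
                key = (r.region_id, row.sample_id)
                m, t = out.get(key, (0, 0))
                out[key] = (m + row.meth, t + row.total)
    return out


def mwu_enumeration(a, b):
    """Exhaustive two-sided Mann-Whitney p over all group splits of the pool."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n_a, n = len(a), len(pooled)
    order = pooled.argsort(kind="mergesort")
    sorted_vals = pooled[order]
    # midranks
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[i:j] = (i + j + 1) / 2
        i = j
    rank_of = np.empty(n)
    rank_of[order] = ranks

    def u_of(idx):
        return rank_of[list(idx)].sum() - n_a * (n_a + 1) / 2

    mu = n_a * (n - n_a) / 2
    u_obs = u_of(range(n_a))
    hits = total = 0
    for idx in combinations(range(n), n_a):
        total += 1
        if abs(u_of(idx) - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return u_obs, hits / total
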