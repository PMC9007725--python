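"""Region-level methylation quantification.

Collapses per-cytosine methylated/total read counts onto capture target
regions, converts counts to methylation fractions (beta values), and
applies the all-sample coverage filter used before differential testing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import TargetRegion, check_unique_ids

logger = logging.getLogger(__name__)

CYTOSINE_COLUMNS = ["chrom", "pos", "sample_id", "meth", "total"]


@dataclass
class MethCountMatrix:
    """Paired regions x samples matrices of (methylated reads, total reads).

    Both frames share the same region_id index and sample_id columns and
    satisfy 0 <= meth <= total cell-wise.
    """

    meth: pd.DataFrame
    total: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.total.index):
            raise ValueError("meth/total region indices differ")
        if not self.meth.columns.equals(self.total.columns):
            raise ValueError("meth/total sample columns differ")
        if self.meth.index.has_duplicates:
            raise ValueError("duplicate region_id in count matrix")
        m = self.meth.to_numpy()
        t = self.total.to_numpy()
        if (m < 0).any() or (t < 0).any():
            raise ValueError("negative read counts")
        bad = m > t
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"meth > total at region {self.meth.index[i]!r}, "
                f"sample {self.meth.columns[j]!r}"
            )

    @property
    def region_ids(self) -> pd.Index:
        return self.meth.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.meth.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.meth.shape

    def subset_regions(self, region_ids) -> "MethCountMatrix":
        return MethCountMatrix(self.meth.loc[region_ids], self.total.loc[region_ids])

    def equals(self, other: "MethCountMatrix") -> bool:
        return self.meth.equals(other.meth) and self.total.equals(other.total)


def validate_cytosine_table(cytosines: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CYTOSINE_COLUMNS if c not in cytosines.columns]
    if missing:
        raise ValueError(f"cytosine table missing columns: {missing}")
    if ((cytosines["meth"] < 0) | (cytosines["meth"] > cytosines["total"])).any():
        raise ValueError("cytosine table violates 0 <= meth <= total")
    return cytosines


def collapse_to_regions(
    cytosines: pd.DataFrame,
    regions: list[TargetRegion],
    *,
    allow_overlapping_regions: bool = False,
) -> MethCountMatrix:
    """Sum cytosine counts into their containing target regions.

    A cytosine at position p contributes to a region [start, end) iff
    start <= p < end. Regions with no cytosine get (0, 0). Cytosines on
    chromosomes absent from the region set are skipped with a logged count.

    By default regions must be non-overlapping; with
    ``allow_overlapping_regions`` a cytosine contributes to every region
    containing it.
    """
    validate_cytosine_table(cytosines)
    check_unique_ids(regions)
    region_ids = [r.region_id for r in regions]
    samples = sorted(cytosines["sample_id"].unique())

    if allow_overlapping_regions:
        assigned = _assign_overlapping(cytosines, regions)
    else:
        _check_disjoint(regions)
        assigned = _assign_disjoint(cytosines, regions)

    n_skipped = len(cytosines) - assigned["__in_any__"].sum()
    known_chroms = {r.chrom for r in regions}
    n_unknown = (~cytosines["chrom"].isin(known_chroms)).sum()
    if n_unknown:
        logger.warning(
            "%d cytosines on chromosomes absent from the region set were skipped",
            n_unknown,
        )
    logger.info(
        "collapse: %d cytosines, %d assigned to %d regions, %d outside all regions",
        len(cytosines), int(assigned["__in_any__"].sum()), len(regions),
        int(n_skipped),
    )

    hits = assigned[assigned["region_id"].notna()]
    agg = (
        hits.groupby(["region_id", "sample_id"])[["meth", "total"]]
        .sum()
        .unstack("sample_id", fill_value=0)
    )
    meth = pd.DataFrame(0, index=region_ids, columns=samples, dtype=np.int64)
    total = meth.copy()
    if len(agg):
        meth.update(agg["meth"])
        total.update(agg["total"])
    meth.index.name = total.index.name = "region_id"
    return MethCountMatrix(meth.astype(np.int64), total.astype(np.int64))


def _check_disjoint(regions: list[TargetRegion]) -> None:
    by_chrom: dict[str, list[TargetRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: (r.start, r.end))
        for a, b in zip(rs, rs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping regions {a.region_id}/{b.region_id} on {chrom}; "
                    "pass allow_overlapping_regions=True to permit"
                )


def _assign_disjoint(cytosines: pd.DataFrame, regions: list[TargetRegion]) -> pd.DataFrame:
    """Vectorised interval lookup via searchsorted on sorted disjoint regions."""
    out = cytosines.copy()
    out["region_id"] = pd.Series([None] * len(out), index=out.index, dtype=object)
    for chrom, grp in cytosines.groupby("chrom", sort=False):
        rs = sorted((r for r in regions if r.chrom == chrom), key=lambda r: r.start)
        if not rs:
            continue
        starts = np.array([r.start for r in rs])
        ends = np.array([r.end for r in rs])
        ids = np.array([r.region_id for r in rs], dtype=object)
        pos = grp["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        hit = np.where(inside, ids[np.clip(idx, 0, None)], None)
        out.loc[grp.index, "region_id"] = hit
    out["__in_any__"] = out["region_id"].notna()
    return out


def _assign_overlapping(cytosines: pd.DataFrame, regions: list[TargetRegion]) -> pd.DataFrame:
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.region_id)
    rows = []
    in_any = []
    for row in cytosines.itertuples(index=False):
        tree = trees.get(row.chrom)
        hits = sorted(iv.data for iv in tree[row.pos]) if tree is not None else []
        in_any.append(bool(hits))
        if not hits:
            rows.append((None, row.sample_id, row.meth, row.total))
        for rid in hits:
            rows.append((rid, row.sample_id, row.meth, row.total))
    out = pd.DataFrame(rows, columns=["region_id", "sample_id", "meth", "total"])
    out["__in_any__"] = out["region_id"].notna()
    return out


def compute_beta(counts: MethCountMatrix) -> pd.DataFrame:
    """Methylation fraction meth/total per cell; NaN (undefined) where total == 0.

    Fractions range from 0 (unmethylated) to 1 (fully methylated).
    """
    total = counts.total.to_numpy(dtype=float)
    meth = counts.meth.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, meth / np.where(total > 0, total, 1.0), np.nan)
    return pd.DataFrame(beta, index=counts.region_ids, columns=counts.sample_ids)


def filter_covered_regions(
    counts: MethCountMatrix,
    samplesheet: pd.Series,
    groups: set[str],
    min_total: int = 1,
) -> MethCountMatrix:
    """Keep regions covered (total >= min_total) in every sample of the named groups.

    Mirrors the pre-test consistency filter: only regions observed in all
    tumour samples of both contrasted groups enter differential testing.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    unknown = groups - set(samplesheet.unique())
    if unknown:
        raise ValueError(f"groups not present in sample sheet: {sorted(unknown)}")
    members = samplesheet.index[samplesheet.isin(groups)]
    members = [s for s in members if s in counts.sample_ids]
    if not members:
        raise ValueError("no sample-sheet sample of the named groups appears in the matrix")
    keep = (counts.total[members] >= min_total).all(axis=1)
    kept = counts.subset_regions(counts.region_ids[keep])
    logger.info(
        "coverage filter (min_total=%d, groups=%s): retained %d / %d regions",
        min_total, sorted(groups), int(keep.sum()), len(keep),
    )
    return kept
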