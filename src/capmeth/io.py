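"""Readers and writers for the pipeline's text formats.

BED intervals are strictly 0-based half-open. Count matrices are wide
TSVs with a ``region_id`` key column followed by ``<sample>_meth`` /
``<sample>_total`` pairs. All output is UTF-8, LF, tab-delimited.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import MethCountMatrix
from .regions import GeneModel, GenomicInterval, TargetRegion, check_unique_ids

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file; message carries the file and line number."""


def _parse_bed_line(path, lineno: int, line: str, min_fields: int):
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_fields:
        raise FormatError(f"{path}:{lineno}: expected >= {min_fields} fields")
    chrom, start, end = fields[0], fields[1], fields[2]
    try:
        start, end = int(start), int(end)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer coordinates")
    if end <= start:
        raise FormatError(f"{path}:{lineno}: empty or inverted interval {start}-{end}")
    if start < 0:
        raise FormatError(f"{path}:{lineno}: negative start")
    return chrom, start, end, fields


def read_bed(path) -> list[TargetRegion]:
    """BED3+name; a missing name column gets a positional id."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, fields = _parse_bed_line(path, lineno, line, 3)
            name = fields[3] if len(fields) > 3 else f"region_{lineno:06d}"
            regions.append(TargetRegion(GenomicInterval(chrom, start, end), name))
    check_unique_ids(regions)
    return regions


def write_bed(path, regions: list[TargetRegion]) -> None:
    with open(path, "w", newline="\n") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


def read_islands(path) -> list[GenomicInterval]:
    return [r.interval for r in read_bed(path)]


def write_islands(path, islands: list[GenomicInterval]) -> None:
    with open(path, "w", newline="\n") as fh:
        for i, isl in enumerate(islands, 1):
            fh.write(f"{isl.chrom}\t{isl.start}\t{isl.end}\tisland_{i:05d}\n")


def read_bed12(path) -> list[GeneModel]:
    """BED12 gene models: blocks are exons, thickStart/thickEnd the CDS span.

    thickStart == thickEnd marks a noncoding gene.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, f = _parse_bed_line(path, lineno, line, 12)
            name, strand = f[3], f[5]
            try:
                thick_s, thick_e = int(f[6]), int(f[7])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed BED12 block fields")
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}:{lineno}: blockCount does not match block lists")
            exons = tuple(
                GenomicInterval(chrom, start + o, start + o + s)
                for o, s in zip(offsets, sizes)
            )
            cds: tuple[GenomicInterval, ...] = ()
            if thick_e > thick_s:
                cds = tuple(
                    GenomicInterval(chrom, max(ex.start, thick_s), min(ex.end, thick_e))
                    for ex in exons
                    if ex.start < thick_e and ex.end > thick_s
                )
            genes.append(GeneModel(name, strand, GenomicInterval(chrom, start, end), exons, cds))
    return genes


def write_bed12(path, genes: list[GeneModel]) -> None:
    with open(path, "w", newline="\n") as fh:
        for g in genes:
            if g.coding:
                thick_s = min(c.start for c in g.cds)
                thick_e = max(c.end for c in g.cds)
            else:
                thick_s = thick_e = g.transcript.start
            sizes = ",".join(str(ex.length) for ex in g.exons)
            offsets = ",".join(str(ex.start - g.transcript.start) for ex in g.exons)
            fh.write(
                f"{g.chrom}\t{g.transcript.start}\t{g.transcript.end}\t{g.gene_id}\t0\t"
                f"{g.strand}\t{thick_s}\t{thick_e}\t0\t{len(g.exons)}\t{sizes}\t{offsets}\n"
            )


def read_gtf_lite(path) -> list[GeneModel]:
    """Minimal GTF dialect: exon/CDS features with a gene_id attribute.

    Coordinates are 1-based inclusive on input and converted to 0-based
    half-open here. Transcript extent is the exon hull; strand comes from
    the features.
    """
    import re

    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    strands: dict[str, str] = {}
    chroms: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF fields")
            chrom, _, feature, start, end, _, strand = f[0], f[1], f[2], f[3], f[4], f[5], f[6]
            if feature not in ("exon", "CDS"):
                continue
            m = re.search(r'gene_id "([^"]+)"', f[8])
            if not m:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            gid = m.group(1)
            iv = GenomicInterval(chrom, int(start) - 1, int(end))
            (exons if feature == "exon" else cds).setdefault(gid, []).append(iv)
            strands[gid], chroms[gid] = strand, chrom
    genes = []
    for gid, exs in exons.items():
        exs = sorted(exs, key=lambda e: e.start)
        tx = GenomicInterval(chroms[gid], exs[0].start, exs[-1].end)
        genes.append(GeneModel(gid, strands[gid], tx, tuple(exs),
                               tuple(sorted(cds.get(gid, []), key=lambda c: c.start))))
    return genes


def write_counts(path, counts: MethCountMatrix) -> None:
    cols = {}
    for s in counts.sample_ids:
        cols[f"{s}_meth"] = counts.meth[s]
        cols[f"{s}_total"] = counts.total[s]
    pd.DataFrame(cols, index=counts.region_ids).to_csv(path, sep="\t")


def read_counts(path) -> MethCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="region_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate region_id {dup!r}")
    samples = []
    for c in df.columns:
        if c.endswith("_meth"):
            s = c[: -len("_meth")]
            if f"{s}_total" not in df.columns:
                raise FormatError(f"{path}: column {c} lacks a matching {s}_total")
            samples.append(s)
    if not samples:
        raise FormatError(f"{path}: no <sample>_meth/<sample>_total column pairs")
    meth = df[[f"{s}_meth" for s in samples]].set_axis(samples, axis=1)
    total = df[[f"{s}_total" for s in samples]].set_axis(samples, axis=1)
    bad = (meth.to_numpy() > total.to_numpy())
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: meth > total at region {meth.index[i]!r}, sample {samples[j]!r}"
        )
    return MethCountMatrix(meth.astype(np.int64), total.astype(np.int64))


def write_beta(path, betas: pd.DataFrame) -> None:
    betas.to_csv(path, sep="\t", na_rep="NA")


def read_samplesheet(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise FormatError(f"{path}: sample sheet needs sample_id and group columns")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return pd.Series(
        df["group"].to_numpy(), index=pd.Index(df["sample_id"], name="sample_id"),
        name="group",
    )


def write_samplesheet(path, sheet: pd.Series) -> None:
    sheet.rename_axis("sample_id").to_frame("group").to_csv(path, sep="\t")


def write_truth(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    required = {"patient_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_tsv(path, frame: pd.DataFrame, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, na_rep="NA")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
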