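#!/usr/bin/env python
"""Annotate regions (CpG context, genic category) and contrast the groups.

Produces the annotation proportion tables and the Mann-Whitney contrasts:
global NFPA-vs-GH beta distributions, per CpG context, and DMR-restricted
strata by coding class.
"""
import pathlib
import sys

import pandas as pd

from capmeth import io
from capmeth.annotate import (
    annotate_regions_cpg,
    annotate_regions_genic,
    build_context_map,
    summarize_annotation,
)
from capmeth.compare import compare_by_context, compare_dmr_strata, compare_global, results_to_frame
from capmeth.quantify import compute_beta, filter_covered_regions

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sim = BASE / "sim"
    if not (BASE / "dmrs.tsv").exists():
        sys.exit("run 02_call_dmrs.py first")
    regions = io.read_bed(sim / "regions.bed")
    islands = io.read_islands(sim / "islands.bed")
    genes = io.read_bed12(sim / "genes.bed12")
    counts = io.read_counts(sim / "counts.tsv")
    sheet = io.read_samplesheet(sim / "samplesheet.tsv")
    dmrs = pd.read_csv(BASE / "dmrs.tsv", sep="\t", index_col="region_id")

    lengths: dict[str, int] = {}
    for iv in [r.interval for r in regions] + islands:
        lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end)
    cmap = build_context_map(islands, lengths)
    ann = annotate_regions_cpg(regions, cmap).to_frame()
    ann = ann.join(annotate_regions_genic(regions, genes))
    io.write_tsv(BASE / "annotations.tsv", ann)

    sig = dmrs[dmrs["significant"]]
    print(f"CpG-context mix of the {len(sig)} DMRs:")
    print(summarize_annotation(ann.loc[sig.index, "cpg_context"]).round(2).to_string())
    print(f"\ncoding/noncoding mix of the {len(sig)} DMRs:")
    print(summarize_annotation(ann.loc[sig.index, "coding_class"]).round(2).to_string())

    kept = filter_covered_regions(counts, sheet, {"GH", "NFPA"})
    betas = compute_beta(kept)
    results = [compare_global(betas, sheet)]
    results += compare_by_context(betas, sheet, ann["cpg_context"])
    frame = results_to_frame(results)
    frame.to_csv(BASE / "group_comparisons.tsv", sep="\t", index=False)
    print("\nNFPA vs GH beta distributions (Mann-Whitney):")
    print(frame.round(4).to_string(index=False))

    strata = compare_dmr_strata(dmrs, ann["coding_class"])
    strata += compare_dmr_strata(dmrs, ann["cpg_context"])
    sframe = results_to_frame(strata)
    sframe.to_csv(BASE / "dmr_strata_comparisons.tsv", sep="\t", index=False)
    print("\nDMR-restricted strata (per-region group means):")
    print(sframe.round(4).to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
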