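#!/usr/bin/env python
"""Generate the synthetic targeted-methylome study used by the later steps.

Desk-scale stand-in for the capture dataset: 5,000 target regions over a
two-chromosome toy genome, 11 GH / 10 NFPA / 5 normal samples, a global
NFPA hypermethylation shift and 2% planted DMRs at |LFC| = 2.
Writes a run directory under results/sim/.
"""
import pathlib
import sys

from capmeth import io
from capmeth.simulate import SimConfig, simulate_run

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 1


def main() -> None:
    cfg = SimConfig(seed=SEED)
    genome, regions, sheet, counts, truth = simulate_run(cfg)
    io.ensure_dir(OUT)
    io.write_bed(OUT / "regions.bed", regions)
    io.write_islands(OUT / "islands.bed", list(genome.islands))
    io.write_bed12(OUT / "genes.bed12", list(genome.genes))
    io.write_counts(OUT / "counts.tsv", counts)
    io.write_samplesheet(OUT / "samplesheet.tsv", sheet)
    io.write_truth(OUT / "truth.tsv", truth)
    print(f"simulated {len(regions)} regions x {len(sheet)} samples (seed={SEED})")
    print(f"planted DMRs: {int(truth['is_planted_dmr'].sum())}")
    print(f"run directory: {OUT}")


if __name__ == "__main__":
    sys.exit(main())
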