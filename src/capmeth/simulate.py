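"""Synthetic targeted-methylome data generation.

Emulates targeted-capture bisulfite count data for a two-tumour-group
(plus normal tissue) study design: a small genome with CpG islands and
gene models, capture target regions with the panel's length geometry
(mean 245 bp, range 2-8,131 bp), context-dependent baseline methylation
(islands low, open sea high), a global logit-scale hypermethylation shift
for the NFPA group, planted differential regions of specified log2 effect,
beta-binomial read counts, and a Table-1-like clinical cohort table.

Every generator is deterministic for a fixed seed.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotate import CpGContext, annotate_regions_cpg, build_context_map
from .quantify import MethCountMatrix
from .regions import GeneModel, GenomicInterval, TargetRegion

logger = logging.getLogger(__name__)

#: requesting at least this many regions is logged as beyond desk scale
DESK_SCALE_LIMIT = 100_000

DEFAULT_BASELINES = {
    CpGContext.ISLAND: 0.03,
    CpGContext.N_SHORE: 0.45,
    CpGContext.S_SHORE: 0.46,
    CpGContext.N_SHELF: 0.58,
    CpGContext.S_SHELF: 0.59,
    CpGContext.OPEN_SEA: 0.52,
}


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class SimConfig:
    """Study-scale simulation parameters.

    Sample sizes default to the study design (11 GH, 10 NFPA, 5 normal);
    region geometry to the capture panel's printed mean/min/max lengths.
    ``group_shift`` is the global NFPA logit-scale hypermethylation;
    ``planted_lfc`` the target log2 fold enrichment of planted DMRs;
    ``overdispersion`` the beta-binomial concentration (meth fractions are
    drawn from Beta(mu*c, (1-mu)*c) per cell).
    """

    n_regions: int = 5000
    region_length_mean: float = 245.0
    region_length_min: int = 2
    region_length_max: int = 8131
    region_length_sigma: float = 1.0
    n_gh: int = 11
    n_nfpa: int = 10
    n_normal: int = 5
    baseline_beta_by_context: dict = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    group_shift: float = 0.8
    dmr_fraction: float = 0.02
    planted_lfc: float = 2.0
    coverage_mean: float = 100.0
    coverage_shape: float = 10.0
    overdispersion: float = 150.0
    region_logit_sd: float = 0.5
    plant_mean_bounds: tuple[float, float] = (0.05, 0.95)
    seed: int = 0
    # genome geometry
    n_chromosomes: int = 2
    chrom_length: int = 3_000_000
    n_islands_per_chrom: int = 40
    island_length_mean: float = 800.0
    island_min_spacing: int = 8000
    n_genes_per_chrom: int = 30
    island_target_fraction: float = 0.15

    def __post_init__(self) -> None:
        for name in ("dmr_fraction", "island_target_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0,1]")
        for name, v in self.baseline_beta_by_context.items():
            if not (0 < v < 1):
                raise ValueError(f"baseline beta for {name} must lie in (0,1)")
        for name in ("n_regions", "n_gh", "n_nfpa", "n_chromosomes", "chrom_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_normal < 0:
            raise ValueError("n_normal must be >= 0")
        if not (self.region_length_min <= self.region_length_mean <= self.region_length_max):
            raise ValueError("require region_length_min <= mean <= max")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion (concentration) must be positive")


@dataclass(frozen=True)
class GenomeModel:
    chromosomes: tuple[tuple[str, int], ...]
    islands: tuple[GenomicInterval, ...]
    genes: tuple[GeneModel, ...]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def __post_init__(self) -> None:
        lengths = self.chrom_lengths
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for isl in self.islands:
            if isl.chrom not in lengths or isl.end > lengths[isl.chrom]:
                raise ValueError(f"island {isl} outside chromosome bounds")
            by_chrom.setdefault(isl.chrom, []).append(isl)
        for chrom, isls in by_chrom.items():
            for a, b in zip(isls, isls[1:]):
                if b.start < a.end:
                    raise ValueError(f"islands overlap or are unsorted on {chrom}")
        for g in self.genes:
            if g.chrom not in lengths or g.transcript.end > lengths[g.chrom]:
                raise ValueError(f"gene {g.gene_id} outside chromosome bounds")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per generator stage
    return np.random.default_rng([config.seed, stream])


def build_genome_model(config: SimConfig) -> GenomeModel:
    """Random genome with spaced CpG islands and single-transcript genes.

    Islands are kept >= island_min_spacing apart (default 8 kb) so shores
    and shelves of neighbours do not collide; an infeasible packing is an
    error.
    """
    rng = _rng(config, 1)
    chroms = tuple(
        (f"chr{i + 1}", config.chrom_length) for i in range(config.n_chromosomes)
    )
    islands: list[GenomicInterval] = []
    genes: list[GeneModel] = []
    for chrom, length in chroms:
        lens = np.clip(
            np.round(rng.lognormal(math.log(config.island_length_mean) - 0.045, 0.3,
                                   config.n_islands_per_chrom)),
            200, 4000,
        ).astype(int)
        n = len(lens)
        spacing = config.island_min_spacing
        needed = int(lens.sum()) + (n - 1) * spacing if n else 0
        if needed > length:
            raise ValueError(
                f"cannot place {n} islands with {spacing} bp spacing on a "
                f"{length} bp chromosome"
            )
        slack = length - needed
        extras = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for i in range(n):
            pos += extras[i] + (spacing if i else 0)
            islands.append(GenomicInterval(chrom, pos, pos + int(lens[i])))
            pos += int(lens[i])
        genes.extend(_make_genes(rng, chrom, length, config.n_genes_per_chrom))
    return GenomeModel(chroms, tuple(islands), tuple(genes))


def _make_genes(rng: np.random.Generator, chrom: str, length: int, n_genes: int) -> list[GeneModel]:
    genes = []
    for i in range(n_genes):
        n_exons = int(rng.integers(2, 7))
        exon_lens = rng.integers(100, 500, n_exons)
        intron_lens = rng.integers(200, 3000, n_exons - 1)
        tx_len = int(exon_lens.sum() + intron_lens.sum())
        start = int(rng.integers(0, max(1, length - tx_len)))
        exons = []
        pos = start
        for j in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        strand = "+" if rng.random() < 0.5 else "-"
        coding = rng.random() < 0.7
        cds: tuple[GenomicInterval, ...] = ()
        if coding:
            first, last = exons[0], exons[-1]
            utr5 = int(rng.integers(20, max(21, first.length // 2)))
            utr3 = int(rng.integers(20, max(21, last.length // 2)))
            cds_list = []
            for ex in exons:
                lo = ex.start + utr5 if ex is first else ex.start
                hi = ex.end - utr3 if ex is last else ex.end
                if lo < hi:
                    cds_list.append(GenomicInterval(chrom, lo, hi))
            cds = tuple(cds_list)
        genes.append(
            GeneModel(f"{chrom}_g{i + 1:03d}", strand, GenomicInterval(chrom, start, pos),
                      tuple(exons), cds)
        )
    return genes


def generate_target_regions(genome: GenomeModel, config: SimConfig) -> list[TargetRegion]:
    """Non-overlapping capture regions with truncated log-normal lengths.

    A fraction of regions is anchored on CpG islands to emulate the
    island enrichment of capture panels; the rest are uniform. Regions are
    returned sorted by coordinate with unique sequential ids.
    """
    if config.n_regions >= DESK_SCALE_LIMIT:
        logger.warning(
            "n_regions=%d is beyond desk scale; expect long runtimes", config.n_regions
        )
    rng = _rng(config, 2)
    mu = math.log(config.region_length_mean) - config.region_length_sigma**2 / 2
    lengths = _truncated_lognormal_lengths(rng, config, mu)

    chrom_lengths = genome.chrom_lengths
    chrom_names = list(chrom_lengths)
    islands_by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_names}
    for isl in genome.islands:
        islands_by_chrom[isl.chrom].append(isl)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    import bisect

    intervals: list[GenomicInterval] = []
    for L in lengths:
        ok = False
        for _ in range(1000):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            clen = chrom_lengths[chrom]
            if L > clen:
                continue
            isls = islands_by_chrom[chrom]
            if isls and rng.random() < config.island_target_fraction:
                isl = isls[int(rng.integers(len(isls)))]
                lo = max(0, isl.start - L + 1)
                hi = min(clen - L, isl.end - 1)
                if hi < lo:
                    continue
                start = int(rng.integers(lo, hi + 1))
            else:
                start = int(rng.integers(0, clen - L + 1))
            occ = placed[chrom]
            i = bisect.bisect_right(occ, (start, start + L))
            if i > 0 and occ[i - 1][1] > start:
                continue
            if i < len(occ) and occ[i][0] < start + L:
                continue
            bisect.insort(occ, (start, start + L))
            intervals.append(GenomicInterval(chrom, start, start + L))
            ok = True
            break
        if not ok:
            raise ValueError("could not place all regions without overlap; enlarge genome")
    intervals.sort()
    width = max(6, len(str(len(intervals))))
    return [
        TargetRegion(iv, f"region_{i + 1:0{width}d}") for i, iv in enumerate(intervals)
    ]


def _truncated_lognormal_lengths(rng, config: SimConfig, mu: float) -> np.ndarray:
    lo, hi = config.region_length_min, config.region_length_max
    if lo == hi:
        return np.full(config.n_regions, lo, dtype=int)
    out = np.empty(config.n_regions, dtype=int)
    filled = 0
    while filled < config.n_regions:
        draw = np.round(
            rng.lognormal(mu, config.region_length_sigma, 2 * (config.n_regions - filled))
        ).astype(int)
        keep = draw[(draw >= max(lo, 1)) & (draw <= hi)]
        take = min(len(keep), config.n_regions - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def make_samplesheet(config: SimConfig) -> pd.Series:
    ids, groups = [], []
    for prefix, n, grp in (("GH", config.n_gh, "GH"), ("NFPA", config.n_nfpa, "NFPA"),
                           ("NORM", config.n_normal, "NORMAL")):
        for i in range(n):
            ids.append(f"{prefix}{i + 1:02d}")
            groups.append(grp)
    return pd.Series(groups, index=pd.Index(ids, name="sample_id"), name="group")


def _plant_dmrs(
    rng: np.random.Generator, mu_gh: np.ndarray, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Choose planted regions and signed effects.

    A candidate (region, direction) is feasible only if both the unshifted
    mean and the target mean mu*2^(+/-lfc) lie inside plant_mean_bounds, so
    the nominal fold change is realized inside the measurable dynamic
    range. Returns (is_planted, signed_lfc).
    """
    n = len(mu_gh)
    n_wanted = int(round(config.dmr_fraction * n))
    planted = np.zeros(n, dtype=bool)
    signed = np.zeros(n, dtype=float)
    if n_wanted == 0 or config.planted_lfc == 0:
        return planted, signed
    lo, hi = config.plant_mean_bounds
    order = rng.permutation(n)
    n_done = 0
    for i in order:
        if n_done >= n_wanted:
            break
        if not (lo <= mu_gh[i] <= hi):
            continue
        feasible = [
            s
            for s in (config.planted_lfc, -config.planted_lfc)
            if lo <= mu_gh[i] * 2.0**s <= hi
        ]
        if not feasible:
            continue
        signed[i] = feasible[int(rng.integers(len(feasible)))]
        planted[i] = True
        n_done += 1
    if n_done < n_wanted:
        logger.warning(
            "only %d of %d requested DMRs could be planted within mean bounds %s",
            n_done, n_wanted, config.plant_mean_bounds,
        )
    return planted, signed


def simulate_meth_counts(
    regions: list[TargetRegion],
    genome: GenomeModel,
    samplesheet: pd.Series,
    config: SimConfig,
) -> tuple[MethCountMatrix, pd.DataFrame]:
    """Simulate region-level methylated/total counts plus ground truth.

    Per region, a GH-side mean is drawn around the context baseline on the
    logit scale; the NFPA mean adds the global group shift and, for planted
    regions, the logit offset realizing the planted log2 fold change.
    Totals are negative-binomial around coverage_mean; methylated counts
    are beta-binomial with the configured concentration.

    Returns the count matrix and a truth table (region_id ->
    is_planted_dmr, true_lfc, direction).
    """
    if samplesheet.isna().any() or (samplesheet == "").any():
        raise ValueError("every sample needs a group label")
    rng = _rng(config, 3)
    region_ids = [r.region_id for r in regions]
    cmap = build_context_map(list(genome.islands), genome.chrom_lengths)
    contexts = annotate_regions_cpg(regions, cmap)

    base = np.array(
        [config.baseline_beta_by_context[CpGContext(contexts[rid])] for rid in region_ids]
    )
    mu_gh = _expit(_logit(base) + rng.normal(0.0, config.region_logit_sd, len(base)))

    planted, signed_lfc = _plant_dmrs(rng, mu_gh, config)
    delta = np.zeros(len(mu_gh))
    target = np.clip(mu_gh * 2.0**signed_lfc, 1e-6, 1 - 1e-6)
    delta[planted] = (_logit(target) - _logit(mu_gh))[planted]
    mu_nfpa = _expit(_logit(mu_gh) + config.group_shift + delta)

    group_mu = {"GH": mu_gh, "NORMAL": mu_gh, "NFPA": mu_nfpa}
    c = config.overdispersion
    p_nb = config.coverage_shape / (config.coverage_shape + config.coverage_mean)
    meth = {}
    total = {}
    for sample in samplesheet.index:
        mu = group_mu[samplesheet[sample]]
        tot = rng.negative_binomial(config.coverage_shape, p_nb, len(mu))
        frac = rng.beta(mu * c, (1 - mu) * c)
        meth[sample] = rng.binomial(tot, frac)
        total[sample] = tot
    idx = pd.Index(region_ids, name="region_id")
    counts = MethCountMatrix(
        pd.DataFrame(meth, index=idx), pd.DataFrame(total, index=idx)
    )

    true_lfc = np.log2(mu_nfpa / mu_gh)
    truth = pd.DataFrame(
        {
            "is_planted_dmr": planted,
            "true_lfc": true_lfc,
            "direction": np.where(
                ~planted, "NONE", np.where(signed_lfc > 0, "NFPA_HYPER", "NFPA_HYPO")
            ),
        },
        index=idx,
    )
    logger.info(
        "simulated %d regions x %d samples; %d planted DMRs",
        len(regions), len(samplesheet), int(planted.sum()),
    )
    return counts, truth


def simulate_run(config: SimConfig):
    """Convenience wrapper: genome -> regions -> samplesheet -> counts/truth."""
    genome = build_genome_model(config)
    regions = generate_target_regions(genome, config)
    sheet = make_samplesheet(config)
    counts, truth = simulate_meth_counts(regions, genome, sheet, config)
    return genome, regions, sheet, counts, truth


COHORT_COLUMNS = [
    "patient_id", "group", "sex", "high_risk_area", "age", "macro", "dmax_mm",
    "cavernous_invasion", "ki67_pct", "p53_pct", "n_surgeries", "aip_mutation",
]


def generate_cohort_table(
    n_gh: int = 11,
    n_nfpa: int = 10,
    censor_rate: float = 0.3,
    missing_rate: float = 0.1,
    seed: int = 0,
    fixture: str | None = None,
) -> pd.DataFrame:
    """A Table-1-like clinical cohort table with censored and missing cells.

    With ``fixture="table1"`` the packaged 21-patient study table is
    returned verbatim. Otherwise both groups are drawn from identical
    distributions (a null cohort); Ki-67 values below 1% are censored to
    "<1", and ``censor_rate``/``missing_rate`` inject extra "<1" and "NA"
    entries.
    """
    if fixture == "table1":
        from .cohort import load_table1

        return load_table1()
    if fixture is not None:
        raise ValueError(f"unknown fixture {fixture!r}")
    if n_gh < 1 or n_nfpa < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= censor_rate <= 1 and 0 <= missing_rate <= 1):
        raise ValueError("rates must lie in [0,1]")
    rng = np.random.default_rng([seed, 4])
    rows = []
    for group, n in (("GH", n_gh), ("NFPA", n_nfpa)):
        for i in range(n):
            age = int(np.clip(round(rng.normal(50, 15)), 20, 85))
            dmax = round(float(np.clip(rng.lognormal(math.log(18), 0.45), 3, 60)), 1)
            ki67 = round(float(rng.lognormal(math.log(1.5), 0.7)), 1)
            p53 = int(rng.integers(0, 4))
            row = {
                "patient_id": f"{group}{i + 1}",
                "group": group,
                "sex": "M" if rng.random() < 0.4 else "F",
                "high_risk_area": "Yes" if rng.random() < 0.15 else "",
                "age": str(age),
                "macro": "Macro" if dmax >= 10 else "Micro",
                "dmax_mm": f"{dmax:g}",
                "cavernous_invasion": "Yes" if rng.random() < 0.25 else "No",
                "ki67_pct": "<1" if (ki67 < 1 or rng.random() < censor_rate) else f"{ki67:g}",
                "p53_pct": str(p53),
                "n_surgeries": str(1 + int(rng.random() < 0.15) + int(rng.random() < 0.05)),
                "aip_mutation": "Yes" if rng.random() < 0.05 else "",
            }
            for col in ("age", "dmax_mm", "ki67_pct", "p53_pct"):
                if rng.random() < missing_rate:
                    row[col] = "NA"
            rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def null_config(config: SimConfig) -> SimConfig:
    """The matching no-effect configuration (no shift, nothing planted)."""
    return replace(config, group_shift=0.0, dmr_fraction=0.0)
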