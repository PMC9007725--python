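"""Group-level methylation distribution contrasts.

Mann-Whitney U comparisons of beta-value distributions between NFPA and
GH tumours: globally, stratified by CpG context, and restricted to DMRs
stratified by coding class or context.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .differential import GROUP_GH, GROUP_NFPA, group_samples

logger = logging.getLogger(__name__)

#: exact null distribution when the product of sample sizes is at most this
EXACT_MAX_PRODUCT = 400
#: with ties, exact conditional enumeration only up to this pooled size
EXACT_TIES_MAX_POOLED = 16


@dataclass(frozen=True)
class ComparisonResult:
    stratum: str
    median_a: float
    median_b: float
    u_stat: float
    p: float
    n_a: int
    n_b: int


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Rank-sum U for sample a (midranks for ties)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2)


def _exact_tie_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumerating all splits of the pooled multiset.

    Conditional on the observed values; correct in the presence of ties but
    limited to small pooled sizes.
    """
    pooled = np.concatenate([a, b])
    n_a, n = len(a), len(pooled)
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(a, b)
    mu = len(a) * len(b) / 2
    count = 0
    total = comb(n, n_a)
    for idx in combinations(range(n), n_a):
        r_a = ranks[list(idx)].sum()
        u = r_a - n_a * (n_a + 1) / 2
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


def mann_whitney_u(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for the first sample, p).

    Uses the exact null distribution for small tie-free samples
    (n_a*n_b <= 400), exact conditional enumeration for small samples with
    ties, and the tie- and continuity-corrected normal approximation
    otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("Mann-Whitney requires non-empty samples")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if a.size * b.size <= EXACT_MAX_PRODUCT and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    if has_ties and a.size + b.size <= EXACT_TIES_MAX_POOLED:
        return _u_statistic(a, b), _exact_tie_p(a, b)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _pool_group(betas: pd.DataFrame, samplesheet: pd.Series, group: str) -> np.ndarray:
    cols = [s for s in group_samples(samplesheet, group) if s in betas.columns]
    if not cols:
        raise ValueError(f"no sample of group {group!r} in beta matrix")
    vals = betas[cols].to_numpy().ravel()
    return vals[~np.isnan(vals)]


def compare_global(
    betas: pd.DataFrame,
    samplesheet: pd.Series,
    group_a: str = GROUP_NFPA,
    group_b: str = GROUP_GH,
    stratum: str = "GLOBAL",
) -> ComparisonResult:
    """Pool every defined per-region per-sample beta within each group and compare."""
    a = _pool_group(betas, samplesheet, group_a)
    b = _pool_group(betas, samplesheet, group_b)
    u, p = mann_whitney_u(a, b)
    return ComparisonResult(
        stratum, float(np.median(a)), float(np.median(b)), u, p, a.size, b.size
    )


def compare_by_context(
    betas: pd.DataFrame,
    samplesheet: pd.Series,
    contexts: pd.Series,
    group_a: str = GROUP_NFPA,
    group_b: str = GROUP_GH,
) -> list[ComparisonResult]:
    """One comparison per CpG context, pooling rule as in compare_global."""
    missing = betas.index.difference(contexts.index)
    if len(missing):
        raise ValueError(f"{len(missing)} regions lack a context annotation")
    results = []
    for ctx in pd.unique(contexts.loc[betas.index]):
        rids = betas.index[contexts.loc[betas.index] == ctx]
        if len(rids) == 0:
            logger.warning("context %s has no regions; omitted", ctx)
            continue
        results.append(
            compare_global(betas.loc[rids], samplesheet, group_a, group_b, stratum=str(ctx))
        )
    return results


def compare_dmr_strata(
    dmrs: pd.DataFrame,
    stratifier: pd.Series,
    significant_only: bool = True,
) -> list[ComparisonResult]:
    """Compare per-region group-mean betas between groups within DMR strata.

    ``stratifier`` maps region_id to a stratum label (e.g. coding class or
    CpG context); comparisons run on the DMR table's mean_beta columns,
    restricted to significant regions by default.
    """
    if len(dmrs) == 0:
        raise ValueError("empty DMR table")
    sub = dmrs[dmrs["significant"]] if significant_only else dmrs
    results = []
    for stratum in pd.unique(stratifier.loc[sub.index.intersection(stratifier.index)]):
        rids = [r for r in sub.index if stratifier.get(r) == stratum]
        if not rids:
            logger.warning("stratum %s empty; skipped", stratum)
            continue
        a = sub.loc[rids, "mean_beta_nfpa"].to_numpy()
        b = sub.loc[rids, "mean_beta_gh"].to_numpy()
        u, p = mann_whitney_u(a, b)
        results.append(
            ComparisonResult(str(stratum), float(np.median(a)), float(np.median(b)),
                             u, p, a.size, b.size)
        )
    return results


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "stratum": r.stratum,
                "median_nfpa": r.median_a,
                "median_gh": r.median_b,
                "u_stat": r.u_stat,
                "p": r.p,
                "n_nfpa": r.n_a,
                "n_gh": r.n_b,
            }
            for r in results
        ]
    )
    return df
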