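"""Differentially methylated region (DMR) calling.

The caller contrasts two tumour groups (NFPA vs GH) on region-level beta
values: group means, log2 fold enrichment of NFPA over GH, a per-region
two-sample t-test, Bonferroni correction across all tested regions, a dual
significance rule (adjusted P <= alpha AND |LFC| > lfc_cut), and a
high/low magnitude split of the significant set at |LFC| = 2.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GROUP_NFPA = "NFPA"
GROUP_GH = "GH"


@dataclass(frozen=True)
class DMRConfig:
    alpha: float = 0.05
    lfc_cut: float = 0.5
    h_cut: float = 2.0
    epsilon: float = 1e-6
    test_variant: str = "welch"  # or "student"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if not (0 < self.lfc_cut < self.h_cut):
            raise ValueError("require 0 < lfc_cut < h_cut")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.test_variant not in ("welch", "student"):
            raise ValueError("test_variant must be 'welch' or 'student'")


def group_samples(samplesheet: pd.Series, group: str) -> list[str]:
    if group not in set(samplesheet.unique()):
        raise ValueError(f"group {group!r} absent from sample sheet")
    return list(samplesheet.index[samplesheet == group])


def group_mean_beta(betas: pd.DataFrame, samplesheet: pd.Series, group: str) -> pd.Series:
    """Arithmetic mean beta over the group's samples, per region."""
    cols = [s for s in group_samples(samplesheet, group) if s in betas.columns]
    if not cols:
        raise ValueError(f"no sample of group {group!r} present in the beta matrix")
    return betas[cols].mean(axis=1)


def log2_fold_enrichment(mean_nfpa, mean_gh, epsilon: float = 1e-6):
    """log2((mean_nfpa + eps) / (mean_gh + eps)); positive = NFPA-hypermethylated."""
    a = np.asarray(mean_nfpa, dtype=float)
    b = np.asarray(mean_gh, dtype=float)
    out = np.log2((a + epsilon) / (b + epsilon))
    if np.isscalar(mean_nfpa) or np.ndim(mean_nfpa) == 0:
        return float(out)
    if isinstance(mean_nfpa, pd.Series):
        return pd.Series(out, index=mean_nfpa.index)
    return out


def region_t_test(
    betas_a: np.ndarray,
    betas_b: np.ndarray,
    variant: str = "welch",
    axis: int = -1,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided two-sample t-test per region (rows), vectorised.

    ``variant="welch"`` uses unequal variances with Welch-Satterthwaite
    degrees of freedom; ``"student"`` pools the variance. Degenerate rows
    (both groups constant) get t=0, p=1 when the constants agree and
    p=0 with a warning when they differ.
    """
    a = np.asarray(betas_a, dtype=float)
    b = np.asarray(betas_b, dtype=float)
    if a.shape[axis] < 2 or b.shape[axis] < 2:
        raise ValueError("each group needs at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=axis, equal_var=(variant == "student"))
    t = np.atleast_1d(np.asarray(res.statistic, dtype=float)).copy()
    p = np.atleast_1d(np.asarray(res.pvalue, dtype=float)).copy()
    var_a = np.atleast_1d(a.var(axis=axis))
    var_b = np.atleast_1d(b.var(axis=axis))
    mean_a = np.atleast_1d(a.mean(axis=axis))
    mean_b = np.atleast_1d(b.mean(axis=axis))
    degenerate = (var_a == 0) & (var_b == 0)
    same = degenerate & (mean_a == mean_b)
    diff = degenerate & (mean_a != mean_b)
    t[same], p[same] = 0.0, 1.0
    if diff.any():
        warnings.warn(
            f"{int(diff.sum())} region(s) with zero variance in both groups but "
            "different means: p set to 0",
            stacklevel=2,
        )
        t[diff] = np.where(mean_a[diff] > mean_b[diff], np.inf, -np.inf)
        p[diff] = 0.0
    if np.ndim(res.statistic) == 0:
        return float(t[0]), float(p[0])
    return t, p


def bonferroni_adjust(p_values) -> np.ndarray:
    """p_adj = min(1, m * p), m = number of tested regions."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    adj = np.minimum(1.0, p * p.size)
    if isinstance(p_values, pd.Series):
        return pd.Series(adj, index=p_values.index)
    return adj


def call_dmrs(
    betas: pd.DataFrame,
    samplesheet: pd.Series,
    config: DMRConfig = DMRConfig(),
) -> pd.DataFrame:
    """Full DMR table, one row per region, sorted by p_adj then |lfc| desc.

    Expects a coverage-filtered beta matrix (no undefined cells among the
    tested groups). Significance requires BOTH the Bonferroni-adjusted
    p <= alpha and |lfc| > lfc_cut; significant regions split into
    H_DMR (|lfc| > h_cut) and L_DMR.
    """
    nfpa = [s for s in group_samples(samplesheet, GROUP_NFPA) if s in betas.columns]
    gh = [s for s in group_samples(samplesheet, GROUP_GH) if s in betas.columns]
    if len(nfpa) < 2 or len(gh) < 2:
        raise ValueError("need at least 2 samples per tested group")
    sub = betas[nfpa + gh]
    if sub.isna().any().any():
        raise ValueError("undefined beta values among tested samples; filter coverage first")

    mean_nfpa = sub[nfpa].mean(axis=1)
    mean_gh = sub[gh].mean(axis=1)
    lfc = log2_fold_enrichment(mean_nfpa, mean_gh, config.epsilon)
    t, p_raw = region_t_test(
        sub[nfpa].to_numpy(), sub[gh].to_numpy(), config.test_variant, axis=1
    )
    p_adj = bonferroni_adjust(p_raw)

    significant = (p_adj <= config.alpha) & (np.abs(lfc) > config.lfc_cut)
    direction = np.where(
        ~significant, "NONE", np.where(lfc > 0, "NFPA_HYPER", "NFPA_HYPO")
    )
    out = pd.DataFrame(
        {
            "mean_beta_nfpa": mean_nfpa,
            "mean_beta_gh": mean_gh,
            "lfc": lfc,
            "t_stat": t,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": significant.to_numpy() if isinstance(significant, pd.Series) else significant,
            "direction": direction,
        },
        index=sub.index,
    )
    out["magnitude_class"] = classify_magnitude(out, config)
    out = out.sort_values(
        by=["p_adj", "lfc"],
        key=lambda s: s.abs() if s.name == "lfc" else s,
        ascending=[True, False],
        kind="mergesort",
    )
    out.index.name = "region_id"
    n_sig = int(out["significant"].sum())
    logger.info(
        "DMR call: %d regions tested, %d significant (H=%d, L=%d)",
        len(out), n_sig,
        int((out["magnitude_class"] == "H_DMR").sum()),
        int((out["magnitude_class"] == "L_DMR").sum()),
    )
    return out


def classify_magnitude(records: pd.DataFrame, config: DMRConfig = DMRConfig()) -> pd.Series:
    """H_DMR iff significant and |lfc| > h_cut; significant otherwise L_DMR; else NONE.

    H and L partition the significant set.
    """
    sig = records["significant"].to_numpy(dtype=bool)
    high = np.abs(records["lfc"].to_numpy()) > config.h_cut
    cls = np.where(~sig, "NONE", np.where(high, "H_DMR", "L_DMR"))
    return pd.Series(cls, index=records.index, name="magnitude_class")
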