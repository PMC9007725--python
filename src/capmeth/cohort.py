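"""Clinical cohort descriptive statistics and two-group comparisons.

Handles the three value states found in clinical tables — numeric,
left-censored ("<1", typical for Ki-67 immunohistochemistry), and missing
("NA") — and reproduces the usual summary layout: per-group median and
sample SD, Welch t-tests for continuous variables and Yates-corrected
chi-square tests for 2x2 categorical contrasts.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .differential import region_t_test

logger = logging.getLogger(__name__)


class ValueState(str, Enum):
    NUMERIC = "NUMERIC"
    CENSORED_LT = "CENSORED_LT"
    MISSING = "MISSING"


@dataclass(frozen=True)
class ClinicalValue:
    state: ValueState
    value: float | None = None

    def __post_init__(self) -> None:
        if self.state is ValueState.MISSING and self.value is not None:
            raise ValueError("MISSING carries no value")
        if self.state is ValueState.CENSORED_LT and not (self.value and self.value > 0):
            raise ValueError("CENSORED_LT bound must be positive")
        if self.state is ValueState.NUMERIC and self.value is None:
            raise ValueError("NUMERIC requires a value")


def parse_clinical_value(raw, *, where: str = "") -> ClinicalValue:
    """Parse a clinical table cell: 'NA'/empty -> missing, '<x' -> censored, else numeric."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ClinicalValue(ValueState.MISSING)
    text = str(raw).strip()
    if text in ("", "NA", "na", "NaN", "nan"):
        return ClinicalValue(ValueState.MISSING)
    if text.startswith("<"):
        try:
            return ClinicalValue(ValueState.CENSORED_LT, float(text[1:]))
        except ValueError:
            pass
    try:
        return ClinicalValue(ValueState.NUMERIC, float(text.replace(",", "")))
    except ValueError:
        raise ValueError(f"unparseable clinical value {text!r}" + (f" at {where}" if where else ""))


def _retained(values: list[ClinicalValue], policy: str) -> np.ndarray:
    if policy not in ("exclude", "substitute"):
        raise ValueError("policy must be 'exclude' or 'substitute'")
    out = []
    for v in values:
        if v.state is ValueState.NUMERIC:
            out.append(v.value)
        elif v.state is ValueState.CENSORED_LT and policy == "substitute":
            out.append(v.value / 2)
    return np.asarray(out, dtype=float)


def descriptive_stats(
    values: list[ClinicalValue], policy: str = "exclude"
) -> tuple[int, float | None, float | None]:
    """(n_used, median, sample SD with the n-1 denominator).

    ``policy="exclude"`` drops missing AND censored entries;
    ``"substitute"`` replaces '<x' by x/2. Returns (0, None, None) when
    nothing is retained.
    """
    vals = _retained(values, policy)
    if vals.size == 0:
        return 0, None, None
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return int(vals.size), float(np.median(vals)), sd


def compare_continuous(
    values_a: list[ClinicalValue],
    values_b: list[ClinicalValue],
    policy: str = "exclude",
    variant: str = "welch",
) -> tuple[float, str]:
    """Two-sided two-sample t-test on retained values; returns (p, test name)."""
    a = _retained(values_a, policy)
    b = _retained(values_b, policy)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 retained values per group")
    _, p = region_t_test(a, b, variant=variant)
    return float(p), f"{variant}_t"


def compare_categorical(a_yes: int, a_no: int, b_yes: int, b_no: int) -> tuple[float, str]:
    """Chi-square with Yates continuity correction on a 2x2 table.

    The correction term is floored at zero (no overshoot when
    |ad - bc| < n/2). A zero margin makes the test undefined: p = 1 with a
    warning.
    """
    table = np.array([[a_yes, a_no], [b_yes, b_no]], dtype=float)
    if (table < 0).any():
        raise ValueError("cell counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("empty 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("2x2 table has a zero margin; chi-square undefined, p set to 1")
        return 1.0, "yates_chi2"
    a, b, c, d = float(a_yes), float(a_no), float(b_yes), float(b_no)
    n = a + b + c + d
    # Yates: n*(|ad-bc| - n/2)^2 / (r1*r2*c1*c2), correction floored at 0
    num = max(abs(a * d - b * c) - n / 2, 0.0)
    chi2 = n * num**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(stats.chi2.sf(chi2, df=1)), "yates_chi2"


CONTINUOUS_VARIABLES = ["age", "dmax_mm", "ki67_pct", "n_surgeries"]


def parse_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Parse raw string columns of a cohort table into ClinicalValue columns."""
    if table["patient_id"].duplicated().any():
        raise ValueError("duplicate patient ids")
    out = table.copy()
    for col in CONTINUOUS_VARIABLES + ["p53_pct"]:
        out[col] = [
            parse_clinical_value(v, where=f"{col}/{pid}")
            for v, pid in zip(table[col], table["patient_id"])
        ]
    return out


def cohort_summary(table: pd.DataFrame, policy: str = "exclude") -> dict:
    """Full summary of a two-group cohort table.

    Continuous variables: per-group n/median/SD and a Welch t-test.
    Sex and cavernous-sinus invasion: Yates chi-square; a blank invasion
    cell is counted as non-invasive so group denominators stay at the full
    group size, and invasion fractions/percentages are reported per group.
    """
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    parsed = parse_cohort(table)
    by_group = {g: parsed[parsed["group"] == g] for g in groups}

    summary: dict = {"groups": groups, "variables": {}}
    for var in CONTINUOUS_VARIABLES:
        entry: dict = {}
        for g in groups:
            n, med, sd = descriptive_stats(list(by_group[g][var]), policy)
            entry[g] = {"n_used": n, "median": med, "sd": sd}
        p, test = compare_continuous(
            list(by_group[groups[0]][var]), list(by_group[groups[1]][var]), policy
        )
        entry["p_value"], entry["test"] = p, test
        summary["variables"][var] = entry

    # sex: M vs F
    sex_counts = {g: (int((df["sex"] == "M").sum()), int((df["sex"] == "F").sum()))
                  for g, df in by_group.items()}
    p, test = compare_categorical(*sex_counts[groups[0]], *sex_counts[groups[1]])
    summary["variables"]["sex"] = {
        **{g: {"M": m, "F": f} for g, (m, f) in sex_counts.items()},
        "p_value": p, "test": test,
    }

    # cavernous sinus invasion: yes vs not-yes (missing counted as No)
    inv = {}
    for g, df in by_group.items():
        yes = int((df["cavernous_invasion"].fillna("") == "Yes").sum())
        n = len(df)
        inv[g] = {"yes": yes, "no": n - yes, "n": n,
                  "fraction": yes / n, "percent": round(100.0 * yes / n, 1)}
    p, test = compare_categorical(
        inv[groups[0]]["yes"], inv[groups[0]]["no"],
        inv[groups[1]]["yes"], inv[groups[1]]["no"],
    )
    summary["variables"]["cavernous_invasion"] = {**inv, "p_value": p, "test": test}

    # p53 summarised descriptively only
    p53 = {}
    for g in groups:
        n, med, sd = descriptive_stats(list(by_group[g]["p53_pct"]), policy)
        p53[g] = {"n_used": n, "median": med, "sd": sd}
    summary["variables"]["p53_pct"] = p53
    return summary


def display_round(x: float | None, ndigits: int = 2) -> float | None:
    """Half-even rounding to 2 decimals, the display convention for summaries."""
    return None if x is None else round(float(x), ndigits)


def summary_to_frame(summary: dict) -> pd.DataFrame:
    """Flatten a cohort summary into a display table rounded to 2 decimals."""
    rows = []
    g0, g1 = summary["groups"]
    for var, entry in summary["variables"].items():
        row = {"variable": var, "p_value": display_round(entry.get("p_value")),
               "test": entry.get("test")}
        for g in (g0, g1):
            stats_g = entry.get(g, {})
            if "median" in stats_g:
                row[f"{g}_n"] = stats_g["n_used"]
                row[f"{g}_median"] = display_round(stats_g["median"])
                row[f"{g}_sd"] = display_round(stats_g["sd"])
            elif "percent" in stats_g:
                row[f"{g}_n"] = stats_g["n"]
                row[f"{g}_median"] = stats_g["percent"]
        rows.append(row)
    return pd.DataFrame(rows)


def load_table1() -> pd.DataFrame:
    """The packaged 21-patient pituitary adenoma cohort table."""
    with resources.files("capmeth.data").joinpath("pituitary_cohort.csv").open() as fh:
        return pd.read_csv(fh, dtype=str)
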