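"""Participant-flow filtering and baseline ("Table 1") statistics.

The flow filter applies an ordered list of exclusion criteria to an enrolment
registry; a subject flagged for several criteria is counted once, under the
first criterion in order, so the flow-chart subtraction is exact.  Baseline
comparisons use Welch's unequal-variance t-test for continuous
characteristics and the uncorrected Pearson chi-square test for categorical
ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("guildscope")


@dataclass
class FlowReport:
    """Ordered exclusion counts for a participant flow chart."""

    n_enrolled: int
    exclusions: list[tuple[str, int]]
    n_final: int

    def to_frame(self) -> pd.DataFrame:
        rows = [("enrolled", self.n_enrolled)]
        rows += [(f"excluded: {name}", n) for name, n in self.exclusions]
        rows.append(("final", self.n_final))
        return pd.DataFrame(rows, columns=["step", "n"])


def apply_exclusions(registry: pd.DataFrame, criteria: list[str]) -> tuple[pd.Index, FlowReport]:
    """Apply ordered exclusion criteria; return retained subjects and report."""
    for crit in criteria:
        if crit not in registry.columns:
            raise ValueError(f"unknown exclusion criterion {crit!r}")
    excluded = np.zeros(len(registry), dtype=bool)
    counts = []
    for crit in criteria:
        flag = registry[crit].astype(bool).to_numpy() & ~excluded
        counts.append((crit, int(flag.sum())))
        excluded |= flag
    retained = registry.index[~excluded]
    report = FlowReport(len(registry), counts, int((~excluded).sum()))
    return retained, report


def chi_square_independence(table) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square test of independence on an r x c table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t-test; returns (statistic, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def classify_anemia(hb: float, threshold: float = 100.0) -> str:
    """Anemia call from haemoglobin (g/L): 'GA' iff hb < threshold (strict)."""
    if hb <= 0:
        raise ValueError("haemoglobin must be positive")
    return "GA" if hb < threshold else "normal"


def summarize_table1(
    meta: pd.DataFrame,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group baseline summary with tests, one row per characteristic/level.

    Continuous characteristics: mean +/- SD per group, Welch t p-value.
    Categorical: n (%) per level with percentages against the full group n,
    uncorrected chi-square across non-missing levels.  Missing values are
    excluded listwise per characteristic; absent characteristics are skipped
    with a warning.
    """
    if group_col not in meta.columns:
        raise ValueError(f"missing group column {group_col!r}")
    groups = sorted(meta[group_col].dropna().unique().tolist())
    if len(groups) != 2:
        raise ValueError("baseline summary expects exactly two groups")
    g0, g1 = groups
    rows = []
    for name in continuous or []:
        if name not in meta.columns:
            logger.warning("characteristic %r absent; skipped", name)
            continue
        sub = meta[[group_col, name]].dropna()
        a = sub.loc[sub[group_col] == g0, name].to_numpy(dtype=float)
        b = sub.loc[sub[group_col] == g1, name].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            logger.warning("characteristic %r has too few non-missing values; skipped", name)
            continue
        _, _, p = welch_t(a, b)
        rows.append(
            {
                "characteristic": name,
                "level": "",
                g0: f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                g1: f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
                "test": "welch_t",
                "p": p,
                "n_missing": len(meta) - len(sub),
            }
        )
    group_n = meta[group_col].value_counts()
    for name in categorical or []:
        if name not in meta.columns:
            logger.warning("characteristic %r absent; skipped", name)
            continue
        sub = meta[[group_col, name]].dropna()
        if sub.empty:
            logger.warning("characteristic %r all missing; omitted", name)
            continue
        ct = pd.crosstab(sub[name], sub[group_col])
        if ct.shape[0] < 2 or (ct.sum(axis=0) == 0).any():
            logger.warning("characteristic %r degenerate; skipped", name)
            continue
        _, _, p = chi_square_independence(ct.to_numpy())
        for i, level in enumerate(ct.index):
            rows.append(
                {
                    "characteristic": name,
                    "level": str(level),
                    g0: f"{ct.loc[level, g0]} ({100 * ct.loc[level, g0] / group_n[g0]:.2f})",
                    g1: f"{ct.loc[level, g1]} ({100 * ct.loc[level, g1] / group_n[g1]:.2f})",
                    "test": "chi_square",
                    "p": p if i == 0 else np.nan,
                    "n_missing": len(meta) - len(sub),
                }
            )
    return pd.DataFrame(rows)


def prevalence(n_cases: int, n_total: int) -> float:
    """Outcome prevalence in percent."""
    if n_total <= 0 or n_cases < 0 or n_cases > n_total:
        raise ValueError("invalid case/total counts")
    return 100.0 * n_cases / n_total
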