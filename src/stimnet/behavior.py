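"""Stimulation-related memory change and cohort-level behavioral statistics.

In each free-recall session, word lists are either stimulated or not.  The
memory-change score of a site is

    delta = (R_S - R_NS) / R_NS * 100

where R_S is mean percent recall over stimulated lists and R_NS over
non-stimulated lists, the first three lists of a session being excluded from
R_NS (practice/titration lists are never stimulated and do not count as
baseline).  Sites with R_NS below 8.33% (one word per 12-word list) are
excluded: the ratio is unstable near a zero denominator.

Baseline recall for stratification and correlation is R_NS itself, matching
the denominator of delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SessionRecord",
    "MemoryOutcome",
    "MIN_BASELINE_PCT",
    "memory_change",
    "one_sample_t",
    "t_from_summary",
    "two_sample_t",
    "stratify_baseline",
    "pearson_r",
    "spearman_rho",
    "kendall_tau_b",
    "outcomes_to_frame",
]

#: Minimum baseline recall (%) for inclusion: one word per 12-word list.
MIN_BASELINE_PCT = 100.0 / 12.0

#: Number of leading lists excluded from the R_NS baseline.
N_BASELINE_EXCLUDED_LISTS = 3


@dataclass
class SessionRecord:
    """Per-list recall outcomes of one stimulation session."""

    site_id: str
    list_index: np.ndarray  # 1-based, ordered
    stimulated: np.ndarray  # bool per list
    n_words: np.ndarray
    n_recalled: np.ndarray
    mode: str = "closed"

    def __post_init__(self) -> None:
        self.list_index = np.asarray(self.list_index, int)
        self.stimulated = np.asarray(self.stimulated, bool)
        self.n_words = np.asarray(self.n_words, int)
        self.n_recalled = np.asarray(self.n_recalled, int)
        if np.unique(self.list_index).size != self.list_index.size:
            raise ValueError("list_index values must be unique")
        if np.any(np.diff(self.list_index) <= 0):
            raise ValueError("list_index must be increasing")
        if np.any(self.n_recalled < 0) or np.any(self.n_recalled > self.n_words):
            raise ValueError("n_recalled must lie in [0, n_words]")
        if np.any(self.stimulated[self.list_index <= N_BASELINE_EXCLUDED_LISTS]):
            raise ValueError("the first three lists must be non-stimulated")


@dataclass
class MemoryOutcome:
    """Session-level summary: baseline (r_ns), stimulated recall (r_s) and
    delta, all in percent; ``exclusion_code`` is None for included sites."""

    site_id: str
    mode: str
    r_ns: float
    r_s: float
    delta: float
    included: bool
    exclusion_code: str | None = None


def memory_change(session: SessionRecord) -> MemoryOutcome:
    """Compute delta = (R_S - R_NS)/R_NS * 100 for one session.

    Lists 1-3 are excluded from the R_NS baseline.  Sessions whose R_NS falls
    below 8.33% are returned with ``included=False`` and exclusion code
    ``"low_baseline"``; their delta is NaN.
    """
    stim = session.stimulated
    eligible_ns = (~stim) & (session.list_index > N_BASELINE_EXCLUDED_LISTS)
    if not stim.any():
        raise ValueError("session has no stimulated lists")
    if not eligible_ns.any():
        raise ValueError("session has no eligible non-stimulated lists")
    r_s = 100.0 * session.n_recalled[stim].sum() / session.n_words[stim].sum()
    r_ns = 100.0 * session.n_recalled[eligible_ns].sum() / session.n_words[eligible_ns].sum()
    if r_ns < MIN_BASELINE_PCT:
        return MemoryOutcome(session.site_id, session.mode, r_ns, r_s, np.nan, False, "low_baseline")
    delta = (r_s - r_ns) / r_ns * 100.0
    return MemoryOutcome(session.site_id, session.mode, r_ns, r_s, delta, True)


def one_sample_t(deltas) -> tuple[float, int, float]:
    """One-sample t-test of mean delta against 0: returns (t, df, two-tailed p)."""
    x = np.asarray(deltas, float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance")
    res = stats.ttest_1samp(x, 0.0)
    return float(res.statistic), x.size - 1, float(res.pvalue)


def t_from_summary(mean: float, sem: float, df: int) -> tuple[float, float]:
    """t statistic (and two-tailed p) from a printed mean and SEM."""
    if sem <= 0:
        raise ValueError("sem must be positive")
    t = mean / sem
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p


def two_sample_t(a, b, pooled: bool = False) -> tuple[float, float, float]:
    """Two-sample t-test (Welch by default): returns (t, df, two-tailed p).

    ``pooled=True`` uses the equal-variance test with df = n_a + n_b - 2.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    if pooled:
        df = a.size + b.size - 2.0
    else:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def stratify_baseline(
    outcomes: list[MemoryOutcome], threshold: float = 30.0
) -> tuple[list[MemoryOutcome], list[MemoryOutcome]]:
    """Split outcomes into low (r_ns < threshold) and high (r_ns >= threshold)
    baseline groups.  Ties at the threshold go to the high group."""
    if not outcomes:
        raise ValueError("outcomes must be non-empty")
    low = [o for o in outcomes if o.r_ns < threshold]
    high = [o for o in outcomes if o.r_ns >= threshold]
    return low, high


def _check_corr_input(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    return x, y


def pearson_r(x, y) -> tuple[float, float]:
    x, y = _check_corr_input(x, y)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spearman_rho(x, y) -> tuple[float, float]:
    x, y = _check_corr_input(x, y)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def kendall_tau_b(x, y) -> tuple[float, float]:
    """Kendall's tau-b with tie-corrected denominator — the default statistic
    for zero-inflated structural connectivity values."""
    x, y = _check_corr_input(x, y)
    tau, p = stats.kendalltau(x, y, variant="b")
    return float(tau), float(p)


def outcomes_to_frame(outcomes: list[MemoryOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [o.site_id for o in outcomes],
            "mode": [o.mode for o in outcomes],
            "r_ns": [o.r_ns for o in outcomes],
            "r_s": [o.r_s for o in outcomes],
            "delta": [o.delta for o in outcomes],
            "included_flag": [o.included for o in outcomes],
            "exclusion_code": [o.exclusion_code or "" for o in outcomes],
        }
    )
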