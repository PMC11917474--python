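"""Per-generation copy-number change rates across generational intervals.

A change rate over an interval is (diploid copy number at the later
generation minus at the earlier) divided by the generations elapsed;
its absolute value is the magnitude of drift per generation. Rates are
computed either from a progenitor baseline (the median control copy
number, standing in for generation 0) or between repeated samplings of
the same line, with the baseline excluded from interval analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import one_sample_t


@dataclass(frozen=True)
class ChangeRate:
    """Signed and absolute per-generation change over one interval."""

    line_id: str
    from_generation: int
    to_generation: int
    cn_from: float
    cn_to: float

    def __post_init__(self) -> None:
        if self.to_generation <= self.from_generation:
            raise ValueError("interval must be positive")

    @property
    def interval(self) -> int:
        return self.to_generation - self.from_generation

    @property
    def rate(self) -> float:
        return (self.cn_to - self.cn_from) / self.interval

    @property
    def abs_rate(self) -> float:
        return abs(self.rate)


def progenitor_baseline(control_cn: Sequence[float]) -> float:
    """Median diploid copy number of control samples, as the generation-0
    stand-in for the lineage progenitor (linear interpolation for even n)."""
    control_cn = np.asarray(control_cn, dtype=float)
    if control_cn.size < 1:
        raise ValueError("need >= 1 control estimate")
    return float(np.median(control_cn))


def rate_from_baseline(cn: float, generation: int, baseline: float,
                       line_id: str = "") -> ChangeRate:
    """Change rate from the generation-0 baseline to one sampled generation."""
    if generation <= 0:
        raise ValueError("sampled generation must be > 0")
    return ChangeRate(line_id=line_id, from_generation=0,
                      to_generation=generation, cn_from=baseline, cn_to=cn)


def interval_rates(samples_of_line: Sequence[tuple[int, float]],
                   line_id: str = "") -> list[ChangeRate]:
    """All ordered-pair change rates among repeated samplings of one line.

    Baseline-derived (generation-0) rates are deliberately not part of
    this analysis; with 3 samplings this yields the 3 pairs
    (1→2, 1→3, 2→3).
    """
    if len(samples_of_line) < 2:
        raise ValueError("need >= 2 samplings")
    gens = [g for g, _ in samples_of_line]
    if len(set(gens)) != len(gens):
        raise ValueError("sampling generations must be distinct")
    ordered = sorted(samples_of_line)
    return [
        ChangeRate(line_id=line_id, from_generation=g1, to_generation=g2,
                   cn_from=c1, cn_to=c2)
        for (g1, c1), (g2, c2) in combinations(ordered, 2)
    ]


def direction_counts(rates: Sequence[ChangeRate]) -> tuple[int, int, int]:
    """(increases, decreases, ties); exact-zero rates are ties, kept out of
    the downstream 1:1 χ² test."""
    n_inc = sum(1 for r in rates if r.rate > 0)
    n_dec = sum(1 for r in rates if r.rate < 0)
    n_tie = len(rates) - n_inc - n_dec
    return n_inc, n_dec, n_tie


def rates_frame(rates: Sequence[ChangeRate]) -> pd.DataFrame:
    return pd.DataFrame([
        {"line_id": r.line_id, "from_generation": r.from_generation,
         "to_generation": r.to_generation, "cn_from": r.cn_from,
         "cn_to": r.cn_to, "interval": r.interval, "rate": r.rate,
         "abs_rate": r.abs_rate}
        for r in rates
    ])


def interval_group_summary(rates: Sequence[ChangeRate],
                           breaks: Mapping[str, tuple[int, int]]) -> pd.DataFrame:
    """Per-bin n, mean and variance of the absolute change rate.

    ``breaks`` maps bin label -> inclusive (lo, hi) interval-length range;
    the bins must cover every observed interval. Empty bins are reported
    with n = 0 and an explicit undefined flag rather than NaN-propagated
    summaries.
    """
    assigned: dict[str, list[float]] = {label: [] for label in breaks}
    for r in rates:
        for label, (lo, hi) in breaks.items():
            if lo <= r.interval <= hi:
                assigned[label].append(r.abs_rate)
                break
        else:
            raise ValueError(f"interval {r.interval} not covered by any bin")
    rows = []
    for label, vals in assigned.items():
        if vals:
            rows.append({"bin": label, "n": len(vals),
                         "mean_abs_rate": float(np.mean(vals)),
                         "var_abs_rate": float(np.var(vals, ddof=1)) if len(vals) > 1 else 0.0,
                         "defined": True})
        else:
            rows.append({"bin": label, "n": 0, "mean_abs_rate": np.nan,
                         "var_abs_rate": np.nan, "defined": False})
    return pd.DataFrame(rows)


def compare_bins(rates: Sequence[ChangeRate],
                 breaks: Mapping[str, tuple[int, int]],
                 bin_a: str, bin_b: str) -> tuple[float, float]:
    """Two-sample (Welch) t between the absolute rates of two named bins."""
    from scipy import stats as sps

    groups: dict[str, list[float]] = {bin_a: [], bin_b: []}
    for r in rates:
        for label in (bin_a, bin_b):
            lo, hi = breaks[label]
            if lo <= r.interval <= hi:
                groups[label].append(r.abs_rate)
    if min(len(v) for v in groups.values()) < 2:
        raise ValueError("each bin needs >= 2 rates")
    res = sps.ttest_ind(groups[bin_a], groups[bin_b], equal_var=False)
    return float(res.statistic), float(res.pvalue)


def signed_rate_test(rates: Sequence[ChangeRate], mu: float = 0.0
                     ) -> tuple[float, float]:
    """One-sample t of the signed rates against ``mu`` (no direction bias)."""
    return one_sample_t([r.rate for r in rates], mu)
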