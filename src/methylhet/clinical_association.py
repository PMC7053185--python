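"""Clinical associations of heterogeneity metrics.

Median-split stratification of samples by any per-sample metric, the
Kaplan–Meier product-limit estimator, the two-sample log-rank test
(observed − expected over hypergeometric variance, 1 df), two-group
rank-sum contrasts of sample metrics, and the within-sample comparison of
locus metrics inside versus outside supplied CNA segments.

The survival machinery is implemented directly from the product-limit and
log-rank definitions so its behaviour under the package's simulated cohorts
is fully transparent; times may be in any unit as long as they are
consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SurvivalRecord:
    """One sample's follow-up: time ≥ 0, event 1 = death/relapse, 0 = censored."""

    sample_id: str
    time: float
    event: int
    stratum: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.sample_id}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class StratificationRule:
    """How to dichotomize a per-sample metric (median split by default)."""

    metric: str
    threshold: str = "median"  # only rule implemented
    ties: str = "low"  # median-tied samples go to the low stratum ("high" flips)

    def __post_init__(self) -> None:
        if self.threshold != "median":
            raise ValueError("only the median threshold rule is implemented")
        if self.ties not in ("low", "high"):
            raise ValueError("ties must be 'low' or 'high'")


class StratificationError(ValueError):
    """The metric cannot produce two non-empty strata."""


def stratify_by_metric(
    values: pd.Series | dict, rule: StratificationRule
) -> tuple[list, list]:
    """Split sample ids at the cohort median of a metric.

    Returns ``(low_ids, high_ids)``. Samples exactly at the median follow the
    tie policy (low stratum by default). Requires at least 4 samples with a
    defined value and at least two distinct values.
    """
    s = pd.Series(values).dropna()
    if len(s) < 4:
        raise StratificationError(f"need >= 4 samples with defined {rule.metric}")
    if s.nunique() < 2:
        raise StratificationError(f"all {rule.metric} values identical")
    med = float(s.median())
    if rule.ties == "low":
        low = s.index[s <= med].tolist()
        high = s.index[s > med].tolist()
    else:
        low = s.index[s < med].tolist()
        high = s.index[s >= med].tolist()
    if not low or not high:
        raise StratificationError("median split produced an empty stratum")
    return low, high


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

def kaplan_meier(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit estimate of the survival function.

    One row per distinct event time t: the number at risk just before t
    (records censored exactly at t are still at risk), the number of events,
    and S(t) = Π (1 − d/n) over event times ≤ t. S = 1 when no events occur.
    """
    if not records:
        raise ValueError("no survival records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    event_times = np.unique(times[events == 1])
    rows = []
    surv = 1.0
    for t in event_times:
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        surv *= 1.0 - d / at_risk
        rows.append((float(t), at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def survival_at(km: pd.DataFrame, t: float) -> float:
    """Step-function value S(t) from a Kaplan–Meier table."""
    past = km[km["time"] <= t]
    return float(past["survival"].iloc[-1]) if len(past) else 1.0


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def log_rank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> LogRankResult:
    """Two-sample log-rank test (1 df chi-square).

    At each pooled distinct event time, the observed events in group A are
    compared with their conditional expectation under the hypergeometric
    draw of events from the pooled risk set; the statistic is
    ``(O_A − E_A)² / V``. Undefined (NaN statistic, NaN p) when the pooled
    data contain no events or the variance is zero.
    """
    ta = np.array([r.time for r in group_a], dtype=float)
    ea = np.array([r.event for r in group_a], dtype=int)
    tb = np.array([r.time for r in group_b], dtype=float)
    eb = np.array([r.event for r in group_b], dtype=int)
    pooled = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    if pooled.size == 0:
        return LogRankResult(math.nan, math.nan, (0.0, 0.0), (math.nan, math.nan))
    oa = ob = exp_a = exp_b = var = 0.0
    for t in pooled:
        na = int(np.sum(ta >= t))
        nb = int(np.sum(tb >= t))
        n = na + nb
        da = int(np.sum((ta == t) & (ea == 1)))
        db = int(np.sum((tb == t) & (eb == 1)))
        d = da + db
        if n == 0 or d == 0:
            continue
        oa += da
        ob += db
        exp_a += d * na / n
        exp_b += d * nb / n
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if var == 0:
        return LogRankResult(math.nan, math.nan, (oa, ob), (exp_a, exp_b))
    stat = (oa - exp_a) ** 2 / var
    return LogRankResult(
        statistic=float(stat),
        p_value=float(stats.chi2.sf(stat, df=1)),
        observed=(oa, ob),
        expected=(exp_a, exp_b),
    )


# ---------------------------------------------------------------------------
# Group contrasts
# ---------------------------------------------------------------------------

def metric_group_test(
    values_a: Sequence[float], values_b: Sequence[float], exact_max_n: int = 8
) -> tuple[float, float]:
    """Mann–Whitney U (for the first group) and two-sided p.

    Exact null distribution when both groups are small (≤ ``exact_max_n``)
    and tie-free; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two defined values")
    method = "exact" if max(a.size, b.size) <= exact_max_n else "asymptotic"
    if method == "exact" and np.unique(np.concatenate([a, b])).size < a.size + b.size:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# CNA versus non-CNA contrast
# ---------------------------------------------------------------------------

def assign_loci_to_regions(
    loci: pd.DataFrame, regions: pd.DataFrame, mode: str = "midpoint"
) -> np.ndarray:
    """Boolean mask: locus falls inside some region.

    ``loci`` needs contig/start/end columns; assignment is by the locus
    midpoint landing in a half-open region interval (``midpoint``, default)
    or by full containment (``containment``).
    """
    if mode not in ("midpoint", "containment"):
        raise ValueError("mode must be 'midpoint' or 'containment'")
    inside = np.zeros(len(loci), dtype=bool)
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for r in regions.itertuples(index=False):
        by_contig.setdefault(r.contig, []).append((int(r.start), int(r.end)))
    for i, loc in enumerate(loci.itertuples(index=False)):
        spans = by_contig.get(loc.contig, [])
        if not spans:
            continue
        if mode == "midpoint":
            mid = (int(loc.start) + int(loc.end)) // 2
            inside[i] = any(s <= mid < e for s, e in spans)
        else:
            inside[i] = any(
                s <= int(loc.start) and int(loc.end) <= e for s, e in spans
            )
    return inside


def cna_region_contrast(
    locus_metrics: dict[str, pd.DataFrame],
    cna_regions: pd.DataFrame,
    metric: str = "entropy_norm",
    mode: str = "midpoint",
) -> pd.DataFrame:
    """Per-sample mean metric inside vs outside CNA segments, with a paired test.

    ``locus_metrics`` maps sample id to a per-locus metrics frame carrying
    contig/start/end and the metric column. Returns one row per sample
    (inside mean, outside mean, difference) plus a ``paired_p`` attribute in
    ``DataFrame.attrs`` from a Wilcoxon signed-rank test across samples
    (NaN when fewer than two complete pairs or all differences are zero).
    """
    rows = []
    for sample_id, df in locus_metrics.items():
        inside = assign_loci_to_regions(df, cna_regions, mode=mode)
        vals = df[metric].to_numpy(dtype=float)
        m_in = float(np.nanmean(vals[inside])) if inside.any() else math.nan
        m_out = float(np.nanmean(vals[~inside])) if (~inside).any() else math.nan
        rows.append((sample_id, m_in, m_out, m_in - m_out))
    out = pd.DataFrame(rows, columns=["sample_id", "inside_mean", "outside_mean", "difference"])
    diffs = out["difference"].to_numpy(dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    if diffs.size >= 2 and np.any(diffs != 0):
        out.attrs["paired_p"] = float(stats.wilcoxon(diffs).pvalue)
    else:
        out.attrs["paired_p"] = math.nan
    return out


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_metadata_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"metadata table needs columns {sorted(required)}")
    return df


def records_from_frame(df: pd.DataFrame, stratum: str = "") -> list[SurvivalRecord]:
    return [
        SurvivalRecord(
            sample_id=str(r.sample_id),
            time=float(r.time),
            event=int(r.event),
            stratum=stratum,
        )
        for r in df.itertuples(index=False)
    ]


def write_km_tsv(km: pd.DataFrame, path) -> None:
    km.to_csv(path, sep="\t", index=False, float_format="%.10g")
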