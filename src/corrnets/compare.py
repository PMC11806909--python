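"""Bootstrap summaries and replicate-paired binomial comparison of networks.

Two networks are compared one metric at a time with a sign-test-style
procedure: replicate i of project A is paired with replicate i of project B,
exact ties are dropped, and the count of pairs where A exceeds B is referred
to Binomial(n, 1/2).  Under the null of no difference the two networks
should each "win" about half the replicates; if A wins all 500 pairs the
outcome is as improbable as 500 coin flips all landing the same way.

Tail probabilities are summed in log space so the reported log10 p-value
stays finite even when the p-value itself underflows an IEEE double (an
all-wins outcome at B = 500 has p ~ 3e-151; larger B or multiple metrics
can go far below 1e-308).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .graphs import METRIC_NAMES, NetworkStats
from .tables import write_table

__all__ = [
    "StatsSummary",
    "MetricComparison",
    "analyze_network_statistics",
    "exact_binomial_pvalue",
    "net_stat_binomial_test",
    "comparisons_to_records",
]

#: Two-sided significance level used to set the direction field.
ALPHA = 0.05

#: Smallest positive normal double; p-values below it print as 0.0 and the
#: log10 value is the faithful record (mirrors "p-value below e-320" notes).
_MIN_REPRESENTABLE = 2.2250738585072014e-308


@dataclass(frozen=True)
class StatsSummary:
    """Bootstrap mean and spread of one metric within one project.

    ``std_error`` is the sample standard deviation (denominator n-1) of the
    bootstrap metric values — the bootstrap standard error of the statistic.
    """

    project: str
    metric: str
    mean: float
    std_error: float
    n_replicates: int


@dataclass(frozen=True)
class MetricComparison:
    """Result of the paired binomial test for one metric between A and B."""

    metric: str
    n_effective: int
    k_successes: int
    statistic: float
    p_value: float
    log10_p: float
    direction: str  # "A-greater" | "B-greater" | "none"
    testable: bool = True


def _log_binom_tail(k_lo: int, k_hi: int, n: int) -> float:
    """log P(k_lo <= X <= k_hi) for X ~ Binomial(n, 1/2), in natural log."""
    ks = np.arange(k_lo, k_hi + 1)
    log_terms = gammaln(n + 1) - gammaln(ks + 1) - gammaln(n - ks + 1) - n * math.log(2.0)
    return float(logsumexp(log_terms))


def exact_binomial_pvalue(k: int, n: int) -> tuple[float, float]:
    """Two-tailed exact binomial p-value at success probability 1/2.

    ``p = min(1, 2 * min(P(X <= k), P(X >= k)))`` with X ~ Binomial(n, 1/2).
    Returns ``(p_value, log10_p)``; log10_p is computed from the log-space
    tail sum and is finite even when p_value underflows to 0.0.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    log_lower = _log_binom_tail(0, k, n)
    log_upper = _log_binom_tail(k, n, n)
    log_p = min(0.0, math.log(2.0) + min(log_lower, log_upper))
    log10_p = log_p / math.log(10.0)
    p_value = math.exp(log_p)
    return p_value, log10_p


def net_stat_binomial_test(
    stats_a: Sequence[NetworkStats],
    stats_b: Sequence[NetworkStats],
    alpha: float = ALPHA,
) -> list[MetricComparison]:
    """Replicate-paired two-tailed binomial test for each of the 7 metrics.

    Replicate i of A is compared with replicate i of B; exact ties are
    dropped (a tie is evidence for neither direction, and integer metrics
    such as edge counts tie often).  A metric where every pair ties is
    returned with ``testable=False`` rather than raising.

    ``direction`` is set toward the majority side when p < ``alpha``,
    otherwise "none".  No multiple-testing correction is applied; all seven
    raw p-values are reported so users may correct externally.
    """
    if len(stats_a) != len(stats_b):
        raise ValueError(
            f"replicate counts differ: {len(stats_a)} vs {len(stats_b)}; "
            "pairing requires equal bootstrap iterations"
        )
    if len(stats_a) < 10:
        raise ValueError(f"need >= 10 paired replicates, got {len(stats_a)}")

    results = []
    for metric in METRIC_NAMES:
        a_vals = [getattr(s, metric) for s in stats_a]
        b_vals = [getattr(s, metric) for s in stats_b]
        wins = sum(1 for a, b in zip(a_vals, b_vals) if a > b)
        losses = sum(1 for a, b in zip(a_vals, b_vals) if a < b)
        n_eff = wins + losses
        if n_eff == 0:
            results.append(
                MetricComparison(metric, 0, 0, math.nan, math.nan, math.nan, "none", False)
            )
            continue
        p_value, log10_p = exact_binomial_pvalue(wins, n_eff)
        if p_value < alpha:
            direction = "A-greater" if wins * 2 > n_eff else "B-greater"
        else:
            direction = "none"
        results.append(
            MetricComparison(metric, n_eff, wins, wins / n_eff, p_value, log10_p, direction)
        )
    return results


def analyze_network_statistics(
    projects: Mapping[str, Sequence[NetworkStats]],
    out_dir: str | Path | None = None,
    plot_prefix: str = "boxplot",
) -> list[StatsSummary]:
    """Summarize bootstrapped statistics per project; optionally plot.

    Computes the mean and standard error (standard deviation of the
    bootstrap values) of each of the seven metrics within each project.
    With ``out_dir`` set, writes a long-format ``network_stats_summary.csv``
    and one box-and-whisker SVG per metric comparing the projects.
    """
    if not projects:
        raise ValueError("no projects given")
    for name, stats in projects.items():
        if len(stats) < 2:
            raise ValueError(f"project {name!r} has {len(stats)} replicates; need >= 2")

    summaries = []
    for name, stats in projects.items():
        for metric in METRIC_NAMES:
            vals = np.array([getattr(s, metric) for s in stats], dtype=float)
            summaries.append(
                StatsSummary(name, metric, float(vals.mean()), float(vals.std(ddof=1)), len(vals))
            )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = [
            {
                "project": s.project,
                "metric": s.metric,
                "mean": s.mean,
                "std_error": s.std_error,
                "n_replicates": s.n_replicates,
            }
            for s in summaries
        ]
        write_table(rows, out_dir / "network_stats_summary.csv")
        for metric in METRIC_NAMES:
            _boxplot_metric(projects, metric, out_dir / f"{plot_prefix}_{metric}.svg")
    return summaries


def _boxplot_metric(
    projects: Mapping[str, Sequence[NetworkStats]], metric: str, path: Path
) -> None:
    fig, ax = plt.subplots(figsize=(1.6 + 1.2 * len(projects), 4.0))
    names = list(projects)
    data = [[getattr(s, metric) for s in projects[name]] for name in names]
    ax.boxplot(data, tick_labels=names)
    ax.set_ylabel(metric)
    ax.set_title(f"Bootstrapped {metric}")
    fig.tight_layout()
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)


def format_pvalue(p_value: float, log10_p: float) -> str:
    """Human-readable p-value; underflowed values carry their log10 record."""
    if math.isnan(p_value):
        return "untestable"
    if p_value == 0.0 or p_value < _MIN_REPRESENTABLE:
        return f"0.0 (below representable minimum; log10 p = {log10_p:.1f})"
    return f"{p_value:.3g}"


def comparisons_to_records(comparisons: Sequence[MetricComparison]) -> list[dict[str, object]]:
    """Flat records (one per metric) for CSV export of comparison results."""
    return [
        {
            "metric": c.metric,
            "n_effective": c.n_effective,
            "k_successes": c.k_successes,
            "statistic": c.statistic,
            "p_value": c.p_value,
            "log10_p": c.log10_p,
            "direction": c.direction,
            "testable": c.testable,
        }
        for c in comparisons
    ]
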