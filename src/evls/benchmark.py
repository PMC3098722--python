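"""Benchmarking MRC protocols against the distribution of SRC runs.

The key summary is *percentile placement*: where a combined (MRC) result
falls within the frequency distribution of the target's single-conformer
results.  With ``k`` SRC values and ``c`` of them strictly worse than the
MRC value, the percentile is ``floor(100*(c+1)/(k+1))`` — so outperforming
all runs gives the 100th percentile and outperforming none of ``k`` gives
``floor(100/(k+1))``.  Equal values never count as outperformed (strict
wins only).  This convention is one of several plausible ones; it is the
package default and can be replaced by passing a different callable.

A one-tailed paired t-test over targets (MRC value minus the target's mean
SRC value) quantifies whether a protocol beats the average individual run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .combine import combine
from .data_model import EnsembleScreen, LigandLibrary, RankedList, rank_single_run
from .metrics import (
    DEFAULT_ALPHA,
    DEFAULT_CHI,
    accumulation_curve,
    auac,
    bedroc,
    enrichment_factor,
    max_enrichment_factor,
    metric_report,
    rie,
    roc_auc,
)

SUPPORTED_METRICS = ("auac", "roc_auc", "ef", "rie", "bedroc")


def floor_percentile(n_outperformed: int, n_src: int) -> int:
    """Default percentile convention, ``floor(100*(c+1)/(k+1))``."""
    return math.floor(100 * (n_outperformed + 1) / (n_src + 1))


@dataclass
class PercentileSummary:
    target_id: str
    metric: str
    src_values: list[float]
    mrc_value: float
    percentile: int
    n_outperformed: int


def percentile_placement(
    mrc_value: float,
    src_values: Sequence[float],
    higher_is_better: bool = True,
    target_id: str = "",
    metric: str = "",
    convention: Callable[[int, int], int] = floor_percentile,
) -> PercentileSummary:
    """Place one MRC result within its SRC distribution.

    ``n_outperformed`` counts SRC values *strictly* worse than the MRC
    value; ties are not wins.
    """
    src = list(src_values)
    if not src:
        raise ValueError("percentile placement requires at least one SRC value")
    if higher_is_better:
        c = sum(1 for v in src if v < mrc_value)
    else:
        c = sum(1 for v in src if v > mrc_value)
    return PercentileSummary(
        target_id=target_id,
        metric=metric,
        src_values=src,
        mrc_value=float(mrc_value),
        percentile=convention(c, len(src)),
        n_outperformed=c,
    )


def paired_one_tailed_ttest(
    mrc_values: Sequence[float], src_reference: Sequence[float]
) -> tuple[float, float]:
    """Paired t statistic on (MRC - SRC reference) differences, with the
    one-tailed p-value for mean difference > 0.

    Degenerate inputs: all-zero differences give ``(0, 0.5)``; zero-variance
    nonzero differences give ``(+/-inf, 0 or 1)`` by sign.
    """
    d = np.asarray(mrc_values, dtype=float) - np.asarray(src_reference, dtype=float)
    if len(d) < 2:
        raise ValueError("paired t-test requires at least two pairs")
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, 0.5
        return (math.inf, 0.0) if mean > 0 else (-math.inf, 1.0)
    t_stat = mean / (sd / math.sqrt(len(d)))
    p = float(t_dist.sf(t_stat, df=len(d) - 1))
    return float(t_stat), p


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def metric_value(
    ranked: RankedList,
    library: LigandLibrary,
    metric: str,
    chi: float = 0.01,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Evaluate one named figure of merit on one ranked list."""
    if metric not in SUPPORTED_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    curve = accumulation_curve(ranked, library)
    if metric == "auac":
        return auac(curve)
    if metric == "roc_auc":
        return roc_auc(ranked, library)
    if metric == "ef":
        return enrichment_factor(curve, chi)
    ranks = ranked.binder_ranks(library)
    if metric == "rie":
        return rie(ranks, curve.n_binders, curve.n_total, alpha)
    return bedroc(ranks, curve.n_binders, curve.n_total, alpha)


def ideal_metric_value(
    n: int, n_total: int, metric: str, chi: float = 0.01, alpha: float = DEFAULT_ALPHA
) -> float:
    """Value of a figure of merit under a perfect ranking (binders at
    ranks ``1..n``)."""
    if metric == "auac":
        return 1 - (n - 1) / (2 * n_total)
    if metric == "roc_auc":
        return 1.0
    if metric == "ef":
        return max_enrichment_factor(n, n_total, chi)
    if metric == "rie":
        return rie(np.arange(1, n + 1), n, n_total, alpha)
    if metric == "bedroc":
        return 1.0
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class BenchmarkReport:
    """Per-target benchmark rows plus cross-target histograms.

    ``per_target`` columns: target, metric, chi, n_binders, n_total,
    src_min/src_max/src_mean, ideal, then ``<method>`` /
    ``<method>_percentile`` / ``<method>_outperformed`` per MRC method.
    """

    per_target: pd.DataFrame
    histograms: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_target": self.per_target.to_dict(orient="records"),
            "histograms": self.histograms,
        }


def _histogram(values: Sequence[float], bin_width: float = 0.05) -> dict:
    edges = np.arange(0, 1 + bin_width / 2, bin_width)
    counts, _ = np.histogram(np.clip(values, 0, 1), bins=edges)
    return {"bin_edges": edges.round(6).tolist(), "counts": counts.tolist()}


def benchmark_report(
    screens: Mapping[str, EnsembleScreen] | Sequence[EnsembleScreen],
    methods: Sequence[str] = ("mrc_score", "mrc_rank"),
    metrics: Sequence[str] = ("auac", "ef", "bedroc"),
    chi_values: Sequence[float] = (0.01,),
    alpha: float = DEFAULT_ALPHA,
    bin_width: float = 0.05,
) -> BenchmarkReport:
    """Per-target SRC statistics (min/max/mean), MRC values with percentile
    placements, and ideal values, for every requested metric; plus
    frequency-distribution histograms over targets for [0, 1]-bounded
    metrics (fixed 0.05 bin width by default)."""
    if isinstance(screens, Mapping):
        screens = list(screens.values())
    rows = []
    dist: dict[str, dict[str, list[float]]] = {}
    for screen in screens:
        if screen.excluded or not screen.runs:
            continue
        library = screen.library
        if library is None:
            raise ValueError(f"target {screen.target_id!r}: annotations required")
        src_ranked = [rank_single_run(run, library) for run in screen.runs]
        mrc_ranked = {m: combine(screen, m) for m in methods}
        n = library.n_binders
        n_total = len(library)
        for metric in metrics:
            for chi in chi_values if metric == "ef" else (None,):
                kw = {"chi": chi} if chi is not None else {}
                src_values = [
                    metric_value(r, library, metric, alpha=alpha, **kw)
                    for r in src_ranked
                ]
                row = {
                    "target": screen.target_id,
                    "metric": metric,
                    "chi": chi,
                    "n_binders": n,
                    "n_total": n_total,
                    "src_min": min(src_values),
                    "src_max": max(src_values),
                    "src_mean": float(np.mean(src_values)),
                    "ideal": ideal_metric_value(
                        n, n_total, metric, chi=chi or 0.01, alpha=alpha
                    ),
                }
                key = metric if chi is None else f"{metric}_{chi:g}"
                hist = dist.setdefault(key, {"src_mean": []})
                hist["src_mean"].append(row["src_mean"])
                for m in methods:
                    value = metric_value(
                        mrc_ranked[m], library, metric, alpha=alpha, **kw
                    )
                    summary = percentile_placement(
                        value, src_values, target_id=screen.target_id, metric=metric
                    )
                    row[m] = value
                    row[f"{m}_percentile"] = summary.percentile
                    row[f"{m}_outperformed"] = summary.n_outperformed
                    hist.setdefault(m, []).append(value)
                rows.append(row)

    histograms = {
        key: {
            series: _histogram(vals, bin_width)
            for series, vals in groups.items()
        }
        for key, groups in dist.items()
        # only [0,1]-bounded metrics are histogrammed on a fixed grid
        if not key.startswith(("ef", "rie"))
    }
    return BenchmarkReport(per_target=pd.DataFrame(rows), histograms=histograms)
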