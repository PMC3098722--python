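"""Early-recognition figures of merit for ranked screening results.

Five metrics are computed from a ranked list of ``N`` molecules containing
``n`` annotated binders, all derived from the accumulation curve
``F_a(k)`` = number of binders at rank <= k:

AUAC
    area under the accumulation curve, ``(1/(nN)) * sum_k F_a(k)``.
ROC AUC
    probability that a random binder outranks a random decoy
    (Mann-Whitney form; tied score pairs receive half credit).  For a
    tie-free ranking it is the linear transform
    ``(N*AUAC - (n+1)/2) / (N - n)`` of the AUAC.
EF_chi (enrichment factor)
    ``F_a(floor(chi*N)) / (n*chi)`` — binder concentration in the top
    fraction ``chi`` relative to random expectation.
RIE (robust initial enhancement)
    exponentially rank-weighted enrichment,
    ``sum_i exp(-alpha*r_i/N) / [(n/N) * (1-e^-alpha)/(e^(alpha/N)-1)]``;
    a uniformly random ranking has expectation 1.
BEDROC
    RIE standardized to [0, 1] against the ideal (ranks ``1..n``) and worst
    (ranks ``N-n+1..N``) orderings, so the endpoints are exactly 0 and 1 for
    every ``(n, N, alpha)``.

``alpha`` defaults to 20, the value conventionally used so that early
recognition dominates; ``chi`` defaults to the 1% and 10% fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .data_model import LigandLibrary, RankedList

DEFAULT_ALPHA = 20.0
DEFAULT_CHI = (0.01, 0.10)


class MetricError(ValueError):
    """A metric is undefined for the given inputs."""


@dataclass
class AccumulationCurve:
    """``F_a(k)`` for k = 1..N, plus the (n, N) counts it was built from."""

    values: np.ndarray
    n_binders: int
    n_total: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if len(self.values) != self.n_total:
            raise MetricError("accumulation curve length must equal library size")
        if self.values[-1] != self.n_binders:
            raise MetricError("accumulation curve must end at the binder count")


@dataclass
class MetricReport:
    """The five figures of merit for one ranked list."""

    auac: float
    roc_auc: float
    ef: dict[float, float]
    rie: float
    bedroc: float
    n_binders: int
    n_total: int
    alpha: float = DEFAULT_ALPHA
    chi_values: tuple[float, ...] = DEFAULT_CHI

    def to_dict(self) -> dict:
        return {
            "auac": self.auac,
            "roc_auc": self.roc_auc,
            "ef": {f"{chi:g}": v for chi, v in self.ef.items()},
            "rie": self.rie,
            "bedroc": self.bedroc,
            "n_binders": self.n_binders,
            "n_total": self.n_total,
            "alpha": self.alpha,
        }


def accumulation_curve(ranked: RankedList, library: LigandLibrary) -> AccumulationCurve:
    """Count binders at rank <= k for every k."""
    is_binder = library.binder_mask(ranked.ligand_ids)
    n = int(is_binder.sum())
    if n == 0:
        raise MetricError("metrics undefined without actives")
    return AccumulationCurve(np.cumsum(is_binder), n, len(ranked))


def auac(curve: AccumulationCurve) -> float:
    """Area under the accumulation curve, normalized to at most
    ``1 - (n-1)/(2N)`` (ideal) and at least ``(n+1)/(2N)`` (worst)."""
    return float(curve.values.sum()) / (curve.n_binders * curve.n_total)


def roc_auc(ranked: RankedList, library: LigandLibrary) -> float:
    """Mann-Whitney ROC AUC with half credit for binder/decoy pairs whose
    primary sort keys are tied."""
    is_binder = library.binder_mask(ranked.ligand_ids)
    n = int(is_binder.sum())
    n_decoys = len(ranked) - n
    if n == 0:
        raise MetricError("metrics undefined without actives")
    if n_decoys == 0:
        raise MetricError("ROC AUC undefined without decoys")
    keys = np.array([e.primary_key for e in ranked.entries])
    avg_ranks = rankdata(keys)  # ascending, ties -> average rank
    r_binders = avg_ranks[is_binder].sum()
    # pairs where the binder's key is larger (worse), ties half-counted
    u_worse = r_binders - n * (n + 1) / 2
    return float((n * n_decoys - u_worse) / (n * n_decoys))


def roc_from_auac(auac_value: float, n: int, n_total: int) -> float:
    """Linear transform relating AUAC and ROC AUC for tie-free rankings."""
    return (n_total * auac_value - (n + 1) / 2) / (n_total - n)


def enrichment_factor(curve: AccumulationCurve, chi: float) -> float:
    """EF at the early-recognition fraction ``chi``."""
    k = math.floor(chi * curve.n_total)
    if k < 1:
        raise MetricError(
            f"fraction {chi} too small for library size {curve.n_total}"
        )
    return float(curve.values[k - 1]) / (curve.n_binders * chi)


def max_enrichment_factor(n: int, n_total: int, chi: float) -> float:
    """The ideal-ranking EF: ``min(n, floor(chi*N)) / (n*chi)``."""
    k = math.floor(chi * n_total)
    if k < 1:
        raise MetricError(f"fraction {chi} too small for library size {n_total}")
    return min(n, k) / (n * chi)


def rie(
    binder_ranks: Sequence[int] | np.ndarray,
    n: int,
    n_total: int,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Robust initial enhancement of the given binder ranks."""
    if alpha <= 0:
        raise MetricError("alpha must be positive")
    r = np.asarray(binder_ranks, dtype=float)
    if len(r) != n:
        raise MetricError("binder_ranks length must equal n")
    numerator = np.exp(-alpha * r / n_total).sum()
    denominator = (n / n_total) * (1 - math.exp(-alpha)) / (math.exp(alpha / n_total) - 1)
    return float(numerator / denominator)


def bedroc(
    binder_ranks: Sequence[int] | np.ndarray,
    n: int,
    n_total: int,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """RIE standardized against the ideal and worst orderings."""
    if n >= n_total:
        raise MetricError("BEDROC requires at least one decoy (n < N)")
    observed = rie(binder_ranks, n, n_total, alpha)
    ideal = rie(np.arange(1, n + 1), n, n_total, alpha)
    worst = rie(np.arange(n_total - n + 1, n_total + 1), n, n_total, alpha)
    return float((observed - worst) / (ideal - worst))


def random_bedroc(n: int, n_total: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Expected BEDROC of a uniformly random ranking, ``(1 - RIE_min) /
    (RIE_max - RIE_min)`` (random RIE has expectation 1)."""
    ideal = rie(np.arange(1, n + 1), n, n_total, alpha)
    worst = rie(np.arange(n_total - n + 1, n_total + 1), n, n_total, alpha)
    return float((1.0 - worst) / (ideal - worst))


def metric_report(
    ranked: RankedList,
    library: LigandLibrary,
    chi_values: Sequence[float] = DEFAULT_CHI,
    alpha: float = DEFAULT_ALPHA,
) -> MetricReport:
    """Bundle all five figures of merit for one ranked list."""
    curve = accumulation_curve(ranked, library)
    ranks = ranked.binder_ranks(library)
    n, n_total = curve.n_binders, curve.n_total
    return MetricReport(
        auac=auac(curve),
        roc_auc=roc_auc(ranked, library),
        ef={chi: enrichment_factor(curve, chi) for chi in chi_values},
        rie=rie(ranks, n, n_total, alpha),
        bedroc=bedroc(ranks, n, n_total, alpha),
        n_binders=n,
        n_total=n_total,
        alpha=alpha,
        chi_values=tuple(chi_values),
    )


def truncate_decimals(x: float, ndigits: int = 1) -> float:
    """Truncate (not round) toward zero at ``ndigits`` decimals, the
    convention used by the published benchmark tables this package's
    fixtures mirror (e.g. 46.15 prints as 46.1)."""
    factor = 10 ** ndigits
    return math.trunc(x * factor + math.copysign(1e-9, x)) / factor
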