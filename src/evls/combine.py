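"""Fuse per-conformer screening runs into a single ranked list.

The two canonical multiple-receptor-conformation (MRC) protocols:

MRC-score
    merge all per-run scores, keep each ligand's best (minimum) score, sort
    ascending.  Ties are broken by lower molecular weight, then ligand id.
MRC-rank
    rank each run independently, keep each ligand's best (minimum) rank,
    sort ascending.  Ties on best rank are broken by the ligand's best score
    across runs, then molecular weight, then ligand id.

Alternative schemes (provided for completeness; none is expected to beat the
two above):

mrc_rank_deep
    MRC-rank with ties resolved by the second- then third-best rank before
    falling back to best score / MW / id.
boltzmann_score
    soft-minimum key ``-T * ln sum_j exp(-s_j / T)``; converges to MRC-score
    as ``T -> 0+``.  The functional form is this package's reconstruction,
    not a published formula.
boltzmann_score_mw
    same key plus an additive molecular-weight penalty ``lambda * MW``
    (``lambda`` defaults to 0 and must be set explicitly to have an effect).
rank_consensus
    key = sum of the per-run ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data_model import EnsembleScreen, RankedList, _ordered_entries, rank_single_run

METHODS = (
    "mrc_score",
    "mrc_rank",
    "mrc_rank_deep",
    "boltzmann_score",
    "boltzmann_score_mw",
    "rank_consensus",
)
_BOLTZMANN_METHODS = ("boltzmann_score", "boltzmann_score_mw")


@dataclass(frozen=True)
class CombinationSpec:
    """How to merge an ensemble's runs into one list.

    temperature : softness of the Boltzmann soft-minimum, in score units
        (boltzmann methods only).
    mw_lambda : weight of the additive molecular-weight penalty in
        ``boltzmann_score_mw``, score units per Dalton.
    """

    method: str = "mrc_rank"
    temperature: float = 1.0
    mw_lambda: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown combination method {self.method!r}")
        if self.method in _BOLTZMANN_METHODS and not self.temperature > 0:
            raise ValueError("Boltzmann combination requires a positive temperature")


def _matrix(screen: EnsembleScreen):
    if screen.library is None:
        raise ValueError("combination requires ligand annotations (molecular weights)")
    scores, lids = screen.score_matrix()
    mw = screen.library.molecular_weights(lids)
    return scores, lids, mw


def _rank_matrix(screen: EnsembleScreen, lids) -> np.ndarray:
    """(n_runs, N) matrix of the tie-broken per-run rank of each ligand."""
    pos = {l: i for i, l in enumerate(lids)}
    out = np.empty((len(screen.runs), len(lids)), dtype=float)
    for j, run in enumerate(screen.runs):
        ranked = rank_single_run(run, screen.library)
        for rank, lid in enumerate(ranked.ligand_ids, start=1):
            out[j, pos[lid]] = rank
    return out


def combine_mrc_score(screen: EnsembleScreen) -> RankedList:
    """Best score over runs, ascending; ties by MW then ligand id."""
    scores, lids, mw = _matrix(screen)
    best = scores.min(axis=0)
    return RankedList(screen.target_id, "mrc_score", _ordered_entries(lids, best, mw))


def combine_mrc_rank(screen: EnsembleScreen) -> RankedList:
    """Best per-run rank, ascending; ties by best score, then MW, then id."""
    scores, lids, mw = _matrix(screen)
    ranks = _rank_matrix(screen, lids)
    best_rank = ranks.min(axis=0)
    best_score = scores.min(axis=0)
    return RankedList(
        screen.target_id,
        "mrc_rank",
        _ordered_entries(lids, best_rank, best_score, mw),
    )


def combine_alternative(screen: EnsembleScreen, spec: CombinationSpec) -> RankedList:
    """Apply one of the documented alternative combination schemes."""
    scores, lids, mw = _matrix(screen)
    best_score = scores.min(axis=0)

    if spec.method == "mrc_score":
        return combine_mrc_score(screen)
    if spec.method == "mrc_rank":
        return combine_mrc_rank(screen)

    if spec.method == "mrc_rank_deep":
        ranks = np.sort(_rank_matrix(screen, lids), axis=0)
        n_runs = ranks.shape[0]
        inf = np.full(len(lids), np.inf)
        r1 = ranks[0]
        r2 = ranks[1] if n_runs > 1 else inf
        r3 = ranks[2] if n_runs > 2 else inf
        entries = _ordered_entries(lids, r1, r2, r3, best_score, mw)
        return RankedList(screen.target_id, "mrc_rank_deep", entries)

    if spec.method == "rank_consensus":
        key = _rank_matrix(screen, lids).sum(axis=0)
        entries = _ordered_entries(lids, key, best_score, mw)
        return RankedList(screen.target_id, "rank_consensus", entries)

    if spec.method in _BOLTZMANN_METHODS:
        T = spec.temperature
        key = -T * logsumexp(-scores / T, axis=0)
        if spec.method == "boltzmann_score_mw":
            key = key + spec.mw_lambda * mw
        entries = _ordered_entries(lids, key, mw)
        return RankedList(screen.target_id, spec.method, entries)

    raise ValueError(f"unknown combination method {spec.method!r}")


def combine(screen: EnsembleScreen, spec: CombinationSpec | str) -> RankedList:
    """Dispatch on method name or :class:`CombinationSpec`."""
    if isinstance(spec, str):
        spec = CombinationSpec(method=spec)
    return combine_alternative(screen, spec)
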