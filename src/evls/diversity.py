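"""Chemotype-aware evaluation of ranked screening results.

Highly populated scaffold clusters can dominate enrichment statistics: a
single well-recognized chemotype with many members inflates every figure of
merit without adding chemical diversity.  Two tools address this:

``chemotype_representative_relabel``
    keeps only the best-ranked binder of each chemotype as a binder and
    relabels the rest as decoys (library size N stays fixed; the active
    count drops to the number of chemotypes).  Because the representative
    depends on the ordering, relabeling is done per ranked list.

``top_fraction_chemotypes``
    counts binders and distinct chemotypes in the top fraction of a ranking
    (the quantity a prospective screen actually cares about).
"""

from __future__ import annotations

import math
from dataclasses import replace

from .data_model import LigandLibrary, RankedList
from .metrics import MetricError


def chemotype_representative_relabel(
    ranked: RankedList, library: LigandLibrary
) -> LigandLibrary:
    """Relabel all but the best-ranked binder of each chemotype as decoys.

    Every binder must carry a chemotype.  The returned library has the same
    ligands (N unchanged); its binder count equals the number of chemotypes
    represented.  Relabeled records lose their chemotype and co-crystal
    annotations (decoys carry neither).
    """
    best_seen: set[str] = set()
    keep_as_binder: set[str] = set()
    for entry in ranked.entries:  # best rank first
        rec = library[entry.ligand_id]
        if not rec.is_binder:
            continue
        if rec.chemotype is None:
            raise ValueError(
                f"binder {rec.ligand_id!r} has no chemotype; relabeling requires "
                "chemotyped binders"
            )
        if rec.chemotype not in best_seen:
            best_seen.add(rec.chemotype)
            keep_as_binder.add(rec.ligand_id)
    relabeled = [
        replace(rec, is_binder=False, chemotype=None, cocrystal_of=None)
        for rec in library.binders
        if rec.ligand_id not in keep_as_binder
    ]
    return library.replace(relabeled)


def top_fraction_chemotypes(
    ranked: RankedList, library: LigandLibrary, chi: float
) -> tuple[int, int, tuple[str, ...]]:
    """Binder count, distinct chemotype count, and the sorted chemotype
    labels among ranks ``1..floor(chi*N)``."""
    k = math.floor(chi * len(ranked))
    if k < 1:
        raise MetricError(f"fraction {chi} too small for library size {len(ranked)}")
    chemotypes: set[str] = set()
    n_binders_top = 0
    for entry in ranked.entries[:k]:
        rec = library[entry.ligand_id]
        if rec.is_binder:
            n_binders_top += 1
            if rec.chemotype is not None:
                chemotypes.add(rec.chemotype)
    return n_binders_top, len(chemotypes), tuple(sorted(chemotypes))


def format_chemotype_set(chemotypes: tuple[str, ...]) -> str:
    """Dash-joined label set, e.g. ``('1','3','4','9') -> '1-3-4-9'``."""
    return "-".join(chemotypes)
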