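"""Conformer and ligand-set filters for ensemble screens.

Two filters shown empirically to de-noise MRC protocols:

1. ``drop_all_positive_runs`` removes degenerate runs in which every ligand
   received a strictly positive (unfavorable) docking score — such runs
   carry no useful ranking signal (their early enrichment is worse than
   random) and only inject noise into a combined list.
2. ``cognate_ligand_filter`` removes co-crystallized binders and all binders
   sharing their chemotype, so that self-docking of a pocket against the very
   ligand it was crystallized with (or a close analog) cannot inflate
   ensemble performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .data_model import EnsembleScreen, LigandLibrary


def drop_all_positive_runs(
    screen: EnsembleScreen,
) -> tuple[EnsembleScreen, list[str]]:
    """Remove every run whose minimum score is strictly positive.

    A run with even one score <= 0 is kept (a zero score is treated as
    non-positive).  Returns the reduced ensemble and the removed conformer
    ids; an ensemble left with no runs is returned with ``excluded=True``
    rather than raising.
    """
    kept = [run for run in screen.runs if not run.min_score > 0]
    removed = [run.conformer_id for run in screen.runs if run.min_score > 0]
    return (
        EnsembleScreen(
            target_id=screen.target_id,
            runs=kept,
            library=screen.library,
            excluded=not kept,
        ),
        removed,
    )


@dataclass
class CognateFilterResult:
    """Outcome of the co-crystal filter on one target's library."""

    library: LigandLibrary
    removed_binders: list[str]
    removed_chemotypes: list[str]
    excluded: bool = False

    def __iter__(self):
        # allow (library, removed_binders, removed_chemotypes) unpacking
        return iter((self.library, self.removed_binders, self.removed_chemotypes))


def cognate_ligand_filter(
    screen: EnsembleScreen, library: LigandLibrary | None = None
) -> CognateFilterResult:
    """Delete binders co-crystallized with an in-ensemble conformer, and all
    binders of the same chemotype.

    Removal applies only when ``cocrystal_of`` names a conformer actually
    present in the screen; unknown conformer references draw a warning and
    are ignored.  Decoys are never touched.  If no binders remain the target
    is flagged ``excluded``.
    """
    if library is None:
        library = screen.library
    if library is None:
        raise ValueError("cognate_ligand_filter requires ligand annotations")
    conformers = set(screen.conformer_ids)

    cognate_ids: set[str] = set()
    cognate_chemotypes: set[str] = set()
    for rec in library.binders:
        if rec.cocrystal_of is None:
            continue
        if rec.cocrystal_of not in conformers:
            warnings.warn(
                f"ligand {rec.ligand_id!r}: cocrystal_of names conformer "
                f"{rec.cocrystal_of!r} absent from target {screen.target_id!r}; "
                "not removed",
                stacklevel=2,
            )
            continue
        cognate_ids.add(rec.ligand_id)
        if rec.chemotype is not None:
            cognate_chemotypes.add(rec.chemotype)

    removed = [
        rec.ligand_id
        for rec in library.binders
        if rec.ligand_id in cognate_ids
        or (rec.chemotype is not None and rec.chemotype in cognate_chemotypes)
    ]
    removed_set = set(removed)
    filtered = library.subset(
        r.ligand_id for r in library if r.ligand_id not in removed_set
    )
    return CognateFilterResult(
        library=filtered,
        removed_binders=sorted(removed),
        removed_chemotypes=sorted(cognate_chemotypes),
        excluded=filtered.n_binders == 0,
    )


def apply_library_filter(
    screen: EnsembleScreen, library: LigandLibrary
) -> EnsembleScreen:
    """Restrict every run of a screen to the ligands of a filtered library."""
    keep = set(library.ligand_ids)
    runs = [
        replace(run, scores={l: s for l, s in run.scores.items() if l in keep})
        for run in screen.runs
    ]
    return EnsembleScreen(
        target_id=screen.target_id,
        runs=runs,
        library=library,
        excluded=screen.excluded,
    )
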