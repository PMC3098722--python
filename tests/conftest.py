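import numpy as np
import pytest

from evls import (
    ConformerRun,
    EnsembleScreen,
    LigandLibrary,
    LigandRecord,
    RankedList,
    RankEntry,
)


def make_library(n_binders, n_decoys, chemotypes=None, cocrystals=None, mw=None):
    """Small helper: binders B0.., decoys D0.., optional per-binder
    chemotype/cocrystal assignments."""
    chemotypes = chemotypes or {}
    cocrystals = cocrystals or {}
    mw = mw or {}
    records = []
    for i in range(n_binders):
        lid = f"B{i}"
        records.append(
            LigandRecord(lid, mw.get(lid, 300.0 + i), True,
                         chemotype=chemotypes.get(lid),
                         cocrystal_of=cocrystals.get(lid))
        )
    for i in range(n_decoys):
        lid = f"D{i}"
        records.append(LigandRecord(lid, mw.get(lid, 250.0 + i), False))
    return LigandLibrary(records)


def ranking_from_binder_positions(binder_positions, n_binders, n_total):
    """Build (RankedList, LigandLibrary) with binders at the given 1-based
    ranks and tie-free keys equal to the rank."""
    binder_positions = set(binder_positions)
    assert len(binder_positions) == n_binders
    library = make_library(n_binders, n_total - n_binders)
    b = iter(range(n_binders))
    d = iter(range(n_total - n_binders))
    entries = []
    for rank in range(1, n_total + 1):
        lid = f"B{next(b)}" if rank in binder_positions else f"D{next(d)}"
        entries.append(RankEntry(lid, float(rank), 0.0))
    return RankedList("T", "synthetic", entries), library


@pytest.fixture
def tiny_screen():
    """One target, 2 conformers, 4 ligands (2 binders, 2 decoys)."""
    library = make_library(2, 2, chemotypes={"B0": "C1", "B1": "C2"})
    runs = [
        ConformerRun("c1", {"B0": -30.0, "B1": -10.0, "D0": -15.0, "D1": -12.0}),
        ConformerRun("c2", {"B0": -11.0, "B1": -28.0, "D0": -14.0, "D1": -16.0}),
    ]
    return EnsembleScreen("T1", runs, library)


@pytest.fixture
def rng():
    return np.random.default_rng(20)
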