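"""Domain types, validation, and table IO for ensemble virtual-screening data.

Score convention
----------------
Docking scores here follow the ICM-style convention: **lower (more negative)
score = more favorable**.  Every ranking in this package sorts scores in
ascending order.  If your engine emits higher-is-better scores, load tables
with ``invert_sign=True``.

Containers
----------
``LigandRecord``    one screened molecule (weight, binder/decoy label,
                    optional chemotype and co-crystal provenance).
``LigandLibrary``   the annotated compound library shared by all runs of a
                    target.
``ConformerRun``    one receptor conformer's complete score vector (a
                    single-receptor-conformation, SRC, screening run).
``EnsembleScreen``  a target's set of runs over one shared library (the raw
                    material of a multiple-receptor-conformation, MRC,
                    protocol).
``RankedList``      a deduplicated 1-based ordering of all ligands together
                    with the sort keys that produced it.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("evls")

SCORE_TABLE_COLUMNS = ("target", "conformer", "ligand", "score")
ANNOTATION_COLUMNS = ("ligand", "mw", "label", "chemotype", "cocrystal_of")

#: significant digits used when writing float columns
FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """A table violates the expected column layout or value domain."""


class CoverageError(ValueError):
    """A conformer run does not score every ligand of its target's library."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LigandRecord:
    """One screened molecule.

    ``chemotype`` is a scaffold-cluster label and is only meaningful for
    binders; decoys are never chemotyped.  ``cocrystal_of`` names the receptor
    conformer this binder was co-crystallized with, if any.
    """

    ligand_id: str
    molecular_weight: float
    is_binder: bool
    chemotype: str | None = None
    cocrystal_of: str | None = None

    def __post_init__(self) -> None:
        if not self.ligand_id:
            raise ValidationError("ligand_id must be a non-empty string")
        if not (self.molecular_weight > 0) or not math.isfinite(self.molecular_weight):
            raise ValidationError(
                f"ligand {self.ligand_id!r}: molecular weight must be a positive, "
                f"finite number of Da, got {self.molecular_weight!r}"
            )
        if self.chemotype is not None and not self.is_binder:
            raise ValidationError(
                f"ligand {self.ligand_id!r}: decoys cannot carry a chemotype label"
            )
        if self.cocrystal_of is not None and not self.is_binder:
            raise ValidationError(
                f"ligand {self.ligand_id!r}: decoys cannot be co-crystallized ligands"
            )


class LigandLibrary:
    """An ordered, id-unique collection of :class:`LigandRecord`."""

    def __init__(self, records: Iterable[LigandRecord]):
        self._records: dict[str, LigandRecord] = {}
        for rec in records:
            if rec.ligand_id in self._records:
                raise ValidationError(f"duplicate ligand_id {rec.ligand_id!r}")
            self._records[rec.ligand_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[LigandRecord]:
        return iter(self._records.values())

    def __contains__(self, ligand_id: str) -> bool:
        return ligand_id in self._records

    def __getitem__(self, ligand_id: str) -> LigandRecord:
        return self._records[ligand_id]

    @property
    def ligand_ids(self) -> list[str]:
        return list(self._records)

    @property
    def binders(self) -> list[LigandRecord]:
        return [r for r in self if r.is_binder]

    @property
    def decoys(self) -> list[LigandRecord]:
        return [r for r in self if not r.is_binder]

    @property
    def n_binders(self) -> int:
        return sum(1 for r in self if r.is_binder)

    def molecular_weights(self, ligand_ids: Sequence[str]) -> np.ndarray:
        return np.array([self._records[l].molecular_weight for l in ligand_ids])

    def binder_mask(self, ligand_ids: Sequence[str]) -> np.ndarray:
        return np.array([self._records[l].is_binder for l in ligand_ids])

    def replace(self, records: Iterable[LigandRecord]) -> "LigandLibrary":
        """A new library with the given records substituted by ligand_id."""
        updated = dict(self._records)
        for rec in records:
            if rec.ligand_id not in updated:
                raise ValidationError(f"unknown ligand_id {rec.ligand_id!r}")
            updated[rec.ligand_id] = rec
        return LigandLibrary(updated.values())

    def subset(self, ligand_ids: Iterable[str]) -> "LigandLibrary":
        keep = set(ligand_ids)
        return LigandLibrary(r for r in self if r.ligand_id in keep)


@dataclass
class ConformerRun:
    """One conformer's complete score vector over the ligand library."""

    conformer_id: str
    scores: dict[str, float]

    @property
    def min_score(self) -> float:
        return min(self.scores.values())


@dataclass
class EnsembleScreen:
    """All SRC runs of one target over a shared ligand library.

    ``excluded`` marks targets whose ensembles were emptied by filtering and
    can no longer be evaluated; it is never set by construction.
    """

    target_id: str
    runs: list[ConformerRun]
    library: LigandLibrary | None = None
    excluded: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.runs and not self.excluded:
            raise ValidationError(f"target {self.target_id!r}: at least one run required")
        seen = set()
        for run in self.runs:
            if run.conformer_id in seen:
                raise ValidationError(
                    f"target {self.target_id!r}: duplicate conformer {run.conformer_id!r}"
                )
            seen.add(run.conformer_id)
        if self.runs:
            ref = set(self.runs[0].scores)
            for run in self.runs[1:]:
                if set(run.scores) != ref:
                    raise CoverageError(
                        f"target {self.target_id!r}: conformer {run.conformer_id!r} "
                        "does not score the same ligand set as the other runs"
                    )
            if self.library is not None:
                lib_ids = set(self.library.ligand_ids)
                if ref != lib_ids:
                    missing = sorted(lib_ids - ref)[:5]
                    extra = sorted(ref - lib_ids)[:5]
                    raise CoverageError(
                        f"target {self.target_id!r}: run ligand set does not match "
                        f"annotations (missing {missing}, unannotated {extra})"
                    )

    @property
    def conformer_ids(self) -> list[str]:
        return [r.conformer_id for r in self.runs]

    @property
    def ligand_ids(self) -> list[str]:
        if self.library is not None:
            return self.library.ligand_ids
        return sorted(self.runs[0].scores) if self.runs else []

    def score_matrix(self) -> tuple[np.ndarray, list[str]]:
        """(n_runs, N) score matrix and the ligand id column order."""
        lids = self.ligand_ids
        mat = np.array([[run.scores[l] for l in lids] for run in self.runs])
        return mat, lids


@dataclass(frozen=True)
class RankEntry:
    ligand_id: str
    primary_key: float
    secondary_key: float


@dataclass
class RankedList:
    """A dense 1-based ordering of every ligand in a library.

    ``entries[k-1]`` is the ligand at rank ``k``.  ``primary_key`` is the
    quantity the list was sorted by (a score for SRC/MRC-score, a best rank
    for MRC-rank, ...); ``secondary_key`` the first tie-break quantity.
    """

    target_id: str
    method: str
    entries: list[RankEntry]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ligand_ids(self) -> list[str]:
        return [e.ligand_id for e in self.entries]

    @property
    def ranks(self) -> dict[str, int]:
        """ligand_id -> 1-based rank."""
        return {e.ligand_id: k for k, e in enumerate(self.entries, start=1)}

    def binder_ranks(self, library: LigandLibrary) -> np.ndarray:
        """Sorted 1-based ranks of the binders in this ordering."""
        return np.array(
            [k for k, e in enumerate(self.entries, start=1) if library[e.ligand_id].is_binder]
        )

    def relative_ranks(self, library: LigandLibrary) -> np.ndarray:
        """Binder ranks divided by library size (the x-axis of a binder
        rank-distribution plot)."""
        return self.binder_ranks(library) / len(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": self.target_id,
                "rank": np.arange(1, len(self) + 1),
                "ligand": self.ligand_ids,
                "primary_key": [e.primary_key for e in self.entries],
                "secondary_key": [e.secondary_key for e in self.entries],
                "method": self.method,
            }
        )


# ---------------------------------------------------------------------------
# Sorting
# ---------------------------------------------------------------------------

def _ordered_entries(
    ligand_ids: Sequence[str],
    primary: np.ndarray,
    secondary: np.ndarray,
    *extra_tiebreaks: np.ndarray,
) -> list[RankEntry]:
    """Sort ligands by (primary, secondary, *extra, ligand_id), ascending.

    The trailing lexicographic ligand_id key makes every ordering fully
    deterministic regardless of input row order.
    """
    lids = np.asarray(ligand_ids, dtype=object)
    keys = (lids,) + tuple(reversed(extra_tiebreaks)) + (secondary, primary)
    order = np.lexsort(keys)
    return [
        RankEntry(str(lids[i]), float(primary[i]), float(secondary[i])) for i in order
    ]


def rank_single_run(run: ConformerRun, library: LigandLibrary) -> RankedList:
    """Rank one SRC run: ascending score, ties broken by lower molecular
    weight, then lexicographic ligand id."""
    lids = library.ligand_ids
    missing = [l for l in lids if l not in run.scores]
    if missing:
        raise CoverageError(
            f"conformer {run.conformer_id!r}: no score for ligands {missing[:5]}"
        )
    scores = np.array([run.scores[l] for l in lids])
    mw = library.molecular_weights(lids)
    return RankedList(
        target_id=run.conformer_id,
        method="SRC",
        entries=_ordered_entries(lids, scores, mw),
    )


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if str(path).endswith(".csv") else "tsv"
    if dialect not in ("tsv", "csv"):
        raise FormatError(f"unknown dialect {dialect!r}, expected 'tsv' or 'csv'")
    return "\t" if dialect == "tsv" else ","


def _read_table(path: str | Path, dialect: str | None, required: Sequence[str]) -> pd.DataFrame:
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    for col in df.columns:
        df[col] = df[col].str.strip()
    return df


def _numeric_column(df: pd.DataFrame, col: str, path: str | Path) -> pd.Series:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.isna() & (df[col] != "")
    if bad.any():
        # +2: 1-based with a header line
        line = int(bad.idxmax()) + 2
        raise FormatError(
            f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
            f"{col!r} at line {line}"
        )
    if (df[col] == "").any():
        line = int((df[col] == "").idxmax()) + 2
        raise FormatError(f"{path}: empty value in column {col!r} at line {line}")
    return values


def read_score_table(
    path: str | Path,
    dialect: str | None = None,
    library: LigandLibrary | Mapping[str, LigandLibrary] | None = None,
    invert_sign: bool = False,
) -> dict[str, EnsembleScreen]:
    """Read a long-form per-conformer score table into one
    :class:`EnsembleScreen` per target.

    Parameters
    ----------
    path : file with columns ``target, conformer, ligand, score``.
    dialect : ``"tsv"`` (default) or ``"csv"``; inferred from a ``.csv``
        suffix when omitted.
    library : annotations to attach — either one shared library or a mapping
        ``target -> library``.  Optional; metrics require annotations.
    invert_sign : negate scores on load for higher-is-better engines.
    """
    df = _read_table(path, dialect, SCORE_TABLE_COLUMNS)
    if df.empty:
        logger.warning("score table %s contains a header but no rows", path)
        return {}
    scores = _numeric_column(df, "score", path)
    if invert_sign:
        scores = -scores
    df = df.assign(score=scores)

    dup = df.duplicated(subset=["target", "conformer", "ligand"])
    if dup.any():
        t, c, l = df.loc[dup.idxmax(), ["target", "conformer", "ligand"]]
        raise FormatError(f"{path}: duplicate score row for ({t}, {c}, {l})")

    screens: dict[str, EnsembleScreen] = {}
    for target, tdf in df.groupby("target", sort=True):
        lig_ids = sorted(tdf["ligand"].unique())
        lig_set = set(lig_ids)
        runs = []
        for conformer, cdf in tdf.groupby("conformer", sort=True):
            run_scores = dict(zip(cdf["ligand"], cdf["score"].astype(float)))
            missing = sorted(lig_set - set(run_scores))
            if missing:
                raise CoverageError(
                    f"{path}: target {target!r}, conformer {conformer!r} is "
                    f"missing scores for ligands {missing[:5]}"
                    + (" ..." if len(missing) > 5 else "")
                )
            runs.append(ConformerRun(str(conformer), run_scores))
        lib = library.get(str(target)) if isinstance(library, Mapping) else library
        screens[str(target)] = EnsembleScreen(str(target), runs, lib)
    return screens


def write_score_table(
    screens: Iterable[EnsembleScreen] | Mapping[str, EnsembleScreen],
    path: str | Path,
    dialect: str | None = None,
) -> None:
    if isinstance(screens, Mapping):
        screens = screens.values()
    sep = _sep_for(path, dialect)
    rows = []
    for screen in screens:
        for run in screen.runs:
            for lid, s in run.scores.items():
                rows.append((screen.target_id, run.conformer_id, lid, s))
    df = pd.DataFrame(rows, columns=list(SCORE_TABLE_COLUMNS))
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)


def read_ligand_annotations(path: str | Path, dialect: str | None = None) -> LigandLibrary:
    """Read a ligand annotation table (columns ``ligand, mw, label,
    chemotype, cocrystal_of``; label in {binder, decoy})."""
    df = _read_table(path, dialect, ANNOTATION_COLUMNS)
    mw = _numeric_column(df, "mw", path)
    records = []
    for i, row in df.iterrows():
        label = row["label"].lower()
        if label not in ("binder", "decoy"):
            raise FormatError(
                f"{path}: label must be 'binder' or 'decoy', got {row['label']!r} "
                f"at line {int(i) + 2}"
            )
        records.append(
            LigandRecord(
                ligand_id=row["ligand"],
                molecular_weight=float(mw[i]),
                is_binder=label == "binder",
                chemotype=row["chemotype"] or None,
                cocrystal_of=row["cocrystal_of"] or None,
            )
        )
    return LigandLibrary(records)


def write_ligand_annotations(
    library: LigandLibrary, path: str | Path, dialect: str | None = None
) -> None:
    sep = _sep_for(path, dialect)
    df = pd.DataFrame(
        {
            "ligand": [r.ligand_id for r in library],
            "mw": [r.molecular_weight for r in library],
            "label": ["binder" if r.is_binder else "decoy" for r in library],
            "chemotype": [r.chemotype or "" for r in library],
            "cocrystal_of": [r.cocrystal_of or "" for r in library],
        }
    )
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT,
              quoting=csv.QUOTE_MINIMAL)


def write_ranked_list(ranked: RankedList, path: str | Path, dialect: str | None = None) -> None:
    ranked.to_frame().to_csv(path, sep=_sep_for(path, dialect), index=False,
                             float_format=FLOAT_FORMAT)


def read_ranked_list(path: str | Path, dialect: str | None = None) -> RankedList:
    df = _read_table(path, dialect, ("target", "rank", "ligand", "primary_key",
                                     "secondary_key", "method"))
    df = df.assign(rank=_numeric_column(df, "rank", path).astype(int))
    df = df.sort_values("rank")
    entries = [
        RankEntry(row["ligand"], float(row["primary_key"]), float(row["secondary_key"]))
        for _, row in df.iterrows()
    ]
    target = df["target"].iloc[0] if len(df) else ""
    method = df["method"].iloc[0] if len(df) else ""
    return RankedList(target_id=target, method=method, entries=entries)
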