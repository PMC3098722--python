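"""Reference tables from the published 36-target DUD/Pocketome ensemble
screening benchmark.

These small fixtures record the benchmark's composition (conformer, binder
and decoy counts per target) and its per-target summary statistics for
AUAC, EF at 1%, and BEDROC (alpha = 20).  They are used to validate the
metric implementations against printed closed-form cells (e.g. the ideal
EF_1% column follows directly from the binder and library counts) and to
provide realistic target compositions to examples and tests.

Printed decimals in the source tables are truncated, not rounded; use
:func:`evls.metrics.truncate_decimals` when comparing.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: worked example from the benchmark: the six single-conformer AUAC values
#: for the progesterone receptor target, and the two combined-protocol AUACs
PRGR_SRC_AUAC = (0.72, 0.70, 0.65, 0.62, 0.61, 0.61)
PRGR_MRC_SCORE_AUAC = 0.71
PRGR_MRC_RANK_AUAC = 0.84


def _load(name: str) -> pd.DataFrame:
    with resources.files("evls.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def benchmark_composition() -> pd.DataFrame:
    """Per-target conformer/binder/decoy counts of the reference benchmark
    (36 targets, 457 conformers in total)."""
    return _load("dud_benchmark_composition.tsv")


def auac_summary() -> pd.DataFrame:
    """Per-target SRC min/max/mean, MRC-score, MRC-rank and ideal AUAC."""
    return _load("dud_auac_summary.tsv")


def ef1_summary() -> pd.DataFrame:
    """Per-target SRC min/max/mean, MRC-score, MRC-rank and ideal EF_1%."""
    return _load("dud_ef1_summary.tsv")


def bedroc_summary() -> pd.DataFrame:
    """Per-target SRC min/max/mean, MRC-score, MRC-rank and ideal BEDROC
    (alpha = 20)."""
    return _load("dud_bedroc_summary.tsv")


def target_counts(target: str) -> tuple[int, int]:
    """(n_binders, n_total) for one benchmark target."""
    df = benchmark_composition().set_index("target")
    row = df.loc[target]
    return int(row["binders"]), int(row["total"])
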