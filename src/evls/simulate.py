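"""Synthetic ensemble-docking score generator with explicit induced-fit
structure.

The generator emulates the statistical shape of a retrospective ensemble
screening benchmark without running any docking engine:

* each target carries 2-30 receptor conformers and a library with a
  binder:decoy ratio of about 1:43;
* binders fall into scaffold clusters (chemotypes), and each conformer
  "recognizes" a random subset of chemotypes — the discrete induced-fit
  mechanism.  A binder docked against a compatible conformer draws its score
  from a favorable distribution; against an incompatible conformer it draws
  from a distribution *worse than the decoys'*, reproducing the
  characteristic bimodal distribution of binder relative ranks in
  single-conformer runs;
* a configurable fraction of runs is degenerate ("bad runs"): the conformer
  recognizes no chemotype (all binders draw from the incompatible
  distribution) and every ligand receives a strictly positive score — the
  situation the all-positive conformer filter is designed to remove.  The
  noise they inject is real: in a merged list their decoys get an extra
  chance at a good best-rank/best-score while their binders do not;
* a configurable fraction of binders is annotated as co-crystallized with a
  compatible conformer, to exercise the cognate-ligand filter.

Scores are Gaussian with three means (compatible binder, incompatible
binder, decoy); lower = better throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import (
    ConformerRun,
    EnsembleScreen,
    LigandLibrary,
    LigandRecord,
    rank_single_run,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the composition of the published 36-target benchmark
    this package's fixtures describe: 1:43 binder:decoy ratio, 2-30
    conformers per target, scaffold-clustered binders.  Score means are in
    dimensionless docking-score units (lower = better): compatible binders
    around -35, decoys around -15, incompatible binders around -12 (worse
    than an average decoy).
    """

    n_targets: int = 20
    conformers_range: tuple[int, int] = (2, 30)
    n_binders: int = 25
    n_decoys: int = 1075
    n_chemotypes: int = 6
    compat_fraction: float = 0.5
    mu_active: float = -35.0
    mu_incompatible: float = -12.0
    mu_decoy: float = -15.0
    sigma: float = 4.0
    frac_bad_runs: float = 0.1
    cocrystal_fraction: float = 0.2
    mw_range: tuple[float, float] = (150.0, 550.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.mu_active < self.mu_decoy <= self.mu_incompatible):
            raise ValueError(
                "score means must satisfy mu_active < mu_decoy <= mu_incompatible "
                "(compatible binders outscore decoys; incompatible binders do not)"
            )
        for name in ("compat_fraction", "frac_bad_runs", "cocrystal_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_chemotypes > self.n_binders:
            raise ValueError("n_chemotypes cannot exceed n_binders")
        if self.n_chemotypes < 1 or self.n_binders < 1 or self.n_decoys < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.conformers_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid conformers_range")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


#: shift applied to degenerate runs; raised further if needed so the
#: minimum score is strictly positive by construction
BAD_RUN_SHIFT = 30.0


def _target_rng(config: SyntheticConfig, index: int) -> np.random.Generator:
    # one generator per target, derived from (master seed, target index), so
    # per-target data is stable when n_targets changes
    return np.random.default_rng((config.seed, index))


def _generate_target(config: SyntheticConfig, index: int) -> EnsembleScreen:
    rng = _target_rng(config, index)
    target = f"T{index:03d}"
    nb, nd, nc = config.n_binders, config.n_decoys, config.n_chemotypes

    # chemotype assignment: every chemotype gets at least one binder
    chemo = np.concatenate(
        [np.arange(nc), rng.integers(0, nc, size=nb - nc)]
    )
    rng.shuffle(chemo)

    mw = rng.uniform(*config.mw_range, size=nb + nd).round(1)
    binder_ids = [f"{target}_B{i:03d}" for i in range(nb)]
    decoy_ids = [f"{target}_D{i:04d}" for i in range(nd)]

    lo, hi = config.conformers_range
    n_conf = int(rng.integers(lo, hi + 1))
    conformer_ids = [f"{target}_c{j:02d}" for j in range(n_conf)]
    compat = rng.random((n_conf, nc)) < config.compat_fraction
    bad = rng.random(n_conf) < config.frac_bad_runs

    runs = []
    for j in range(n_conf):
        if bad[j]:
            # degenerate conformer: recognizes nothing
            mu_b = np.full(nb, config.mu_incompatible)
        else:
            mu_b = np.where(compat[j, chemo], config.mu_active, config.mu_incompatible)
        b_scores = rng.normal(mu_b, config.sigma)
        d_scores = rng.normal(config.mu_decoy, config.sigma, size=nd)
        scores = np.concatenate([b_scores, d_scores])
        if bad[j]:
            scores += max(BAD_RUN_SHIFT, 1.0 - scores.min())
        runs.append(
            ConformerRun(
                conformer_ids[j],
                dict(zip(binder_ids + decoy_ids, scores.tolist())),
            )
        )

    # co-crystal annotations: each selected binder is paired with a
    # conformer compatible with its chemotype (skipped if none is)
    n_cocrystal = int(round(config.cocrystal_fraction * nb))
    cocrystal: dict[str, str] = {}
    if n_cocrystal:
        for i in rng.choice(nb, size=n_cocrystal, replace=False):
            compatible = np.flatnonzero(compat[:, chemo[i]])
            if compatible.size:
                j = int(rng.choice(compatible))
                cocrystal[binder_ids[i]] = conformer_ids[j]

    records = [
        LigandRecord(
            ligand_id=binder_ids[i],
            molecular_weight=float(mw[i]),
            is_binder=True,
            chemotype=f"C{chemo[i] + 1}",
            cocrystal_of=cocrystal.get(binder_ids[i]),
        )
        for i in range(nb)
    ] + [
        LigandRecord(
            ligand_id=decoy_ids[i],
            molecular_weight=float(mw[nb + i]),
            is_binder=False,
        )
        for i in range(nd)
    ]
    return EnsembleScreen(target, runs, LigandLibrary(records))


def generate_screen(config: SyntheticConfig) -> list[EnsembleScreen]:
    """Generate one :class:`EnsembleScreen` (with attached annotations) per
    target.  Deterministic given ``config.seed``."""
    return [_generate_target(config, i) for i in range(config.n_targets)]


@dataclass
class BimodalityResult:
    """Pooled binder relative-rank histogram over all SRC runs."""

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def is_bimodal(self) -> bool:
        """True when the leftmost bin and the mean rightmost-quartile bin
        each carry more mass than the average middle-half bin."""
        nbins = len(self.counts)
        mid = self.counts[nbins // 4 : 3 * nbins // 4]
        right = self.counts[3 * nbins // 4 :]
        middle_avg = float(mid.mean())
        return float(self.counts[0]) > middle_avg and float(right.mean()) > middle_avg


def generate_bimodality_check(
    config: SyntheticConfig, n_bins: int = 20
) -> BimodalityResult:
    """Histogram of binder relative ranks pooled over every SRC run of every
    generated target.

    With partial chemotype compatibility (0 < compat_fraction < 1) the
    distribution is bimodal: compatible binders pile up near relative rank
    0, incompatible binders rank below an average decoy and pile up in the
    right tail.
    """
    pooled = []
    for screen in generate_screen(config):
        for run in screen.runs:
            ranked = rank_single_run(run, screen.library)
            pooled.append(ranked.relative_ranks(screen.library))
    edges = np.linspace(0, 1, n_bins + 1)
    counts, _ = np.histogram(np.concatenate(pooled), bins=edges)
    return BimodalityResult(bin_edges=edges, counts=counts)
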