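# Methods

## Problem setting

Ensemble (multiple receptor conformation, MRC) virtual screening docks every
molecule of a library against each crystallographic conformer of a target
and fuses the per-conformer results into one ranked list. The scientific
question the toolkit quantifies is whether the fused list separates
annotated binders from decoys better than the single-conformer (SRC) runs it
was built from, particularly in the topmost fraction of the ranking. All
scores follow the lower-is-better convention; every sort is ascending.

## Ranking and fusion

An SRC run is ranked by score, with deterministic tie-breaks: lower
molecular weight first (the smaller molecule earns the better rank), then
lexicographic ligand id. The trailing id key is this package's own addition
so that identical inputs always produce byte-identical orderings regardless
of input row order; it only ever acts on exact score-and-weight ties.

MRC-score keys each ligand by its minimum score over runs; MRC-rank by its
minimum per-run rank, with ties broken by the ligand's best score *across
all runs* (not the score from the best-rank run — the two readings differ
only on exact best-rank ties, and the global-best reading keeps MRC-rank
consistent with MRC-score semantics; this is an interpretive choice and is
configurable only by editing the sort keys). Both deduplicate by
construction: each ligand contributes exactly one entry.

The alternative schemes are provided for completeness. The Boltzmann
combination uses the soft-minimum key −T·ln Σ_j exp(−s_j/T), implemented
via `scipy.special.logsumexp`; this functional form is a reconstruction —
no canonical definition exists for score fusion of this kind — and is
labeled non-canonical. Defaults: T = 1 score unit; the molecular-weight
penalty weight λ in `boltzmann_score_mw` defaults to 0 (inactive) and must
be set deliberately, because any nonzero λ mixes units (score per Dalton)
and its scale is screen-specific.

## Figures of merit

All five metrics are functionals of the accumulation curve
F_a(k) = #{binders with rank ≤ k}, for a library of N molecules with n
binders:

* AUAC = (1/nN) Σ_{k=1..N} F_a(k); range [(n+1)/2N, 1 − (n−1)/2N].
* ROC AUC via the Mann–Whitney statistic: the fraction of (binder, decoy)
  pairs in which the binder has the better primary sort key, with half
  credit for key ties. For tie-free rankings this equals the linear
  transform (N·AUAC − (n+1)/2)/(N − n), an identity the suite checks to
  1e−12. Tie handling matters: rank-based metrics consume the tie-broken
  deterministic ranks, while ROC deliberately does not let an arbitrary
  tie-break manufacture discrimination.
* EF_χ = F_a(⌊χN⌋)/(nχ), undefined (an error) when ⌊χN⌋ = 0; maximum
  min(n, ⌊χN⌋)/(nχ).
* RIE = Σ_i exp(−α·r_i/N) / [(n/N)(1 − e^{−α})/(e^{α/N} − 1)]; a uniformly
  random ranking has expectation 1 (checked by Monte-Carlo to three
  standard errors).
* BEDROC standardizes RIE between its minimum and maximum, both obtained by
  *evaluating the same RIE formula* at the worst (ranks N−n+1..N) and ideal
  (ranks 1..n) orderings rather than with a closed-form approximation, so
  BEDROC is exactly 0 and 1 at the endpoints for every (n, N, α).

α defaults to 20, the conventional choice that concentrates ~80% of the
BEDROC weight in the top ~8% of the list; χ defaults to {0.01, 0.10}.

When comparing against the published benchmark tables shipped as fixtures,
printed decimals are *truncated*, not rounded (`truncate_decimals`); the
library itself always returns full precision.

## Percentile placement and significance

An MRC value is placed within its target's SRC distribution as
percentile = ⌊100·(c+1)/(k+1)⌋, where k is the number of SRC runs and c
the number of SRC values *strictly* worse (ties are not wins). The
benchmark literature does not state a formula; this convention is the one
consistent with the published worked example (outperforming 5 of 6 runs →
85th percentile; all 6 → 100th) and is exposed as a replaceable callable.

The paired one-tailed t-test compares each target's MRC value against that
target's mean SRC value (the most literal reading of "the average
individual run"). It is implemented from the textbook formula so the
degenerate cases are defined: all-zero differences → p = 0.5; zero-variance
nonzero differences → p ∈ {0, 1} by sign. On regular inputs it matches
`scipy.stats.ttest_rel(…, alternative="greater")` to 1e−10.

## Filters

*All-positive runs.* A run is dropped iff its minimum score is strictly
positive; a single zero score keeps the run (strictness chosen so the
filter removes only runs with literally no favorable score — the boundary
is not specified by the empirical rule the filter implements). The filter
is idempotent; an ensemble emptied by it is flagged `excluded`, not an
error. An EF_1% < 1 criterion is deliberately *not* treated as equivalent,
even though the two coincided empirically in the motivating benchmark; it
can be applied separately via the metrics API.

*Cognate ligands.* Binders co-crystallized with an in-ensemble conformer,
and all binders sharing their chemotype, are *deleted* (not relabeled):
the binder count n is recomputed after exclusion while N shrinks
accordingly. References to conformers absent from the screen warn and do
not remove. Decoys are never touched.

## Chemotype diversity

`chemotype_representative_relabel` keeps, per chemotype, only the binder
with the best rank *in the ranking under evaluation* and relabels the rest
as decoys — here N stays fixed and only n drops to the chemotype count,
because the question is how much of the original list's enrichment survives
when each scaffold may count once. The representative is recomputed per
ranked list (a fixed global representative would give different numbers);
ties for best rank cannot occur because ranks are unique after
tie-breaking. Relabeling is idempotent for a fixed ranking.

## Synthetic generator

The generator emulates the statistical structure of a retrospective
ensemble-screening benchmark; its defaults are the package's fixed study
conditions:

| parameter | default | meaning |
|---|---|---|
| n_targets | 20 | independent targets per replicate |
| conformers_range | (2, 30) | uniform per-target conformer count |
| n_binders / n_decoys | 25 / 1075 | 1:43 binder:decoy ratio |
| n_chemotypes | 6 | scaffold clusters among binders |
| compat_fraction | 0.5 | P(conformer recognizes a chemotype) |
| mu_active / mu_decoy / mu_incompatible | −35 / −15 / −12 | Gaussian score means |
| sigma | 4 | score spread |
| frac_bad_runs | 0.1 | P(run is degenerate/all-positive) |
| cocrystal_fraction | 0.2 | fraction of binders with a cognate conformer |
| mw_range | (150, 550) Da | uniform molecular weights |

The three-mean Gaussian score model is the simplest mechanism that
reproduces the two empirical signatures of induced fit: binders docked into
a compatible conformer outscore decoys (left peak of the binder
relative-rank distribution), while binders docked into an incompatible
conformer score *worse than an average decoy* (right peak). The constraint
mu_active < mu_decoy ≤ mu_incompatible is enforced. The ratio, conformer
range and chemotype clustering mirror the published benchmark composition;
sigma, frac_bad_runs and cocrystal_fraction are this package's choices of a
realistic noise level, degenerate-run rate and benchmark/structure overlap.

A degenerate ("bad") run recognizes no chemotype at all and is then shifted
so every score is strictly positive. The shift is max(30, 1 − min score)
rather than a flat +30, so the all-positive property holds by construction
for any sigma. Two modeling points matter: a pure constant shift would be
invisible to both fusion protocols (per-run rankings are shift-invariant),
so degeneracy must — and does — also scramble the binder signal; and bad
runs injure a merged list through their decoys, which get an extra draw at
a good best-rank/best-score while the run's binders do not.

Randomness: one `numpy` generator per target, seeded by the pair (master
seed, target index), so per-target data is reproducible and stable when
n_targets changes.

What the generator does **not** emulate: correlated scores between similar
decoys, target-to-target variation in library size or difficulty,
score–weight correlation, non-Gaussian score tails, and partially
degenerate runs. Passing tests therefore demonstrate correctness of the
post-processing machinery and the *direction* of the ensemble effect under
an idealized induced-fit mechanism — not quantitative performance on real
docking output.

## Bimodality check

The pooled binder relative-rank histogram (20 bins on [0, 1]) is called
bimodal when the leftmost bin and the mean rightmost-quartile bin each
carry more mass than the average middle-half bin. This is a coarse
predicate chosen to be robust to bin noise, not a statistical test.

## Problem sizes and numerical choices

The protocol-superiority suite runs 100 seeded replicates of the default
20-target configuration (2,000 target instances) and asserts that MRC-rank
BEDROC ≥ the target's mean SRC BEDROC in ≥95% of instances, and that
dropping injected all-positive runs does not decrease the mean MRC-rank
BEDROC; the Monte-Carlo RIE normalization uses 10⁴ random rankings at
N = 100, n = 10. Exact identities (AUAC↔ROC, metric oracle equivalence for
all binder placements at N ≤ 8) are asserted at 1e−12. Sorting uses
`numpy.lexsort` over (primary, secondary, …, ligand id) keys; no tolerance
enters any ordering.

## Known limitations

* Missing scores are a hard error — the design assumes everything was
  docked everywhere; there is no imputation path.
* The Boltzmann variants are reconstructions and should not be cited as
  canonical protocols.
* The percentile convention, while consistent with the published worked
  example, is an inference from two data points; other conventions shift
  single-target placements by a few points (never the strict-win count).
* Reference fixture tables reproduce the published benchmark summaries as
  printed; two printed columns (ideal AUAC, and one ideal-EF cell) are
  internally inconsistent with their own closed forms and are not used for
  validation.
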