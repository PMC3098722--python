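# evls — ensemble virtual-screening post-processing

`evls` post-processes **ensemble docking** (multiple receptor conformation,
MRC) virtual-screening results. In MRC screening every candidate molecule is
docked independently against each crystallographic conformer of a target;
the per-conformer score tables must then be fused into a single ranked list
and judged for how well they separate annotated binders from decoys —
especially in the topmost fraction, the only part of a ranking that is ever
tested experimentally.

The package provides, for whoever runs retrospective screening benchmarks or
prospective ensemble campaigns:

* **Score fusion** — the two canonical protocols plus documented variants:
  * *MRC-score*: per-ligand key = best (minimum) score over runs, sorted
    ascending; score ties broken by lower molecular weight, then ligand id.
  * *MRC-rank*: per-ligand key = best rank over independently ranked runs;
    ties broken by best score, then molecular weight, then id.
  * variants: deeper rank tie-breaks (2nd/3rd-best rank), Boltzmann
    soft-minimum of scores −*T* ln Σ<sub>j</sub> e<sup>−s<sub>j</sub>/T</sup>
    (with optional molecular-weight penalty), and rank-sum consensus.
* **Five figures of merit**, all derived from the accumulation curve
  F<sub>a</sub>(k) = #{binders with rank ≤ k} for a library of N molecules
  with n binders:
  AUAC = (1/nN) Σ<sub>k</sub> F<sub>a</sub>(k);
  ROC AUC (Mann–Whitney, half credit for score ties);
  EF<sub>χ</sub> = F<sub>a</sub>(⌊χN⌋)/(nχ);
  RIE = Σ<sub>i</sub> e<sup>−αr<sub>i</sub>/N</sup> /
  [(n/N)(1−e<sup>−α</sup>)/(e<sup>α/N</sup>−1)];
  BEDROC = (RIE − RIE<sub>min</sub>)/(RIE<sub>max</sub> − RIE<sub>min</sub>)
  with α = 20 by default.
* **Benchmarking** — percentile placement of an MRC result within the
  distribution of its single-conformer (SRC) runs, paired one-tailed
  t-tests, per-target min/max/mean tables and cross-target histograms.
* **Filters** — removal of degenerate runs in which *every* ligand received
  a strictly positive docking score, and of co-crystallized binders together
  with all binders of the same chemotype (scaffold cluster).
* **Chemotype diversity** — binder/chemotype content of the top fraction,
  and best-representative-per-chemotype relabeling.
* **A synthetic generator** of ensemble score tables with explicit
  induced-fit structure (conformer-specific chemotype recognition), so every
  analysis is testable without a docking engine.

Scores follow the lower-is-better convention throughout (load with
`invert_sign=True` for the opposite convention).

## Worked example

```python
import evls

# synthetic benchmark: 2 targets, 1:43 binder:decoy ratio, induced fit
screens = evls.generate_screen(evls.SyntheticConfig(n_targets=2, seed=0))
screen = screens[0]
lib = screen.library

src_bedroc = [
    evls.metric_report(evls.rank_single_run(run, lib), lib).bedroc
    for run in screen.runs
]
mrc = evls.metric_report(evls.combine_mrc_rank(screen), lib)
place = evls.percentile_placement(mrc.bedroc, src_bedroc, metric="bedroc")
print(f"SRC BEDROC mean {sum(src_bedroc)/len(src_bedroc):.3f}  "
      f"MRC-rank BEDROC {mrc.bedroc:.3f}  "
      f"EF1% {mrc.ef[0.01]:.1f}  percentile {place.percentile}")
```

prints

```
SRC BEDROC mean 0.446  MRC-rank BEDROC 0.962  EF1% 36.0  percentile 100
```

i.e. on this target the rank-merged ensemble list (BEDROC 0.962, 36-fold
enrichment in the top 1%) outperforms all of the individual conformer runs
(mean BEDROC 0.446), landing in the 100th percentile of the SRC
distribution — the ensemble effect the toolkit is built to measure.

The same pipeline runs from the shell:

```sh
evls run --config config.yaml --seed 0 --out-dir out/
```

with subcommands `simulate | filter | combine | metrics | diversity |
benchmark` for the individual stages.

Reference tables for a published 36-target DUD/Pocketome screening benchmark
(per-target conformer/binder/decoy counts and AUAC/EF/BEDROC summaries) ship
with the package under `evls.reference`.

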