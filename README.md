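# comra

Retrieved-context simulation of individual and collaborative free recall.

`comra` implements a CMR-style memory-search model in which a drifting,
unit-norm context vector is bound to studied items and later cues retrieval,
plus a turn-taking group extension: whenever a member recalls a word new to
the group, every other active member independently attends to it with
probability `p_cue` and drifts their own context toward it. With that single
added mechanism, collaborative groups recall fewer unique items than the same
number of individuals recalling alone (collaborative inhibition), because
members' contexts converge and constrain the area of memory they search.

## What's inside

| Module | Purpose |
| --- | --- |
| `comra.semantic` | semantic spaces: synthetic cluster generator, word2vec-text I/O, cosine queries |
| `comra.cmr` | the individual model: context drift, Hebbian item–context learning, sampling retrieval, stopping rule |
| `comra.simulate` | nominal (independent) and collaborative (turn-taking, broadcast + listening) group sessions, transcript CSV/JSON I/O |
| `comra.metrics` | serial position curve, probability of first recall, semantic similarity by output lag (own/group scope), proportion recalled, inhibition by group size, lag-CRP |
| `comra.context` | context-trajectory analyses: pairwise similarity, convergence, within-subject traversal, two-way ANOVA, convergence–performance Spearman correlation, group-size permutation test |
| `comra.fitting` | range-normalized RMSE objective, Gaussian-process (EI) sequential fitting of individual parameters, grid search for `p_cue` |
| `comra.experiment` | experiment configs (desk and full presets), matched nominal/collaborative generation, figure-style summary bundles |
| `comra.cli` | `comra` command-line interface |

Everything runs offline: semantic spaces, word lists and recall transcripts
are generated synthetically (no downloads, no binary fixtures).

## CLI

```bash
comra gen-fixtures --n-items 60 --out fixtures/
comra simulate --condition collaborative --group-size 3 --n-groups 20 \
      --list-length 20 --seed 1 --trajectories --out runs/
comra analyze --transcripts runs/transcripts.json --embeddings runs/embeddings.txt --out summaries/
comra context --transcripts runs/transcripts.json --analysis convergence --late 10
comra fit --targets summaries/summary.json --mode pcue --out fit.json
comra figures --preset desk --seed 0 --out figures/
```

Parameter files are flat JSON (see `comra.cmr.CMRParams`); unknown keys are
rejected.

## Notes on scale

Tests and the acceptance report use a reduced "desk" preset (20–60 item
lists, tens to hundreds of simulated groups) so everything completes in
minutes on one CPU. `ExperimentConfig()` (no arguments) mirrors the
reference design: 60-item lists and 48/32/24/12/12 groups of sizes
2/3/4/8/16 per condition.
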