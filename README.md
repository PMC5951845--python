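# nestevo

Comparative phylogenetic analysis of avian nest characters: how nest
**structure** (scrape, platform, cup, simple dome, dome with tunnel,
primary cavity, secondary cavity), nest **site** (ground, tree, non-tree
vegetation, cliff/bank, underground, water bodies, termite/ant nests) and
nest **attachment** (basal, lateral, horizontally forked, pensile) evolved
across bird families, and how strongly these characters depend on one
another and on shared ancestry.

The package is aimed at comparative biologists who have (a) a set of
family-level time-calibrated trees and (b) a family × character table in
which each family may carry one *or several* states per character
(polymorphic families) or none (brood parasites, mound builders, no
data).  A fully synthetic data generator with the same statistical shape
is included, so the entire pipeline is testable without any external
download.

## What it computes

**Ancestral states under the Mk model.**  Each character evolves as a
k-state continuous-time Markov chain with equal rates (ER): transition
probability along a branch of length *t* is

    P(same) = 1/k + (k-1)/k * exp(-k q t),   P(diff) = 1/k - 1/k * exp(-k q t)

(an all-rates-different variant uses the matrix exponential).  The rate
*q* carries an exponential prior with mean 0.1 and is sampled by
Metropolis–Hastings with sliding-window proposals on log *q*, auto-tuned
during burn-in to a 20–40% acceptance band.  Tree uncertainty is
integrated over by treating the tree index as a sampled parameter drawn
from the supplied tree set.  Polymorphic tips enter the pruning
likelihood as indicator vectors, missing tips as all-ones vectors.
Convergence is gated on split R-hat and effective sample size; marginal
ancestral states are averaged per clade over the posterior sample.

**Evolutionary interdependence (Discrete framework).**  Pairs of binary
recodings of the characters (scrape × ground, cup × non-tree vegetation,
cup/dome × non-basal) are compared under an *independent* model (4 rates)
versus a *dependent* model whose 8 rates are contingent on the other
trait's state, with simultaneous double transitions forbidden.  Models
are compared by

    BF = 2 (lnML_dependent − lnML_independent)

with log marginal likelihoods estimated by the harmonic mean of sampled
likelihoods (per-chain estimates averaged across chains; a
stepping-stone estimator is available as a robustness check).  BF > 5 is
read as strong support for dependence, and posterior rate orderings
summarize which character's change drives the other's.

**Phylogenetic signal for set-valued characters.**  Trait dissimilarity
between families is Bray–Curtis on state sets, `1 − 2|A∩B|/(|A|+|B|)`;
phylogenetic distance is patristic distance on the majority-rule
consensus tree (least-squares branch lengths).  The conventional Mantel
test permutes family labels; the evolutionary-model (EM-)Mantel test
instead re-simulates the character under the fitted neutral Mk model, so
its null already contains the correlation expected from shared ancestry.
Both report two-sided, add-one-corrected p-values.

## Worked example

```python
from nestevo.pipeline import make_demo_dataset, run_full_analysis

files = make_demo_dataset("demo", seed=1)       # 242 families, 100 trees
cfg = files["config"]                           # ready-to-run AnalysisConfig
cfg.mcmc = {"n_iter": 20_000, "burn_in": 5_000, "thin": 10, "n_chains": 2}
log = run_full_analysis(cfg)
print(log["stages"]["asr_attachment"])
```

prints (seed 1):

```
{'posterior_mean_rate': 0.0256, 'acceptance': [0.322, 0.323],
 'rhat': {'q': 0.999}, 'ess': {'q': 2995.0}, 'map_root_state': 'basal'}
```

i.e. attachment evolves several-fold slower than the prior mean,
chains mix inside the 20–40% band and agree (R-hat ≈ 1), and the most
probable root state is basal attachment — the pattern expected from a
character in which ~80% of families use only basal attachment.  The
output directory also contains `coevolution_*.json` (Bayes factors and
rate-ordering probabilities per recoding preset), `mantel_*_*.json`
(Mantel r, permutation and EM p-values per character × subset) and TSV
traces/null samples for plotting.

The same pipeline is scriptable from the shell:

```
nestevo demo --out demo --seed 1
nestevo report --config demo/demo_config.json
```

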