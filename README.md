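# ternmix

Constrained ternary-label normal mixtures for multi-condition genomic
score data.

## The problem

Genomic experiments are routinely repeated across many conditions — cell
types along a differentiation lineage, tissues, treatments — and a central
question is *condition specificity*: in which conditions does a feature (a
binding site, a peak, a gene) carry signal, in which is it null, and in
which does the effect point the other way?  With scores summarized as
Z-scores across `D` conditions, each feature carries a latent **association
vector** `h ∈ {-1, 0, 1}^D` (negative / null / positive association per
condition).  Modelling all `3^D` possible vectors as mixture classes is
exact but intractable beyond a handful of conditions; testing each
condition separately throws away the correlation structure that makes
joint analysis powerful.

`ternmix` is for analysts who want the joint model anyway: it learns
*which* of the `3^D` patterns are actually present, fits a constrained
Bayesian normal mixture over only those, and tests each feature for
sign-aware consistency of its effect across conditions.

## The model

Observations follow a constrained `D`-variate normal mixture: given
`H = h`, `x ~ N_D(mu_h, Sigma_h)` with

* `mu_d = 0`, `Sigma_dd = 1` for every null dimension (`h_d = 0`) — the
  null is the standard normal, as Z-scores are calibrated to be;
* `sgn(mu_d) = h_d` for non-null dimensions;
* `Sigma_rt = 0` whenever `r` or `t` is null;
* `sgn(Sigma_rt) = h_r · h_t` for non-null pairs — concordant labels
  correlate positively, discordant negatively.

Because the constraints pin each class to its label, classes are
identifiable and label switching cannot occur.  Estimation runs in four
steps:

1. **Pairwise fitting.**  Each of the `C(D,2)` condition pairs is fit
   with a 9-class constrained bivariate mixture under a mixing-weight
   penalty (strength chosen by BIC), eliminating unsupported pairwise
   labels.
2. **Graph enumeration.**  The retained labels of adjacent pairs define a
   layered DAG whose source-to-target paths are the candidate
   `D`-dimensional vectors; candidates contradicted by any non-adjacent
   pair are pruned.  The enumeration provably retains every true class
   and is invariant to reordering of the conditions.
3. **Concordance weights.**  Pairwise labels are sampled from the
   pairwise posteriors; a candidate's prior weight `alpha_h` is the
   normalized share of observations whose sampled labels agree with it on
   at least `C(D,2) − delta` pairs.  Classes with `n·alpha_h ≤ D` are
   dropped, and the pairwise estimates are recycled into empirical-Bayes
   hyperparameters (normal–inverse-Wishart, Dirichlet on the weights).
4. **MCMC.**  A Metropolis–Hastings-within-Gibbs sampler draws class
   means from truncated conjugate normals, covariances from a
   sign-constrained inverse-Wishart (conjugate independence proposal with
   indicator rejection), mixing weights from a Dirichlet, and labels from
   their full conditionals.

From the retained draws, the **sign-aware partial-conjunction test**
computes, per feature, the posterior probability that at least `u` of `D`
conditions share the label `+1` (and likewise for `0` and `-1`); the
maximum of the three, `P^{u/D}`, is compared to a confidence threshold
`b ≥ 0.5`.  The classical partial-conjunction test (≥ `u` non-null, signs
ignored) is also available, as are post-fit tools: condition dendrograms
from class covariances, class merging into parent groups, group signal
profiles, and Baker's Gamma for comparing dendrograms.

## Worked example

```python
import numpy as np
from ternmix.simulate import build_classes, SimulationSpec, sample_from_mixture
from ternmix import ChainConfig, PipelineConfig, run_pipeline
from ternmix.consistency import call_consistent_vs_differential

classes = build_classes(
    [(0, 0, 0), (1, 1, 1), (1, 0, 0), (0, -1, -1)], mean_scale=4.0, corr=0.5
)
spec = SimulationSpec(classes=classes, weights=[0.3, 0.3, 0.2, 0.2], n=3000, seed=11)
sim = sample_from_mixture(spec)

config = PipelineConfig(outdir="demo_out", seed=11,
                        chain=ChainConfig(n_iter=1500, burn_in=500))
result = run_pipeline(config, data=sim.scores)

print("retained classes and mixing weights:")
for cls, w in zip(result.model.classes, result.model.pi):
    print(f"  {cls.h}  pi = {w:.3f}  mu = {np.round(cls.mu, 2)}")
calls = call_consistent_vs_differential(result.draws, b=0.5)
print("consistent features:", int((calls == "consistent").sum()), "of", sim.scores.n)
```

prints

```
retained classes and mixing weights:
  (0,-1,-1)  pi = 0.187  mu = [ 0.   -4.05 -4.08]
  (0,0,0)  pi = 0.306  mu = [0. 0. 0.]
  (1,0,0)  pi = 0.202  mu = [4. 0. 0.]
  (1,1,1)  pi = 0.305  mu = [4.02 4.   4.01]
consistent features: 1838 of 3000
```

The pipeline recovered exactly the four planted patterns with mixing
weights within ~0.015 of the truth and means within ~0.08.  The 1838
"consistent" features are those almost surely in a constant-label class —
the all-null and all-positive classes together carry weight 0.61, i.e.
about 1833 of 3000 features; every other feature is called differential.

The same run is available from the shell:

```sh
ternmix simulate --regime desk --seed 11 --out scores.tsv --truth-out truth.tsv
ternmix run --input scores.tsv --outdir demo_out --seed 11
ternmix test --draws demo_out/draws.npz --u 3 --b 0.5 --out calls.tsv
```

Per-step artifacts (pairwise battery, candidate sets before/after
pruning, `alpha`/`delta`, hyperparameters, posterior draws, class
summaries, consistency calls, run manifest) land in the output directory,
and `--resume` reuses whatever is already there.

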