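# ionclust

Bayesian clustering-based annotation of LC–MS peaks.

## The problem

An untargeted LC–MS metabolomics run yields hundreds to thousands of aligned
features, each a triple (m/z `x_n`, retention time `r_n`, intensity `w_n`).
Matching features to a compound database by mass alone is ambiguous: instrument
accuracy of a few ppm admits many candidate formulas per peak, and every
metabolite produces several peaks (its isotopologue series M, M+1, M+2, … for
each adduct form such as [M+H]⁺ or [M+Na]⁺). But those derivative peaks are
also the signal that resolves the ambiguity: the true compound's peaks
co-elute, their masses sit on one formula's isotope grid, and their intensity
ratios follow the natural isotope abundances.

`ionclust` turns this reasoning into a generative model. Peaks are clustered by
a Dirichlet-process mixture in which every cluster k is linked to one molecular
formula φ_k and each member peak to an (adduct a, isotope i) slot of that
formula. The likelihood factorises per peak:

- mass: `log x_n ~ N(log y_{φ a i}, ζ⁻¹)`, truncated to a ppm window;
- intensity: `w_n ~ N(β_{φ a i} λ_{ka}, κ⁻¹)` with a per-cluster, per-adduct
  scale `λ_{ka} ~ N(λ₀, κ₀⁻¹)` integrated out analytically;
- retention time: `r_n ~ N(l_k, γ⁻¹)` with the cluster elution time
  `l_k ~ N(μ₀, δ₀⁻¹)` integrated out.

A collapsed Gibbs sampler alternates over peak assignments (join an existing
cluster with probability ∝ c_k times its marginal likelihood, or open a new
one with probability ∝ α) and cluster formula links. Averaging the sampled
assignments gives, for every peak, the posterior probability of each
(formula, adduct, isotope) annotation, and for every formula, the probability
that it is present in the sample at support level l (at least l "good" peaks
backing it, where a peak is good only if the more-abundant isotopologues of
its assigned adduct series are also observed).

## Worked example

Simulate a two-compound mixture (glucose, phenylalanine) with two mass-matched
decoy formulas and two noise peaks, then annotate it:

```sh
ionclust simulate --db db.tsv --adducts adducts.tsv --out sim \
    --n-decoys 2 --noise-peaks 2 --seed 7
ionclust annotate --peaks sim/peaks.tsv --db sim/database.tsv \
    --adducts adducts.tsv --out results --iterations 1000 --burnin 200 --seed 42
```

`results/peak_annotations.tsv`:

```
peak_id  formula_id  adduct  isotope_index  prob_prior  prob_posterior  prob_filtered
P00000   glc         M+Na    0              0.497       1.0             1.0
P00000   decoy_0     M+Na    0              0.503       0.0             0.0
P00001   glc         M+Na    1              1.0         1.0             1.0
P00002   phe         M+H     0              0.970       0.909           0.909
P00002   decoy_1     M+H     0              0.030       0.091           0.091
P00003   phe         M+H     1              0.311       0.909           0.909
P00003   decoy_1     M+H     1              0.689       0.091           0.091
```

`prob_prior` is the mass-only probability: peak P00000 is a near coin-flip
between glucose and a decoy 0.7 ppm away, and P00003 even favours its decoy.
`prob_posterior` is the clustering posterior: because P00000 co-elutes with an
M+1 partner whose mass and intensity sit exactly on glucose's isotope grid,
the annotation flips to certainty, and phenylalanine's M+1 is pulled from 0.31
to 0.91. `prob_filtered` additionally zeroes samples in which a peak is an
orphan isotopologue (its more-abundant partners unobserved).

`results/formula_presence.tsv` gives per-compound presence probabilities at
support levels 1–5; scoring them against the known composition:

```
ionclust evaluate --presence results/formula_presence.tsv \
    --truth sim/truth.tsv --out roc.tsv
AUC=1.0000 TPR@FPR0.05=1.0000
```

The same machinery is available as a library (`ionclust.build_library`,
`ionclust.run`, `ionclust.summarize`, `ionclust.synthetic`,
`ionclust.evaluation`); `ionclust isotopes C6H12O6` prints aggregated isotope
patterns.

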