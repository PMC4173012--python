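# Methods

## Model

Each aligned LC–MS feature n is a triple d_n = (x_n, w_n, r_n): mass-to-charge
ratio, intensity (detector counts) and retention time (seconds). A library of
M candidate formulas and A adduct rules defines theoretical species: for
formula m and adduct a, isotope entries i = 0, 1, 2, … with ion m/z y_mai and
relative abundance β_mai (Σ_i β_mai = 1).

Peaks are clustered with a Dirichlet-process mixture. A configuration consists
of a partition of the peaks into K clusters, a formula link φ_k per cluster
(prior π_m, uniform 1/M by default), and a per-peak slot v_nkai selecting one
(adduct, isotope) of the cluster's formula (uniform prior over the A_m × I_ma
slots, applied as 1/A_m per adduct and 1/I_ma per isotope within the adduct).
The partition prior is the Chinese restaurant process with concentration α:
an existing cluster is joined with weight c_k (its current size), a new one
opened with weight α.

Given an assignment, the likelihood factorises into three Gaussian terms:

* **Mass** — log x_n ~ N(log y_φai, ζ⁻¹). Working on the log scale makes the
  noise proportional to the mass, matching ppm-specified instrument accuracy.
  ζ is derived from the user's ppm tolerance by treating it as a 3σ bound:
  σ_log = ppm·10⁻⁶/3, ζ = σ_log⁻². Candidates outside the full ppm window
  (|log x − log y| > ppm·10⁻⁶) have likelihood exactly zero, which keeps each
  peak's candidate set small and the sweep cost near-linear.
* **Intensity** — w_n ~ N(β_φai·λ_ka, κ⁻¹), where λ_ka is a latent intensity
  scale shared by all isotopes of one adduct in one cluster, with prior
  λ_ka ~ N(λ₀, κ₀⁻¹). λ_ka is conjugate and integrated out: with member sums
  S₂ = Σβ² and S₁ = Σβw, κ* = κ₀ + κS₂, λ* = (κ₀λ₀ + κS₁)/κ*, and the
  predictive for a new member is N(βλ*, κ⁻¹ + β²/κ*).
* **Retention time** — r_n ~ N(l_k, γ⁻¹) with l_k ~ N(μ₀, δ₀⁻¹); the
  conjugate update is δ* = δ₀ + γc_k, μ* = (δ₀μ₀ + γΣr)/δ*, predictive
  N(μ*, δ*⁻¹ + γ⁻¹).

Both conjugate forms are verified in the test suite against direct numerical
integration of prior × likelihood.

### Hyperparameters

| name | meaning | default | rationale |
|------|---------|---------|-----------|
| α | DP concentration | 1.0 | weak preference for few clusters; configurable |
| ppm | mass window (3σ) | 3 | orbitrap-class accuracy |
| λ₀ | intensity prior mean | data mean | set per run from observed intensities |
| κ₀ | intensity prior precision | 1e-14 | near-flat over detector range |
| κ | intensity observation precision | 1e-8 | noise s.d. 10⁴ counts |
| μ₀ | RT prior mean | data mean | set per run |
| δ₀ | RT prior precision | 1e-5 | near-flat (s.d. ≈ 316 s) |
| γ | RT observation precision | 0.25 | co-elution jitter s.d. 2 s |
| π_m | formula prior | 1/M | no compound favoured a priori |

γ = 0.25 presumes retention times in **seconds**; data recorded in minutes
must either be converted (`--rt-minutes`) or γ rescaled. All likelihood
arithmetic is in log space with log-sum-exp marginalisation — the κ₀ = 1e-14
scale underflows otherwise.

## Inference

A collapsed Gibbs sweep resamples every matchable peak once, in a random
order redrawn each sweep from the run seed. Removing a peak updates the
cached sufficient statistics (per-adduct Σβ², Σβw; cluster Σr, c_k) in O(1);
its new assignment is drawn as a single categorical over all in-window
(cluster, adduct, isotope) triples — weight c_k × mass × intensity ×
RT predictive — plus all (new cluster, formula, adduct, isotope) options —
weight α·π_m × prior predictives. This one-draw scheme is distributionally
identical to first picking the cluster and then the within-cluster slot, a
fact asserted in the tests.

After each sweep every cluster's formula link φ_k is re-drawn from its exact
conditional given the members' (adduct, isotope) slots:
P(φ_k = m) ∝ π_m · Π_n [slot weight × mass term under m] × intensity
marginals with m's β values (the RT marginal cancels). Without this move the
chain can freeze when a cluster coalesces on a near-isobaric twin of the true
formula: escaping requires dissolving the cluster through very improbable
singleton states, and annotation accuracy on decoy-spiked data degrades
markedly. The move is an ordinary Gibbs update of a model variable, so the
stationary distribution is unchanged — the suite verifies the combined kernel
against an exhaustive enumeration of the exact posterior (sum over all set
partitions × formula links × slot assignments, with joint multivariate-normal
cluster marginals computed independently via scipy) on a 4-peak instance,
agreeing to total variation < 0.003 at 50 000 retained sweeps.

Peaks that match no theoretical species in any formula's window cannot be
expressed by the model; they are held in permanent noise singletons outside
the sampler and reported with empty annotation maps. Two clusters may link to
the same formula simultaneously (isomers at distinct retention times).

Defaults: 1000 sweeps, 200 burn-in. The per-sweep log joint (CRP term +
formula priors + slot weights + mass terms + sequential-predictive RT and
intensity marginals) is written as a convergence trace.

## Outputs

For each peak, three probability variants over its candidate
(formula, adduct, isotope) annotations:

* **prior** — normalised truncated mass densities (mass-only evidence);
* **posterior** — fraction of retained sweeps carrying that assignment;
* **filtered** — as posterior, but counting only sweeps in which the peak's
  good flag g_n = 1. Within one adduct series of a cluster, a member is good
  iff every theoretical isotope with strictly higher β than its own is
  occupied by a member that is itself good; members of the highest-β index
  are always good. Ties in β impose no requirement. The comparison is made
  within an adduct series, not across adducts, because "more abundant than"
  is only well defined on one isotope ladder.

Formula presence at support level l is the fraction of sweeps with S_m ≥ l,
where S_m counts good peaks over all clusters linked to m. Presence is
non-increasing in l and the filtered variant never exceeds the posterior; both
invariants are tested. Summaries depend only on assignments, never cluster
labels, so they are invariant to label switching.

## Synthetic data

The generator draws data from the model's own structure, which is what makes
the recovery tests meaningful: per present formula one elution time uniform in
the RT range; per adduct (kept with probability 0.8) a log-normal intensity
scale around a mean of 5×10⁵ counts; one peak per isotope whose expected
intensity β·λ clears a detection floor of 5000 counts (the typical
pre-filter level), with 1 ppm log-normal mass noise, 2 s Gaussian RT jitter
and 10% multiplicative intensity noise; plus uniformly scattered noise peaks.

Decoy formulas — absent compounds mass-matched to the present ones — are
built by bounded enumeration of CHNOPS compositions whose monoisotopic mass
falls within 3 ppm of a present mass and whose composition differs (a loose
hydrogen bound H ≤ 2C+N+3 excludes absurd compositions). No database access
is needed; every accepted decoy's 3 ppm constraint is hard-asserted.

What the generator does **not** emulate: chromatographic peak shape,
correlated or heteroscedastic (beyond proportional-mass) noise, in-source
fragments, contaminant series, replicate misalignment, or additive intensity
noise matching the model's κ exactly (the generator's multiplicative 10% CV
deliberately mismatches the model's additive noise, as real data would).
Passing recovery tests therefore demonstrates correct inference under
realistic-but-idealised structure, not field performance.

## Evaluation

Peak-level scoring follows the present/absent support scheme: per peak,
p_n = summed support for known-present compounds, a_n = for known-absent
ones; at a threshold, p_n above → TP, a_n above → FP, p_n below → FN, a_n
below → TN. Zero values are discarded, except in multi-algorithm comparisons
where a value is kept if any algorithm scores it, making TP+FP+TN+FN equal
across algorithms. "Above" means ≥ t for t > 0 and > 0 at t = 0 (so the zero
threshold closes the useful 0 < t ≤ 1 range); a `strict` flag exposes both
conventions, since tie handling at a threshold is a genuine convention
choice. List-style outputs of other tools get the uniform 1/|A| support per
annotated candidate. Formula-level calls are scored as TPR/FPR curves over
presence scores; the operating point TPR at 5% FPR is linearly interpolated.

## Problem sizes and numerics

The shipped studies run at desk scale: five mixtures of 20 compounds + 80
decoys (~100 peaks each, ~1000 theoretical species) at 1000 sweeps, a few
seconds per mixture; the enumeration cross-check uses 4 peaks × 2 formulas ×
2 adducts × 2 isotopes. Isotope fine structure is aggregated by nominal mass
shift (abundance-weighted mean masses), with a 1e-12 pruning floor during
convolution and a default 1e-4 relative-abundance cutoff; dimer adducts (nM)
convolve the multiplied formula rather than scaling the monomer pattern.
Adduct gain/loss atoms contribute their monoisotopic mass only (their own
isotope distributions are ignored — negligible for H/Na/K gains, a known
approximation for Cl/Br adducts).

## Known limitations

* Confident errors on sub-ppm decoys are possible and expected: when a decoy
  sits within the mass noise of a true compound and a particular noise
  realisation makes its isotope ratios fit better, the posterior honestly
  (and wrongly) prefers it. Consequently, strict monotonicity of empirical
  truth frequency across five equal posterior-probability bins can fail on
  small studies — the mid bins hold only a handful of genuinely ambiguous
  annotations, and the top bin carries the rare decoy captures. Coarse
  calibration (low-probability annotations almost never true, high-probability
  ones almost always true) holds throughout.
* The model has no explicit noise component; unmatchable peaks are excluded
  rather than modelled, and matchable noise peaks must be absorbed as
  (usually bad-flagged) singletons.
* One intensity scale per (cluster, adduct) assumes isotope intensities scale
  exactly with β; detector saturation or resolution-dependent effects are not
  modelled.
* Replicates are consolidated to one consensus peak list (mean m/z, RT,
  intensity per aligned id) before inference; no hierarchical per-replicate
  model.
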