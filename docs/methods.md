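# Methods

This note documents the models implemented in `csiaa`, the defaults and
why, the numerical choices, and what the synthetic-data tests do and do
not demonstrate about real data.

## Trophic position estimators

Both estimators are the standard linear inversion of per-step ¹⁵N
enrichment:

    TP = (δ¹⁵N_trophic − δ¹⁵N_source − β) / TDF + 1

with the Glu/Phe pair (β = 3.4‰, TDF = 7.6‰) for metazoan-dominated
chains and the Ala/Phe pair (β = 3.2‰, TDF = 4.5‰) for
protozoan-dominated chains. β is the producer-level offset between the
trophic and the source amino acid, so TP = 1 identifies a primary
producer; the TDF is the per-step enrichment of the trophic amino acid.
Printed renderings of these formulas sometimes lose the division bar; the
implementation keeps the division, which is both the form of the original
estimator literature and the only reading that reproduces the worked
value (26.3 − 16.2 − 3.4)/7.6 + 1 = 1.88 ≈ 1.9. Constants are carried in
a `TrophicConstants` object and can be overridden wholesale.

No uncertainty propagation from per-amino-acid measurement SDs into TP is
attempted: studies in this domain report plain means ± SD across samples,
and the measurement SD is stored alongside the values for anyone who
wants to do better.

## ΣV resynthesis index

ΣV is the mean absolute deviation of the available trophic-amino-acid
δ¹⁵N values (Ala, Val, Leu, Ile, Pro, Asp, Glu) from their arithmetic
mean. Conventional interpretation: < 1 non-degraded, 1–2 metazoan
resynthesis, > 2 microbial resynthesis. Two conventions are not fixed by
the literature wording and are therefore declared here:

* the 1–2 band is a closed interval (1.0 and 2.0 both read "metazoan");
* partial panels are accepted down to `min_aa = 3` of the seven amino
  acids (the count used is reported next to the value); fewer is an
  undefined result, never silently zero.

ΣV is translation-invariant and scales linearly with a positive rescaling
of the δ values; both properties are tested.

## THAA averages, Phe-normalization, ε_x/Glu

THAA δ¹⁵N/δ¹³C is the mol%-weighted mean over amino acids that carry both
an isotope value and a mol%; weights renormalize over that intersection so
partial panels behave sensibly and exact-100% panels are unchanged.
Phe-normalized values are δ¹⁵N_x − δ¹⁵N_Phe. The apparent fractionation
relative to glutamic acid is implemented as the simple difference
ε_x/Glu = δ¹⁵N_x − δ¹⁵N_Glu: the concept is used in the literature
without a printed formula, and the simple difference reproduces the
magnitudes (≈ −11.6‰ for Gly, −11.7‰ for Ser against Glu ≈ 23‰) that
accompany it. The sign convention (negative = depleted relative to Glu)
is therefore a documented package choice.

## Hydro-chemistry

* **N\*** = (NO₃⁻ + NO₂⁻ + NH₄⁺) − 16·PO₄³⁻ + 2.9, in µmol/kg.
  Classification: < −3 denitrification, > 2 nitrogen fixation; the gap —
  including both boundary values — is labelled intermediate, since only
  the two open-ended bands are defined in the source literature.
* **Oxygen saturation** uses the Weiss (1970) solubility fit evaluated in
  mL/L and converted with 1 mL O₂ = 44.659 µmol (ideal molar volume
  22.392 L/mol), giving µmol/L to match sensor units. AOU is saturation
  minus measured O₂ and may be negative (supersaturation).
* **Inventories** integrate O₂ (µM = mmol/m³) trapezoidally over the
  measured depth span only — no extrapolation above the shallowest or
  below the deepest record, a conservative choice that matters for casts
  starting at 5 m.
* **Buoyancy frequency** uses the EOS-80 1-atm density polynomial (casts
  here are ≤ 45 m, so pressure effects are negligible and the vintage
  matches the profile software of the era), finite differences on layer
  midpoints with no smoothing, unstable layers clamped to 0, and
  conversion N/(2π)·3600 to cycles/h. Profile-software outputs with
  unknown smoothing cannot be bit-matched and are not a target; the
  implementation is instead validated against the closed form
  N² = g·Δρ/(ρ̄·Δz) (17.7 cycles/h for Δρ = 1 kg/m³ over 10 m).

## Bayesian mixing model

Observation model, per tracer t:

    x_t ~ Normal( Σ_k p_k μ_kt ,  Σ_k p_k² σ_kt² )

— the process-error formulation in which the mixture variance is the
p²-weighted sum of end-member variances. Tracers are conditionally
independent (diagonal covariance): a documented simplification, adequate
for the 1–2 tracers (Phe-normalized Ala and Thr) this package typically
feeds it. An optional per-tracer multiplicative residual scale
(`error_structure="process_plus_residual"`) inflates the process SD. No
trophic-discrimination offset is added to end-members by default; the
end-member tables are assumed to characterize the source classes as
consumed.

Prior: Dirichlet(α), default α = 1. Sampler: random-walk Metropolis on
additive-log-ratio coordinates (the p-dependent variance breaks the
conjugacy a Gibbs sampler would need), with step-size adaptation every 50
burn-in iterations targeting 20–40% acceptance. In ALR coordinates the
Dirichlet prior and the transform Jacobian combine to Σ αₖ log pₖ.
Defaults are 3 chains × 30,000 iterations, 10,000 burn-in, thinning 10; a
seed is mandatory and chains draw independent streams from it.
Convergence is summarised by split-R̂ and bulk ESS (via arviz); R̂ > 1.1
flags the source as non-converged in the results rather than raising,
with ESS ≥ 400 the working target.

Two degeneracies worth knowing about. First, with sources of identical
means the posterior mean falls back to the prior mean by symmetry, but
the likelihood is *not* flat in p: the p²-weighted variance still varies
along the simplex, so the posterior concentrates where the implied
variance matches the data spread. Second, with more sources than
tracers + 1 the model is unidentifiable along a ridge and chains mix
poorly; diagnostics flag this honestly, and tests use identifiable
configurations.

Validation: an independent quadrature oracle for the likelihood, exact
Dirichlet-moment recovery in prior-only runs, label-permutation
equivariance, truth recovery at 10σ separation, and simulation-based
calibration (uniformity of the truth's posterior rank over 200 synthetic
datasets).

## ANOSIM and rank tests

ANOSIM ranks all n(n−1)/2 pairwise Euclidean distances with mid-ranks and
computes R = (r̄_between − r̄_within)/(n(n−1)/4), which lies in [−1, 1];
negative values are reported as-is. The p-value is the add-one Monte-Carlo
estimator (1 + #{R* ≥ R})/(1 + B), so p = 0 is impossible and
p ≥ 1/(B + 1) always. Permutations are seeded; a battery of tests fans
sub-seeds out from one top-level seed via spawn keys, so adding a test
never perturbs the others. The univariate tests delegate to scipy with an
explicit policy: Mann-Whitney exact for combined n ≤ 20 without ties,
Wilcoxon exact for n ≤ 15 without tied magnitudes (zeros dropped;
all-zero input is undefined), tie-corrected normal approximations
otherwise; Spearman is Pearson on mid-ranks with the t-approximation.

## Synthetic-data generators

The generators define the conditions under which the estimators are
exercised; their defaults are fixed once and shared by tests and
examples.

* **Trophic chain**: δ¹⁵N_aa = baseline_aa + TDF_aa·(TP − 1) + N(0, σ).
  The producer baseline anchors Glu at Phe + 3.4‰ and Ala at Phe + 3.2‰
  (so TP = 1 is exactly self-consistent with the estimators) and the
  remaining trophic amino acids at Phe + 3.3‰. Per-step TDFs default to
  7.6 (Glu), 4.5 (Ala), 5.0 (Val, Leu, Ile, Pro, Asp — these only affect
  ΣV-style dispersion, not TP recovery), 0 for source amino acids and
  Gly, −2 for Thr, which depletes with transfer. Measurement noise
  defaults to σ = 0.5‰, a declared choice consistent with instrument
  reproducibility typically quoted as "better than 1‰". Default baseline
  δ¹⁵N-Phe is 15‰, in the range observed for upwelling-bay POM.
* **Degradation scenario**: each of the seven trophic amino acids is
  shifted by ±s_deg with independent random signs — a fixed-magnitude,
  random-direction model of the characteristic per-amino-acid offsets
  heterotrophic reworking imprints (its offset SD equals s_deg). At the
  default s_deg = 3‰ most draws exceed ΣV = 2 (the microbial band);
  smooth Gaussian offsets of the same SD would scatter a substantial
  minority of draws below 2, which is why the scenario is defined by
  magnitude rather than by a Gaussian.
* **Mixtures** draw tracers from the exact process-error model, so mixing
  fits are tested against their own forward model.
* **Profiles** use logistic temperature/oxygen/salinity/pH transitions
  centred near 18–20 m over default depths (5, 20, 35, 45 m), with
  nutrients increasing downward; defaults keep all values inside
  13–21 °C and 11–370 µM O₂.

What passing these tests shows: the estimators invert their own forward
models without bias, the sampler is calibrated, and the statistics attain
their nominal error rates. What they do not show: robustness to real-data
features the generators omit — per-amino-acid baseline variability
between producer communities, correlated measurement error across amino
acids from shared chromatography, non-Gaussian degradation patterns,
tracer covariance between end-members, and advective structure in
profiles.

## Reporting conventions

Internal arithmetic is full precision; bay-level report tables round to 1
decimal at output time. Sample SD uses n − 1 (reported as 0 for a single
sample). POC downward flux is a pass-through input column (mg/m²/day):
deriving it from trap mass would require trap geometry that is not part
of this package's inputs. Published bay-level field values (e.g. a
bay-mean ΣV or THAA δ¹⁵N) depend on raw per-sample tables that are not
redistributable, so the test suite validates the machinery on synthetic
truth plus the printed worked values rather than attempting to reproduce
field tables.

The acceptance script and the test suite size their simulations (e.g.
100 mixing replicates with 2 × 3000-iteration chains, 1000 ANOSIM null
simulations × 999 permutations) to finish in minutes on one CPU while
keeping Monte-Carlo error well inside the asserted tolerances; these
problem sizes are package choices and are stated in the tests that use
them.
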