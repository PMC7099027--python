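# Methods

## Isotope bookkeeping

All δ¹³C values are ‰ relative to the PDB standard (¹³C/¹²C ratio
0.0112372). The conversion chain is δ → ratio R = R_std·(1 + δ/1000) →
¹³C atom fraction x = R/(1+R) → ¹³C mass M₁₃ = M_c·x. The round trip
δ → x → δ is exact to better than 1e-9 ‰ over δ ∈ [−100, 1000] (tested).
δ values at or below −1000 ‰ are rejected (the implied ratio would be
non-positive).

**Two end-member mixing.** The straw contribution to a pool's carbon,
F_m = (δ_sm − δ_s)/(δ_m − δ_s) × 100, is evaluated in δ space, with the
control soil at the *matched sampling day* (not day 0) as the unamended
end member. Mixing is exactly linear in atom-fraction space, not in δ
space; at the straw enrichment used here (+357 ‰ vs −27.78 ‰) the two
spaces differ by under 0.5 % relative (≤1.5 % up to +400 ‰, tested on a
grid). `source_contribution(..., space="atom")` gives the exact variant.

**Allocation fraction conventions.** Because the amended pool holds the
control's native C *plus* straw C, two numerator/denominator pairings are
self-consistent and, on noise-free data, both return exactly
(straw-derived pool C)/(straw C added):

* `excess` (default): c_am·(x_am − x_ctrl) over the excess ¹³C added above
  the soil baseline, straw C·(x_straw − x_soil);
* `gross`: the pool's ¹³C-mass increase over the control,
  c_am·x_am − c_ctrl·x_ctrl, over the gross straw ¹³C, straw C·x_straw.

Mixing the mass-difference numerator with the excess denominator — a
tempting but inconsistent combination — overstates allocation by
x_straw/(x_straw − x_soil) ≈ 3.6 at this enrichment; the package therefore
pairs each denominator with its like numerator.

**Derived pools.** MBC is the fumigation flush divided by k_EC (default
0.45, configurable; F_m of MBC is independent of k_EC because it cancels in
the δ of the flush, while the MBC allocation fraction does scale with it).
MaOC is SOC − POC; its δ¹³C (like the flush's) comes from ¹³C mass balance
(`delta_of_difference`), which conserves ¹³C to 1e-9 relative under
re-mixing (tested). The soil's initial MaOC is taken as 4.10 g kg⁻¹
(= SOC 6.66 − POC 2.56) so that SOC = POC + MaOC holds exactly in the
simulator; reported initial values round this to 4.08.

**Flags, not clips.** Allocation fractions and F_m outside [0, 100] % are
genuine consequences of measurement noise near zero-enrichment pools; they
are returned as-is with a warning flag and surface in the `flags` column of
the output tables. Replicates are aggregated as mean ± sd (n per cell);
missing design cells abort with an explicit list of
(treatment, replicate, day, pool) keys — no imputation.

## Community linkage statistics

Counts are column-normalised to relative abundances; zero-sum samples are
dropped with a log entry. Bray-Curtis dissimilarity
1 − 2·Σmin(x,y)/Σ(x+y) is used for both the community matrix and the
straw-derived-fraction matrix (per-sample vectors of the four pools'
allocation values; negative values are shifted to zero with a warning, or
Euclidean distance can be selected). The Mantel test correlates the
n(n−1)/2 upper-triangle entries (Spearman by default, average ranks,
Pearson optional), builds the null by jointly permuting rows and columns of
the second matrix, and reports the one-sided add-one p-value
(1 + #{r* ≥ r})/(1 + n_perm) with ties counted as ≥; default n_perm = 999.
Its empirical type-I error at α = 0.05 is calibrated within the binomial
confidence band over 500 null simulations (tested). The genus × fraction
Spearman table uses average ranks, the t-approximation for raw p-values and
the conventional stars (* < 0.05, ** < 0.01, *** < 0.001); no
multiple-testing correction by default, with an optional Benjamini-Hochberg
column. Linkage is computed within the amended arm; the control arm is
analysed separately. Pooling replicates to day means before the distance
step is a config switch (`link.pool_replicates`), not a default, since the
appropriate pooling is a genuine analysis choice.

## Forward simulator

The simulator emulates a 180-day microcosm incubation: 2 treatments ×
sampling days (7, 14, 28, 60, 180) × 3 replicates, with initial pools
DOC 26.64, MBC 357.26 mg kg⁻¹, POC 2.56, MaOC 4.10 g kg⁻¹ (SOC 6.66),
soil δ¹³C −27.78 ‰, and 30 g kg⁻¹ of enriched wheat straw (352.9 g C,
6.38 g N per kg straw, δ¹³C +357.48 ‰).

Native and straw-derived C are tracked separately per pool; with isotopic
fractionation neglected each component keeps its source atom fraction, so
pool δ values are exact atom-fraction mixtures and both C and ¹³C are
conserved identically before noise (CO₂ loss is the residual sink).
Straw decays as a two-component first-order pool (labile fraction 0.75 at
0.35 day⁻¹, recalcitrant at 0.004 day⁻¹) — the standard double-exponential
litter form, needed because a single rate fast enough for ~50 % conversion
by day 7 would exhaust the straw long before the late POC accumulation.
The decomposition flux is routed to {DOC, MBC, POC, MaOC, CO₂} by
time-varying fractions (linear between knots at days 0, 7, 14, 28, 60,
180; validated to sum to 1), with first-order transfers: DOC sorption to
MaOC (0.02 day⁻¹), DOC mineralisation (0.05), microbial turnover (0.19, of
which 30 % stabilises as MaOC), slow POC turnover (0.0008) and MaOC
desorption/mineralisation (0.055). Defaults were chosen once to give the
qualitative trajectory of the emulated study — roughly half of straw C in
soil pools at day 7 falling to roughly a fifth by day 180, a non-monotone
MaOC pulse (rise to ~29 % of straw C, sharp fall after day 14), an early
MBC peak, and monotone POC accumulation. They do not reproduce every
printed number (in particular the late slight MaOC rise and a flat
late-time MBC plateau would require substrate recycling the model omits);
parameters are configuration, not claims.

Measurement noise is additive Gaussian on δ (sd 0.3 ‰, typical EA-IRMS
replicate precision at enrichment) and multiplicative Gaussian on C
contents (relative sd 0.05, typical fractionation-assay variability),
independent per record. Native pools are held at their initial values in
both arms (quasi-steady state), so matched-day control subtraction isolates
straw-derived C exactly in the noise-free limit. Real incubations violate
this (e.g. incubation itself raises control DOC severalfold), so simulated
F_m values for small pools are higher than field-realistic ones; passing
recovery tests demonstrates correctness of the mass-balance algebra, not
realism of any particular trajectory.

The community generator draws 40 genera with lognormal baselines; 12 are
coupled (3 per pool, alternating sign) with expected log relative abundance
baseline + 2.0 × the standardised straw-derived C of their pool at the
sample's day (amended arm only). Counts are negative-binomial
(gamma-Poisson, dispersion 0.3) at library size 20 000 — overdispersion
matching real genus tables in kind, not fitted to any dataset. No
sequence-level simulation is attempted.

All randomness derives from one root seed through named SeedSequence
streams (pools 101, taxa 202, community 303, Mantel 404), so every output
is byte-reproducible and stages are independently reproducible.

## Numerical choices

The forward model is integrated with LSODA at rtol = atol = 1e-10; CO₂ as
residual makes conservation exact regardless of integrator error. Ranks
use average tie-handling everywhere. The Mantel permutation loop ranks the
condensed distance vector once and permutes the square rank matrix (joint
row/column permutation only rearranges the condensed entries, so ranks,
means and variances are permutation-invariant), making the test exact and
fast. Degenerate inputs fail loudly: coincident end members, non-positive
ratios, fumigated < non-fumigated extracts, POC > SOC, all-zero abundance
vectors, constant distance matrices, label mismatches.

## Problem sizes

Tests and the acceptance script use the study's own design (150 pool
records, 30 community samples) throughout; calibration studies use 500
null simulations at 199 permutations for the type-I error, 50 seeded noisy
datasets for unbiasedness, and 25 seeded runs for the coupled-vs-uncoupled
contrast — sizes at which the Monte-Carlo error is small against the
tolerances being checked.

## Known limitations

Constant native pools (no priming, no native-C dynamics); no isotopic
fractionation; no CO₂ flux measurements to close the budget empirically;
no error propagation beyond replicate spread; no fitting of the simulator
to data; community coupling is log-linear and static in sign. BIOM support
covers the JSON (1.0) flavour only.
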