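# Methods

## The gating model

The allosteric model treats the hemichannel's slow gate as a chain of
one open state O and three closed tiers C1, C2, C3. Three ingredients
carry the physics:

1. **Fast first closure.** O ↔ C1 is a voltage-dependent equilibrium
   L1(V) = [C1]/[O] = exp(−z₁(V−V₁)/v_T), with v_T = RT/F (25.42 mV at
   the default 295 K). Its kinetics are assumed far faster than the
   deeper transitions (sub-5-ms, below the resolution of a
   two-electrode clamp), which is what prevents the Ca²⁺ inhibition
   curves from saturating at depolarized potentials.
2. **Two slow voltage-dependent steps.** C1 → C2 and C2 → C3 close
   with rates A₀exp(−z_a V/v_T) and C₀exp(−z_c V/v_T); the openings
   carry B₀exp(+z_b V/v_T) and D₀exp(+z_d V/v_T). Prefactors are the
   rates at 0 mV. The assignment — A₀/z_a and C₀/z_c to closing,
   B₀/z_b and D₀/z_d to opening — is the one consistent with the
   deactivation rates being far more voltage dependent (z_d ≈ 2.0)
   than the activation rates (z_a ≈ 0, z_c ≈ 0.18). Two slow steps
   produce exactly two observable relaxation components, matching the
   bi-exponential current relaxations.
3. **Closed-state Ca²⁺ binding, allosterically coupled.** m identical,
   independent sites (m = 6 for the hexamer-preferred model) bind Ca²⁺
   only in the closed tiers, with per-site dissociation constant K_d
   in C1. Each bound ion multiplies closing rates by c_b and opening
   rates by c_f. Detailed balance then forces the tier affinities to
   scale as K_a, C·K_a, C²·K_a with C = c_b/c_f: since C > 1, each
   deeper closed state binds Ca²⁺ more tightly, and conversely bound
   Ca²⁺ stabilizes the deeper closed states. c_f multiplies opening
   and c_b closing rates — the only assignment under which Ca²⁺ slows
   activation (c_f < 1) and accelerates deactivation (c_b > 1) while
   C = 1.28 > 1 stabilizes closure.

Binding and the O ↔ C1 step are treated as rapid equilibria
(diffusion-limited binding; default per-site on-rate 10⁴ mM⁻¹s⁻¹).
Two representations implement this and cross-check each other:

* the **microscopic generator** over all 1 + 3(m+1) states, with
  binomial binding multiplicities (m−n)·k_on·Ca and (n+1)·k_off, and
  the fast edge realized with finite rates ≥100× the largest slow
  rate. It obeys row-sum-zero and detailed balance on every edge and
  cycle, and its null space gives the stationary distribution.
* the **rapid-equilibrium reduction**: the closed-form partition-sum
  open probability and a 3-aggregate chain {O∪C1}, {C2}, {C3} with
  occupancy-weighted effective rates (binomial sums collapse to
  (1 + c_b x)^m-type factors). The reduction is exact for equilibria
  and agrees with the two slowest eigenvalues of the full generator
  to well under 2% at the default on-rate, improving as k_on → ∞.

Pulse responses propagate the full generator segment-by-segment with
the exact matrix exponential. A deliberate consequence of the model,
relevant to experiment design: at saturating Ca²⁺ the slow gating
modes lose almost all their amplitude in the open probability (the
relaxation is dominated by the fast O ↔ C1 re-equilibration), so
trace-based tau extraction is only meaningful below roughly 1 mM Ca²⁺;
the eigen-spectrum route covers the full range.

## Equilibrium analyses

Boltzmann (G–V) and Hill (inhibition) fits are weighted nonlinear
least squares (weights 1/sem² when provided), multi-started over
gating-charge or slope initializations, with asymptotic standard
errors; Hill fits operate on log₁₀Ca. Hill slopes are reported as
magnitudes. The linear closed-state-stabilization schemes (Hill,
two-site, three-site sequential) are fitted globally across test
voltages with the Boltzmann parameters shared and fixed; singular
designs are flagged per parameter (standard error ≥ |estimate|) rather
than raised, which reproduces the expected pathology of the
over-parameterized three-site scheme on Hill-like data.

The IC50–voltage relation is implemented with exponent
**+zδ(V−V_1/2)**. With the opposite sign (which appears in some
printed forms of the relation) the stated limiting behavior inverts —
saturation would occur at depolarized rather than hyperpolarized
potentials; the positive sign is the one that reproduces the measured
log IC50 values at −30 and +10 mV and the 3/8/5 µM closed-state K_D
estimates, and we treat the negative form as a typographical slip.
K_D follows the Hill convention and formally carries units of mMⁿ;
numbers are quoted directly in mM-based units (µM in reports), the
field's usual shorthand.

## Relaxation kinetics

One- and two-exponential fits use exponential peeling for
initialization (tail log-linear fit for the slow component, residual
refit for the fast one), multi-start over fast/slow tau ratios, and
box bounds tying time constants to the observable window — without
the bounds, noise drift supports runaway slow components. Fits exclude
the first 5 ms after a step (voltage-electrode settling). Model order
is chosen by an extra-sum-of-squares F-test at α = 0.05 (the
literature rarely states its test; this is the standard choice), whose
type-I error calibrates to ≤7% at the nominal 5% in simulation. Tau
errors come from the asymptotic covariance; no bootstrap.

## Bayesian global fit

The likelihood is independent Gaussian per observable — normalized
G–V points, inhibition ratios, and both time constants of each tau
table — with per-point SDs taken from the dataset. The 13 continuous
parameters are sampled by random-walk Metropolis: positive parameters
on a log scale, charges and V₁ untransformed. Priors are proper and
deliberately broad: log-uniform on A₀…D₀ ∈ [10⁻³,10³] s⁻¹,
K_d ∈ [10⁻³,10²] mM, c_b, c_f ∈ [0.1,10]; uniform on charges [0,4] e₀
and V₁ ∈ [−300,+100] mV. During the first half of each chain
(burn-in) a global step factor tracks 20–30% acceptance and the full
proposal covariance is re-estimated from the recent history (scaled
2.38/√d); both are then frozen, so the kept half is Markov. Three
chains from different starts feed the classic Gelman–Rubin potential
scale reduction (pass iff all < 1.1). Summaries report the
maximum-a-posteriori sample as the most-likely value, marginal
2.5/97.5% quantiles (not HPD) as the 95% credible interval, posterior
SDs and Pearson correlations.

A property of this posterior worth knowing: at the synthetic-data
noise levels used here (2% SD on relative currents, 10% log-normal on
taus) the posterior has a soft, curved ridge — z₁ trades off against
V₁, A₀ against z_a, and K_d against c_f — so marginal intervals are
wide and the K_d marginal is skewed upward of the generating value for
typical noise realizations. This is a genuine feature of the model's
information geometry at that data quality, not a sampler artifact:
with 10× smaller noise the posterior collapses tightly onto the
generating parameters. Recovery tests of the machinery are therefore
run at informative noise, and inferences at realistic noise should
lean on the joint posterior, not single marginals.

Model evidence for m ∈ {2, 3, 6} uses a stepping-stone estimator over
a power-posterior ladder β_k = (k/K)⁴ (K = 24 by default; chosen over
harmonic-mean estimators for stability). Because the likelihood
surface is rugged, each model's posterior mode is located first —
multi-start Powell over prior draws plus the library's published
reference estimates applied identically to every candidate m, then a
short Metropolis polish — and the rung chains run from β = 1
downward, each relaxing into a broader distribution (the numerically
easy direction). The β = 0 rung is sampled i.i.d. from the prior. The
reported evidence is the mean over three independent ladders and its
SE the between-ladder standard error; the naive within-ladder SE
grossly understates the real error, which is dominated by incomplete
rung equilibration. Odds ratios assume equal model priors.

## Synthetic data

Generators draw every dataset class from the model under the standard
protocols: G–V from +20 to −60 mV in 10 mV steps; inhibition at test
voltages {+20, +10, 0, −20, −30, −50} mV over a log-spaced
10⁻³–10 mM Ca²⁺ grid; tau–voltage over −100…+20 mV at nominal
(zero-divalent) Ca²⁺ and tau–Ca²⁺ at −100 mV; paired ±Ca²⁺ swelling
area series at 1 Hz for 900 s. Noise defaults: Gaussian SD 0.02 on
relative currents (G–V values clipped to [0, 1.05]; inhibition values
deliberately not clipped at zero, since truncation would bias the
apparent IC50 upward), log-normal σ = 0.1 on time constants (with
per-point SDs computed from the noiseless values, so likelihood
weights are undistorted), additive Gaussian 1% of amplitude on traces,
and 0.05% of initial area on swelling series — the last calibrated so
a single oocyte's last-50-s rate estimate is precise relative to the
±Ca²⁺ group difference, making a four-oocyte comparison decisive, as
in the experiments being emulated. The swelling rates default to
volume gains of ~8% (Ca²⁺-free) and ~3% (5 mM Ca²⁺) at 900 s.
Everything regenerates bit-for-bit from a seed.

What the generators do not emulate: endogenous (Cx38) currents, leak
and series-resistance artifacts, capacitive transients, Mg²⁺
competition (the nominal-Ca condition is treated as zero divalent),
replicate-averaging across oocytes, and any drift or correlated noise.
Tests passing on this synthetic data therefore demonstrate the
correctness and calibration of the algorithms under the model's own
assumptions, not robustness to those real-data features.

## Osmotic swelling

Volume follows from focal-plane area under spherical symmetry
(r = √(A/π), V = 4/3 πr³), expressed relative to the first frame; the
swelling rate is the least-squares slope of V/V_i over the final 50 s,
and groups of per-oocyte rates are compared with a two-sample t-test
at α = 0.05 (n = 4 by default, configurable). Rates are computed on
relative volume, so units cancel in the group comparison.

## Numerical choices and edge cases

* Stationary distributions come from the SVD null space of Qᵀ; a
  multi-dimensional null space (disconnected chain) raises rather than
  returning an arbitrary vector.
* The fast O ↔ C1 edge is scaled by max(1, 1/L1) so both directions
  stay ≥100× the slow rates at any voltage.
* IC50 root-finding brackets log₁₀Ca ∈ [−6, 3] and raises a no-root
  error when the relative current never crosses one half.
* Degenerate curve fits (flat G–V, rising "inhibition", merged or
  vanishing exponential components) raise or flag rather than return
  plausible-looking numbers.
* Problem sizes in the test suite — chain lengths of a few thousand
  steps, two-ladder evidence runs, ~200-replicate calibrations — are
  the package's reduced defaults for routine verification; production
  analyses should scale them up (the examples note where).

## Known limitations

* The three-aggregate reduction assumes binding and first-closure
  kinetics are infinitely fast; its ~1% tau error at the default
  on-rate is inside the fitting error budget but grows if binding is
  slowed toward the gating rates.
* Evidence estimates inherit annealing noise of a few log-units even
  with replicate ladders; odds ratios below ~e² should not be
  over-interpreted.
* Conductance is modeled as proportional to open probability; no
  permeation, rectification or single-channel structure.
* The apparent Hill slope of the six-site model varies mildly with
  voltage (≈1.4 at −50 mV to ≈2.4 at +20 mV over the experimental
  concentration window); measured slopes near 2 at all voltages are
  reproduced only approximately, consistent with the global fit
  matching inhibition data "reasonably well" rather than exactly.
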