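# Methods

`smfspipe` analyses constant-speed AFM force-extension traces of a
receptor–ligand complex (cohesin:dockerin, "Coh:Doc") pulled through a
fingerprint domain, and ships a synthetic generator that emulates the
experiment so every stage can be validated against known ground truth.
This note records the models, the parameter choices and what they do and
do not capture.

## Polymer model and contour-length transformation

Tether elasticity uses the Marko–Siggia interpolation of the worm-like
chain,

    F(x) = (kBT/p) [ 1/(4 (1 − x/Lc)²) − 1/4 + x/Lc ],

with a fixed persistence length p = 0.4 nm for the polypeptide and an
energy scale kBT = 4.114 pN·nm (room temperature; the thermal
spring-constant calibration uses exact kB·T for the temperature given).
The contour-length transformation inverts this relation pointwise: since
the relative extension u = x/Lc depends only on force, each
(force, extension) sample with F > 0 maps to Lc = x / u(F).  u(F) is
obtained by bisection on the monotone interpolation formula (80
iterations, machine-precision; the round-trip identity holds to < 1e-12
relative error).  Points at or below zero force are excluded — the WLC is
not invertible there.

Two robustness measures stabilise barrier finding on noisy data:

* **Precision weighting.**  Near the force cutoff the transform Jacobian
  dLc/dF is enormous, so force noise scatters low-force points over tens
  of nm of contour length and the scatter can lump into spurious density
  maxima.  Each point's contribution to the contour-length KDE is
  therefore weighted by (dF/dLc)², its inverse contour-length variance up
  to the constant force-noise factor.  Noise-free barrier positions are
  unchanged by the weighting.
* **Contact-region exclusion.**  Points with extension below 5 nm are
  dropped: a noise spike there inverts to a spuriously precise, tiny Lc.

Barrier positions are the local maxima of a fixed-bandwidth (1 nm)
Gaussian KDE over the retained contour values, on a 0.2 nm grid; maxima
with prominence below 2% of the global maximum are treated as noise.  All
thresholds (cutoff 10 pN, bandwidths, prominence, grid) are config
fields.

## Rupture kinetics

Barrier crossings follow the Bell–Evans model at a constant nominal
loading rate r = v·k_eff: the rupture-force density is

    p(F) = (k0/r) exp(βF) exp(−a (exp(βF) − 1)),  β = Δx/kBT,
    a = k0·kBT/(r·Δx),

with analytic mode F* = (kBT/Δx) ln(rΔx/(k0·kBT)) and closed-form
inverse CDF (used for exact sampling).  The effective stiffness defaults
to 15 pN/nm; the force-dependent stiffness of a real WLC tether is not
modelled in the analytic sampler.  All barriers use Δx = 0.4 nm, giving a
rupture-force scale kBT/Δx ≈ 10.3 pN (distribution sd ≈ 13 pN).
Measured rupture-force distribution widths are not published for this
system, so the widths here are a modelling choice exposed through the
barrier parameters.

## Synthetic experiment

A trace is generated by a threshold-order model: one rupture force is
drawn per intact barrier (fingerprint domain; optional extra domains; the
complex's sub-step barrier when the latent binding mode is A; the
mode-appropriate final barrier), the piezo ramps at fixed speed, the
noise-free force follows the lever/WLC force balance at the current total
contour length, and whichever outstanding threshold is reached first
fires.  Unfolding adds the domain's contour gain (the force relaxes onto
the new WLC branch); the final rupture truncates the trace to baseline.
Gaussian force noise (default sd 5 pN) is added last.  The binding mode
is latent and fixed before loading, as in the experiment.

Consequences built into the model:

* **Censoring.**  If the fingerprint threshold exceeds the final-rupture
  threshold the trace never shows the fingerprint increment and is
  rejected downstream — the natural selection effect that undercounts the
  mechanically weaker event class.
* **Apparent singles.**  A mode-A complex whose final threshold falls at
  or below its sub-step threshold passes both barriers together and
  presents as a single event.  The pipeline therefore recovers the
  apparent-class (double/single) ratio, not the latent mode ratio.
* **Early doubles.**  If the sub-step threshold is below the fingerprint
  threshold, the ~8 nm increment precedes the fingerprint increment.
  Such curves cannot be counted as doubles by the final-increment rule
  and are excluded (`early_double` rejection) rather than miscounted as
  singles.

Default calibration (all at 800 nm/s): mode-B (single) final barrier
F* = 104 pN; mode-A final 140 pN; sub-step 120 pN (final ≈ 15% above the
first peak of a double); xylanase fingerprint 108.3 pN, placed so that it
unfolds below a single-event rupture with probability 0.40; iLOV
fingerprint 103 pN, in the same force range as the complex ruptures so
that fingerprint biasing is effective (conditional unfolding-force modes
near 96/103 pN).  Under these widths an iLOV overlap probability as high
as 0.85 would require an iLOV mode near 86 pN, inconsistent with
conditional modes around 100 pN; the calibration here prioritises the
force modes, and the iLOV overlap comes out near 0.5.  Other defaults:
linker contour 60 nm, spring constant 100 pN/nm, sample spacing 0.2 nm,
fingerprint gains 89 nm (xylanase, optionally 45+44 nm substeps), 36 nm
(iLOV), 57 nm (CBM marker, barrier 170 pN so it rarely unfolds), sub-step
gain 7.6 nm (19 residues × 0.4 nm/aa).

Reproducibility: one root seed; per-curve substreams are derived by
counter (`SeedSequence(seed, spawn_key=(i,))`) and recorded in the
manifest.

## Per-curve analysis

1. **Baseline/bending correction** — zero force is the mean of the
   trailing 10% of the trace (post-rupture by construction); tip–sample
   separation is piezo position minus force/k.
2. **Peak screening** — sudden drops in force: moving-average smoothing
   (5 points), local maxima at least 20 points apart, qualified by a
   ≥ 20 pN drop within 50 points.  The reported peak force is re-read
   from the fitted WLC branch of the peak's barrier (force balance at the
   drop position), which removes most of the single-point noise; a
   refinement disagreeing with the raw reading by > 15 pN is discarded.
3. **Rejection** — configurable minimum peak count, force and distance
   limits.  The default pipeline minimum is 2 peaks because the default
   simulated construct carries one single-step fingerprint (fingerprint
   peak + final rupture); constructs with multi-substep fingerprints
   warrant 3, the `reject_curve` default.
4. **Fingerprint screening** — an increment (or, with substep summing, a
   consecutive run) matching 89 ± 5 nm (xylanase), 36 ± 3 nm (iLOV) or
   57 ± 4 nm (CBM).  Curves without a fingerprint are rejected.
5. **Classification** — double iff the final increment lies in
   8 ± 4 nm; increments between 12 nm and the fingerprint window count as
   singles, not a third class.  The relative force difference of a double
   is 100·(final − first)/first; negative values mark shielded events.

Rejected curves keep their measurable quantities (final rupture force,
final increment, sub-step peak force) because the censoring correction
needs them.

## Censoring correction

Observed class counts are inflated by the probability that a trace of
that class survived fingerprint screening:

    corrected = (n_double / o_double) / (n_single / o_single)

where o_single = P(F_fp < F_single-rupture) and, for countable doubles,
o_double = P(F_fp < F_sub): a double is countable only when the
fingerprint unfolds below the sub-step.  The overlap probabilities are
estimated pairwise (ties ½) from:

* per-class rupture/sub-step marginals pooled over kept **and**
  rejected curves — every trace ends in an observable rupture and every
  fired sub-step is an observable peak, so these pools are free of the
  fingerprint-selection bias;
* the fingerprint marginal from every curve where a fingerprint force
  was measured, reweighted by inverse observation probability
  1/S_R(F) (S_R = survival function of the pooled final ruptures),
  because a fingerprint draw at force F is only observed when its
  complex survives past F.  Weights are clipped at the rupture-sample
  resolution.

A naive estimator using kept curves only over-corrects severely under
strong censoring (simulation: corrected ratio 1.4–1.7 when the truth is
≈ 0.8); the pooled/IPW estimator tracks a ground-truth-threshold oracle
to < 0.01 in the overlaps.  Uncertainty comes from a seeded percentile
bootstrap (default 2000 replicates) resampling both the class counts and
the force pools.

The fingerprint-biasing report compares fingerprint unfolding forces
conditioned on termination class (single- vs double-terminated; early
doubles belong to the double-terminated class here even though the
counting statistics exclude them), via fixed- or Silverman-bandwidth KDE
modes and a two-sample KS test (asymptotic p).  Counting uncertainties
are exact Clopper–Pearson beta-quantile intervals.

## Problem sizes

Dataset-level checks run at the scales the study design states: 450-trace
replicates for the biasing direction (20 seeded replicates), 500 mode-A
traces for increment recovery, 5000 traces for the correction-recovery
check, 1e5 draws for sampler validation.  The correction-recovery
scenario places the sub-step barrier at 125 pN and the mode-A prior at
0.6164 so that the latent apparent-class odds are exactly 1 (the sub-step
precedes the final rupture in a fraction 0.811 of mode-A traces for that
barrier pair).

## What the generator does not capture

Thermal drift, piezo nonlinearity, multiple simultaneous tethers,
approach/contact mechanics, force-dependent loading rates in the sampler,
and the non-Bell-Evans (superposed) shape of real single-rupture
distributions.  Passing tests therefore demonstrate correctness of the
analysis under the stated statistical model of the experiment, not
robustness to every instrumental artefact of real AFM data.
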