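# Methods

## Model structure and assumptions

The model describes one patient with advanced HCC on oral TKI therapy as a
deterministic ODE system (units: days; ng/mL for AFP; mAU/mL for PIVKA-II;
mg/day for dose; mg/mL for drug level; "cell-units" for tumor burden,
anchored to CT total tumor volume).

**Tumor growth.** Cancer cells are produced at `ξ1·C^ξ2` with ξ2 < 1 — the
per-cell productivity falls as the mass grows, consistent with
vascular/nutrient limitation — and die at `ξ4·C` (mean cell lifetime
1/ξ4 ≈ 9 days).  Drug-free, this has an exact solution via the substitution
`u = C^(1−ξ2)` (a linear ODE in u), used as the analytic oracle for the
integrator and for growth-time calculations.  The fixed point
`(ξ1/ξ4)^(1/(1−ξ2))` acts as a carrying capacity.  Because 1/(1−ξ2) ≈ 14 is
large, the capacity is extremely sensitive to any multiplicative reduction
of production: a 40% cut collapses it by roughly three orders of
magnitude.  Several design consequences below follow from this.

**Pharmacokinetics and effectiveness lag.** Plasma drug follows
`dF/dt = μ1·D(t) − μ2·F` (steady state μ1·D/μ2).  Effectiveness acts
through a delayed level `G` with a first-order lag `dG/dt = μ3·(F − G)`.
μ3 defaults to 0.15/day so that the combined PK + lag reaches ~95% of its
steady effect about three weeks after the start of therapy, matching the
observed delay between dosing and full drug activity.  The lag formula
itself is an implementation choice: the source material asserts a delay
without giving its form, and a first-order lag is the minimal one.

**Drug effectiveness.** Two saturating fractions,
`ε_υ = 1/(1 + ϑ1·G)` and `ε_r = 1/(1 + ψ1·G)`, scale neo-angiogenesis and
cell replication; `1 − ε` is the percent reduction quoted in summaries.
This is the standard Emax-type form used in viral-kinetics and
anti-angiogenic PK/PD modeling.

**Vasculature coupling.** Relative vasculature `V` obeys
`dV/dt = α2·ε_υ(G) − (α2 + α3·G/g_ref)·V`: neo-angiogenesis (throttled by
the drug) balances natural decay so that V ≡ 1 without drug, and `α3`
adds a drug-dependent decay of existing vasculature.  V multiplies cell
production (`dC/dt = ξ1·ε_r·V·C^ξ2 − ξ4·C`).  The published account of the
model's vasculature block is not fully specified; this coupling is a
reconstruction.  The printed α3 values (0.2–0.4) cannot multiply G
(~0.01 mg/mL) directly and still produce the reported ~23-day vasculature
lifetime at 400 mg/day, so the decay term is normalized by a reference
level `g_ref`; g_ref = 0.09 mg/mL reproduces that lifetime with the Case-1
constants.  With α3 = 0 vasculature decay is exactly drug-independent.

**Biomarkers.** AFP is a single first-order pool fed at `ω1·C`.  PIVKA-II
is three additive pools sharing the decay π3: cell-derived (`π1·C^π2`,
π2 > 1 for most cases — per-cell PIVKA-II output rises with tumor mass), an
ischemic spike after therapy start, and a drug-toxicity term
`Tox = π4·F·t^π5` attributed to anti-vascular effects on non-neoplastic
hepatocytes.  The decomposition of observed PIVKA-II is exact by
construction.  The spike is modeled as a delayed unimodal pulse
`σ_sp·P(0)·R·(s/τ_sp)·exp(1 − s/τ_sp)`, `s = t − t_sp` (peak amplitude
σ_sp·P(0)·R at s = τ_sp): the source states only proportionality to the
baseline PIVKA-II P(0) and cell density R with a possible delay, so the
pulse shape (3 parameters: amplitude, onset, scale) is an implementation
choice, disabled by default (σ_sp = 0).

**Imaging anchors.** Initial cells are `C(0) = occupancy·TTV·κ` with
occupancy 0.5 (HCC cells assumed the size of hepatocytes, occupying half
the tumor volume).  κ is per-case, not universal: the printed C(0)/TTV
ratios differ by an order of magnitude across the three prototype cases,
so κ is stored per case where derivable and defaults to the Case-1 value
(2.561×10⁴ per cm³) otherwise.  The tumor vascularization index (TVI) is
the arterial-phase Hounsfield-unit difference between tumor and non-tumor
liver and is compared against baseline-normalized V(t).

## Numerical choices

Integration uses adaptive explicit Runge-Kutta (scipy `solve_ivp`, RK45)
with rtol 1e-8 / atol 1e-10 by default, restarted at dose-segment
boundaries, at t = 0 and at the spike onset so the right-hand side is
smooth within each interval.  States are clamped at a positivity floor of
zero inside the rate laws and between segments.  Dose schedules are
piecewise-constant on half-open `[start, end)` intervals; intermittent
regimens (e.g. 160 mg/day regorafenib, 3 weeks on / 1 week off) expand
deterministically into explicit segments, and alternate-day dosing is
represented by its daily average (200 mg every other day → 100 mg/day).
t = 0 is the start of therapy; pre-therapy initial states put V at 1 and
the biomarkers at the quasi-steady level of a pool fed by an exponentially
growing source (`u/(k + g)` rather than `u/k`).

## Calibration

The objective is a weighted sum of squared residuals of
`log10(model) − log10(observed)` for AFP and PIVKA-II — the biomarkers span
3+ decades, so log residuals make the fit scale-invariant — plus a linear
residual on baseline-normalized TVI when at least three TVI points exist
(TVI can be negative for hypo-vascular lesions).  Model predictions are
clipped to the assay dynamic range before comparison (PIVKA-II
1.37–75,000 mAU/mL; AFP detection limit 1 ng/mL), because observations are
reported that way: a trajectory far below the detection limit should match
a censored observation rather than be penalized for unobservable depth.
Reported values below the detection limit are replaced by LOD/2 and
down-weighted ×0.25.  ξ2 is held fixed during fitting (it is constrained
only by sparse pre-therapy data).

Optimization is bounded Nelder-Mead in log10 parameter space from a seeded
Latin-hypercube set of starts (default 16; the bundled recovery experiment
uses 4 starts and objective-internal rtol 1e-6 as its default experiment
size).  Fits are bit-reproducible for a fixed seed.  A profile-flatness
probe flags the known `ω1·C(0)` product degeneracy when both are fitted
from AFP data alone: the objective increase along the ridge
(ω1·k, C(0)/k) is compared to the increase for the same move in ω1 alone,
and a ratio below 5% raises the `degenerate` flag.  Pre-therapy samples
spanning a wide growth range can break this ridge, because the power-law
growth rate depends on the absolute cell level.

Cohort summaries group cases as CR, PR-SD (partial response and stable
disease merged) and PD by the target-lesion response, with even-group
medians taken as the midpoint of the two central order statistics.

## Synthetic data: what it emulates, and what it does not

`generate_patient` simulates the true trajectory, reads it at jittered
visit times, multiplies by lognormal noise (unit median; CV 0.15 by
default, mimicking immunoassay plus short-term biological variability) and
clips to the assay range.  The default sampling plan is a biweekly
pre-therapy run-in, weekly visits during the first month on therapy (the
window in which the drug transient and the ischemic spike play out, and
which the prototype cases sampled densely), biweekly visits to month four
and four-weekly visits to about month eight — all spacings within the
2–6-week clinical window.  Visit jitter is ±3 days; the baseline visit at
t = 0 is never moved.

The generator does not emulate: new lesions appearing at other sites
(the model stops at target-lesion dynamics), assay batch effects or drifts,
dose-recording errors, missed visits, or inter-patient parameter
heterogeneity (each replicate reuses the same truth).  Passing recovery
tests therefore show that the *fitting machinery* is correct and quantify
identifiability under idealized compliance — not that real-cohort fits
reach the same accuracy.

## Identifiability: a known, quantified limitation

With the drug-accelerated vasculature decay active (α3 = 0.35 at Case-1
truth), the term `α3·G/g_ref` (~0.06/day at 600 mg/day) dominates
α2 = 0.0042/day, so V collapses on a ~2-week timescale *regardless of ϑ1*;
thereafter cell production is negligible against ξ4 and both biomarkers
fall below the assay range within ~3–4 months.  A Cramér–Rao analysis at
the truth (finite-difference Jacobian of the log10 observables, σ = 0.065
log10 per point at CV = 0.15) gives lower bounds on the relative standard
errors of ~0.3% (ξ1), ~4% (ω1), ~125% (ϑ1) and ~47% (ψ1), with a ϑ1–ψ1
correlation of −0.92.  The bundled 10-replicate recovery experiment
reproduces this pattern: ξ1 and ω1 recover to a few percent, ψ1 to ~20–25%,
ϑ1 essentially does not.  Noise-free recovery of {ϑ1, ψ1} is near-exact
(the residual surface still has its minimum at the truth).  TVI cannot
rescue ϑ1 here: the V differences it would need to resolve are an order of
magnitude below routine CT densitometry noise.  This is a structural
property of the reconstructed coupling, not an optimizer artifact, and it
is asserted as-is by the test suite.

## Counterfactual dose-response scenario

Under the reconstructed coupling, regrowth from the full pre-therapy
burden is impossible at maintenance doses even without the α3 mechanism
(the ε_υ-limited capacity at 100 mg/day is ~2.8×10⁴ cell-units, far below
the 1.78×10⁶ baseline, again because of the 1/(1−ξ2) amplification).  The
package therefore frames the dose-taper counterfactual from the
minimal-residual-disease state reached at the time of dose reduction
(C = 10³ cell-units with V, F, G at their 400 mg/day treated steady
state), and flags recurrence when C regains that reference burden within a
5-year horizon.  With α3 = 0.35 the residual tumor continues to
extinction under the taper; with α3 = 0 it regrows past the reference —
the qualitative sustained-response vs recurrence contrast the additional
decay mechanism was introduced to explain.

## Parameter defaults that matter

| parameter | default | units | why |
|---|---|---|---|
| μ3 | 0.15 | day⁻¹ | ~95% of steady effect ≈3 weeks after start |
| g_ref | 0.09 | mg/mL | 23-day vasculature lifetime at 400 mg/day (Case-1) |
| σ_sp, t_sp, τ_sp | 0, 0, 14 | day⁻¹, d, d | spike disabled unless fitted |
| occupancy | 0.5 | — | HCC cells ≈ hepatocyte volume, half of TTV |
| κ | 2.561×10⁴ | cells/cm³ | back-solved from Case-1 C(0)/TTV; per-case |
| noise CV | 0.15 | — | immunoassay + biological variability |
| LOD handling | LOD/2, ×0.25 | — | standard substitution with down-weight |
| multi-start | 16 (4 in recovery) | — | LHS coverage vs runtime |
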