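# hccdyn

Kinetic ODE modeling of advanced hepatocellular carcinoma (HCC) under
tyrosine-kinase inhibitor (TKI) therapy — sorafenib and regorafenib — from
serum biomarkers (α-fetoprotein AFP, PIVKA-II) and CT-derived tumor volume
and vascularization.

## Who this is for

Mathematical-oncology and hepatology modelers who want to (i) simulate
coupled cancer-cell / tumor-vasculature / biomarker / drug dynamics under
realistic dose schedules (dose reductions, 3-weeks-on / 1-week-off
cycling), (ii) fit the model parameters to per-patient biomarker time
series, and (iii) test whether such parameters are recoverable at clinical
sampling frequencies and assay noise levels, using synthetic patients.

## The model

State: cancer cells `C` (cell-units anchored to CT tumor volume), relative
tumor vasculature `V` (1 = pre-therapy equilibrium), serum AFP `A` (ng/mL),
three additive PIVKA-II pools `P_c`, `P_sp`, `P_tox` (mAU/mL; cell-derived,
ischemic spike, drug toxicity), plasma drug `F` and delayed effective drug
`G` (mg/mL), driven by the daily oral dose `D(t)` (mg/day):

```
dF/dt     = μ1·D(t) − μ2·F
dG/dt     = μ3·(F − G)                          (effectiveness lag)
ε_υ(G)    = 1/(1 + ϑ1·G)     ε_r(G) = 1/(1 + ψ1·G)
dV/dt     = α2·ε_υ(G) − (α2 + α3·G/g_ref)·V
dC/dt     = ξ1·ε_r(G)·V·C^ξ2 − ξ4·C
dA/dt     = ω1·C − ω2·A
dP_c/dt   = π1·C^π2 − π3·P_c
dP_sp/dt  = Sp(t) − π3·P_sp     Sp: delayed pulse ∝ P(0)·R
dP_tox/dt = Tox(t) − π3·P_tox   Tox(t) = π4·F·t^π5
```

`1 − ε_υ` and `1 − ε_r` are the fractional reductions of neo-angiogenesis
and of cell replication at effective drug level `G`; drug-free growth
(`dC/dt = ξ1·C^ξ2 − ξ4·C`, ξ2 < 1) has the exact closed form used
throughout for oracle checks.  Observed PIVKA-II is `P_c + P_sp + P_tox`
by construction.

The package bundles the best-fit parameter sets and baseline values of ten
advanced-HCC cases (four complete responses, four partial/stable, two
progressors) and reproduces their cohort-level medians by response group.

## Worked example

```python
import hccdyn as h

cases = h.load_case_fixtures()          # ten bundled patients
p = cases[1].params                     # CR-to-sorafenib prototype

s = h.kinetic_summary(p, 600.0)         # maximum tolerated dose, mg/day
print(f"steady-state drug level : {s['drug_steady_state']:.4f} mg/mL")
print(f"neo-angiogenesis reduced: {s['neoangiogenesis_reduction_pct']:.1f} %")
print(f"cell replication reduced: {s['replication_reduction_pct']:.1f} %")
print(f"growth 1 cell -> baseline burden: {h.time_to_reach(1.0, 1.78e6, p):.1f} d")

gen = h.generate_patient(p, h.DoseSchedule.constant(600.0),
                         h.default_sampling_plan(), h.NoiseModel(seed=42),
                         c0=1.78e6)     # noisy synthetic patient
spec = h.FitSpec(base=p, free={"xi1": (0.1, 1.0), "omega1": (1e-4, 5e-2)},
                 multi_start=4, seed=42, rtol=1e-6, atol=1e-9)
res = h.fit_patient(gen.dataset, spec)
print(f"recovered xi1 = {res.params.xi1:.3f} (truth 0.360), "
      f"omega1 = {res.params.omega1:.5f} (truth 0.00220)")
```

prints

```
steady-state drug level : 0.0156 mg/mL
neo-angiogenesis reduced: 77.4 %
cell replication reduced: 13.5 %
growth 1 cell -> baseline burden: 181.5 d
recovered xi1 = 0.359 (truth 0.360), omega1 = 0.00224 (truth 0.00220)
```

At the 600 mg/day steady state the drug blocks 77.4% of neo-angiogenesis
but only 13.5% of cell replication — the anti-vascular action dominates —
and a single surviving cell regrows to the baseline burden of 1.78×10⁶
cell-units in about six months.  The fit recovers the growth and AFP
production constants from one noisy synthetic patient to within a few
percent.

A `hccdyn` command-line tool exposes the same operations
(`simulate`, `kinetic-summary`, `fit`, `cohort-summary`, `synth`); see
`hccdyn --help`.

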