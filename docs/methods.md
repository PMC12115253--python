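# Methods

## Scope and model structure

`igpbpk` implements a whole-body, permeability-limited PBPK model for
IgG-like therapeutic proteins (mAbs, ADCs, bispecific T-cell engagers) in
cynomolgus monkey and human, together with the translational workflow built
on top of it: minimal-input monkey prediction, and human prediction without,
with allometrically scaled, and with optimised additional systemic clearance.

The body is represented by 15 compartments: 12 perfused tissues (lung,
adipose, bone, brain, heart, kidney, muscle, skin, gut, pancreas, spleen,
liver), a central lymph node, and the venous and arterial plasma pools.
Each perfused tissue is split into a vascular space, the endosome of the
endothelial cell layer, the interstitial space and an intracellular space.
The intracellular space carries volume only — no transport or elimination
process is assigned to it, so it stays empty; it is retained as an explicit
(inert) sub-space of the topology.  The lymph node is a single well-stirred
volume collecting every tissue's lymph flow and draining to venous plasma;
its entry in the tissue table exists for completeness and its FcRn and
catabolism shares default to zero.

Wiring: the lung is perfused in series with the full cardiac plasma output;
all other tissues are in parallel between the arterial and venous pools.
The lung plasma flow is derived at load time as the sum of the parallel
tissue flows plus the lung lymph flow, which makes the fluid circuit
(including lymph return) balance exactly; overriding it directly is
rejected.  Portal circulation is not modelled — liver, gut, spleen and
pancreas are perfused in parallel.

Amounts are carried in µmol, concentrations in µM (mg/L at the I/O
boundary via the molecular weight), time in hours.

## Distribution: two-pore transcapillary exchange

Paracellular exchange between vascular and interstitial space follows the
two-pore formalism: small (r_s = 4.5 nm) and large (r_l = 25 nm; 40 nm in
the sinusoidal liver and spleen) cylindrical pores.  For a solute of
Stokes–Einstein radius a_e = 0.0483·MW^0.386 nm and λ = a_e/r:

* partition coefficient Φ = (1 − λ)²,
* diffusive hindrance H_D = 1 − 2.104 λ + 2.09 λ³ − 0.95 λ⁵ (Renkin,
  clipped at 0),
* convective hindrance 1 − σ = Φ(2 − Φ)(1 − λ²/3),

with complete exclusion (Φ = 0, σ = 1) for λ ≥ 1.  This polynomial set is
one documented choice among the standard hindered-transport variants; it is
isolated in `twopore.hindrance` and the tests verify it against an
independent high-precision re-implementation, so swapping the set only
touches that function.

Solute flux through each pore class is the Patlak convection–diffusion
expression with Peclet number Pe = J_v(1 − σ)/PS.  Below Pe = 1e-4 a series
expansion (second order in Pe) replaces the exact form; the two branches
agree to better than 1e-9 relative, which removes the 0/0 at Pe → 0 without
a visible seam.  PS per pore class is (A₀/Δx) · D · Φ · H_D, with the free
diffusivity D from the Stokes–Einstein relation at 37 °C (η = 0.6913 mPa·s)
and the pore area-to-length density A₀/Δx a per-tissue configured constant
(shipped values scale with the tissue vascular volume: 2·10⁵ cm per L for
small pores, 1·10⁴ cm per L for large).  The net transcapillary fluid flow
equals the tissue lymph flow and splits as J_v,L = α_L·L + J_iso,
J_v,S = α_S·L − J_iso (α_L = 0.042, 0.30 in liver/spleen; the
isogravimetric recirculation flow J_iso defaults to 10% of the lymph flow —
a flagged assumption, configurable per tissue).  Lymphatic drainage of the
interstitium is convective with no sieving.

A full-size IgG (a_e ≈ 4.8 nm) is excluded from the small pores entirely
and exchanges essentially by large-pore convection — the expected two-pore
behaviour for antibodies.

## The endosomal FcRn pathway

Drug enters each tissue endosome by fluid-phase macropinocytosis at
k_pino = 0.0298 1/h (identical in all tissues), referenced to the endosomal
volume and drawn equally from the vascular and interstitial sides
(`uptake_split_vascular` = 0.5; the split is not identified by plasma data
and is configurable).  In the endosome the drug binds FcRn at pH 6.0 in 1:1
quasi-equilibrium: bound concentration is the stable root of the
mass-action quadratic, computed without cancellation.  Quasi-equilibrium
(KD only) rather than kon/koff kinetics is used because endosomal transit
is slow relative to binding.  Receptor occupancy by endogenous IgG is not
modelled; at therapeutic doses the endosomal drug concentration stays well
below the ~34–50 µM FcRn pool, so the system is effectively linear (dose
proportionality holds to ~0.1% at low doses and within a few percent at
30 mg/kg).

Bound complex leaves the endosome at k_rec (1/h); a fraction
fr_vascular = 0.7 returns to the vascular space and the remainder is
transcytosed to the interstitium (one rate plus a routing fraction — the
competing two-rate formulation is observationally equivalent for plasma
data).  Unbound endosomal drug is degraded at k_deg·w̃_t, where the
per-tissue weight w̃_t = w_t·(ΣV_e)/V_e,t renormalises the configured
catabolism weights w_t so the whole-body catabolic clearance distributes
across tissues by w_t at uniform endosomal exposure.

For monkey simulations the measured human-FcRn KD is multiplied by 0.45
(species factor for IgG binding, configurable per drug).

## Elimination pathways and dosing

Three unspecific pathways: endothelial catabolism (above); an additional
systemic clearance CL_add drawn from venous plasma, standing in for
mechanisms not represented (APC uptake, non-FcRn pinocytosis); and renal
filtration drawn from the kidney vascular space, used only for the small
Bi-TCE format.  ADC deconjugation is a first-order loss (k_deconj) of the
conjugated analyte from every drug-containing space; the naked antibody and
payload are not tracked.  IV dosing is a constant-rate infusion into venous
plasma; SC dosing is a first-order depot (ka) into the lymph node with
bioavailability f_sc applied at absorption, the non-absorbed fraction
booked as presystemic loss.  The integrator (LSODA, rtol 1e-8 / atol 1e-12
µmol by default) restarts at every dose event, so discontinuities are
exact.  Every simulation carries cumulative per-pathway elimination states
and a mass-balance audit: administered = in-system + eliminated to < 1e-6
relative (typically ~1e-12).

## Physiology tables

The shipped monkey (4 kg) and human (70 kg) tables are authored defaults
representative of standard reference-body compilations, stored as editable
YAML with flat-path overrides.  Two values deserve emphasis:

* The endosomal sub-space is an *effective* volume — 1.7% of tissue volume
  in human, 2.5% in monkey.  With the pinocytosis rate fixed at its
  measured value, k_pino·ΣV_e bounds the attainable catabolic clearance;
  the effective volumes are set so the calibrated models reproduce
  realistic exogenous-IgG kinetics (terminal half-life ≈ 22 d human,
  ≈ 11 d monkey; total IgG clearance ≈ 0.013 L/h human) while the monkey's
  higher per-kg clearance is absorbed into its larger effective fraction.
* Whole-body FcRn is 49.8 µM referenced to total endosomal volume in
  human, distributed across tissues by configured shares; the monkey value
  (33.9 µM) follows from applying the human per-gram tissue abundance to
  the monkey tissue masses (`scale_monkey_fcrn`).

No quantitative test depends on a specific physiological value: closed
forms, independent oracles and synthetic ground truth carry all numeric
assertions.

## Calibration and the 20% rule

`calibrate_igg` fits the endosomal rates so a 150 kDa reference IgG
(KD 0.7 µM) reproduces the configured exogenous-IgG targets after a
standard 1 mg/kg IV study.  With a half-life target alone only k_rec is
fitted; with both targets (half-life and plasma concentration at a
reference time, the shipped mode) k_rec and k_deg are fitted jointly.  The
two targets pin the two parameters through complementary sensitivities:
the catabolised fraction of pinocytosed drug k_deg(1−β)/(k_deg(1−β)+k_rec·β)
sets the clearance scale, while the endosomal escape rate sets a (weak)
transit-time signature — the fit is a shallow valley, so the residuals are
integrated at rtol 1e-9 and the log-parameter least-squares uses bounded
TRF with a 1e-3 finite-difference step.  Closed-loop tests regenerate the
targets from a stated (k_rec, k_deg) pair and recover it to well under 2%.
The shipped targets are themselves rounded model-attainable values flagged
as editable assumptions.

The additional systemic clearance of IgG is 20% of the *total* IgG
clearance.  Because adding CL_add changes the total, the value is the fixed
point CL_add = 0.2·CL_total(CL_add), solved by direct iteration (a
contraction; ~5 iterations to |ratio − 0.2| < 1e-4), where CL_total =
dose/AUC_inf from the simulated reference study.  The ratio is taken against the
post-addition total (20% *of the final* clearance — the self-consistent
reading); a configuration whose mechanistic pathways are disabled is
rejected as infeasible, since the ratio is then pinned at 1.

## Translation workflow and evaluation

Monkey predictions are deliberately minimal-input: molecular weight and
human-FcRn KD from the user, KD species-scaled by 0.45, CL_add auto-filled
with the monkey IgG default; provenance of every auto-filled value is
recorded on the model.  Human scenarios: `no_cladd` (CL_add = 0),
`allometric` (CL_add fitted to the observed monkey PK, scaled by
(70/4)^0.75 — exponent 0.75 is the classic clearance exponent,
configurable and surfaced in reports), and `optimized` (CL_add fitted to
the observed human PK).  The allometric scenario requires monkey data and
is skipped otherwise.  Fitting minimises summed squared log-concentration
deviations jointly across dose groups (PK spans orders of magnitude;
LLOQ-censored points excluded) by bounded scalar search over log10 CL_add.

Performance is judged by PE(%) = (predicted/observed − 1)·100 for Cmax and
AUClast against a ±50% margin.  Observed NCA uses the observed sampling
times only (linear trapezoid; lin-up/log-down available); predicted metrics
use the simulation evaluated at the same times, so the comparison is
grid-matched.  Cmax ties resolve to the earliest time.

## Synthetic case studies

Because real case-study PK of this kind is proprietary, the generator
produces complete bundles with known ground truth.  A virtual drug is drawn
per case (MW uniform in 145–155 kDa for mAbs, KD log-uniform in 0.2–2 µM);
the true human CL_add is set to a configured fraction of the drug's total
clearance (default range 0.2–0.6, resolved by the same fixed point as the
IgG rule).  The true monkey CL_add is, by default, drawn within ±25% of
the monkey IgG default — encoding the empirical finding that monkey
disposition of IgG-like drugs is well approximated by the IgG value, which
is what makes minimal-input monkey prediction work.  The
`allometric_consistent` mode instead derives the monkey truth from the
human truth through the body-weight power law, making the allometric
scenario exact by construction; comparing the two modes reproduces the
qualitative translation pattern (severe AUC overprediction without CL_add,
intermediate allometric behaviour, best-case optimisation).

Observed profiles carry multiplicative log-normal noise
exp(N(0, σ²)), σ = √ln(1 + CV²), i.i.d. across samples (default CV 15%),
with optional LLOQ censoring.  Sampling is dense-early/sparse-late:
0.5 h–28 d in monkey and 0.5 h–42 d in human (the two late human samples
at 35 and 42 d anchor the terminal phase of long-half-life antibodies and
give the clearance fit its precision: at 20% CV and three dose levels, the
true human CL_add is recovered with ~4% mean and <15% worst-case error
over 20 replicates).  Ground truth is sealed in a separate
`ground_truth/` directory that the bundle loader never reads; the public
drug description has CL_add unset.  Same seed ⇒ bit-identical bundles.

What the generator does not emulate: target-mediated disposition (doses
are assumed target-saturating throughout), inter-individual variability
beyond the single typical subject, time-varying clearance, immunogenicity,
and assay drift.  Passing tests therefore demonstrate the correctness and
internal consistency of the machinery under the stated noise model, not
predictive accuracy on real clinical data.

## Numerical choices and limitations

* Solver LSODA; dose events by integrator restart; default rtol 1e-8,
  atol 1e-12 µmol; mass-balance audits at rtol 1e-10 where asserted.
  Negative excursions beyond max(1e-9, 1000·atol) µmol abort; smaller ones
  are clipped and counted.
* Terminal half-life: log-linear regression over the final third of the
  observation span (at least 3 points, falling back to the last 3);
  non-decreasing terminal phases raise.
* AUC_inf for clearance probing: trapezoid to t_end plus C(t_end)/k_z tail.
* Deterministic throughout: fits are derivative-based or bounded scalar
  searches from fixed starts; all randomness flows from explicit seeds.
* Problem sizes in the shipped studies (a handful of cases, two to three
  dose levels, 20 fit replicates) are chosen to exercise every pathway at
  desk scale.
* Known limitations: no TMDD; no portal vein; no endogenous-IgG
  competition for FcRn; no pH-dependent two-state binding or 2:1
  stoichiometry; ADC payload and naked-antibody species not tracked; the
  Bi-TCE is treated as a generic small IgG-like protein with SC absorption
  and renal filtration rather than a full format-specific model.
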