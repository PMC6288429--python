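# Methods

`hfmicro` simulates a family of human ventricular myocyte models spanning
the transition from a healthy cell to a heart-failure (HF) phenotype with
degraded T-tubular microdomains and disrupted β2-adrenergic/cAMP
compartmentation. This note documents the model, its assumptions, the
numerical choices, and the design decisions taken where the design was
genuinely open.

## Baseline cell

The electrophysiological substrate is the O'Hara–Rudy (2011) human
ventricular action-potential model, endocardial parameterization (the
model's default cell type), transcribed in full in
`hfmicro/ord_reference.py` and kept free of any extension so the remodeled
model can be verified to reduce to it *exactly* (to machine precision in
the right-hand side, and within solver tolerance in traces) when all
remodeling is switched off. Units are ms, mV, mM, µA/µF throughout.

## Remodeling state

Three dimensionless fractions describe a cell in the family:

| parameter | meaning | range |
|---|---|---|
| `f_TT` | T-tubule integrity (1 intact, 0 fully de-tubulated) | [0, 1] |
| `f_B2AR` | fraction of L-type Ca channels (LTCCs) associated with a β2-adrenergic receptor | [0, 1] |
| `f_PDE` | fraction of LTCCs experiencing phosphodiesterase activity | [0, 1] |

Treating the three associations as independent, the product of the state
fractions assigns every LTCC to one of six subgroups: A–C in the T-tubular
membrane (with β2AR+PDE, with β2AR only, without β2AR) and D–F their
surface-membrane counterparts. Channels lacking both β2AR and PDE are
physiologically indistinguishable from the never-phosphorylated no-β2AR
subgroup and are absorbed into C (or F), so the six weights always sum
to 1. The whole-cell LTCC current is the weighted sum over subgroups; the
total channel number and unitary conductance are held constant across
remodeling.

**Case presets.** Six canonical weightings put 80% of the channels into one
subgroup each. A case is generated from actual `(f_TT, f_B2AR, f_PDE)`
values solved so the product-form weight of the dominant subgroup is
exactly 0.8 (case 1: all three equal to 0.8^(1/3) ≈ 0.9283); a parameter
that does not enter the dominant weight is set to the neutral value 0.5.
The remaining 20% therefore spreads over the other five subgroups in
proportion to their association probabilities. Cases are configuration
presets, editable without code changes.

## Sub-sarcolemmal compartment

Surface-membrane channels cannot sense the dyadic subspace, so the cell
gains a sub-sarcolemmal Ca pool (`casl`) under the non-tubular membrane:

* volume fraction 0.02 of cell volume and a Ca diffusion time constant to
  the myoplasm of 0.177 ms, both scaled from the Shannon–Bers rabbit
  formulation (J_Ca,slmyo = 3.7243·10⁻¹² L/ms over v_sl = 0.02·33 pL) and
  exposed in configuration, not hard-coded;
* the same anionic-site buffering (BSR/BSL) as the dyadic subspace;
* surface LTCC Ca flux, redistributed NCX flux and diffusion to the
  myoplasm are its only sources/sinks; the pool is flux-conservative
  against the myoplasm.

When no channel population occupies the surface membrane and `f_TT = 1`,
the pool is not distinguished from bulk myoplasm (no exchange flux), which
makes the healthy-cell reduction exact rather than approximate.

## Dyad loss, NCX redistribution, RyR orphaning

* **Dyads.** The dyadic subspace volume scales with `f_TT` (floor 10⁻³):
  de-tubulation removes dyads, and the dyads that remain keep their local
  geometry, so per-dyad Ca influx density is preserved. Without this the
  remaining T-tubular channels would see a vanishing dyadic Ca signal at
  low `f_TT` and their Ca-dependent inactivation (CDI) would artificially
  collapse.
* **NCX.** In the intact cell a fifth of the exchangers face the surface
  membrane (the baseline junctional component); de-tubulation moves a
  share of the T-tubular exchangers to the surface in proportion to
  `1 − f_TT`, where they sense and flux into `casl`. The bookkeeping is
  `surface = 0.2 + 0.8·(1 − f_TT)`. At `f_TT = 1` the formulation is
  exactly the baseline model's; the constitutive junctional fifth keeps its
  baseline (dyadic-sensing) formulation while the redistributed share
  senses the sub-sarcolemmal pool.
* **RyRs.** A fraction `f_TT` of ryanodine receptors remains coupled to its
  dyadic LTCC partners; the coupled release drive is the baseline
  formulation evaluated on the T-tubular LTCC current component (the
  per-dyad trigger normalization and the coupled-fraction weight cancel for
  product-form subgroup weights). The orphaned fraction `1 − f_TT` is gated
  by the bulk cytosolic Ca transient through a steep (Hill-4) regenerative
  CICR drive — half-activation 0.9 µM, gain 4.0 mM/ms, the same
  JSR-load gating and relaxation time constant as coupled release — and
  releases into the myoplasm. The steep activation keeps the diastolic
  orphan leak negligible while reproducing a distinctly weaker SR release
  in de-tubulated cells.

## Phosphorylation populations

Phosphorylation is binary and quasi-static (a channel is phosphorylated or
not; no partial states), so every target is a weighted sum of populations.

**PKA / LTCC.** Subgroup phosphorylated fractions: with β2AR+PDE — 25%
basal, 75% stimulated; with β2AR but no PDE — 25% basal, 100% stimulated
(PDE activity is itself PKA-driven, so the missing brake matters only when
PKA is active; this also makes PDE removal inert at baseline, as the
protective role of PDE is a stimulation-only phenomenon); without β2AR —
never phosphorylated. A PKA-phosphorylated LTCC carries **2.5× current
amplitude** and an **8 mV hyperpolarizing shift of its activation gate**
(a separate gate state `dp`). The shift is the classic β-adrenergic effect
on the L-type channel (reported range ≈5–14 mV); without it no level of
amplitude scaling destabilizes repolarization in this substrate, because
dyadic CDI self-compensates (verified directly: 3.5× LTCC amplitude in the
unmodified baseline prolongs APD90 by only ~35 ms with no
afterdepolarizations). 8 mV was fixed by requiring that the intact
stimulated cell remain free of afterdepolarizations at its reported APD
while strongly remodeled stimulated cells become arrhythmic; it is
configuration-exposed (`phospho.pka_activation_shift_mv`).

**PKA / other targets.** RyR, phospholamban (PLB), IKs, INa, INaK, IKur and
troponin I are each split 25%/75% (basal/stimulated) into populations whose
currents (or fluxes, or buffer terms) are summed. Effect magnitudes applied
to the phosphorylated population live in `data/pka_targets.yaml` as data
with per-target source strings: RyR release gain ×1.75, SERCA Ca
half-saturation ×0.5 (PLB), IKs conductance ×1.4, INa conductance ×1.25,
Na/K-pump Na affinity ×0.8 (Knai ×0.8), troponin Km ×1.6. Human ventricle
expresses no functional IKur and the baseline model carries none, so that
target is listed with an identity effect. Effect *directions* follow the
Heijman et al. (2011) β-adrenergic signaling formulation; *magnitudes* were
calibrated once against the intact cell's reported basal and stimulated
APD90 (the same kind of anchoring the phosphorylation fractions themselves
received in the source modeling literature) and then frozen.

**CaMKII.** The baseline model's dynamic CaMKII machinery (INa, INaL, Ito,
ICaL, release, uptake) is retained unchanged — it is part of the baseline
and of T-tubular channel behavior. Surface-membrane LTCCs, which have no
baseline precedent, carry a *constant* CaMKII-phosphorylated fraction
(default 0.1, configuration-exposed); T-tubular channels receive no extra
constant term.

**Surface-channel CDI.** The baseline CaM-mode kinetics tie the mode-exit
rate to the voltage-dependent recovery gate (`km2n = jca`), which drives
any maintained depolarized current into near-complete inactivation
regardless of the Ca actually sensed — a calibration appropriate for the
dyad, where sensed Ca is tens of µM. Channels relocated to the
sub-sarcolemmal space sense sub-µM Ca, so their mode-exit rate is held at
a constant 0.2 ms⁻¹, placing the CDI midpoint between diastolic
(~0.1 µM) and systolic (~0.5–0.7 µM) sub-sarcolemmal Ca. Mode entry
remains Ca-driven exactly as in the baseline. This is the package's
concrete reading of "CDI depends on the Ca concentration the channel
senses"; the two constants (exit rate, and the activation shift above)
were calibrated once against the reported intact-cell APDs and the
de-tubulated cell's +44 ms basal prolongation, then frozen.

## Protocols and metrics

* **Voltage clamp**: hold at −96.7 mV until the clamped state stops
  changing (relative change < 10⁻⁶ per 10 s chunk), step to −6.7 mV for
  500 ms, record per-component LTCC currents at 0.1 ms. Each component's
  post-peak decay is fitted by least squares with a single exponential plus
  offset, window from 95% of the post-peak magnitude to the step end; slow
  decays are extrapolated beyond the window and ill-conditioned fits are
  flagged (residual reported), never silently dropped.
* **Pacing**: cycle length 1000 ms, stimulus −80 µA/µF for 0.5 ms (baseline
  convention), conditioning until the maximum relative state change at
  successive beat starts falls below 10⁻⁴ (capped at 1000 beats), then 3
  recorded beats (APD analysis) or 15 (EAD analysis).
* **APD90**: time of 90% repolarization minus time of maximal upstroke
  velocity; diastolic reference just before the stimulus; linear
  interpolation at the crossing. A beat that never reaches 90%
  repolarization before the next stimulus is *oscillatory* and carries no
  finite APD90; its diastolic reference is carried over from the last
  polarized diastole.
* **EADs**: a local minimum followed by a local maximum during
  repolarization, ≥1 mV prominence on a 1-ms-smoothed trace, with take-off
  potential restricted to −70…+10 mV so the normal notch–dome morphology
  (take-off above +10 mV) is not counted.
* **Sweep**: `(f_TT × f_PDE)` grids (default 11×11, step 0.1) at f_B2AR
  levels 0–1 in steps of 0.25, 15 recorded beats per point; mean APD90
  excludes oscillatory beats, which are reported as a separate class.
  The sweep is deterministic and order-independent; individual grid-point
  failures are recorded and the sweep continues.

## Numerics

LSODA (adaptive, stiffness-switching) with rtol 10⁻⁶ / atol 10⁻⁸; every
discontinuity (stimulus edge, clamp step) starts a fresh solver segment.
The right-hand side is jit-compiled (numba; a pure-Python fallback keeps
the package importable without it). Halving the tolerances moves a paced
beat's APD90 by < 0.5 ms, and pacing 30 beats past the steady-state
criterion moves it by < 1 ms (both under test). Conservation: with all
sarcolemmal Ca fluxes zeroed, total cell Ca (free + buffered,
volume-weighted over all compartments) is constant to < 10⁻⁶ relative over
10 s of pacing.

## Test problem sizes

The test suite runs serially on one CPU. Pacing tests condition with the
full criterion (cap 1000 beats; typical convergence 130–400 beats). Grid
phenotype checks subsample the remodeling grid — 3×3 (`f_TT`, `f_PDE` ∈
{0, 0.5, 1}) for the f_B2AR = 0.25 no-EAD check, 2×3 low-`f_TT` points for
the f_B2AR = 1.0 oscillation check, three basal points for the
basal-no-EAD check — and the determinism/runtime check uses a reduced
3×3×2 sweep with a 150-beat conditioning cap. The full 11×11×5 sweep with
full conditioning is available through `hfmicro sweep` and the
`sweep_heatmap` API.

## What the model family does and does not capture

The family isolates the consequences of T-tubule loss, LTCC/NCX
redistribution, RyR orphaning and β2AR/PDE delocalization under an
otherwise healthy ionic substrate. It deliberately excludes HF remodeling
of INaL/IKs/IKr, β1-adrenergic signaling, dynamic cAMP/PKA/PDE kinetics
(phosphorylation is quasi-static), CaMKII remodeling, mechanics and tissue
coupling. Compartments are well mixed (no reaction–diffusion). Conclusions
about arrhythmia propensity therefore concern the cell-level trigger
mechanism, not whole-heart risk.

Two documented quantitative limitations remain. (1) The *slow*
(surface-component) clamp decay constants: the committed per-component
offset fit reports the fast phase of a current that genuinely persists
(26% of peak at 500 ms in the fully de-tubulated cell), so these constants
come out far smaller than values obtained with window-limited or
offset-free fitting of a slowly decaying current; no fit convention
reproduces all published values simultaneously under this LTCC kernel, and
the choice here follows the stated design (see the flagged-fit residuals
in the output tables). (2) Discrete early-afterdepolarization morphology:
this substrate transitions from normal repolarization to alternating
repolarization failure with only a narrow window of discrete EAD beats, so
strongly remodeled stimulated cells tend to classify as oscillatory rather
than as multi-EAD.
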