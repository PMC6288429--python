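# hfmicro

Human ventricular heart-failure myocyte models with T-tubule microdomain
remodeling, L-type Ca-channel subpopulations and β2-adrenergic
phosphorylation compartmentation.

## The problem

Heart failure progressively destroys the transverse-tubule (T-tubule)
system of ventricular myocytes. L-type Ca channels (LTCCs) that normally
cluster in dyads — facing ryanodine receptors (RyRs) across a nanoscopic
subspace where Ca-dependent inactivation (CDI) is strong — are
redistributed to the bulk surface membrane, where they sense only the thin
sub-sarcolemmal Ca shell. At the same time the β2-adrenergic receptors
(β2ARs) and phosphodiesterases (PDEs) that confine cAMP/PKA signaling to
the dyad are delocalized. `hfmicro` implements a *family* of single-cell
models spanning this transition, for electrophysiologists studying how the
resulting longer-lasting, larger LTCC current creates cell-level arrhythmia
triggers (early afterdepolarizations, repolarization failure).

## The model

The substrate is the O'Hara–Rudy human ventricular action-potential model
(endocardial), extended with:

* three remodeling fractions — T-tubule integrity `f_TT`, β2AR association
  `f_B2AR`, PDE association `f_PDE` — whose products assign every LTCC to
  one of six subgroups A–F (T-tubular vs surface × with β2AR+PDE / β2AR
  only / no β2AR); whole-cell I_CaL is the weighted sum over subgroups,

      w_A = f_TT·f_B2AR·f_PDE,  w_B = f_TT·f_B2AR·(1−f_PDE),
      w_C = f_TT·(1−f_B2AR),    w_D–w_F analogous with (1−f_TT);

* a sub-sarcolemmal Ca compartment sensed by surface LTCCs and
  redistributed Na/Ca exchangers; NCX redistribution
  (surface fraction 0.2 + 0.8·(1−f_TT)) and RyR orphaning (coupled
  fraction f_TT) proportional to T-tubule loss;
* binary, quasi-static PKA phosphorylation: 25% of each target population
  at rest, 75% under β2AR stimulation (100% for LTCCs that lost PDE
  control); a phosphorylated LTCC carries 2.5× amplitude and an 8-mV
  hyperpolarized activation shift; seven further targets (RyR, PLB, IKs,
  INa, INaK, IKur, TnI) are population-weighted with documented effect
  constants; surface LTCCs additionally carry a constant
  CaMKII-phosphorylated fraction;
* APD90 measured from maximal upstroke velocity to 90% repolarization;
  EAD detection and a normal / EAD / oscillatory beat classification.

Six canonical cases put 80% of the LTCCs into one subgroup each (case 1:
healthy intact cell; case 4: fully remodeled surface-dominant cell; ...).
See `docs/methods.md` for assumptions, constants and limitations.

## Worked example

```python
from hfmicro import PhosphoConfig, case_definition
from hfmicro.protocols import run_case_experiment, run_voltage_clamp

# intact myocyte, basal conditions: steady-state pacing at 1000 ms
res = run_case_experiment(case_id=1, stimulated=False, recorded_beats=3)
print(f"APD90 = {res.mean_apd90_ms:.1f} ms, class = {res.classification}")

# clamp -96.7 -> -6.7 mV: component decay constants
case = case_definition(1, stimulated=False)
clamp = run_voltage_clamp(case.params, PhosphoConfig(stimulated=False),
                          fractions=case.fractions)
print(f"tau1 (T-tubular) = {clamp.tau1_ms:.1f} ms, "
      f"tau2 (surface) = {clamp.tau2_ms:.1f} ms")
```

prints

```
APD90 = 288.6 ms, class = normal
tau1 (T-tubular) = 22.0 ms, tau2 (surface) = 19.0 ms
```

— the healthy cell repolarizes in ~289 ms with no afterdepolarizations,
and its T-tubular I_CaL component inactivates within tens of milliseconds
(strong dyadic CDI). Under β2AR stimulation the same cell prolongs to
~310 ms; the fully de-tubulated basal cell (case 4) prolongs to ~340 ms
and its surface current decays far more slowly (26% of peak remains at
500 ms; the mono-exponential summary of such a persistent current is
fit-convention-sensitive — see `docs/methods.md`).

The same protocols are available from the shell:

```sh
hfmicro case 1 --basal --out out/
hfmicro clamp --case 4 --basal --out out/
hfmicro sweep --stimulated --steps 11 --levels 0,0.25,0.5,0.75,1 --out out/
```

Outputs are tidy CSV/JSON tables with provenance headers (full expanded
configuration and solver settings); identical configurations produce
byte-identical files.

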