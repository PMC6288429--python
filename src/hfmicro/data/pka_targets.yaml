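# PKA phosphorylation effects, applied to the phosphorylated population of
# each target.  Values are data, not code: edit here, never in the model
# source.
#
# Effect directions follow the beta-adrenergic signaling formulation of
# Heijman, Volders, Westra & Rudy (2011, J Mol Cell Cardiol 50:863-871);
# magnitudes are calibrated once so that the intact (case 1) myocyte
# reproduces the reported basal and beta2-stimulated action-potential
# durations, staying within literature-reported ranges.  See
# docs/methods.md for the calibration rationale.
#
# Multipliers are applied to the named model parameter for the
# phosphorylated population only; unphosphorylated populations keep the
# baseline O'Hara-Rudy (2011) values.
schema: hfmicro-pka-targets-v1
targets:
  LTCC:
    description: L-type Ca channel; whole-channel current amplitude
    effects:
      amplitude: 2.5
    source: "Heijman et al. 2011 (PKA raises LTCC open probability); 2.5x amplitude per phosphorylated channel"
  RyR:
    description: ryanodine receptor; SR release trigger sensitivity
    effects:
      release_gain: 1.75
    source: "Heijman et al. 2011; enhanced SR Ca release flux of the phosphorylated population"
  PLB:
    description: phospholamban; relief of SERCA inhibition
    effects:
      serca_km: 0.5
    source: "Heijman et al. 2011; PKA-phosphorylated PLB halves the SERCA Ca half-saturation"
  IKs:
    description: slow delayed-rectifier K current
    effects:
      conductance: 1.4
    source: "direction per Heijman et al. 2011; magnitude calibrated to the intact-cell AP duration under stimulation (IKs is small in human ventricle)"
  INa:
    description: fast Na current
    effects:
      conductance: 1.25
    source: "Heijman et al. 2011; modest PKA enhancement of peak INa"
  INaK:
    description: Na/K ATPase via phospholemman
    effects:
      knai: 0.8
    source: "Despa & Bers; increased intracellular Na affinity of the phosphorylated pump population"
  IKur:
    description: >
      rapidly activating plateau K current; human ventricle expresses no
      functional IKur and the O'Hara-Rudy model carries none, so the target
      is listed for completeness with an identity effect
    effects:
      conductance: 1.0
    source: "no human-ventricular IKur substrate in the baseline model"
  TnI:
    description: troponin I; reduced myofilament Ca affinity
    effects:
      trpn_km: 1.6
    source: "Heijman et al. 2011; Km of troponin for Ca increased 1.6x"
  INaL:
    description: late Na current; PKA effect not part of the seven-target set
    effects: {}
    source: "CaMKII-regulated only (baseline O'Hara-Rudy dynamic handling)"
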