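# Demo pipeline: synthesize a small wide-cell population under the
# calibrated repulsive model, compute pattern metrics, and export the
# strip-model SF/DF phase diagram.
name: demo
stages:
  - kind: synthesize
    seed: 11
    population: VL3
    n_cells: 4
    mode: model_equilibrium
    model:
      sign_N: 1
      alpha_N: -1
      sign_S: 1
      alpha_S: -1
      M_S: 2.2
      M_P: 3.2
  - kind: metrics
    seed: 11
  - kind: bifurcation
    model_class: M2
    M_S: 2.2
    spacings: [25, 30, 35, 40, 45, 50, 55, 60]
    half_widths: [15, 20, 25, 30, 35, 40, 45, 50, 55, 60]
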