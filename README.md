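# ipsense

Sensitivity analysis of neuronal rate coding under plasticity of a generic
voltage-gated conductance.

A single-compartment conductance-based neuron (leak + fast AP currents +
a generic "X" conductance with Boltzmann gating, optionally driven by
background Poisson synaptic noise) is used to quantify how changes of the
X conductance reshape the frequency–current (f–I) relation. The package
provides:

- **`model_core`** – fixed-step RK4 simulation of the full model (numba
  accelerated), spike detection, AP-duration measurement.
- **`excitability`** – f–I construction: mean frequency over a fixed ISI
  count, current threshold (first current eliciting a non-null mean rate),
  linear fit of the f–I window and the model-I regression with the
  correlation-coefficient test.
- **`sensitivity`** – threshold sensitivity `S_theta = dI_theta/dgmax` and
  inverse-gain sensitivity `S_E = dE/dgmax` as regression slopes over an
  admissible geometric gmax progression, plus resumable (V_half, k) map
  sweeps with a seven-category admissibility filter.
- **`iaf_theory`** – reduced integrate-and-fire theories: closed-form
  threshold sensitivity `(V_theta − E_X)·x_inf(V_theta)^p`, iso-sensitivity
  lines meeting at the central point `(V_theta, 0)`, and the pre-, post-
  and pre/post-spike inverse-gain theories with activation loading across
  the stereotyped AP waveform; analytic ISI trajectories.
- **`generalization`** – chain-rule sensitivities to kinetic parameters
  (V_half, k, E_X, tau) with a finite-difference oracle.
- **`ip_loop`** – homeostatic plasticity loop: high-threshold calcium
  current → shell calcium dynamics → kinase/phosphatase cycle →
  phosphorylated fraction scaling the X conductance; HH and rate-based
  engines plus spontaneous-discharge maps and the analytic firing border
  `I_theta + S_theta·g_sup ≤ 0`.
- **`io_cli`** – YAML scenarios, presets, CSV/JSON writers, deterministic
  per-component seeding.

## CLI

```sh
ipsense simulate --template na_standard -I 0.5 --duration 1000 --out trace.csv
ipsense fi --template na_standard --noise --seed 1 --out fi.csv
ipsense sweep --template na_standard --out sweep.csv
ipsense map --template na_standard --grid-vhalf=-80:-40:9 --grid-k 1:15:9 --out map.csv
ipsense theory-map --theory prepost --out tmap.csv
ipsense loop --engine hh --template loop_subthreshold --out loop.csv
ipsense loop-map --engine rate --out loopmap.csv
ipsense param-sens --q V_half --gmax 1e-3
```

Every command writing CSV also writes a `.meta.json` sidecar with the
resolved parameters, seed and software version; `--seed` reruns are
byte-identical.

## Units

mV, ms, µA/cm², mS/cm², µF/cm², µM throughout.
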