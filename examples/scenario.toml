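# Full pipeline scenario: field map, synthetic trials, dosimetry, validation.
# Run with:  thermosar run --config examples/scenario.toml --out run_dir --seed 7

[coil]
alpha_deg = 45.0        # fixture half-angle (the fabricated value is unpublished)
s1_m = 0.02
s2_m = 0.12
n_turns = 40
current_rms_a = 0.75

[waveform]
freq_hz = 10000.0
duty = 0.5
polarity = "unipolar"

[stages]
run = ["field", "synthetic", "dosimetry", "validation"]

[field]
bounds = [[-0.02, 0.02], [-0.02, 0.02], [0.03, 0.07]]
spacing = 0.01
roi = [[-0.02, 0.02], [-0.02, 0.02], [0.03, 0.07]]

[synthetic]
preset = "implant-0.75A"
n_trials = 10

[dosimetry]
heat_capacity = 500.0          # J/(kg K), metallic implant
c_interval = [450.0, 550.0]

[material.resin]
density = 1150.0
heat_capacity = 1300.0
thermal_conductivity = 0.25
electrical_conductivity = 1e-8
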