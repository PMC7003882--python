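# Demonstration pipeline configuration: all inputs synthetic.
# Run with:  daphnegain run-all --config examples/demo.toml --out demo_out

seed = 0
out_dir = "demo_out"
n_plants = 5
lab_noise_sd = 0.4
aging_mode = "geometric"

[climate]
latitude_deg = 35.4
year_start = 2006
year_end = 2006
openness_closed = 0.08
openness_open = 0.30

[traits]
n_per_group = 50
noise_sd = 0.05
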