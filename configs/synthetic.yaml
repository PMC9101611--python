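# End-to-end synthetic run: `lesiontex run --config configs/synthetic.yaml`
input: synthetic
synthetic:
  n_per_group: 166
  lighting_modes: [polarized, nonpolarized]
  side: 450
quantization:
  levels: 64
texture:
  distance: 5
  reducer: mean
stats:
  alpha: 0.05
output_dir: results
seed: 1
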