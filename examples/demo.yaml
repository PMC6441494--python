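# Full-pipeline demo on a self-generated synthetic bundle.
# Run from the repository root:
#   cico run --config examples/demo.yaml
out_dir: demo_out
seed: 1
simulate:
  seed: 1
  noise: none     # noiseless counts so the run manifest funnel equals truth
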