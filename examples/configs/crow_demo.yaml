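# Crow-style demonstration run at reduced scale (about a third of the full
# study's pecks per phase) so it completes in a few seconds.
outdir: crow_demo_run
seed: 5
preset: crow-like
scale: 0.34
quiet: true
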