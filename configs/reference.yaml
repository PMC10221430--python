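# Reference training protocol (GPU-scale): full-size scenes and the
# published optimization settings. Expect hours on CPU.
seed: 0
n: 650
epochs: 300
depth: 4
base_channels: 32
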