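# CPU-scale smoke profile: 64x64 synthetic scenes, depth-2/base-8 U-Net.
# The reference protocol (300 epochs, batch 4, Adam 1e-4, 128x128 inputs)
# is the CLI default; this profile trades resolution and width for minutes
# of CPU time while keeping every pipeline stage intact.
seed: 0
n: 120
epochs: 100
depth: 2
base_channels: 8
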