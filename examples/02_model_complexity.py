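"""Inspect the network: stage table, parameter count, compute cost.

Prints the layer-by-layer architecture summary and the analytic complexity
accounting for the two standard input sizes, then verifies the analytic
parameter count against an instantiated model.
"""

from hbpnet import NetConfig, build_model, count_macs, count_parameters, summary

cfg = NetConfig(input_dims=(128, 128, 128))
print(summary(cfg))

p = count_parameters(cfg)
m128 = count_macs(cfg, (128, 128, 128))
m160 = count_macs(cfg, (160, 128, 128))
print(f"\nparameters:        {p:,}  ({p / 1e6:.3f} M)")
print(f"MACs @ 128 frames: {m128:,}  ({m128 / 1e9:.3f} G)")
print(f"MACs @ 160 frames: {m160:,}  ({m160 / 1e9:.3f} G)")
print(f"MAC ratio equals 160/128 exactly: {m160 * 128 == m128 * 160}")

model = build_model(cfg, seed=0)
print(f"instantiated model parameters: {model.n_parameters():,} "
      f"(matches analytic count: {model.n_parameters() == p})")
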