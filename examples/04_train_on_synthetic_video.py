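"""End-to-end: train the reduced network on synthetic video, recover HR.

Runs the package's canonical desk-scale experiment: simulate recordings at
known heart rates, train the reduced network on heartbeat-probability
labels, and estimate held-out heart rates from the predicted curves.
Takes a few minutes on one CPU.
"""

from hbpnet.evaluation import scaled_down_recovery

result = scaled_down_recovery(seed=0)

print(f"confidence threshold (grid-searched): {result.confidence}")
print(f"final training loss: {result.final_train_loss:.3f}   "
      f"validation loss: {result.final_val_loss:.3f}")
print("\nheld-out recordings:")
for pred, true in zip(result.predictions, result.truths):
    print(f"  true {true:6.1f} bpm   predicted {pred:6.1f} bpm")
print(f"\ntrained   MAE: {result.mae_trained:.2f} bpm")
print(f"untrained MAE: {result.mae_untrained:.2f} bpm")
print("\nThe trained network locks onto the pulse phase in the green"
      "\nchannel and generalizes to heart rates it never saw; the"
      "\nuntrained baseline produces an unusable, noisy curve.")
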