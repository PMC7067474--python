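"""Probe the stability of the orientation code across time and space.

Three analyses on one synthetic participant:
1. leave-one-out decoding of impulse identity (is there a time-specific
   pattern? chance = 50%),
2. orientation decoding trained on one impulse epoch and tested on the
   other (does the orientation code generalise across the delay?),
3. orientation decoding trained on one cued location and tested on the
   other (is the code location specific?).

The generator mimics the hybrid regime: a time stamp separates the two
impulses, the orientation code carries across them, and the code does not
transfer between presentation sides.
"""

import wmdrift as wd

cfg = wd.SynthConfig(n_participants=1, n_trials=320, n_channels=8, seed=2)
epochs, table, _ = wd.generate_dataset(cfg)
ori = table["cued_orientation"].to_numpy()
side = table["cue_side"].to_numpy()
f1 = wd.featurize(epochs["impulse1"])
f2 = wd.featurize(epochs["impulse2"])

loo = wd.decode_impulse_loo(f1, f2)
print(f"impulse identity (LOO): {loo.accuracy:.1f}% correct (chance 50%)")

r12, r21 = wd.cross_impulse_reconstruct(f1, f2, ori, n_repeats=5, rng=0)
cross = (r12.accuracies + r21.accuracies) / 2
within = wd.reconstruct(f2, ori, n_repeats=5, rng=0).accuracies
print(f"orientation, within impulse 2:   {within.mean():.4f} (a.u.)")
print(f"orientation, across impulses:    {cross.mean():.4f} (a.u.)")

xloc = wd.cross_location_reconstruct(f2, ori, side, n_repeats=10, rng=0)
print(f"orientation, across locations:   {xloc.accuracies.mean():.4f} (a.u.)")

print("\nreading: the impulses are perfectly separable in time, the "
      "orientation code generalises across them, and it does not "
      "generalise across presentation sides.")
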