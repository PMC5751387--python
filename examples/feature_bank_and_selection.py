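"""Extract the movement-planning feature bank and prune it unsupervised.

Generates labeled gait-planning / rest epochs, spatially filters the three
target channels, computes the 12-feature bank (36 features over Cz, CP1,
CP2) on sliding 250 ms windows, and runs the representation-entropy / MICI
selection.  The printed ledger shows which features were deemed redundant
and the entropy trajectory of the working set.
"""

import numpy as np
import pandas as pd

from adaptref import (
    FilterConfig,
    filter_record,
    gen_gait_epochs,
    load_builtin_montage,
    select_features,
    sliding_features,
)

montage = load_builtin_montage("gait_1020")
epochs, truth = gen_gait_epochs(channels=montage.electrodes, seed=3)

frames = []
for ep in epochs[:20]:
    filtered, _ = filter_record(
        ep.record.data, ep.record.channels, truth.fs, montage,
        montage.targets, FilterConfig(mode="ad_war"),
    )
    data = np.vstack([filtered[t] for t in montage.targets])
    frames.append(sliding_features(data, truth.fs, montage.targets, stride=50))
feats = pd.concat(frames, ignore_index=True).drop(columns="end_sample")

print(f"feature matrix: {feats.shape[0]} windows x {feats.shape[1]} features")
ledger = select_features(feats, n_subsets=50, seed=3)
print(f"selected {len(ledger.selected)} / {feats.shape[1]} features")
print(f"RE trajectory: {[round(v, 3) for v in ledger.re_history]}")
print(f"thresholds:    {[round(v, 3) for v in ledger.threshold_history]}")
for rec in ledger.removed_pairs:
    print(f"redundant pair {rec['pair']} (MICI {rec['mici']:.3g}) "
          f"-> kept {rec['winner']}")
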