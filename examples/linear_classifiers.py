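"""Train the two linear decoders on windowed mean-amplitude features.

Features are the per-channel, per-chromophore temporal means over the
0-5 / 5-10 / 10-15 s windows of each epoch (96 features for the 16-channel
montage).  Shows shrinkage LDA with the analytic (Ledoit-Wolf) intensity
and the 50-learner bagged regularized-LDA ensemble.
"""

import numpy as np

import nirsbci as nb

cfg = nb.SimulationConfig(n_subjects=2, rng_seed=1)
recs, _, _ = nb.simulate_dataset(cfg)
ep = nb.epochs_from_recordings(recs)
feats = nb.extract_mean_features(ep)
print(f"feature matrix: {feats.values.shape} (trials x features), "
      f"first name: {feats.feature_names[0]}")

slda = nb.fit_slda(feats)
print(f"shrinkage LDA: analytic gamma = {slda.shrinkage_intensity:.3f}")
acc = np.mean(nb.predict_lda(slda, feats) == feats.labels)
print(f"training accuracy {100 * acc:.1f}% (optimistic: same-subject resubstitution)")

bag = nb.fit_bagged_rlda(feats, seed=0)
acc_bag = np.mean(nb.predict_vote(bag, feats) == feats.labels)
print(f"bagged rLDA (50 learners, gamma 0.1): training accuracy {100 * acc_bag:.1f}%")
print("Both decoders operate on identical features; the honest comparison "
      "is leave-one-subject-out - see loso_comparison.py.")
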