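"""Train a small network on phantoms and segment a held-out case.

Uses a two-level network and tiny patches so the whole script runs in about
a minute on one CPU; the pipeline (sampling, masked Dice loss, validation
Jaccard, best-checkpoint selection, tiled inference, morphological
post-processing) is identical to a full-scale run.
"""

import numpy as np

import hepaseg as hs


def make_cases(n, seed0, lesion_counts=(1, 2)):
    cases = []
    for i in range(n):
        spec = hs.PhantomSpec(shape=(48, 48, 16), lesion_radius_mm=(4.0, 7.0),
                              n_lesions=lesion_counts[i % len(lesion_counts)],
                              seed=seed0 + i)
        v, liver, lesions = hs.generate_phantom(spec)
        img, lv, (ls,), _ = hs.preprocess_case(v, liver, [lesions])
        cases.append(hs.Case(name=f"case{i}", image=img, liver=lv, lesions=ls))
    return cases


net_cfg = hs.NetworkConfig(levels=2, base_features=2, max_features=4,
                           dropout=0.0, zconv_levels=(2,), zconvs_per_conv=1)
train_cfg = hs.TrainConfig(batch_size=1, learning_rate=3e-3,
                           total_iterations=200, val_interval=50,
                           input_patch=(24, 24, 9))

train_cases = make_cases(4, 0)
val_cases = make_cases(1, 100)
test_case = make_cases(1, 200)[0]

net = hs.AUNet(net_cfg, seed=0)
state, trainer = hs.train_model(net, train_cases, val_cases, train_cfg, seed=0)
print("validation Jaccard:", [(it, round(j, 3)) for it, j in state.history])
print(f"best checkpoint: iteration {state.best_iteration} "
      f"(Jaccard {state.best_jaccard:.3f})")

prob = hs.predict_volume(net, test_case.image, test_case.liver, trainer.geometry)
pred = hs.postprocess_prediction(prob, test_case.liver)
print(f"held-out case: Dice {hs.dice(pred, test_case.lesions):.3f} vs ground truth")
counts = hs.detection_metrics(hs.match_lesions(test_case.lesions, pred))
print(f"detection: recall {counts.recall:.2f}, precision {counts.precision:.2f}, "
      f"false positives {counts.fpc}")
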