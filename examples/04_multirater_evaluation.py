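"""Multi-rater evaluation: uncertainty-aware score and N:M detection.

Simulates three disagreeing raters from one phantom's ground truth and
scores a prediction against all of them. Shows how the uncertainty-aware
score phi relates the algorithm's discrepancy to the raters' own
disagreement (phi >= 0.9 means human-level at alpha = 0.1), and how lesion
detection is counted through N:M correspondences.
"""

import numpy as np

import hepaseg as hs

_, _, lesions = hs.generate_phantom(hs.PhantomSpec(n_lesions=3, seed=7))
raters = hs.simulate_raters(lesions, n_raters=3, magnitude_mm=2.0, seed=1,
                            drop_prob=0.0)

# a plausible "algorithm": the ground truth slightly perturbed
(pred,) = hs.simulate_raters(lesions, 1, magnitude_mm=2.0, seed=99, drop_prob=0.0)

scores = hs.score_case(pred, raters)
print("Dice vs raters:   ", [round(d, 3) for d in scores.rater_dice],
      f"-> mean {scores.mean_rater_dice:.3f}")
print("inter-rater Dice: ", [round(d, 3) for d in scores.pairwise_dice],
      f"-> mean {scores.mean_pairwise_dice:.3f}")
print(f"discrepancies: algorithm {scores.eps_hat:.3f} vs raters {scores.eps_bar:.3f}")
print(f"uncertainty-aware score phi = {scores.phi:.3f} "
      f"({'>= 0.9: human-level' if scores.phi >= 0.9 else 'below human-level'})")

cs = hs.match_lesions(raters[0], pred)
counts = hs.detection_metrics(cs)
print(f"\ncorrespondences vs rater 1: "
      f"{[(c.ref_ids, c.pred_ids, round(c.dice, 3)) for c in cs.correspondences]}")
print(f"detection: TP {counts.tp}, FP {counts.fp}, FN {counts.fn} -> "
      f"recall {counts.recall:.2f}, precision {counts.precision:.2f}, "
      f"F1 {counts.f1:.2f}, FPC {counts.fpc}")

# paired significance testing across a small cohort of cases
phis_a, phis_b = [], []
for seed in range(10):
    _, _, les = hs.generate_phantom(hs.PhantomSpec(n_lesions=2, seed=100 + seed))
    panel = hs.simulate_raters(les, 3, 2.0, seed=seed, drop_prob=0.0)
    (good,) = hs.simulate_raters(les, 1, 0.5, seed=500 + seed, drop_prob=0.0)
    (bad,) = hs.simulate_raters(les, 1, 3.0, seed=900 + seed, drop_prob=0.0)
    phis_a.append(hs.score_case(good, panel).phi)
    phis_b.append(hs.score_case(bad, panel).phi)
df = hs.paired_tests({"mild_vs_strong_perturbation": (phis_a, phis_b)})
print("\npaired Wilcoxon + Benjamini-Hochberg:")
print(df.to_string(index=False))
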