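"""Multi-rater scoring, lesion correspondence matching, and paired testing."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

import hepaseg as hs
from hepaseg.evaluate import match_lesions, score_case, uncertainty_aware_score


def _mask(data, spacing=(1, 1, 1)):
    return hs.MaskVolume(np.asarray(data, np.uint8), spacing)


# --------------------------------------------------------------------- dice

class TestDice:
    def test_identical_disjoint_and_counting(self):
        a = np.zeros((4, 4, 1), np.uint8)
        a[:2, :2, 0] = 1
        assert hs.dice(a, a) == 1.0
        b = np.zeros_like(a)
        b[2:, 2:, 0] = 1
        assert hs.dice(a, b) == 0.0
        c = np.zeros_like(a)
        c[1:3, :2, 0] = 1              # |a| = |c| = 4, overlap 2 -> 0.5
        assert hs.dice(a, c) == 0.5

    def test_symmetry_and_empty_convention(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = (rng.random((5, 5, 2)) < 0.4).astype(np.uint8)
            b = (rng.random((5, 5, 2)) < 0.4).astype(np.uint8)
            assert hs.dice(a, b) == hs.dice(b, a)
        z = np.zeros((3, 3, 1), np.uint8)
        assert hs.dice(z, z) == 1.0


# --------------------------------------------------- uncertainty-aware score

class TestUncertaintyAwareScore:
    def test_equal_discrepancies_give_human_level_mark(self):
        # eps_hat == eps_bar -> phi = 1 - alpha = 0.9 at alpha = 0.1
        assert uncertainty_aware_score(0.8, 0.8, alpha=0.1) == pytest.approx(0.9)

    def test_perfect_agreement_gives_one(self):
        assert uncertainty_aware_score(1.0, 0.8, alpha=0.1) == 1.0

    def test_clamped_at_zero(self):
        # eps_hat = 16 * eps_bar (both exactly representable) -> clamped to 0
        assert uncertainty_aware_score(0.5, 0.96875, alpha=0.1) == 0.0
        # at the exact 10x boundary the unclamped value is already ~0
        assert uncertainty_aware_score(0.5, 0.95, alpha=0.1) == pytest.approx(0.0, abs=1e-12)

    def test_summary_dice_example(self):
        # 1 - 0.1 * 0.262 / 0.219
        phi = uncertainty_aware_score(0.738, 0.781, alpha=0.1)
        assert phi == pytest.approx(1 - 0.1 * 0.262 / 0.219, abs=1e-12)
        assert phi == pytest.approx(0.8804, abs=5e-4)

    def test_perfect_rater_agreement_is_undefined(self):
        with pytest.raises(ValueError, match="perfect"):
            uncertainty_aware_score(0.9, 1.0)

    def test_monotonicity(self):
        grid = np.linspace(0.1, 0.95, 15)
        phis = [uncertainty_aware_score(d, 0.8) for d in grid]
        assert all(a <= b + 1e-12 for a, b in zip(phis, phis[1:]))
        alphas = [uncertainty_aware_score(0.7, 0.8, alpha=a)
                  for a in (0.05, 0.1, 0.2, 0.5)]
        assert all(a >= b - 1e-12 for a, b in zip(alphas, alphas[1:]))


# --------------------------------------------------------- component labeling

class TestLabelLesions:
    def test_empty_mask_zero_components(self):
        labels, n = hs.label_lesions(_mask(np.zeros((4, 4, 2))))
        assert n == 0 and not labels.any()

    def test_diagonal_voxels_are_two_components(self):
        data = np.zeros((3, 3, 1))
        data[0, 0, 0] = data[1, 1, 0] = 1
        _, n = hs.label_lesions(_mask(data))
        assert n == 2

    def test_phantom_lesion_count_matches_generator(self, phantom_case):
        _, _, lesions = phantom_case
        _, n = hs.label_lesions(lesions)
        assert n == 3


# ------------------------------------------------------ correspondence match

def brute_force_best_mean_dice(ref_labels, n_ref, pred_labels, n_pred):
    """Independent exhaustive oracle over all overlap-edge subsets.

    Groups are connected components of the kept-edge bipartite graph;
    components without any partner count as zero-Dice singletons.
    """
    ref_sizes = [int((ref_labels == i + 1).sum()) for i in range(n_ref)]
    pred_sizes = [int((pred_labels == j + 1).sum()) for j in range(n_pred)]
    overlap = np.zeros((n_ref, n_pred), int)
    for i in range(n_ref):
        for j in range(n_pred):
            overlap[i, j] = int(((ref_labels == i + 1) & (pred_labels == j + 1)).sum())
    all_edges = [(i, j) for i in range(n_ref) for j in range(n_pred)
                 if overlap[i, j] > 0]

    def mean_dice(edges):
        # union-find free grouping by repeated expansion
        nodes = [("r", i) for i in range(n_ref)] + [("p", j) for j in range(n_pred)]
        adj = {node: set() for node in nodes}
        for i, j in edges:
            adj[("r", i)].add(("p", j))
            adj[("p", j)].add(("r", i))
        seen, dices = set(), []
        for node in nodes:
            if node in seen:
                continue
            stack, comp = [node], []
            while stack:
                cur = stack.pop()
                if cur in seen:
                    continue
                seen.add(cur)
                comp.append(cur)
                stack.extend(adj[cur])
            refs = [i for kind, i in comp if kind == "r"]
            preds = [j for kind, j in comp if kind == "p"]
            ov = sum(overlap[i, j] for i in refs for j in preds)
            size = sum(ref_sizes[i] for i in refs) + sum(pred_sizes[j] for j in preds)
            dices.append(2 * ov / size if size else 1.0)
        return float(np.mean(dices)) if dices else 1.0

    best = -1.0
    for k in range(len(all_edges) + 1):
        for subset in itertools.combinations(all_edges, k):
            best = max(best, mean_dice(list(subset)))
    return best


def random_instance(rng, shape=(24, 24, 1), max_components=8):
    """Random pair of small masks with at most ``max_components`` components."""
    while True:
        ref = np.zeros(shape, np.uint8)
        pred = np.zeros(shape, np.uint8)
        for arr in (ref, pred):
            for _ in range(rng.integers(1, 4)):
                x, y = rng.integers(0, shape[0] - 6, 2)
                w, h = rng.integers(2, 7, 2)
                arr[x:x + w, y:y + h, 0] = 1
        struct = ndimage.generate_binary_structure(3, 1)
        _, nr = ndimage.label(ref, structure=struct)
        _, np_ = ndimage.label(pred, structure=struct)
        if 1 <= nr + np_ <= max_components:
            return ref, pred


class TestMatchLesions:
    def test_identity_yields_one_to_one_perfect_matches(self, phantom_case):
        _, _, lesions = phantom_case
        cs = match_lesions(lesions, lesions)
        assert len(cs.correspondences) == 3
        assert all(c.dice == 1.0 and len(c.ref_ids) == 1 and len(c.pred_ids) == 1
                   for c in cs.correspondences)
        assert not cs.unmatched_ref and not cs.unmatched_pred

    def test_split_prediction_forms_one_to_two_group(self):
        """A 10-voxel lesion predicted as two 4-voxel pieces inside it."""
        ref = np.zeros((12, 5, 1))
        ref[1:11, 2, 0] = 1                 # 10 voxels in a line
        pred = np.zeros_like(ref)
        pred[1:5, 2, 0] = 1                 # 4 voxels
        pred[7:11, 2, 0] = 1                # 4 voxels, separate component
        cs = match_lesions(_mask(ref), _mask(pred))
        assert len(cs.correspondences) == 1
        corr = cs.correspondences[0]
        assert len(corr.ref_ids) == 1 and len(corr.pred_ids) == 2
        assert corr.dice == pytest.approx(2 * 8 / (10 + 8))

    def test_weak_overlap_still_forms_correspondence(self):
        """Dice 0.15 pair stays matched; thresholding happens downstream."""
        ref = np.zeros((42, 3, 1))
        ref[0:20, 1, 0] = 1                 # 20 voxels
        pred = np.zeros_like(ref)
        pred[17:37, 1, 0] = 1               # 20 voxels, overlap 3 -> dice 0.15
        cs = match_lesions(_mask(ref), _mask(pred))
        assert len(cs.correspondences) == 1
        assert cs.correspondences[0].dice == pytest.approx(0.15)
        counts = hs.detection_metrics(cs)
        assert (counts.tp, counts.fp, counts.fn) == (0, 1, 1)

    def test_matches_brute_force_on_random_small_instances(self):
        """100 seeded random instances with <= 8 components: the matcher's
        mean per-correspondence Dice equals the exhaustive optimum."""
        rng = np.random.default_rng(2024)
        for trial in range(100):
            ref, pred = random_instance(rng)
            struct = ndimage.generate_binary_structure(3, 1)
            ref_labels, nr = ndimage.label(ref, structure=struct)
            pred_labels, np_ = ndimage.label(pred, structure=struct)
            cs = match_lesions(_mask(ref), _mask(pred))
            optimum = brute_force_best_mean_dice(ref_labels, nr, pred_labels, np_)
            assert cs.mean_dice() == pytest.approx(optimum, abs=1e-9), \
                f"trial {trial}: greedy {cs.mean_dice()} vs optimum {optimum}"

    def test_component_conservation(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            ref, pred = random_instance(rng)
            cs = match_lesions(_mask(ref), _mask(pred))
            matched_ref = sum(len(c.ref_ids) for c in cs.correspondences)
            matched_pred = sum(len(c.pred_ids) for c in cs.correspondences)
            assert matched_ref + len(cs.unmatched_ref) == cs.n_ref
            assert matched_pred + len(cs.unmatched_pred) == cs.n_pred


# ----------------------------------------------------------- detection counts

class TestDetectionMetrics:
    def test_formula_evaluation(self):
        cs = hs.CorrespondenceSet(
            correspondences=[hs.Correspondence((1,), (1,), 0.9),
                             hs.Correspondence((2,), (2,), 0.8),
                             hs.Correspondence((3,), (3,), 0.7),
                             hs.Correspondence((4,), (4,), 0.1)],
            unmatched_ref=[5], unmatched_pred=[], n_ref=5, n_pred=4)
        d = hs.detection_metrics(cs)
        assert (d.tp, d.fp, d.fn) == (3, 1, 2)
        assert d.recall == pytest.approx(0.6)
        assert d.precision == pytest.approx(0.75)
        assert d.f1 == pytest.approx(6 / 9)
        assert d.fpc == 1

    def test_perfect_match(self, phantom_case):
        _, _, lesions = phantom_case
        d = hs.detection_metrics(match_lesions(lesions, lesions))
        assert (d.recall, d.precision, d.f1, d.fpc) == (1.0, 1.0, 1.0, 0)

    def test_empty_prediction_conventions(self, phantom_case):
        _, _, lesions = phantom_case
        empty = lesions.like(np.zeros_like(lesions.data))
        d = hs.detection_metrics(match_lesions(lesions, empty))
        assert d.recall == 0.0
        assert d.precision == 1.0          # no positive calls
        assert d.fpc == 0

    def test_detection_count_conservation(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            ref, pred = random_instance(rng)
            cs = match_lesions(_mask(ref), _mask(pred))
            d = hs.detection_metrics(cs)
            sub = sum(1 for c in cs.correspondences if c.dice <= 0.2)
            assert d.tp + len(cs.unmatched_ref) + sub == \
                len(cs.correspondences) + len(cs.unmatched_ref)


# ------------------------------------------------------------------ score_case

class TestScoreCase:
    def test_identical_raters_exercise_undefined_phi(self, phantom_case):
        _, _, lesions = phantom_case
        scores = score_case(lesions, [lesions, lesions, lesions])
        assert scores.rater_dice == [1.0, 1.0, 1.0]
        assert scores.eps_bar == 0.0
        assert not scores.phi_defined

    def test_prediction_equal_to_one_rater_scores_high(self, phantom_case):
        """When the prediction IS one rater, its mean discrepancy is below the
        inter-rater discrepancy, so phi exceeds the 0.9 human-level mark."""
        _, _, lesions = phantom_case
        raters = hs.simulate_raters(lesions, 3, magnitude_mm=2.0, seed=21,
                                    drop_prob=0.0)
        scores = score_case(raters[0], raters)
        assert scores.rater_dice[0] == 1.0
        assert scores.phi_defined
        assert scores.phi > 0.9

    def test_hand_evaluated_phi(self):
        # mean algo dice 0.7, inter-rater 0.8 -> 1 - 0.1 * (0.3 / 0.2) = 0.85
        assert uncertainty_aware_score(0.7, 0.8, 0.1) == pytest.approx(0.85)

    def test_single_rater_has_no_phi(self, phantom_case):
        _, _, lesions = phantom_case
        scores = score_case(lesions, [lesions])
        assert not scores.phi_defined
        assert scores.mean_rater_dice == 1.0


# ---------------------------------------------------------------- paired tests

class TestPairedTests:
    def test_identical_samples_not_rejected(self):
        x = np.linspace(0.3, 0.9, 12)
        df = hs.paired_tests({"a_vs_b": (x, x)})
        assert not df["reject"].any()
        assert df["p_raw"].iloc[0] == 1.0

    def test_benjamini_hochberg_step_up_rule(self, monkeypatch):
        """p-values {0.01, 0.02, 0.04, 0.2} at FDR 0.05: exactly the two
        smallest are rejected (largest k with p_(k) <= k/4 * 0.05 is k = 2)."""
        from hepaseg import evaluate as ev
        fixed = iter([0.01, 0.02, 0.04, 0.2])

        class _R:
            def __init__(self):
                self.pvalue = next(fixed)

        monkeypatch.setattr(ev.stats, "wilcoxon",
                            lambda a, b, alternative: _R())
        x = np.arange(8.0)
        df = hs.paired_tests({f"c{i}": (x, x + i + 1) for i in range(4)})
        assert list(df["reject"]) == [True, True, False, False]

    def test_single_comparison_reduces_to_plain_level(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20)
        b = a + 1.5                          # strong paired shift
        df = hs.paired_tests({"shift": (a, b)})
        assert df["reject"].iloc[0]
        assert df["p_adjusted"].iloc[0] == pytest.approx(df["p_raw"].iloc[0])

    def test_clear_difference_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.7, 0.05, 19)
        b = a - 0.04                          # consistent paired decrease
        df = hs.paired_tests({"a_vs_b": (a, b)})
        assert df["reject"].iloc[0]

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            hs.paired_tests({"bad": (np.ones(5), np.ones(6))})
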