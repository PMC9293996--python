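"""Patch sampling, liver-masked Dice loss, and the optimization loop.

Training is a binary voxel classification (lesion vs. everything else,
including liver parenchyma) driven by randomly sampled patches. Patches are
biased toward lesions: 90 % must contain at least one tumor voxel in their
loss-contributing (output) region and the remaining 10 % at least one liver
voxel, enforced as a deterministic 9:1 cycle. The Dice loss is computed
within a dilated liver mask only, so voxels far outside the liver never
drive the gradients. Validation runs every ``val_interval`` iterations (and
at the end of every training segment): full-volume predictions on the
validation cases are binarized at 0.5 within the (undilated) liver mask and
scored with the Jaccard coefficient; the parameter state with the highest
validation Jaccard (ties: earliest) is kept as the final model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .augment import AugmentConfig, augment_patch
from .config import TrainConfig
from .nn import Adam, AUNet, PatchGeometry, compute_patch_geometry, predict_volume, reflect_pad
from .volume import MaskVolume, Volume

log = logging.getLogger("hepaseg")


# ---------------------------------------------------------------- case data

@dataclass
class Case:
    """One preprocessed training/validation case."""

    name: str
    image: Volume
    liver: MaskVolume
    lesions: MaskVolume
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.image.check_same_grid(self.liver)
        self.image.check_same_grid(self.lesions)

    def padded(self, key: str, data: np.ndarray, pad: tuple[int, int, int]) -> np.ndarray:
        tag = (key, pad)
        if tag not in self._cache:
            self._cache[tag] = reflect_pad(np.ascontiguousarray(data), pad)
        return self._cache[tag]

    def voxel_pool(self, which: str) -> np.ndarray:
        if which not in self._cache:
            mask = self.lesions.data if which == "lesion" else self.liver.data
            self._cache[which] = np.argwhere(mask > 0)
        return self._cache[which]


def dilate_liver(liver: MaskVolume, r_inplane: int = 5, r_z: int = 1) -> np.ndarray:
    """Dilate the liver per slice by a disk, then across slices.

    The dilation defines the loss weight mask; it includes the liver border
    context (the region the morphological post-processing later targets).
    """
    x, y = np.ogrid[-r_inplane:r_inplane + 1, -r_inplane:r_inplane + 1]
    disk = (x ** 2 + y ** 2 <= r_inplane ** 2)[:, :, None]
    out = ndimage.binary_dilation(liver.data > 0, structure=disk)
    if r_z > 0:
        line = np.ones((1, 1, 2 * r_z + 1), dtype=bool)
        out = ndimage.binary_dilation(out, structure=line)
    return out


# ------------------------------------------------------------------- losses

def masked_dice_loss(pred: np.ndarray, target: np.ndarray, weight: np.ndarray,
                     smooth: float = 1.0, with_grad: bool = False):
    """Dice loss restricted to ``weight == 1`` voxels.

    loss = 1 - (2 * sum(w p t) + s) / (sum(w p) + sum(w t) + s), s = smooth.
    Only voxels with weight 1 contribute. An all-zero weight patch gives the
    smoothed degenerate value 0 (logged); gradients are then zero.
    """
    if not (pred.shape == target.shape == weight.shape):
        raise ValueError("pred/target/weight shape mismatch")
    w = weight.astype(np.float64)
    p = pred.astype(np.float64)
    t = target.astype(np.float64)
    if not w.any():
        log.warning("degenerate batch: all-zero weight patch, Dice loss = 0")
        return (0.0, np.zeros_like(p, np.float32)) if with_grad else 0.0
    wp, wt, wpt = float((w * p).sum()), float((w * t).sum()), float((w * p * t).sum())
    num = 2.0 * wpt + smooth
    den = wp + wt + smooth
    loss = 1.0 - num / den
    if not with_grad:
        return loss
    grad = -(2.0 * w * t * den - num * w) / den ** 2
    return loss, grad


def jaccard(pred: np.ndarray, ref: np.ndarray) -> float:
    """|intersection| / |union| of two binary arrays; 1 when both are empty."""
    if pred.shape != ref.shape:
        raise ValueError("shape mismatch")
    p = pred > 0
    r = ref > 0
    union = int(np.logical_or(p, r).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(p, r).sum()) / union


# ----------------------------------------------------------------- sampling

def sample_patch(case: Case, geometry: PatchGeometry, tumor_biased: bool,
                 rng: np.random.Generator,
                 weight_mask: np.ndarray | None = None,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one (image, label, weight) patch triple at the input extent.

    The patch position is chosen so that the output-sized central region
    contains at least one lesion voxel (tumor-biased) or liver voxel
    (unbiased). A tumor-biased request on a case without lesions falls back
    to liver-biased (logged). All three patches are read at the input extent
    with mirror padding at volume borders, so flips in augmentation act
    identically; the loss later uses only the central output region.
    """
    if weight_mask is None:
        weight_mask = dilate_liver(case.liver)
    if tumor_biased and case.voxel_pool("lesion").size == 0:
        log.info("case %s has no lesions; tumor-biased sample falls back to liver",
                 case.name)
        tumor_biased = False
    pool = case.voxel_pool("lesion" if tumor_biased else "liver")
    if pool.size == 0:
        raise ValueError(f"case {case.name} has an empty liver mask")
    voxel = pool[rng.integers(len(pool))]
    oext, margin = geometry.output_extent, geometry.margin
    origin = np.array([rng.integers(v - e + 1, v + 1) for v, e in zip(voxel, oext)])

    pad = tuple(m + e for m, e in zip(margin, oext))  # covers any admissible window
    start = origin - margin + pad
    stop = start + np.array(geometry.input_extent)
    sl = tuple(slice(a, b) for a, b in zip(start, stop))
    img = case.padded("image", case.image.data.astype(np.float32), pad)[sl]
    label = case.padded("label", case.lesions.data, pad)[sl]
    weight = case.padded("weight", weight_mask.astype(np.uint8), pad)[sl]
    return img.copy(), label.copy(), weight.copy()


# ------------------------------------------------------------ training loop

@dataclass
class TrainState:
    """Bookkeeping of one training run."""

    iteration: int = 0
    history: list[tuple[int, float]] = field(default_factory=list)  # (iter, val Jaccard)
    losses: list[tuple[int, float]] = field(default_factory=list)
    best_iteration: int = -1
    best_jaccard: float = -np.inf

    def jaccard_at(self, iteration: int) -> float:
        for it, j in self.history:
            if it == iteration:
                return j
        raise KeyError(f"no validation record at iteration {iteration}")


class Trainer:
    """Stateful training driver; supports segment-wise runs for halving."""

    def __init__(self, net: AUNet, cases: list[Case], val_cases: list[Case],
                 cfg: TrainConfig, augment_cfg: AugmentConfig | None = None,
                 seed: int = 0) -> None:
        if not cases or not val_cases:
            raise ValueError("need at least one training and one validation case")
        self.net = net
        self.cases = cases
        self.val_cases = val_cases
        self.cfg = cfg
        self.augment_cfg = augment_cfg if augment_cfg is not None else AugmentConfig()
        self.seed = seed
        self.rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A1]))
        self.opt = Adam(net.params(), lr=cfg.learning_rate)
        self.geometry = compute_patch_geometry(net.cfg, cfg.input_patch)
        self.state = TrainState()
        self._patch_counter = 0
        self._tumor_per_cycle = int(round(10 * cfg.tumor_fraction))
        self._weights = {c.name: dilate_liver(c.liver, cfg.liver_dilate_inplane,
                                              cfg.liver_dilate_z)
                         for c in cases}
        self._best_state: dict | None = None

    # -- patch scheduling: deterministic 9:1 tumor/liver cycle
    def _next_patch(self):
        tumor = (self._patch_counter % 10) < self._tumor_per_cycle
        self._patch_counter += 1
        case = self.cases[self.rng.integers(len(self.cases))]
        img, label, weight = sample_patch(case, self.geometry, tumor, self.rng,
                                          self._weights[case.name])
        if self.augment_cfg.enabled:
            img, label, weight = augment_patch(img, label, weight,
                                               self.augment_cfg, self.rng)
        m = self.geometry.margin
        o = self.geometry.output_extent
        core = tuple(slice(mm, mm + oo) for mm, oo in zip(m, o))
        return img, label[core], weight[core]

    def _step(self) -> float:
        cfg = self.cfg
        batch = [self._next_patch() for _ in range(cfg.batch_size)]
        x = np.stack([b[0] for b in batch])[:, None].astype(np.float32)
        self.net.zero_grad()
        probs = self.net.forward(x, training=True)
        losses = []
        gp = np.zeros_like(probs)
        for n, (_, label, weight) in enumerate(batch):
            loss, grad = masked_dice_loss(probs[n, 0], label, weight,
                                          smooth=cfg.dice_smooth, with_grad=True)
            losses.append(loss)
            gp[n, 0] = grad / cfg.batch_size
        self.net.backward(gp)
        self.opt.step()
        loss = float(np.mean(losses))
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss {loss} at iteration {self.state.iteration + 1}; "
                f"per-patch losses: {losses}")
        return loss

    def validate(self) -> float:
        """Mean validation Jaccard (binarized at 0.5 within the liver mask)."""
        scores = []
        for case in self.val_cases:
            prob = predict_volume(self.net, case.image, case.liver, self.geometry)
            pred = (prob.data > 0.5) & (case.liver.data > 0)
            scores.append(jaccard(pred, case.lesions.data > 0))
        return float(np.mean(scores))

    def _record_validation(self) -> None:
        it = self.state.iteration
        j = self.validate()
        self.state.history.append((it, j))
        if j > self.state.best_jaccard:   # strict: ties keep the earliest
            self.state.best_jaccard = j
            self.state.best_iteration = it
            self._best_state = {k: v.copy() for k, v in self.net.state_dict().items()}
        log.info("iteration %d: validation Jaccard %.4f (best %.4f @ %d)",
                 it, j, self.state.best_jaccard, self.state.best_iteration)

    def run(self, until_iteration: int) -> TrainState:
        """Train to the given cumulative iteration; validates periodically
        and always at the segment end."""
        cfg = self.cfg
        while self.state.iteration < until_iteration:
            loss = self._step()
            self.state.iteration += 1
            self.state.losses.append((self.state.iteration, loss))
            if (self.state.iteration % cfg.val_interval == 0
                    or self.state.iteration == until_iteration):
                self._record_validation()
        return self.state

    def restore_best(self) -> None:
        """Load the parameter state with the highest validation Jaccard."""
        if self._best_state is not None:
            self.net.load_state_dict(self._best_state)

    @property
    def best_state(self) -> dict | None:
        return self._best_state


def train_model(net: AUNet, cases: list[Case], val_cases: list[Case],
                cfg: TrainConfig, augment_cfg: AugmentConfig | None = None,
                seed: int = 0) -> tuple[TrainState, Trainer]:
    """Train for ``cfg.total_iterations`` and restore the best checkpoint."""
    trainer = Trainer(net, cases, val_cases, cfg, augment_cfg, seed=seed)
    state = trainer.run(cfg.total_iterations)
    trainer.restore_best()
    return state, trainer
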