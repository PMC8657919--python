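"""Crop-based training: grids, MSA subsampling, the weighted loss, and the
epoch loop.

Each epoch lays a freshly offset non-overlapping crop grid over every
domain's L x L map (so the network sees different crops every epoch) and
re-derives input features from a fresh 50% subsample of the domain's MSA.
The loss is a weighted sum of five cross-entropies — distances plus the
four per-residue auxiliary tasks — with printed weights 15 (dist), 0.5
(SS), 0.25 (phi), 0.25 (psi) and 0.5 (ASA).  Validation uses static
offset-(0, 0) grids, and the three checkpoints with the lowest validation
loss are retained.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import nn
from .featurization import CH_MASK, PairwiseInput, featurize
from .io_formats import Alignment
from .labeling import IGNORE, LabelSet
from .network import AUX_HEAD_SIZES, CropPrediction, DistogramNetwork


# ---------------------------------------------------------------------------
# crops
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CropSpec:
    """One grid cell: a c x c window over the pairwise map.

    ``origin`` is the clipped 0-based start of the real (unpadded) region;
    ``pad`` = (top, bottom, left, right) zero-padding applied when the grid
    cell extends past the sequence.
    """

    origin: tuple[int, int]
    size: int
    pad: tuple[int, int, int, int] = (0, 0, 0, 0)

    @property
    def rows(self) -> slice:
        t, b, _, _ = self.pad
        return slice(self.origin[0], self.origin[0] + self.size - t - b)

    @property
    def cols(self) -> slice:
        _, _, l, r = self.pad
        return slice(self.origin[1], self.origin[1] + self.size - l - r)


def _axis_cells(L: int, c: int, d: int) -> list[tuple[int, int, int]]:
    """(start, pad_before, pad_after) for each grid cell along one axis."""
    cells = []
    g = -d
    while g < L:
        lo, hi = max(g, 0), min(g + c, L)
        if hi > lo:
            cells.append((lo, lo - g, g + c - hi))
        g += c
    return cells


def crop_grid(L: int, c: int, offset: tuple[int, int] = (0, 0),
              rng: np.random.Generator | None = None) -> list[CropSpec]:
    """Non-overlapping crop grid anchored at (-dr, -dc), covering [0, L)^2.

    With ``rng`` supplied, the offset is drawn uniformly from [0, c)^2 and
    the ``offset`` argument is ignored.
    """
    if c <= 0:
        raise ValueError("crop size must be positive")
    if rng is not None:
        offset = (int(rng.integers(0, c)), int(rng.integers(0, c)))
    dr, dc = offset
    if not (0 <= dr < c and 0 <= dc < c):
        raise ValueError(f"offset {offset} must lie in [0, {c})^2")
    crops = []
    for r0, pt, pb in _axis_cells(L, c, dr):
        for c0, pl, pr in _axis_cells(L, c, dc):
            crops.append(CropSpec(origin=(r0, c0), size=c,
                                  pad=(pt, pb, pl, pr)))
    return crops


def extract_feature_crop(features: PairwiseInput | np.ndarray,
                         spec: CropSpec) -> np.ndarray:
    """(c, c, C) feature crop; padded cells are zero with mask channel 0."""
    tensor = features.tensor if isinstance(features, PairwiseInput) else features
    c = spec.size
    out = np.zeros((c, c, tensor.shape[2]), dtype=np.float32)
    t, b, l, r = spec.pad
    out[t: c - b, l: c - r] = tensor[spec.rows, spec.cols]
    return out


@dataclasses.dataclass
class CropLabels:
    """Labels aligned to one crop; padding carries the ignore value."""

    dist: np.ndarray                 # (c, c)
    aux_i: dict[str, np.ndarray]     # each (c,)
    aux_j: dict[str, np.ndarray]


def extract_label_crop(labels: LabelSet, spec: CropSpec) -> CropLabels:
    c = spec.size
    t, b, l, r = spec.pad
    dist = np.full((c, c), IGNORE, dtype=np.int64)
    dist[t: c - b, l: c - r] = labels.dist_bins[spec.rows, spec.cols]
    per_res = {"ss": labels.ss, "phi": labels.phi,
               "psi": labels.psi, "asa": labels.asa}
    aux_i, aux_j = {}, {}
    for name, arr in per_res.items():
        row = np.full(c, IGNORE, dtype=np.int64)
        row[t: c - b] = arr[spec.rows]
        col = np.full(c, IGNORE, dtype=np.int64)
        col[l: c - r] = arr[spec.cols]
        aux_i[name] = row
        aux_j[name] = col
    return CropLabels(dist=dist, aux_i=aux_i, aux_j=aux_j)


# ---------------------------------------------------------------------------
# MSA subsampling
# ---------------------------------------------------------------------------

def subsample_msa(aln: Alignment, fraction: float = 0.5,
                  rng: np.random.Generator | int | None = None) -> Alignment:
    """Random subsample of the alignment rows, query always retained.

    Of the depth-1 non-query rows, round(fraction * (depth-1)) are kept,
    sampled without replacement.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if aln.depth == 1:
        return aln
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_keep = int(round(fraction * (aln.depth - 1)))
    chosen = np.sort(rng.choice(aln.depth - 1, size=n_keep, replace=False)) + 1
    keep = [0] + chosen.tolist()
    return Alignment(query_id=aln.query_id,
                     sequences=[aln.sequences[k] for k in keep],
                     ids=[aln.ids[k] for k in keep])


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class LossWeights:
    dist: float = 15.0
    ss: float = 0.5
    phi: float = 0.25
    psi: float = 0.25
    asa: float = 0.5

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"loss weight {f.name} must be non-negative")


def combine_losses(components: dict[str, float],
                   w: LossWeights = LossWeights()) -> float:
    """Weighted sum of the five per-task cross-entropies."""
    return (w.dist * components.get("dist", 0.0)
            + w.ss * components.get("ss", 0.0)
            + w.phi * components.get("phi", 0.0)
            + w.psi * components.get("psi", 0.0)
            + w.asa * components.get("asa", 0.0))


def _prob_ce(probs: np.ndarray, labels: np.ndarray) -> float:
    valid = labels != IGNORE
    if not valid.any():
        return 0.0
    p = probs.reshape(-1, probs.shape[-1])[valid.ravel()]
    picked = p[np.arange(len(p)), labels[valid]]
    return float(-np.log(np.clip(picked, 1e-30, None)).mean())


def multicomponent_loss(pred: CropPrediction, labels: CropLabels,
                        w: LossWeights = LossWeights()) -> float:
    """Weighted multicomponent cross-entropy of a crop prediction.

    Each component is a mean over its non-ignored positions; a component
    with no valid positions contributes 0.
    """
    components = {"dist": _prob_ce(pred.dist, labels.dist)}
    for name in AUX_HEAD_SIZES:
        ce_i = _prob_ce(pred.aux_head(name, "i"), labels.aux_i[name])
        ce_j = _prob_ce(pred.aux_head(name, "j"), labels.aux_j[name])
        n_i = int((labels.aux_i[name] != IGNORE).sum())
        n_j = int((labels.aux_j[name] != IGNORE).sum())
        denom = (n_i > 0) + (n_j > 0)
        components[name] = (ce_i + ce_j) / denom if denom else 0.0
    return combine_losses(components, w)


def _batch_loss_and_grads(logits: dict[str, np.ndarray],
                          batch_labels: list[CropLabels],
                          w: LossWeights
                          ) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and d(loss)/d(logits) for a batch of crops."""
    B = logits["dist"].shape[0]
    grads: dict[str, np.ndarray] = {}
    # distance head: (B, 10, c, c) -> positions (B*c*c, 10)
    dl = logits["dist"].transpose(0, 2, 3, 1)
    flat = dl.reshape(-1, dl.shape[-1])
    labels = np.stack([lb.dist for lb in batch_labels]).ravel()
    ce_dist, g = nn.cross_entropy(flat, labels, IGNORE)
    grads["dist"] = g.reshape(dl.shape).transpose(0, 3, 1, 2)
    total = w.dist * ce_dist
    weight_of = {"ss": w.ss, "phi": w.phi, "psi": w.psi, "asa": w.asa}
    for name in AUX_HEAD_SIZES:
        for axis in ("i", "j"):
            key = f"{name}_{axis}"
            al = logits[key].transpose(0, 2, 1)  # (B, c, K)
            flat = al.reshape(-1, al.shape[-1])
            lab_src = [lb.aux_i if axis == "i" else lb.aux_j
                       for lb in batch_labels]
            labels = np.stack([ls[name] for ls in lab_src]).ravel()
            ce, g = nn.cross_entropy(flat, labels, IGNORE)
            # i and j views are two estimates of the same per-residue task;
            # each carries half the task weight
            total += 0.5 * weight_of[name] * ce
            grads[key] = (0.5 * weight_of[name]
                          * g.reshape(al.shape).transpose(0, 2, 1))
    grads["dist"] *= w.dist
    return total, grads


# ---------------------------------------------------------------------------
# learning-rate schedules
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Schedule:
    """Piecewise-constant LR schedule; decays apply from their epoch on."""

    model_id: str
    initial_lr: float = 1e-3
    decay_points: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        lr = self.initial_lr
        for _, v in self.decay_points:
            if v > lr:
                raise ValueError("learning rate must be non-increasing")
            lr = v


SCHEDULES = {
    "A": Schedule("A", 1e-3, ((5, 5e-4), (15, 1e-4))),
    "B": Schedule("B", 1e-3, ((10, 5e-4), (25, 1e-4))),
    "C": Schedule("C", 1e-3, ((8, 5e-4), (20, 1e-4))),
}


def lr_at(epoch: int, s: Schedule) -> float:
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    lr = s.initial_lr
    for start, value in s.decay_points:
        if epoch >= start:
            lr = value
    return lr


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainingDomain:
    """One training example: an MSA plus its structure-derived labels.

    ``features`` may hold a precomputed input tensor; when absent (or when
    the epoch subsamples the MSA) features are recomputed from the MSA.
    """

    alignment: Alignment
    labels: LabelSet
    features: PairwiseInput | None = None

    @property
    def length(self) -> int:
        return self.alignment.length


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 2
    batch_size: int = 8
    schedule: str = "A"
    seed: int = 0
    subsample_fraction: float = 0.5
    loss_weights: LossWeights = dataclasses.field(default_factory=LossWeights)
    keep_checkpoints: int = 3
    recompute_features: bool = True


@dataclasses.dataclass
class Checkpoint:
    val_loss: float
    epoch: int
    state: dict[str, np.ndarray]


@dataclasses.dataclass
class TrainResult:
    checkpoints: list[Checkpoint]
    step_losses: list[float]
    epoch_val_losses: list[float]


def _domain_features(domain: TrainingDomain, cfg: TrainConfig,
                     rng: np.random.Generator) -> PairwiseInput:
    if cfg.recompute_features or domain.features is None:
        aln = subsample_msa(domain.alignment, cfg.subsample_fraction, rng)
        return featurize(aln)
    return domain.features


def _epoch_crops(domain: TrainingDomain, features: PairwiseInput,
                 grid: list[CropSpec]
                 ) -> list[tuple[np.ndarray, CropLabels]]:
    return [(extract_feature_crop(features, spec),
             extract_label_crop(domain.labels, spec)) for spec in grid]


def validation_loss(model: DistogramNetwork,
                    domains: list[TrainingDomain],
                    w: LossWeights) -> float:
    """Mean multicomponent loss over static offset-(0,0) grids."""
    model.train(False)
    losses = []
    for domain in domains:
        features = domain.features or featurize(domain.alignment)
        for spec in crop_grid(domain.length, model.cfg.crop_size, (0, 0)):
            x = extract_feature_crop(features, spec)
            lbl = extract_label_crop(domain.labels, spec)
            logits = model.forward_logits(x)
            loss, _ = _batch_loss_and_grads(logits, [lbl], w)
            losses.append(loss)
    return float(np.mean(losses))


def train(model: DistogramNetwork, train_domains: list[TrainingDomain],
          cfg: TrainConfig,
          val_domains: list[TrainingDomain] | None = None) -> TrainResult:
    """Epoch loop with per-epoch crop grids, MSA subsampling, and
    lowest-validation-loss checkpoint retention."""
    rng = np.random.default_rng(cfg.seed)
    schedule = SCHEDULES[cfg.schedule] if isinstance(cfg.schedule, str) \
        else cfg.schedule
    opt = nn.Adam(model.params(), lr=schedule.initial_lr)
    val_domains = val_domains or train_domains
    step_losses: list[float] = []
    epoch_val: list[float] = []
    checkpoints: list[Checkpoint] = []
    for epoch in range(cfg.epochs):
        opt.lr = lr_at(epoch, schedule)
        model.train(True)
        batch: list[tuple[np.ndarray, CropLabels]] = []
        pending: list[list[tuple[np.ndarray, CropLabels]]] = []
        for domain in train_domains:
            features = _domain_features(domain, cfg, rng)
            grid = crop_grid(domain.length, model.cfg.crop_size, rng=rng)
            pending.append(_epoch_crops(domain, features, grid))
        crops = [c for dom in pending for c in dom]
        order = rng.permutation(len(crops))
        for start in range(0, len(crops), cfg.batch_size):
            chunk = [crops[k] for k in order[start: start + cfg.batch_size]]
            x = np.stack([c[0] for c in chunk])
            labels = [c[1] for c in chunk]
            logits = model.forward_logits(x)
            loss, grads = _batch_loss_and_grads(logits, labels,
                                                cfg.loss_weights)
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss {loss} at epoch {epoch}, "
                    f"step {len(step_losses)}"
                )
            opt.zero_grad()
            model.backward(grads)
            opt.step()
            step_losses.append(loss)
        val = validation_loss(model, val_domains, cfg.loss_weights)
        epoch_val.append(val)
        checkpoints.append(Checkpoint(val_loss=val, epoch=epoch,
                                      state=model.state_arrays()))
        checkpoints.sort(key=lambda c: c.val_loss)
        checkpoints = checkpoints[: cfg.keep_checkpoints]
    return TrainResult(checkpoints=checkpoints, step_losses=step_losses,
                       epoch_val_losses=epoch_val)
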