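"""Full-length prediction: crop tiling, aggregation, ensembling, contacts.

The network only ever sees c x c crops, so a full L x L distogram is built
by predicting a set of grids that jointly cover the map, averaging the
per-cell probability vectors across all covering crops (cells covered by
more crops simply average more terms), and symmetrizing by averaging the
(i, j) and (j, i) cells.  Ensembling averages the distograms of several
models and renormalizes.  Contact probability is the summed mass of the
first three distance bins (< 8 Å).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .network import AUX_HEAD_SIZES, CropPrediction, DistogramNetwork, N_DIST_CLASSES
from .training import CropSpec, crop_grid, extract_feature_crop
from .featurization import PairwiseInput

N_CONTACT_BINS = 3  # bins <4, 4-6, 6-8 Å together cover distances < 8 Å


@dataclasses.dataclass
class Distogram:
    """L x L x 10 per-pair distance distribution plus aggregation metadata."""

    probs: np.ndarray          # (L, L, 10)
    coverage: np.ndarray       # (L, L) int, crops contributing per cell
    aux: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.probs.shape[0]


def coverage_crops(L: int, c: int, n_offsets: int = 1,
                   rng: np.random.Generator | None = None) -> list[CropSpec]:
    """Crop grids guaranteeing full coverage of [0, L)^2.

    The first grid is the (0, 0) base grid; further grids are shifted to
    cover the boundaries between base crops — deterministic half-stride
    (and stride-fraction) shifts by default, random offsets when ``rng``
    is supplied.  Every grid individually covers the whole map, so with
    ``n_offsets`` grids every cell is covered at least ``n_offsets`` times.
    """
    if n_offsets < 1:
        raise ValueError("n_offsets must be >= 1")
    crops = list(crop_grid(L, c, (0, 0)))
    seen = {(0, 0)}
    for k in range(1, n_offsets):
        if rng is not None:
            while True:
                off = (int(rng.integers(0, c)), int(rng.integers(0, c)))
                if off not in seen or len(seen) >= c * c:
                    break
        else:
            # spread offsets over the diagonal of the crop, half-stride first
            step = (k * c) // n_offsets if n_offsets > 2 else c // 2
            off = (step % c, step % c)
            if off in seen:
                off = ((off[0] + k) % c, (off[1] + k) % c)
        seen.add(off)
        crops.extend(crop_grid(L, c, off))
    return crops


def predict_crops(model: DistogramNetwork,
                  features: PairwiseInput | np.ndarray,
                  crops: list[CropSpec]) -> list[CropPrediction]:
    preds = []
    for spec in crops:
        x = extract_feature_crop(features, spec)
        pred = model.predict_crop(x, origin=spec.origin)
        preds.append(_strip_padding(pred, spec))
    return preds


def _strip_padding(pred: CropPrediction, spec: CropSpec) -> CropPrediction:
    """Drop padded rows/columns so aggregation only sees real cells."""
    c = spec.size
    t, b, l, r = spec.pad
    return CropPrediction(dist=pred.dist[t: c - b, l: c - r],
                          aux_i=pred.aux_i[t: c - b],
                          aux_j=pred.aux_j[l: c - r],
                          origin=spec.origin)


def aggregate(crop_preds: list[CropPrediction], L: int) -> Distogram:
    """Average crop predictions per cell, then symmetrize the distogram.

    Every cell's distribution is the arithmetic mean over all crops that
    cover it; cells some grids pad are simply covered by fewer crops.  The
    per-residue auxiliary predictions are averaged the same way.
    """
    dist_sum = np.zeros((L, L, N_DIST_CLASSES))
    count = np.zeros((L, L), dtype=np.int64)
    n_aux = sum(AUX_HEAD_SIZES.values())
    aux_sum = np.zeros((L, n_aux))
    aux_count = np.zeros(L, dtype=np.int64)
    for pred in crop_preds:
        r0, c0 = pred.origin
        h, w = pred.dist.shape[:2]
        dist_sum[r0: r0 + h, c0: c0 + w] += pred.dist
        count[r0: r0 + h, c0: c0 + w] += 1
        aux_sum[r0: r0 + h] += pred.aux_i
        aux_count[r0: r0 + h] += 1
        aux_sum[c0: c0 + w] += pred.aux_j
        aux_count[c0: c0 + w] += 1
    if (count == 0).any():
        missing = np.argwhere(count == 0)
        raise ValueError(
            f"{len(missing)} cells not covered by any crop, e.g. "
            f"{[tuple(m) for m in missing[:5]]}"
        )
    probs = dist_sum / count[:, :, None]
    probs = 0.5 * (probs + probs.transpose(1, 0, 2))
    aux = aux_sum / aux_count[:, None]
    aux_tables = {}
    start = 0
    for name, size in AUX_HEAD_SIZES.items():
        aux_tables[name] = aux[:, start: start + size]
        start += size
    return Distogram(probs=probs, coverage=count + count.T, aux=aux_tables)


def ensemble(distograms: list[Distogram]) -> Distogram:
    """Average several models' distograms and renormalize each cell."""
    if not distograms:
        raise ValueError("ensemble needs at least one distogram")
    L = distograms[0].length
    for dg in distograms:
        if dg.length != L:
            raise ValueError(
                f"distogram lengths differ: {dg.length} vs {L}"
            )
    probs = np.mean([dg.probs for dg in distograms], axis=0)
    probs = probs / probs.sum(axis=2, keepdims=True)
    aux = {}
    for name in distograms[0].aux:
        aux[name] = np.mean([dg.aux[name] for dg in distograms], axis=0)
    coverage = np.sum([dg.coverage for dg in distograms], axis=0)
    return Distogram(probs=probs, coverage=coverage, aux=aux)


def contact_probability(dg: Distogram | np.ndarray) -> np.ndarray:
    """P(contact) = summed probability of the first three bins (< 8 Å)."""
    probs = dg.probs if isinstance(dg, Distogram) else np.asarray(dg)
    return probs[:, :, :N_CONTACT_BINS].sum(axis=2)


def predict_distogram(model: DistogramNetwork,
                      features: PairwiseInput | np.ndarray,
                      n_offsets: int = 1,
                      rng: np.random.Generator | None = None) -> Distogram:
    """Tile, predict, and aggregate a full-length distogram."""
    tensor = features.tensor if isinstance(features, PairwiseInput) else features
    L = tensor.shape[0]
    crops = coverage_crops(L, model.cfg.crop_size, n_offsets, rng)
    return aggregate(predict_crops(model, features, crops), L)
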