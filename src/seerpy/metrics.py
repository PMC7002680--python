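"""No-reference color image quality metrics and spectral separation accuracy.

Fluorescence renderings have no ground-truth color image to compare
against, so quality is scored without a reference:

* colorfulness — log-moment statistic of the red–green (α = R − G) and
  yellow–blue (β = ½(R+G) − B) opponent spaces;
* sharpness — NTSC-weighted EME, a Weber-law block measure of enhancement;
* contrast — NTSC-weighted AME, a Michelson-law block measure;
* CQE — the fixed linear poll of the three.

Separation accuracy scores how far apart three designated regions land in
RGB space: the sum of pairwise Euclidean distances between region-mean
colors, normalized by 3√2 — the maximum, attained exactly when the regions
are pure red, green and blue.

Conventions (configurable, reported with the scores): colorfulness, EME and
AME work on the 0–255 intensity scale with natural logarithms; separation
accuracy works on [0, 1] colors. All log/division guards use ε = 255·1e−4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ValidationError
from .render import NTSC_WEIGHTS

logger = logging.getLogger(__name__)

#: guard for logs and divisions, in 0-255 intensity units
EPS = 255.0 * 1e-4

#: fixed CQE polling coefficients (colorfulness, sharpness, contrast)
CQE_COEFFS = (0.4358, 0.1722, 0.3920)

MAX_SEPARATION = 3.0 * np.sqrt(2.0)


@dataclass(frozen=True)
class BlockSpec:
    """Tiling of the image into k1 × k2 blocks (rows × columns); remainder
    pixels are merged into the last block along each axis."""

    k1: int = 8
    k2: int = 8

    def __post_init__(self) -> None:
        if self.k1 < 1 or self.k2 < 1:
            raise ValidationError(f"block counts must be ≥ 1, got ({self.k1}, {self.k2})")

    def split(self, channel: np.ndarray):
        """Yield the blocks of a 2D channel."""
        h, w = channel.shape
        k1, k2 = min(self.k1, h), min(self.k2, w)
        row_edges = np.linspace(0, h, k1 + 1).astype(int)
        col_edges = np.linspace(0, w, k2 + 1).astype(int)
        for r0, r1 in zip(row_edges[:-1], row_edges[1:]):
            for c0, c1 in zip(col_edges[:-1], col_edges[1:]):
                yield channel[r0:r1, c0:c1]


@dataclass
class QualityScores:
    colorfulness: float
    sharpness: float
    contrast: float
    cqe: float


def _as_255(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValidationError(f"expected (y, x, 3) RGB image, got shape {img.shape}")
    if img.max() <= 1.0:
        img = img * 255.0
    return img


def colorfulness(img: np.ndarray, log=np.log) -> float:
    """Opponent-space colorfulness: 0.02·log(σ²_α/|μ_α|^0.2)·log(σ²_β/|μ_β|^0.2)."""
    rgb = _as_255(img)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    alpha = r - g
    beta = 0.5 * (r + g) - b
    var_a, var_b = alpha.var(), beta.var()
    if var_a == 0 or var_b == 0:
        logger.warning("colorfulness: constant opponent channel; ε-guarded value")
    term_a = log(max(var_a, EPS) / max(abs(alpha.mean()) ** 0.2, EPS))
    term_b = log(max(var_b, EPS) / max(abs(beta.mean()) ** 0.2, EPS))
    return float(0.02 * term_a * term_b)


def sharpness_eme(img: np.ndarray, blocks: BlockSpec = BlockSpec(), log=np.log) -> float:
    """NTSC-weighted EME: per channel, (2/k1k2)·ΣΣ log(I_max/I_min) over blocks."""
    rgb = _as_255(img)
    score = 0.0
    for c, weight in enumerate(NTSC_WEIGHTS):
        eme = 0.0
        n_blocks = 0
        for block in blocks.split(rgb[..., c]):
            imax, imin = block.max(), block.min()
            eme += log(max(imax, EPS) / max(imin, EPS))
            n_blocks += 1
        score += weight * 2.0 / n_blocks * eme
    return float(score)


def contrast_ame(img: np.ndarray, blocks: BlockSpec = BlockSpec(), log=np.log) -> float:
    """NTSC-weighted AME: per channel,
    (1/k1k2)·Σ_rows (Σ_cols log((I_max+I_min)/(I_max−I_min)))^−0.5."""
    rgb = _as_255(img)
    score = 0.0
    for c, weight in enumerate(NTSC_WEIGHTS):
        channel = rgb[..., c]
        h, w = channel.shape
        k1, k2 = min(blocks.k1, h), min(blocks.k2, w)
        row_edges = np.linspace(0, h, k1 + 1).astype(int)
        col_edges = np.linspace(0, w, k2 + 1).astype(int)
        ame = 0.0
        for r0, r1 in zip(row_edges[:-1], row_edges[1:]):
            inner = 0.0
            for c0, c1 in zip(col_edges[:-1], col_edges[1:]):
                block = channel[r0:r1, c0:c1]
                imax, imin = block.max(), block.min()
                inner += log(max(imax + imin, EPS) / max(imax - imin, EPS))
            ame += max(inner, EPS) ** -0.5
        score += weight * ame / (k1 * k2)
    return float(score)


def cqe(img: np.ndarray, blocks: BlockSpec = BlockSpec()) -> QualityScores:
    """Color Quality Enhancement: the fixed linear poll of colorfulness,
    sharpness and contrast approximating perceived color image quality."""
    col = colorfulness(img)
    sharp = sharpness_eme(img, blocks)
    con = contrast_ame(img, blocks)
    c1, c2, c3 = CQE_COEFFS
    return QualityScores(
        colorfulness=col, sharpness=sharp, contrast=con,
        cqe=c1 * col + c2 * sharp + c3 * con,
    )


def separation_accuracy(img: np.ndarray, masks) -> float:
    """Spectral separation accuracy of three regions of a rendering.

    ``masks`` is a sequence of three disjoint boolean pixel masks. Region
    mean RGB vectors (colors on [0, 1]) are treated as points in Euclidean
    space; the score is the sum of the three pairwise distances over the
    pure-R/G/B maximum 3√2, so it lies in [0, 1] and reaches 1 exactly for
    a permutation of pure red/green/blue.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if len(masks) != 3:
        raise ValidationError(f"need exactly 3 region masks, got {len(masks)}")
    for i, m in enumerate(masks):
        if not m.any():
            raise ValidationError(f"region mask {i} is empty")
    flat = img.reshape(-1, 3)
    means = [flat[m.reshape(-1)].mean(axis=0) for m in masks]
    l12 = np.linalg.norm(means[0] - means[1])
    l13 = np.linalg.norm(means[0] - means[2])
    l23 = np.linalg.norm(means[1] - means[2])
    return float((l12 + l13 + l23) / MAX_SEPARATION)
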