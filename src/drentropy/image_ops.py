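"""Grayscale conversion, global SSIM, duplicate removal and gamma correction.

The structural similarity index is computed with *global* image statistics
(one window covering the whole frame), i.e. the textbook single-window form

    l(x,y) = (2 mu_x mu_y + C1) / (mu_x^2 + mu_y^2 + C1)
    c(x,y) = (2 sigma_x sigma_y + C2) / (sigma_x^2 + sigma_y^2 + C2)
    s(x,y) = (sigma_xy + C3) / (sigma_x sigma_y + C3)
    SSIM   = l^alpha * c^beta * s^gamma

with C1 = (K1 L)^2, C2 = (K2 L)^2, C3 = C2 / 2 and the unbiased (N-1)
covariance.  This is the form needed for exact-duplicate detection, not the
sliding-window mean-SSIM variant used for perceptual quality assessment.

Gamma correction is the power-law intensity map

    T(u) = (L-1) * (u / (L-1))**gamma

applied per pixel; gamma > 1 darkens mid-tones, gamma < 1 brightens them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SSIMParams",
    "SSIMReport",
    "rgb_to_gray",
    "ssim",
    "gamma_transform",
    "dedup_images",
]

#: ITU-R BT.601 luma weights used for color -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero.

    numpy's default rounds halves to even; a fixed away-from-zero convention
    keeps quantization bit-stable across platforms.
    """
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def rgb_to_gray(color_image: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) color image to 8-bit grayscale.

    Per-pixel luminance 0.299 R + 0.587 G + 0.114 B, rounded to integer.
    A 2-D input is already gray and is returned as uint8 unchanged.
    """
    arr = np.asarray(color_image, dtype=np.float64)
    if arr.ndim == 2:
        return np.asarray(color_image).astype(np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected an (H, W, 3) color image, got shape {arr.shape}"
        )
    r, g, b = LUMA_WEIGHTS
    gray = r * arr[..., 0] + g * arr[..., 1] + b * arr[..., 2]
    return np.clip(round_half_away(gray), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class SSIMParams:
    """Constants and exponents of the similarity index.

    K1 and K2 are the usual small stabilisers (0.01 and 0.03); L is the
    dynamic range of the pixel values.  With alpha = beta = gamma_exp = 1
    and C3 = C2/2 the three-factor product collapses to the standard
    two-factor SSIM.
    """

    K1: float = 0.01
    K2: float = 0.03
    L: float = 255.0
    alpha: float = 1.0
    beta: float = 1.0
    gamma_exp: float = 1.0

    def __post_init__(self) -> None:
        if self.K1 <= 0 or self.K2 <= 0 or self.L <= 0:
            raise ValueError("K1, K2 and L must be positive")
        if min(self.alpha, self.beta, self.gamma_exp) <= 0:
            raise ValueError("exponents must be positive")

    @property
    def C1(self) -> float:
        return (self.K1 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (self.K2 * self.L) ** 2

    @property
    def C3(self) -> float:
        return self.C2 / 2.0


@dataclass(frozen=True)
class SSIMReport:
    """Luminance, contrast and structure terms plus their combination."""

    luminance: float
    contrast: float
    structure: float
    ssim: float


class ResolutionMismatch(ValueError):
    """Two images cannot be compared because their shapes differ."""


def ssim(x: np.ndarray, y: np.ndarray, params: SSIMParams | None = None) -> SSIMReport:
    """Global structural similarity between two equal-resolution images."""
    params = params or SSIMParams()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ResolutionMismatch(f"shapes {x.shape} and {y.shape} differ")
    if np.array_equal(x, y):
        # pixel-identical pair: every term is exactly 1, independent of the
        # floating-point path the general formula would take
        return SSIMReport(luminance=1.0, contrast=1.0, structure=1.0, ssim=1.0)
    n = x.size
    mu_x, mu_y = x.mean(), y.mean()
    # unbiased variance / covariance (N - 1 denominator)
    sig_x = x.std(ddof=1) if n > 1 else 0.0
    sig_y = y.std(ddof=1) if n > 1 else 0.0
    cov = ((x - mu_x) * (y - mu_y)).sum() / (n - 1) if n > 1 else 0.0

    C1, C2, C3 = params.C1, params.C2, params.C3
    lum = (2 * mu_x * mu_y + C1) / (mu_x**2 + mu_y**2 + C1)
    con = (2 * sig_x * sig_y + C2) / (sig_x**2 + sig_y**2 + C2)
    struct = (cov + C3) / (sig_x * sig_y + C3)
    combined = (
        lum**params.alpha * con**params.beta * struct**params.gamma_exp
    )
    return SSIMReport(luminance=lum, contrast=con, structure=struct, ssim=combined)


def gamma_transform(
    image: np.ndarray, gamma: float, levels: int = 256
) -> np.ndarray:
    """Power-law contrast map T(u) = (L-1) (u/(L-1))^gamma on integer pixels.

    The endpoints 0 and L-1 are fixed points for every gamma.  Output is
    rounded half-away-from-zero and clipped back to [0, L-1].
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    arr = np.asarray(image, dtype=np.float64)
    top = float(levels - 1)
    out = top * (arr / top) ** gamma
    return np.clip(round_half_away(out), 0, top).astype(np.uint8 if levels <= 256 else np.int64)


def dedup_images(image_set, tol: float = 1e-9, params: SSIMParams | None = None):
    """Remove near-duplicate images within each class label.

    Within each class, all ordered same-resolution pairs (i, j), i < j, are
    compared; if the combined SSIM is >= 1 - tol the later image j is
    dropped.  Removal is transitive over the scan: once removed, an image is
    never used as a keeper.  Comparisons never cross class labels, so exact
    copies in different classes both survive.

    Parameters
    ----------
    image_set : LabeledImageSet
    tol : float
        "SSIM equal to 1" is implemented as >= 1 - tol, since floating-point
        equality is unreliable; exact pixel copies always score >= 1 - tol.

    Returns
    -------
    (kept, removed) : (LabeledImageSet, list[tuple[int, int]])
        ``removed`` lists (kept_index, removed_index) pairs in the original
        indexing of ``image_set``.
    """
    from .synthetic import LabeledImageSet  # local import to avoid a cycle

    params = params or SSIMParams()
    n = len(image_set.images)
    alive = [True] * n
    removed_pairs: list[tuple[int, int]] = []

    by_class: dict[str, list[int]] = {}
    for idx, label in enumerate(image_set.labels):
        by_class.setdefault(label, []).append(idx)

    for indices in by_class.values():
        for a, i in enumerate(indices):
            if not alive[i]:
                continue
            for j in indices[a + 1:]:
                if not alive[j]:
                    continue
                if image_set.images[i].shape != image_set.images[j].shape:
                    continue  # different resolution: comparison not defined
                rep = ssim(image_set.images[i], image_set.images[j], params)
                if rep.ssim >= 1.0 - tol:
                    alive[j] = False
                    removed_pairs.append((i, j))

    old_to_new = {}
    for old_idx, a in enumerate(alive):
        if a:
            old_to_new[old_idx] = len(old_to_new)
    kept_images = [im for im, a in zip(image_set.images, alive) if a]
    kept_labels = [lb for lb, a in zip(image_set.labels, alive) if a]
    kept_prov = []
    for pv, a in zip(image_set.provenance, alive):
        if not a:
            continue
        if isinstance(pv, (int, np.integer)):
            # re-index a surviving duplicate's source; if the source itself
            # was removed the record no longer points anywhere meaningful
            pv = old_to_new.get(int(pv), "generated")
        kept_prov.append(pv)
    kept = LabeledImageSet(images=kept_images, labels=kept_labels, provenance=kept_prov)
    return kept, removed_pairs
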