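"""Gray-level histograms and the two entropy texture statistics.

Shannon entropy of the normalized gray-level histogram,

    SE = - sum_i p_i log2 p_i          (bits; empty bins contribute 0)

measures the randomness of an image's intensity distribution.  Fuzzy entropy
reweights the histogram by a membership function over gray levels before
taking a Shannon-type sum in natural log:

    q_i = p_i mu_i / sum_j p_j mu_j,   FE = - sum_i q_i ln q_i   (nats)

where the default membership is a Gaussian in gray-level distance from the
mean gray level i_bar = sum_i i p_i, mu_i = exp(-(i - i_bar)^2 / (2 sigma^2)),
so gray levels near the image's typical brightness count more.  With uniform
membership (mu_i = 1) and no bin exclusion, FE reduces exactly to Shannon
entropy in nats.

For each image, both entropies are computed on the unprocessed frame (level
"O") and after gamma correction at each configured gamma, yielding the
2 * (1 + n_gammas) feature record (8 values for the standard triple
0.9 / 1.65 / 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_ops import gamma_transform

__all__ = [
    "Histogram",
    "MembershipSpec",
    "FeatureRecord",
    "STANDARD_GAMMAS",
    "PREPROCESSING_LEVELS",
    "gray_histogram",
    "shannon_entropy",
    "fuzzy_entropy",
    "extract_feature_record",
    "build_feature_table",
]

#: Gamma triple used throughout: gamma1 brightens slightly, gamma2 is the
#: upper end of the moderate-contrast band, gamma3 darkens strongly.
STANDARD_GAMMAS = (0.9, 1.65, 3.0)

#: Preprocessing level names: original plus the gamma triple.
PREPROCESSING_LEVELS = ("O", "g1", "g2", "g3")


@dataclass(frozen=True)
class Histogram:
    """Normalized gray-level histogram: p[i] over levels i = 0 .. N-1."""

    p: np.ndarray
    N: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64)
        if p.shape != (self.N,):
            raise ValueError("p must have length N")
        if (p < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class MembershipSpec:
    """Membership function over gray levels for fuzzy entropy.

    kind="gaussian-about-mean" (default) uses mu_i = exp(-(i - i_bar)^2 /
    (2 sigma^2)) with i_bar the mean gray level; sigma defaults to (L-1)/4.
    kind="uniform" sets mu_i = 1 for every level, under which fuzzy entropy
    equals Shannon entropy in nats.  epsilon excludes low-probability bins:
    only bins with p_i > epsilon enter the sum (default 0: only empty bins
    are excluded).
    """

    kind: str = "gaussian-about-mean"
    sigma: float = 255.0 / 4.0
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian-about-mean", "uniform"):
            raise ValueError(f"unknown membership kind {self.kind!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")

    def memberships(self, h: Histogram) -> np.ndarray:
        if self.kind == "uniform":
            return np.ones(h.N)
        levels = np.arange(h.N, dtype=np.float64)
        mean_level = float((levels * h.p).sum())
        return np.exp(-((levels - mean_level) ** 2) / (2.0 * self.sigma**2))


class DegenerateHistogram(ValueError):
    """All histogram bins were excluded; fuzzy entropy is undefined."""


def gray_histogram(image: np.ndarray, levels: int = 256) -> Histogram:
    """Normalized bin counts over the full image frame."""
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("cannot histogram an empty image")
    counts = np.bincount(arr.ravel().astype(np.int64), minlength=levels)
    if len(counts) > levels:
        raise ValueError("pixel value exceeds the configured number of levels")
    return Histogram(p=counts / arr.size, N=levels)


def shannon_entropy(h: Histogram, base: float = 2.0) -> float:
    """- sum p_i log_base p_i with 0 log 0 := 0."""
    p = h.p[h.p > 0]
    return float(-(p * (np.log(p) / np.log(base))).sum())


def fuzzy_entropy(h: Histogram, m: MembershipSpec | None = None) -> float:
    """Shannon-type entropy (natural log) of the membership-reweighted histogram."""
    m = m or MembershipSpec()
    mu = m.memberships(h)
    include = h.p > m.epsilon
    w = h.p[include] * mu[include]
    total = w.sum()
    if not include.any() or total <= 0:
        raise DegenerateHistogram("no bins left after exclusion/weighting")
    q = w / total
    q = q[q > 0]
    return float(-(q * np.log(q)).sum())


@dataclass(frozen=True)
class FeatureRecord:
    """Per-image entropy features keyed by preprocessing level.

    values maps level name ("O", "g1", ...) to an (SE, FE) pair — SE in
    bits, FE in nats.
    """

    image_id: str
    label: str
    values: dict

    def as_row(self) -> dict:
        row: dict = {"image_id": self.image_id, "label": self.label}
        for level, (se, fe) in self.values.items():
            row[f"SE_{level}"] = se
            row[f"FE_{level}"] = fe
        return row


def extract_feature_record(
    image: np.ndarray,
    gammas: tuple[float, ...] = STANDARD_GAMMAS,
    membership: MembershipSpec | None = None,
    image_id: str = "",
    label: str = "",
    levels: int = 256,
    se_base: float = 2.0,
) -> FeatureRecord:
    """Entropy pair at the original level and after each gamma correction."""
    if not gammas or any(g <= 0 for g in gammas):
        raise ValueError("gammas must be a non-empty tuple of positive values")
    membership = membership or MembershipSpec(sigma=(levels - 1) / 4.0)
    values: dict = {}
    h0 = gray_histogram(image, levels)
    values["O"] = (shannon_entropy(h0, se_base), fuzzy_entropy(h0, membership))
    for k, g in enumerate(gammas, start=1):
        hg = gray_histogram(gamma_transform(image, g, levels), levels)
        values[f"g{k}"] = (shannon_entropy(hg, se_base), fuzzy_entropy(hg, membership))
    return FeatureRecord(image_id=image_id, label=label, values=values)


def build_feature_table(
    image_set,
    gammas: tuple[float, ...] = STANDARD_GAMMAS,
    membership: MembershipSpec | None = None,
    levels: int = 256,
) -> pd.DataFrame:
    """One row per image: image_id, label, then SE/FE at each level.

    Column order for the standard triple:
    image_id, label, SE_O, FE_O, SE_g1, FE_g1, SE_g2, FE_g2, SE_g3, FE_g3.
    """
    rows = []
    for idx, (img, lbl) in enumerate(zip(image_set.images, image_set.labels)):
        rec = extract_feature_record(
            img, gammas, membership, image_id=f"img_{idx:05d}", label=lbl, levels=levels
        )
        rows.append(rec.as_row())
    return pd.DataFrame(rows)
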