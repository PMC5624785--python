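"""Spatial association between two puncta populations.

Implements the within-threshold colocalization fraction (strict < 500 nm by
default), a mask-constrained Monte Carlo randomization null (complete spatial
randomness within the dendrite), minimum-distance CDF comparison via a
hand-rolled two-sample Kolmogorov–Smirnov test, and pixel-wise Pearson
colocalization. The conditioning direction is explicit throughout:
operations take (reference, target), never assuming symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .imaging_io import RoiMask
from .synthgen import PunctaSet

__all__ = [
    "ProximityParams",
    "ProximityResult",
    "KsResult",
    "min_distances",
    "fraction_within",
    "randomize_in_mask",
    "proximity_null",
    "ks_two_sample",
    "pearson_coloc",
]


@dataclass
class ProximityParams:
    """threshold_um is a strict less-than colocalization radius (default 500 nm)."""

    threshold_um: float = 0.5
    n_randomizations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.threshold_um > 0:
            raise ValueError("threshold_um must be > 0")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")


@dataclass
class ProximityResult:
    n_reference: int
    observed_fraction: float
    null_fractions: np.ndarray
    p_empirical: float
    min_distances_um: np.ndarray
    null_min_distances_um: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_fractions))


@dataclass
class KsResult:
    D: float
    p: float
    n1: int
    n2: int


def min_distances(reference: PunctaSet | np.ndarray, target: PunctaSet | np.ndarray) -> np.ndarray:
    """Per-reference-punctum minimum Euclidean distance (µm) to the target set."""
    ref = reference.points if isinstance(reference, PunctaSet) else np.asarray(reference, float)
    tgt = target.points if isinstance(target, PunctaSet) else np.asarray(target, float)
    ref = ref.reshape(-1, 2)
    tgt = tgt.reshape(-1, 2)
    if len(tgt) == 0:
        raise ValueError("target set is empty")
    if len(ref) == 0:
        return np.empty(0)
    return cKDTree(tgt).query(ref)[0]


def fraction_within(reference, target, params: ProximityParams) -> float:
    """Fraction of reference puncta with at least one target punctum strictly
    closer than the threshold."""
    d = min_distances(reference, target)
    if len(d) == 0:
        raise ValueError("reference set is empty")
    return float(np.mean(d < params.threshold_um))


def randomize_in_mask(target: PunctaSet, mask: RoiMask | np.ndarray, seed=0,
                      pixel_size_um: float | None = None) -> PunctaSet:
    """Redistribute the target puncta uniformly within the mask (CSR null).

    Each point is drawn by choosing a mask pixel uniformly, then a uniform
    position within that pixel; intensities are carried over unchanged.
    """
    if isinstance(mask, RoiMask):
        px = mask.pixel_size_um
        raster = mask.raster > 0
    else:
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required with a bare boolean mask")
        px = pixel_size_um
        raster = np.asarray(mask, dtype=bool)
    pix = np.argwhere(raster)
    if len(pix) == 0:
        raise ValueError("mask is empty")
    rng = np.random.default_rng(seed)
    n = len(target)
    chosen = pix[rng.integers(len(pix), size=n)]
    offsets = rng.uniform(0.0, 1.0, size=(n, 2))
    x = (chosen[:, 1] + offsets[:, 0]) * px
    y = (chosen[:, 0] + offsets[:, 1]) * px
    return PunctaSet(target.channel, target.frame, np.column_stack([x, y]),
                     target.intensities.copy())


def proximity_null(
    reference: PunctaSet,
    target: PunctaSet,
    mask: RoiMask,
    params: ProximityParams,
) -> ProximityResult:
    """Observed within-threshold fraction against a mask-constrained CSR null.

    null_fractions[i] uses randomize_in_mask(target, mask, seed + i). The
    empirical p uses the add-one estimator
    p = (1 + #{null >= observed}) / (n_randomizations + 1), which never
    returns 0.
    """
    obs_d = min_distances(reference, target)
    observed = float(np.mean(obs_d < params.threshold_um))
    null_fracs = np.empty(params.n_randomizations)
    null_d = []
    for i in range(params.n_randomizations):
        rand = randomize_in_mask(target, mask, seed=params.seed + i)
        d = min_distances(reference, rand)
        null_fracs[i] = np.mean(d < params.threshold_um)
        null_d.append(d)
    p = (1.0 + np.sum(null_fracs >= observed)) / (params.n_randomizations + 1.0)
    return ProximityResult(
        n_reference=len(reference),
        observed_fraction=observed,
        null_fractions=null_fracs,
        p_empirical=float(p),
        min_distances_um=obs_d,
        null_min_distances_um=np.concatenate(null_d),
    )


def ks_two_sample(x, y) -> KsResult:
    """Two-sample Kolmogorov–Smirnov test (asymptotic p), from scratch.

    D is the supremum over the pooled sample of |ECDF_x - ECDF_y|; the
    p-value uses the Kolmogorov series with effective size
    n = n1*n2/(n1+n2) and the standard small-sample correction.
    """
    x = np.sort(np.asarray(x, dtype=float).ravel())
    y = np.sort(np.asarray(y, dtype=float).ravel())
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / n1
    cdf_y = np.searchsorted(y, pooled, side="right") / n2
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    ne = n1 * n2 / (n1 + n2)
    lam = (np.sqrt(ne) + 0.12 + 0.11 / np.sqrt(ne)) * d
    if lam <= 0:
        p = 1.0
    else:
        k = np.arange(1, 101)
        p = float(2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * (k * lam) ** 2)))
    return KsResult(D=d, p=float(np.clip(p, np.finfo(float).tiny, 1.0)), n1=n1, n2=n2)


def pearson_coloc(channel_a: np.ndarray, channel_b: np.ndarray,
                  mask: np.ndarray | RoiMask) -> float:
    """Pearson correlation between two channels over mask pixels only."""
    if isinstance(mask, RoiMask):
        mask = mask.raster > 0
    mask = np.asarray(mask, dtype=bool)
    a = np.asarray(channel_a, dtype=float)[mask]
    b = np.asarray(channel_b, dtype=float)[mask]
    if a.size < 2:
        raise ValueError("mask must contain at least 2 pixels")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Pearson r undefined: a channel is constant under the mask")
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))
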