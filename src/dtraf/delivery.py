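"""Surface-delivery, spine-occupancy and fusion-event quantification.

Surface signal is measured as the masked, background-subtracted mean and
normalized to a no-release control group. Spine occupancy uses a
threshold-above-shaft-background rule (mean + k·SD, default k = 2) with exact
(Clopper–Pearson) binomial confidence intervals. Group comparisons use the
pooled-variance unpaired two-tailed Student's t-test, implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import beta
from skimage.filters import threshold_otsu

__all__ = [
    "SpineOccupancy",
    "surface_intensity",
    "normalize_to_control",
    "delivery_timecourse",
    "spine_occupancy",
    "cooccupancy",
    "classify_events",
    "t_test_unpaired",
    "binomial_ci",
]


@dataclass
class SpineOccupancy:
    n_spines: int
    n_re_positive: int
    n_cargo_gain: int
    re_fraction_ci: tuple[float, float]
    gain_fraction_ci: tuple[float, float]

    @property
    def re_fraction(self) -> float:
        return self.n_re_positive / self.n_spines

    @property
    def gain_fraction(self) -> float:
        """Cargo-positive fraction among RE-positive spines."""
        if self.n_re_positive == 0:
            return np.nan
        return self.n_cargo_gain / self.n_re_positive


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact Clopper–Pearson interval for a binomial proportion."""
    if n == 0:
        return (np.nan, np.nan)
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (lo, hi)


def surface_intensity(
    image: np.ndarray,
    morphology_mask: np.ndarray | None,
    background_roi: np.ndarray,
    cell_fill: np.ndarray | None = None,
) -> float:
    """Masked mean minus background-ROI mean, floored at 0.

    When no morphology mask is supplied it is derived from the cell-fill
    channel by Otsu thresholding. The background ROI must lie outside the
    morphology mask.
    """
    image = np.asarray(image, dtype=float)
    background_roi = np.asarray(background_roi, dtype=bool)
    if morphology_mask is None:
        if cell_fill is None:
            raise ValueError("need a morphology_mask or a cell_fill channel")
        morphology_mask = np.asarray(cell_fill) > threshold_otsu(np.asarray(cell_fill))
    morphology_mask = np.asarray(morphology_mask, dtype=bool)
    if not morphology_mask.any():
        raise ValueError("morphology mask is empty")
    if not background_roi.any():
        raise ValueError("background ROI is empty")
    if np.any(morphology_mask & background_roi):
        raise ValueError("background ROI must be outside the morphology mask")
    value = image[morphology_mask].mean() - image[background_roi].mean()
    return float(max(value, 0.0))


def normalize_to_control(
    measurements: pd.DataFrame,
    control_condition: str,
    value_column: str = "raw_mean",
    background_column: str | None = "background",
) -> pd.DataFrame:
    """Add a ``normalized`` column: background-subtracted value over the
    control-group mean (control cells average 1 by construction)."""
    df = measurements.copy()
    raw = df[value_column].astype(float)
    if background_column is not None and background_column in df:
        raw = (raw - df[background_column].astype(float)).clip(lower=0.0)
    control = raw[df["condition"] == control_condition]
    if len(control) == 0:
        raise ValueError(f"no cells in control condition {control_condition!r}")
    control_mean = control.mean()
    if control_mean == 0:
        raise ValueError("control mean is zero; cannot normalize")
    df["normalized"] = raw / control_mean
    return df


def delivery_timecourse(measurements: pd.DataFrame,
                        value_column: str = "normalized") -> pd.DataFrame:
    """Per-(condition, timepoint) mean ± SEM table; single-cell groups get
    SEM = NaN, empty groups are dropped with a warning."""
    rows = []
    for (cond, t), grp in measurements.groupby(["condition", "timepoint_h"]):
        vals = grp[value_column].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            warnings.warn(f"dropping empty group ({cond}, t={t})")
            continue
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        rows.append({"condition": cond, "timepoint_h": t, "mean": vals.mean(),
                     "sem": sem, "n": len(vals)})
    return pd.DataFrame(rows).sort_values(["condition", "timepoint_h"]).reset_index(drop=True)


def _roi_max(image: np.ndarray, center: np.ndarray, radius: float, px: float,
             exclude: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Max value and its µm position inside a disc ROI.

    Pixels under ``exclude`` (e.g. the shaft-background mask) are ignored:
    they belong to the background region the threshold is estimated from,
    so counting them in the spine maximum would score background noise
    as spine signal.
    """
    n_rows, n_cols = image.shape
    half = int(np.ceil(radius / px)) + 1
    c0, r0 = int(center[0] / px), int(center[1] / px)
    rr = np.arange(max(0, r0 - half), min(n_rows, r0 + half + 1))
    cc = np.arange(max(0, c0 - half), min(n_cols, c0 + half + 1))
    dy = (rr + 0.5) * px - center[1]
    dx = (cc + 0.5) * px - center[0]
    disc = dy[:, None] ** 2 + dx[None, :] ** 2 <= radius ** 2
    if exclude is not None:
        disc &= ~exclude[np.ix_(rr, cc)]
    if not disc.any():
        return -np.inf, center
    patch = np.where(disc, image[np.ix_(rr, cc)], -np.inf)
    r, c = np.unravel_index(np.argmax(patch), patch.shape)
    pos = np.array([(cc[c] + 0.5) * px, (rr[r] + 0.5) * px])
    return float(patch[r, c]), pos


def spine_occupancy(
    spine_rois: list[tuple[np.ndarray, float]],
    re_channel: np.ndarray,
    cargo_channel: np.ndarray,
    shaft_mask: np.ndarray,
    pixel_size_um: float,
    k_sd: float = 2.0,
    punctum_radius_um: float = 0.3,
    ci_level: float = 0.95,
) -> SpineOccupancy:
    """Spine RE occupancy and cargo gain with the mean + k·SD positivity rule.

    A spine is RE-positive iff the maximum RE intensity inside its ROI
    exceeds the dendritic-shaft background mean + k_sd·SD; an RE-positive
    spine is cargo-positive by the same rule on the cargo channel within a
    small disc at the RE punctum. ROI pixels lying under the shaft mask are
    excluded from the maxima — they are part of the background region the
    threshold is estimated from, and including them scores shaft noise as
    spine signal.
    """
    if not spine_rois:
        raise ValueError("no spine ROIs given")
    shaft_mask = np.asarray(shaft_mask, dtype=bool)
    re_img = np.asarray(re_channel, dtype=float)
    cargo_img = np.asarray(cargo_channel, dtype=float)
    re_thresh = re_img[shaft_mask].mean() + k_sd * re_img[shaft_mask].std()
    cargo_thresh = cargo_img[shaft_mask].mean() + k_sd * cargo_img[shaft_mask].std()
    n_re = 0
    n_gain = 0
    for center, radius in spine_rois:
        re_max, re_pos = _roi_max(re_img, np.asarray(center, float), radius,
                                  pixel_size_um, exclude=shaft_mask)
        if re_max > re_thresh:
            n_re += 1
            cargo_max, _ = _roi_max(cargo_img, re_pos, punctum_radius_um,
                                    pixel_size_um, exclude=shaft_mask)
            if cargo_max > cargo_thresh:
                n_gain += 1
    return SpineOccupancy(
        n_spines=len(spine_rois),
        n_re_positive=n_re,
        n_cargo_gain=n_gain,
        re_fraction_ci=binomial_ci(n_re, len(spine_rois), ci_level),
        gain_fraction_ci=binomial_ci(n_gain, n_re, ci_level) if n_re else (np.nan, np.nan),
    )


def cooccupancy(
    spine_rois: list[tuple[np.ndarray, float]],
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    shaft_mask: np.ndarray,
    pixel_size_um: float,
    k_sd: float = 2.0,
) -> dict:
    """Conditional fraction P(B-positive | A-positive) over spines.

    Positivity follows the spine_occupancy rule independently per channel
    (B is scored over the whole spine ROI, not only at A's punctum).
    """
    if not spine_rois:
        raise ValueError("no spine ROIs given")
    shaft_mask = np.asarray(shaft_mask, dtype=bool)
    a_img = np.asarray(channel_a, dtype=float)
    b_img = np.asarray(channel_b, dtype=float)
    a_thresh = a_img[shaft_mask].mean() + k_sd * a_img[shaft_mask].std()
    b_thresh = b_img[shaft_mask].mean() + k_sd * b_img[shaft_mask].std()
    n_a = 0
    n_ab = 0
    for center, radius in spine_rois:
        center = np.asarray(center, float)
        a_max, _ = _roi_max(a_img, center, radius, pixel_size_um, exclude=shaft_mask)
        if a_max > a_thresh:
            n_a += 1
            b_max, _ = _roi_max(b_img, center, radius, pixel_size_um, exclude=shaft_mask)
            if b_max > b_thresh:
                n_ab += 1
    if n_a == 0:
        raise ValueError("zero A-positive spines; conditional fraction undefined")
    return {"n_a_positive": n_a, "n_both": n_ab, "fraction": n_ab / n_a,
            "ci": binomial_ci(n_ab, n_a)}


def classify_events(
    event_coords: np.ndarray,
    soma_mask: np.ndarray,
    cell_mask: np.ndarray,
    pixel_size_um: float,
) -> dict:
    """Classify fusion events as somatic (inside the soma mask) or dendritic.

    Events outside the cell mask are flagged and excluded from the
    denominator; the two fractions sum to 1.
    """
    pts = np.asarray(event_coords, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("need at least one event")
    soma_mask = np.asarray(soma_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    cols = np.floor(pts[:, 0] / pixel_size_um).astype(int)
    rows = np.floor(pts[:, 1] / pixel_size_um).astype(int)
    on_image = ((rows >= 0) & (rows < cell_mask.shape[0])
                & (cols >= 0) & (cols < cell_mask.shape[1]))
    in_cell = np.zeros(len(pts), dtype=bool)
    in_soma = np.zeros(len(pts), dtype=bool)
    in_cell[on_image] = cell_mask[rows[on_image], cols[on_image]]
    in_soma[on_image] = soma_mask[rows[on_image], cols[on_image]]
    n_excluded = int((~in_cell).sum())
    n_soma = int((in_cell & in_soma).sum())
    n_dend = int((in_cell & ~in_soma).sum())
    total = n_soma + n_dend
    if total == 0:
        raise ValueError("all events fall outside the cell mask")
    return {
        "n_somatic": n_soma,
        "n_dendritic": n_dend,
        "n_excluded": n_excluded,
        "fraction_somatic": n_soma / total,
        "fraction_dendritic": n_dend / total,
    }


def t_test_unpaired(x, y, welch: bool = False) -> tuple[float, float, float]:
    """Unpaired two-tailed Student's t-test (pooled variance by default).

    Returns (t, df, p). With zero pooled variance: equal means give
    (0, df, 1); unequal means are an error. Welch's correction is available
    by flag. Implemented directly; the p-value comes from the regularized
    incomplete beta closed form of the t distribution tail.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("both samples need n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if welch:
        se2 = vx / nx + vy / ny
        df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)) if se2 > 0 else nx + ny - 2
    else:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se2 = sp2 * (1.0 / nx + 1.0 / ny)
        df = nx + ny - 2
    diff = x.mean() - y.mean()
    if se2 == 0:
        if diff == 0:
            return 0.0, float(df), 1.0
        raise ValueError("zero pooled variance with unequal means; t undefined")
    t = diff / np.sqrt(se2)
    # two-tailed p: P(|T_df| >= |t|) = I_{df/(df+t^2)}(df/2, 1/2)
    p = float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))
    return float(t), float(df), p
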