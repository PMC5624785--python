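"""Synthetic dendritic-microscopy generator with recorded ground truth.

Emulates the study conditions of live-cell secretory-trafficking imaging:
a neuron with a soma and spiny dendrites, two puncta populations that are
coupled or independent, Gaussian-PSF spot images with Poisson + Gaussian
camera noise, run-and-pause two-channel vesicle movies with a controllable
double-positive fraction, photoconverted puncta whose intensity decays
exponentially with arc distance from the conversion zone, Bernoulli spine
occupancy, and saturating surface-delivery time courses.

Every generator is a pure function of (config, seed): identical inputs
yield identical outputs. Ground truth is returned alongside the rendered
data so each downstream measurement can be validated without external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imaging_io import ImageStack, RoiMask

__all__ = [
    "SynthConfig",
    "Dendrite",
    "Spine",
    "DendriteGeometry",
    "PunctaSet",
    "Track",
    "TrackSet",
    "LABEL_SOMA",
    "LABEL_DENDRITE",
    "gen_geometry",
    "rasterize_geometry",
    "place_puncta",
    "render_frame",
    "gen_tracks",
    "per_frame_detections",
    "gen_photoconversion",
    "gen_spine_field",
    "gen_delivery_course",
]

LABEL_SOMA = 1
LABEL_DENDRITE = 2


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass
class Dendrite:
    """One dendrite: ordered centerline vertices (µm) with per-vertex half width."""

    centerline: np.ndarray  # (N, 2) µm
    half_width: np.ndarray  # (N,) µm

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        self.half_width = np.asarray(self.half_width, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 2:
            raise ValueError("centerline must be (N, 2)")
        if len(self.half_width) != len(self.centerline):
            raise ValueError("half_width must match centerline length")
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("centerline vertices must strictly increase in arc length")
        if np.any(self.half_width <= 0):
            raise ValueError("half_width must be > 0 everywhere")

    @property
    def arc(self) -> np.ndarray:
        """Cumulative arc length at each vertex (starts at 0)."""
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc[-1])

    def point_at(self, s: float | np.ndarray):
        """Interpolate (position, unit tangent, unit normal, half width) at arc s."""
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, self.length)
        arc = self.arc
        x = np.interp(s, arc, self.centerline[:, 0])
        y = np.interp(s, arc, self.centerline[:, 1])
        hw = np.interp(s, arc, self.half_width)
        idx = np.clip(np.searchsorted(arc, s, side="right") - 1, 0, len(arc) - 2)
        d = self.centerline[idx + 1] - self.centerline[idx]
        t = d / np.linalg.norm(d, axis=1, keepdims=True)
        n = np.column_stack([-t[:, 1], t[:, 0]])
        return np.column_stack([x, y]), t, n, hw


@dataclass
class Spine:
    dendrite_index: int
    arc_pos: float
    side: int  # +1 / -1
    radius: float


@dataclass
class DendriteGeometry:
    """Soma disc plus dendrites with width profiles and spine positions."""

    soma_center: tuple[float, float]
    soma_radius: float
    dendrites: list[Dendrite] = field(default_factory=list)
    spines: list[Spine] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.soma_radius > 0:
            raise ValueError("soma_radius must be > 0")
        for sp in self.spines:
            if sp.side not in (-1, 1):
                raise ValueError("spine side must be +1 or -1")
            length = self.dendrites[sp.dendrite_index].length
            if not (0.0 <= sp.arc_pos <= length):
                raise ValueError("spine arc_pos outside its dendrite's arc range")

    @property
    def total_centerline_length(self) -> float:
        return float(sum(d.length for d in self.dendrites))

    def spine_center(self, spine: Spine) -> np.ndarray:
        den = self.dendrites[spine.dendrite_index]
        pos, _t, n, hw = den.point_at(spine.arc_pos)
        # center offset so the spine disc straddles the dendrite mask boundary
        return (pos + spine.side * (hw + 0.5 * spine.radius)[:, None] * n)[0]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    """All tunable generator parameters (lengths µm, times s unless noted).

    Camera model: counts = Poisson((signal + background) * photon_scale)
    + N(0, read_noise_sd). Defaults give punctum peak SNR ≈ 15 at the
    default amplitude, comfortably inside the detection contract regime.
    """

    seed: int = 0
    # calibration (spinning-disk defaults: 0.1 µm pixels, 4 Hz imaging)
    pixel_size_um: float = 0.1
    frame_interval_s: float = 0.25
    psf_sigma_um: float = 0.13
    # camera
    background_level: float = 50.0
    read_noise_sd: float = 2.0
    photon_scale: float = 1.0
    # geometry
    image_shape: tuple[int, int] = (240, 1040)  # rows, cols
    soma_center_um: tuple[float, float] = (12.0, 12.0)  # (x, y)
    soma_radius_um: float = 8.0
    n_dendrites: int = 1
    dendrite_length_um: float = 80.0
    dendrite_half_width_um: float = 1.0
    dendrite_spacing_um: float = 8.0
    spine_spacing_um: float = 4.0
    spine_radius_um: float = 0.4
    # puncta
    density_per_um: float = 0.5
    amplitude: float = 2000.0
    intensity_cv: float = 0.0
    p_couple: float = 0.0
    sigma_couple_um: float = 0.2
    # vesicle motion
    run_speed_um_s: float = 1.0
    p_pause: float = 0.3
    p_reverse: float = 0.05
    double_positive_fraction: float = 0.5
    marker_only_fraction: float = 0.25
    marker_jitter_um: float = 0.05
    # photoconversion
    zone_um: tuple[float, float] = (10.0, 30.0)
    lambda_true_um: float = 11.6
    # spines
    p_re: float = 0.48
    p_gain: float = 0.206
    # delivery kinetics (hours)
    plateau: float = 3.0
    tau_h: float = 2.0
    delay_h: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_couple", "p_pause", "p_reverse", "double_positive_fraction",
                     "marker_only_fraction", "p_re", "p_gain"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]; got {v}")
        for name in ("pixel_size_um", "psf_sigma_um", "photon_scale",
                     "soma_radius_um", "dendrite_half_width_um", "lambda_true_um",
                     "sigma_couple_um", "tau_h"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.frame_interval_s < 0 or self.read_noise_sd < 0 or self.background_level < 0:
            raise ValueError("frame_interval_s, read_noise_sd, background_level must be >= 0")


# ---------------------------------------------------------------------------
# Puncta / track containers (shared with analysis modules)
# ---------------------------------------------------------------------------

@dataclass
class PunctaSet:
    """Point coordinates (µm) with intensities for one channel and frame."""

    channel: str
    frame: int
    points: np.ndarray  # (N, 2) µm, columns (x, y)
    intensities: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.intensities = np.asarray(self.intensities, dtype=float).reshape(-1)
        if len(self.intensities) != len(self.points):
            raise ValueError("points and intensities must have equal length")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Track:
    track_id: int
    frames: np.ndarray  # strictly increasing frame indices
    positions: np.ndarray  # (N, 2) µm
    intensities: dict = field(default_factory=dict)  # channel -> (N,)
    # per-channel emitter positions when they differ from `positions`
    # (e.g. the jittered marker position of a double-positive vesicle)
    channel_positions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    @property
    def net_displacement(self) -> float:
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))


@dataclass
class TrackSet:
    tracks: list[Track]
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tracks)


# ---------------------------------------------------------------------------
# gen_geometry
# ---------------------------------------------------------------------------

def gen_geometry(config: SynthConfig) -> tuple[DendriteGeometry, RoiMask]:
    """Build a deterministic soma + parallel-dendrites geometry and its label mask.

    Dendrites run horizontally from the soma edge; spines alternate sides at
    regular spacing. The soma label wins where soma and dendrite overlap.
    Raises if any dendrite leaves the image, naming the offender.
    """
    px = config.pixel_size_um
    n_rows, n_cols = config.image_shape
    width_um, height_um = n_cols * px, n_rows * px
    cx, cy = config.soma_center_um
    if (cx - config.soma_radius_um < 0 or cx + config.soma_radius_um > width_um
            or cy - config.soma_radius_um < 0 or cy + config.soma_radius_um > height_um):
        raise ValueError("soma disc exceeds image bounds")

    dendrites: list[Dendrite] = []
    spines: list[Spine] = []
    for i in range(config.n_dendrites):
        y = cy + (i - (config.n_dendrites - 1) / 2) * config.dendrite_spacing_um
        x0 = cx + config.soma_radius_um * 0.8
        x1 = x0 + config.dendrite_length_um
        hw = config.dendrite_half_width_um
        if x1 + hw > width_um or y - hw < 0 or y + hw > height_um:
            raise ValueError(f"dendrite {i} exceeds image bounds")
        n_vert = max(2, int(config.dendrite_length_um // 10) + 1)
        xs = np.linspace(x0, x1, n_vert)
        den = Dendrite(np.column_stack([xs, np.full(n_vert, y)]), np.full(n_vert, hw))
        dendrites.append(den)
        if config.spine_spacing_um > 0:
            arc_positions = np.arange(
                config.spine_spacing_um, den.length - 1e-9, config.spine_spacing_um
            )
            for j, s in enumerate(arc_positions):
                spines.append(Spine(i, float(s), 1 if j % 2 == 0 else -1,
                                    config.spine_radius_um))

    geometry = DendriteGeometry((cx, cy), config.soma_radius_um, dendrites, spines)
    return geometry, rasterize_geometry(geometry, config.image_shape, px)


def rasterize_geometry(
    geometry: DendriteGeometry, image_shape: tuple[int, int], pixel_size_um: float
) -> RoiMask:
    """Label raster: 0 background, 1 soma, 2 dendrite (soma wins on overlap)."""
    n_rows, n_cols = image_shape
    raster = np.zeros((n_rows, n_cols), dtype=np.int32)
    px = pixel_size_um
    xs = (np.arange(n_cols) + 0.5) * px
    ys = (np.arange(n_rows) + 0.5) * px

    for den in geometry.dendrites:
        # stamp discs along a densely sampled centerline
        step = px / 2
        s_samples = np.arange(0.0, den.length + step / 2, step)
        pos, _t, _n, hw = den.point_at(s_samples)
        for (x, y), h in zip(pos, hw):
            r_px = int(np.ceil(h / px)) + 1
            c0 = int(x / px)
            r0 = int(y / px)
            rr = slice(max(0, r0 - r_px), min(n_rows, r0 + r_px + 1))
            cc = slice(max(0, c0 - r_px), min(n_cols, c0 + r_px + 1))
            dy = ys[rr, None] - y
            dx = xs[None, cc] - x
            raster[rr, cc][dy * dy + dx * dx <= h * h] = LABEL_DENDRITE

    cx, cy = geometry.soma_center
    r = geometry.soma_radius
    dy = ys[:, None] - cy
    dx = xs[None, :] - cx
    raster[dy * dy + dx * dx <= r * r] = LABEL_SOMA
    return RoiMask(raster, px, {0: "background", LABEL_SOMA: "soma", LABEL_DENDRITE: "dendrite"})


def _points_in_mask(points: np.ndarray, mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Boolean membership of µm points in a boolean raster (False off-image)."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    cols = np.floor(points[:, 0] / pixel_size_um).astype(int)
    rows = np.floor(points[:, 1] / pixel_size_um).astype(int)
    ok = (rows >= 0) & (rows < mask.shape[0]) & (cols >= 0) & (cols < mask.shape[1])
    out = np.zeros(len(points), dtype=bool)
    out[ok] = mask[rows[ok], cols[ok]]
    return out


# ---------------------------------------------------------------------------
# place_puncta
# ---------------------------------------------------------------------------

def _sample_on_dendrites(geometry: DendriteGeometry, n: int, rng: np.random.Generator):
    """Uniform arc positions over all dendrites with uniform lateral offset."""
    lengths = np.array([d.length for d in geometry.dendrites])
    total = lengths.sum()
    s_global = rng.uniform(0.0, total, n)
    edges = np.concatenate([[0.0], np.cumsum(lengths)])
    den_idx = np.clip(np.searchsorted(edges, s_global, side="right") - 1, 0, len(lengths) - 1)
    points = np.empty((n, 2))
    arc_pos = np.empty(n)
    for i in range(len(geometry.dendrites)):
        sel = den_idx == i
        if not sel.any():
            continue
        s_local = s_global[sel] - edges[i]
        pos, _t, nrm, hw = geometry.dendrites[i].point_at(s_local)
        lateral = rng.uniform(-1.0, 1.0, sel.sum()) * hw
        points[sel] = pos + lateral[:, None] * nrm
        arc_pos[sel] = s_local
    return points, den_idx, arc_pos


def place_puncta(
    geometry: DendriteGeometry,
    mask: RoiMask,
    density_per_um: float,
    coupling: dict | None = None,
    partner: PunctaSet | None = None,
    seed=0,
    channel: str = "ch0",
    amplitude: float = 2000.0,
    intensity_cv: float = 0.0,
) -> tuple[PunctaSet, pd.DataFrame]:
    """Place a Poisson number of puncta along the dendritic arbor.

    Uncoupled puncta are uniform along arc length with uniform lateral
    offset within the local half-width. With ``coupling = {"p_couple": p,
    "sigma_couple_um": s}`` a Bernoulli(p) subset is instead placed at a
    folded-normal radial offset |N(0, s)| (uniform angle) from a uniformly
    chosen partner punctum, resampled until it lands inside the cell mask.

    Returns the puncta and a ground-truth table (x, y, coupled flag).
    """
    if not density_per_um > 0:
        raise ValueError("density_per_um must be > 0")
    p_couple = float(coupling.get("p_couple", 0.0)) if coupling else 0.0
    sigma = float(coupling.get("sigma_couple_um", 0.2)) if coupling else 0.2
    if p_couple > 0 and (partner is None or len(partner) == 0):
        raise ValueError("coupled placement requires a nonempty partner PunctaSet")
    rng = _rng(seed)
    cell = (mask.raster == LABEL_SOMA) | (mask.raster == LABEL_DENDRITE)

    n = rng.poisson(density_per_um * geometry.total_centerline_length)
    coupled = rng.random(n) < p_couple
    points = np.empty((n, 2))
    if (~coupled).any():
        pts, _d, _s = _sample_on_dendrites(geometry, int((~coupled).sum()), rng)
        # resample the rare raster-edge miss so every point is inside the mask
        bad = ~_points_in_mask(pts, cell, mask.pixel_size_um)
        while bad.any():
            pts[bad] = _sample_on_dendrites(geometry, int(bad.sum()), rng)[0]
            bad = ~_points_in_mask(pts, cell, mask.pixel_size_um)
        points[~coupled] = pts
    for i in np.flatnonzero(coupled):
        placed = False
        while not placed:
            base = partner.points[rng.integers(len(partner))]
            for _ in range(100):
                r = abs(rng.normal(0.0, sigma))
                theta = rng.uniform(0.0, 2 * np.pi)
                cand = base + r * np.array([np.cos(theta), np.sin(theta)])
                if _points_in_mask(cand[None], cell, mask.pixel_size_um)[0]:
                    points[i] = cand
                    placed = True
                    break
            else:
                warnings.warn("coupled placement failed after 100 attempts; resampling partner")
    if intensity_cv > 0:
        intensities = amplitude * np.clip(1.0 + rng.normal(0.0, intensity_cv, n), 0.05, None)
    else:
        intensities = np.full(n, amplitude)
    truth = pd.DataFrame({"x_um": points[:, 0], "y_um": points[:, 1],
                          "coupled": coupled, "amplitude": intensities})
    return PunctaSet(channel, 0, points, intensities), truth


# ---------------------------------------------------------------------------
# render_frame
# ---------------------------------------------------------------------------

def _stamp_spots(frame: np.ndarray, points: np.ndarray, amplitudes: np.ndarray,
                 sigma_px: float, px: float) -> None:
    """Add integrated-normalized Gaussian spots in place."""
    half = int(np.ceil(5 * sigma_px))
    n_rows, n_cols = frame.shape
    for (x, y), amp in zip(points, amplitudes):
        c = x / px - 0.5  # pixel-index coordinates of the spot center
        r = y / px - 0.5
        c0, r0 = int(round(c)), int(round(r))
        rr = np.arange(max(0, r0 - half), min(n_rows, r0 + half + 1))
        cc = np.arange(max(0, c0 - half), min(n_cols, c0 + half + 1))
        if len(rr) == 0 or len(cc) == 0:
            continue
        gy = np.exp(-0.5 * ((rr - r) / sigma_px) ** 2)
        gx = np.exp(-0.5 * ((cc - c) / sigma_px) ** 2)
        kernel = np.outer(gy, gx)
        total = kernel.sum()
        if total > 0:
            frame[np.ix_(rr, cc)] += amp * kernel / total


def render_frame(
    geometry_mask: RoiMask,
    puncta_sets: list[PunctaSet],
    config: SynthConfig,
    rng=None,
    noise: bool = True,
) -> ImageStack:
    """Render one frame per channel: Gaussian spots + background + camera noise.

    Each punctum contributes an isotropic Gaussian of width ``psf_sigma_um``
    whose *integrated* counts equal ``amplitude * photon_scale``. Background
    is added inside the cell mask, then Poisson noise is applied to
    ``(signal + background) * photon_scale`` followed by Gaussian read noise;
    values are clipped to the 16-bit range.
    """
    rng = _rng(config.seed if rng is None else rng)
    px = config.pixel_size_um
    sigma_px = config.psf_sigma_um / px
    cell = (geometry_mask.raster == LABEL_SOMA) | (geometry_mask.raster == LABEL_DENDRITE)
    channels = []
    for ps in puncta_sets:
        frame = np.zeros(geometry_mask.raster.shape, dtype=np.float64)
        _stamp_spots(frame, ps.points, ps.intensities, sigma_px, px)
        frame = (frame + config.background_level * cell) * config.photon_scale
        if noise:
            frame = rng.poisson(frame).astype(np.float64)
            frame += rng.normal(0.0, config.read_noise_sd, frame.shape)
        channels.append(np.clip(frame, 0.0, 65535.0))
    data = np.stack(channels)[:, None]  # (C, T=1, Y, X)
    return ImageStack(data, px, config.frame_interval_s, [ps.channel for ps in puncta_sets])


# ---------------------------------------------------------------------------
# gen_tracks
# ---------------------------------------------------------------------------

def gen_tracks(
    geometry: DendriteGeometry,
    n_tracks: int,
    f_dp: float,
    config: SynthConfig,
    n_frames: int = 60,
    seed=0,
    mask: RoiMask | None = None,
    render: bool = True,
) -> tuple[TrackSet, pd.DataFrame, ImageStack | None]:
    """Simulate run-and-pause vesicles on the dendrites and render a 2-channel movie.

    ``n_tracks`` cargo-carrying vesicles are generated; each is independently
    double-positive (also carries marker signal) with probability ``f_dp``.
    An additional ``round(marker_only_fraction * n_tracks)`` vesicles carry
    marker signal only. The marker-channel position of a double-positive
    vesicle is the cargo position plus isotropic N(0, marker_jitter_um)
    jitter per frame. Ground truth records the double-positive labels.
    """
    if not 0.0 <= f_dp <= 1.0:
        raise ValueError("f_dp must be in [0, 1]")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = _rng(seed)
    dt = config.frame_interval_s
    lengths = np.array([d.length for d in geometry.dendrites])
    n_marker_only = int(round(config.marker_only_fraction * n_tracks))
    n_total = n_tracks + n_marker_only
    dp = np.zeros(n_total, dtype=bool)
    dp[:n_tracks] = rng.random(n_tracks) < f_dp
    kind = np.array(["cargo"] * n_tracks + ["marker_only"] * n_marker_only)

    tracks: list[Track] = []
    rows = []
    for tid in range(n_total):
        den_i = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
        den = geometry.dendrites[den_i]
        s = rng.uniform(0.0, den.length)
        direction = rng.choice([-1.0, 1.0])
        lateral = rng.uniform(-0.5, 0.5) * den.half_width.min()
        arc_history = np.empty(n_frames)
        for f in range(n_frames):
            arc_history[f] = s
            if rng.random() < config.p_reverse:
                direction = -direction
            if rng.random() >= config.p_pause:  # running this frame
                s = s + direction * config.run_speed_um_s * dt
                if s < 0.0 or s > den.length:  # reflect at the ends
                    direction = -direction
                    s = float(np.clip(s, 0.0, den.length))
        pos, _t, nrm, _hw = den.point_at(arc_history)
        positions = pos + lateral * nrm
        is_dp = bool(dp[tid])
        carries_cargo = kind[tid] == "cargo"
        carries_marker = is_dp or kind[tid] == "marker_only"
        intensities = {}
        channel_positions = {}
        if carries_cargo:
            intensities["cargo"] = np.full(n_frames, config.amplitude)
        if carries_marker:
            intensities["marker"] = np.full(n_frames, config.amplitude)
            if is_dp and config.marker_jitter_um > 0:
                channel_positions["marker"] = positions + rng.normal(
                    0.0, config.marker_jitter_um, positions.shape)
        tracks.append(Track(tid, np.arange(n_frames), positions, intensities,
                            channel_positions))
        rows.append({"track_id": tid, "kind": kind[tid], "double_positive": is_dp,
                     "dendrite": den_i})
    truth = pd.DataFrame(rows)
    tset = TrackSet(tracks, {"f_dp": f_dp, "n_frames": n_frames,
                             "run_speed_um_s": config.run_speed_um_s,
                             "p_pause": config.p_pause, "p_reverse": config.p_reverse})
    movie = None
    if render:
        if mask is None:
            mask = rasterize_geometry(geometry, config.image_shape, config.pixel_size_um)
        frames_c, frames_m = [], []
        for f in range(n_frames):
            cargo_pts, cargo_amp, marker_pts, marker_amp = [], [], [], []
            for tr in tracks:
                if "cargo" in tr.intensities:
                    cargo_pts.append(tr.positions[f])
                    cargo_amp.append(tr.intensities["cargo"][f])
                if "marker" in tr.intensities:
                    marker_pts.append(tr.channel_positions.get("marker", tr.positions)[f])
                    marker_amp.append(tr.intensities["marker"][f])
            sets = [
                PunctaSet("cargo", f, np.array(cargo_pts).reshape(-1, 2), cargo_amp),
                PunctaSet("marker", f, np.array(marker_pts).reshape(-1, 2), marker_amp),
            ]
            img = render_frame(mask, sets, config, rng=rng)
            frames_c.append(img.data[0, 0])
            frames_m.append(img.data[1, 0])
        movie = ImageStack(np.stack([np.stack(frames_c), np.stack(frames_m)]),
                           config.pixel_size_um, dt, ["cargo", "marker"])
    return tset, truth, movie


def per_frame_detections(tset: TrackSet, channel: str, n_frames: int) -> list[np.ndarray]:
    """Ground-truth per-frame detection coordinates for one channel.

    Emulates a perfect detector on the generated movie, so matching logic can
    be exercised at scale without rendering images.
    """
    buckets: list[list[np.ndarray]] = [[] for _ in range(n_frames)]
    for tr in tset.tracks:
        if channel not in tr.intensities:
            continue
        pos = tr.channel_positions.get(channel, tr.positions)
        for i, f in enumerate(tr.frames):
            if 0 <= f < n_frames:
                buckets[f].append(pos[i])
    return [np.array(b).reshape(-1, 2) for b in buckets]


# ---------------------------------------------------------------------------
# gen_photoconversion
# ---------------------------------------------------------------------------

def gen_photoconversion(
    geometry: DendriteGeometry,
    zone_um: tuple[float, float],
    lambda_true_um: float,
    amplitude: float,
    seed=0,
    n_puncta: int = 200,
    arc_range_um: tuple[float, float] | None = None,
    intensity_cv: float = 0.0,
    dendrite_index: int = 0,
) -> tuple[PunctaSet, PunctaSet, pd.DataFrame]:
    """Photoconversion pulse-chase field on one dendrite.

    Green-channel amplitudes are uniform; the red (converted) amplitude of a
    punctum at arc distance x from the nearest zone edge is
    ``amplitude * exp(-x / lambda_true_um)`` (x > 0) and ``amplitude`` inside
    the zone. Truth records λ and per-punctum distances.
    """
    a, b = zone_um
    den = geometry.dendrites[dendrite_index]
    if not (0.0 <= a < b <= den.length):
        raise ValueError("conversion zone must be a nonempty interval within the dendrite")
    if not lambda_true_um > 0:
        raise ValueError("lambda_true_um must be > 0")
    rng = _rng(seed)
    lo, hi = arc_range_um if arc_range_um is not None else (0.0, den.length)
    arc = rng.uniform(lo, hi, n_puncta)
    pos, _t, nrm, hw = den.point_at(arc)
    lateral = rng.uniform(-1.0, 1.0, n_puncta) * hw
    points = pos + lateral[:, None] * nrm
    dist = np.where((arc >= a) & (arc <= b), 0.0, np.minimum(np.abs(arc - a), np.abs(arc - b)))
    red_amp = amplitude * np.exp(-dist / lambda_true_um)
    green_amp = np.full(n_puncta, amplitude)
    if intensity_cv > 0:
        red_amp = red_amp * np.clip(1.0 + rng.normal(0.0, intensity_cv, n_puncta), 0.05, None)
        green_amp = green_amp * np.clip(1.0 + rng.normal(0.0, intensity_cv, n_puncta), 0.05, None)
    truth = pd.DataFrame({"arc_um": arc, "distance_um": dist, "x_um": points[:, 0],
                          "y_um": points[:, 1], "red_amplitude": red_amp,
                          "lambda_true_um": lambda_true_um})
    red = PunctaSet("converted", 0, points, red_amp)
    green = PunctaSet("total", 0, points, green_amp)
    return red, green, truth


# ---------------------------------------------------------------------------
# gen_spine_field
# ---------------------------------------------------------------------------

def gen_spine_field(
    geometry: DendriteGeometry,
    p_re: float,
    p_gain: float,
    config: SynthConfig,
    seed=0,
    mask: RoiMask | None = None,
    render: bool = True,
) -> tuple[list[tuple[np.ndarray, float]], pd.DataFrame, ImageStack | None]:
    """Bernoulli spine occupancy: RE-positive w.p. p_re; of those, cargo w.p. p_gain.

    Returns spine ROIs as (center_xy_um, radius_um), per-spine truth flags,
    and an optional rendered 2-channel (re, cargo) image whose spot peaks sit
    well above the shaft noise floor.
    """
    if not geometry.spines:
        raise ValueError("geometry has no spines")
    rng = _rng(seed)
    n = len(geometry.spines)
    re_pos = rng.random(n) < p_re
    gain = re_pos & (rng.random(n) < p_gain)
    centers = np.array([geometry.spine_center(sp) for sp in geometry.spines])
    rois = [(centers[i], geometry.spines[i].radius) for i in range(n)]
    truth = pd.DataFrame({"spine": np.arange(n), "x_um": centers[:, 0],
                          "y_um": centers[:, 1], "re_positive": re_pos,
                          "cargo_positive": gain})
    image = None
    if render:
        if mask is None:
            mask = rasterize_geometry(geometry, config.image_shape, config.pixel_size_um)
        re_set = PunctaSet("re", 0, centers[re_pos], np.full(int(re_pos.sum()), config.amplitude))
        cargo_set = PunctaSet("cargo", 0, centers[gain], np.full(int(gain.sum()), config.amplitude))
        image = render_frame(mask, [re_set, cargo_set], config, rng=rng)
    return rois, truth, image


# ---------------------------------------------------------------------------
# gen_delivery_course
# ---------------------------------------------------------------------------

def gen_delivery_course(
    kinetics: dict,
    timepoints_h,
    n_cells: int,
    noise_cv: float,
    seed=0,
    n_control: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Saturating surface-delivery time course in fold-over-control units.

    Per-cell fold at time t: ``1 + (plateau - 1) * (1 - exp(-max(t - delay, 0)
    / tau))``, times ``(1 + N(0, noise_cv))``; no-release control cells sit at
    baseline fold 1. Raw means are emitted at 100 counts per fold unit with a
    constant camera background so the measurement path exercises background
    subtraction and control normalization.
    """
    plateau = float(kinetics["plateau"])
    tau = float(kinetics["tau_h"])
    delay = float(kinetics.get("delay_h", 0.0))
    if plateau < 0:
        raise ValueError("plateau must be nonnegative")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    timepoints_h = np.asarray(timepoints_h, dtype=float)
    if np.any(timepoints_h < 0):
        raise ValueError("timepoints must be nonnegative")
    rng = _rng(seed)
    n_control = n_cells if n_control is None else n_control
    scale, background = 100.0, 10.0
    rows = []
    cid = 0
    for t in timepoints_h:
        fold = 1.0 + (plateau - 1.0) * (1.0 - np.exp(-max(t - delay, 0.0) / tau))
        for _ in range(n_cells):
            v = fold * (1.0 + rng.normal(0.0, noise_cv))
            rows.append({"cell_id": cid, "condition": "release", "timepoint_h": t,
                         "raw_mean": max(v, 0.0) * scale + background,
                         "background": background})
            cid += 1
        for _ in range(n_control):
            v = 1.0 * (1.0 + rng.normal(0.0, noise_cv))
            rows.append({"cell_id": cid, "condition": "no-release", "timepoint_h": t,
                         "raw_mean": max(v, 0.0) * scale + background,
                         "background": background})
            cid += 1
    truth = {"plateau": plateau, "tau_h": tau, "delay_h": delay,
             "scale": scale, "background": background}
    return pd.DataFrame(rows), truth
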