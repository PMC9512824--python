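"""Visual stimulus generation.

Builds every stimulus class used by the simulators as a space-time luminance
movie: full-field and masked static flashes, moving bars with occluding masks
(emergence / exit conditions), apparent-motion bar sequences, and synthetic
naturalistic movies in which a bright silhouette emerges from behind a static
occluder over a textured background.

Conventions: model-input movies use background = 0 with bar amplitude equal to
the contrast value; naturalistic movies use the 8-bit 0-255 luminance scale.
Positions are reported in µm from the array start; mask extents are half-open
``[start, end)`` intervals; 1-D movies have shape ``(n_x, n_t)`` and 2-D
movies ``(n_y, n_x, n_t)`` (time last).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "StimulusMovie",
    "BarSpec",
    "NaturalMovieParams",
    "make_static_flash",
    "make_moving_bar",
    "apply_mask",
    "make_apparent_motion",
    "apparent_motion_shuffles",
    "make_synthetic_natural_movie",
    "make_natural_movie_pair",
]

CONDITION_LABELS = (
    "flash_full",
    "flash_masked",
    "motion_full",
    "motion_emerging",
    "motion_exiting",
    "apparent_motion",
    "natural_movie",
)

#: Named seed from which the seven fixed apparent-motion shuffle patterns are
#: generated once (mirroring a precomputed pseudorandom stimulus set).
SHUFFLE_SEED = 140_350

#: Default pre-stimulus baseline prepended to generated movies (ms).
DEFAULT_BASELINE_MS = 200.0


@dataclass
class StimulusMovie:
    """Space-time luminance movie with geometry and mask annotations."""

    frames: np.ndarray
    dx: float
    dt: float
    background: float = 0.0
    mask_regions: list[tuple[float, float]] = field(default_factory=list)
    condition_label: str = "motion_full"
    #: for naturalistic movies, boolean occluder silhouette (n_y, n_x)
    mask_silhouette: np.ndarray | None = None
    #: (x_um, y_um) where the stimulus first becomes visible, if applicable
    emergence_site: tuple[float, float] | None = None
    #: time (ms) at which the stimulus first becomes visible, if applicable
    emergence_time_ms: float | None = None
    #: visible-stimulus centroid once the silhouette has fully emerged
    full_emergence_site: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim not in (2, 3):
            raise ValueError("frames must be (n_x, n_t) or (n_y, n_x, n_t)")
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite luminance")
        for lo, hi in self.mask_regions:
            if not (0 <= lo < hi <= self.extent_x_um + 1e-9):
                raise ValueError(f"mask region ({lo}, {hi}) outside spatial bounds")

    @property
    def is_2d(self) -> bool:
        return self.frames.ndim == 3

    @property
    def n_t(self) -> int:
        return self.frames.shape[-1]

    @property
    def n_x(self) -> int:
        return self.frames.shape[-2] if self.is_2d else self.frames.shape[0]

    @property
    def n_y(self) -> int:
        return self.frames.shape[0] if self.is_2d else 1

    @property
    def extent_x_um(self) -> float:
        return self.n_x * self.dx

    @property
    def extent_y_um(self) -> float:
        return self.n_y * self.dx

    @property
    def duration_ms(self) -> float:
        return self.n_t * self.dt

    @property
    def x_um(self) -> np.ndarray:
        """Spatial sample coordinates along x (µm, 0-based sample centers)."""
        return np.arange(self.n_x) * self.dx

    @property
    def y_um(self) -> np.ndarray:
        return np.arange(self.n_y) * self.dx

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_t) * self.dt

    def upsampled_to(self, dt: float) -> "StimulusMovie":
        """Frame-hold resample to a finer time step (dt must divide self.dt)."""
        if np.isclose(dt, self.dt):
            return self
        rep = self.dt / dt
        if abs(rep - round(rep)) > 1e-9:
            raise ValueError("target dt must integer-divide movie dt")
        frames = np.repeat(self.frames, int(round(rep)), axis=-1)
        return replace(self, frames=frames, dt=dt)

    def mirrored(self) -> "StimulusMovie":
        """Spatial mirror along x, with mask intervals mirrored accordingly."""
        frames = self.frames[..., ::-1, :] if self.is_2d else self.frames[::-1, :]
        regions = [
            (self.extent_x_um - hi, self.extent_x_um - lo)
            for lo, hi in self.mask_regions
        ]
        sil = None
        if self.mask_silhouette is not None:
            sil = self.mask_silhouette[:, ::-1]
        site = None
        if self.emergence_site is not None:
            site = (self.extent_x_um - self.emergence_site[0], self.emergence_site[1])
        return replace(
            self,
            frames=frames.copy(),
            mask_regions=regions,
            mask_silhouette=sil,
            emergence_site=site,
        )


@dataclass(frozen=True)
class BarSpec:
    """Geometry and contrast of a bar stimulus.

    ``contrast`` follows the Michelson convention (fraction in [-1, 1]); for
    the model-input luminance scale the bar amplitude simply equals this
    value. ``speed`` is in mm/s; ``flash_duration`` in ms.
    """

    bar_length: float = 800.0
    bar_width: float = 800.0
    speed: float = 0.5
    direction: str = "right"
    contrast: float = 1.0
    flash_duration: float = 2000.0

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if abs(self.contrast) > 1:
            raise ValueError("|contrast| must be <= 1")
        if self.direction not in ("left", "right"):
            raise ValueError("direction must be 'left' or 'right'")


def _n_samples(extent: float, dx: float) -> int:
    n = extent / dx
    if abs(n - round(n)) > 1e-9:
        raise ValueError("dx must divide the spatial extent")
    return int(round(n))


def make_static_flash(
    spec: BarSpec,
    extent: float = 1500.0,
    dx: float = 10.0,
    dt: float = 1.0,
    onset: float = DEFAULT_BASELINE_MS,
    tail: float = 500.0,
    center: float | None = None,
) -> StimulusMovie:
    """Stationary bar flashed for ``spec.flash_duration`` ms.

    The bar of length ``spec.bar_length`` (µm along x) is centered at
    ``center`` (default: array midpoint) and set to ``spec.contrast`` during
    ``[onset, onset + flash_duration)``; luminance is background elsewhere.
    """
    if spec.flash_duration <= 0:
        raise ValueError("flash_duration must be positive")
    if spec.bar_length > extent:
        raise ValueError("geometry smaller than bar")
    n_x = _n_samples(extent, dx)
    n_t = int(round((onset + spec.flash_duration + tail) / dt))
    frames = np.zeros((n_x, n_t))
    c = extent / 2 if center is None else center
    x = np.arange(n_x) * dx
    inside = (x >= c - spec.bar_length / 2) & (x < c + spec.bar_length / 2)
    t0 = int(round(onset / dt))
    t1 = int(round((onset + spec.flash_duration) / dt))
    frames[inside, t0:t1] = spec.contrast
    return StimulusMovie(frames, dx=dx, dt=dt, condition_label="flash_full")


def make_moving_bar(
    spec: BarSpec,
    extent: float = 1500.0,
    dx: float = 10.0,
    dt: float = 1.0,
    onset: float = DEFAULT_BASELINE_MS,
    tail: float = 200.0,
) -> StimulusMovie:
    """Bar translating across the full array at ``spec.speed`` mm/s.

    The leading edge enters the array at ``onset`` and advances
    ``speed * dt`` µm per frame (speed in mm/s equals µm/ms); each spatial
    sample is covered for ``bar_length / speed`` ms.  ``direction='left'``
    yields the exact spatial mirror of the rightward movie.
    """
    if spec.speed <= 0:
        raise ValueError("speed must be positive for a moving bar")
    n_x = _n_samples(extent, dx)
    v = spec.speed  # mm/s == µm/ms
    travel = (extent + spec.bar_length) / v
    n_t = int(round((onset + travel + tail) / dt))
    t = np.arange(n_t) * dt
    x = np.arange(n_x) * dx
    lead = (t - onset) * v  # leading-edge position, µm
    # sample covered while lead - bar_length <= x < lead
    cover = (x[:, None] < lead[None, :]) & (x[:, None] >= lead[None, :] - spec.bar_length)
    frames = np.where(cover, spec.contrast, 0.0)
    movie = StimulusMovie(frames, dx=dx, dt=dt, condition_label="motion_full")
    if spec.direction == "left":
        movie = movie.mirrored()
        movie.condition_label = "motion_full"
    return movie


def _derive_masked_label(movie: StimulusMovie, region: tuple[float, float]) -> str:
    base = movie.condition_label
    if base.startswith("flash"):
        return "flash_masked"
    if base.startswith("motion"):
        at_start = region[0] <= 1e-9
        at_end = region[1] >= movie.extent_x_um - 1e-9
        # infer motion direction from the center-of-luminance drift
        s = movie.frames.sum(axis=tuple(range(movie.frames.ndim - 1)))
        on = np.flatnonzero(s > 0)
        if on.size >= 2:
            xw = movie.x_um
            w0 = movie.frames[..., on[0]].reshape(-1, movie.n_x).sum(axis=0)
            w1 = movie.frames[..., on[-1]].reshape(-1, movie.n_x).sum(axis=0)
            moving_right = (w1 @ xw) / max(w1.sum(), 1e-12) >= (w0 @ xw) / max(
                w0.sum(), 1e-12
            )
        else:
            moving_right = True
        if (moving_right and at_start) or ((not moving_right) and at_end):
            return "motion_emerging"
        if (moving_right and at_end) or ((not moving_right) and at_start):
            return "motion_exiting"
    return base


def apply_mask(
    movie: StimulusMovie, region: tuple[float, float], label: str | None = None
) -> StimulusMovie:
    """Clamp luminance to background inside ``region`` (µm, half-open) at all times.

    The mask is recorded in ``mask_regions`` and the condition label is
    re-derived: a mask at the start side of motion yields ``motion_emerging``
    (the bar appears from behind the occluder), at the far side
    ``motion_exiting``; masked flashes become ``flash_masked``.  Masking is
    idempotent.
    """
    lo, hi = region
    if hi <= lo:
        warnings.warn("empty mask region; returning movie unchanged", stacklevel=2)
        return movie
    if lo < 0 or hi > movie.extent_x_um + 1e-9:
        raise ValueError("mask region outside movie bounds")
    new_label = label if label is not None else _derive_masked_label(movie, region)
    x = movie.x_um
    inside = (x >= lo) & (x < hi)
    frames = movie.frames.copy()
    if movie.is_2d:
        frames[:, inside, :] = movie.background
    else:
        frames[inside, :] = movie.background
    regions = list(movie.mask_regions)
    if region not in regions:
        regions.append((float(lo), float(hi)))
    return replace(
        movie, frames=frames, mask_regions=regions, condition_label=new_label
    )


def apparent_motion_shuffles(
    n_positions: int = 14, n_patterns: int = 7, seed: int = SHUFFLE_SEED
) -> list[np.ndarray]:
    """The fixed pseudorandom presentation orders (permutations of positions)."""
    rng = np.random.default_rng(seed)
    return [rng.permutation(n_positions) for _ in range(n_patterns)]


def make_apparent_motion(
    order: str = "sequential_right",
    seed: int = SHUFFLE_SEED,
    dx: float = 25.0,
    extent: float | None = None,
    flash_ms: float = 50.0,
    n_positions: int = 14,
    pitch: float = 25.0,
    contrast: float = 1.0,
    onset: float = DEFAULT_BASELINE_MS,
    offset_um: float = 0.0,
) -> StimulusMovie:
    """Apparent-motion sequence of brief bar flashes.

    Fourteen 25-µm-wide bars tile a 350-µm span at 25-µm pitch; each is
    flashed for 50 ms.  ``order`` selects sequential presentation (leftward or
    rightward apparent motion) or one of the seven fixed pseudorandom
    patterns (``"shuffle_1"`` .. ``"shuffle_7"``).  Shuffled orders are
    permutations: the multiset of per-position flash frames is identical to
    the sequential movie.
    """
    span = n_positions * pitch
    if extent is None:
        extent = offset_um + span
    n_x = _n_samples(extent, dx)
    if order == "sequential_right":
        seq = np.arange(n_positions)
    elif order == "sequential_left":
        seq = np.arange(n_positions)[::-1]
    elif order.startswith("shuffle_"):
        k = int(order.split("_")[1])
        if not 1 <= k <= 7:
            raise ValueError("shuffle index must be in 1..7")
        seq = apparent_motion_shuffles(n_positions, seed=seed)[k - 1]
    else:
        raise ValueError(f"unknown order {order!r}")
    n_t = int(round((onset + n_positions * flash_ms) / 1.0))
    frames = np.zeros((n_x, n_t))
    x = np.arange(n_x) * dx
    for slot, pos in enumerate(seq):
        lo = offset_um + pos * pitch
        inside = (x >= lo) & (x < lo + pitch)
        t0 = int(round(onset + slot * flash_ms))
        t1 = int(round(onset + (slot + 1) * flash_ms))
        frames[inside, t0:t1] = contrast
    return StimulusMovie(frames, dx=dx, dt=1.0, condition_label="apparent_motion")


# ---------------------------------------------------------------------------
# synthetic naturalistic movies


#: Named seed fixing the foreground scene (stimulus silhouette, its texture
#: and the occluder) across background permutations.
SCENE_SEED = 424_242


@dataclass(frozen=True)
class NaturalMovieParams:
    """Conditions of the synthetic naturalistic-movie ensemble.

    A spatially correlated random background (Gaussian-smoothed noise,
    rescaled to mean 128 / SD 30 on the 8-bit scale) fills a 100 x 100-sample
    frame (10 µm/sample -> 1 x 1 mm of visual space).  A bright silhouette
    ("the stimulus" — a predator-sized blob spanning about half the field,
    mean luminance 2 SD above background) translates rightward at 0.5 mm/s;
    in the masked variant a static occluder with an irregular boundary hides
    its approach so it pops into view at the mask edge, while the unmasked
    variant shows the full continuous trajectory.  The foreground scene
    (silhouette, its texture, the occluder) is drawn once from
    ``scene_seed`` and held fixed, so that an ensemble of trials permutes
    only the background; the display refreshes every 20 ms (50 Hz) and
    simulators frame-hold to 1 ms.
    """

    n_y: int = 100
    n_x: int = 100
    dx: float = 10.0
    frame_ms: float = 20.0
    duration_ms: float = 1800.0
    background_mean: float = 128.0
    background_sd: float = 30.0
    stimulus_sd_above: float = 2.0
    smooth_fwhm_px: float = 5.0
    speed: float = 0.5  # mm/s
    masked: bool = True
    mask_boundary_um: float = 400.0
    mask_edge_jitter_um: float = 30.0
    stim_diameter_um: float = 500.0
    stim_start_um: float = 100.0  # silhouette center x at movie start
    baseline_ms: float = DEFAULT_BASELINE_MS
    scene_seed: int = SCENE_SEED


def _smooth_noise(rng: np.random.Generator, shape, fwhm_px: float) -> np.ndarray:
    sigma = fwhm_px / (2 * np.sqrt(2 * np.log(2)))
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return z


def _rescale(z: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return (z - z.mean()) / z.std() * sd + mean


def _blob_silhouette(
    rng: np.random.Generator, radius_px: float, n: int = 41
) -> np.ndarray:
    """Irregular compact silhouette: disc modulated by smooth noise."""
    yy, xx = np.mgrid[:n, :n] - (n - 1) / 2
    r = np.hypot(yy, xx)
    wobble = _smooth_noise(rng, (n, n), 5.0)
    wobble = wobble / max(np.abs(wobble).max(), 1e-9)
    return r <= radius_px * (1.0 + 0.3 * wobble)


def make_synthetic_natural_movie(
    params: NaturalMovieParams | None = None, seed: int = 0
) -> StimulusMovie:
    """Render one synthetic naturalistic movie (see :class:`NaturalMovieParams`).

    Returns a 2-D :class:`StimulusMovie` on the 0-255 luminance scale whose
    ``emergence_site`` records where the stimulus first becomes visible.  The
    same ``seed`` with ``masked`` toggled yields the identical background,
    silhouette and trajectory, giving paired mask-on/off trials.
    """
    p = params or NaturalMovieParams()
    rng = np.random.default_rng(seed)  # background permutation
    scene = np.random.default_rng(p.scene_seed)  # fixed foreground scene
    n_frames = int(round(p.duration_ms / p.frame_ms))

    background = _rescale(
        _smooth_noise(rng, (p.n_y, p.n_x), p.smooth_fwhm_px),
        p.background_mean,
        p.background_sd,
    )

    # stimulus silhouette and texture (mean 2 SD above the background mean)
    radius_px = p.stim_diameter_um / 2 / p.dx
    blob = _blob_silhouette(scene, radius_px)
    stim_mean = p.background_mean + p.stimulus_sd_above * p.background_sd
    blob_tex = _rescale(
        _smooth_noise(scene, blob.shape, p.smooth_fwhm_px), stim_mean, p.background_sd
    )

    # static occluder: left band with an irregular vertical boundary
    edge_noise = _smooth_noise(scene, (p.n_y,), p.smooth_fwhm_px)
    edge_noise = edge_noise / max(np.abs(edge_noise).max(), 1e-9)
    boundary_x = p.mask_boundary_um + p.mask_edge_jitter_um * edge_noise
    mask_sil = (np.arange(p.n_x)[None, :] * p.dx) < boundary_x[:, None]
    mask_tex = _rescale(
        _smooth_noise(scene, (p.n_y, p.n_x), p.smooth_fwhm_px),
        p.background_mean,
        p.background_sd,
    )

    frames = np.empty((p.n_y, p.n_x, n_frames))
    y_c = p.n_y // 2
    bh = blob.shape[0]
    half = bh // 2
    n_blob_px = int(blob.sum())
    emergence: tuple[float, float] | None = None
    emergence_t: float | None = None
    full_emergence: tuple[float, float] | None = None
    for f in range(n_frames):
        t = f * p.frame_ms
        frame = background.copy()
        stim_visible = np.zeros((p.n_y, p.n_x), dtype=bool)
        on_screen = t >= p.baseline_ms
        if on_screen:
            x_c = int(round((p.stim_start_um + (t - p.baseline_ms) * p.speed) / p.dx))
            x0, y0 = x_c - half, y_c - half
            fy = slice(max(y0, 0), min(y0 + bh, p.n_y))
            fx = slice(max(x0, 0), min(x0 + bh, p.n_x))
            by = slice(fy.start - y0, fy.stop - y0)
            bx = slice(fx.start - x0, fx.stop - x0)
            cut = blob[by, bx]
            frame[fy, fx][cut] = blob_tex[by, bx][cut]
            stim_visible[fy, fx] = cut
        if p.masked:
            frame[mask_sil] = mask_tex[mask_sil]
            stim_visible &= ~mask_sil
        if stim_visible.any():
            if emergence is None:
                ys, xs = np.nonzero(stim_visible)
                emergence = (float(xs.mean() * p.dx), float(ys.mean() * p.dx))
                emergence_t = t
            if full_emergence is None and stim_visible.sum() >= 0.98 * n_blob_px:
                ys, xs = np.nonzero(stim_visible)
                full_emergence = (float(xs.mean() * p.dx), float(ys.mean() * p.dx))
        frames[..., f] = frame

    regions = []
    if p.masked:
        regions.append((0.0, float(np.floor(boundary_x.min() / p.dx)) * p.dx))
    return StimulusMovie(
        frames,
        dx=p.dx,
        dt=p.frame_ms,
        background=p.background_mean,
        mask_regions=regions,
        condition_label="natural_movie",
        mask_silhouette=mask_sil if p.masked else None,
        emergence_site=emergence,
        emergence_time_ms=emergence_t,
        full_emergence_site=full_emergence,
    )


def make_natural_movie_pair(
    params: NaturalMovieParams | None = None, seed: int = 0
) -> tuple[StimulusMovie, StimulusMovie, tuple[float, float]]:
    """Paired masked / unmasked trials sharing background, silhouette and path.

    Returns ``(masked, unmasked, emergence_site)`` where the emergence site is
    taken from the masked trial (the unmasked trial shows established motion
    through the same location).
    """
    p = params or NaturalMovieParams()
    masked = make_synthetic_natural_movie(replace(p, masked=True), seed=seed)
    unmasked = make_synthetic_natural_movie(replace(p, masked=False), seed=seed)
    if masked.emergence_site is None:
        raise RuntimeError("stimulus never emerged; extend duration_ms")
    return masked, unmasked, masked.emergence_site
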