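"""Ground-truth-labelled synthetic inputs for the analysis pipeline.

Generates kinetic response templates (sigmoid rise, optional plateau,
exponential decay), lays them out as spatially compact pixel patches in a
mock imaging field, and renders glutamate-sensor-like movies for a battery of
stimulus conditions with known cluster membership — so every pipeline stage
can be validated against a manifest instead of real recordings.

Default field geometry mirrors a typical two-photon acquisition: an
82 x 82 µm window sampled at 0.64 µm/px (rendered post-binning at
1.28 µm/px) and ~50 Hz frames.  Motion conditions time-shift each patch's
response by its receptive-field position divided by the bar speed and apply
the template's motion modifiers, making motion-vs-stationary kinetics a
controllable ground truth.  Noise is additive white Gaussian on dF/F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import stimuli as _stimuli
from .roi_pipeline import ConditionSegment, ImagingMovie

__all__ = [
    "ClusterTemplate",
    "GroundTruthManifest",
    "template_waveform",
    "make_cluster_templates",
    "make_layout",
    "render_imaging_movie",
    "make_condition_battery",
]


@dataclass(frozen=True)
class ClusterTemplate:
    """Kinetic ground truth for one functional release type."""

    polarity: str = "on"
    rise_t50: float = 100.0  # ms from response onset to 50% of peak
    decay_tau: float = 300.0  # ms
    plateau_ms: float = 0.0  # dwell at peak before decay begins
    delay_ms: float = 0.0  # response latency after stimulus onset
    sustained_frac: float = 0.0  # post-decay plateau level relative to peak
    undershoot: float = 0.0  # post-peak dip amplitude relative to peak
    rebound: float = 0.0  # secondary release lobe amplitude relative to peak
    rebound_delay_ms: float = 450.0  # secondary lobe center after the peak
    amplitude: float = 1.0  # peak dF/F
    #: multiplicative changes applied in motion conditions
    motion_amp: float = 1.0
    motion_rise: float = 1.0

    def __post_init__(self) -> None:
        if self.rise_t50 <= 0 or self.decay_tau <= 0 or self.amplitude <= 0:
            raise ValueError("rise_t50, decay_tau and amplitude must be positive")


def template_waveform(
    tpl: ClusterTemplate,
    t_ms: np.ndarray,
    onset_ms: float = 0.0,
    motion: bool = False,
) -> np.ndarray:
    """Evaluate the template response at times ``t_ms``.

    Logistic rise reaching 50% of amplitude ``rise_t50`` ms after onset
    (plus ``delay_ms`` latency), holding near peak for ``plateau_ms``, then
    single-exponential decay with ``decay_tau`` toward a sustained plateau
    at ``sustained_frac`` of the peak, optionally overshooting into a
    transient dip of relative depth ``undershoot``.  Motion conditions scale
    amplitude and rise time by the template's motion modifiers.
    """
    rise = tpl.rise_t50 * (tpl.motion_rise if motion else 1.0)
    amp = tpl.amplitude * (tpl.motion_amp if motion else 1.0)
    slope = rise / 4.0
    mid = onset_ms + tpl.delay_ms + rise
    t_peak = mid + 6.0 * slope + tpl.plateau_ms
    t = np.asarray(t_ms, dtype=float)
    rising = amp / (1.0 + np.exp(-(np.minimum(t, t_peak) - mid) / slope))
    peak_val = amp / (1.0 + np.exp(-6.0))
    dt_pk = np.maximum(t - t_peak, 0.0)
    level = tpl.sustained_frac * peak_val
    decay = level + (peak_val - level) * np.exp(-dt_pk / tpl.decay_tau)
    dip = (
        tpl.undershoot
        * peak_val
        * (1.0 - np.exp(-dt_pk / tpl.decay_tau))
        * np.exp(-dt_pk / (2.0 * tpl.decay_tau))
    )
    out = np.where(t <= t_peak, rising, decay - dip)
    if tpl.rebound > 0:
        # multiphasic release: a secondary Gaussian lobe after the main peak
        out = out + tpl.rebound * peak_val * np.exp(
            -0.5 * ((t - t_peak - tpl.rebound_delay_ms) / (tpl.rebound_delay_ms / 3.0))
            ** 2
        )
    sign = 1.0 if tpl.polarity == "on" else -1.0
    return sign * out


def make_cluster_templates(
    k: int,
    seed: int = 0,
    rise_range: tuple[float, float] = (40.0, 280.0),
    decay_range: tuple[float, float] = (120.0, 1500.0),
    delay_range: tuple[float, float] = (0.0, 200.0),
    amp_range: tuple[float, float] = (0.5, 1.5),
    pool_size: int = 256,
    min_separation: float = 0.3,
) -> list[ClusterTemplate]:
    """Draw ``k`` mutually distinguishable templates.

    A seeded pool of candidate (rise, decay, latency) triples is reduced to
    ``k`` members by greedy maximin selection on the correlation distance
    between their 1-s flash waveforms, so that any two templates differ by
    more than realistic within-type variability and measurement noise.  The
    first selected pair is the most dissimilar of the pool, which guarantees
    one clearly transient and one clearly sustained member for every k >= 2.
    If the selected set falls below ``min_separation`` (correlation
    distance), the pool is enlarged and selection repeated, so the returned
    ground truth is distinguishable by construction whenever the waveform
    space permits.  Templates are returned sorted by rise time.
    """
    if k < 2:
        raise ValueError("need k >= 2 templates")
    for lo, hi in (rise_range, decay_range, amp_range):
        if not hi > lo > 0:
            raise ValueError("degenerate parameter range")
    best: list[ClusterTemplate] | None = None
    best_sep = -1.0
    for attempt in range(4):
        chosen, sep = _maximin_templates(
            k, seed + 100_003 * attempt, rise_range, decay_range, delay_range,
            amp_range, pool_size * (2**attempt),
        )
        if sep > best_sep:
            best, best_sep = chosen, sep
        if best_sep >= min_separation:
            break
    return sorted(best, key=lambda c: c.rise_t50)


def _maximin_templates(
    k, seed, rise_range, decay_range, delay_range, amp_range, pool_size
) -> tuple[list[ClusterTemplate], float]:
    rng = np.random.default_rng(seed)
    rises = rng.uniform(*rise_range, pool_size)
    decays = np.exp(rng.uniform(np.log(decay_range[0]), np.log(decay_range[1]), pool_size))
    delays = rng.uniform(*delay_range, pool_size)
    amps = rng.uniform(*amp_range, pool_size)
    sus = rng.uniform(0.0, 0.8, pool_size)
    under = np.where(rng.uniform(size=pool_size) < 0.5, rng.uniform(0, 0.4, pool_size), 0.0)
    reb = np.where(rng.uniform(size=pool_size) < 0.3, rng.uniform(0.2, 0.6, pool_size), 0.0)
    reb_delay = rng.uniform(300.0, 600.0, pool_size)
    t = np.arange(0, 1000.0, 20.0)  # 1-s window at 50 Hz
    cands = [
        ClusterTemplate(
            polarity="on",
            rise_t50=float(rises[i]),
            decay_tau=float(decays[i]),
            delay_ms=float(delays[i]),
            sustained_frac=float(sus[i]),
            undershoot=float(under[i] if sus[i] < 0.3 else 0.0),
            rebound=float(reb[i]),
            rebound_delay_ms=float(reb_delay[i]),
            amplitude=float(amps[i]),
            motion_amp=float(rng.uniform(0.7, 1.3)),
            motion_rise=float(rng.uniform(1.0, 2.0)),
        )
        for i in range(pool_size)
    ]
    wfs = np.array([template_waveform(c, t) for c in cands])
    z = wfs - wfs.mean(axis=1, keepdims=True)
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    dist = 1.0 - z @ z.T
    sel = list(np.unravel_index(np.argmax(dist), dist.shape))
    while len(sel) < k:
        dmin = dist[sel].min(axis=0)
        dmin[sel] = -1.0
        sel.append(int(np.argmax(dmin)))
    sub = dist[np.ix_(sel, sel)] + np.eye(k) * 9.0
    return [cands[i] for i in sel], float(sub.min())


@dataclass(frozen=True)
class Patch:
    """Spatially compact pixel group expressing one template."""

    template: int
    y0: int
    x0: int
    height: int
    width: int
    rf_x_um: float  # horizontal RF offset from field center


@dataclass
class GroundTruthManifest:
    """Everything needed to reproduce a rendered movie bit-exactly."""

    templates: list[ClusterTemplate]
    patches: list[Patch]
    label_image: np.ndarray  # (n_y, n_x) template index per pixel, -1 = none
    noise_sd: float
    seed: int
    segments: list[ConditionSegment]
    frame_hz: float
    um_per_px: float

    def pixel_labels(self, selected: np.ndarray | None = None) -> np.ndarray:
        """Flat template labels for (optionally selected) pixels."""
        if selected is None:
            return self.label_image.ravel()
        return self.label_image[selected]


def make_layout(
    n_templates: int,
    rois_per_template: int = 3,
    field_px: tuple[int, int] = (32, 32),
    patch_px: int = 4,
    um_per_px: float = 2.56,
    seed: int = 0,
) -> list[Patch]:
    """Place non-overlapping square patches on a grid, cycling templates.

    RF positions are drawn uniformly within ±40 µm of the field center.
    """
    rng = np.random.default_rng(seed)
    gap = patch_px + 2
    slots = [
        (y, x)
        for y in range(1, field_px[0] - patch_px, gap)
        for x in range(1, field_px[1] - patch_px, gap)
    ]
    need = n_templates * rois_per_template
    if need > len(slots):
        raise ValueError("field too small for requested patches")
    order = rng.permutation(len(slots))[:need]
    patches = []
    for i, s in enumerate(order):
        y, x = slots[s]
        patches.append(
            Patch(
                template=i % n_templates,
                y0=y,
                x0=x,
                height=patch_px,
                width=patch_px,
                rf_x_um=float(rng.uniform(-40.0, 40.0)),
            )
        )
    return patches


DEFAULT_BATTERY = (
    ("flash_full", False),
    ("motion_right", True),
    ("motion_left", True),
)


def render_imaging_movie(
    templates: list[ClusterTemplate],
    patches: list[Patch] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    battery=DEFAULT_BATTERY,
    field_px: tuple[int, int] = (32, 32),
    frame_hz: float = 50.0,
    segment_s: float = 3.0,
    onset_s: float = 0.5,
    speed: float = 0.5,
    um_per_px: float = 2.56,
    raw: bool = False,
    n_repeats: int = 1,
    patch_jitter: float = 0.05,
) -> tuple[ImagingMovie, GroundTruthManifest]:
    """Render a labelled synthetic imaging movie for a condition battery.

    Each patch's pixels share the patch template's response; motion
    conditions shift the onset by ``rf_x_um / speed`` ms (leftward motion
    with the opposite sign) and apply the template motion modifiers.  Seeded
    white Gaussian noise of SD ``noise_sd`` is added per pixel and frame.
    With ``raw=True`` the movie is returned as fluorescence ``F = 1 + dF/F``
    with a one-segment baseline for :func:`csretina.roi_pipeline.preprocess`;
    ``n_repeats > 1`` stacks independent noise realizations of the same
    protocol on a leading repeat axis (averaged during preprocessing).
    ``patch_jitter`` applies seeded per-patch spread (fractional SD on rise,
    decay and amplitude, plus latency jitter), emulating cell-to-cell
    variability within a functional type; without it, identical-waveform
    patches make internal cluster-validity indices degenerate.
    """
    if patches is None:
        patches = make_layout(len(templates), seed=seed)
    label_image = np.full(field_px, -1, dtype=int)
    for p in patches:
        if np.any(label_image[p.y0 : p.y0 + p.height, p.x0 : p.x0 + p.width] >= 0):
            raise ValueError("overlapping patches")
        label_image[p.y0 : p.y0 + p.height, p.x0 : p.x0 + p.width] = p.template

    n_seg = int(round(segment_s * frame_hz))
    baseline_frames = int(round(onset_s * frame_hz))
    dt_ms = 1000.0 / frame_hz
    segments = []
    start = baseline_frames  # global baseline chunk first
    data = [np.zeros((*field_px, baseline_frames))]
    rng = np.random.default_rng(seed)
    from dataclasses import replace as _replace

    patch_tpls = []
    for p in patches:
        tpl = templates[p.template]
        if patch_jitter > 0:
            mul = rng.normal(1.0, patch_jitter, 3).clip(0.5, 1.5)
            dly = rng.normal(0.0, 250.0 * patch_jitter)
            tpl = _replace(
                tpl,
                rise_t50=tpl.rise_t50 * mul[0],
                decay_tau=tpl.decay_tau * mul[1],
                amplitude=tpl.amplitude * mul[2],
                delay_ms=max(tpl.delay_ms + dly, 0.0),
            )
        patch_tpls.append(tpl)
    for name, is_motion in battery:
        t_ms = np.arange(n_seg) * dt_ms
        seg_frames = np.zeros((*field_px, n_seg))
        for p, tpl in zip(patches, patch_tpls):
            onset = onset_s * 1000.0
            if is_motion:
                shift = p.rf_x_um / speed
                onset += shift if name.endswith("right") else -shift
            wf = template_waveform(tpl, t_ms, onset_ms=onset, motion=is_motion)
            seg_frames[p.y0 : p.y0 + p.height, p.x0 : p.x0 + p.width, :] = wf
        entrance = start + baseline_frames
        segments.append(ConditionSegment(name, start, start + n_seg, entrance))
        data.append(seg_frames)
        start += n_seg
    dff = np.concatenate(data, axis=-1)
    if n_repeats > 1:
        dff = dff[None] + rng.normal(0.0, noise_sd, (n_repeats, *dff.shape))
    else:
        dff = dff + rng.normal(0.0, noise_sd, dff.shape)
    manifest = GroundTruthManifest(
        templates=list(templates),
        patches=list(patches),
        label_image=label_image,
        noise_sd=noise_sd,
        seed=seed,
        segments=segments,
        frame_hz=frame_hz,
        um_per_px=um_per_px,
    )
    if raw:
        movie = ImagingMovie(
            1.0 + dff,
            um_per_px=um_per_px,
            frame_hz=frame_hz,
            segments=segments,
            baseline=(0, baseline_frames),
            is_dff=False,
        )
    else:
        movie = ImagingMovie(
            dff,
            um_per_px=um_per_px,
            frame_hz=frame_hz,
            segments=segments,
            baseline=(0, baseline_frames),
            is_dff=True,
        )
    return movie, manifest


def make_condition_battery(
    extent: float = 1500.0,
    dx: float = 10.0,
    mask_um: float = 300.0,
    contrast: float = 1.0,
    include_apparent_motion: bool = True,
) -> dict[str, _stimuli.StimulusMovie]:
    """The standard stimulus battery as space-time movies.

    Full-field flash, masked flash (static edge), full-field motion in both
    directions, emergence and exit variants for each mask side, and the
    apparent-motion sequences (sequential plus the seven fixed shuffles).
    """
    flash = _stimuli.BarSpec(
        bar_length=extent, contrast=contrast, flash_duration=2000.0
    )
    bar = _stimuli.BarSpec(bar_length=1000.0, speed=0.5, contrast=contrast)
    right = _stimuli.make_moving_bar(bar, extent=extent, dx=dx)
    left = _stimuli.make_moving_bar(
        _stimuli.BarSpec(bar_length=1000.0, speed=0.5, direction="left", contrast=contrast),
        extent=extent,
        dx=dx,
    )
    battery = {
        "flash_full": _stimuli.make_static_flash(flash, extent=extent, dx=dx),
        "flash_masked": _stimuli.apply_mask(
            _stimuli.make_static_flash(flash, extent=extent, dx=dx),
            (0.0, mask_um),
        ),
        "motion_right": right,
        "motion_left": left,
        # rightward bar: left mask -> emergence, right mask -> exit
        "motion_right_emerging": _stimuli.apply_mask(right, (0.0, mask_um)),
        "motion_right_exiting": _stimuli.apply_mask(right, (extent - mask_um, extent)),
        "motion_left_emerging": _stimuli.apply_mask(left, (extent - mask_um, extent)),
        "motion_left_exiting": _stimuli.apply_mask(left, (0.0, mask_um)),
    }
    if include_apparent_motion:
        battery["apparent_right"] = _stimuli.make_apparent_motion("sequential_right")
        battery["apparent_left"] = _stimuli.make_apparent_motion("sequential_left")
        for k in range(1, 8):
            battery[f"apparent_shuffle_{k}"] = _stimuli.make_apparent_motion(
                f"shuffle_{k}"
            )
    return battery
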