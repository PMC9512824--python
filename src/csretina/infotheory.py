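"""Information-theoretic readout of novel-object responses.

Quantifies how much a population of linear center-surround units tells a
downstream observer about whether a stimulus appeared from behind an occluder
(mask present) or moved in continuously (mask absent).  Peak responses in a
500-ms window from object appearance are rounded to the nearest integer and
the plug-in (maximum-likelihood) mutual information

    I(VS; R) = H(VS) - H(VS | R)

is computed per cell from the joint counts of condition label and discretized
peak across paired background permutations.  No bias correction is applied;
the estimator is the direct empirical formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .linear_rf import LinearRFParams, component_traces
from .stimuli import NaturalMovieParams, make_natural_movie_pair

__all__ = [
    "discretize_peaks",
    "entropy",
    "mutual_information",
    "permutation_null_mi",
    "select_emergence_cells",
    "NoveltyEnsemble",
    "run_novelty_ensemble",
    "per_cell_mi",
    "mi_surround_sweep",
    "enhancement_vs_distance",
    "half_max_width",
]


def discretize_peaks(peaks) -> np.ndarray:
    """Round peak amplitudes to the nearest integer (half away from zero).

    Negative inputs clamp to 0: peaks are rectified before discretization
    because the expected response range starts at zero.
    """
    peaks = np.asarray(peaks, dtype=float)
    if not np.all(np.isfinite(peaks)):
        raise ValueError("peaks must be finite")
    out = np.floor(np.abs(peaks) + 0.5) * np.sign(peaks)
    return np.maximum(out, 0.0).astype(np.int64)


def entropy(symbols) -> float:
    """Plug-in entropy (bits) of an observed symbol sample, -sum p log2 p."""
    symbols = np.asarray(symbols)
    if symbols.size == 0:
        raise ValueError("empty sample")
    _, counts = np.unique(symbols, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information(conditions, responses) -> float:
    """Plug-in mutual information (bits) between condition labels and responses.

    ``I = H(VS) - H(VS|R)`` from the empirical joint contingency of the two
    aligned sequences; responses are used as-is (discretize first if they are
    continuous).  A single observed condition yields 0 with a warning.
    """
    conditions = np.asarray(conditions)
    responses = np.asarray(responses)
    if conditions.shape != responses.shape:
        raise ValueError("conditions and responses must be aligned")
    cond_vals, cond_idx = np.unique(conditions, return_inverse=True)
    if cond_vals.size < 2:
        warnings.warn("single condition present; MI = 0", stacklevel=2)
        return 0.0
    resp_vals, resp_idx = np.unique(responses, return_inverse=True)
    joint = np.zeros((cond_vals.size, resp_vals.size))
    np.add.at(joint, (cond_idx, resp_idx), 1.0)
    n = joint.sum()
    h_vs = entropy(conditions)
    # H(VS|R) = sum_r p(r) H(VS | R = r)
    p_r = joint.sum(axis=0) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        p_c_given_r = joint / joint.sum(axis=0, keepdims=True)
        terms = np.where(p_c_given_r > 0, p_c_given_r * np.log2(p_c_given_r), 0.0)
    h_cond = float(-(p_r * terms.sum(axis=0)).sum())
    return max(h_vs - h_cond, 0.0)


def permutation_null_mi(
    conditions, responses, n_perm: int = 200, seed: int = 0
) -> np.ndarray:
    """MI values under random permutation of the condition labels."""
    rng = np.random.default_rng(seed)
    conditions = np.asarray(conditions)
    return np.array(
        [
            mutual_information(rng.permutation(conditions), responses)
            for _ in range(n_perm)
        ]
    )


def select_emergence_cells(
    positions: np.ndarray, emergence_site, radius: float = 100.0
) -> np.ndarray:
    """Indices of cells strictly within ``radius`` µm of the emergence site."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    site = np.asarray(emergence_site, dtype=float)
    d = np.hypot(positions[:, 0] - site[0], positions[:, 1] - site[1])
    idx = np.flatnonzero(d < radius)
    if idx.size == 0:
        raise ValueError("no cells within radius of the emergence site")
    return idx


# ---------------------------------------------------------------------------
# paired mask-on/off ensemble over background permutations


@dataclass
class NoveltyEnsemble:
    """Peak responses of a linear RF population across paired trials.

    ``peaks`` has shape ``(n_factors, n_cells, n_trials, 2)`` with the last
    axis ordering (mask present, mask absent); entries are rectified peak
    activations within each cell's 500-ms appearance window.
    """

    factors: np.ndarray
    positions: np.ndarray  # (n_cells, 2) µm
    peaks: np.ndarray
    #: centroid of the stimulus once fully emerged (anchors cell selection)
    emergence_site: tuple[float, float]
    #: centroid of first visibility, at the occluder boundary (anchors the
    #: distance axis of the enhancement profile)
    boundary_site: tuple[float, float] = (0.0, 0.0)
    window_ms: float = 500.0
    movie_params: NaturalMovieParams = field(default_factory=NaturalMovieParams)

    def factor_index(self, factor: float) -> int:
        i = int(np.argmin(np.abs(self.factors - factor)))
        if not np.isclose(self.factors[i], factor):
            raise KeyError(f"factor {factor} not simulated")
        return i


def _cell_grid(p: NaturalMovieParams, spacing: float) -> np.ndarray:
    """Cells covering the analysis region around the emergence zone."""
    y_c = (p.n_y // 2) * p.dx
    xs = np.arange(
        p.mask_boundary_um - 100.0,
        p.mask_boundary_um + p.stim_diameter_um + 200.0 + 1e-9,
        spacing,
    )
    ys = np.arange(y_c - 120.0, y_c + 120.0 + 1e-9, spacing)
    xs = xs[(xs >= 0) & (xs <= (p.n_x - 1) * p.dx)]
    ys = ys[(ys >= 0) & (ys <= (p.n_y - 1) * p.dx)]
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def run_novelty_ensemble(
    movie_params: NaturalMovieParams | None = None,
    rf_params: LinearRFParams | None = None,
    factors=(0.0, 0.5),
    n_trials: int = 1000,
    seed: int = 0,
    grid_spacing: float = 10.0,
    window_ms: float = 500.0,
) -> NoveltyEnsemble:
    """Simulate paired masked/unmasked naturalistic trials and collect peaks.

    Each trial redraws the background from a fresh seed (``seed + trial``)
    while the foreground scene (stimulus silhouette and occluder) stays
    fixed, emulating an ensemble of background permutations; the masked and
    unmasked members of a pair share every random draw.  For each cell the
    response window spans ``window_ms`` from the time the stimulus reaches
    the cell's x position (appearance time at the emergence boundary plus
    travel time), identical across the pair.  Peaks are stored for every
    requested surround factor; because the model is linear the factors reuse
    one center/surround simulation per movie.
    """
    p = movie_params or NaturalMovieParams()
    rf = rf_params or LinearRFParams()
    factors = np.asarray(sorted(set(float(f) for f in factors)))
    positions = _cell_grid(p, grid_spacing)
    n_cells = positions.shape[0]
    peaks = np.zeros((factors.size, n_cells, n_trials, 2), dtype=np.float32)
    sites = np.zeros((n_trials, 2))
    full_sites = np.zeros((n_trials, 2))
    for trial in range(n_trials):
        masked, unmasked, site = make_natural_movie_pair(p, seed=seed + trial)
        sites[trial] = site
        full_sites[trial] = masked.full_emergence_site
        t_em = masked.emergence_time_ms
        # per-cell appearance window (same for both pair members)
        travel = np.maximum(positions[:, 0] - site[0], 0.0) / p.speed
        w_lo = (t_em + travel).astype(int)
        for c_i, movie in enumerate((masked, unmasked)):
            center, surround = component_traces(movie, rf, positions)
            n_t = center.shape[1]
            w = int(window_ms)
            lo = np.minimum(w_lo, max(n_t - w, 0))
            idx = lo[:, None] + np.arange(min(w, n_t))[None, :]
            c_w = np.take_along_axis(center, idx, axis=1)
            s_w = np.take_along_axis(surround, idx, axis=1)
            for f_i, f in enumerate(factors):
                peaks[f_i, :, trial, c_i] = np.maximum(
                    (c_w - f * s_w).max(axis=1), 0.0
                )
    return NoveltyEnsemble(
        factors=factors,
        positions=positions,
        peaks=peaks,
        emergence_site=tuple(full_sites.mean(axis=0)),
        boundary_site=tuple(sites.mean(axis=0)),
        window_ms=window_ms,
        movie_params=p,
    )


def per_cell_mi(
    ens: NoveltyEnsemble, factor: float = 0.5, radius: float = 100.0
) -> tuple[np.ndarray, float]:
    """Per-cell MI (bits) for cells within ``radius`` of the emergence site.

    Returns ``(mi_per_cell, mean_mi)``; MI is computed from integer-rounded
    peaks against the mask-present / mask-absent labels, pooled over all
    trials of both conditions.
    """
    f_i = ens.factor_index(factor)
    cells = select_emergence_cells(ens.positions, ens.emergence_site, radius)
    n_trials = ens.peaks.shape[2]
    labels = np.concatenate([np.zeros(n_trials, int), np.ones(n_trials, int)])
    mi = np.empty(cells.size)
    for k, u in enumerate(cells):
        resp = discretize_peaks(
            np.concatenate([ens.peaks[f_i, u, :, 0], ens.peaks[f_i, u, :, 1]])
        )
        mi[k] = mutual_information(labels, resp)
    return mi, float(mi.mean())


def mi_surround_sweep(
    ens: NoveltyEnsemble, radius: float = 100.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean (and across-cell SD) MI for every simulated surround factor."""
    means = np.empty(ens.factors.size)
    sds = np.empty(ens.factors.size)
    for i, f in enumerate(ens.factors):
        mi, m = per_cell_mi(ens, factor=f, radius=radius)
        means[i], sds[i] = m, mi.std()
    return ens.factors.copy(), means, sds


def enhancement_vs_distance(
    ens: NoveltyEnsemble, factor: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Masked-minus-unmasked peak change vs distance from the mask boundary.

    Cells are binned by signed x distance from the emergence site (one bin
    per grid column, averaging over rows and trials); returns
    ``(distance_um, mean_change, sd_change)`` where the SD is across trials
    of the row-averaged change.
    """
    f_i = ens.factor_index(factor)
    dist = ens.positions[:, 0] - ens.boundary_site[0]
    uniq = np.unique(dist)
    diff = ens.peaks[f_i, :, :, 0].astype(float) - ens.peaks[f_i, :, :, 1]
    mean = np.empty(uniq.size)
    sd = np.empty(uniq.size)
    for i, d in enumerate(uniq):
        sel = np.isclose(dist, d)
        per_trial = diff[sel].mean(axis=0)
        mean[i], sd[i] = per_trial.mean(), per_trial.std()
    return uniq, mean, sd


def half_max_width(distance_um: np.ndarray, profile: np.ndarray) -> float:
    """Width (µm) of the contiguous region around the profile peak above half-max.

    Uses linear interpolation at the half-maximum crossings.
    """
    i_max = int(np.argmax(profile))
    half = profile[i_max] / 2.0
    if profile[i_max] <= 0:
        return 0.0
    lo = i_max
    while lo > 0 and profile[lo - 1] > half:
        lo -= 1
    hi = i_max
    while hi < profile.size - 1 and profile[hi + 1] > half:
        hi += 1
    d_lo = distance_um[lo]
    if lo > 0:
        frac = (profile[lo] - half) / (profile[lo] - profile[lo - 1])
        d_lo = distance_um[lo] - frac * (distance_um[lo] - distance_um[lo - 1])
    d_hi = distance_um[hi]
    if hi < profile.size - 1:
        frac = (profile[hi] - half) / (profile[hi] - profile[hi + 1])
        d_hi = distance_um[hi] + frac * (distance_um[hi + 1] - distance_um[hi])
    return float(d_hi - d_lo)
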