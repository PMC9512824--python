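"""Imaging-analysis pipeline for glutamate-sensor movies.

Stages mirror a standard two-photon functional-imaging workflow:

1. ``preprocess`` — average repeats, 2x2 spatial binning, 20-Hz zero-phase
   low-pass, dF/F against a pre-stimulus baseline;
2. ``select_pixels`` — keep pixels whose peak dF/F across conditions exceeds
   20%;
3. ``primary_cluster`` — within-field grouping of pixels by the shape of
   their responses (concatenated 1-s windows around stimulus entrance, one
   per condition) with farthest-point (maximin) clustering on a pairwise
   distance matrix; spatially connected members of a cluster become ROIs;
4. ``curate_rois`` — drop ROIs whose across-pixel coefficient of variation
   exceeds 1;
5. ``secondary_cluster`` — across-experiment agglomerative clustering of ROI
   waveforms (static-flash responses only, per polarity) with the c-index
   selecting the cluster count;
6. ``cluster_summary`` — per-cluster mean waveforms, transiency and kinetics.

Distances default to 1 - Pearson correlation (amplitude-invariant);
Euclidean is available via ``metric="euclidean"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import butter, sosfiltfilt
from scipy.spatial.distance import pdist, squareform
from skimage.measure import block_reduce, label as cc_label

from . import metrics as _metrics

__all__ = [
    "ConditionSegment",
    "ImagingMovie",
    "ROI",
    "ClusterModel",
    "preprocess",
    "select_pixels",
    "farthest_point_cluster",
    "primary_cluster",
    "curate_rois",
    "c_index",
    "secondary_cluster",
    "cluster_summary",
]


@dataclass(frozen=True)
class ConditionSegment:
    """Frame range of one stimulus condition within the movie.

    ``entrance_frame`` marks when the stimulus enters the imaging window;
    feature windows for clustering are taken around it.
    """

    name: str
    start: int
    stop: int  # half-open
    entrance_frame: int


@dataclass
class ImagingMovie:
    """Pixels-x-time fluorescence movie with condition annotations.

    ``data`` is ``(n_y, n_x, n_t)`` (dF/F after preprocessing) or
    ``(n_rep, n_y, n_x, n_t)`` raw with a repeat axis.
    """

    data: np.ndarray
    um_per_px: float = 1.28
    frame_hz: float = 50.0
    segments: list[ConditionSegment] = field(default_factory=list)
    baseline: tuple[int, int] | None = None
    is_dff: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (n_y, n_x, n_t) or (n_rep, n_y, n_x, n_t)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")
        spans = sorted((s.start, s.stop) for s in self.segments)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("condition segments overlap")

    @property
    def n_t(self) -> int:
        return self.data.shape[-1]

    def segment(self, name: str) -> ConditionSegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)


def preprocess(
    movie: ImagingMovie,
    bin_factor: int = 2,
    lowpass_hz: float = 20.0,
) -> ImagingMovie:
    """Repeat-average, spatially bin, low-pass filter and convert to dF/F.

    The movie must declare a pre-stimulus ``baseline`` frame range; dF/F is
    computed per pixel against the baseline mean.  The temporal filter is a
    zero-phase 4th-order Butterworth (skipped when the cutoff is at or above
    Nyquist).  Frame indices in ``segments`` are preserved.
    """
    if movie.baseline is None:
        raise ValueError("movie has no baseline segment")
    data = movie.data
    if data.ndim == 4:
        data = data.mean(axis=0)
    if bin_factor > 1:
        data = block_reduce(data, (bin_factor, bin_factor, 1), np.mean)
    nyq = movie.frame_hz / 2.0
    if lowpass_hz < nyq:
        sos = butter(4, lowpass_hz / nyq, output="sos")
        data = sosfiltfilt(sos, data, axis=-1)
    b0, b1 = movie.baseline
    f0 = data[..., b0:b1].mean(axis=-1, keepdims=True)
    if np.any(f0 == 0):
        raise ValueError("zero baseline fluorescence; cannot form dF/F")
    dff = data / f0 - 1.0
    return ImagingMovie(
        dff,
        um_per_px=movie.um_per_px * bin_factor,
        frame_hz=movie.frame_hz,
        segments=list(movie.segments),
        baseline=movie.baseline,
        is_dff=True,
    )


def select_pixels(movie: ImagingMovie, threshold: float = 0.20) -> np.ndarray:
    """Boolean map of pixels whose peak dF/F across conditions exceeds threshold."""
    if movie.segments:
        peak = np.max(
            [movie.data[..., s.start : s.stop].max(axis=-1) for s in movie.segments],
            axis=0,
        )
    else:
        peak = movie.data.max(axis=-1)
    sel = peak > threshold
    if not sel.any():
        warnings.warn("no pixels exceeded the dF/F threshold", stacklevel=2)
    return sel


def _feature_windows(
    movie: ImagingMovie, window_ms: tuple[float, float] = (-200.0, 800.0)
) -> np.ndarray:
    """Concatenated per-condition windows around stimulus entrance, per pixel.

    Returns ``(n_y, n_x, n_feat)``.
    """
    fps = movie.frame_hz
    lo = int(round(window_ms[0] / 1000.0 * fps))
    hi = int(round(window_ms[1] / 1000.0 * fps))
    chunks = []
    for s in movie.segments:
        a = max(s.entrance_frame + lo, s.start)
        b = min(s.entrance_frame + hi, s.stop)
        chunks.append(movie.data[..., a:b])
    return np.concatenate(chunks, axis=-1)


def _distance_matrix(features: np.ndarray, metric: str) -> np.ndarray:
    if metric == "correlation":
        return squareform(pdist(features, metric="correlation"), checks=False)
    if metric == "euclidean":
        return squareform(pdist(features, metric="euclidean"), checks=False)
    raise ValueError("metric must be 'correlation' or 'euclidean'")


def farthest_point_cluster(
    dist: np.ndarray, threshold: float, max_clusters: int | None = None
) -> np.ndarray:
    """Maximin-seeded partitioning of items given their distance matrix.

    Seeds start from the item with the largest summed distance; new seeds are
    added at the item farthest from its nearest seed until that distance
    falls below ``threshold`` (or ``max_clusters`` is reached); every item is
    then assigned to its nearest seed.  Deterministic given the matrix.
    """
    n = dist.shape[0]
    if n == 0:
        return np.empty(0, dtype=int)
    seeds = [int(np.argmax(dist.sum(axis=1)))]
    d_near = dist[seeds[0]].copy()
    while True:
        far = int(np.argmax(d_near))
        if d_near[far] < threshold:
            break
        if max_clusters is not None and len(seeds) >= max_clusters:
            break
        seeds.append(far)
        d_near = np.minimum(d_near, dist[far])
    return np.argmin(dist[seeds], axis=0)


@dataclass
class ROI:
    """A spatially contiguous group of pixels with similar responses."""

    pixels: np.ndarray  # (n_px, 2) integer (row, col)
    member_traces: np.ndarray  # (n_px, n_t)
    cluster: int
    um_per_px: float = 1.28
    frame_hz: float = 50.0

    @property
    def mean_trace(self) -> np.ndarray:
        return self.member_traces.mean(axis=0)

    @property
    def extent_um(self) -> float:
        """Largest pixel-to-pixel span of the ROI (µm)."""
        if len(self.pixels) == 1:
            return self.um_per_px
        span = self.pixels.max(axis=0) - self.pixels.min(axis=0) + 1
        return float(np.hypot(*span) * self.um_per_px)

    def cov(self, window: slice | None = None) -> float:
        """Across-pixel coefficient of variation of the response.

        Mean over window timepoints of (SD across member pixels) / |mean
        across member pixels|, restricted to timepoints where the mean is
        appreciably nonzero.
        """
        tr = self.member_traces if window is None else self.member_traces[:, window]
        if tr.shape[0] == 1:
            return 0.0
        m = tr.mean(axis=0)
        s = tr.std(axis=0, ddof=0)
        strong = np.abs(m) > 0.05 * np.abs(m).max()
        if not strong.any():
            return float("inf")
        return float((s[strong] / np.abs(m[strong])).mean())


def primary_cluster(
    movie: ImagingMovie,
    selected: np.ndarray | None = None,
    metric: str = "correlation",
    threshold: float = 0.5,
    window_ms: tuple[float, float] = (-200.0, 800.0),
    max_clusters: int | None = 32,
) -> list[ROI]:
    """Group selected pixels into ROIs by response-shape similarity.

    Feature vectors are the concatenated 1-s windows around stimulus
    entrance, one per condition; pixels are partitioned by farthest-point
    clustering on the pairwise distance matrix and spatially connected
    members of a cluster become ROIs.
    """
    if selected is None:
        selected = select_pixels(movie)
    ys, xs = np.nonzero(selected)
    if ys.size < 2:
        raise ValueError("need at least 2 selected pixels")
    feats = _feature_windows(movie, window_ms)[ys, xs]
    dist = _distance_matrix(feats, metric)
    assign = farthest_point_cluster(dist, threshold, max_clusters)
    rois: list[ROI] = []
    for c in np.unique(assign):
        mask = np.zeros(selected.shape, dtype=int)
        mask[ys[assign == c], xs[assign == c]] = 1
        comps = cc_label(mask, connectivity=2)
        for lab in range(1, comps.max() + 1):
            py, px = np.nonzero(comps == lab)
            rois.append(
                ROI(
                    pixels=np.column_stack([py, px]),
                    member_traces=movie.data[py, px],
                    cluster=int(c),
                    um_per_px=movie.um_per_px,
                    frame_hz=movie.frame_hz,
                )
            )
    return rois


def curate_rois(
    rois: list[ROI], max_cov: float = 1.0, window: slice | None = None
) -> list[ROI]:
    """Drop ROIs whose across-pixel coefficient of variation exceeds ``max_cov``.

    The threshold is a strict inequality: CoV exactly at the limit is kept.
    """
    return [r for r in rois if not r.cov(window) > max_cov]


def c_index(dist: np.ndarray, labels: np.ndarray) -> float:
    """Internal cluster-validity c-index (0 good .. 1 bad).

    ``C = (S - S_min) / (S_max - S_min)`` where S is the sum of all
    within-cluster pairwise distances, and S_min / S_max are the sums of the
    same number of smallest / largest distances in the whole matrix.
    """
    labels = np.asarray(labels)
    n = dist.shape[0]
    iu = np.triu_indices(n, 1)
    all_d = dist[iu]
    within = labels[iu[0]] == labels[iu[1]]
    n_w = int(within.sum())
    if n_w == 0 or n_w == all_d.size:
        return float("nan")
    s = all_d[within].sum()
    d_sorted = np.sort(all_d)
    s_min = d_sorted[:n_w].sum()
    s_max = d_sorted[-n_w:].sum()
    if s_max == s_min:
        return 0.0
    return float((s - s_min) / (s_max - s_min))


@dataclass
class ClusterModel:
    """Result of the secondary (across-experiment) clustering."""

    assignments: np.ndarray
    k: int
    cluster_means: np.ndarray  # (k, n_feat)
    cindex_curve: dict[int, float]
    polarity: str = "on"
    linkage_method: str = "average"


def secondary_cluster(
    waveforms: np.ndarray,
    k_range=range(2, 17),
    polarity: str = "on",
    metric: str = "correlation",
    linkage_method: str = "average",
    plausible: tuple[int, int] = (3, 15),
) -> ClusterModel:
    """Hierarchical clustering of ROI waveforms with c-index model selection.

    ``waveforms`` is (n_rois, n_feat) — typically the 1-s static-flash
    response of each curated ROI, polarity pre-split.  The c-index is
    computed for every k in ``k_range``; the chosen k is the first local
    minimum of the curve within the ``plausible`` bounds (internal validity
    curves typically fall steeply to the true cluster count and dip again
    when near-identical sub-groups are split, so extreme or late minima are
    reported in the curve but not selected); if no interior local minimum
    exists the bounded global minimum is used.
    """
    waveforms = np.asarray(waveforms, dtype=float)
    if len(list(k_range)) == 0:
        raise ValueError("k_range is empty")
    dist = _distance_matrix(waveforms, metric)
    n = waveforms.shape[0]
    iu = np.triu_indices(n, 1)
    Z = linkage(dist[iu], method=linkage_method)
    curve: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in k_range:
        if k < 1 or k > n:
            continue
        lab = fcluster(Z, t=k, criterion="maxclust")
        labelings[k] = lab
        curve[k] = c_index(dist, lab)
    candidates = [
        k for k in curve if plausible[0] <= k <= plausible[1] and np.isfinite(curve[k])
    ]
    if not candidates:
        candidates = [k for k in curve if np.isfinite(curve[k])]

    def _val(k: int) -> float:
        v = curve.get(k, np.inf)
        return v if np.isfinite(v) else np.inf

    eps = 1e-9
    local_minima = [
        k for k in candidates if _val(k) <= _val(k - 1) + eps and _val(k) <= _val(k + 1) + eps
    ]
    best_k = local_minima[0] if local_minima else min(candidates, key=_val)
    lab = labelings[best_k]
    means = np.vstack(
        [waveforms[lab == c].mean(axis=0) for c in np.unique(lab)]
    )
    # relabel to consecutive 0..k-1
    _, lab0 = np.unique(lab, return_inverse=True)
    return ClusterModel(
        assignments=lab0,
        k=best_k,
        cluster_means=means,
        cindex_curve=curve,
        polarity=polarity,
        linkage_method=linkage_method,
    )


def cluster_summary(
    model: ClusterModel,
    waveforms: np.ndarray,
    frame_hz: float = 50.0,
    window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-cluster mean waveform metrics: size, TI, rise and decay kinetics."""
    dt_ms = 1000.0 / frame_hz
    rows = []
    for c in np.unique(model.assignments):
        members = waveforms[model.assignments == c]
        mean_wf = members.mean(axis=0)
        fit = _metrics.fit_kinetics(mean_wf, dt=dt_ms)
        rows.append(
            {
                "cluster": int(c),
                "n_rois": int(members.shape[0]),
                "peak": float(mean_wf.max()),
                "transiency_index": _metrics.transiency_index(mean_wf),
                "rise_t50_ms": fit.rise_t50,
                "decay_tau_ms": fit.decay_tau,
                "time_to_peak_ms": fit.time_to_peak,
                "fit_ok": fit.fit_ok,
            }
        )
    return pd.DataFrame(rows)
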