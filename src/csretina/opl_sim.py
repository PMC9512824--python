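"""Outer-retina circuit simulator.

A one-dimensional array (default 1500 µm, 10-µm spacing) of photoreceptors,
horizontal cells (HC), bipolar cells (BC) and an optional feed-forward
amacrine cell (AC) circuit, advanced with explicit 1-ms difference equations:

* photoreceptor light response = difference of two first-order activation
  functions (decay constants 60 and 400 ms, weight 0.8), giving a biphasic,
  transient-then-sustained waveform;
* HC integrates photoreceptor output over a wide Gaussian RF (FWHM 300 µm,
  weights normalized to unit sum), passes it through a saturating function
  and relaxes with tau = 300 ms;
* each photoreceptor's drive combines HC feedback with the local luminance
  through a divisive expression whose driving forces are E_HC = 2 mV and
  E_VS = -10 mV (light hyperpolarizes);
* BCs sample photoreceptors through a sigmoidal, baseline-subtracted synapse
  (transient: slope 1.1 /mV, half 4 mV; sustained: 0.1 /mV, 1 mV), relax with
  tau = 50 ms, and convert synaptic drive to membrane potential through a
  conductance-like divisive stage;
* ACs are driven by a separate "driver" BC population (slope 2 /mV, half
  4 mV) through a sigmoidal synapse (gain 1, slope 1.5 /mV, half 7 mV),
  relax with tau = 80 ms and shunt the BC membrane stage (E_AC = 0 mV).

The time-step divisors are the literal per-ms constants of the difference
equations; dt is fixed at 1 ms.  The circular photoreceptor<->HC dependency
is resolved with a one-step lag (the drive at t uses HC from t-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .stimuli import StimulusMovie
from .traces import TraceSet

__all__ = [
    "CircuitParams",
    "CircuitState",
    "spatial_kernel",
    "photoreceptor_drive",
    "photoreceptor_step",
    "hc_step",
    "bc_synaptic_input",
    "bc_step",
    "bc_vm",
    "ac_step",
    "run_simulation",
    "hc_lead_time",
]

LN2 = np.log(2.0)


@dataclass(frozen=True)
class CircuitParams:
    """All constants of the circuit model (times in ms, space in µm, mV)."""

    n_cells: int = 150
    spacing: float = 10.0
    dt: float = 1.0
    tau_phA: float = 60.0
    tau_phB: float = 400.0
    phB_weight: float = 0.8
    fwhm_hc: float = 300.0
    fwhm_bc: float = 50.0
    fwhm_ac: float = 300.0
    gain_ph_hc: float = 1.0
    gain_hc_ph: float = 0.5
    tau_hc: float = 300.0
    tau_bc: float = 50.0
    tau_ac: float = 80.0
    E_Ph: float = 10.0
    E_HC: float = 2.0
    E_VS: float = -10.0
    E_AC: float = 0.0
    v_slope_transient: float = 1.1
    v_half_transient: float = 4.0
    v_slope_sustained: float = 0.1
    v_half_sustained: float = 1.0
    v_slope_driver: float = 2.0
    v_half_driver: float = 4.0
    ac_syn_gain: float = 1.0
    ac_syn_v_slope: float = 1.5
    ac_syn_v_half: float = 7.0
    ac_enabled: bool = False
    hc_enabled: bool = True
    kernel_mode: str = "normalized_fwhm"  # or "literal"

    def __post_init__(self) -> None:
        for tau in (self.tau_phA, self.tau_phB, self.tau_hc, self.tau_bc, self.tau_ac):
            if tau < self.dt:
                raise ValueError("all time constants must be >= dt")
        if self.gain_ph_hc < 0 or self.gain_hc_ph < 0 or self.ac_syn_gain < 0:
            raise ValueError("gains must be >= 0")
        if self.kernel_mode not in ("normalized_fwhm", "literal"):
            raise ValueError("kernel_mode must be 'normalized_fwhm' or 'literal'")

    @property
    def array_length_um(self) -> float:
        return self.n_cells * self.spacing

    def sigmoid_params(self, population: str) -> tuple[float, float]:
        return {
            "transient": (self.v_slope_transient, self.v_half_transient),
            "sustained": (self.v_slope_sustained, self.v_half_sustained),
            "driver": (self.v_slope_driver, self.v_half_driver),
        }[population]


@dataclass
class CircuitState:
    """Per-cell state arrays at one time step (all length n_cells, zeros at rest)."""

    ph_drive: np.ndarray
    ph_A: np.ndarray
    ph_B: np.ndarray
    ph: np.ndarray
    hc: np.ndarray
    hc_inf: np.ndarray
    bc_syn_transient: np.ndarray
    bc_syn_sustained: np.ndarray
    bc_vm_transient: np.ndarray
    bc_vm_sustained: np.ndarray
    bc_syn_driver: np.ndarray
    ac: np.ndarray
    ac_drive: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "CircuitState":
        return cls(*(np.zeros(n) for _ in range(13)))


def spatial_kernel(
    fwhm: float, spacing: float, n_cells: int, mode: str = "normalized_fwhm"
) -> np.ndarray:
    """Pairwise interaction weight matrix d[i, j] over cell distances.

    ``normalized_fwhm`` realizes the stated FWHM exactly
    (``exp(-4 ln2 x^2 / FWHM^2)``); ``literal`` evaluates
    ``exp(-x^2 / (FWHM / 11.09)^2)``, an alternative transcription whose
    realized width is much narrower than its nominal FWHM.  Kernels are truncated at the array
    bounds; callers that need unit-sum weights normalize explicitly.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    x = np.arange(n_cells) * spacing
    d = np.abs(x[:, None] - x[None, :])
    if mode == "normalized_fwhm":
        return np.exp(-4 * LN2 * (d / fwhm) ** 2)
    if mode == "literal":
        return np.exp(-(d**2) / (fwhm / 11.09) ** 2)
    raise ValueError("mode must be 'normalized_fwhm' or 'literal'")


def photoreceptor_drive(
    stimulus_col: np.ndarray,
    hc_prev: np.ndarray,
    params: CircuitParams,
    kern_hc: np.ndarray | None = None,
) -> np.ndarray:
    """Combined light + HC-feedback drive onto each photoreceptor.

    ``drive_i = g * (sum_j E_HC d_ij HC_j + E_VS VS_i)
              / (sum_j |d_ij HC_j| + VS_i + 1)``

    with HC taken from the previous time step and the interaction weights
    ``d_ij`` normalized to unit sum per cell (the HC signals are averaged,
    not summed, over the feedback RF; an unnormalized sum would let the
    feedback loop dominate the light term and spread across the whole
    array).  Light (VS > 0) always drives the photoreceptor negative when HC
    is silent.
    """
    if kern_hc is None:
        kern_hc = spatial_kernel(
            params.fwhm_hc, params.spacing, params.n_cells, params.kernel_mode
        )
    kern_norm = kern_hc / kern_hc.sum(axis=1, keepdims=True)
    fb = kern_norm @ hc_prev
    fb_mag = kern_norm @ np.abs(hc_prev)
    denom = fb_mag + stimulus_col + 1.0
    if np.any(denom <= 0):
        raise FloatingPointError("non-positive denominator in photoreceptor drive")
    return params.gain_hc_ph * (params.E_HC * fb + params.E_VS * stimulus_col) / denom


def photoreceptor_step(
    ph_A: np.ndarray, ph_B: np.ndarray, drive: np.ndarray, params: CircuitParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance the biphasic photoreceptor kinetics one step.

    Returns updated ``(ph_A, ph_B, ph)`` with ``ph = ph_A - 0.8 ph_B``; a
    sustained drive D settles at ``ph = 0.2 D``.
    """
    ph_A = ph_A + (drive - ph_A) / params.tau_phA
    ph_B = ph_B + (drive - ph_B) / params.tau_phB
    return ph_A, ph_B, ph_A - params.phB_weight * ph_B


def hc_step(
    ph: np.ndarray,
    hc_prev: np.ndarray,
    params: CircuitParams,
    kern_hc_norm: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal-cell update: RF-averaged photoreceptor signal, saturated, relaxed.

    ``hc_inf_i = gain * sum_j d_ij Ph_j / sum_j d_ij`` and
    ``hc_i += (E_Ph * hc_inf_i / (hc_inf_i + E_Ph) - hc_i) / tau_hc``.
    """
    if kern_hc_norm is None:
        k = spatial_kernel(
            params.fwhm_hc, params.spacing, params.n_cells, params.kernel_mode
        )
        kern_hc_norm = k / k.sum(axis=1, keepdims=True)
    hc_inf = params.gain_ph_hc * (kern_hc_norm @ ph)
    if np.any(np.isclose(hc_inf, -params.E_Ph)):
        raise FloatingPointError("HC saturation singularity (hc_inf = -E_Ph)")
    target = params.E_Ph * hc_inf / (hc_inf + params.E_Ph)
    hc = hc_prev + (target - hc_prev) / params.tau_hc
    return hc, hc_inf


def _sigmoid(v: np.ndarray | float, v_slope: float, v_half: float):
    return 1.0 / (1.0 + np.exp(v_slope * (v_half - v)))


def bc_synaptic_input(
    ph: np.ndarray,
    params: CircuitParams,
    population: str = "transient",
    kern_bc: np.ndarray | None = None,
) -> np.ndarray:
    """Steady-state photoreceptor->BC synaptic drive (baseline-subtracted).

    ``bc_inf_i = -sum_j d_ij [sigma(Ph_j) - sigma(0)]`` with the population's
    sigmoid; hyperpolarizing (light-driven) photoreceptor signals yield
    positive drive.  No denominator normalization; the kernel is truncated at
    the array bounds.
    """
    v_slope, v_half = params.sigmoid_params(population)
    if kern_bc is None:
        kern_bc = spatial_kernel(
            params.fwhm_bc, params.spacing, params.n_cells, params.kernel_mode
        )
    return -(kern_bc @ (_sigmoid(ph, v_slope, v_half) - _sigmoid(0.0, v_slope, v_half)))


def bc_step(
    bc_syn_prev: np.ndarray, bc_inf: np.ndarray, params: CircuitParams
) -> np.ndarray:
    """Relax the BC synaptic activation toward its steady state (tau = 50 ms)."""
    return bc_syn_prev + (bc_inf - bc_syn_prev) / params.tau_bc


def bc_vm(
    bc_syn: np.ndarray | float, ac: np.ndarray | float, params: CircuitParams
) -> np.ndarray | float:
    """Divisive conversion of synaptic drive (+ AC shunt) to membrane potential.

    ``Vm = E_Ph (E_Ph BC + E_AC AC) / (|BC| + |AC| + E_Ph)``; with E_AC = 0
    the AC term acts purely as a shunt.
    """
    return (
        params.E_Ph
        * (params.E_Ph * bc_syn + params.E_AC * ac)
        / (np.abs(bc_syn) + np.abs(ac) + params.E_Ph)
    )


def ac_step(
    bc_driver_vm: np.ndarray,
    ac_prev: np.ndarray,
    params: CircuitParams,
    kern_ac: np.ndarray | None = None,
) -> np.ndarray:
    """Amacrine update: sigmoidal BC->AC synapse relaxed with tau = 80 ms."""
    if kern_ac is None:
        kern_ac = spatial_kernel(
            params.fwhm_ac, params.spacing, params.n_cells, params.kernel_mode
        )
    s = _sigmoid(bc_driver_vm, params.ac_syn_v_slope, params.ac_syn_v_half)
    s0 = _sigmoid(0.0, params.ac_syn_v_slope, params.ac_syn_v_half)
    ac_inf = params.ac_syn_gain * (kern_ac @ (s - s0))
    return ac_prev + (ac_inf - ac_prev) / params.tau_ac


def ac_drive(
    ac: np.ndarray, params: CircuitParams, kern_ac_norm: np.ndarray | None = None
) -> np.ndarray:
    """AC drive onto each BC: kernel-weighted, distance-normalized AC output."""
    if kern_ac_norm is None:
        k = spatial_kernel(
            params.fwhm_ac, params.spacing, params.n_cells, params.kernel_mode
        )
        kern_ac_norm = k / k.sum(axis=1, keepdims=True)
    return kern_ac_norm @ ac


def run_simulation(
    movie: StimulusMovie,
    params: CircuitParams | None = None,
    record: tuple[str, ...] = (
        "ph",
        "hc",
        "bc_vm_transient",
        "bc_vm_sustained",
        "ac",
    ),
) -> dict[str, TraceSet]:
    """Run the full circuit on a 1-D stimulus movie.

    Update order per step: photoreceptor drive (with HC from t-1) ->
    photoreceptor kinetics -> HC -> driver BC -> AC -> transient/sustained
    BC synapse and membrane stage.  ``hc_enabled = False`` severs the
    HC->photoreceptor feedback synapse (the gain multiplies the whole drive
    numerator, light term included, so zeroing the gain would silence the
    retina outright); ``ac_enabled = False`` (default) bypasses the AC
    circuit entirely (identical to ``ac_syn_gain = 0``).

    Returns a dict of :class:`TraceSet` (n_cells x n_t) for the recorded
    state variables.
    """
    params = params or CircuitParams()
    if movie.is_2d:
        raise ValueError("circuit simulator expects a 1-D movie")
    if movie.n_x != params.n_cells or not np.isclose(movie.dx, params.spacing):
        raise ValueError("movie geometry does not match circuit parameters")
    movie = movie.upsampled_to(params.dt)

    n, n_t = params.n_cells, movie.n_t
    kern_hc = spatial_kernel(params.fwhm_hc, params.spacing, n, params.kernel_mode)
    kern_hc_norm = kern_hc / kern_hc.sum(axis=1, keepdims=True)
    kern_bc = spatial_kernel(params.fwhm_bc, params.spacing, n, params.kernel_mode)
    kern_ac = spatial_kernel(params.fwhm_ac, params.spacing, n, params.kernel_mode)
    kern_ac_norm = kern_ac / kern_ac.sum(axis=1, keepdims=True)

    st = CircuitState.zeros(n)
    rec = {name: np.zeros((n, n_t)) for name in record}
    hc_silent = np.zeros(n)
    for t in range(n_t):
        vs = movie.frames[:, t]
        # hc_enabled=False severs the feedback synapse (HC silent in the
        # drive) while leaving the light term of the drive equation intact
        fb_src = st.hc if params.hc_enabled else hc_silent
        st.ph_drive = photoreceptor_drive(vs, fb_src, params, kern_hc_norm)
        st.ph_A, st.ph_B, st.ph = photoreceptor_step(
            st.ph_A, st.ph_B, st.ph_drive, params
        )
        st.hc, st.hc_inf = hc_step(st.ph, st.hc, params, kern_hc_norm)
        if params.ac_enabled:
            drv_inf = bc_synaptic_input(st.ph, params, "driver", kern_bc)
            st.bc_syn_driver = bc_step(st.bc_syn_driver, drv_inf, params)
            driver_vm = bc_vm(st.bc_syn_driver, 0.0, params)
            st.ac = ac_step(driver_vm, st.ac, params, kern_ac)
            st.ac_drive = ac_drive(st.ac, params, kern_ac_norm)
        for pop in ("transient", "sustained"):
            syn_attr = f"bc_syn_{pop}"
            inf = bc_synaptic_input(st.ph, params, pop, kern_bc)
            syn = bc_step(getattr(st, syn_attr), inf, params)
            setattr(st, syn_attr, syn)
            setattr(st, f"bc_vm_{pop}", bc_vm(syn, st.ac_drive, params))
        for name in record:
            rec[name][:, t] = getattr(st, name)

    positions = np.arange(n) * params.spacing
    return {
        name: TraceSet(
            arr,
            dt=params.dt,
            positions=np.column_stack([positions, np.zeros(n)]),
            condition_label=movie.condition_label,
        )
        for name, arr in rec.items()
    }


def hc_lead_time(
    traces: dict[str, TraceSet] | TraceSet,
    movie: StimulusMovie,
    threshold_frac: float = 0.10,
    border_um: float = 300.0,
) -> tuple[np.ndarray, float]:
    """Lead of HC-signal initiation over direct photoreceptor stimulation.

    For each cell the lead is ``(first time the bar covers the cell) - (first
    time |HC| exceeds threshold_frac of its eventual peak)``; positive values
    mean the HC signal started before the light reached the cell.  Cells the
    bar never covers are excluded (NaN); the returned maximum is taken over
    cells at least ``border_um`` from the array ends.

    Returns ``(per_cell_lead_ms, max_lead_ms)``.
    """
    hc = traces["hc"] if isinstance(traces, dict) else traces
    movie = movie.upsampled_to(hc.dt)
    n, n_t = hc.values.shape
    leads = np.full(n, np.nan)
    for i in range(n):
        lum = np.abs(movie.frames[i])
        covered = np.flatnonzero(lum > 0)
        if covered.size == 0:
            continue
        h = np.abs(hc.values[i])
        peak = h.max()
        if peak <= 0:
            continue
        init = np.flatnonzero(h >= threshold_frac * peak)
        if init.size == 0:
            continue
        leads[i] = (covered[0] - init[0]) * hc.dt
    x = np.arange(n) * movie.dx
    interior = (x >= border_um) & (x <= x[-1] - border_um)
    valid = interior & np.isfinite(leads)
    max_lead = float(np.nanmax(leads[valid])) if valid.any() else float("nan")
    return leads, max_lead
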