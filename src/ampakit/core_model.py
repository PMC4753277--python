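"""Leaky integrate-and-fire point neuron with a double-exponential synaptic
conductance, rheobase search by bisection, and a software emulation of the
discrete conductance-clamp (dynamic-clamp) loop.

Units throughout: time in ms, voltage in mV, conductance in nS, current in pA,
capacitance in pF, resistance in MOhm.  With these units ``(mV / MOhm) * 1000``
is pA and ``pA / pF`` is mV/ms, so no hidden conversion factors appear in the
integrator.

Numerical conventions (frozen; see docs/methods.md):

* forward Euler with the synaptic conductance taken as the average of its
  values at the two ends of the step;
* a threshold crossing (``V >= v_thresh`` evaluated after the Euler update)
  registers a spike, the crossing sample is displayed at ``v_peak``, the next
  sample is forced to ``v_reset``, and integration resumes from there.  No
  refractory period beyond that one reset sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "LIFParams",
    "SynapticKernel",
    "SimConfig",
    "SimResult",
    "RheobaseResult",
    "InvalidKernelError",
    "BracketError",
    "conductance_waveform",
    "simulate_lif",
    "find_rheobase",
    "response_metrics",
    "emulate_conductance_clamp",
    "default_lif_params",
    "default_kernel",
    "default_sim_config",
    "load_model_config",
    "save_model_config",
]


class InvalidKernelError(ValueError):
    """Raised when a synaptic kernel has tau_rise >= tau_decay."""


class BracketError(ValueError):
    """Raised when a bisection bracket does not straddle the target."""


@dataclass(frozen=True)
class LIFParams:
    """Membrane and spike parameters of the point-neuron model.

    ``c_m`` may be omitted, in which case it is derived from
    ``c_m = tau_m / r_in`` (10 ms / 160 MOhm = 62.5 pF with the defaults).
    """

    tau_m: float = 10.0      # membrane time constant (ms)
    e_leak: float = -70.0    # leak reversal / resting potential (mV)
    r_in: float = 160.0      # input resistance (MOhm)
    c_m: float | None = None  # capacitance (pF); derived if None
    v_thresh: float = -37.0  # spike threshold (mV)
    v_peak: float = 20.0     # spike display amplitude (mV)
    v_reset: float = -80.0   # post-spike reset (mV)

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.r_in <= 0:
            raise ValueError("tau_m and r_in must be positive")
        derived = self.tau_m / self.r_in * 1000.0  # ms/MOhm -> pF
        if self.c_m is None:
            object.__setattr__(self, "c_m", derived)
        elif not np.isclose(self.c_m, derived, rtol=1e-6):
            raise ValueError(
                f"inconsistent capacitance: c_m={self.c_m} pF but "
                f"tau_m/r_in={derived} pF"
            )
        if not (self.v_reset < self.v_thresh < self.v_peak):
            raise ValueError("require v_reset < v_thresh < v_peak")


@dataclass(frozen=True)
class SynapticKernel:
    """Double-exponential conductance waveform specification.

    The waveform is normalised so that its analytic (continuous-time) maximum
    equals ``g_peak`` — the peak conductance is literally the peak.
    """

    tau_rise: float = 1.4    # ms
    tau_decay: float = 3.0   # ms
    g_peak: float = 1.0      # nS
    e_rev: float = 0.0       # mV
    t_onset: float = 10.0    # ms

    def __post_init__(self) -> None:
        if not (0.0 < self.tau_rise < self.tau_decay):
            raise InvalidKernelError(
                f"require 0 < tau_rise < tau_decay, got "
                f"({self.tau_rise}, {self.tau_decay})"
            )
        if self.g_peak < 0:
            raise InvalidKernelError("g_peak must be nonnegative")

    @property
    def t_peak(self) -> float:
        """Time from onset to the waveform maximum (closed form)."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * np.log(td / tr)

    @property
    def peak_norm(self) -> float:
        """Maximum of the unnormalised difference of exponentials."""
        tp = self.t_peak
        return float(np.exp(-tp / self.tau_decay) - np.exp(-tp / self.tau_rise))


@dataclass(frozen=True)
class SimConfig:
    dt: float = 0.1          # integration step (ms)
    duration: float = 100.0  # total simulated time (ms)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class SimResult:
    time: np.ndarray         # ms
    voltage: np.ndarray      # mV
    conductance: np.ndarray  # nS
    current: np.ndarray      # pA (synaptic)
    spike_times: np.ndarray  # ms, strictly increasing

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_ms": self.time,
                "voltage_mV": self.voltage,
                "conductance_nS": self.conductance,
                "current_pA": self.current,
            }
        )

    def to_csv(self, path, spike_path=None) -> None:
        """Write the traces as CSV plus an optional spike-times sidecar."""
        self.to_frame().to_csv(path, index=False)
        if spike_path is not None:
            np.savetxt(spike_path, self.spike_times, header="spike_time_ms",
                       comments="# ")


@dataclass
class RheobaseResult:
    g_rheo: float            # nS
    n_spikes_target: int
    iterations: int
    bracket: tuple[float, float]  # final (low, high) bracket (nS)

    @property
    def resolution(self) -> float:
        return self.bracket[1] - self.bracket[0]


def conductance_waveform(kernel: SynapticKernel, grid: np.ndarray) -> np.ndarray:
    """Evaluate the normalised double-exponential conductance on a time grid.

    g(t) = g_peak * [exp(-(t-t0)/tau_decay) - exp(-(t-t0)/tau_rise)] / N for
    t >= t0 and 0 before, with N the analytic waveform maximum so that the
    continuous-time peak equals ``g_peak`` exactly.
    """
    grid = np.asarray(grid, dtype=float)
    tt = grid - kernel.t_onset
    g = np.zeros_like(grid)
    on = tt >= 0
    g[on] = (
        np.exp(-tt[on] / kernel.tau_decay) - np.exp(-tt[on] / kernel.tau_rise)
    ) / kernel.peak_norm
    return kernel.g_peak * g


def _check_step(kernel: SynapticKernel, dt: float) -> None:
    if dt > kernel.tau_rise:
        warnings.warn(
            f"integration step dt={dt} ms is large relative to "
            f"tau_rise={kernel.tau_rise} ms; forward Euler may be inaccurate",
            RuntimeWarning,
            stacklevel=3,
        )


def simulate_lif(
    params: LIFParams, kernel: SynapticKernel, cfg: SimConfig | None = None
) -> SimResult:
    """Forward-Euler integration of the conductance-driven LIF neuron.

    C dV/dt = (e_leak - V)/r_in + g(t) (e_rev - V), with the spike convention
    described in the module docstring.  The conductance waveform is not
    affected by spiking.
    """
    if cfg is None:
        cfg = SimConfig()
    _check_step(kernel, cfg.dt)
    t = np.arange(0.0, cfg.duration + cfg.dt / 2, cfg.dt)
    g = conductance_waveform(kernel, t)
    # conductance drive averaged over each Euler step
    gmid = 0.5 * (g[:-1] + g[1:])
    v = np.empty_like(t)
    v[0] = params.e_leak
    spikes: list[float] = []
    el, rin, cm = params.e_leak, params.r_in, params.c_m
    vth, vpk, vrs, erev = params.v_thresh, params.v_peak, params.v_reset, kernel.e_rev
    dt = cfg.dt
    i = 1
    n = len(t)
    vv = v[0]
    while i < n:
        i_total = (el - vv) / rin * 1000.0 + gmid[i - 1] * (erev - vv)
        vn = vv + dt * i_total / cm
        if vn >= vth:
            spikes.append(t[i])
            v[i] = vpk
            if i + 1 < n:
                v[i + 1] = vrs
            vv = vrs
            i += 2
        else:
            v[i] = vn
            vv = vn
            i += 1
    i_syn = g * (erev - v)
    return SimResult(
        time=t,
        voltage=v,
        conductance=g,
        current=i_syn,
        spike_times=np.asarray(spikes),
    )


def _spike_count(
    params: LIFParams, kernel: SynapticKernel, g_peak: float, cfg: SimConfig
) -> int:
    return simulate_lif(params, replace(kernel, g_peak=g_peak), cfg).n_spikes


def find_rheobase(
    params: LIFParams,
    kernel: SynapticKernel,
    n_spikes_target: int = 1,
    bracket: tuple[float, float] = (0.0, 100.0),
    iterations: int = 15,
    cfg: SimConfig | None = None,
) -> RheobaseResult:
    """Bisection search for the lowest peak conductance giving the target
    spike count.

    ``kernel.g_peak`` is ignored; the bracket must straddle the target
    (fewer spikes at the low end, at least the target at the high end).
    The returned value is the bracket midpoint after the stated number of
    iterations, so the resolution is ``(hi - lo) / 2**iterations``.
    """
    if cfg is None:
        cfg = SimConfig()
    lo, hi = bracket
    if not lo < hi:
        raise BracketError(f"invalid bracket {bracket}")
    if _spike_count(params, kernel, lo, cfg) >= n_spikes_target:
        raise BracketError(f"low end {lo} nS already reaches the target count")
    if _spike_count(params, kernel, hi, cfg) < n_spikes_target:
        raise BracketError(f"high end {hi} nS does not reach the target count")
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if _spike_count(params, kernel, mid, cfg) >= n_spikes_target:
            hi = mid
        else:
            lo = mid
    return RheobaseResult(
        g_rheo=0.5 * (lo + hi),
        n_spikes_target=n_spikes_target,
        iterations=iterations,
        bracket=(lo, hi),
    )


class UndefinedMetricError(ValueError):
    """Raised when a response metric is undefined for the given result."""


@dataclass
class ResponseMetrics:
    epsp_rise_tau: float | None      # ms, subthreshold runs only
    epsp_peak_latency: float | None  # ms, subthreshold runs only
    ap_latency: float | None         # ms, first spike - onset
    response_duration: float | None  # ms, first-to-second spike interval


def response_metrics(result: SimResult, kernel: SynapticKernel) -> ResponseMetrics:
    """EPSP/AP timing metrics of a simulated response.

    ``ap_latency`` requires at least one spike and ``response_duration`` at
    least two; each is ``None`` when undefined.  EPSP shape metrics (rise tau
    from a single-exponential fit to the 20-100%-of-peak rising phase, and
    peak latency) are reported for subthreshold runs only.
    """
    t0 = kernel.t_onset
    n = result.n_spikes
    ap_latency = float(result.spike_times[0] - t0) if n >= 1 else None
    response_duration = (
        float(result.spike_times[1] - result.spike_times[0]) if n >= 2 else None
    )
    epsp_rise_tau = epsp_peak_latency = None
    if n == 0:
        v = result.voltage
        t = result.time
        base = v[result.time <= t0][-1] if np.any(t <= t0) else v[0]
        ipk = int(np.argmax(v))
        amp = v[ipk] - base
        epsp_peak_latency = float(t[ipk] - t0)
        if amp > 0:
            rel = (v[: ipk + 1] - base) / amp
            sel = np.nonzero(rel >= 0.2)[0]
            sel = sel[sel <= ipk]
            if len(sel) >= 3:
                from scipy.optimize import curve_fit

                ts = t[sel] - t[sel[0]]
                vs = v[sel]

                def rising(x, tau, b):
                    return v[ipk] - b * np.exp(-x / tau)

                try:
                    popt, _ = curve_fit(
                        rising, ts, vs, p0=[kernel.tau_decay, amp], maxfev=5000
                    )
                    epsp_rise_tau = float(abs(popt[0]))
                except RuntimeError:
                    epsp_rise_tau = None
    return ResponseMetrics(
        epsp_rise_tau=epsp_rise_tau,
        epsp_peak_latency=epsp_peak_latency,
        ap_latency=ap_latency,
        response_duration=response_duration,
    )


def emulate_conductance_clamp(
    membrane: LIFParams,
    kernel: SynapticKernel,
    loop_rate: float = 30000.0,
    cfg: SimConfig | None = None,
) -> SimResult:
    """Discrete dynamic-clamp loop emulated in software.

    A hardware conductance clamp reads the membrane potential, computes
    i = g(t) (e_rev - V_m) and writes that current back, all at a finite loop
    rate.  Here the membrane integrates at ``cfg.dt`` while the injected
    current is updated only at loop ticks, using the voltage read one tick
    earlier (zero-order hold with a one-tick delay).
    """
    if loop_rate <= 0:
        raise ValueError("loop_rate must be positive")
    if cfg is None:
        cfg = SimConfig()
    tick_ms = 1000.0 / loop_rate
    if tick_ms < cfg.dt - 1e-12:
        # the loop outpaces the membrane grid: integrate at the tick rate
        cfg = SimConfig(dt=tick_ms, duration=cfg.duration)
    stride = max(1, int(round(tick_ms / cfg.dt)))
    _check_step(kernel, cfg.dt)
    t = np.arange(0.0, cfg.duration + cfg.dt / 2, cfg.dt)
    g = conductance_waveform(kernel, t)
    v = np.empty_like(t)
    i_inj = np.zeros_like(t)
    v[0] = membrane.e_leak
    el, rin, cm = membrane.e_leak, membrane.r_in, membrane.c_m
    vth, vpk, vrs, erev = (
        membrane.v_thresh,
        membrane.v_peak,
        membrane.v_reset,
        kernel.e_rev,
    )
    dt = cfg.dt
    spikes: list[float] = []
    held = 0.0          # current being injected (zero-order hold)
    v_read = v[0]       # voltage read at the previous tick
    i = 1
    n = len(t)
    vv = v[0]
    while i < n:
        k = i - 1
        if k % stride == 0:
            held = g[k] * (erev - v_read)  # one-tick-old voltage
            v_read = vv
        i_inj[k] = held
        i_total = (el - vv) / rin * 1000.0 + held
        vn = vv + dt * i_total / cm
        if vn >= vth:
            spikes.append(t[i])
            v[i] = vpk
            if i + 1 < n:
                v[i + 1] = vrs
            vv = vrs
            i += 2
        else:
            v[i] = vn
            vv = vn
            i += 1
    i_inj[-1] = held
    return SimResult(
        time=t,
        voltage=v,
        conductance=g,
        current=i_inj,
        spike_times=np.asarray(spikes),
    )


# --- default parameter set and config round-trip ---------------------------

def default_lif_params() -> LIFParams:
    return LIFParams()


def default_kernel(tau_decay: float = 3.0, g_peak: float = 1.0) -> SynapticKernel:
    return SynapticKernel(tau_rise=1.4, tau_decay=tau_decay, g_peak=g_peak)


def default_sim_config() -> SimConfig:
    return SimConfig()


def save_model_config(path, params: LIFParams, kernel: SynapticKernel,
                      cfg: SimConfig) -> None:
    doc = {
        "lif": {
            "tau_m": params.tau_m, "e_leak": params.e_leak,
            "r_in": params.r_in, "c_m": params.c_m,
            "v_thresh": params.v_thresh, "v_peak": params.v_peak,
            "v_reset": params.v_reset,
        },
        "kernel": {
            "tau_rise": kernel.tau_rise, "tau_decay": kernel.tau_decay,
            "g_peak": kernel.g_peak, "e_rev": kernel.e_rev,
            "t_onset": kernel.t_onset,
        },
        "sim": {"dt": cfg.dt, "duration": cfg.duration},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model_config(path) -> tuple[LIFParams, SynapticKernel, SimConfig]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    allowed = {"lif", "kernel", "sim"}
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return (
        LIFParams(**doc.get("lif", {})),
        SynapticKernel(**doc.get("kernel", {})),
        SimConfig(**doc.get("sim", {})),
    )
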