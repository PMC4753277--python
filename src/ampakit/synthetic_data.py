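"""Synthetic electrophysiology and morphology generators with ground truth.

Every generator takes a cell-type preset and a seed and returns both the
simulated data (in the same containers the analysis modules consume) and a
``GroundTruth`` record sufficient to score every downstream estimator.

Default preset values emulate the statistical structure of excitatory inputs
to layer-5 neocortical interneurons:

* basket cells (BC): short-term depressing trains (paired-pulse ratio 0.36),
  fast EPSC decay (2.9 ms), inwardly rectifying I-V (polyamine-style outward
  block), ~12 Hz miniature EPSCs;
* Martinotti cells (MC): facilitating trains (paired-pulse ratio 5.2), slower
  decay (5.1 ms), linear I-V;
* pyramidal cells (PC): linear I-V, depressing trains.

The outward polyamine block is emulated as a Boltzmann function of voltage —
a convenient phenomenological shape, not a biophysical receptor model.
Short-term plasticity is a deterministic geometric per-pulse scaling whose
second/first ratio equals the preset paired-pulse ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mepsc import RecordingTrace
from .morphometry import AXON, DENDRITE, SOMA, LayerBoundaries, Morphology
from .rectification import IVDataset

__all__ = [
    "SynthCellPreset",
    "GroundTruth",
    "PRESETS",
    "iv_block_model",
    "gen_epsc_train",
    "gen_mepsc_recording",
    "gen_morphology",
    "default_boundaries",
]


@dataclass(frozen=True)
class SynthCellPreset:
    """Ground-truth parameters of one synthetic cell type."""

    label: str                    # BC, MC or PC
    ppr: float                    # paired-pulse ratio (EPSC2/EPSC1)
    tau_rise_epsc: float          # evoked EPSC rise time constant (ms)
    tau_decay_epsc: float         # evoked EPSC decay time constant (ms)
    uncaging_tau_decay: float     # slow agonist-evoked decay (s)
    e_rev: float = 0.0            # synaptic reversal (mV)
    block_v_half: float | None = None  # Boltzmann half-block voltage (mV)
    block_slope: float = 12.0     # Boltzmann slope (mV)
    g_max: float = 1.0            # underlying conductance scale (nS)
    mini_rate: float = 12.0       # Hz
    mini_amp_mean: float = 20.0   # pA, mean quantal amplitude at -60 mV
    mini_amp_cv: float = 0.3      # lognormal CV of quantal amplitudes
    mini_tau_rise: float = 0.12   # ms (quantal kernel, somatic events)
    mini_tau_decay: float = 3.0   # ms
    noise_sd: float = 3.2         # pA Gaussian recording noise

    def block(self, v) -> np.ndarray:
        """Outward-block fraction b(V) in [0, 1]; 0 everywhere if linear."""
        v = np.asarray(v, dtype=float)
        if self.block_v_half is None:
            return np.zeros_like(v)
        return 1.0 / (1.0 + np.exp(-(v - self.block_v_half) / self.block_slope))


PRESETS: dict[str, SynthCellPreset] = {
    "BC": SynthCellPreset(
        label="BC", ppr=0.36, tau_rise_epsc=1.8, tau_decay_epsc=2.9,
        uncaging_tau_decay=1.0, block_v_half=-10.0,
    ),
    "MC": SynthCellPreset(
        label="MC", ppr=5.2, tau_rise_epsc=1.9, tau_decay_epsc=5.1,
        uncaging_tau_decay=1.7, block_v_half=None,
    ),
    "PC": SynthCellPreset(
        label="PC", ppr=0.7, tau_rise_epsc=1.5, tau_decay_epsc=4.0,
        uncaging_tau_decay=1.2, block_v_half=None,
    ),
}


@dataclass
class GroundTruth:
    """What the generator actually put into the data."""

    event_times: np.ndarray = field(default_factory=lambda: np.empty(0))   # s
    amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))    # pA
    charges: np.ndarray = field(default_factory=lambda: np.empty(0))       # pC
    conductances: np.ndarray = field(default_factory=lambda: np.empty(0))  # nS
    pulse_scales: np.ndarray = field(default_factory=lambda: np.empty(0))
    morph_class: str | None = None


def iv_block_model(preset: SynthCellPreset, voltages) -> IVDataset:
    """Noiseless I-V family: I(V) = g_max (V - e_rev) (1 - b(V)).

    With the Boltzmann outward block this is inwardly rectifying; with
    ``block_v_half=None`` (CI presets) it is a straight line.
    """
    v = np.asarray(voltages, dtype=float)
    i = preset.g_max * (v - preset.e_rev) * (1.0 - preset.block(v))
    return IVDataset(voltages=v, currents=i)


def _norm_kernel(t_ms: np.ndarray, tau_r: float, tau_d: float) -> np.ndarray:
    """Difference-of-exponentials kernel with unit peak; t in ms, t<0 -> 0."""
    tp = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    norm = np.exp(-tp / tau_d) - np.exp(-tp / tau_r)
    out = np.zeros_like(t_ms)
    m = t_ms >= 0
    out[m] = (np.exp(-t_ms[m] / tau_d) - np.exp(-t_ms[m] / tau_r)) / norm
    return out


def gen_epsc_train(
    preset: SynthCellPreset,
    n_pulses: int = 5,
    rate: float = 30.0,
    holding: float = -60.0,
    seed: int = 0,
    sample_rate: float = 20_000.0,
    duration: float = 0.4,
    t_first: float = 0.05,
    noise_sd: float | None = None,
) -> tuple[RecordingTrace, GroundTruth]:
    """Evoked EPSC train with deterministic short-term plasticity.

    Pulse k (0-based) is scaled by ``ppr**k``, so EPSC2/EPSC1 equals the
    preset paired-pulse ratio; the first-pulse amplitude comes from the
    preset I-V model evaluated at the holding potential.  Gaussian recording
    noise is added on top; the ground truth records the noiseless per-pulse
    amplitudes and scale factors.
    """
    if rate <= 0:
        raise ValueError("stimulation rate must be positive")
    if n_pulses < 1:
        raise ValueError("need at least one pulse")
    rng = np.random.default_rng(seed)
    if noise_sd is None:
        noise_sd = preset.noise_sd
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    i1 = float(iv_block_model(preset, [holding]).currents[0])
    scales = preset.ppr ** np.arange(n_pulses)
    onsets = t_first + np.arange(n_pulses) / rate
    trace = np.zeros_like(t)
    for onset, s in zip(onsets, scales):
        trace += i1 * s * _norm_kernel(
            (t - onset) * 1e3, preset.tau_rise_epsc, preset.tau_decay_epsc
        )
    clean_amps = i1 * scales
    trace = trace + rng.normal(0.0, noise_sd, len(t))
    rec = RecordingTrace(current=trace, sample_rate=sample_rate,
                         holding_potential=holding)
    gt = GroundTruth(event_times=onsets, amplitudes=clean_amps,
                     pulse_scales=scales)
    return rec, gt


def gen_mepsc_recording(
    preset: SynthCellPreset,
    duration: float = 60.0,
    holding: float = -60.0,
    seed: int = 0,
    sample_rate: float = 20_000.0,
    junction_potential: float = 0.0,
) -> tuple[RecordingTrace, GroundTruth]:
    """Poisson miniature-EPSC recording with Gaussian noise.

    Quantal conductances are lognormal (CV ``mini_amp_cv``) around the value
    that gives ``mini_amp_mean`` pA of driving-force-scaled current at
    -60 mV; each event's current amplitude at the (junction-corrected)
    holding potential is scaled by ``(V - e_rev)(1 - b(V))``, which programs
    the rectification that the charge-ratio estimator should recover.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    v_m = holding - junction_potential
    n = rng.poisson(preset.mini_rate * duration)
    times = np.sort(rng.uniform(0.0, duration, n))
    # conductance scale: mini_amp_mean pA at -60 mV driving force, no block
    g_mean = preset.mini_amp_mean / abs(-60.0 - preset.e_rev)
    sigma = np.sqrt(np.log(1.0 + preset.mini_amp_cv**2))
    mu = np.log(g_mean) - sigma**2 / 2
    g_q = rng.lognormal(mu, sigma, n)
    block = float(preset.block(np.asarray([v_m]))[0])
    amps = g_q * (v_m - preset.e_rev) * (1.0 - block)  # pA, signed
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    trace = rng.normal(0.0, preset.noise_sd, len(t))
    tau_r, tau_d = preset.mini_tau_rise, preset.mini_tau_decay
    klen = int(round((6 * tau_d) * 1e-3 * sample_rate))
    kt = np.arange(klen) / sample_rate * 1e3  # ms
    kern = _norm_kernel(kt, tau_r, tau_d)
    for t0, a in zip(times, amps):
        i0 = int(round(t0 * sample_rate))
        hi = min(len(t), i0 + klen)
        if i0 >= len(t):
            continue
        trace[i0:hi] += a * kern[: hi - i0]
    # charge of a unit-peak difference kernel: (tau_d - tau_r)/norm, ms
    tp = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    norm = np.exp(-tp / tau_d) - np.exp(-tp / tau_r)
    q_unit_ms = (tau_d - tau_r) / norm
    charges = amps * q_unit_ms * 1e-3  # pA*ms -> pC
    rec = RecordingTrace(current=trace, sample_rate=sample_rate,
                         holding_potential=holding)
    gt = GroundTruth(event_times=times, amplitudes=amps, charges=charges,
                     conductances=g_q)
    return rec, gt


def default_boundaries() -> LayerBoundaries:
    """Representative mouse-visual-cortex layer depths (um below the pia)."""
    return LayerBoundaries(l1_l23=100.0, l23_l4=350.0, l4_l5=450.0,
                           l5_l6=700.0)


def _random_subtree(
    rng, nodes, parent_id, origin, n_branches, seg_len, depth_range,
    lateral_sd, stype, next_id,
):
    """Grow short random-walk branches from origin, clipped to a depth band."""
    for _ in range(n_branches):
        x, y = origin
        pid = parent_id
        n_seg = rng.integers(3, 8)
        for _ in range(n_seg):
            x = x + rng.normal(0.0, lateral_sd)
            y = float(np.clip(y + rng.normal(0.0, seg_len), *depth_range))
            nodes.append((next_id[0], stype, x, y, rng.normal(0.0, 2.0), 0.4,
                          pid))
            pid = next_id[0]
            next_id[0] += 1


def gen_morphology(
    morph_class: str,
    boundaries: LayerBoundaries | None = None,
    seed: int = 0,
) -> tuple[Morphology, GroundTruth]:
    """Stochastic branching morphology with a class-specific laminar envelope.

    * ``MC`` — soma in L5, ascending axon that ramifies in L2/3 and reaches
      L1, dendrites descending below the soma;
    * ``BC1`` — soma in L5, ascending axon ramifying in L2/3 but stopping
      short of L1, local dendrites;
    * ``BC2`` — soma in L5, axon confined near L5, local dendrites.
    """
    if boundaries is None:
        boundaries = default_boundaries()
    if morph_class not in {"MC", "BC1", "BC2"}:
        raise ValueError(f"unknown morphology class {morph_class!r}")
    b = boundaries
    rng = np.random.default_rng(seed)
    soma_y = rng.uniform(b.l4_l5 + 50.0, b.l5_l6 - 50.0)
    nodes: list[tuple] = [(1, SOMA, 0.0, soma_y, 0.0, 6.0, -1)]
    next_id = [2]

    def add_trunk(x0, y0, y1, stype, jitter=8.0):
        """Straight-ish trunk from depth y0 to y1; returns (last_id, x, y)."""
        n_step = max(3, int(abs(y1 - y0) / 40.0))
        ys = np.linspace(y0, y1, n_step + 1)[1:]
        pid = 1
        x = x0
        for y in ys:
            x += rng.normal(0.0, jitter)
            nodes.append((next_id[0], stype, x, float(y),
                          rng.normal(0.0, 2.0), 0.5, pid))
            pid = next_id[0]
            next_id[0] += 1
        return pid, x, float(ys[-1])

    if morph_class == "MC":
        # ascending axon into L1
        tip, tx, ty = add_trunk(0.0, soma_y, b.l1_l23 * 0.4, AXON)
        _random_subtree(rng, nodes, tip, (tx, ty), 6, 25.0,
                        (5.0, b.l1_l23), 40.0, AXON, next_id)
        mid = (b.l1_l23 + b.l23_l4) / 2
        tip2, tx2, ty2 = add_trunk(0.0, soma_y, mid, AXON)
        _random_subtree(rng, nodes, tip2, (tx2, ty2), 5, 30.0,
                        (b.l1_l23, b.l23_l4), 60.0, AXON, next_id)
        # descending dendrites
        dtip, dx, dy = add_trunk(0.0, soma_y, min(soma_y + 150.0, b.l5_l6), DENDRITE)
        _random_subtree(rng, nodes, dtip, (dx, dy), 4, 25.0,
                        (soma_y, b.l5_l6), 50.0, DENDRITE, next_id)
    elif morph_class == "BC1":
        # ascending axon ramifying in L2/3, never entering L1
        mid = (b.l1_l23 + b.l23_l4) / 2
        tip, tx, ty = add_trunk(0.0, soma_y, mid, AXON)
        _random_subtree(rng, nodes, tip, (tx, ty), 8, 30.0,
                        (b.l1_l23 + 10.0, b.l23_l4), 60.0, AXON, next_id)
        _random_subtree(rng, nodes, 1, (0.0, soma_y), 3, 25.0,
                        (b.l4_l5, b.l5_l6), 60.0, AXON, next_id)
        _random_subtree(rng, nodes, 1, (0.0, soma_y), 5, 25.0,
                        (b.l4_l5, b.l5_l6), 60.0, DENDRITE, next_id)
    else:  # BC2: axon confined near L5
        _random_subtree(rng, nodes, 1, (0.0, soma_y), 10, 30.0,
                        (b.l4_l5 + 5.0, b.l5_l6), 80.0, AXON, next_id)
        _random_subtree(rng, nodes, 1, (0.0, soma_y), 5, 25.0,
                        (b.l4_l5, b.l5_l6), 60.0, DENDRITE, next_id)

    morph = Morphology(
        nodes=pd.DataFrame(
            nodes, columns=["id", "type", "x", "y", "z", "radius", "parent"]
        )
    )
    return morph, GroundTruth(morph_class=morph_class)
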