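"""Rectification and amplitude statistics for AMPA-receptor currents.

Calcium-permeable (GluA2-lacking) AMPA receptors are blocked by intracellular
polyamines at depolarised potentials, so their I-V relationship is inwardly
rectifying.  This module quantifies that rectification three ways:

* ``fit_ri_slope`` — the two-slope rectification index RI_slope = s2/s1,
  where s1 (and the reversal potential E_rev) come from an unconstrained
  linear fit to points with inward (negative) current and s2 from a fit
  through the fixed point (E_rev, 0) to points above the reversal;
* ``charge_ratio_ri`` — the ratio of summed miniature-EPSC charge at +60 vs
  -60 mV command potentials, corrected for driving force so a linear
  conductance maps to 1;
* ``nmda_ampa_ratio`` — windowed NMDA/AMPA current ratio (1 ms window on the
  first-EPSC peak; NMDA measured 20 ms later at the depolarised potential).

All voltages are corrected for the liquid junction potential before fitting
(membrane potential = command potential - junction potential).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "IVDataset",
    "RectificationFit",
    "ChargeRatioResult",
    "AmplitudeWindows",
    "InsufficientDataError",
    "DegenerateFitError",
    "UndefinedRatioError",
    "UnstableBaselineError",
    "fit_ri_slope",
    "normalize_and_average_iv",
    "charge_ratio_ri",
    "nmda_ampa_ratio",
    "wash_in_effect",
]


class InsufficientDataError(ValueError):
    pass


class DegenerateFitError(ValueError):
    pass


class UndefinedRatioError(ValueError):
    pass


class UnstableBaselineError(ValueError):
    pass


@dataclass
class IVDataset:
    """Per-voltage mean peak currents of one recording.

    ``voltages`` are command potentials in mV, ``currents`` mean peak currents
    in pA, ``n_repeats`` the sweeps averaged per point.  ``junction_potential``
    (mV) is subtracted from the command voltages during analysis.
    """

    voltages: np.ndarray
    currents: np.ndarray
    n_repeats: np.ndarray | None = None
    junction_potential: float = 0.0

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.voltages.shape != self.currents.shape:
            raise ValueError("voltages and currents must have matching shapes")
        if len(np.unique(self.voltages)) != len(self.voltages):
            raise ValueError("command voltages must be unique")
        if self.n_repeats is None:
            self.n_repeats = np.ones_like(self.voltages, dtype=int)

    @property
    def corrected_voltages(self) -> np.ndarray:
        return self.voltages - self.junction_potential

    @classmethod
    def from_csv(cls, path, junction_potential: float = 0.0) -> "IVDataset":
        df = pd.read_csv(path)
        n = df["n"].to_numpy() if "n" in df else None
        return cls(
            voltages=df["voltage_mV"].to_numpy(),
            currents=df["current_pA"].to_numpy(),
            n_repeats=n,
            junction_potential=junction_potential,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "voltage_mV": self.voltages,
                "current_pA": self.currents,
                "n": self.n_repeats,
            }
        ).to_csv(path, index=False)


@dataclass
class RectificationFit:
    s1: float        # slope below reversal (nS)
    s2: float        # constrained slope above reversal (nS)
    e_rev: float     # fitted reversal potential (mV, junction-corrected)
    ri_slope: float  # s2 / s1

    def to_row(self) -> dict:
        return {"s1_nS": self.s1, "s2_nS": self.s2, "e_rev_mV": self.e_rev,
                "ri_slope": self.ri_slope}


def fit_ri_slope(data: IVDataset) -> RectificationFit:
    """Two-slope rectification index of an I-V dataset.

    s1 and the reversal potential come from ordinary least squares on points
    with negative current; s2 from least squares through (E_rev, 0) on all
    points with (junction-corrected) voltage above E_rev — the s2 regime is
    voltage-defined, so fully blocked (zero-current) points count toward it.
    """
    v = data.corrected_voltages
    i = data.currents
    below = i < 0
    if below.sum() < 2:
        raise InsufficientDataError(
            f"need >= 2 points with inward current, got {below.sum()}"
        )
    s1, intercept, *_ = stats.linregress(v[below], i[below])
    if s1 <= 0:
        raise DegenerateFitError(f"nonpositive inward slope s1={s1}")
    e_rev = -intercept / s1
    above = v > e_rev
    if above.sum() < 2:
        raise InsufficientDataError(
            f"need >= 2 points above the fitted reversal, got {above.sum()}"
        )
    dv = v[above] - e_rev
    s2 = float(np.dot(dv, i[above]) / np.dot(dv, dv))
    logger.debug(
        "fit_ri_slope: jp=%.1f mV, s1=%.4g nS, s2=%.4g nS, e_rev=%.2f mV",
        data.junction_potential, s1, s2, e_rev,
    )
    return RectificationFit(s1=float(s1), s2=s2, e_rev=float(e_rev),
                            ri_slope=s2 / float(s1))


def normalize_and_average_iv(
    datasets: list[IVDataset], v_ref: float = -60.0
) -> pd.DataFrame:
    """Normalise each I-V curve to |I(v_ref)| and average across recordings.

    Voltages are junction-corrected before anything else; the reference
    current is linearly interpolated when v_ref is not a sampled voltage.
    Datasets whose voltage range does not cover v_ref are excluded with a
    logged warning.  Returns a table (voltage_mV, mean, sem, n) where the
    normalised current keeps its sign, so an inward current at v_ref is -1.
    """
    rows: list[pd.DataFrame] = []
    for k, ds in enumerate(datasets):
        v = ds.corrected_voltages
        order = np.argsort(v)
        v, i = v[order], ds.currents[order]
        if not (v.min() <= v_ref <= v.max()):
            logger.warning(
                "dataset %d lacks coverage of v_ref=%.1f mV; excluded", k, v_ref
            )
            continue
        i_ref = float(np.interp(v_ref, v, i))
        if i_ref == 0:
            logger.warning("dataset %d has zero current at v_ref; excluded", k)
            continue
        rows.append(pd.DataFrame({"voltage_mV": v, "norm": i / abs(i_ref)}))
    if not rows:
        raise InsufficientDataError("no dataset covers the reference voltage")
    allpts = pd.concat(rows)
    grp = allpts.groupby("voltage_mV")["norm"]
    out = grp.agg(["mean", "sem", "count"]).reset_index()
    out = out.rename(columns={"count": "n"})
    out["sem"] = out["sem"].fillna(0.0)
    return out


@dataclass
class ChargeRatioResult:
    q_pos: float         # summed charge at the positive potential (pC)
    q_neg: float         # summed charge at the negative potential (pC)
    epoch_length: float  # s
    ri: float            # |q_pos|/|q_neg| after driving-force correction


def _charges(events) -> np.ndarray:
    arr = []
    for e in events:
        arr.append(e.charge if hasattr(e, "charge") else float(e))
    return np.asarray(arr, dtype=float)


def charge_ratio_ri(
    events_pos,
    events_neg,
    epoch_length: float,
    junction_potential: float = 11.0,
    e_rev: float = 0.0,
    v_pos: float = 60.0,
    v_neg: float = -60.0,
) -> ChargeRatioResult:
    """Summed-charge rectification index from mEPSCs at two potentials.

    ``events_pos``/``events_neg`` are events (or plain charges, pC) collected
    over equal-length epochs at the positive and negative command potentials.
    Each summed charge is divided by the absolute driving force at the
    junction-corrected potential, so that an ohmic (linear) conductance with
    the given reversal yields ri = 1 and a fully rectifying one yields 0.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    q_pos = float(np.abs(_charges(events_pos)).sum())
    q_neg = float(np.abs(_charges(events_neg)).sum())
    if q_neg == 0:
        raise UndefinedRatioError("no charge at the negative potential")
    df_pos = abs((v_pos - junction_potential) - e_rev)
    df_neg = abs((v_neg - junction_potential) - e_rev)
    ri = (q_pos / df_pos) / (q_neg / df_neg)
    return ChargeRatioResult(q_pos=q_pos, q_neg=q_neg,
                             epoch_length=epoch_length, ri=ri)


@dataclass
class AmplitudeWindows:
    """Measurement windows for evoked AMPA and NMDA current components."""

    ampa_width: float = 1.0    # ms window centred on the first-EPSC peak
    nmda_offset: float = 20.0  # ms after the AMPA window
    search_window: float = 10.0  # ms after stimulus onset to search the peak
    smooth: float = 0.5          # ms boxcar used for peak localisation


def _window_mean(t: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    sel = (t >= lo) & (t <= hi)
    if not np.any(sel):
        raise ValueError(f"window [{lo}, {hi}] ms is outside the trace")
    return float(y[sel].mean())


def nmda_ampa_ratio(
    traces: dict[float, tuple[np.ndarray, np.ndarray]],
    windows: AmplitudeWindows | None = None,
    t_stim: float = 0.0,
    v_ampa: float = -60.0,
    v_nmda: float = 50.0,
) -> float:
    """NMDA/AMPA current ratio from traces at two holding potentials.

    ``traces`` maps holding potential (mV) to a ``(time_ms, current_pA)``
    pair.  The AMPA current is the mean over a 1 ms window centred on the
    first-EPSC peak at the hyperpolarised potential (peak located on a
    0.5 ms-smoothed copy within 10 ms of stimulus onset); the NMDA current
    is the mean over the same-width window 20 ms later at the depolarised
    potential.  Returns NMDA / |AMPA|.
    """
    if windows is None:
        windows = AmplitudeWindows()
    if not traces:
        raise ValueError("no traces given")
    try:
        t_a, i_a = traces[v_ampa]
        t_n, i_n = traces[v_nmda]
    except KeyError as exc:
        raise ValueError(f"missing trace at holding potential {exc}") from exc
    t_a = np.asarray(t_a, dtype=float)
    i_a = np.asarray(i_a, dtype=float)
    dt = float(np.median(np.diff(t_a)))
    w = max(1, int(round(windows.smooth / dt)))
    smooth = np.convolve(i_a, np.ones(w) / w, mode="same")
    sel = (t_a >= t_stim) & (t_a <= t_stim + windows.search_window)
    if not np.any(sel):
        raise ValueError("peak search window outside the trace")
    idx = np.nonzero(sel)[0]
    ipk = idx[int(np.argmin(smooth[idx]))]  # inward peak (most negative)
    t_pk = float(t_a[ipk])
    half = windows.ampa_width / 2
    ampa = _window_mean(t_a, i_a, t_pk - half, t_pk + half)
    nmda = _window_mean(
        np.asarray(t_n, dtype=float),
        np.asarray(i_n, dtype=float),
        t_pk + windows.nmda_offset - half,
        t_pk + windows.nmda_offset + half,
    )
    if ampa == 0:
        raise UndefinedRatioError("zero AMPA current")
    return nmda / abs(ampa)


def wash_in_effect(
    baseline_amplitudes, treatment_amplitudes, p_stability: float = 0.05
) -> float:
    """Drug effect as a percentage of the baseline first-EPSC amplitude.

    The baseline must be stable: a significant linear trend (t test on
    Pearson's r at ``p_stability``) raises ``UnstableBaselineError``, the
    recording being a candidate for discarding or truncation.  Returns
    mean(treatment)/mean(baseline) * 100.
    """
    base = np.asarray(baseline_amplitudes, dtype=float)
    treat = np.asarray(treatment_amplitudes, dtype=float)
    if len(base) < 3 or len(treat) < 1:
        raise InsufficientDataError("need >= 3 baseline and >= 1 treatment points")
    if np.std(base) > 0:
        r, p = stats.pearsonr(np.arange(len(base)), base)
        if p < p_stability:
            raise UnstableBaselineError(
                f"baseline has a significant trend (r={r:.3f}, P={p:.4f})"
            )
    mb = base.mean()
    if mb == 0:
        raise UndefinedRatioError("zero mean baseline amplitude")
    return float(treat.mean() / mb * 100.0)
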