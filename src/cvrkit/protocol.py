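"""Hypercapnia protocol, capnograph traces and the end-tidal CO2 regressor.

A CVR study raises the subject's arterial CO2 in controlled steps while BOLD
volumes are acquired.  This module models that stimulus side of the
experiment:

* :class:`HypercapniaProtocol` — the target PetCO2 schedule (baseline with
  hypercapnic blocks of +``step_mmHg``);
* :func:`build_protocol_waveform` — the schedule sampled on the scanner TR
  grid, used both as a fitting regressor and as the phantom driving signal;
* :func:`simulate_capnograph` — a synthetic airway-pCO2 recording with one
  respiratory cycle per breath (stand-in for a sequential-gas-delivery
  capnograph recording);
* :func:`detect_end_tidal` — automatic per-breath end-tidal (expiratory
  maximum) extraction;
* :func:`resample_to_tr` — linear interpolation of breath-wise PetCO2 points
  onto volume midpoints.

Conventions (fixed so that downstream tests are bit-exact): BOLD volume ``i``
is timestamped at its midpoint ``t0 + (i + 0.5) * TR``; interpolation between
end-tidal points is linear with flat extrapolation beyond the first/last
breath.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import DetectionError, InvalidArgumentError

__all__ = [
    "HypercapniaProtocol",
    "CapnoTrace",
    "EndTidalSeries",
    "Regressor",
    "build_protocol_waveform",
    "simulate_capnograph",
    "detect_end_tidal",
    "resample_to_tr",
]

#: default PetCO2 baseline (mmHg); typical normocapnic end-tidal CO2
DEFAULT_BASELINE_MMHG = 35.0


@dataclass(frozen=True)
class HypercapniaProtocol:
    """Target PetCO2 schedule: baseline with square hypercapnic blocks.

    The default protocol is two +10 mmHg blocks of 45 s and 130 s separated
    by 90 s of baseline, preceded by a 60 s lead-in; the tail returns to
    baseline until the end of the acquisition.

    Parameters
    ----------
    baseline_mmHg : float
        Normocapnic target (mmHg).
    step_mmHg : float
        Hypercapnic increment above baseline (mmHg); 0 gives a flat protocol.
    block_durations_s : tuple of float
        Length of each hypercapnic block, in order (s).
    inter_block_s : float
        Baseline interval between consecutive blocks (s).
    lead_in_s, tail_s : float
        Baseline before the first and after the last block (s).
    """

    baseline_mmHg: float = DEFAULT_BASELINE_MMHG
    step_mmHg: float = 10.0
    block_durations_s: tuple[float, ...] = (45.0, 130.0)
    inter_block_s: float = 90.0
    lead_in_s: float = 60.0
    tail_s: float = 185.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "block_durations_s", tuple(float(d) for d in self.block_durations_s)
        )
        if not self.block_durations_s:
            raise InvalidArgumentError("protocol needs at least one block")
        durations = (*self.block_durations_s, self.inter_block_s, self.lead_in_s, self.tail_s)
        if any(not np.isfinite(d) or d <= 0 for d in durations):
            raise InvalidArgumentError("all protocol durations must be positive and finite")
        if not np.isfinite(self.baseline_mmHg) or self.baseline_mmHg < 0:
            raise InvalidArgumentError("baseline_mmHg must be finite and non-negative")
        if not np.isfinite(self.step_mmHg):
            raise InvalidArgumentError("step_mmHg must be finite")

    @property
    def n_blocks(self) -> int:
        return len(self.block_durations_s)

    @property
    def total_duration_s(self) -> float:
        return (
            self.lead_in_s
            + sum(self.block_durations_s)
            + self.inter_block_s * (self.n_blocks - 1)
            + self.tail_s
        )

    def block_intervals(self) -> list[tuple[float, float]]:
        """Start/end times (s) of each hypercapnic block."""
        out = []
        start = self.lead_in_s
        for dur in self.block_durations_s:
            out.append((start, start + dur))
            start += dur + self.inter_block_s
        return out

    def target_at(self, t) -> np.ndarray:
        """Scheduled PetCO2 target (mmHg) at time(s) ``t``.

        Times beyond the schedule evaluate to baseline (baseline padding).
        """
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.baseline_mmHg)
        for start, end in self.block_intervals():
            out[(t >= start) & (t < end)] += self.step_mmHg
        return out


@dataclass(frozen=True)
class CapnoTrace:
    """An instantaneous airway pCO2 recording."""

    time_s: np.ndarray
    pco2_mmHg: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        p = np.asarray(self.pco2_mmHg, dtype=float)
        if t.shape != p.shape or t.ndim != 1:
            raise InvalidArgumentError("time and pco2 must be 1-D arrays of equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise InvalidArgumentError("time must be strictly increasing")
        if np.any(p < 0) or not np.all(np.isfinite(p)):
            raise InvalidArgumentError("pCO2 must be finite and non-negative")
        if self.sample_rate_hz <= 0:
            raise InvalidArgumentError("sample_rate_hz must be positive")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "pco2_mmHg", p)


@dataclass(frozen=True)
class EndTidalSeries:
    """Breath-wise end-tidal pCO2 points (one per detected breath)."""

    breath_time_s: np.ndarray
    petco2_mmHg: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.breath_time_s, dtype=float)
        p = np.asarray(self.petco2_mmHg, dtype=float)
        if t.shape != p.shape or t.ndim != 1:
            raise InvalidArgumentError("breath times and values must match in length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise InvalidArgumentError("breath times must be strictly increasing")
        object.__setattr__(self, "breath_time_s", t)
        object.__setattr__(self, "petco2_mmHg", p)

    def __len__(self) -> int:
        return len(self.breath_time_s)


@dataclass(frozen=True)
class Regressor:
    """PetCO2 sampled per retained BOLD volume, on the TR grid."""

    values_mmHg: np.ndarray
    tr_s: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values_mmHg, dtype=float)
        if v.ndim != 1 or len(v) < 1:
            raise InvalidArgumentError("regressor must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError("regressor values must be finite")
        if self.tr_s <= 0:
            raise InvalidArgumentError("tr_s must be positive")
        object.__setattr__(self, "values_mmHg", v)

    @property
    def n_volumes(self) -> int:
        return len(self.values_mmHg)

    def __len__(self) -> int:
        return len(self.values_mmHg)


def volume_midpoints(tr_s: float, n_volumes: int, t0_s: float = 0.0) -> np.ndarray:
    """Midpoint timestamps ``t0 + (i + 0.5) * TR`` for each volume."""
    if tr_s <= 0:
        raise InvalidArgumentError("tr_s must be positive")
    if n_volumes < 1:
        raise InvalidArgumentError("n_volumes must be >= 1")
    return t0_s + (np.arange(n_volumes) + 0.5) * tr_s


def build_protocol_waveform(
    protocol: HypercapniaProtocol, tr_s: float, n_volumes: int, t0_s: float = 0.0
) -> Regressor:
    """Sample the piecewise-constant PetCO2 schedule at volume midpoints.

    Values are exactly ``baseline`` or ``baseline + step``; acquisitions
    longer than the schedule are padded with baseline, shorter ones truncate.
    """
    mids = volume_midpoints(tr_s, n_volumes, t0_s)
    return Regressor(protocol.target_at(mids), tr_s, t0_s)


def _target_function(source):
    if isinstance(source, HypercapniaProtocol):
        return source.target_at, source.total_duration_s
    if isinstance(source, Regressor):
        mids = volume_midpoints(source.tr_s, source.n_volumes, source.t0_s)

        def lookup(t):
            return np.interp(np.asarray(t, dtype=float), mids, source.values_mmHg)

        return lookup, source.t0_s + source.n_volumes * source.tr_s
    raise InvalidArgumentError("source must be a HypercapniaProtocol or Regressor")


def simulate_capnograph(
    source,
    breath_rate_per_min: float = 12.0,
    noise_sd_mmHg: float = 0.0,
    seed: int = 0,
    sample_rate_hz: float = 10.0,
    duration_s: float | None = None,
    inspired_mmHg: float = 2.0,
) -> CapnoTrace:
    """Synthesize an airway-pCO2 trace following a protocol or regressor.

    Each respiratory cycle has an inspiratory trough near ``inspired_mmHg``
    followed by an expiratory rise to a flat plateau; the plateau sits at the
    scheduled target for the breath's end time, plus per-breath Gaussian
    noise of SD ``noise_sd_mmHg``.  Seeded and reproducible.
    """
    if breath_rate_per_min <= 0:
        raise InvalidArgumentError("breath_rate_per_min must be positive")
    if noise_sd_mmHg < 0:
        raise InvalidArgumentError("noise_sd_mmHg must be non-negative")
    if sample_rate_hz <= 0:
        raise InvalidArgumentError("sample_rate_hz must be positive")

    target, total = _target_function(source)
    if duration_s is None:
        duration_s = total
    if duration_s <= 0:
        raise InvalidArgumentError("duration_s must be positive")

    rng = np.random.default_rng(seed)
    period = 60.0 / breath_rate_per_min
    n_breaths = int(np.ceil(duration_s / period))
    # per-breath plateau: scheduled target at end of exhalation (+ noise)
    breath_ends = (np.arange(n_breaths) + 1) * period
    plateaus = target(breath_ends) + rng.normal(0.0, noise_sd_mmHg, n_breaths)
    plateaus = np.maximum(plateaus, inspired_mmHg)

    t = np.arange(int(np.floor(duration_s * sample_rate_hz)) + 1) / sample_rate_hz
    breath_idx = np.minimum((t / period).astype(int), n_breaths - 1)
    phase = (t - breath_idx * period) / period

    p = np.empty_like(t)
    insp = phase < 0.35
    rise = (phase >= 0.35) & (phase < 0.55)
    plat = phase >= 0.55
    p[insp] = inspired_mmHg
    frac = (phase[rise] - 0.35) / 0.20
    p[rise] = inspired_mmHg + frac * (plateaus[breath_idx[rise]] - inspired_mmHg)
    p[plat] = plateaus[breath_idx[plat]]

    return CapnoTrace(t, p, sample_rate_hz)


def detect_end_tidal(trace: CapnoTrace, min_breath_interval_s: float = 2.0) -> EndTidalSeries:
    """Extract one end-tidal point per breath from a capnograph trace.

    A breath's end-tidal point is the maximum of its expiratory excursion; on
    a flat plateau the point is timestamped at the plateau's trailing edge
    (closest to the start of the next inspiration).  Peaks are separated by
    at least ``min_breath_interval_s`` (default 2 s, i.e. <= 30 breaths/min).
    """
    if min_breath_interval_s <= 0:
        raise InvalidArgumentError("min_breath_interval_s must be positive")
    p = trace.pco2_mmHg
    span = float(np.ptp(p)) if len(p) else 0.0
    if len(p) < 4 or span < 1.0:
        raise DetectionError("no respiratory oscillation found in trace")

    distance = max(1, int(round(min_breath_interval_s * trace.sample_rate_hz)))
    peaks, props = find_peaks(
        p, distance=distance, prominence=0.25 * span, plateau_size=(1, None)
    )
    if len(peaks) < 2:
        raise DetectionError("fewer than two breaths detected")
    edges = props["right_edges"]
    return EndTidalSeries(trace.time_s[edges], p[edges])


def resample_to_tr(
    etseries: EndTidalSeries, tr_s: float, n_volumes: int, t0_s: float = 0.0
) -> Regressor:
    """Interpolate breath-wise PetCO2 points onto volume midpoints.

    Linear between breaths, constant beyond the first/last breath.
    """
    if len(etseries) < 2:
        raise InvalidArgumentError("need at least two end-tidal points to resample")
    mids = volume_midpoints(tr_s, n_volumes, t0_s)
    values = np.interp(mids, etseries.breath_time_s, etseries.petco2_mmHg)
    return Regressor(values, tr_s, t0_s)
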