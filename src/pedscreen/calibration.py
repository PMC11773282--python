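"""Level calibration and ambient-noise metering.

Maps between three level scales used by the screener:

* device volume (%)  <->  dB SPL, via a measured calibration table
  (sound-level-meter readings at a set of volume settings per frequency);
* dB SPL  <->  dB HL, via the transducer's RETSPL table
  (reference equivalent threshold SPL: the SPL the transducer produces at
  0 dB HL, so SPL = HL + RETSPL(f));
* digital full-scale RMS  ->  dBA, via the standard A-weighting network
  and a metering calibration offset, feeding the pre-session noise gate.

The headphone RETSPL table shipped with the package was derived by the
Wilber procedure — the mean, over a normal-hearing panel, of the device
SPL at each listener's threshold minus that listener's audiometric
threshold in dB HL — and :func:`derive_retspl_wilber` re-implements that
derivation for new transducers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .stimuli import Waveform

__all__ = [
    "CalibrationTable",
    "RetsplTable",
    "NoiseGateConfig",
    "OutOfRangeError",
    "MissingFrequencyError",
    "default_headphone_retspl",
    "default_soundfield_retspl",
    "volume_to_spl",
    "spl_to_volume",
    "hl_to_spl",
    "spl_to_hl",
    "derive_retspl_wilber",
    "a_weighting_sos",
    "measure_dba",
    "noise_gate",
    "measure_harmonic_distortion",
]

SCREEN_FREQUENCIES = (500.0, 1000.0, 2000.0, 4000.0)
DBA_FLOOR = -120.0


class OutOfRangeError(ValueError):
    """Requested level/volume lies outside the measured calibration range."""


class MissingFrequencyError(KeyError):
    """Frequency absent from a calibration or RETSPL table."""


@dataclass(frozen=True)
class CalibrationTable:
    """Per-frequency measured (volume %, dB SPL) pairs.

    Volume must be strictly increasing and SPL non-decreasing within each
    frequency; interpolation is piecewise linear and never extrapolates.
    """

    points: dict[float, list[tuple[float, float]]]

    def __post_init__(self) -> None:
        for f, pairs in self.points.items():
            if len(pairs) < 2:
                raise ValueError(f"need >=2 calibration points at {f} Hz")
            vols = [v for v, _ in pairs]
            spls = [s for _, s in pairs]
            if any(b <= a for a, b in zip(vols, vols[1:])):
                raise ValueError(f"volumes not strictly increasing at {f} Hz")
            if any(b < a for a, b in zip(spls, spls[1:])):
                raise ValueError(f"SPL not non-decreasing at {f} Hz")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CalibrationTable":
        df = pd.read_csv(path, sep="\t")
        pts: dict[float, list[tuple[float, float]]] = {}
        for f, grp in df.groupby("frequency"):
            grp = grp.sort_values("volume_percent")
            pts[float(f)] = list(zip(grp["volume_percent"].astype(float),
                                     grp["spl_db"].astype(float)))
        return cls(pts)


@dataclass(frozen=True)
class RetsplTable:
    """frequency (Hz) -> RETSPL (dB); unrounded values kept alongside."""

    values: dict[float, int]
    unrounded: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.unrounded:
            object.__setattr__(self, "unrounded", {f: float(v) for f, v in self.values.items()})
        for f, v in self.values.items():
            if not (-20 <= v <= 30):
                raise ValueError(f"implausible RETSPL {v} dB at {f} Hz")

    def retspl(self, freq: float) -> float:
        try:
            return self.values[float(freq)]
        except KeyError:
            raise MissingFrequencyError(f"no RETSPL at {freq} Hz") from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RetsplTable":
        df = pd.read_csv(path, sep="\t")
        return cls({float(r["frequency"]): int(r["retspl_db"]) for _, r in df.iterrows()})

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"frequency": list(self.values), "retspl_db": list(self.values.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class NoiseGateConfig:
    """Pre-session ambient-noise gate: allow screening only below the threshold."""

    threshold_dba: float = 50.0
    window: float = 1.0       # seconds of signal metered
    cal_offset: float = 0.0   # dB SPL = dBFS_RMS + cal_offset


def _package_table(name: str) -> RetsplTable:
    ref = resources.files("pedscreen").joinpath(f"data/{name}")
    with resources.as_file(ref) as p:
        return RetsplTable.from_tsv(p)


def default_headphone_retspl() -> RetsplTable:
    """Shipped headphone RETSPL table (Wilber-derived for the stock headphones)."""
    return _package_table("headphone_retspl.tsv")


def default_soundfield_retspl() -> RetsplTable:
    """Shipped sound-field RETSPL table (free-field, 0-degree azimuth reference values)."""
    return _package_table("soundfield_retspl.tsv")


def _freq_points(table: CalibrationTable, freq: float) -> list[tuple[float, float]]:
    try:
        return table.points[float(freq)]
    except KeyError:
        raise MissingFrequencyError(f"no calibration at {freq} Hz") from None


def volume_to_spl(table: CalibrationTable, freq: float, volume: float) -> float:
    """Piecewise-linear interpolation of measured SPL at a volume setting."""
    pairs = _freq_points(table, freq)
    vols = np.array([v for v, _ in pairs])
    spls = np.array([s for _, s in pairs])
    if not (vols[0] <= volume <= vols[-1]):
        raise OutOfRangeError(
            f"volume {volume}% outside measured range [{vols[0]}, {vols[-1]}] at {freq} Hz"
        )
    return float(np.interp(volume, vols, spls))


def spl_to_volume(table: CalibrationTable, freq: float, spl: float) -> float:
    """Inverse of :func:`volume_to_spl` on the measured range (no extrapolation)."""
    pairs = _freq_points(table, freq)
    vols = np.array([v for v, _ in pairs])
    spls = np.array([s for _, s in pairs])
    if not (spls[0] <= spl <= spls[-1]):
        raise OutOfRangeError(
            f"{spl} dB SPL outside achievable range [{spls[0]}, {spls[-1]}] at {freq} Hz"
        )
    return float(np.interp(spl, spls, vols))


def hl_to_spl(retspl: RetsplTable, freq: float, level_hl: float) -> float:
    """dB SPL = dB HL + RETSPL(f)."""
    return level_hl + retspl.retspl(freq)


def spl_to_hl(retspl: RetsplTable, freq: float, spl: float) -> float:
    """dB HL = dB SPL - RETSPL(f)."""
    return spl - retspl.retspl(freq)


def derive_retspl_wilber(
    measurements: pd.DataFrame,
) -> RetsplTable:
    """Derive a RETSPL table from paired thresholds on a normal-hearing panel.

    ``measurements`` columns: subject, frequency, audiometer_hl (dB HL on a
    reference audiometer), device_spl (device output SPL at that subject's
    threshold).  RETSPL(f) is the panel mean of device_spl - audiometer_hl,
    rounded to the nearest dB for table export; unrounded means are kept.
    """
    required = {"subject", "frequency", "audiometer_hl", "device_spl"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurements need columns {sorted(required)}")
    if measurements.empty:
        raise ValueError("no measurements supplied")
    offsets = measurements["device_spl"] - measurements["audiometer_hl"]
    means = offsets.groupby(measurements["frequency"].astype(float)).mean()
    unrounded = {float(f): float(v) for f, v in means.items()}
    # round half away from zero so e.g. a +10.5 panel mean exports as 11
    rounded = {f: int(np.floor(v + 0.5)) if v >= 0 else -int(np.floor(-v + 0.5))
               for f, v in unrounded.items()}
    return RetsplTable(values=rounded, unrounded=unrounded)


def a_weighting_sos(sample_rate: int) -> np.ndarray:
    """A-weighting network (IEC 61672 analog transfer function, bilinear-discretized)."""
    f1, f2, f3, f4 = 20.598997, 107.65265, 737.86223, 12194.217
    z = [0.0, 0.0, 0.0, 0.0]
    p = [
        -2 * np.pi * f4, -2 * np.pi * f4,
        -2 * np.pi * f1, -2 * np.pi * f1,
        -2 * np.pi * f2, -2 * np.pi * f3,
    ]
    # normalize to 0 dB at 1 kHz (the 1.9997 dB analog correction)
    k = (2 * np.pi * f4) ** 2 * 10 ** (1.9997 / 20)
    zd, pd_, kd = signal.bilinear_zpk(z, p, k, sample_rate)
    return signal.zpk2sos(zd, pd_, kd)


def measure_dba(w: Waveform, cfg: NoiseGateConfig) -> float:
    """A-weighted level (dBA) of the most recent metering window.

    dBA = 20*log10(RMS of the A-weighted signal) + cal_offset.  Digital
    silence returns the -120 dBA floor rather than raising.
    """
    n_window = int(round(cfg.window * w.sample_rate))
    if len(w.samples) < n_window:
        raise ValueError(
            f"need at least {cfg.window} s of signal, got {w.duration:.3f} s"
        )
    sos = a_weighting_sos(w.sample_rate)
    weighted = signal.sosfilt(sos, w.samples)[-n_window:]
    rms = float(np.sqrt(np.mean(weighted**2)))
    if rms <= 10 ** ((DBA_FLOOR - cfg.cal_offset) / 20):
        return DBA_FLOOR
    return 20 * np.log10(rms) + cfg.cal_offset


def noise_gate(dba: float, cfg: NoiseGateConfig) -> bool:
    """True (allow) iff the ambient level is strictly below the gate threshold."""
    return dba < cfg.threshold_dba


def measure_harmonic_distortion(
    w: Waveform, fundamental: float, n_harmonics: int = 5
) -> float:
    """Total harmonic distortion (%) of a steady tone, harmonics 2..n_harmonics.

    RMS of the harmonic components relative to the fundamental, each
    estimated from an averaged spectrum in a narrow window around the
    harmonic frequency.
    """
    if fundamental * n_harmonics >= w.sample_rate / 2:
        raise ValueError("highest requested harmonic at or above Nyquist")
    if w.duration < 0.5:
        raise ValueError("need a steady tone of at least 0.5 s")
    nperseg = min(8192, len(w.samples))
    freqs, psd = signal.welch(w.samples, fs=w.sample_rate, nperseg=nperseg)

    def component_power(f0: float) -> float:
        half = max(3 * (freqs[1] - freqs[0]), 0.02 * f0)
        m = (freqs >= f0 - half) & (freqs <= f0 + half)
        return float(np.sum(psd[m]))

    p1 = component_power(fundamental)
    if p1 <= 0:
        raise ValueError("no energy at the fundamental")
    ph = sum(component_power(k * fundamental) for k in range(2, n_harmonics + 1))
    return 100.0 * float(np.sqrt(ph / p1))
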