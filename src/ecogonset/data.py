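"""Core containers shared across the pipeline.

Conventions
-----------
* ``signal`` arrays are ``(n_channels, n_samples)``; epoched arrays are
  ``(n_trials, n_channels, n_times)``.
* All times are seconds; epoched time axes are relative to the per-trial
  marker (time 0 = marker).
* Channel metadata lives in a :class:`pandas.DataFrame` with columns
  ``name``, ``region`` (one of ``M1``/``S1``/``CS``/``Other``), ``in_car``,
  ``bad`` and ``in_hand_region``.
* Samples invalidated by edge effects are NaN and every downstream
  statistic is NaN-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

REGIONS = ("M1", "S1", "CS", "Other")

CHANNEL_COLUMNS = ("name", "region", "in_car", "bad", "in_hand_region")


def make_channel_table(
    regions: Sequence[str],
    names: Sequence[str] | None = None,
    in_car: Sequence[bool] | None = None,
    in_hand_region: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Build a channel-metadata table from per-channel region labels."""
    regions = list(regions)
    n = len(regions)
    for r in regions:
        if r not in REGIONS:
            raise ValueError(f"unknown region label {r!r}; expected one of {REGIONS}")
    if names is None:
        names = [f"ch{i:03d}" for i in range(n)]
    if in_car is None:
        in_car = [True] * n
    if in_hand_region is None:
        in_hand_region = [True] * n
    if not (len(names) == len(in_car) == len(in_hand_region) == n):
        raise ValueError("channel metadata columns must all have the same length")
    return pd.DataFrame(
        {
            "name": list(names),
            "region": regions,
            "in_car": list(map(bool, in_car)),
            "bad": [False] * n,
            "in_hand_region": list(map(bool, in_hand_region)),
        }
    )


@dataclass
class Recording:
    """Continuous multichannel recording.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Voltage traces in microvolt-scale arbitrary units.
    fs : float
        Sampling rate in Hz.
    channels : DataFrame
        Channel metadata (see module docstring).
    """

    signal: np.ndarray
    fs: float
    channels: pd.DataFrame

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.signal.shape[0]:
            raise ValueError(
                f"channel table has {len(self.channels)} rows but signal has "
                f"{self.signal.shape[0]} channels"
            )
        missing = set(CHANNEL_COLUMNS) - set(self.channels.columns)
        if missing:
            raise ValueError(f"channel table missing columns {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return Recording(self.signal.copy(), self.fs, self.channels.copy())


EVENT_COLUMNS = ("trial_id", "finger", "cue_time_s", "marker_time_s", "excluded")


def make_event_table(
    fingers: Sequence[str],
    cue_time_s: Sequence[float],
    marker_time_s: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Build an event table; one row per trial, cue times strictly increasing."""
    cues = np.asarray(cue_time_s, dtype=float)
    if len(fingers) != len(cues):
        raise ValueError("fingers and cue_time_s must have equal length")
    if np.any(np.diff(cues) <= 0):
        raise ValueError("cue times must be strictly increasing")
    markers = (
        np.full(len(cues), np.nan)
        if marker_time_s is None
        else np.asarray(marker_time_s, dtype=float)
    )
    return pd.DataFrame(
        {
            "trial_id": np.arange(len(cues)),
            "finger": list(fingers),
            "cue_time_s": cues,
            "marker_time_s": markers,
            "excluded": np.zeros(len(cues), dtype=bool),
        }
    )


@dataclass
class TrialSet:
    """Epoched data: ``data`` is (n_trials, n_channels, n_times)."""

    data: np.ndarray
    time_s: np.ndarray
    fs: float
    fingers: np.ndarray
    channels: pd.DataFrame
    trial_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fingers = np.asarray(self.fingers)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x times)")
        if self.data.shape[2] != self.time_s.size:
            raise ValueError("time axis length mismatch")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel table length mismatch")
        if self.data.shape[0] != self.fingers.size:
            raise ValueError("one finger label per trial required")
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.data.shape[0])
        else:
            self.trial_ids = np.asarray(self.trial_ids)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def select_trials(self, mask: np.ndarray) -> "TrialSet":
        mask = np.asarray(mask)
        return TrialSet(
            self.data[mask],
            self.time_s,
            self.fs,
            self.fingers[mask],
            self.channels,
            self.trial_ids[mask],
        )

    def select_channels(self, idx: np.ndarray) -> "TrialSet":
        idx = np.asarray(idx)
        return TrialSet(
            self.data[:, idx],
            self.time_s,
            self.fs,
            self.fingers,
            self.channels.iloc[idx].reset_index(drop=True),
            self.trial_ids,
        )


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with its expected response direction."""

    name: str
    low: float
    high: float
    direction: str  # "increase" or "decrease"

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("band low must be below high")
        if self.direction not in ("increase", "decrease"):
            raise ValueError("direction must be 'increase' or 'decrease'")

    @property
    def sign(self) -> int:
        return 1 if self.direction == "increase" else -1


#: Canonical bands: power decreases with movement in the low bands
#: (event-related desynchronization), increases in the high band.
DEFAULT_BANDS: dict[str, BandSpec] = {
    "alpha": BandSpec("alpha", 8.0, 12.0, "decrease"),
    "beta": BandSpec("beta", 13.0, 30.0, "decrease"),
    "lfb": BandSpec("lfb", 8.0, 30.0, "decrease"),
    "hfb": BandSpec("hfb", 60.0, 100.0, "increase"),
}


def bands_from_overrides(overrides: dict[str, Sequence[float]] | None = None) -> dict[str, BandSpec]:
    """Default band set with optional per-participant ``name -> (low, high)`` overrides.

    Response direction is fixed by the band name (increase for ``hfb``,
    decrease otherwise); only the frequency edges may be overridden, e.g.
    ``{"hfb": (30, 100)}`` for a participant with a wider gamma response.
    """
    bands = dict(DEFAULT_BANDS)
    for name, (low, high) in (overrides or {}).items():
        if name not in bands:
            raise KeyError(f"unknown band {name!r}")
        bands[name] = replace(bands[name], low=float(low), high=float(high))
    return bands


@dataclass
class BandPower(TrialSet):
    """Band-averaged spectral power; same layout as :class:`TrialSet`."""

    band: BandSpec = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.band is None:
            raise ValueError("BandPower requires a band")
        finite = self.data[np.isfinite(self.data)]
        if finite.size and finite.min() < 0:
            raise ValueError("band power must be non-negative")

    def select_trials(self, mask: np.ndarray) -> "BandPower":
        ts = super().select_trials(mask)
        return BandPower(ts.data, ts.time_s, ts.fs, ts.fingers, ts.channels, ts.trial_ids, band=self.band)

    def select_channels(self, idx: np.ndarray) -> "BandPower":
        ts = super().select_channels(idx)
        return BandPower(ts.data, ts.time_s, ts.fs, ts.fingers, ts.channels, ts.trial_ids, band=self.band)


@dataclass
class GroundTruth:
    """Synthetic-only truth: per-trial movement times, per-channel lags."""

    true_movement_time_s: np.ndarray
    true_onset_s: np.ndarray
    region_of_channel: list[str]

    def __post_init__(self) -> None:
        self.true_movement_time_s = np.asarray(self.true_movement_time_s, dtype=float)
        self.true_onset_s = np.asarray(self.true_onset_s, dtype=float)
        if len(self.region_of_channel) != self.true_onset_s.size:
            raise ValueError("one region label per channel required")


@dataclass
class GloveTrace:
    """Continuous dataglove traces, one row per finger sensor."""

    traces: np.ndarray  # (n_fingers, n_samples)
    fingers: list[str]
    fs: float

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2 or self.traces.shape[0] != len(self.fingers):
            raise ValueError("traces must be (n_fingers, n_samples)")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("glove traces must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def trace_for(self, finger: str) -> np.ndarray:
        return self.traces[self.fingers.index(finger)]
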