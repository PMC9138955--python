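"""Twitch-waveform representation and contractile-parameter extraction.

Tensiomyography (TMG) records the radial displacement of a muscle belly
during an electrically evoked isometric twitch.  Three parameters summarise
the twitch:

* ``Td`` (delay time, ms) — time from the stimulus to the first upward
  crossing of 10 % of the maximal displacement;
* ``Tc`` (contraction time, ms) — time from the 10 % crossing to the first
  upward crossing of 90 % of the maximal displacement;
* ``Dm`` (maximal displacement, mm) — the peak radial displacement.

Thresholds are fractions of the peak, so the times rarely fall on sample
points; crossings are located by linear interpolation between the two
bracketing samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "TMGSignal",
    "TwitchParams",
    "SupramaximalResult",
    "SignalFormatError",
    "NoContractionError",
    "ExtractionError",
    "load_signal",
    "save_signal",
    "baseline_correct",
    "extract_twitch_params",
    "select_supramaximal",
    "TwitchParamExtractor",
]

_UNIFORMITY_RTOL = 1e-9


class SignalFormatError(ValueError):
    """Raised for malformed waveform files or invalid signal arrays."""


class NoContractionError(ValueError):
    """Raised when a waveform has no measurable contraction (peak too small)."""


class ExtractionError(ValueError):
    """Raised when a threshold crossing cannot be located on the rise."""


@dataclass(frozen=True)
class TwitchParams:
    """The contractile-parameter triple of one twitch.

    Attributes
    ----------
    td : float
        Delay time in ms (stimulus to 10 % of peak).
    tc : float
        Contraction time in ms (10 % to 90 % of peak).
    dm : float
        Maximal radial displacement in mm.
    """

    td: float
    tc: float
    dm: float

    def __post_init__(self) -> None:
        for name in ("td", "tc", "dm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class TMGSignal:
    """A uniformly sampled radial-displacement waveform, stimulus at t = 0.

    ``time`` is in ms and must start at 0 with uniform spacing;
    ``displacement`` is in mm.  ``meta`` holds free-form labels such as
    muscle, side or stimulation current.
    """

    time: np.ndarray
    displacement: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.displacement, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "displacement", y)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise SignalFormatError("time and displacement must be 1-D arrays of equal length")
        if t.size < 50:
            raise SignalFormatError(f"signal too short: {t.size} samples (minimum 50)")
        if not np.isfinite(y).all() or not np.isfinite(t).all():
            raise SignalFormatError("signal contains non-finite values")
        if t[0] != 0.0:
            raise SignalFormatError(f"first sample must be at t = 0, got {t[0]}")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise SignalFormatError("time must be strictly increasing")
        dt0 = dt[0]
        if np.any(np.abs(dt - dt0) > _UNIFORMITY_RTOL * max(abs(dt0), 1.0)):
            raise SignalFormatError("non-uniform sampling beyond tolerance")

    @property
    def sampling_interval(self) -> float:
        """Sampling interval in ms."""
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        """Record duration in ms."""
        return float(self.time[-1])


class SupramaximalResult(NamedTuple):
    index: int
    params: TwitchParams
    plateau_reached: bool


def load_signal(path: str | Path, delimiter: str | None = None) -> TMGSignal:
    """Read a two-column delimited waveform file (time ms, displacement mm).

    Comma- or whitespace-delimited; one optional header line is tolerated.
    Time is re-based so the first sample sits at t = 0.

    Raises
    ------
    SignalFormatError
        Naming the offending line for non-numeric rows, or if the sampling
        is non-uniform beyond tolerance.
    """
    path = Path(path)
    times: list[float] = []
    disps: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(delimiter) if delimiter else line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                if lineno == 1 and not times:  # header tolerance
                    continue
                raise SignalFormatError(f"{path.name}: non-numeric data on line {lineno}: {line!r}") from None
            if len(vals) != 2:
                raise SignalFormatError(f"{path.name}: expected 2 columns on line {lineno}, got {len(vals)}")
            times.append(vals[0])
            disps.append(vals[1])
    if not times:
        raise SignalFormatError(f"{path.name}: no data rows")
    t = np.asarray(times)
    return TMGSignal(time=t - t[0], displacement=np.asarray(disps), meta={"source": str(path)})


def save_signal(signal: TMGSignal, path: str | Path, header: bool = True) -> None:
    """Write a waveform as two-column CSV; floats use round-trip precision."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header:
            fh.write("time_ms,displacement_mm\n")
        for t, y in zip(signal.time, signal.displacement):
            fh.write(f"{float(t)!r},{float(y)!r}\n")


def baseline_correct(signal: TMGSignal, pre_window: float = 0.0) -> TMGSignal:
    """Subtract the early-record baseline from a waveform.

    The record starts at the stimulus (t = 0); displacement is still at rest
    during the initial latency, so the mean over the first ``pre_window`` ms
    serves as the baseline.  ``pre_window = 0`` subtracts the t = 0 sample.
    Only the mean is removed — a linear drift is not.
    """
    if pre_window < 0:
        raise ValueError("pre_window must be >= 0")
    if pre_window >= signal.duration:
        raise ValueError("pre_window must be shorter than the signal duration")
    if pre_window == 0:
        baseline = signal.displacement[0]
    else:
        mask = signal.time <= pre_window
        baseline = float(signal.displacement[mask].mean())
    return TMGSignal(
        time=signal.time,
        displacement=signal.displacement - baseline,
        meta=dict(signal.meta),
    )


def _first_upward_crossing(t: np.ndarray, y: np.ndarray, level: float, stop: int) -> float:
    """Time of the first upward crossing of ``level`` in y[: stop + 1].

    Linear interpolation between the bracketing samples.  ``stop`` is the
    index of the peak; the crossing must occur at or before it.
    """
    if y[0] >= level:
        raise ExtractionError(
            f"signal already above {level:.4g} mm at t = 0; cannot locate onset crossing"
        )
    below = y[: stop + 1] < level
    idx = np.nonzero(~below)[0]
    if idx.size == 0:
        raise ExtractionError(f"no upward crossing of {level:.4g} mm found before the peak")
    i = int(idx[0])  # first sample at or above the level
    if y[i] == level:
        return float(t[i])
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def _moving_average(y: np.ndarray, width: int) -> np.ndarray:
    if width % 2 != 1 or width < 1:
        raise ValueError("smoothing width must be a positive odd integer")
    if width == 1:
        return y
    pad = width // 2
    padded = np.pad(y, pad, mode="edge")
    kernel = np.full(width, 1.0 / width)
    return np.convolve(padded, kernel, mode="valid")


def extract_twitch_params(
    signal: TMGSignal,
    min_peak: float = 0.1,
    window: float = 1000.0,
    smooth_width: int | None = None,
) -> TwitchParams:
    """Extract (Td, Tc, Dm) from a baseline-corrected twitch waveform.

    Dm is the maximal displacement within the analysis ``window`` (ms after
    the stimulus); Td is the time of the first upward crossing of 0.10·Dm,
    Tc the time from there to the first upward crossing of 0.90·Dm.
    Crossings are linearly interpolated between bracketing samples.

    Parameters
    ----------
    min_peak : float
        Minimal acceptable peak in mm; below it a :class:`NoContractionError`
        is raised.
    smooth_width : int, optional
        Odd width of a centred moving average applied before extraction
        (off by default; the raw device signal is already smooth).
    """
    mask = signal.time <= window
    t = signal.time[mask]
    y = signal.displacement[mask]
    if smooth_width is not None:
        y = _moving_average(y, smooth_width)
    peak_idx = int(np.argmax(y))
    dm = float(y[peak_idx])
    if dm <= 0 or dm < min_peak:
        raise NoContractionError(
            f"peak displacement {dm:.4g} mm below the minimum of {min_peak} mm"
        )
    td = _first_upward_crossing(t, y, 0.10 * dm, peak_idx)
    t90 = _first_upward_crossing(t, y, 0.90 * dm, peak_idx)
    tc = t90 - td
    if tc <= 0:
        raise ExtractionError("non-positive contraction time; degenerate rise")
    if td <= 0:
        raise ExtractionError("non-positive delay time; signal rises at the stimulus sample")
    return TwitchParams(td=td, tc=tc, dm=dm)


def select_supramaximal(
    ramp: Sequence[tuple[float, TMGSignal]],
    rel_tol: float = 0.02,
    **extract_kwargs,
) -> SupramaximalResult:
    """Pick the supramaximal response from a stimulation-current ramp.

    The current is increased stepwise until the twitch amplitude plateaus;
    the supramaximal entry is the first whose Dm exceeds the previous Dm by
    less than ``rel_tol`` (relative).  If no plateau is found, the last entry
    is returned with ``plateau_reached=False``.
    """
    if len(ramp) == 0:
        raise ValueError("empty stimulation ramp")
    currents = [c for c, _ in ramp]
    if len(ramp) >= 2 and any(b <= a for a, b in zip(currents, currents[1:])):
        raise ValueError("ramp currents must be strictly increasing")
    params = [extract_twitch_params(sig, **extract_kwargs) for _, sig in ramp]
    for i in range(1, len(params)):
        if params[i].dm < params[i - 1].dm * (1.0 + rel_tol):
            return SupramaximalResult(index=i, params=params[i], plateau_reached=True)
    return SupramaximalResult(index=len(params) - 1, params=params[-1], plateau_reached=False)


class TwitchParamExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping twitch waveforms to (Td, Tc, Dm) rows.

    Accepts a sequence of :class:`TMGSignal` and returns an ``(n, 3)`` array
    in the column order ``(td, tc, dm)``.  Composes with sklearn pipelines
    operating on the extracted feature matrix.
    """

    def __init__(
        self,
        baseline_window: float = 0.0,
        min_peak: float = 0.1,
        window: float = 1000.0,
        smooth_width: int | None = None,
    ) -> None:
        self.baseline_window = baseline_window
        self.min_peak = min_peak
        self.window = window
        self.smooth_width = smooth_width

    def fit(self, X: Sequence[TMGSignal], y=None) -> "TwitchParamExtractor":
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[TMGSignal]) -> np.ndarray:
        out = np.empty((len(X), 3), dtype=float)
        for i, sig in enumerate(X):
            corrected = baseline_correct(sig, self.baseline_window)
            p = extract_twitch_params(
                corrected,
                min_peak=self.min_peak,
                window=self.window,
                smooth_width=self.smooth_width,
            )
            out[i] = (p.td, p.tc, p.dm)
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(["td", "tc", "dm"], dtype=object)
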