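"""Multichannel ECG records and the 8-lead initial-QRS time integrals.

The localization regression consumes exactly eight features per beat: the
time integral of each of the eight independent leads of the 12-lead ECG
(I, II, V1-V6) over the initial 120 ms of the QRS complex, in uV*s.  The
augmented/derived limb leads (III, aVR, aVL, aVF) are linear combinations
of I and II and carry no extra information, so they are never required.

ECG files are plain delimited text: comment-prefixed header lines
``# rate_hz: <float>`` and ``# units: uV|mV|V`` followed by a tab-separated
table whose columns are lead names.  Potentials are normalized to uV on
read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LEAD_ORDER",
    "ECGRecord",
    "IntegralVector",
    "qrs_integrals",
    "detect_qrs_onset",
    "read_ecg",
    "write_ecg",
    "EcgSchemaError",
    "WindowError",
    "OnsetDetectionError",
]

#: Fixed feature order used everywhere downstream.
LEAD_ORDER: tuple[str, ...] = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

_UNIT_TO_UV = {"uv": 1.0, "µv": 1.0, "mv": 1000.0, "v": 1e6}


class EcgSchemaError(ValueError):
    """Missing leads, malformed header, or unknown units."""


class WindowError(ValueError):
    """Integration window does not fit inside the record."""


class OnsetDetectionError(RuntimeError):
    """Automatic QRS-onset detection found no threshold crossing."""


@dataclass
class ECGRecord:
    """A multichannel ECG segment in uV.

    ``signals`` is a DataFrame with one column per lead; all leads share a
    sample axis at ``sampling_rate`` Hz.  ``qrs_onset`` is an optional
    annotated onset (sample index) that always overrides detection.
    """

    signals: pd.DataFrame
    sampling_rate: float
    qrs_onset: int | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise EcgSchemaError("sampling_rate must be positive")
        missing = [l for l in LEAD_ORDER if l not in self.signals.columns]
        if missing:
            raise EcgSchemaError(f"missing required lead(s): {', '.join(missing)}")

    @property
    def lead_names(self) -> list[str]:
        return list(self.signals.columns)

    @property
    def n_samples(self) -> int:
        return len(self.signals)


@dataclass(frozen=True)
class IntegralVector:
    """The 8 QRS time integrals in uV*s, fixed order I, II, V1..V6."""

    values: np.ndarray
    lead_order: tuple[str, ...] = LEAD_ORDER

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).reshape(-1)
        if vals.shape != (8,):
            raise EcgSchemaError("IntegralVector needs exactly 8 values")
        if not np.all(np.isfinite(vals)):
            raise EcgSchemaError("IntegralVector values must be finite")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "lead_order", tuple(self.lead_order))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.values], columns=list(self.lead_order))


def qrs_integrals(
    ecg: ECGRecord, onset: int | None = None, window_ms: float = 120.0,
    subtract_pre_onset_baseline: bool = False,
) -> IntegralVector:
    """Integrate each required lead over the initial QRS window.

    Left-rectangle rule: the sum of the ``floor(window_ms/1000 * rate)``
    samples starting at ``onset``, times the sample period.  Result in uV*s.

    ``subtract_pre_onset_baseline`` optionally removes the mean of the
    pre-onset samples from each lead first (off by default; the method as
    published applies no baseline correction).
    """
    if onset is None:
        onset = ecg.qrs_onset
    if onset is None:
        raise WindowError("no onset given and record carries no annotation")
    onset = int(onset)
    n_win = int(np.floor(window_ms / 1000.0 * ecg.sampling_rate))
    if onset < 0 or onset + n_win > ecg.n_samples:
        raise WindowError(
            f"window [{onset}, {onset + n_win}) exceeds record of "
            f"{ecg.n_samples} samples; refusing a partial integral"
        )
    data = ecg.signals[list(LEAD_ORDER)].to_numpy(dtype=float)
    seg = data[onset : onset + n_win]
    if subtract_pre_onset_baseline and onset > 0:
        seg = seg - data[:onset].mean(axis=0)
    dt = 1.0 / ecg.sampling_rate
    return IntegralVector(seg.sum(axis=0) * dt)


def detect_qrs_onset(
    ecg: ECGRecord,
    smooth_ms: float = 10.0,
    rel_threshold: float = 0.1,
    min_slope_uv_per_ms: float = 1.0,
) -> int:
    """Locate the QRS onset from a smoothed multi-lead slope statistic.

    The statistic is the across-lead mean absolute first difference
    (uV/ms), smoothed by a ``smooth_ms`` moving average.  The onset is the
    first sample where the statistic exceeds the baseline (its median,
    dominated by non-QRS samples) by ``rel_threshold`` of the
    baseline-to-peak excursion.  A peak below ``min_slope_uv_per_ms``, or
    one not clearly separated from the baseline, means no QRS-like
    activity and raises :class:`OnsetDetectionError` so the user can
    supply the onset manually.

    An annotated ``ecg.qrs_onset`` always wins; this detector is never
    consulted when one is present.
    """
    if ecg.qrs_onset is not None:
        return int(ecg.qrs_onset)
    data = ecg.signals[list(LEAD_ORDER)].to_numpy(dtype=float)
    if len(data) < 3:
        raise OnsetDetectionError("record too short for onset detection")
    slope = np.abs(np.diff(data, axis=0)).mean(axis=1) * ecg.sampling_rate / 1000.0
    k = max(1, int(round(smooth_ms / 1000.0 * ecg.sampling_rate)))
    stat = np.convolve(slope, np.ones(k) / k, mode="same")
    peak = float(stat.max())
    baseline = float(np.median(stat))
    if peak < min_slope_uv_per_ms or peak < 3.0 * baseline:
        raise OnsetDetectionError(
            "no QRS-like slope found; supply the onset manually"
        )
    threshold = baseline + rel_threshold * (peak - baseline)
    return int(np.argmax(stat >= threshold))


def write_ecg(ecg: ECGRecord, path: str | Path, units: str = "uV") -> None:
    """Write the delimited-text ECG format (header + TSV lead columns)."""
    scale = _UNIT_TO_UV.get(units.lower())
    if scale is None:
        raise EcgSchemaError(f"unknown units '{units}'")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# rate_hz: {ecg.sampling_rate!r}\n")
        fh.write(f"# units: {units}\n")
        if ecg.qrs_onset is not None:
            fh.write(f"# qrs_onset: {int(ecg.qrs_onset)}\n")
        (ecg.signals / scale).to_csv(fh, sep="\t", index=False)


def read_ecg(path: str | Path) -> ECGRecord:
    """Read the delimited-text ECG format; potentials normalized to uV."""
    path = Path(path)
    header: dict[str, str] = {}
    body_start = 0
    with path.open() as fh:
        lines = fh.readlines()
    for ln in lines:
        if not ln.startswith("#"):
            break
        body_start += 1
        if ":" in ln:
            key, val = ln.lstrip("#").split(":", 1)
            header[key.strip().lower()] = val.strip()
    if "rate_hz" not in header:
        raise EcgSchemaError(f"{path}: header missing 'rate_hz'")
    if "units" not in header:
        raise EcgSchemaError(f"{path}: header missing 'units'")
    scale = _UNIT_TO_UV.get(header["units"].lower())
    if scale is None:
        raise EcgSchemaError(f"{path}: unknown units '{header['units']}'")
    from io import StringIO

    table = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    onset = header.get("qrs_onset")
    return ECGRecord(
        signals=table * scale,
        sampling_rate=float(header["rate_hz"]),
        qrs_onset=int(onset) if onset is not None else None,
    )
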