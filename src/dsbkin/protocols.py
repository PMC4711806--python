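"""Exposure protocols and measurement datasets.

An exposure protocol is an ordered list of piecewise-constant dose-rate
segments (dose rate in Gy/h, duration in h).  A zero dose rate encodes a
rest interval during which rejoining proceeds without further DSB
induction.  The measurement clock starts at the end of the last segment:
``measurement_time`` is the rejoining time, in hours, between the end of
irradiation and the DSB assay.  A single acute dose D delivered at rate R
is one segment of duration D/R; a split exposure is irradiation, rest,
irradiation, with equal per-fraction doses.

Measurements are net radiation-induced DSBs per cell (background taken as
zero) and carry a radiation-class label that determines which joint fit
the row enters: all sparsely-ionizing exposures (high-dose-rate single and
split doses, low-dose-rate single doses) are pooled into one fit, while
densely-ionizing (alpha-particle) data are fitted separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "SPARSELY_IONIZING",
    "DENSELY_IONIZING",
    "ExposureSegment",
    "ExposureProtocol",
    "Measurement",
    "Dataset",
    "read_dataset",
    "write_dataset",
    "expand_mean_se",
    "expand_mean_range",
]

SPARSELY_IONIZING = "sparsely_ionizing"
DENSELY_IONIZING = "densely_ionizing"
_RADIATION_CLASSES = (SPARSELY_IONIZING, DENSELY_IONIZING)

#: Columns of the delimited dataset format (UTF-8, comma-separated, one
#: header row, dot decimal separator).  ``split_interval_h`` is blank for
#: single-dose rows; ``dose_Gy`` is the per-fraction dose for split rows.
DATASET_COLUMNS = [
    "radiation_class",
    "protocol_type",
    "dose_Gy",
    "dose_rate_Gy_per_h",
    "split_interval_h",
    "rejoin_time_h",
    "dsb_per_cell",
]


@dataclass(frozen=True)
class ExposureSegment:
    """One piecewise-constant exposure segment.

    Parameters
    ----------
    dose_rate : float
        Dose rate in Gy/h; 0 encodes a rest (rejoining-only) interval.
    duration : float
        Segment length in hours, > 0.
    dose : float, optional
        Dose delivered by the segment (Gy).  Defaults to
        ``dose_rate * duration``; passing it explicitly keeps the stated
        dose exact across table round trips (duration is the derived
        quantity when a segment comes from a dose/dose-rate pair).
    """

    dose_rate: float
    duration: float
    dose: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dose_rate) and self.dose_rate >= 0):
            raise ValidationError(f"dose_rate must be finite and >= 0, got {self.dose_rate}")
        if not (math.isfinite(self.duration) and self.duration > 0):
            raise ValidationError(f"duration must be finite and > 0, got {self.duration}")
        if self.dose is None:
            object.__setattr__(self, "dose", self.dose_rate * self.duration)
        implied = self.dose_rate * self.duration
        if not math.isclose(self.dose, implied, rel_tol=1e-9, abs_tol=1e-12):
            raise ValidationError(
                f"segment dose {self.dose} inconsistent with dose_rate*duration = {implied}"
            )


@dataclass(frozen=True)
class ExposureProtocol:
    """Ordered exposure segments plus the rejoining time before assay.

    ``measurement_time`` is counted from the end of the last segment
    (0 means "immediately after the end of irradiation").
    """

    segments: tuple[ExposureSegment, ...]
    measurement_time: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not (math.isfinite(self.measurement_time) and self.measurement_time >= 0):
            raise ValidationError(
                f"measurement_time must be finite and >= 0, got {self.measurement_time}"
            )

    @property
    def total_dose(self) -> float:
        """Total dose across all segments (Gy)."""
        return float(sum(s.dose for s in self.segments))

    @property
    def irradiation_segments(self) -> tuple[ExposureSegment, ...]:
        return tuple(s for s in self.segments if s.dose_rate > 0)

    @classmethod
    def single_dose(cls, dose: float, dose_rate: float, rejoin_time: float) -> "ExposureProtocol":
        """Acute/protracted single exposure of `dose` Gy at `dose_rate` Gy/h."""
        if dose < 0 or dose_rate <= 0:
            raise ValidationError("single_dose requires dose >= 0 and dose_rate > 0")
        segments = (
            () if dose == 0 else (ExposureSegment(dose_rate, dose / dose_rate, dose),)
        )
        return cls(segments, rejoin_time)

    @classmethod
    def split_dose(
        cls,
        dose_per_fraction: float,
        dose_rate: float,
        interval: float,
        rejoin_time: float,
    ) -> "ExposureProtocol":
        """Two equal fractions separated by a rest interval.

        The rejoining time is counted after the second fraction; rejoining
        proceeds during the inter-fraction rest (a zero-dose-rate segment).
        """
        if dose_per_fraction <= 0 or dose_rate <= 0 or interval <= 0:
            raise ValidationError("split_dose requires positive dose, dose_rate and interval")
        irr = ExposureSegment(dose_rate, dose_per_fraction / dose_rate, dose_per_fraction)
        rest = ExposureSegment(0.0, interval)
        return cls((irr, rest, irr), rejoin_time)


@dataclass(frozen=True)
class Measurement:
    """One observed data point: a protocol and the DSBs/cell it produced."""

    radiation_class: str
    protocol: ExposureProtocol
    observed_dsb: float
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.radiation_class not in _RADIATION_CLASSES:
            raise ValidationError(
                f"radiation_class must be one of {_RADIATION_CLASSES}, got {self.radiation_class!r}"
            )
        if not math.isfinite(self.observed_dsb) or self.observed_dsb < 0:
            raise ValidationError(f"observed_dsb must be finite and >= 0, got {self.observed_dsb}")


@dataclass
class Dataset:
    """A list of measurements, grouped by radiation class for joint fits."""

    measurements: list[Measurement] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    @property
    def n_points(self) -> dict[str, int]:
        counts = {c: 0 for c in _RADIATION_CLASSES}
        for m in self.measurements:
            counts[m.radiation_class] += 1
        return counts

    def subset(self, radiation_class: str) -> "Dataset":
        if radiation_class not in _RADIATION_CLASSES:
            raise ValidationError(f"unknown radiation class {radiation_class!r}")
        return Dataset([m for m in self.measurements if m.radiation_class == radiation_class])

    @property
    def observations(self) -> np.ndarray:
        return np.array([m.observed_dsb for m in self.measurements], dtype=float)


def _protocol_to_row(m: Measurement) -> dict:
    p = m.protocol
    segs = p.segments
    if len(segs) == 0:
        row = {"protocol_type": "single", "dose_Gy": 0.0, "dose_rate_Gy_per_h": 1.0,
               "split_interval_h": None}
    elif len(segs) == 1 and segs[0].dose_rate > 0:
        row = {"protocol_type": "single", "dose_Gy": segs[0].dose,
               "dose_rate_Gy_per_h": segs[0].dose_rate, "split_interval_h": None}
    elif (
        len(segs) == 3
        and segs[0].dose_rate > 0
        and segs[1].dose_rate == 0
        and segs[2] == segs[0]
    ):
        row = {"protocol_type": "split", "dose_Gy": segs[0].dose,
               "dose_rate_Gy_per_h": segs[0].dose_rate,
               "split_interval_h": segs[1].duration}
    else:
        raise FormatError("protocol cannot be expressed in the single/split table format")
    row["radiation_class"] = m.radiation_class
    row["rejoin_time_h"] = p.measurement_time
    row["dsb_per_cell"] = m.observed_dsb
    row["source_tag"] = m.source_tag
    return row


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset as a comma-separated table (see ``DATASET_COLUMNS``)."""
    rows = [_protocol_to_row(m) for m in dataset.measurements]
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS + ["source_tag"])
    # repr keeps the shortest decimal that round-trips the binary float
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)), na_rep="")


def read_dataset(path, dialect: str = "csv") -> Dataset:
    """Read a dataset from a delimited table.

    Single-dose rows become one-segment protocols of duration
    dose/dose-rate; split rows (``dose_Gy`` = per-fraction dose) expand to
    irradiation / rest / irradiation with equal fractions.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise FormatError(f"unknown table dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file without header") from exc
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    measurements = []
    for idx, row in df.iterrows():
        label = f"{path} row {idx + 2}"  # 1-based, counting the header line
        dose = float(row["dose_Gy"])
        rate = float(row["dose_rate_Gy_per_h"])
        t = float(row["rejoin_time_h"])
        obs = float(row["dsb_per_cell"])
        for name, value in [("dose_Gy", dose), ("dose_rate_Gy_per_h", rate),
                            ("rejoin_time_h", t), ("dsb_per_cell", obs)]:
            if not math.isfinite(value) or value < 0:
                raise ValidationError(f"{label}: {name} must be finite and >= 0, got {value}")
        ptype = str(row["protocol_type"]).strip()
        try:
            if ptype == "single":
                protocol = ExposureProtocol.single_dose(dose, rate, t)
            elif ptype == "split":
                interval = float(row["split_interval_h"])
                if not math.isfinite(interval) or interval <= 0:
                    raise ValidationError(
                        f"{label}: split rows need a positive split_interval_h, got {interval}"
                    )
                protocol = ExposureProtocol.split_dose(dose, rate, interval, t)
            else:
                raise FormatError(f"{label}: protocol_type must be 'single' or 'split', got {ptype!r}")
        except ValidationError as exc:
            raise ValidationError(f"{label}: {exc}") from exc
        tag = row.get("source_tag", "")
        tag = "" if pd.isna(tag) else str(tag)
        measurements.append(
            Measurement(str(row["radiation_class"]).strip(), protocol, obs, tag)
        )
    return Dataset(measurements)


def expand_mean_se(mean: float, se: float) -> tuple[float, float, float]:
    """Reconstruct three pseudo-replicates from a reported mean and SE.

    Returns ``(mean - d, mean, mean + d)`` with ``d`` chosen so the sample
    mean of the triple equals ``mean`` and its sample standard error
    (sd/sqrt(3), sd with the n-1 convention) equals ``se``.  For a
    symmetric triple the sample sd equals ``d``, hence ``d = se*sqrt(3)``.
    """
    if not math.isfinite(mean):
        raise ValidationError(f"mean must be finite, got {mean}")
    if not (math.isfinite(se) and se >= 0):
        raise ValidationError(f"se must be finite and >= 0, got {se}")
    d = se * math.sqrt(3.0)
    return (mean - d, mean, mean + d)


def expand_mean_range(mean: float, low: float, high: float) -> tuple[float, float, float]:
    """Reconstruct three pseudo-replicates from a reported mean and range.

    The published summaries sometimes give a range rather than an SE.  The
    half-width d = (high-low)/2 is used as the symmetric offset, so the
    triple is ``(mean-d, mean, mean+d)``: its sample mean is exactly
    ``mean`` and its extremes match the reported range width (they bracket
    the mean even when the printed range is slightly asymmetric about it).
    """
    if high < low:
        raise ValidationError(f"range high < low: ({low}, {high})")
    if not (low <= mean <= high):
        raise ValidationError(f"mean {mean} outside reported range ({low}, {high})")
    d = 0.5 * (high - low)
    return (mean - d, mean, mean + d)
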