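"""Reading and writing SisFall-dialect trial files.

The SisFall corpus stores each trial as a plain-text file, one sample per
line, comma-separated integer ADC readings, with an optional trailing
semicolon.  A raw file carries nine channels: a wide-range accelerometer
(ADXL345, ±16 g, 13 bit), a gyroscope (ITG3200, ±2000 °/s, 16 bit) and a
second, narrow-range accelerometer (MMA8451Q, ±8 g, 14 bit).  File names
encode activity, subject and trial: ``F01_SA01_R01.txt``.

Raw integers are converted to physical units (g, °/s) with the linear map

    physical = raw * 2 * range / 2**resolution_bits

so a reading of ``2**(bits-1)`` equals the sensor's full-scale value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import AnnotationError, ConfigError, MetadataError, ParseError

__all__ = [
    "SensorSpec",
    "RecordingTrial",
    "SISFALL_SCHEMA",
    "SIM_SCHEMA",
    "DEFAULT_CHANNELS",
    "read_trial",
    "write_trial",
    "select_channels",
    "parse_filename",
    "trial_filename",
    "read_annotations",
    "write_annotations",
]

_FILENAME_RE = re.compile(
    r"^(?P<act>[A-Za-z]\d{2})_(?P<subj>S[AE]\d{2})_R(?P<trial>\d{2,3})$"
)


@dataclass(frozen=True)
class SensorSpec:
    """One tri-axial sensor: full-scale range and ADC resolution."""

    name: str
    range: float  # full scale, in g or °/s
    resolution_bits: int
    axes: int = 3

    def __post_init__(self) -> None:
        if self.range <= 0:
            raise ConfigError(f"sensor {self.name!r}: range must be > 0")
        if not 8 <= self.resolution_bits <= 16:
            raise ConfigError(
                f"sensor {self.name!r}: resolution_bits must be in 8..16"
            )

    @property
    def scale(self) -> float:
        """Physical units per ADC count."""
        return 2.0 * self.range / float(2 ** self.resolution_bits)


#: The sensor layout of real SisFall raw files (9 channels).
SISFALL_SCHEMA: tuple[SensorSpec, ...] = (
    SensorSpec("ADXL345", range=16.0, resolution_bits=13),
    SensorSpec("ITG3200", range=2000.0, resolution_bits=16),
    SensorSpec("MMA8451Q", range=8.0, resolution_bits=14),
)

#: Simulator output layout: one accelerometer + one gyroscope (6 channels).
SIM_SCHEMA: tuple[SensorSpec, ...] = (
    SensorSpec("ADXL345", range=16.0, resolution_bits=13),
    SensorSpec("ITG3200", range=2000.0, resolution_bits=16),
)

#: Wide-range accelerometer + gyroscope out of a 9-channel SisFall file.
DEFAULT_CHANNELS: tuple[int, ...] = (0, 1, 2, 3, 4, 5)


@dataclass
class RecordingTrial:
    """A multichannel inertial recording with its subject/activity metadata.

    ``samples`` is a [T × C] float array in physical units: g for
    accelerometer channels, °/s for gyroscope channels.
    """

    samples: np.ndarray
    rate_hz: float = 200.0
    subject_id: str = ""
    subject_group: str = "young"  # {"young", "elderly"}
    activity_code: str = ""
    trial_index: int = 0
    is_fall_activity: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ConfigError("trial samples must be a [T x C] matrix")
        if self.rate_hz <= 0:
            raise ConfigError("rate_hz must be > 0")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


def parse_filename(path: str | Path) -> dict:
    """Extract activity/subject/trial metadata from a SisFall-style name."""
    stem = Path(path).stem
    m = _FILENAME_RE.match(stem)
    if m is None:
        raise MetadataError(
            f"filename {stem!r} does not match '<ACT>_<SUBJ>_R<trial>'"
        )
    subj = m.group("subj")
    act = m.group("act")
    return {
        "activity_code": act,
        "subject_id": subj,
        "subject_group": "elderly" if subj.startswith("SE") else "young",
        "trial_index": int(m.group("trial")),
        "is_fall_activity": act[0].upper() == "F",
    }


def trial_filename(trial: RecordingTrial) -> str:
    return f"{trial.activity_code}_{trial.subject_id}_R{trial.trial_index:02d}.txt"


def _channel_scales(schema: Sequence[SensorSpec]) -> np.ndarray:
    return np.concatenate([[s.scale] * s.axes for s in schema])


def read_trial(
    path: str | Path, schema: Sequence[SensorSpec] = SISFALL_SCHEMA, rate_hz: float = 200.0
) -> RecordingTrial:
    """Read one trial file, converting raw ADC integers to physical units."""
    path = Path(path)
    meta = parse_filename(path)
    scales = _channel_scales(schema)
    n_chan = scales.size
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip().rstrip(";").strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split(",")]
            if len(fields) != n_chan:
                raise ParseError(
                    f"{path.name}:{lineno}: expected {n_chan} channels, "
                    f"got {len(fields)}"
                )
            try:
                rows.append([int(f) for f in fields])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
    raw = np.asarray(rows, dtype=np.float64).reshape(len(rows), n_chan)
    return RecordingTrial(samples=raw * scales, rate_hz=rate_hz, **meta)


def write_trial(
    trial: RecordingTrial, path: str | Path, schema: Sequence[SensorSpec] = SISFALL_SCHEMA
) -> Path:
    """Write a trial in the SisFall dialect, quantizing to ADC integers."""
    scales = _channel_scales(schema)
    if trial.n_channels != scales.size:
        raise ConfigError(
            f"trial has {trial.n_channels} channels but schema implies {scales.size}"
        )
    raw = np.rint(trial.samples / scales).astype(np.int64)
    path = Path(path)
    with open(path, "w") as fh:
        for row in raw:
            fh.write(",".join(str(int(v)) for v in row) + ";\n")
    return path


def select_channels(trial: RecordingTrial, channel_spec: Sequence[int]) -> RecordingTrial:
    """Return a trial restricted to the given channel indices, in order."""
    spec = list(channel_spec)
    if len(set(spec)) != len(spec):
        raise ConfigError(f"duplicate channel index in {spec}")
    for i in spec:
        if not 0 <= i < trial.n_channels:
            raise ConfigError(
                f"channel index {i} out of range for {trial.n_channels} channels"
            )
    return replace(trial, samples=trial.samples[:, spec].copy())


# ---------------------------------------------------------------------------
# Annotation sidecar: one CSV row per trial.

def read_annotations(path: str | Path) -> dict[str, tuple[int, int, int]]:
    """Read the annotation CSV mapping trial id -> (pre_start, pre_end, fall_end)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"trial_id", "pre_impact_start", "pre_impact_end", "fall_end"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"annotation file missing columns: {sorted(missing)}")
    return {
        str(r.trial_id): (int(r.pre_impact_start), int(r.pre_impact_end), int(r.fall_end))
        for r in df.itertuples()
    }


def write_annotations(
    rows: dict[str, tuple[int, int, int]], path: str | Path
) -> Path:
    import pandas as pd

    df = pd.DataFrame(
        [(k, *v) for k, v in sorted(rows.items())],
        columns=["trial_id", "pre_impact_start", "pre_impact_end", "fall_end"],
    )
    df.to_csv(path, index=False)
    return Path(path)
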