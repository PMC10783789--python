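"""Session data model and on-disk formats.

A recording session pairs a calcium-trace matrix (neurons x frames, 20 Hz,
z-scored fluorescence) with frame-aligned behavior annotations: the context
(homecage baseline vs tail suspension), the manually labeled coping style
during suspension (struggle / immobility / ambiguous), and per-body-part
speed traces.  Sessions are stored as HDF5 with a fixed layout; cross-day
neuron registration is a plain CSV mapping global neuron identities to
per-day trace rows (-1 = not detected that day).

Conventions: frames are 0-based, windows are half-open ``[start, end)`` in
frames, and seconds-to-frames conversion rounds to the nearest integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

# context codes
BASELINE, TS = 0, 1
# coping codes
IMMOBILITY, STRUGGLE, AMBIGUOUS, NOT_APPLICABLE = 0, 1, 2, 3

_CONTEXT_NAMES = {"baseline": BASELINE, "TS": TS}
_COPING_NAMES = {
    "immobility": IMMOBILITY,
    "struggle": STRUGGLE,
    "ambiguous": AMBIGUOUS,
    "not_applicable": NOT_APPLICABLE,
}


class FormatError(ValueError):
    """On-disk layout does not match the expected session format."""


class InvariantError(ValueError):
    """In-memory object violates a data-model invariant."""


@dataclass
class BehaviorTrack:
    """Per-frame behavior annotations for one session.

    ``context`` is 0 (baseline) / 1 (TS); ``coping`` uses the module-level
    codes and is ``NOT_APPLICABLE`` exactly on baseline frames.  Speeds are
    non-negative, in arbitrary but consistent units (cm/s in the generator).
    """

    frame_rate: float
    context: np.ndarray
    coping: np.ndarray
    speed_parts: dict[str, np.ndarray]
    speed_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.context = np.asarray(self.context, dtype=np.int8)
        self.coping = np.asarray(self.coping, dtype=np.int8)
        self.speed_parts = {k: np.asarray(v, dtype=np.float64) for k, v in self.speed_parts.items()}
        if self.speed_mean is None:
            if self.speed_parts:
                self.speed_mean = np.mean(list(self.speed_parts.values()), axis=0)
            else:
                raise InvariantError("need speed_parts or speed_mean")
        self.speed_mean = np.asarray(self.speed_mean, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        n = len(self.context)
        arrays = [self.coping, self.speed_mean, *self.speed_parts.values()]
        if any(len(a) != n for a in arrays):
            raise InvariantError("per-frame arrays have unequal lengths")
        if self.frame_rate <= 0:
            raise InvariantError("frame_rate must be positive")
        base = self.context == BASELINE
        if not np.all((self.coping == NOT_APPLICABLE) == base):
            raise InvariantError("coping must be not_applicable exactly on baseline frames")
        for name, sp in [("speed_mean", self.speed_mean), *self.speed_parts.items()]:
            if not np.all(np.isfinite(sp)) or np.any(sp < 0):
                raise InvariantError(f"speed trace {name!r} must be finite and >= 0")

    @property
    def n_frames(self) -> int:
        return len(self.context)

    def frames_of_context(self, context: int | str) -> np.ndarray:
        code = _CONTEXT_NAMES.get(context, context)
        return np.flatnonzero(self.context == code)

    def frames_of_coping(self, coping: int | str) -> np.ndarray:
        code = _COPING_NAMES.get(coping, coping)
        return np.flatnonzero(self.coping == code)


@dataclass
class CalciumTraces:
    """Z-scored fluorescence (neurons x frames) with a transient mask."""

    values: np.ndarray
    neuron_ids: np.ndarray
    transients: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.transients = np.asarray(self.transients, dtype=bool)
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise InvariantError("values must be 2-d (neurons x frames)")
        if not np.all(np.isfinite(self.values)):
            raise InvariantError("trace values must be finite")
        if self.transients.shape != self.values.shape:
            raise InvariantError("transients shape must equal values shape")
        if len(self.neuron_ids) != self.values.shape[0]:
            raise InvariantError("one neuron_id per trace row required")
        if len(np.unique(self.neuron_ids)) != len(self.neuron_ids):
            raise InvariantError("neuron_ids must be unique")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class SessionRecording:
    """One animal-day: calcium traces plus behavior, frame-aligned."""

    animal_id: str
    day: int
    calcium: CalciumTraces
    behavior: BehaviorTrack
    speed_units: str = "cm/s"

    def __post_init__(self) -> None:
        if self.day < 1:
            raise InvariantError("day must be >= 1")
        if self.calcium.n_frames != self.behavior.n_frames:
            raise InvariantError(
                f"calcium ({self.calcium.n_frames}) and behavior "
                f"({self.behavior.n_frames}) frame counts differ"
            )


@dataclass
class RegistrationMap:
    """Global neuron identities mapped to per-day local trace rows.

    Stored as a DataFrame indexed by ``global_id`` with one integer column per
    day (``day1``, ``day3``, ...); -1 denotes "not detected on this day".
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.astype(np.int64)
        self.validate()

    def validate(self) -> None:
        if self.table.index.has_duplicates:
            raise InvariantError("global_ids must be unique")
        for col in self.table.columns:
            present = self.table[col][self.table[col] >= 0]
            if present.duplicated().any():
                raise InvariantError(f"duplicate local row index in column {col!r}")

    @property
    def days(self) -> list[int]:
        return [int(c.removeprefix("day")) for c in self.table.columns]

    def column(self, day: int) -> pd.Series:
        name = f"day{day}"
        if name not in self.table.columns:
            raise KeyError(f"unknown day {day}; have {self.days}")
        return self.table[name]

    def local_rows(self, day: int, global_ids: Sequence[int]) -> np.ndarray:
        """Trace-row indices of ``global_ids`` on ``day`` (all must be present)."""
        col = self.column(day).loc[list(global_ids)].to_numpy()
        if np.any(col < 0):
            raise InvariantError("requested neuron absent on day")
        return col


def repeatedly_identified(regmap: RegistrationMap, days: Iterable[int]) -> list[int]:
    """Global ids of neurons detected on *all* requested days, ascending.

    In the study roughly 40% of cells were active on all three imaging days;
    this subpopulation carries every across-day single-neuron analysis.
    """
    days = list(days)
    if not days:
        raise ValueError("days must be non-empty")
    mask = np.ones(len(regmap.table), dtype=bool)
    for d in days:
        mask &= regmap.column(d).to_numpy() >= 0
    return sorted(int(g) for g in regmap.table.index[mask])


# ---------------------------------------------------------------------------
# on-disk formats


def write_session(session: SessionRecording, path: str | Path, *,
                  force: bool = False, compression: str | None = "gzip") -> Path:
    """Write a session to HDF5.  Refuses to overwrite unless ``force``."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    with h5py.File(path, "w") as f:
        cal = f.create_group("calcium")
        cal.create_dataset("values", data=session.calcium.values.astype(np.float32),
                           compression=compression)
        cal.create_dataset("transients", data=session.calcium.transients.astype(np.uint8),
                           compression=compression)
        cal.create_dataset("neuron_ids", data=session.calcium.neuron_ids)
        beh = f.create_group("behavior")
        beh.create_dataset("context", data=session.behavior.context)
        beh.create_dataset("coping", data=session.behavior.coping)
        beh.create_dataset("speed_mean", data=session.behavior.speed_mean.astype(np.float32))
        spd = beh.create_group("speed")
        for part, trace in session.behavior.speed_parts.items():
            spd.create_dataset(part, data=trace.astype(np.float32))
        f.attrs["animal_id"] = session.animal_id
        f.attrs["day"] = session.day
        f.attrs["frame_rate_hz"] = session.behavior.frame_rate
        f.attrs["speed_units"] = session.speed_units
    return path


def _require(f: h5py.File, name: str) -> h5py.Dataset:
    if name not in f:
        raise FormatError(f"missing required dataset {name!r}")
    return f[name]


def read_session(path: str | Path) -> SessionRecording:
    """Read a session HDF5 file written by :func:`write_session`."""
    with h5py.File(path, "r") as f:
        values = _require(f, "/calcium/values")[()]
        transients = _require(f, "/calcium/transients")[()].astype(bool)
        neuron_ids = _require(f, "/calcium/neuron_ids")[()]
        context = _require(f, "/behavior/context")[()]
        coping = _require(f, "/behavior/coping")[()]
        speed_mean = _require(f, "/behavior/speed_mean")[()]
        parts = {}
        if "/behavior/speed" in f:
            for part in f["/behavior/speed"]:
                parts[part] = f["/behavior/speed"][part][()]
        attrs = dict(f.attrs)
    frame_rate = float(attrs.get("frame_rate_hz", 20.0))
    behavior = BehaviorTrack(frame_rate=frame_rate, context=context, coping=coping,
                             speed_parts=parts, speed_mean=speed_mean)
    calcium = CalciumTraces(values=values, neuron_ids=neuron_ids,
                            transients=transients, frame_rate=frame_rate)
    return SessionRecording(
        animal_id=str(attrs.get("animal_id", "unknown")),
        day=int(attrs.get("day", 1)),
        calcium=calcium,
        behavior=behavior,
        speed_units=str(attrs.get("speed_units", "cm/s")),
    )


def write_registration(regmap: RegistrationMap, path: str | Path) -> Path:
    path = Path(path)
    df = regmap.table.copy()
    df.index.name = "global_id"
    df.to_csv(path)
    return path


def read_registration(path: str | Path) -> RegistrationMap:
    df = pd.read_csv(path, index_col="global_id")
    bad = [c for c in df.columns if not c.startswith("day")]
    if bad:
        raise FormatError(f"unexpected registration columns: {bad}")
    return RegistrationMap(df)
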