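"""Shared data model and bundle I/O for patch-clamp sweep collections.

Canonical units throughout the package: voltage in mV, current in pA,
time in ms, capacitance in pF, resistance in MOhm, charge in pA*ms.
A sweep is a uniformly sampled trace; a cell record groups sweeps by
acquisition protocol.  Bundles are stored as a directory holding one JSON
metadata document plus one CSV matrix per protocol group (rows = samples,
columns = sweeps), which keeps them diffable and language-neutral.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Sweep",
    "ProtocolEpoch",
    "CellRecord",
    "FeatureTable",
    "FormatError",
    "UnitError",
    "ProtocolError",
    "PROTOCOL_GROUPS",
    "read_cell_bundle",
    "write_cell_bundle",
    "write_feature_table",
    "read_feature_table",
    "ingest_nwb",
    "export_nwb",
]

#: default sampling interval, ms (10 kHz acquisition)
DEFAULT_DT = 0.1

#: recognised protocol groups and the units their sweeps must carry
PROTOCOL_GROUPS: dict[str, str] = {
    "step_family": "mV",          # current-clamp depolarising step family
    "step_family_retest": "mV",   # step family repeated from depolarised holding
    "passive_neg5mV": "pA",       # -5 mV seal-test family (voltage clamp)
    "passive_60s": "mV",          # long passive current-clamp recording
    "subthreshold_VC": "pA",      # voltage-clamp subthreshold protocol (test sweeps)
    "subthreshold_VC_leak": "pA", # scaled P/N leak subsweeps
    "sepsc_VC": "pA",             # continuous sEPSC voltage-clamp recording
}


class FormatError(ValueError):
    """A bundle or file does not follow the documented layout."""


class UnitError(ValueError):
    """A sweep carries units inconsistent with the requested operation."""


class ProtocolError(ValueError):
    """Protocol annotation is missing or inconsistent with the operation."""


@dataclass
class ProtocolEpoch:
    """A command epoch: holding or step, with its level (pA in CC, mV in VC)."""

    start_ms: float
    duration_ms: float
    command_level: float
    kind: str = "step"  # {"holding", "step"}

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("epoch duration must be positive")
        if self.kind not in ("holding", "step"):
            raise ValueError(f"unknown epoch kind {self.kind!r}")

    @property
    def end_ms(self) -> float:
        return self.start_ms + self.duration_ms

    def to_dict(self) -> dict:
        return {
            "start_ms": self.start_ms,
            "duration_ms": self.duration_ms,
            "command_level": self.command_level,
            "kind": self.kind,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolEpoch":
        return cls(**d)


@dataclass
class Sweep:
    """A uniformly sampled trace.

    Parameters
    ----------
    samples
        Measured values: mV for current clamp, pA for voltage clamp.
    dt
        Sampling interval in ms (> 0); default 0.1 ms (10 kHz).
    units
        ``"mV"`` or ``"pA"``.
    epochs
        Ordered, non-overlapping command epochs within the sweep.
    """

    samples: np.ndarray
    dt: float = DEFAULT_DT
    units: str = "mV"
    epochs: list[ProtocolEpoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.units not in ("mV", "pA"):
            raise UnitError(f"unsupported units {self.units!r}")
        end = self.duration_ms + 1e-9
        prev_end = -np.inf
        for ep in self.epochs:
            if ep.start_ms < prev_end - 1e-9 or ep.end_ms > end:
                raise ProtocolError("epochs must be ordered, non-overlapping and within the sweep")
            prev_end = ep.end_ms

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        return self.samples.size * self.dt

    def time(self) -> np.ndarray:
        """Sample times in ms, starting at 0."""
        return np.arange(self.samples.size) * self.dt

    def step_epoch(self) -> ProtocolEpoch:
        """Return the first epoch of kind 'step'."""
        for ep in self.epochs:
            if ep.kind == "step":
                return ep
        raise ProtocolError("sweep has no step epoch")

    def slice_ms(self, t0: float, t1: float) -> np.ndarray:
        """Samples in the half-open window [t0, t1) ms."""
        i0 = max(0, int(round(t0 / self.dt)))
        i1 = min(self.samples.size, int(round(t1 / self.dt)))
        return self.samples[i0:i1]


def require_units(sweep: Sweep, units: str) -> None:
    if sweep.units != units:
        raise UnitError(f"operation requires a {units} sweep, got {sweep.units}")


@dataclass
class CellRecord:
    """All sweeps and metadata for one recorded neuron."""

    cell_id: str
    identity: str = "UN"          # {"SPBN", "UN"}
    lamina: str = "LI"            # {"LI", "LIII_V"}
    slice_plane: str = "transverse"
    bias_current_pA: float = 0.0
    sweeps: dict[str, list[Sweep]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.identity not in ("SPBN", "UN"):
            raise ValueError(f"unknown identity {self.identity!r}")
        if self.lamina not in ("LI", "LIII_V"):
            raise ValueError(f"unknown lamina {self.lamina!r}")
        if self.slice_plane not in ("transverse", "sagittal"):
            raise ValueError(f"unknown slice plane {self.slice_plane!r}")
        if abs(self.bias_current_pA) > 20.0:
            raise ValueError("bias current outside the +/-20 pA acquisition bound")
        for group, sweeps in self.sweeps.items():
            self._check_group(group, sweeps)

    @staticmethod
    def _check_group(group: str, sweeps: list[Sweep]) -> None:
        if group not in PROTOCOL_GROUPS:
            raise FormatError(
                f"unknown protocol group {group!r}; known: {sorted(PROTOCOL_GROUPS)}"
            )
        units = PROTOCOL_GROUPS[group]
        for sw in sweeps:
            if sw.units != units:
                raise UnitError(f"group {group!r} requires {units} sweeps")
        if sweeps and len({sw.dt for sw in sweeps}) != 1:
            raise ValueError(f"group {group!r} mixes sampling intervals")

    def add_sweeps(self, group: str, sweeps: list[Sweep]) -> None:
        self._check_group(group, sweeps)
        self.sweeps.setdefault(group, []).extend(sweeps)

    def require_group(self, group: str) -> list[Sweep]:
        if group not in self.sweeps or not self.sweeps[group]:
            raise ProtocolError(f"cell {self.cell_id!r} has no {group!r} sweeps")
        return self.sweeps[group]


@dataclass
class FeatureTable:
    """Per-cell feature matrix with a missingness mask (True = missing)."""

    cell_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n, m = len(self.cell_ids), len(self.feature_names)
        if self.values.shape != (n, m):
            raise ValueError("values shape must be (n_cells, n_features)")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (n, m):
            raise ValueError("mask shape must match values")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell_ids")


# ---------------------------------------------------------------------------
# bundle I/O

_FLOAT_FMT = "%.17g"  # round-trips IEEE-754 doubles exactly through text


def write_cell_bundle(record: CellRecord, path: str | Path) -> Path:
    """Write a cell record as a bundle directory (metadata.json + CSVs)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta: dict = {
        "cell_id": record.cell_id,
        "identity": record.identity,
        "lamina": record.lamina,
        "slice_plane": record.slice_plane,
        "bias_current_pA": record.bias_current_pA,
        "groups": {},
    }
    for group, sweeps in record.sweeps.items():
        if not sweeps:
            continue
        meta["groups"][group] = {
            "units": sweeps[0].units,
            "dt": sweeps[0].dt,
            "n_sweeps": len(sweeps),
            "epochs": [[ep.to_dict() for ep in sw.epochs] for sw in sweeps],
        }
        lengths = {sw.n_samples for sw in sweeps}
        if len(lengths) != 1:
            raise FormatError(f"group {group!r} sweeps differ in length; cannot form a matrix")
        mat = np.column_stack([sw.samples for sw in sweeps])
        header = ",".join(f"sweep_{i}" for i in range(len(sweeps)))
        np.savetxt(path / f"{group}.csv", mat, fmt=_FLOAT_FMT, delimiter=",",
                   header=header, comments="")
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))
    return path


def read_cell_bundle(path: str | Path) -> CellRecord:
    """Read and validate a bundle directory written by :func:`write_cell_bundle`."""
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.is_file():
        raise FormatError(f"bundle {path} lacks metadata.json")
    meta = json.loads(meta_path.read_text())
    for key in ("cell_id", "groups"):
        if key not in meta:
            raise FormatError(f"metadata lacks required field {key!r}")
    record = CellRecord(
        cell_id=meta["cell_id"],
        identity=meta.get("identity", "UN"),
        lamina=meta.get("lamina", "LI"),
        slice_plane=meta.get("slice_plane", "transverse"),
        bias_current_pA=meta.get("bias_current_pA", 0.0),
    )
    for group, ginfo in meta["groups"].items():
        for key in ("units", "dt", "n_sweeps"):
            if key not in ginfo:
                raise FormatError(f"group {group!r} metadata lacks {key!r}")
        mat = np.loadtxt(path / f"{group}.csv", delimiter=",", skiprows=1, ndmin=2)
        if mat.shape[1] != ginfo["n_sweeps"]:
            raise FormatError(f"group {group!r}: CSV column count != n_sweeps")
        epochs = ginfo.get("epochs") or [[] for _ in range(ginfo["n_sweeps"])]
        sweeps = [
            Sweep(
                samples=mat[:, i],
                dt=ginfo["dt"],
                units=ginfo["units"],
                epochs=[ProtocolEpoch.from_dict(d) for d in epochs[i]],
            )
            for i in range(ginfo["n_sweeps"])
        ]
        record.add_sweeps(group, sweeps)
    return record


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write a feature table as CSV; masked values become empty fields."""
    path = Path(path)
    lines = ["cell_id," + ",".join(table.feature_names)]
    for i, cid in enumerate(table.cell_ids):
        fields = [
            "" if table.mask[i, j] else _FLOAT_FMT % table.values[i, j]
            for j in range(len(table.feature_names))
        ]
        lines.append(cid + "," + ",".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_feature_table(path: str | Path) -> FeatureTable:
    import pandas as pd

    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    values = df.to_numpy(dtype=np.float64)
    return FeatureTable(
        cell_ids=[str(c) for c in df.index],
        feature_names=[str(c) for c in df.columns],
        values=values,
        mask=np.isnan(values),
    )


# ---------------------------------------------------------------------------
# NWB-layout HDF5 ingestion (optional convenience)
#
# Reads the subset of the NWB 2.x HDF5 layout used by intracellular ephys
# acquisitions: groups under /acquisition carrying a neurodata_type attribute
# of CurrentClampSeries / VoltageClampSeries with `data` and
# `starting_time` (rate attr) members.  export_nwb writes that same subset so
# records round-trip without a full NWB software stack.

_CLAMP_UNITS = {"CurrentClampSeries": "mV", "VoltageClampSeries": "pA"}
_UNIT_SCALE = {"volts": ("mV", 1e3), "amperes": ("pA", 1e12)}


def export_nwb(record: CellRecord, path: str | Path) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["nwb_version"] = "2.6.0"
        f.create_dataset("identifier", data=record.cell_id)
        acq = f.create_group("acquisition")
        for group, sweeps in record.sweeps.items():
            for i, sw in enumerate(sweeps):
                g = acq.create_group(f"{group}__{i:03d}")
                ntype = ("CurrentClampSeries" if sw.units == "mV"
                         else "VoltageClampSeries")
                g.attrs["neurodata_type"] = ntype
                g.attrs["protocol_group"] = group
                unit, scale = (("volts", 1e-3) if sw.units == "mV"
                               else ("amperes", 1e-12))
                d = g.create_dataset("data", data=sw.samples * scale)
                d.attrs["unit"] = unit
                st = g.create_dataset("starting_time", data=0.0)
                st.attrs["rate"] = 1000.0 / sw.dt  # Hz
                g.create_dataset(
                    "epochs_json",
                    data=json.dumps([ep.to_dict() for ep in sw.epochs]),
                )
    return path


def ingest_nwb(path: str | Path) -> CellRecord:
    """Build a :class:`CellRecord` from an NWB-layout HDF5 file.

    Series are mapped to protocol groups via their ``protocol_group``
    attribute when present, otherwise skipped with a warning.  Files that
    are not HDF5 raise an I/O error.
    """
    import h5py

    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise IOError(f"cannot read {path} as HDF5/NWB: {exc}") from exc
    with f:
        cell_id = path.stem
        if "identifier" in f:
            raw = f["identifier"][()]
            cell_id = raw.decode() if isinstance(raw, bytes) else str(raw)
        record = CellRecord(cell_id=cell_id)
        acq = f.get("acquisition")
        if acq is None or len(acq) == 0:
            warnings.warn(f"{path}: no ephys series found; returning empty record")
            return record
        staged: dict[str, list[Sweep]] = {}
        for name, g in acq.items():
            ntype = g.attrs.get("neurodata_type", "")
            if ntype not in _CLAMP_UNITS or "data" not in g:
                warnings.warn(f"{path}: skipping unmappable series {name!r}")
                continue
            group = g.attrs.get("protocol_group")
            if group is None or group not in PROTOCOL_GROUPS:
                warnings.warn(f"{path}: series {name!r} has no known protocol group; skipped")
                continue
            data = np.asarray(g["data"][()], dtype=np.float64)
            unit = g["data"].attrs.get("unit", "")
            if unit in _UNIT_SCALE:
                _, scale = _UNIT_SCALE[unit]
                data = data * scale
            rate = float(g["starting_time"].attrs.get("rate", 1000.0 / DEFAULT_DT))
            epochs = []
            if "epochs_json" in g:
                raw = g["epochs_json"][()]
                txt = raw.decode() if isinstance(raw, bytes) else str(raw)
                epochs = [ProtocolEpoch.from_dict(d) for d in json.loads(txt)]
            staged.setdefault(group, []).append(
                Sweep(data, dt=1000.0 / rate, units=_CLAMP_UNITS[ntype], epochs=epochs)
            )
        for group, sweeps in staged.items():
            record.add_sweeps(group, sweeps)
    return record
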