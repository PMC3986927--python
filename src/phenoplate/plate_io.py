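"""Reading and writing of kinetic plate data and derived tables.

Kinetic data are exchanged in a long (tidy) layout — one row per
(strain, condition, replicate, time) observation — rather than the
instrument's wide 96-well export, which is never standardised across
OmniLog software versions.  Inputs may be comma- or tab-separated
(auto-detected); all outputs are UTF-8, tab-separated, LF-terminated.

Times are hours as decimals; the usual sampling interval of 15 minutes
corresponds to a grid step of 0.25 h, which places the standard 50-h
scoring endpoint exactly on a grid point.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: canonical logical column names for kinetic input tables
KINETICS_COLUMNS = ("strain", "condition", "replicate", "time_h", "signal")

CONDITION_COLUMNS = (
    "condition_id",
    "stressor",
    "dose",
    "unit",
    "temperature_C",
    "endpoint_hours",
    "control_id",
)

STRAIN_COLUMNS = ("strain_id", "species", "origin")

KNOWN_SPECIES = frozenset(
    {
        "S. cerevisiae",
        "S. paradoxus",
        "S. kudriavzevii",
        "S. uvarum",
        "S. arboricolus",
        "S. castellii",
        "S. mikatae",
        "hybrid",
        "other",
    }
)

_REL_TOL_GRID = 1e-9  # relative tolerance for uniform time spacing


@dataclass(frozen=True)
class StrainRecord:
    """Metadata for one strain in a study."""

    strain_id: str
    species: str = "other"
    origin: str = ""

    def __post_init__(self) -> None:
        if not self.strain_id:
            raise ValidationError("strain_id must be non-empty")


@dataclass(frozen=True)
class ConditionSpec:
    """One assay condition and its link to a matched unstressed control.

    ``control_id`` is empty for control conditions themselves.  The
    scoring endpoint defaults to 50 h, except 24 h for thermal stress
    at 40 °C, where evaporation truncates the usable run.
    """

    condition_id: str
    stressor: str
    dose: float = 0.0
    unit: str = ""
    temperature_C: float = 30.0
    endpoint_hours: float = 50.0
    control_id: str = ""

    def __post_init__(self) -> None:
        if not self.condition_id:
            raise ValidationError("condition_id must be non-empty")
        if self.endpoint_hours <= 0:
            raise ValidationError(
                f"condition {self.condition_id!r}: endpoint_hours must be > 0, "
                f"got {self.endpoint_hours}"
            )

    @property
    def is_control(self) -> bool:
        return self.control_id == ""


@dataclass
class KineticSeries:
    """One well's time-resolved redox signal for a strain under a condition.

    ``times`` are hours on a strictly increasing uniform grid (default
    step 0.25 h = 15-min photographs); ``signals`` are redox intensity
    in the instrument's arbitrary units.
    """

    strain_id: str
    condition_id: str
    replicate: int | str
    times: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        label = self.label()
        if self.times.ndim != 1 or self.signals.ndim != 1:
            raise ValidationError(f"series {label}: times and signals must be 1-D")
        if self.times.size != self.signals.size:
            raise ValidationError(
                f"series {label}: times ({self.times.size}) and signals "
                f"({self.signals.size}) differ in length"
            )
        if self.times.size < 2:
            raise ValidationError(f"series {label}: need at least 2 time points")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.signals)):
            raise ValidationError(f"series {label}: non-finite values")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValidationError(f"series {label}: times must be strictly increasing")
        step = steps[0]
        if np.any(np.abs(steps - step) > _REL_TOL_GRID * max(abs(step), 1.0)):
            raise ValidationError(
                f"series {label}: non-uniform time grid (steps range "
                f"{steps.min():g}–{steps.max():g} h)"
            )

    def label(self) -> str:
        return f"({self.strain_id}, {self.condition_id}, rep {self.replicate})"

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])

    def copy_with(self, **changes) -> "KineticSeries":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# readers


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, auto-detecting comma vs tab."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")


def _require_columns(df: pd.DataFrame, required: Iterable[str], where: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{where}: missing column(s) {', '.join(missing)}")


def read_kinetics(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[KineticSeries]:
    """Read long-format kinetic data into one series per (strain, condition, replicate).

    Parameters
    ----------
    path
        Delimited text file with one observation per row.
    schema
        Optional mapping from the logical column names
        ``strain, condition, replicate, time_h, signal`` to the actual
        column names in the file.

    Returns
    -------
    list of :class:`KineticSeries`, one per distinct
    (strain, condition, replicate) triple, rows sorted by time.
    """
    mapping = {name: name for name in KINETICS_COLUMNS}
    if schema:
        mapping.update(schema)
    df = _read_table(path)
    missing = [mapping[n] for n in KINETICS_COLUMNS if mapping[n] not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    df = df.rename(columns={v: k for k, v in mapping.items()})
    df["time_h"] = df["time_h"].astype(float)
    df["signal"] = df["signal"].astype(float)

    out: list[KineticSeries] = []
    for (strain, cond, rep), grp in df.groupby(
        ["strain", "condition", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        times = grp["time_h"].to_numpy()
        if np.unique(times).size != times.size:
            raise ValidationError(
                f"series ({strain}, {cond}, rep {rep}): duplicate time rows"
            )
        rep_val: int | str
        try:
            rep_val = int(rep)
        except (TypeError, ValueError):
            rep_val = str(rep)
        out.append(
            KineticSeries(
                strain_id=str(strain),
                condition_id=str(cond),
                replicate=rep_val,
                times=times,
                signals=grp["signal"].to_numpy(),
            )
        )
    return out


def read_conditions(path: str | Path) -> list[ConditionSpec]:
    """Read and cross-validate the condition table.

    Every non-control condition must reference an existing control row
    through ``control_id``.
    """
    df = _read_table(path)
    _require_columns(df, CONDITION_COLUMNS, str(path))
    specs: list[ConditionSpec] = []
    for _, row in df.iterrows():
        control = row["control_id"]
        control = "" if (pd.isna(control) or str(control).lower() in {"", "none", "nan"}) else str(control)
        specs.append(
            ConditionSpec(
                condition_id=str(row["condition_id"]),
                stressor=str(row["stressor"]),
                dose=float(row["dose"]),
                unit="" if pd.isna(row["unit"]) else str(row["unit"]),
                temperature_C=float(row["temperature_C"]),
                endpoint_hours=float(row["endpoint_hours"]),
                control_id=control,
            )
        )
    ids = [s.condition_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate condition_id")
    known = set(ids)
    for s in specs:
        if s.control_id and s.control_id not in known:
            raise ValidationError(
                f"condition {s.condition_id!r}: control_id {s.control_id!r} "
                "does not match any condition"
            )
    return specs


def read_strains(path: str | Path) -> list[StrainRecord]:
    """Read the strain metadata table."""
    df = _read_table(path)
    _require_columns(df, STRAIN_COLUMNS, str(path))
    records = [
        StrainRecord(
            strain_id=str(row["strain_id"]),
            species=str(row["species"]),
            origin="" if pd.isna(row["origin"]) else str(row["origin"]),
        )
        for _, row in df.iterrows()
    ]
    ids = [r.strain_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate strain_id")
    return records


# ---------------------------------------------------------------------------
# writers


def _fmt(x: float) -> str:
    """Serialize a number with 6 significant digits."""
    if isinstance(x, float) and math.isnan(x):
        return ""
    return f"{x:.6g}"


def write_kinetics(series: Sequence[KineticSeries], path: str | Path) -> None:
    """Write kinetic series in the long layout read back by :func:`read_kinetics`."""
    rows = []
    for s in series:
        for t, v in zip(s.times, s.signals):
            rows.append((s.strain_id, s.condition_id, s.replicate, _fmt(t), _fmt(v)))
    df = pd.DataFrame(rows, columns=list(KINETICS_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_conditions(specs: Sequence[ConditionSpec], path: str | Path) -> None:
    rows = [
        (
            s.condition_id,
            s.stressor,
            _fmt(s.dose),
            s.unit,
            _fmt(s.temperature_C),
            _fmt(s.endpoint_hours),
            s.control_id,
        )
        for s in specs
    ]
    pd.DataFrame(rows, columns=list(CONDITION_COLUMNS)).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def write_strains(records: Sequence[StrainRecord], path: str | Path) -> None:
    rows = [(r.strain_id, r.species, r.origin) for r in records]
    pd.DataFrame(rows, columns=list(STRAIN_COLUMNS)).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def write_tolerance_table(scores, path: str | Path) -> None:
    """Write tolerance scores as TSV.

    Rows are ordered by condition, then descending %RSI, then strain id,
    so the file doubles as a per-condition ranking.  Numbers carry 6
    significant digits.
    """
    scores = list(scores)
    if not scores:
        raise ValidationError("write_tolerance_table: no scores to write")
    ordered = sorted(
        scores, key=lambda s: (s.condition_id, -s.percent_rsi, s.strain_id)
    )
    rows = [
        (
            s.strain_id,
            s.condition_id,
            _fmt(s.rsi_stress),
            _fmt(s.rsi_control),
            _fmt(s.percent_rsi),
            int(s.low_control),
        )
        for s in ordered
    ]
    pd.DataFrame(
        rows,
        columns=[
            "strain_id",
            "condition_id",
            "rsi_stress",
            "rsi_control",
            "percent_rsi",
            "low_control_flag",
        ],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tolerance_table(path: str | Path):
    """Read a tolerance table written by :func:`write_tolerance_table`."""
    from .scoring import ToleranceScore

    df = pd.read_csv(path, sep="\t")
    return [
        ToleranceScore(
            strain_id=str(row["strain_id"]),
            condition_id=str(row["condition_id"]),
            rsi_stress=float(row["rsi_stress"]),
            rsi_control=float(row["rsi_control"]),
            percent_rsi=float(row["percent_rsi"]),
            low_control=bool(row["low_control_flag"]),
        )
        for _, row in df.iterrows()
    ]


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "strain_id") -> None:
    """Write a strains × conditions matrix as TSV with 6 significant digits."""
    out = df.map(lambda v: _fmt(float(v)))
    out.to_csv(path, sep="\t", index=True, index_label=index_label, lineterminator="\n")
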