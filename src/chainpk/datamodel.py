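"""Core data types for compatibility-prescription concentration datasets.

The experimental design is an L9(3^4) orthogonal schedule over the three
herbs of the Wuji pill (coptis, evodia fructus, radix paeoniae alba): nine
mixed prescriptions at three dose levels each, plus nine single-herb
comparison prescriptions.  Dose values are treated as dimensionless levels.
Each sample pairs a prescription's herb proportions (the features) with a
blood-drug concentration time series sampled on a common 9-point grid
(the targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HERBS = ("coptis", "evodia", "peony")

COMPOUNDS = ("ber", "pal", "evo", "rut", "pae")


class SchemaError(ValueError):
    """A tabular input does not match the expected column schema."""


class ValidationError(ValueError):
    """Values violate a dataset invariant (e.g. negative concentration)."""


@dataclass(frozen=True)
class DesignRow:
    """One prescription: a label such as ``"5#"`` and three herb dose levels."""

    label: str
    coptis: float
    evodia: float
    peony: float

    def __post_init__(self) -> None:
        for herb in HERBS:
            if getattr(self, herb) < 0:
                raise ValidationError(f"dose for {herb} in {self.label!r} is negative")

    def amounts(self) -> tuple[float, float, float]:
        return (self.coptis, self.evodia, self.peony)

    def amount(self, herb: str) -> float:
        if herb not in HERBS:
            raise ValueError(f"unknown herb {herb!r}; expected one of {HERBS}")
        return float(getattr(self, herb))


@dataclass(frozen=True)
class DesignTable:
    """An ordered collection of prescriptions with unique labels."""

    rows: tuple[DesignRow, ...]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rows]
        if len(set(labels)) != len(labels):
            raise ValidationError("design labels must be unique")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.rows)

    def row(self, label: str) -> DesignRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def select(self, labels: Iterable[str]) -> "DesignTable":
        """Subset (and reorder) the table by label."""
        return DesignTable(tuple(self.row(lab) for lab in labels))

    def features(self) -> np.ndarray:
        """The m x 3 matrix of herb proportions (features x1, x2, x3)."""
        return np.array([r.amounts() for r in self.rows], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "coptis": [r.coptis for r in self.rows],
                "evodia": [r.evodia for r in self.rows],
                "peony": [r.peony for r in self.rows],
            }
        )


# The L9(3^4) test schedule of the Wuji pill study: prescriptions 1#-9# are
# the orthogonal combinations, 10#-18# single-herb comparisons.  These values
# are a fixed fixture of the package and must never change.
_DESIGN_VALUES: tuple[tuple[str, float, float, float], ...] = (
    ("1#", 0.48, 0.15, 0.23),
    ("2#", 0.48, 0.29, 0.47),
    ("3#", 0.48, 0.88, 0.93),
    ("4#", 0.96, 0.15, 0.47),
    ("5#", 0.96, 0.29, 0.93),
    ("6#", 0.96, 0.88, 0.23),
    ("7#", 1.92, 0.15, 0.93),
    ("8#", 1.92, 0.29, 0.23),
    ("9#", 1.92, 0.88, 0.47),
    ("10#", 0.48, 0.0, 0.0),
    ("11#", 0.96, 0.0, 0.0),
    ("12#", 1.92, 0.0, 0.0),
    ("13#", 0.0, 0.15, 0.0),
    ("14#", 0.0, 0.29, 0.0),
    ("15#", 0.0, 0.88, 0.0),
    ("16#", 0.0, 0.0, 0.23),
    ("17#", 0.0, 0.0, 0.47),
    ("18#", 0.0, 0.0, 0.93),
)

#: The 12 prescriptions used for simulation by default: the nine orthogonal
#: combinations plus the middle-dose single-herb comparison of each herb.
#: Which 12 groups entered the original in-vivo study is not recorded; this
#: is an overridable convention.
DEFAULT_SIMULATION_LABELS: tuple[str, ...] = (
    "1#", "2#", "3#", "4#", "5#", "6#", "7#", "8#", "9#", "11#", "14#", "17#",
)


def builtin_design() -> DesignTable:
    """The embedded 18-prescription L9(3^4) design table."""
    return DesignTable(tuple(DesignRow(*vals) for vals in _DESIGN_VALUES))


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing, positive sampling times in minutes."""

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValidationError("time grid must be a non-empty 1-D sequence")
        if np.any(t <= 0):
            raise ValidationError("all sampling times must be positive")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("sampling times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self):
        return iter(self.times)

    def asarray(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def column_names(self) -> tuple[str, ...]:
        """CSV column names: times encoded as integer minutes, ``t5`` ... ``t480``."""
        return tuple(f"t{int(t) if float(t).is_integer() else t}" for t in self.times)


#: The common 9-point sampling grid (minutes) all curves are aligned to.
STANDARD_TIMES: tuple[float, ...] = (5, 15, 30, 60, 120, 180, 240, 360, 480)


def standard_time_grid() -> TimeGrid:
    """The standard 9-point grid: 5, 15, 30, 60, 120, 180, 240, 360, 480 min."""
    return TimeGrid(tuple(float(t) for t in STANDARD_TIMES))


@dataclass
class ConcentrationDataset:
    """Samples of one marker compound: features ``X`` (m x 3 herb proportions),
    targets ``Y`` (m x n concentrations on ``grid``), and replicate-group ids."""

    compound: str
    X: np.ndarray
    Y: np.ndarray
    grid: TimeGrid
    group_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.compound not in COMPOUNDS:
            raise ValidationError(
                f"unknown compound {self.compound!r}; expected one of {COMPOUNDS}"
            )
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValidationError("X and Y must be 2-D matrices")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValidationError(
                f"X has {self.X.shape[0]} rows but Y has {self.Y.shape[0]}"
            )
        if self.Y.shape[1] != len(self.grid):
            raise ValidationError(
                f"Y has {self.Y.shape[1]} columns but the grid has {len(self.grid)} times"
            )
        if np.any(self.Y < 0):
            raise ValidationError("concentrations must be non-negative")
        if not self.group_ids:
            self.group_ids = tuple(str(i) for i in range(self.X.shape[0]))
        elif len(self.group_ids) != self.X.shape[0]:
            raise ValidationError("group_ids length must equal the number of samples")
        else:
            self.group_ids = tuple(str(g) for g in self.group_ids)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_targets(self) -> int:
        return self.Y.shape[1]


@dataclass(frozen=True)
class PredictionMatrix:
    """Predicted concentrations aligned to a dataset's sample/target layout."""

    Yhat: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "Yhat", np.asarray(self.Yhat, dtype=float))
        if self.Yhat.ndim != 2:
            raise ValidationError("predictions must form a 2-D matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.Yhat.shape


def _canonical_columns(grid: TimeGrid) -> list[str]:
    return list(HERBS) + ["group"] + list(grid.column_names)


def write_dataset(dataset: ConcentrationDataset, path) -> None:
    """Write a dataset as a comma-separated UTF-8 table in canonical column order."""
    df = pd.DataFrame(dataset.X, columns=list(HERBS))
    df["group"] = list(dataset.group_ids)
    for j, name in enumerate(dataset.grid.column_names):
        df[name] = dataset.Y[:, j]
    df.to_csv(path, index=False)


def read_dataset(path, compound: str, grid: TimeGrid | None = None) -> ConcentrationDataset:
    """Read a dataset CSV written by :func:`write_dataset`.

    The target columns are named ``t<minutes>``; their times define the grid
    unless an explicit ``grid`` is given, in which case exactly those columns
    must be present.  Missing feature or target columns raise
    :class:`SchemaError` naming the first absent column.
    """
    df = pd.read_csv(path)
    for herb in HERBS:
        if herb not in df.columns:
            raise SchemaError(f"missing required column {herb!r}")
    if grid is None:
        tcols = [c for c in df.columns if c.startswith("t") and c[1:].replace(".", "", 1).isdigit()]
        if not tcols:
            raise SchemaError("no target columns of the form t<minutes> found")
        times = sorted(float(c[1:]) for c in tcols)
        grid = TimeGrid(tuple(times))
    for name in grid.column_names:
        if name not in df.columns:
            raise SchemaError(f"missing required column {name!r}")
    X = df[list(HERBS)].to_numpy(dtype=float)
    Y = df[list(grid.column_names)].to_numpy(dtype=float)
    if np.any(Y < 0):
        raise ValidationError("concentrations must be non-negative")
    groups = tuple(str(g) for g in df["group"]) if "group" in df.columns else ()
    return ConcentrationDataset(compound=compound, X=X, Y=Y, grid=grid, group_ids=groups)
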