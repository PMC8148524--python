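"""Data model and tidy-table I/O for TBARS storage experiments.

The experimental unit is a single TBARS measurement taken from one meat
sample (one treatment arm, one storage temperature, one replicate) on one
storage day.  TBARS is expressed either in mg malondialdehyde per kg meat
(``raw`` scale) or as a percentage of the day-0 value (``percent`` scale);
all kinetic fitting downstream operates on the percent scale.

The module also exposes the packaged reference tables: the antioxidant
assay results per extract (DPPH, total phenolic content) and the published
first-order rate constants per extract and storage temperature, which the
secondary-model and acceptance code recompute from.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    EmptyDatasetError,
    NormalizationError,
    SchemaError,
    TableParseError,
)

#: Canonical treatment order: control first, then the 13 extracts
#: alphabetically.  One-hot encodings and dummy coding follow this order.
TREATMENTS: tuple[str, ...] = (
    "control",
    "allspice",
    "basil",
    "bay leaf",
    "black seed",
    "cardamom",
    "caraway",
    "clove",
    "garlic",
    "nutmeg",
    "onion",
    "oregano",
    "rosemary",
    "thyme",
)

#: Default Celsius -> kelvin offset.  The published kelvins (277/281/289/293
#: for 4/8/16/20 degC) are integer-rounded, i.e. use an offset of 273; set
#: ``kelvin_offset=273.0`` to reproduce those tables exactly.
KELVIN_OFFSET: float = 273.15

RECORD_COLUMNS = ("treatment", "temperature_c", "replicate", "day", "tbars", "scale")

RAW = "raw"
PERCENT = "percent"


@dataclass(frozen=True)
class TbarsRecord:
    """One TBARS measurement.

    Parameters
    ----------
    treatment
        Study arm label; ``"control"`` is the untreated reference.
    temperature_c
        Storage temperature in degrees Celsius.
    replicate
        Positive integer replicate id.
    day
        Storage time in days (>= 0).
    tbars
        TBARS value: mg MDA/kg on the raw scale, percent of day-0 on the
        percent scale.
    scale
        Either ``"raw"`` or ``"percent"``.
    """

    treatment: str
    temperature_c: float
    replicate: int
    day: float
    tbars: float
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.day < 0:
            raise DomainError(f"storage day must be >= 0, got {self.day}")
        if self.scale not in (RAW, PERCENT):
            raise DomainError(f"scale must be 'raw' or 'percent', got {self.scale!r}")


@dataclass
class KineticDataset:
    """An ordered collection of :class:`TbarsRecord`.

    Treatments and temperatures are kept as ordered sets (order of first
    appearance) so that encodings and reports are deterministic.
    """

    records: list[TbarsRecord] = field(default_factory=list)

    @property
    def treatments(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.treatment)
        return list(seen)

    @property
    def temperatures_c(self) -> list[float]:
        seen: dict[float, None] = {}
        for r in self.records:
            seen.setdefault(r.temperature_c)
        return list(seen)

    @property
    def scale(self) -> str:
        scales = {r.scale for r in self.records}
        if len(scales) > 1:
            raise DomainError(f"mixed scales in dataset: {sorted(scales)}")
        return next(iter(scales)) if scales else RAW

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TbarsRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Return the records as a tidy DataFrame (file order preserved)."""
        return pd.DataFrame(
            [
                (r.treatment, r.temperature_c, r.replicate, r.day, r.tbars, r.scale)
                for r in self.records
            ],
            columns=list(RECORD_COLUMNS),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "KineticDataset":
        missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        records = [
            TbarsRecord(
                treatment=str(row.treatment),
                temperature_c=float(row.temperature_c),
                replicate=int(row.replicate),
                day=float(row.day),
                tbars=float(row.tbars),
                scale=str(row.scale),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(records=records)

    def groups(self) -> dict[tuple[str, float, int], list[TbarsRecord]]:
        """Group records by (treatment, temperature, replicate)."""
        out: dict[tuple[str, float, int], list[TbarsRecord]] = {}
        for r in self.records:
            out.setdefault((r.treatment, r.temperature_c, r.replicate), []).append(r)
        return out


def read_tbars_table(path: str | Path) -> KineticDataset:
    """Read a tidy TBARS CSV into a :class:`KineticDataset`.

    The file must be comma-separated UTF-8 with a header naming the six
    record columns.  Malformed rows are reported with their 1-based line
    numbers.

    Raises
    ------
    SchemaError
        If a required column is absent.
    TableParseError
        If ``day`` or ``tbars`` is non-numeric on some row.
    EmptyDatasetError
        If the file holds a header but no rows, or is empty.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=",", encoding="utf-8", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyDatasetError(f"{path} is empty") from None
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if frame.empty:
        raise EmptyDatasetError(f"{path} contains a header but no records")

    bad_lines: list[int] = []
    for col in ("temperature_c", "replicate", "day", "tbars"):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        # +2: 1-based lines plus the header row
        bad_lines.extend((np.flatnonzero(numeric.isna().to_numpy()) + 2).tolist())
    if bad_lines:
        lines = sorted(set(bad_lines))
        raise TableParseError(
            f"{path}: non-numeric values on line(s) {lines}", lines=lines
        )
    for col in ("temperature_c", "replicate", "day", "tbars"):
        # float() is correctly rounded, so read∘write round-trips exactly
        frame[col] = frame[col].astype(float)
    return KineticDataset.from_frame(frame)


def write_tbars_table(dataset: KineticDataset, path: str | Path) -> Path:
    """Write a dataset as a tidy CSV, sorted by (treatment, temperature,
    replicate, day) so identical record multisets produce identical bytes."""
    if not dataset.records:
        raise EmptyDatasetError("refusing to write an empty dataset")
    path = Path(path)
    frame = dataset.to_frame().sort_values(
        ["treatment", "temperature_c", "replicate", "day"], kind="mergesort"
    )
    buf = io.StringIO()
    # default float repr is shortest-round-trip, so read∘write is identity
    frame.to_csv(buf, index=False, lineterminator="\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def to_percent(dataset: KineticDataset) -> KineticDataset:
    """Normalize raw TBARS to percent of the day-0 value per group.

    Each (treatment, temperature, replicate) group must contain a day-0
    record with ``tbars > 0``; every value in the group is divided by it and
    multiplied by 100.  Idempotent on already-normalized data.
    """
    if dataset.records and dataset.scale == PERCENT:
        return KineticDataset(records=list(dataset.records))
    out: list[TbarsRecord] = []
    baselines: dict[tuple[str, float, int], float] = {}
    for key, recs in dataset.groups().items():
        day0 = [r for r in recs if r.day == 0]
        if not day0:
            raise NormalizationError(f"group {key} lacks a day-0 record")
        if day0[0].tbars <= 0:
            raise DomainError(f"group {key} has a nonpositive day-0 value")
        baselines[key] = day0[0].tbars
    for r in dataset.records:
        base = baselines[(r.treatment, r.temperature_c, r.replicate)]
        out.append(
            TbarsRecord(
                treatment=r.treatment,
                temperature_c=r.temperature_c,
                replicate=r.replicate,
                day=r.day,
                tbars=100.0 * r.tbars / base,
                scale=PERCENT,
            )
        )
    return KineticDataset(records=out)


def celsius_to_kelvin(temperature_c: float | np.ndarray, offset: float = KELVIN_OFFSET):
    """Convert Celsius to kelvin with a configurable offset (see
    :data:`KELVIN_OFFSET`)."""
    return np.asarray(temperature_c, dtype=float) + offset


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

def _load_resource(name: str) -> pd.DataFrame:
    with resources.files("tbars_kinetics.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_extract_assays() -> pd.DataFrame:
    """Published antioxidant assay table: one row per extract with DPPH
    radical-scavenging activity (umol Trolox equiv./g) and total phenolic
    content (mg gallic-acid equiv./g)."""
    return _load_resource("table1_assays.csv")


def load_published_rate_constants() -> pd.DataFrame:
    """Published first-order TBARS rate constants: one row per extract and
    storage temperature (kelvin, as printed) with mean and SD of k (1/day)
    over triplicates."""
    return _load_resource("table2_rate_constants.csv")


def load_published_secondary_params() -> pd.DataFrame:
    """Published Arrhenius (Ea, k0, R2) and log-logistic (c, Tc, R2)
    parameters per extract.  Some printed entries are internally
    inconsistent with the printed rate constants (see the methods note);
    they are shipped verbatim."""
    return _load_resource("table2_secondary_params.csv")


def load_deposited_dataset(path: str | Path) -> KineticDataset:
    """Load the deposited raw study data from a manually supplied file.

    The raw measurements are deposited externally (Mendeley Data,
    doi:10.17632/cs942c8rw3.1) and are never downloaded by this package.
    Supply a tidy CSV export with the six record columns; an Excel sheet
    with the same header also works.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: the deposited dataset must be supplied manually"
        )
    if path.suffix.lower() in (".xlsx", ".xls"):
        frame = pd.read_excel(path)
        return KineticDataset.from_frame(frame)
    return read_tbars_table(path)


def dataset_from_tuples(
    rows: Iterable[tuple], scale: str = PERCENT
) -> KineticDataset:
    """Build a dataset from (treatment, temperature_c, replicate, day, tbars)
    tuples; convenience for tests and examples."""
    return KineticDataset(
        records=[TbarsRecord(t, float(c), int(r), float(d), float(v), scale)
                 for (t, c, r, d, v) in rows]
    )
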