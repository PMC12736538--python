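"""Plot-level trial data model, CSV I/O, and the built-in reference tables.

A replacement-series intercropping trial is described by a set of planting
patterns (``RowConfiguration``), each either a sole crop (``MM`` for maize,
``AM`` for alfalfa) or an alternating row strip pattern (``MA(r:s)``, r rows
of maize then s rows of alfalfa), observed over years x replicates x crops x
traits (``PlotObservation``).  The sowing proportion of each crop, Z, is
derived from its share of rows under the assumption of uniform inter-row
spacing and equal per-row sowing rates; an area-based Z would differ if the
two crops used different row spacings.

The package ships the printed treatment means (+/- SD) of a two-year
maize-alfalfa row-ratio trial as plain-CSV reference tables; see
:func:`load_reference_means` and :func:`load_reference_dataset`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    EmptyDatasetError,
    InvalidConfigurationError,
    MissingCellError,
    SchemaError,
    ValidationError,
)

MAIZE = "maize"
ALFALFA = "alfalfa"
CROPS = (MAIZE, ALFALFA)

#: Canonical unit string per trait; units are validated, never converted.
TRAIT_UNITS: Mapping[str, str] = {
    "grain_yield": "kg ha-1",
    "forage_yield": "kg ha-1",
    "biomass_dm": "kg ha-1",
    "plant_height": "cm",
    "chlorophyll": "SPAD units",
    "photosynthetic_rate": "umol CO2 m-2 s-1",
    "thousand_grain_weight": "g",
}

REQUIRED_COLUMNS = ("year", "configuration", "replicate", "crop", "trait", "value", "units")

_LABEL_RE = re.compile(r"^MA\s*\((\d+):(\d+)\)$")


def derive_sown_proportion(rows_maize: int, rows_alfalfa: int) -> tuple[float, float]:
    """Sowing proportions (Z_M, Z_A) from the row counts of a pattern.

    Z_crop = rows_crop / total rows, so the two proportions always sum to 1
    and scaling both row counts by the same factor leaves Z unchanged
    (a 2:2 strip has the same Z as 1:1 even though the labels differ).

    Raises
    ------
    InvalidConfigurationError
        If both row counts are zero or either is negative.
    """
    if rows_maize < 0 or rows_alfalfa < 0:
        raise InvalidConfigurationError("row counts must be non-negative")
    total = rows_maize + rows_alfalfa
    if total == 0:
        raise InvalidConfigurationError("a planting pattern needs at least one row")
    return rows_maize / total, rows_alfalfa / total


@dataclass(frozen=True)
class RowConfiguration:
    """A planting pattern: sole crop or an r:s maize:alfalfa row strip."""

    label: str
    rows_maize: int
    rows_alfalfa: int

    def __post_init__(self) -> None:
        derive_sown_proportion(self.rows_maize, self.rows_alfalfa)  # validates

    @property
    def z_maize(self) -> float:
        return derive_sown_proportion(self.rows_maize, self.rows_alfalfa)[0]

    @property
    def z_alfalfa(self) -> float:
        return derive_sown_proportion(self.rows_maize, self.rows_alfalfa)[1]

    @property
    def is_mono(self) -> bool:
        return self.rows_maize == 0 or self.rows_alfalfa == 0

    @property
    def is_intercrop(self) -> bool:
        return not self.is_mono

    @property
    def crops(self) -> tuple[str, ...]:
        present = []
        if self.rows_maize > 0:
            present.append(MAIZE)
        if self.rows_alfalfa > 0:
            present.append(ALFALFA)
        return tuple(present)

    def allows_crop(self, crop: str) -> bool:
        return crop in self.crops


def parse_configuration(label: str) -> RowConfiguration:
    """Build a :class:`RowConfiguration` from a label.

    ``"MM"`` is sole maize, ``"AM"`` sole alfalfa, ``"MA(r:s)"`` an
    intercrop strip with r maize rows and s alfalfa rows (whitespace before
    the parenthesis is tolerated).
    """
    clean = label.strip()
    if clean == "MM":
        return RowConfiguration("MM", 1, 0)
    if clean == "AM":
        return RowConfiguration("AM", 0, 1)
    m = _LABEL_RE.match(clean)
    if m:
        r, s = int(m.group(1)), int(m.group(2))
        if r < 1 or s < 1:
            raise InvalidConfigurationError(
                f"intercrop pattern {label!r} needs at least one row of each crop"
            )
        return RowConfiguration(f"MA({r}:{s})", r, s)
    raise InvalidConfigurationError(f"unrecognized configuration label {label!r}")


#: The seven patterns of the reference trial, in table order.
STANDARD_CONFIGURATIONS: tuple[RowConfiguration, ...] = tuple(
    parse_configuration(lbl)
    for lbl in ("MM", "AM", "MA(1:1)", "MA(2:1)", "MA(2:2)", "MA(3:1)", "MA(3:2)", "MA(3:3)")
)
INTERCROP_LABELS = tuple(c.label for c in STANDARD_CONFIGURATIONS if c.is_intercrop)


@dataclass(frozen=True)
class PlotObservation:
    """One plot x crop x trait x year measurement."""

    year: int
    configuration: str
    replicate: int
    crop: str
    trait: str
    value: float
    units: str

    def validate(self, configurations: Mapping[str, RowConfiguration]) -> None:
        if self.crop not in CROPS:
            raise ValidationError(f"unknown crop {self.crop!r}")
        if self.trait not in TRAIT_UNITS:
            raise ValidationError(f"unknown trait {self.trait!r}")
        if self.units != TRAIT_UNITS[self.trait]:
            raise ValidationError(
                f"trait {self.trait!r} must be reported in {TRAIT_UNITS[self.trait]!r}, "
                f"got {self.units!r}"
            )
        if not math.isfinite(self.value) or self.value < 0:
            raise ValidationError(f"value must be a non-negative number, got {self.value!r}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        cfg = configurations.get(self.configuration)
        if cfg is None:
            raise ValidationError(f"unknown configuration label {self.configuration!r}")
        if not cfg.allows_crop(self.crop):
            raise ValidationError(
                f"crop {self.crop!r} cannot occur under configuration {self.configuration!r}"
            )


@dataclass
class TrialDataset:
    """Validated container for a trial: observations plus the design.

    ``observations`` is a tidy DataFrame with the columns of
    :data:`REQUIRED_COLUMNS`; ``configurations`` maps each referenced label
    to its :class:`RowConfiguration`.
    """

    observations: pd.DataFrame
    configurations: dict[str, RowConfiguration] = field(default_factory=dict)
    unbalanced_ok: bool = False

    @classmethod
    def from_observations(
        cls, obs: Iterable[PlotObservation], *, allow_unbalanced: bool = False
    ) -> "TrialDataset":
        rows = list(obs)
        if not rows:
            raise EmptyDatasetError("dataset contains no observations")
        configurations = {}
        for o in rows:
            if o.configuration not in configurations:
                configurations[o.configuration] = parse_configuration(o.configuration)
        for o in rows:
            o.validate(configurations)
        df = pd.DataFrame([o.__dict__ for o in rows], columns=list(REQUIRED_COLUMNS))
        ds = cls(df, configurations, unbalanced_ok=allow_unbalanced)
        ds._check_balance()
        return ds

    def _check_balance(self) -> None:
        counts = self.observations.groupby(
            ["year", "configuration", "crop", "trait"], observed=True
        ).size()
        if counts.nunique() > 1 and not self.unbalanced_ok:
            raise ValidationError(
                "replicate count differs across cells "
                f"(found {sorted(counts.unique())}); pass allow_unbalanced=True to accept"
            )

    @property
    def n_replicates(self) -> int:
        counts = self.observations.groupby(
            ["year", "configuration", "crop", "trait"], observed=True
        ).size()
        return int(counts.max())

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.observations["year"].unique()))

    def intercrop_labels(self) -> tuple[str, ...]:
        return tuple(
            lbl for lbl, cfg in sorted(self.configurations.items()) if cfg.is_intercrop
        )

    def cell(self, year: int, configuration: str, crop: str, trait: str) -> np.ndarray:
        """Replicate values of one cell, in replicate order."""
        df = self.observations
        sel = df[
            (df["year"] == year)
            & (df["configuration"] == configuration)
            & (df["crop"] == crop)
            & (df["trait"] == trait)
        ].sort_values("replicate")
        if sel.empty:
            raise MissingCellError(
                f"no observations for year={year}, configuration={configuration!r}, "
                f"crop={crop!r}, trait={trait!r}"
            )
        return sel["value"].to_numpy(dtype=float)

    def aggregate_means(
        self, year: int, configuration: str, crop: str, trait: str
    ) -> tuple[float, float]:
        """Arithmetic mean and sample SD (ddof=1) over replicates of one cell."""
        values = self.cell(year, configuration, crop, trait)
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
        return mean, sd

    def to_csv(self, path: str | Path) -> None:
        self.observations.to_csv(path, index=False)


def aggregate_means(
    dataset: TrialDataset, year: int, configuration: str, crop: str, trait: str
) -> tuple[float, float]:
    """Functional alias of :meth:`TrialDataset.aggregate_means`."""
    return dataset.aggregate_means(year, configuration, crop, trait)


def load_trial_csv(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    allow_unbalanced: bool = False,
) -> TrialDataset:
    """Read plot observations from a delimited text file.

    Parameters
    ----------
    path
        CSV file with a header row.  Required columns: year, configuration,
        replicate, crop, trait, value, units (UTF-8).
    schema
        Optional mapping from the canonical column names to the names used
        in the file, e.g. ``{"value": "yield_kg_ha"}``.
    allow_unbalanced
        Accept datasets whose replicate count varies between cells.

    Raises
    ------
    SchemaError
        A required column is absent (the message names it).
    ValidationError
        A row violates the data model (the message carries its row number).
    EmptyDatasetError
        The file holds a header but no data rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyDatasetError(f"{path} is empty") from exc
    rename = {v: k for k, v in (schema or {}).items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path} is missing required column(s): {', '.join(missing)}")
    if raw.empty:
        raise EmptyDatasetError(f"{path} contains a header but no observations")

    observations = []
    for idx, row in raw.iterrows():
        try:
            obs = PlotObservation(
                year=int(row["year"]),
                configuration=str(row["configuration"]).strip(),
                replicate=int(row["replicate"]),
                crop=str(row["crop"]).strip(),
                trait=str(row["trait"]).strip(),
                value=float(row["value"]),
                units=str(row["units"]).strip(),
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}, row {idx + 2}: unparseable record ({exc})") from exc
        observations.append((idx, obs))

    configurations: dict[str, RowConfiguration] = {}
    for idx, obs in observations:
        try:
            if obs.configuration not in configurations:
                configurations[obs.configuration] = parse_configuration(obs.configuration)
            obs.validate(configurations)
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {idx + 2}: {exc}") from exc
    dataset = TrialDataset(
        pd.DataFrame([o.__dict__ for _, o in observations], columns=list(REQUIRED_COLUMNS)),
        configurations,
        unbalanced_ok=allow_unbalanced,
    )
    dataset._check_balance()
    return dataset


# ---------------------------------------------------------------------------
# Built-in reference tables (printed treatment means +/- SD of the two-year
# maize-alfalfa row-ratio trial: yields, biomass, grain weight, heights).
# ---------------------------------------------------------------------------

_DATA_PACKAGE = "intercrop.data"
YIELD_TABLE = "tables_1_2.csv"
HEIGHT_TABLE = "heights_s2_1.csv"


def load_reference_means(which: str = "yields") -> pd.DataFrame:
    """The shipped reference tables as a means table.

    Parameters
    ----------
    which
        ``"yields"`` for the grain/forage/biomass/grain-weight table,
        ``"heights"`` for the plant-height table, ``"all"`` for both.

    Returns
    -------
    DataFrame with columns year, configuration, crop, trait, mean, sd, units.
    SD is NaN where the source reports none (plant heights).
    """
    files = {"yields": [YIELD_TABLE], "heights": [HEIGHT_TABLE], "all": [YIELD_TABLE, HEIGHT_TABLE]}
    if which not in files:
        raise ValueError(f"which must be one of {sorted(files)}, got {which!r}")
    frames = []
    for name in files[which]:
        with resources.files(_DATA_PACKAGE).joinpath(name).open("r", encoding="utf-8") as fh:
            frames.append(pd.read_csv(fh))
    return pd.concat(frames, ignore_index=True)


def expand_pseudo_replicates(means: pd.DataFrame, n: int = 3) -> TrialDataset:
    """Expand a means +/- SD table into a dataset of deterministic replicates.

    Each cell becomes the 3-point set ``{m - s, m, m + s}``, whose sample
    mean is exactly m and whose sample SD (ddof=1) is exactly s.  This lets
    the ANOVA/LSD stage run on published tables that print only summaries.
    Only n = 3 is supported; cells with no SD get three copies of the mean.
    """
    if n != 3:
        raise ValueError("pseudo-replicate expansion is defined for n = 3 only")
    obs = []
    for _, row in means.iterrows():
        m = float(row["mean"])
        s = float(row["sd"]) if pd.notna(row["sd"]) else 0.0
        for rep, value in enumerate((m - s, m, m + s), start=1):
            obs.append(
                PlotObservation(
                    year=int(row["year"]),
                    configuration=str(row["configuration"]),
                    replicate=rep,
                    crop=str(row["crop"]),
                    trait=str(row["trait"]),
                    value=max(value, 0.0),
                    units=str(row["units"]),
                )
            )
    return TrialDataset.from_observations(obs, allow_unbalanced=True)


def load_reference_dataset(which: str = "yields") -> TrialDataset:
    """The reference tables as a :class:`TrialDataset` of pseudo-replicates."""
    return expand_pseudo_replicates(load_reference_means(which))
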