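"""Data model and I/O for phosphorus-efficiency phenotyping trials.

The central objects are :class:`TrialDesign` (the factorial layout of a
genotype x P-level Rhizotube trial), :class:`HarvestRecord` (one tube's
destructive harvest measurements) and :class:`MetricTable` (genotype-level
summaries of the five P-efficiency metrics for one platform).

A transcription of the published genotype-mean metric table for the two
phenotyping platforms (4PMI, Dijon and ALSIA, Metaponto) ships with the
package and is loaded with :func:`load_table3_fixture`.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Canonical P-level labels: optimal and deficient supply.
P_PLUS = "P+"
P_MINUS = "P-"

#: Fixed lower-snake-case column order for harvest CSVs.
HARVEST_COLUMNS = (
    "genotype",
    "p_level",
    "replicate",
    "shoot_dw",
    "root_dw",
    "plant_p_concentration",
    "p_uptake",
    "height",
    "culms",
)

#: Column layout of a metric table CSV (mirrors the published table).
METRIC_COLUMNS = (
    "pae_pminus_mean", "pae_pminus_sd",
    "prae_pminus_mean", "prae_pminus_sd",
    "pue_pminus_mean", "pue_pminus_sd",
    "pae_pplus_mean", "pae_pplus_sd",
    "prae_pplus_mean", "prae_pplus_sd",
    "pue_pplus_mean", "pue_pplus_sd",
    "relative_efficiency", "apue",
)


class ValidationError(ValueError):
    """A harvest table row violates the trial design or a domain constraint."""


@dataclass(frozen=True)
class TrialDesign:
    """Layout of a randomized genotype x P-level Rhizotube trial.

    Parameters
    ----------
    genotypes
        Genotype labels, one per cultivar/line under test.
    p_applied
        Mass of P (g) made available per tube under each P level, keyed by
        level label.  The optimal level must receive strictly more P than
        the deficient one.
    replicates_per_cell
        Tubes per genotype x P-level cell.
    platform_label
        Free-text identifier of the phenotyping platform.
    p_levels
        Exactly two level labels; by convention ``("P+", "P-")``.
    """

    genotypes: tuple[str, ...]
    p_applied: dict[str, float]
    replicates_per_cell: int = 6
    platform_label: str = ""
    p_levels: tuple[str, str] = (P_PLUS, P_MINUS)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotypes", tuple(self.genotypes))
        if len(self.p_levels) != 2:
            raise ValueError(f"exactly two P levels required, got {self.p_levels!r}")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValueError("duplicate genotype labels in design")
        missing = set(self.p_levels) - set(self.p_applied)
        if missing:
            raise ValueError(f"p_applied missing levels: {sorted(missing)}")
        hi, lo = (self.p_applied[self.p_levels[0]], self.p_applied[self.p_levels[1]])
        if not (hi > lo > 0):
            raise ValueError(
                f"p_applied must satisfy {self.p_levels[0]} > {self.p_levels[1]} > 0, "
                f"got {hi} and {lo}"
            )
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")

    @property
    def p_plus(self) -> str:
        return self.p_levels[0]

    @property
    def p_minus(self) -> str:
        return self.p_levels[1]

    def p_applied_for(self, level: str) -> float:
        try:
            return self.p_applied[level]
        except KeyError:
            raise KeyError(f"unknown P level {level!r}; design has {self.p_levels}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            genotypes=tuple(raw["genotypes"]),
            p_applied={str(k): float(v) for k, v in raw["p_applied"].items()},
            replicates_per_cell=int(raw.get("replicates_per_cell", 6)),
            platform_label=str(raw.get("platform_label", "")),
            p_levels=tuple(raw.get("p_levels", (P_PLUS, P_MINUS))),
        )


@dataclass
class HarvestRecord:
    """One tube's measurements at destructive harvest.

    ``plant_p_concentration`` is whole-plant tissue P concentration in the
    unit the analysis is configured for; ``p_uptake`` is total plant P in g.
    Optional morphometrics (``height`` in cm, ``culms`` count) are stored as
    ``None`` when absent, never imputed.
    """

    genotype: str
    p_level: str
    replicate: int
    shoot_dw: float
    root_dw: float
    plant_p_concentration: float
    p_uptake: float
    height: float | None = None
    culms: int | None = None

    _NONNEG = ("shoot_dw", "root_dw", "plant_p_concentration", "p_uptake")

    def validate(self, design: TrialDesign | None = None, row: int | None = None) -> None:
        where = f" (row {row})" if row is not None else ""
        for name in self._NONNEG:
            value = getattr(self, name)
            if value < 0:
                raise ValidationError(f"negative {name}={value}{where}")
        if design is not None:
            if self.genotype not in design.genotypes:
                raise ValidationError(f"unknown genotype {self.genotype!r}{where}")
            if self.p_level not in design.p_levels:
                raise ValidationError(f"unknown P level {self.p_level!r}{where}")


def records_to_frame(records: Iterable[HarvestRecord]) -> pd.DataFrame:
    """Tabulate harvest records into a DataFrame with the canonical columns."""
    rows = [{f.name: getattr(r, f.name) for f in fields(HarvestRecord)} for r in records]
    frame = pd.DataFrame(rows, columns=list(HARVEST_COLUMNS))
    return frame


def read_harvest_table(
    path: str | Path,
    design: TrialDesign,
    column_map: dict[str, str] | None = None,
) -> list[HarvestRecord]:
    """Read and validate a harvest CSV against a trial design.

    Parameters
    ----------
    path
        CSV with a header naming the :data:`HARVEST_COLUMNS` fields
        (decimal point ``.``).  ``height`` and ``culms`` are optional.
    design
        Every row's genotype and P level must belong to this design.
    column_map
        Optional remapping ``{external_header: canonical_name}`` for files
        produced with other conventions.

    Returns
    -------
    list of HarvestRecord, in file order.

    Raises
    ------
    ValidationError
        On an unknown genotype/level or a negative measurement, naming the
        offending 1-based data row.
    """
    records: list[HarvestRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file without header")
        for i, raw in enumerate(reader, start=1):
            if column_map:
                raw = {column_map.get(k, k): v for k, v in raw.items()}
            try:
                rec = HarvestRecord(
                    genotype=raw["genotype"],
                    p_level=raw["p_level"],
                    replicate=int(raw["replicate"]),
                    shoot_dw=float(raw["shoot_dw"]),
                    root_dw=float(raw["root_dw"]),
                    plant_p_concentration=float(raw["plant_p_concentration"]),
                    p_uptake=float(raw["p_uptake"]),
                    height=float(raw["height"]) if raw.get("height") not in (None, "") else None,
                    culms=int(raw["culms"]) if raw.get("culms") not in (None, "") else None,
                )
            except (KeyError, ValueError) as exc:
                raise ValidationError(f"row {i}: cannot parse harvest record: {exc}") from exc
            rec.validate(design, row=i)
            records.append(rec)
    if not records:
        logger.warning("harvest table %s contains a header but no data rows", path)
    return records


def write_harvest_table(records: Sequence[HarvestRecord], path: str | Path) -> None:
    """Write harvest records as an RFC-4180 CSV with canonical columns."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(HARVEST_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.genotype, r.p_level, r.replicate,
                    repr(r.shoot_dw), repr(r.root_dw),
                    repr(r.plant_p_concentration), repr(r.p_uptake),
                    "" if r.height is None else repr(r.height),
                    "" if r.culms is None else r.culms,
                ]
            )


@dataclass
class MetricTable:
    """Genotype-level five-metric summary for one platform.

    ``data`` is indexed by genotype and carries :data:`METRIC_COLUMNS`:
    PAE/PRAE/PUE mean and sample SD per P level, plus the level-free
    P relative efficiency (percent) and APUE (g DW per g P) scalars.
    SD columns may hold NaN when a cell had a single replicate.
    """

    data: pd.DataFrame
    platform_label: str = ""
    n_per_cell: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in METRIC_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"metric table missing columns: {missing}")
        if self.data.index.has_duplicates:
            raise ValueError("one row per genotype required")
        sds = self.data[[c for c in METRIC_COLUMNS if c.endswith("_sd")]]
        if (sds.to_numpy() < 0).any():
            raise ValueError("standard deviations must be >= 0")

    @property
    def genotypes(self) -> list[str]:
        return list(self.data.index)

    def metric_mean(self, metric: str, level: str | None = None) -> pd.Series:
        """Genotype-mean column for a metric, at a P level where applicable.

        ``metric`` is one of ``pae``, ``prae``, ``pue`` (level required) or
        ``relative_efficiency``, ``apue`` (level-free).
        """
        if metric in ("relative_efficiency", "apue"):
            return self.data[metric]
        suffix = {P_MINUS: "pminus", P_PLUS: "pplus"}.get(level)
        if suffix is None:
            raise KeyError(f"unknown P level {level!r}")
        return self.data[f"{metric}_{suffix}_mean"]

    def to_csv(self, path: str | Path) -> None:
        self.data.reset_index(names="genotype").to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, platform_label: str = "", n_per_cell: int | None = None
    ) -> "MetricTable":
        frame = pd.read_csv(path).set_index("genotype")
        return cls(frame, platform_label=platform_label, n_per_cell=n_per_cell)


#: Replicates per genotype x level cell in the two published trials.
FIXTURE_N = {"4PMI": 6, "ALSIA": 4}


def load_table3_fixture(platform: str) -> MetricTable:
    """Load the packaged genotype-mean metric table for one platform.

    Values are the published 26-genotype summaries transcribed at printed
    precision (no re-rounding).  ``platform`` is ``"4PMI"`` or ``"ALSIA"``.
    """
    key = platform.upper()
    if key not in FIXTURE_N:
        raise KeyError(f"unknown platform {platform!r}; expected one of {sorted(FIXTURE_N)}")
    name = f"table3_{key.lower()}.csv"
    with resources.files("pindicator.data").joinpath(name).open() as fh:
        frame = pd.read_csv(fh).set_index("genotype")
    return MetricTable(frame, platform_label=key, n_per_cell=FIXTURE_N[key])
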