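"""Nested block / plot / culm stand-inventory data model.

A moso-bamboo inventory is hierarchical: culms (individual stems) are
nested in 20 x 20 m sample plots, which are nested in blocks.  This module
holds the record types, validation, the derived competition covariates
(plot basal area BA, basal area in larger culms BAL, quadratic mean
diameter QMD, relative diameter RD, stem density N) and CSV round-trip
I/O.

Units: DBH in cm, heights in m, areas in m2, BA/BAL in m2 per hectare,
density in culms per hectare.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "CulmRecord",
    "PlotRecord",
    "Dataset",
    "CsvSchema",
    "SchemaError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "derive_covariates",
    "dataset_to_frame",
]

#: minimum DBH of the measurement protocol, cm; smaller culms raise a warning
DBH_PROTOCOL_FLOOR_CM = 5.0


class SchemaError(ValueError):
    """A CSV column required by the schema is missing or unusable."""


class ValidationError(ValueError):
    """Records violate the data-model invariants."""


@dataclass
class CulmRecord:
    """One bamboo culm with measured and derived covariates.

    ``hcb`` (height to crown base) may be absent for prediction-only
    records.  ``bal`` and ``rd`` are derived by :func:`derive_covariates`.
    """

    block_id: str
    plot_id: str
    culm_id: str
    dbh: float
    h: float
    hcb: Optional[float] = None
    age_du: Optional[float] = None
    cw: Optional[float] = None
    bal: Optional[float] = None
    rd: Optional[float] = None

    def basal_area_m2(self) -> float:
        """Cross-sectional stem area at breast height, m2 (DBH is cm)."""
        return math.pi * (self.dbh / 200.0) ** 2

    def validate(self) -> None:
        if not (self.dbh > 0):
            raise ValidationError(f"culm {self.culm_id}: dbh must be > 0, got {self.dbh}")
        if not (self.h > 0):
            raise ValidationError(f"culm {self.culm_id}: h must be > 0, got {self.h}")
        if self.hcb is not None and not (0 < self.hcb < self.h):
            raise ValidationError(
                f"culm {self.culm_id}: hcb must lie in (0, h); got hcb={self.hcb}, h={self.h}"
            )
        if self.dbh < DBH_PROTOCOL_FLOOR_CM:
            warnings.warn(
                f"culm {self.culm_id}: dbh {self.dbh} cm below the {DBH_PROTOCOL_FLOOR_CM} cm "
                "measurement protocol floor",
                stacklevel=2,
            )


@dataclass
class PlotRecord:
    """One sample plot and its stand-level descriptors.

    ``cd`` is canopy density, the shaded-ground fraction in (0, 1].
    ``n_per_ha``, ``ba`` and ``qmd`` are derived from the plot's culms.
    ``site`` optionally carries site descriptors (slope degree, slope
    position, humus thickness, ...) that the model does not use.
    """

    plot_id: str
    block_id: str
    area_m2: float = 400.0
    cd: Optional[float] = None
    n_per_ha: Optional[float] = None
    ba: Optional[float] = None
    qmd: Optional[float] = None
    site: Mapping[str, object] = field(default_factory=dict)

    @property
    def expansion_factor(self) -> float:
        """Per-hectare expansion factor 10000 / area_m2."""
        return 10000.0 / self.area_m2

    def validate(self) -> None:
        if not (self.area_m2 > 0):
            raise ValidationError(f"plot {self.plot_id}: area_m2 must be > 0")
        if self.cd is not None and not (0 < self.cd <= 1):
            raise ValidationError(
                f"plot {self.plot_id}: canopy density must lie in (0, 1], got {self.cd}"
            )


@dataclass
class Dataset:
    """A validated block / plot / culm inventory."""

    blocks: list[str]
    plots: list[PlotRecord]
    culms: list[CulmRecord]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        block_set = set(self.blocks)
        plot_index: dict[tuple[str, str], PlotRecord] = {}
        for p in self.plots:
            p.validate()
            if p.block_id not in block_set:
                raise ValidationError(f"plot {p.plot_id}: unknown block {p.block_id!r}")
            key = (p.block_id, p.plot_id)
            if key in plot_index:
                raise ValidationError(f"duplicate plot {key}")
            plot_index[key] = p
        seen: set[tuple[str, str, str]] = set()
        bad_rows: list[str] = []
        for c in self.culms:
            c.validate()
            if (c.block_id, c.plot_id) not in plot_index:
                raise ValidationError(
                    f"culm {c.culm_id}: no plot ({c.block_id!r}, {c.plot_id!r}) in dataset"
                )
            key3 = (c.block_id, c.plot_id, c.culm_id)
            if key3 in seen:
                bad_rows.append(c.culm_id)
            seen.add(key3)
        if bad_rows:
            raise ValidationError(f"duplicate culm ids within a plot: {bad_rows}")

    def plot(self, block_id: str, plot_id: str) -> PlotRecord:
        for p in self.plots:
            if p.block_id == block_id and p.plot_id == plot_id:
                return p
        raise KeyError((block_id, plot_id))

    def culms_of_plot(self, block_id: str, plot_id: str) -> list[CulmRecord]:
        return [c for c in self.culms if c.block_id == block_id and c.plot_id == plot_id]

    @property
    def n_culms(self) -> int:
        return len(self.culms)


@dataclass(frozen=True)
class CsvSchema:
    """Maps canonical column names onto the columns of a concrete CSV file."""

    block: str = "block"
    plot: str = "plot"
    culm: str = "culm"
    dbh: str = "dbh_cm"
    h: str = "h_m"
    hcb: str = "hcb_m"
    cd: str = "cd"
    area_m2: str = "area_m2"
    age_du: str = "age_du"
    cw: str = "cw_m"

    MANDATORY = ("block", "plot", "dbh", "h")


DEFAULT_SCHEMA = CsvSchema()


def _parse_float(value: str, column: str, row_number: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(
            f"row {row_number}: non-numeric value {value!r} in column {column!r}"
        ) from None


def read_dataset(path, schema: CsvSchema = DEFAULT_SCHEMA) -> Dataset:
    """Read a culm-level inventory CSV into a validated :class:`Dataset`.

    Row order is preserved; derived covariates are left unset (call
    :func:`derive_covariates`).  Missing mandatory columns raise
    :class:`SchemaError` naming the column; out-of-range HCB values raise
    :class:`ValidationError` listing the offending rows.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    for canonical in CsvSchema.MANDATORY:
        col = getattr(schema, canonical)
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} ({canonical}) missing from {path}")

    has = {name: getattr(schema, name) in df.columns for name in
           ("culm", "hcb", "cd", "area_m2", "age_du", "cw")}

    culms: list[CulmRecord] = []
    plots: dict[tuple[str, str], PlotRecord] = {}
    blocks: list[str] = []
    bad_hcb: list[int] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        row = dict(zip(df.columns, row))
        block = str(row[schema.block])
        plot = str(row[schema.plot])
        dbh = _parse_float(row[schema.dbh], schema.dbh, i)
        h = _parse_float(row[schema.h], schema.h, i)
        hcb = None
        if has["hcb"] and row[schema.hcb] != "":
            hcb = _parse_float(row[schema.hcb], schema.hcb, i)
            if hcb >= h:
                bad_hcb.append(i)
        culm_id = str(row[schema.culm]) if has["culm"] else str(len(culms) + 1)
        age = _parse_float(row[schema.age_du], schema.age_du, i) if has["age_du"] and row[schema.age_du] != "" else None
        cw = _parse_float(row[schema.cw], schema.cw, i) if has["cw"] and row[schema.cw] != "" else None

        if block not in blocks:
            blocks.append(block)
        key = (block, plot)
        if key not in plots:
            cd = _parse_float(row[schema.cd], schema.cd, i) if has["cd"] and row[schema.cd] != "" else None
            area = _parse_float(row[schema.area_m2], schema.area_m2, i) if has["area_m2"] and row[schema.area_m2] != "" else 400.0
            plots[key] = PlotRecord(plot_id=plot, block_id=block, area_m2=area, cd=cd)
        culms.append(
            CulmRecord(block_id=block, plot_id=plot, culm_id=culm_id,
                       dbh=dbh, h=h, hcb=hcb, age_du=age, cw=cw)
        )
    if bad_hcb:
        raise ValidationError(f"hcb >= h in rows {bad_hcb}")
    return Dataset(blocks=blocks, plots=list(plots.values()), culms=culms)


def write_dataset(ds: Dataset, path, schema: CsvSchema = DEFAULT_SCHEMA) -> None:
    """Write a dataset as a culm-level CSV, including derived columns."""
    plot_index = {(p.block_id, p.plot_id): p for p in ds.plots}
    fieldnames = [schema.block, schema.plot, schema.culm, schema.dbh, schema.h,
                  schema.hcb, schema.cd, schema.area_m2, schema.age_du, schema.cw,
                  "bal", "rd", "qmd", "ba", "n_per_ha"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(fieldnames)
        for c in ds.culms:
            p = plot_index[(c.block_id, c.plot_id)]
            writer.writerow([
                c.block_id, c.plot_id, c.culm_id,
                _fmt(c.dbh), _fmt(c.h), _fmt(c.hcb), _fmt(p.cd), _fmt(p.area_m2),
                _fmt(c.age_du), _fmt(c.cw),
                _fmt(c.bal), _fmt(c.rd), _fmt(p.qmd), _fmt(p.ba), _fmt(p.n_per_ha),
            ])


def _fmt(x) -> str:
    if x is None:
        return ""
    return repr(float(x))


def derive_covariates(ds: Dataset) -> Dataset:
    """Compute plot and culm competition covariates; returns a new Dataset.

    Per plot (expansion factor E = 10000 / area_m2):
      ba       = E * sum of culm basal areas            [m2/ha]
      n_per_ha = E * culm count                         [culms/ha]
      qmd      = sqrt(mean of dbh^2)                    [cm]
    Per culm:
      bal = E * sum of basal areas of culms in the same plot with strictly
            larger dbh (the plot-maximum culm has bal = 0)  [m2/ha]
      rd  = dbh / qmd

    Idempotent; raises on empty plots.
    """
    new_plots: list[PlotRecord] = []
    new_culms: list[CulmRecord] = []
    by_plot: dict[tuple[str, str], list[CulmRecord]] = {}
    for c in ds.culms:
        by_plot.setdefault((c.block_id, c.plot_id), []).append(c)

    for p in ds.plots:
        culms = by_plot.get((p.block_id, p.plot_id), [])
        if not culms:
            raise ValidationError(f"plot {p.plot_id}: no culms; cannot derive covariates")
        if not (p.area_m2 > 0):
            raise ValidationError(f"plot {p.plot_id}: area_m2 must be > 0")
        e = p.expansion_factor
        areas = [c.basal_area_m2() for c in culms]
        ba = e * sum(areas)
        qmd = math.sqrt(sum(c.dbh ** 2 for c in culms) / len(culms))
        new_plots.append(replace(p, ba=ba, qmd=qmd, n_per_ha=e * len(culms)))
        for c in culms:
            bal = e * sum(a for other, a in zip(culms, areas) if other.dbh > c.dbh)
            new_culms.append(replace(c, bal=bal, rd=c.dbh / qmd))

    # preserve original culm order
    order = {(c.block_id, c.plot_id, c.culm_id): i for i, c in enumerate(ds.culms)}
    new_culms.sort(key=lambda c: order[(c.block_id, c.plot_id, c.culm_id)])
    return Dataset(blocks=list(ds.blocks), plots=new_plots, culms=new_culms)


def dataset_to_frame(ds: Dataset) -> pd.DataFrame:
    """Flatten to a culm-level DataFrame (one row per culm, plot columns joined)."""
    plot_index = {(p.block_id, p.plot_id): p for p in ds.plots}
    rows = []
    for c in ds.culms:
        p = plot_index[(c.block_id, c.plot_id)]
        rows.append({
            "block": c.block_id, "plot": c.plot_id, "culm": c.culm_id,
            "dbh": c.dbh, "h": c.h, "hcb": c.hcb,
            "bal": c.bal, "rd": c.rd, "cd": p.cd,
            "age_du": c.age_du, "cw": c.cw,
            "area_m2": p.area_m2, "qmd": p.qmd, "ba": p.ba, "n_per_ha": p.n_per_ha,
        })
    return pd.DataFrame(rows)
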