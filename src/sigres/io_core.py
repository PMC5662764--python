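"""Shared experimental data model and readers/writers for the text formats
the pipeline touches.

Expression data travel as GCT 1.3 (the text container used for level-3
landmark matrices: 978 genes x wells plus well metadata); viable-cell counts
and drug annotations travel as headered CSV.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    InsufficientControlsError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Sentinel drug name for vehicle-control wells (matched case-insensitively).
VEHICLE = "DMSO"

#: Column-metadata fields required in every expression GCT.
REQUIRED_COL_META = (
    "plate_id",
    "well",
    "cell_line",
    "drug",
    "concentration",
    "time_h",
    "replicate",
)

_OPTIONAL_COL_META = ("target_class", "is_control")


@dataclass(frozen=True)
class WellMeta:
    """Metadata for a single well.

    ``drug2``/``concentration2`` are populated only for combination-treatment
    wells in count tables; expression wells are single-agent.
    """

    plate_id: str
    well: str
    cell_line: str
    drug: str
    concentration: float
    time_h: float
    replicate: int
    target_class: str | None = None
    is_control: bool | None = None
    drug2: str | None = None
    concentration2: float | None = None

    @property
    def is_vehicle(self) -> bool:
        # An explicit is_control flag wins over the drug-name convention.
        if self.is_control is not None:
            return self.is_control
        return self.drug.casefold() == VEHICLE.casefold()

    def validate(self) -> None:
        if self.replicate < 1:
            raise ValidationError(
                f"well {self.plate_id}:{self.well}: replicate must be >= 1"
            )
        if self.is_vehicle != (self.concentration == 0):
            raise ValidationError(
                f"well {self.plate_id}:{self.well}: concentration must be 0 "
                f"iff the well is a vehicle control "
                f"(drug={self.drug!r}, concentration={self.concentration})"
            )

    @property
    def condition_key(self) -> tuple[str, str, float, float]:
        return (self.cell_line, self.drug, self.concentration, self.time_h)


@dataclass
class ExpressionMatrix:
    """Genes x wells matrix of normalized expression with well metadata."""

    gene_ids: list[str]
    wells: list[WellMeta]
    values: np.ndarray
    row_meta: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    def validate(self) -> None:
        if self.values.shape != (self.n_genes, self.n_wells):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{self.n_genes} genes x {self.n_wells} wells"
            )
        if self.n_wells == 0:
            raise ValidationError("expression matrix has no wells")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")
        seen: set[tuple[str, str]] = set()
        for w in self.wells:
            w.validate()
            key = (w.plate_id, w.well)
            if key in seen:
                raise ValidationError(f"duplicate well {key}")
            seen.add(key)
        for name, vals in self.row_meta.items():
            if len(vals) != self.n_genes:
                raise ValidationError(
                    f"row metadata field {name!r} has length {len(vals)}, "
                    f"expected {self.n_genes}"
                )


@dataclass
class Condition:
    """Replicate treated vectors for one experimental condition in a batch."""

    key: tuple[str, str, float, float]  # (cell_line, drug, concentration, time_h)
    plate_ids: list[str]
    vectors: list[np.ndarray]
    complete: bool  # False when replicates were missing on some plates

    @property
    def J(self) -> int:
        return len(self.vectors)

    @property
    def scoreable(self) -> bool:
        return self.J >= 2


@dataclass
class PlateBatch:
    """Replicate plates for one cell line x time point.

    ``controls[plate]`` is the G x N matrix of vehicle wells on that plate;
    each condition carries one treated vector per plate it appears on.
    """

    cell_line: str
    time_h: float
    plate_ids: list[str]
    conditions: dict[tuple[str, str, float, float], Condition]
    controls: dict[str, np.ndarray]

    @property
    def M(self) -> int:
        return len(self.conditions)

    @property
    def J(self) -> int:
        return len(self.plate_ids)

    @property
    def N(self) -> int:
        return min(c.shape[1] for c in self.controls.values())


def _parse_bool(text: str) -> bool:
    t = text.strip().casefold()
    if t in ("1", "true", "yes"):
        return True
    if t in ("0", "false", "no"):
        return False
    raise FormatError(f"cannot parse boolean value {text!r}")


def _format_value(x: float) -> str:
    return format(float(x), ".6f").rstrip("0").rstrip(".")


# ---------------------------------------------------------------------------
# GCT 1.3
# ---------------------------------------------------------------------------

def read_gct(path) -> ExpressionMatrix:
    """Parse a GCT 1.3 text file into an :class:`ExpressionMatrix`.

    The four header counts are validated against the actual content and the
    required well-metadata fields must be present as column metadata rows.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    version = lines[0].strip()
    if version == "#1.2":
        raise FormatError(
            f"{path}: line 1: GCT 1.2 is not supported; the pipeline requires "
            "the 1.3 dialect with column-metadata rows"
        )
    if version != "#1.3":
        raise FormatError(f"{path}: line 1: expected '#1.3', got {version!r}")
    if len(lines) < 3:
        raise FormatError(f"{path}: line 2: missing dimension line")
    dims = lines[1].split("\t")
    if len(dims) != 4:
        raise FormatError(
            f"{path}: line 2: expected 4 tab-separated dimension counts, "
            f"got {len(dims)}"
        )
    try:
        n_rows, n_cols, n_rmeta, n_cmeta = (int(d) for d in dims)
    except ValueError as exc:
        raise FormatError(f"{path}: line 2: non-integer dimension: {exc}") from exc
    if n_cols < 1:
        raise FormatError(f"{path}: line 2: GCT requires at least one data column")

    header = lines[2].split("\t")
    expected_header_len = 1 + n_rmeta + n_cols
    if len(header) != expected_header_len:
        raise FormatError(
            f"{path}: line 3: expected {expected_header_len} header fields "
            f"(id + {n_rmeta} row-meta + {n_cols} columns), got {len(header)}"
        )
    rmeta_names = header[1 : 1 + n_rmeta]
    col_ids = header[1 + n_rmeta :]

    body = lines[3:]
    # Trailing blank lines are tolerated; interior ones are not.
    while body and not body[-1].strip():
        body.pop()
    if len(body) != n_cmeta + n_rows:
        raise FormatError(
            f"{path}: declared {n_cmeta} column-metadata rows + {n_rows} data "
            f"rows but found {len(body)} content lines after the header"
        )

    col_meta: dict[str, list[str]] = {}
    for i in range(n_cmeta):
        fields_ = body[i].split("\t")
        if len(fields_) != expected_header_len:
            raise FormatError(
                f"{path}: line {4 + i}: column-metadata row has "
                f"{len(fields_)} fields, expected {expected_header_len}"
            )
        col_meta[fields_[0]] = fields_[1 + n_rmeta :]

    missing = [f for f in REQUIRED_COL_META if f not in col_meta]
    if missing:
        raise FormatError(
            f"{path}: missing required column-metadata field(s): "
            + ", ".join(missing)
        )

    gene_ids: list[str] = []
    row_meta: dict[str, list[str]] = {name: [] for name in rmeta_names}
    values = np.empty((n_rows, n_cols), dtype=float)
    for r in range(n_rows):
        lineno = 4 + n_cmeta + r
        fields_ = body[n_cmeta + r].split("\t")
        if len(fields_) != expected_header_len:
            raise FormatError(
                f"{path}: line {lineno}: data row has {len(fields_)} fields, "
                f"expected {expected_header_len}"
            )
        gene_ids.append(fields_[0])
        for name, val in zip(rmeta_names, fields_[1 : 1 + n_rmeta]):
            row_meta[name].append(val)
        try:
            values[r, :] = [float(v) for v in fields_[1 + n_rmeta :]]
        except ValueError as exc:
            raise FormatError(
                f"{path}: line {lineno}: non-numeric value: {exc}"
            ) from exc

    wells = []
    for c in range(n_cols):
        tc = col_meta.get("target_class", [""] * n_cols)[c].strip()
        is_ctrl_raw = col_meta.get("is_control", [""] * n_cols)[c].strip()
        try:
            wells.append(
                WellMeta(
                    plate_id=col_meta["plate_id"][c],
                    well=col_meta["well"][c],
                    cell_line=col_meta["cell_line"][c],
                    drug=col_meta["drug"][c],
                    concentration=float(col_meta["concentration"][c]),
                    time_h=float(col_meta["time_h"][c]),
                    replicate=int(col_meta["replicate"][c]),
                    target_class=tc or None,
                    is_control=_parse_bool(is_ctrl_raw) if is_ctrl_raw else None,
                )
            )
        except ValueError as exc:
            raise FormatError(
                f"{path}: column {col_ids[c]!r}: bad metadata value: {exc}"
            ) from exc

    matrix = ExpressionMatrix(
        gene_ids=gene_ids, wells=wells, values=values, row_meta=row_meta
    )
    matrix.validate()
    logger.info(
        "read_gct: %s -> %d genes x %d wells", path, n_rows, n_cols
    )
    return matrix


def write_gct(matrix: ExpressionMatrix, path) -> None:
    """Write an :class:`ExpressionMatrix` as GCT 1.3 text."""
    matrix.validate()
    n_rows, n_cols = matrix.n_genes, matrix.n_wells
    rmeta_names = list(matrix.row_meta)
    n_rmeta = len(rmeta_names)

    cmeta_names = list(REQUIRED_COL_META)
    if any(w.target_class is not None for w in matrix.wells):
        cmeta_names.append("target_class")
    if any(w.is_control is not None for w in matrix.wells):
        cmeta_names.append("is_control")

    def cmeta_value(w: WellMeta, name: str) -> str:
        v = getattr(w, name)
        if v is None:
            return ""
        if name in ("concentration", "time_h"):
            return _format_value(v)
        if name == "is_control":
            return "true" if v else "false"
        return str(v)

    col_ids = [f"{w.plate_id}:{w.well}" for w in matrix.wells]
    out: list[str] = ["#1.3"]
    out.append("\t".join(str(n) for n in (n_rows, n_cols, n_rmeta, len(cmeta_names))))
    out.append("\t".join(["id", *rmeta_names, *col_ids]))
    for name in cmeta_names:
        out.append(
            "\t".join(
                [name, *([""] * n_rmeta),
                 *(cmeta_value(w, name) for w in matrix.wells)]
            )
        )
    for r in range(n_rows):
        rm = [matrix.row_meta[name][r] for name in rmeta_names]
        vals = [_format_value(v) for v in matrix.values[r]]
        out.append("\t".join([matrix.gene_ids[r], *rm, *vals]))
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\n".join(out) + "\n")
    logger.info("write_gct: %d genes x %d wells -> %s", n_rows, n_cols, path)


# ---------------------------------------------------------------------------
# Batch assembly
# ---------------------------------------------------------------------------

def assemble_batches(matrix: ExpressionMatrix) -> list[PlateBatch]:
    """Partition wells into one :class:`PlateBatch` per (cell line, time point).

    Conditions missing replicates on some plates are retained with reduced J
    and flagged incomplete; conditions with J < 2 are kept but marked
    unscoreable (excluded from consistency scoring downstream).
    """
    matrix.validate()
    groups: dict[tuple[str, float], list[int]] = {}
    for idx, w in enumerate(matrix.wells):
        groups.setdefault((w.cell_line, w.time_h), []).append(idx)

    batches: list[PlateBatch] = []
    for (cell_line, time_h), col_idx in sorted(groups.items()):
        plate_ids = sorted({matrix.wells[i].plate_id for i in col_idx})
        controls: dict[str, np.ndarray] = {}
        for pid in plate_ids:
            ctrl_cols = [
                i for i in col_idx
                if matrix.wells[i].plate_id == pid and matrix.wells[i].is_vehicle
            ]
            if len(ctrl_cols) < 2:
                raise InsufficientControlsError(
                    f"plate {pid} ({cell_line} @ {time_h} h) has "
                    f"{len(ctrl_cols)} vehicle-control wells; >= 2 required"
                )
            controls[pid] = matrix.values[:, ctrl_cols]

        per_cond: dict[tuple, dict[str, np.ndarray]] = {}
        for i in col_idx:
            w = matrix.wells[i]
            if w.is_vehicle:
                continue
            per_cond.setdefault(w.condition_key, {})[w.plate_id] = matrix.values[:, i]

        conditions: dict[tuple, Condition] = {}
        n_incomplete = 0
        for key, by_plate in per_cond.items():
            present = [p for p in plate_ids if p in by_plate]
            complete = len(present) == len(plate_ids)
            if not complete:
                n_incomplete += 1
            cond = Condition(
                key=key,
                plate_ids=present,
                vectors=[by_plate[p] for p in present],
                complete=complete,
            )
            if not cond.scoreable:
                logger.warning(
                    "condition %s has J=%d replicate(s); excluded from "
                    "consistency scoring", key, cond.J,
                )
            conditions[key] = cond

        logger.info(
            "assemble_batches: %s @ %s h -> %d plates, %d conditions "
            "(%d incomplete)",
            cell_line, time_h, len(plate_ids), len(conditions), n_incomplete,
        )
        batches.append(
            PlateBatch(
                cell_line=cell_line,
                time_h=time_h,
                plate_ids=plate_ids,
                conditions=conditions,
                controls=controls,
            )
        )
    return batches


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

COUNT_COLUMNS = [
    "plate_id", "well", "cell_line", "drug", "concentration", "time_h",
    "replicate", "target_class", "drug2", "concentration2", "count",
]


@dataclass
class CountTable:
    """Viable-cell counts: treated/control wells plus a day-0 plate.

    Backed by a tidy DataFrame with :data:`COUNT_COLUMNS`. Day-0 rows are
    vehicle wells at ``time_h == 0``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COUNT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"count table missing column(s): {missing}")
        df = self.data[COUNT_COLUMNS].copy()
        # normalize optional columns so in-memory and CSV round-trips agree
        for col in ("target_class", "drug2"):
            df[col] = df[col].where(df[col].notna(), np.nan).astype(object)
            df.loc[df[col].isna(), col] = np.nan
        for col in ("concentration", "concentration2", "time_h", "count"):
            df[col] = df[col].astype(float)
        self.data = df

    def validate(self) -> None:
        if (self.data["count"] < 0).any():
            raise ValidationError("count table contains negative counts")
        if self.data["count"].isna().any():
            raise ValidationError("count table contains missing counts")
        treated = self.treated()
        for (cell_line, plate), grp in treated.groupby(["cell_line", "plate_id"]):
            ctrl = self.data[
                (self.data["cell_line"] == cell_line)
                & (self.data["plate_id"] == plate)
                & (self.data["drug"].str.casefold() == VEHICLE.casefold())
                & (self.data["time_h"] > 0)
            ]
            if ctrl.empty:
                raise ValidationError(
                    f"no vehicle-control counts on plate {plate} for "
                    f"{cell_line}"
                )
        for cell_line in treated["cell_line"].unique():
            if len(self.day0_counts(cell_line)) == 0:
                raise ValidationError(f"no day-0 plate for {cell_line}")

    def treated(self) -> pd.DataFrame:
        d = self.data
        return d[(d["drug"].str.casefold() != VEHICLE.casefold()) & (d["time_h"] > 0)]

    def day0_counts(self, cell_line: str) -> np.ndarray:
        d = self.data
        mask = (d["cell_line"] == cell_line) & (d["time_h"] == 0)
        return d.loc[mask, "count"].to_numpy(dtype=float)

    def controls(self, cell_line: str, plate_id: str) -> np.ndarray:
        d = self.data
        mask = (
            (d["cell_line"] == cell_line)
            & (d["plate_id"] == plate_id)
            & (d["drug"].str.casefold() == VEHICLE.casefold())
            & (d["time_h"] > 0)
        )
        return d.loc[mask, "count"].to_numpy(dtype=float)


def read_counts_csv(path) -> CountTable:
    df = pd.read_csv(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    table = CountTable(df)
    table.validate()
    logger.info("read_counts_csv: %s -> %d rows", path, len(df))
    return table


def write_counts_csv(table: CountTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_drug_annotations(path) -> dict[str, str]:
    """Read a drug -> target-class CSV (columns ``drug,target_class``)."""
    out: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "drug", "target_class"
        } <= set(reader.fieldnames):
            raise FormatError(
                f"{path}: expected header with 'drug' and 'target_class'"
            )
        for row in reader:
            out[row["drug"]] = row["target_class"]
    return out
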