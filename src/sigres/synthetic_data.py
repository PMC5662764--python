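"""Synthetic expression batches, count tables and combination checkerboards
with known ground truth.

The generator emulates the screening design the pipeline assumes: multiple
cell lines x drugs x a 6-point dose series (250-fold range) x two expression
time points, replicated across plates that each carry their own vehicle
controls. Drug classes plant either one universal response direction shared
by all cell lines or one direction per cell line; response amplitude rises
with dose; counts follow sigmoidal GR curves. Everything is deterministic
given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import VEHICLE, CountTable, ExpressionMatrix, WellMeta

logger = logging.getLogger(__name__)

DEFAULT_DOSES = tuple(float(d) for d in np.geomspace(0.04, 10.0, 6))  # 250-fold

COMBO_MODES = ("bliss_independent", "synergistic", "antagonistic")


@dataclass
class SimulationConfig:
    n_genes: int = 978
    n_cell_lines: int = 3
    n_drugs: int = 12
    n_classes: int = 4
    doses: tuple[float, ...] = DEFAULT_DOSES
    time_points: tuple[float, ...] = (3.0, 24.0)
    J: int = 3                      # replicate plates
    N: int = 8                      # vehicle-control wells per plate
    effect_size: float = 1.0
    shared_fraction: float = 0.5    # fraction of classes with a universal direction
    noise_sd: float = 0.1
    baseline_sd: float = 1.0
    plate_effect_sd: float = 0.5
    amplitude_hill: float = 1.0
    amplitude_k: float | None = None     # half-max dose; default geometric mid-dose
    n_rotation_classes: int = 0          # classes whose direction rotates with dose
    rotation_max_deg: float = 60.0
    # Per-line amplitude multiplier range for cell-line-specific classes:
    # specific responses differ across lines in magnitude as well as
    # direction; universal classes always use multiplier 1.
    specific_amplitude_range: tuple[float, float] = (0.25, 1.0)
    gr_params: dict | None = None        # (drug, cell_line) -> (GR_inf, GEC50, hill)
    count_noise_sd: float = 0.05         # log-normal sigma on counts
    division_time_h: float = 24.0
    day0_count: float = 2000.0
    n_day0_wells: int = 16
    count_time_h: float = 72.0
    planted_eob: float = 0.3
    seed: int | None = 0

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        if doses.size < 2 or np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError(
                f"shared_fraction must be in [0, 1], got {self.shared_fraction}"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.day0_count <= 0:
            raise ValueError("day-0 count must be positive")
        if self.n_classes > self.n_drugs:
            raise ValueError("cannot have more classes than drugs")

    @property
    def cell_lines(self) -> list[str]:
        return [f"CL{i + 1}" for i in range(self.n_cell_lines)]

    @property
    def drugs(self) -> list[str]:
        return [f"D{i + 1:03d}" for i in range(self.n_drugs)]

    @property
    def classes(self) -> list[str]:
        return [f"class{i + 1}" for i in range(self.n_classes)]

    def class_of(self, drug: str) -> str:
        return self.classes[self.drugs.index(drug) % self.n_classes]

    def amplitude(self, dose: float) -> float:
        k = self.amplitude_k
        if k is None:
            doses = np.asarray(self.doses)
            k = float(np.exp(np.mean(np.log(doses))))
        h = self.amplitude_hill
        return self.effect_size * dose**h / (dose**h + k**h)


@dataclass
class GroundTruth:
    """Planted structure for recovery oracles."""

    directions: dict[tuple[str, str], np.ndarray]  # (class, cell_line or "*") -> unit vec
    class_of_drug: dict[str, str]
    universal_classes: set[str]
    rotation_classes: set[str]
    cluster_label: dict[tuple, tuple[str, str]]    # condition key -> (class, line or "*")
    line_amplitude: dict[tuple[str, str], float] = field(default_factory=dict)
    gr_params: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=dict
    )
    synergy: dict[tuple[str, str], float] = field(default_factory=dict)

    def direction_for(
        self, drug: str, cell_line: str
    ) -> np.ndarray:
        cls = self.class_of_drug[drug]
        key = (cls, "*") if (cls, "*") in self.directions else (cls, cell_line)
        return self.directions[key]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _plant_directions(
    config: SimulationConfig, rng: np.random.Generator
) -> GroundTruth:
    n_universal = round(config.shared_fraction * config.n_classes)
    universal = set(config.classes[:n_universal])
    rotation = set(config.classes[-config.n_rotation_classes:]) if (
        config.n_rotation_classes > 0
    ) else set()
    directions: dict[tuple[str, str], np.ndarray] = {}
    line_amplitude: dict[tuple[str, str], float] = {}
    lo, hi = config.specific_amplitude_range
    for cls in config.classes:
        if cls in universal:
            directions[(cls, "*")] = _unit(rng.standard_normal(config.n_genes))
            for line in config.cell_lines:
                line_amplitude[(cls, line)] = 1.0
        else:
            for line in config.cell_lines:
                directions[(cls, line)] = _unit(rng.standard_normal(config.n_genes))
                line_amplitude[(cls, line)] = float(rng.uniform(lo, hi))
    return GroundTruth(
        directions=directions,
        class_of_drug={d: config.class_of(d) for d in config.drugs},
        universal_classes=universal,
        rotation_classes=rotation,
        cluster_label={},
        line_amplitude=line_amplitude,
    )


def _rotated(
    base: np.ndarray,
    orth_seedvec: np.ndarray,
    dose_idx: int,
    n_doses: int,
    max_deg: float,
) -> np.ndarray:
    """Rotate ``base`` toward an orthogonal companion as dose rises."""
    orth = orth_seedvec - (orth_seedvec @ base) * base
    orth = _unit(orth)
    theta = np.deg2rad(max_deg) * dose_idx / max(n_doses - 1, 1)
    return np.cos(theta) * base + np.sin(theta) * orth


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Expression wells for every cell line, time point and replicate plate.

    Per well: ``baseline(gene, line) + plate_effect + amplitude(dose) *
    planted_direction + N(0, noise_sd)``. Vehicle wells omit the signal term.
    """
    rng = np.random.default_rng(config.seed)
    truth = _plant_directions(config, rng)
    orth_seeds = {
        cls: rng.standard_normal(config.n_genes) for cls in truth.rotation_classes
    }
    baselines = {
        line: rng.normal(0.0, config.baseline_sd, config.n_genes)
        for line in config.cell_lines
    }

    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    wells: list[WellMeta] = []
    columns: list[np.ndarray] = []
    n_doses = len(config.doses)

    for line in config.cell_lines:
        base = baselines[line]
        for time_h in config.time_points:
            for j in range(1, config.J + 1):
                plate_id = f"{line}_T{int(time_h)}_P{j}"
                plate_effect = rng.normal(0.0, config.plate_effect_sd)
                for w in range(config.N):
                    wells.append(
                        WellMeta(
                            plate_id=plate_id,
                            well=f"ctl{w + 1:02d}",
                            cell_line=line,
                            drug=VEHICLE,
                            concentration=0.0,
                            time_h=time_h,
                            replicate=j,
                        )
                    )
                    columns.append(
                        base + plate_effect
                        + rng.normal(0.0, config.noise_sd, config.n_genes)
                    )
                for drug in config.drugs:
                    cls = truth.class_of_drug[drug]
                    direction = truth.direction_for(drug, line)
                    for d_idx, dose in enumerate(config.doses):
                        if cls in truth.rotation_classes:
                            signal_dir = _rotated(
                                direction, orth_seeds[cls], d_idx, n_doses,
                                config.rotation_max_deg,
                            )
                        else:
                            signal_dir = direction
                        key = (line, drug, float(dose), time_h)
                        label_line = "*" if cls in truth.universal_classes else line
                        truth.cluster_label[key] = (cls, label_line)
                        wells.append(
                            WellMeta(
                                plate_id=plate_id,
                                well=f"{drug}_c{d_idx + 1}",
                                cell_line=line,
                                drug=drug,
                                concentration=float(dose),
                                time_h=time_h,
                                replicate=j,
                                target_class=cls,
                            )
                        )
                        mult = truth.line_amplitude[(cls, line)]
                        columns.append(
                            base + plate_effect
                            + mult * config.amplitude(dose) * signal_dir
                            + rng.normal(0.0, config.noise_sd, config.n_genes)
                        )

    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        wells=wells,
        values=np.column_stack(columns),
    )
    matrix.validate()
    logger.info(
        "simulate_expression: %d wells (%d lines x %d drugs x %d doses x "
        "%d times x %d plates)",
        matrix.n_wells, config.n_cell_lines, config.n_drugs, n_doses,
        len(config.time_points), config.J,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def gr_curve_value(c: float, gr_inf: float, gec50: float, hill: float) -> float:
    return gr_inf + (1.0 - gr_inf) / (1.0 + (c / gec50) ** hill)


def make_gr_params(
    config: SimulationConfig,
) -> dict[tuple[str, str], tuple[float, float, float]]:
    """Random but seed-deterministic GR curve parameters per (drug, line)."""
    rng = np.random.default_rng(
        None if config.seed is None else config.seed + 1_000_003
    )
    doses = np.asarray(config.doses)
    params = {}
    for drug in config.drugs:
        for line in config.cell_lines:
            gr_inf = float(rng.uniform(-0.5, 0.9))
            gec50 = float(
                np.exp(rng.uniform(np.log(doses[1]), np.log(doses[-2])))
            )
            hill = float(rng.uniform(0.8, 2.5))
            params[(drug, line)] = (gr_inf, gec50, hill)
    return params


def _count_from_gr(
    gr: float, x0: float, x_ctrl: float
) -> float:
    """Invert the GR transform: the treated count that yields ``gr``."""
    if gr <= -1.0:
        raise ValueError(f"GR={gr} <= -1 cannot be realized by a positive count")
    return x0 * 2.0 ** (np.log2(1.0 + gr) * np.log2(x_ctrl / x0))


def simulate_counts(config: SimulationConfig) -> CountTable:
    """Viable-cell counts: a day-0 plate plus J treated plates per cell line.

    Controls grow exponentially from the day-0 baseline at the cell line's
    division rate; treated counts satisfy the planted sigmoidal GR curve
    before multiplicative log-normal noise.
    """
    params = config.gr_params if config.gr_params is not None else make_gr_params(config)
    for drug in config.drugs:
        for line in config.cell_lines:
            if (drug, line) not in params:
                raise ValueError(f"gr_params missing for {(drug, line)}")
    rng = np.random.default_rng(
        None if config.seed is None else config.seed + 2_000_003
    )
    t = config.count_time_h
    x0 = config.day0_count
    x_ctrl_true = x0 * 2.0 ** (t / config.division_time_h)

    def noisy(x: float) -> float:
        return float(x * np.exp(rng.normal(0.0, config.count_noise_sd)))

    rows = []
    for line in config.cell_lines:
        for w in range(config.n_day0_wells):
            rows.append(
                _count_row(f"{line}_day0", f"d{w + 1:02d}", line, VEHICLE, 0.0,
                           0.0, 1, None, noisy(x0))
            )
        for j in range(1, config.J + 1):
            plate = f"{line}_CT_P{j}"
            for w in range(config.N):
                rows.append(
                    _count_row(plate, f"ctl{w + 1:02d}", line, VEHICLE, 0.0,
                               t, j, None, noisy(x_ctrl_true))
                )
            for drug in config.drugs:
                gr_inf, gec50, hill = params[(drug, line)]
                for d_idx, dose in enumerate(config.doses):
                    gr = gr_curve_value(dose, gr_inf, gec50, hill)
                    x = _count_from_gr(gr, x0, x_ctrl_true)
                    rows.append(
                        _count_row(plate, f"{drug}_c{d_idx + 1}", line, drug,
                                   float(dose), t, j, config.class_of(drug),
                                   noisy(x))
                    )
    table = CountTable(pd.DataFrame(rows))
    table.validate()
    logger.info("simulate_counts: %d rows", len(table.data))
    return table


def _count_row(plate, well, line, drug, conc, time_h, rep, target_class, count,
               drug2=None, conc2=None) -> dict:
    return {
        "plate_id": plate, "well": well, "cell_line": line, "drug": drug,
        "concentration": conc, "time_h": time_h, "replicate": rep,
        "target_class": target_class, "drug2": drug2, "concentration2": conc2,
        "count": count,
    }


def bliss_gr(gr_a: float, gr_b: float) -> float:
    """Combination GR predicted by Bliss independence on the 1 - GR scale."""
    ea, eb = 1.0 - gr_a, 1.0 - gr_b
    return 1.0 - (ea + eb - ea * eb)


def simulate_combo(
    config: SimulationConfig,
    mode: str,
    drug_a: str | None = None,
    drug_b: str | None = None,
    cell_line: str | None = None,
) -> CountTable:
    """Checkerboard count table for a two-drug combination.

    ``bliss_independent`` realizes the Bliss prediction exactly before noise;
    ``synergistic``/``antagonistic`` add +/- ``config.planted_eob`` to the
    combination effect on the (1 - GR) scale. Margins (single-agent wells at
    every dose) and vehicle controls are included on every plate.
    """
    if mode not in COMBO_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {COMBO_MODES}")
    drug_a = drug_a or config.drugs[0]
    drug_b = drug_b or config.drugs[1]
    if drug_a == drug_b:
        raise ValueError("combination requires two distinct drugs")
    cell_line = cell_line or config.cell_lines[0]
    params = config.gr_params if config.gr_params is not None else make_gr_params(config)
    for d in (drug_a, drug_b):
        if (d, cell_line) not in params:
            raise ValueError(f"gr_params missing for {(d, cell_line)}")
    eob_shift = {
        "bliss_independent": 0.0,
        "synergistic": config.planted_eob,
        "antagonistic": -config.planted_eob,
    }[mode]
    rng = np.random.default_rng(
        None if config.seed is None else config.seed + 3_000_003
    )
    t = config.count_time_h
    x0 = config.day0_count
    x_ctrl_true = x0 * 2.0 ** (t / config.division_time_h)

    def noisy(x: float) -> float:
        return float(x * np.exp(rng.normal(0.0, config.count_noise_sd)))

    def single_gr(drug: str, dose: float) -> float:
        return gr_curve_value(dose, *params[(drug, cell_line)])

    rows = []
    for w in range(config.n_day0_wells):
        rows.append(
            _count_row(f"{cell_line}_day0", f"d{w + 1:02d}", cell_line, VEHICLE,
                       0.0, 0.0, 1, None, noisy(x0))
        )
    for j in range(1, config.J + 1):
        plate = f"{cell_line}_CB_P{j}"
        for w in range(config.N):
            rows.append(
                _count_row(plate, f"ctl{w + 1:02d}", cell_line, VEHICLE, 0.0,
                           t, j, None, noisy(x_ctrl_true))
            )
        for ia, ca in enumerate(config.doses):
            rows.append(
                _count_row(plate, f"A_c{ia + 1}", cell_line, drug_a, float(ca),
                           t, j, config.class_of(drug_a),
                           noisy(_count_from_gr(single_gr(drug_a, ca), x0,
                                                x_ctrl_true)))
            )
        for ib, cb in enumerate(config.doses):
            rows.append(
                _count_row(plate, f"B_c{ib + 1}", cell_line, drug_b, float(cb),
                           t, j, config.class_of(drug_b),
                           noisy(_count_from_gr(single_gr(drug_b, cb), x0,
                                                x_ctrl_true)))
            )
        for ia, ca in enumerate(config.doses):
            for ib, cb in enumerate(config.doses):
                gr_ab = bliss_gr(single_gr(drug_a, ca), single_gr(drug_b, cb))
                gr_ab = max(gr_ab - eob_shift, -0.95)
                rows.append(
                    _count_row(plate, f"AB_c{ia + 1}x{ib + 1}", cell_line,
                               drug_a, float(ca), t, j,
                               config.class_of(drug_a),
                               noisy(_count_from_gr(gr_ab, x0, x_ctrl_true)),
                               drug2=drug_b, conc2=float(cb))
                )
    table = CountTable(pd.DataFrame(rows))
    table.validate()
    return table
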