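"""Drug-combination scoring on the GR scale: excess over Bliss independence.

On the effect scale e = 1 - GR, Bliss independence predicts
``e_AB = e_A + e_B - e_A * e_B``; the excess-over-Bliss score is the observed
combination effect minus that prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gr_metrics import gr_value, trimmed_mean_day0
from .io_core import CountTable

logger = logging.getLogger(__name__)


@dataclass
class SynergyResult:
    drugs: tuple[str, str]
    doses: tuple[float, float]
    eob_mean: float
    eob_se: float | None
    p_value: float | None
    n_replicates: int
    zero_variance: bool = False


def eob_gr(gr_a, gr_b, gr_ab):
    """(1 - GR_AB) - (1 - GR_A) - (1 - GR_B) + (1 - GR_A)(1 - GR_B).

    Zero exactly at the Bliss-independent prediction; positive = synergy,
    negative = antagonism. Accepts scalars or broadcastable arrays.
    """
    ea = 1.0 - np.asarray(gr_a, dtype=float)
    eb = 1.0 - np.asarray(gr_b, dtype=float)
    eab = 1.0 - np.asarray(gr_ab, dtype=float)
    out = eab - ea - eb + ea * eb
    return float(out) if out.ndim == 0 else out


def checkerboard_eob(
    grid: np.ndarray,
    doses_a: np.ndarray,
    doses_b: np.ndarray,
    margin_a: dict[float, float],
    margin_b: dict[float, float],
) -> np.ndarray:
    """Element-wise excess over Bliss for a dose-pair grid of combination GR.

    ``grid[i, j]`` is the combination GR at (doses_a[i], doses_b[j]);
    ``margin_a``/``margin_b`` map single-agent doses to single-agent GR
    (dose 0 maps to GR 1 implicitly).
    """
    grid = np.asarray(grid, dtype=float)
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    if grid.shape != (doses_a.size, doses_b.size):
        raise ValueError(
            f"grid shape {grid.shape} does not match dose axes "
            f"({doses_a.size}, {doses_b.size})"
        )

    def lookup(margin: dict[float, float], dose: float, name: str) -> float:
        if dose == 0:
            return 1.0
        if dose not in margin:
            raise KeyError(f"missing single-agent GR for drug {name} at {dose}")
        return margin[dose]

    ga = np.array([lookup(margin_a, d, "A") for d in doses_a])
    gb = np.array([lookup(margin_b, d, "B") for d in doses_b])
    return eob_gr(ga[:, None], gb[None, :], grid)


def synergy_test(eob_replicates) -> tuple[float, float | None, float | None, bool]:
    """One-sample two-sided t-test of per-replicate EOB against zero.

    Returns ``(mean, se, p, zero_variance)``. With a single replicate the
    test is skipped (se and p are None); with zero variance p is reported
    as 1 and flagged.
    """
    vals = np.asarray(eob_replicates, dtype=float)
    n = vals.size
    if n == 0:
        raise ValueError("no replicate EOB values")
    mean = float(vals.mean())
    if n < 2:
        logger.warning("synergy_test: single replicate, no test performed")
        return mean, None, None, False
    sd = float(vals.std(ddof=1))
    se = sd / np.sqrt(n)
    if sd == 0.0:
        return mean, 0.0, 1.0, True
    t_res = stats.ttest_1samp(vals, 0.0)
    return mean, se, float(t_res.pvalue), False


def score_combination(
    drugs: tuple[str, str],
    doses: tuple[float, float],
    gr_a_reps,
    gr_b_reps,
    gr_ab_reps,
) -> SynergyResult:
    """Per-replicate EOB at one dose pair, with replicate-level significance."""
    eobs = eob_gr(
        np.asarray(gr_a_reps, dtype=float),
        np.asarray(gr_b_reps, dtype=float),
        np.asarray(gr_ab_reps, dtype=float),
    )
    eobs = np.atleast_1d(eobs)
    mean, se, p, flat = synergy_test(eobs)
    return SynergyResult(
        drugs=drugs,
        doses=doses,
        eob_mean=mean,
        eob_se=se,
        p_value=p,
        n_replicates=eobs.size,
        zero_variance=flat,
    )


def checkerboard_from_counts(counts: CountTable) -> list[SynergyResult]:
    """Score every combination dose pair in a checkerboard count table.

    The table must hold, per replicate plate, single-agent margin wells for
    both drugs plus combination wells (``drug2``/``concentration2`` set).
    Each plate is one replicate; EOB is computed per plate and tested across
    plates.
    """
    data = counts.data
    combo_rows = data[data["drug2"].notna()]
    if combo_rows.empty:
        raise ValueError("count table contains no combination wells")
    results = []
    for (cell_line, drug_a, drug_b), sub in combo_rows.groupby(
        ["cell_line", "drug", "drug2"], sort=True
    ):
        x0 = trimmed_mean_day0(counts.day0_counts(cell_line))
        singles = data[
            (data["cell_line"] == cell_line)
            & data["drug2"].isna()
            & (data["time_h"] > 0)
        ]

        def plate_gr(plate: str, drug: str, dose: float) -> float:
            x_ctrl = float(counts.controls(cell_line, plate).mean())
            m = singles[
                (singles["plate_id"] == plate)
                & (singles["drug"] == drug)
                & (singles["concentration"] == dose)
            ]
            if m.empty:
                raise KeyError(
                    f"missing single-agent margin for {drug} at {dose} "
                    f"on plate {plate}"
                )
            return gr_value(float(m["count"].mean()), x_ctrl, x0)

        for (ca, cb), cells in sub.groupby(
            ["concentration", "concentration2"], sort=True
        ):
            eobs = []
            for plate, grp in cells.groupby("plate_id"):
                x_ctrl = float(counts.controls(cell_line, plate).mean())
                gr_ab = gr_value(float(grp["count"].mean()), x_ctrl, x0)
                eobs.append(
                    eob_gr(plate_gr(plate, drug_a, ca),
                           plate_gr(plate, drug_b, cb), gr_ab)
                )
            mean, se, p, flat = synergy_test(eobs)
            results.append(
                SynergyResult(
                    drugs=(drug_a, drug_b),
                    doses=(float(ca), float(cb)),
                    eob_mean=mean,
                    eob_se=se,
                    p_value=p,
                    n_replicates=len(eobs),
                    zero_variance=flat,
                )
            )
    return results
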