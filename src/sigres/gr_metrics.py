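"""Growth-rate inhibition (GR) metrics from viable-cell counts.

GR rescales a treated count by the growth of same-plate vehicle controls
relative to a day-0 baseline: 1 = untreated growth rate, 0 = cytostasis,
negative = cytotoxicity. Summaries are GR_AOC (mean of 1 - GR across the
tested doses) and an optional sigmoidal fit (GR_inf, GEC50, hill).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_core import CountTable

logger = logging.getLogger(__name__)


@dataclass
class DoseResponseProfile:
    cell_line: str
    drug: str
    doses: np.ndarray
    gr: np.ndarray
    gr_aoc: float
    fit: tuple[float, float, float] | None = None  # (GR_inf, GEC50, hill)
    fit_converged: bool = False


def trimmed_mean_day0(counts) -> float:
    """50%-trimmed mean: drop floor(n/4) values from each end, mean the rest."""
    arr = np.sort(np.asarray(counts, dtype=float))
    if arr.size == 0:
        raise ValueError("day-0 counts are empty")
    if np.any(arr < 0):
        raise ValueError("day-0 counts must be >= 0")
    cut = arr.size // 4
    return float(arr[cut : arr.size - cut].mean())


def gr_value(x_c: float, x_ctrl: float, x_0: float) -> float:
    """GR = 2^[log2(x_c/x_0) / log2(x_ctrl/x_0)] - 1."""
    if x_c <= 0 or x_ctrl <= 0 or x_0 <= 0:
        raise ValueError("counts must be positive")
    if x_ctrl == x_0:
        raise ZeroDivisionError(
            "controls did not grow relative to day 0; GR normalization undefined"
        )
    exponent = math.log2(x_c / x_0) / math.log2(x_ctrl / x_0)
    return 2.0**exponent - 1.0


def gr_aoc(gr_values) -> float:
    """Mean of (1 - GR) over the tested doses (0 = no response)."""
    gr = np.asarray(gr_values, dtype=float)
    return float(np.mean(1.0 - gr))


def gr_curve(c, gr_inf: float, gec50: float, hill: float):
    """Sigmoidal GR dose-response: GR_inf + (1 - GR_inf)/(1 + (c/GEC50)^hill)."""
    c = np.asarray(c, dtype=float)
    return gr_inf + (1.0 - gr_inf) / (1.0 + (c / gec50) ** hill)


def fit_gr_curve(
    doses,
    gr_values,
    alpha: float = 0.05,
) -> tuple[tuple[float, float, float], bool]:
    """Bounded least-squares fit of the sigmoidal GR curve.

    Multi-start over a GEC50 grid spanning the tested range x [0.01, 100].
    Falls back to a flat line (GR_inf = mean GR, degenerate GEC50) when the
    sigmoid does not beat the flat fit in an F-test at ``alpha`` or when no
    start converges. Returns ``((GR_inf, GEC50, hill), converged)``.
    """
    doses = np.asarray(doses, dtype=float)
    gr = np.asarray(gr_values, dtype=float)
    if doses.size < 4:
        raise ValueError("need >= 4 doses to fit a GR curve")
    lo, hi = doses.min() * 0.01, doses.max() * 100.0
    bounds = ([-1.0, lo, 0.1], [1.0, hi, 5.0])

    best = None
    for gec0 in np.geomspace(lo * 1.01, hi * 0.99, 7):
        p0 = [float(np.clip(gr.min(), -1, 1)), gec0, 1.0]
        try:
            popt, _ = optimize.curve_fit(
                gr_curve, doses, gr, p0=p0, bounds=bounds, maxfev=5000
            )
        except RuntimeError:
            continue
        rss = float(np.sum((gr_curve(doses, *popt) - gr) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)

    flat = float(gr.mean())
    rss_flat = float(np.sum((gr - flat) ** 2))
    flat_params = (flat, float(np.sqrt(lo * hi)), 1.0)
    if best is None:
        logger.warning("fit_gr_curve: no start converged; flat-line fallback")
        return flat_params, False

    popt, rss_fit = best
    if rss_flat - rss_fit <= 1e-15:  # sigmoid adds nothing over a flat line
        return flat_params, False
    n = doses.size
    df_fit = n - 3
    if df_fit <= 0 or rss_fit <= 1e-30:
        return (float(popt[0]), float(popt[1]), float(popt[2])), True
    f_stat = ((rss_flat - rss_fit) / 2.0) / (rss_fit / df_fit)
    p = stats.f.sf(max(f_stat, 0.0), 2, df_fit)
    if p >= alpha:
        return flat_params, False
    return (float(popt[0]), float(popt[1]), float(popt[2])), True


def gr_table(counts: CountTable) -> pd.DataFrame:
    """Per-replicate GR for every treated single-agent well.

    Technical replicates on one plate are averaged before the GR transform;
    the control reference is the mean vehicle count on the same plate and the
    baseline is the 50%-trimmed day-0 mean for the cell line.
    """
    rows = []
    treated = counts.treated()
    single = treated[treated["drug2"].isna()]
    day0: dict[str, float] = {}
    grouped = single.groupby(
        ["cell_line", "drug", "concentration", "time_h", "plate_id", "replicate"],
        sort=True,
    )
    for (cell_line, drug, conc, time_h, plate, rep), grp in grouped:
        if cell_line not in day0:
            day0[cell_line] = trimmed_mean_day0(counts.day0_counts(cell_line))
        x0 = day0[cell_line]
        x_ctrl = float(counts.controls(cell_line, plate).mean())
        x_c = float(grp["count"].mean())
        rows.append(
            {
                "cell_line": cell_line,
                "drug": drug,
                "concentration": conc,
                "time_h": time_h,
                "plate_id": plate,
                "replicate": rep,
                "GR": gr_value(x_c, x_ctrl, x0),
            }
        )
    logger.info("gr_table: %d treated wells -> %d GR values", len(single), len(rows))
    return pd.DataFrame(rows)


def dose_response_profiles(
    gr_df: pd.DataFrame, fit: bool = True
) -> list[DoseResponseProfile]:
    """Collapse a per-replicate GR table into per-(cell line, drug) profiles.

    Replicates are averaged per dose; profiles report GR_AOC and, when
    requested and at least 4 doses are present, the sigmoidal fit.
    """
    profiles = []
    for (cell_line, drug), grp in gr_df.groupby(["cell_line", "drug"], sort=True):
        per_dose = grp.groupby("concentration")["GR"].mean().sort_index()
        doses = per_dose.index.to_numpy(dtype=float)
        gr = per_dose.to_numpy(dtype=float)
        prof = DoseResponseProfile(
            cell_line=cell_line,
            drug=drug,
            doses=doses,
            gr=gr,
            gr_aoc=gr_aoc(gr),
        )
        if fit and doses.size >= 4:
            prof.fit, prof.fit_converged = fit_gr_curve(doses, gr)
        profiles.append(prof)
    return profiles
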