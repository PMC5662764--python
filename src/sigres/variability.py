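"""Cross-cell-line variability of molecular and phenotypic responses.

Groups drug-level statistics by target class: coefficient of variation of
the consistency score across cell lines, standard deviation of GR_AOC across
cell lines, cosine-distance dose-shift geometry of signatures, and
cross-line variability of log-scale abundance tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chdir import cosine_distance

logger = logging.getLogger(__name__)


@dataclass
class DoseShiftDistribution:
    target_class: str
    dose_pair: tuple[float, float]
    distances: np.ndarray
    baseline: np.ndarray | None = None  # between-class distances


def scs_cv(scs_df: pd.DataFrame) -> pd.DataFrame:
    """CV of the consistency score across cell lines, per drug x dose.

    ``scs_df`` needs columns cell_line, drug, concentration, SCS and
    optionally target_class. Groups with < 2 cell lines or non-positive mean
    are skipped with a flag in the log.
    """
    rows = []
    n_skipped = 0
    keys = ["drug", "concentration"]
    for key, grp in scs_df.groupby(keys, sort=True):
        if grp["cell_line"].nunique() < 2:
            n_skipped += 1
            continue
        per_line = grp.groupby("cell_line")["SCS"].mean()
        mean = float(per_line.mean())
        if mean <= 0:
            n_skipped += 1
            continue
        row = dict(zip(keys, key))
        row["cv"] = float(per_line.std(ddof=1)) / mean
        if "target_class" in grp.columns:
            row["target_class"] = grp["target_class"].iloc[0]
        rows.append(row)
    if n_skipped:
        logger.info("scs_cv: skipped %d drug x dose group(s)", n_skipped)
    return pd.DataFrame(rows)


def gr_aoc_sd(aoc_df: pd.DataFrame) -> pd.DataFrame:
    """Sample SD of GR_AOC across cell lines, per drug.

    ``aoc_df`` needs columns cell_line, drug, GR_AOC and optionally
    target_class; single-cell-line drugs are skipped.
    """
    rows = []
    for drug, grp in aoc_df.groupby("drug", sort=True):
        per_line = grp.groupby("cell_line")["GR_AOC"].mean()
        if per_line.size < 2:
            continue
        row = {"drug": drug, "sd": float(per_line.std(ddof=1))}
        if "target_class" in grp.columns:
            row["target_class"] = grp["target_class"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def class_medians(df: pd.DataFrame, value: str) -> pd.Series:
    """Median of a per-drug statistic pooled by target class."""
    if "target_class" not in df.columns:
        raise ValueError("target_class column required for class pooling")
    return df.groupby("target_class")[value].median()


def dose_shift(
    signatures: dict[tuple, np.ndarray],
    dose_low: float,
    dose_high: float,
    target_class_of: dict[str, str] | None = None,
) -> list[DoseShiftDistribution]:
    """Cosine distance between each condition's signatures at two doses.

    ``signatures`` maps (cell_line, drug, concentration, time_h) to unit
    vectors. Conditions lacking either dose are skipped. When a drug ->
    target-class map is given, distances are pooled per class and a
    between-class baseline (distances between signatures of different
    classes at the high dose) is attached.
    """
    paired: dict[tuple[str, str, float], dict[float, np.ndarray]] = {}
    for (cell_line, drug, conc, time_h), vec in signatures.items():
        if conc in (dose_low, dose_high):
            paired.setdefault((cell_line, drug, time_h), {})[conc] = vec

    per_class: dict[str, list[float]] = {}
    high_vectors: dict[str, list[np.ndarray]] = {}
    n_skipped = 0
    for (cell_line, drug, time_h), by_dose in paired.items():
        if dose_low not in by_dose or dose_high not in by_dose:
            n_skipped += 1
            continue
        cls = target_class_of.get(drug, "all") if target_class_of else "all"
        d = cosine_distance(by_dose[dose_low], by_dose[dose_high])
        per_class.setdefault(cls, []).append(d)
        high_vectors.setdefault(cls, []).append(by_dose[dose_high])
    if n_skipped:
        logger.info("dose_shift: skipped %d condition(s) missing a dose", n_skipped)

    classes = sorted(per_class)
    out = []
    for cls in classes:
        baseline = None
        others = [v for c in classes if c != cls for v in high_vectors[c]]
        own = high_vectors[cls]
        if others:
            baseline = np.array(
                [cosine_distance(a, b) for a in own for b in others]
            )
        out.append(
            DoseShiftDistribution(
                target_class=cls,
                dose_pair=(dose_low, dose_high),
                distances=np.array(per_class[cls]),
                baseline=baseline,
            )
        )
    return out


def cross_line_sd(
    abundance: pd.DataFrame,
    groups: dict[str, str],
    test_pair: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """SD of log10 abundance across cell lines per entity, pooled by group.

    ``abundance`` is entities x cell lines with positive values; ``groups``
    maps entity -> group name. When ``test_pair`` names two groups, their SD
    distributions are compared by a two-sided rank-sum (Mann-Whitney) test.
    """
    if abundance.shape[1] < 2:
        raise ValueError("need >= 2 cell lines")
    if (abundance.to_numpy() <= 0).any():
        raise ValueError("abundances must be positive for the log10 transform")
    sd = np.log10(abundance).std(axis=1, ddof=1)
    df = pd.DataFrame(
        {
            "entity": abundance.index,
            "sd": sd.to_numpy(),
            "group": [groups[e] for e in abundance.index],
        }
    )
    p = None
    if test_pair is not None:
        a = df.loc[df["group"] == test_pair[0], "sd"]
        b = df.loc[df["group"] == test_pair[1], "sd"]
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"empty group in {test_pair}")
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return df, p


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("inputs must be equal length with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
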