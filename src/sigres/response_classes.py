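"""Cross-tabulation of molecular and phenotypic responses into quadrant
classes.

Class I: non-responsive by both measures; Class II: responsive by both;
Class III: phenotypic response without a consistent molecular signature;
Class IV: consistent molecular signature without a phenotypic response.
Boundary values fall on the non-responsive / non-significant side (the
filters are strict: GR < cutoff, score > cutoff).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

GR_CUTOFF = 0.66
SCS_CUTOFF = 1.3

CLASSES = ("I", "II", "III", "IV")


@dataclass
class ResponseClassification:
    condition_key: tuple
    GR_used: float
    SCS_used: float
    response_class: str


def classify_response(
    gr: float,
    scs: float,
    gr_cut: float = GR_CUTOFF,
    scs_cut: float = SCS_CUTOFF,
) -> str:
    """Quadrant of the (GR, SCS) plane."""
    phenotypic = gr < gr_cut       # strict: GR == cutoff is non-responsive
    molecular = scs > scs_cut      # strict: SCS == cutoff is non-significant
    if phenotypic and molecular:
        return "II"
    if phenotypic:
        return "III"
    if molecular:
        return "IV"
    return "I"


def classify_conditions(
    gr_by_key: dict[tuple, float],
    scs_by_key: dict[tuple, float],
    gr_cut: float = GR_CUTOFF,
    scs_cut: float = SCS_CUTOFF,
) -> list[ResponseClassification]:
    """Pair GR and consistency scores by (cell line, drug, concentration).

    Keys present in only one input are skipped with a warning (exact
    concentration match required; time points are allowed to differ between
    the two assays and are excluded from the join key).
    """

    def short(key: tuple) -> tuple:
        return tuple(key[:3])  # (cell_line, drug, concentration)

    gr_short = {short(k): (k, v) for k, v in gr_by_key.items()}
    scs_short = {short(k): (k, v) for k, v in scs_by_key.items()}
    shared = sorted(set(gr_short) & set(scs_short))
    n_skipped = len(set(gr_short) ^ set(scs_short))
    if n_skipped:
        logger.warning(
            "classify_conditions: %d condition(s) present in only one assay "
            "were skipped", n_skipped,
        )
    out = []
    for key in shared:
        full_key, gr = gr_short[key]
        _, scs = scs_short[key]
        out.append(
            ResponseClassification(
                condition_key=full_key,
                GR_used=gr,
                SCS_used=scs,
                response_class=classify_response(gr, scs, gr_cut, scs_cut),
            )
        )
    return out


def class_fractions(
    classifications: list[ResponseClassification],
    group_by,
) -> pd.DataFrame:
    """Per-group class proportions (rows sum to 1).

    ``group_by`` maps a condition key to its group (e.g. cell line or drug
    target class).
    """
    if not classifications:
        raise ValueError("no classifications to summarize")
    rows = [
        {"group": group_by(c.condition_key), "response_class": c.response_class}
        for c in classifications
    ]
    df = pd.DataFrame(rows)
    frac = (
        df.groupby("group")["response_class"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(CLASSES), fill_value=0.0)
    )
    frac.columns.name = None
    return frac
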