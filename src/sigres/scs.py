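"""Signature consistency scoring against a batch-level empirical null.

A condition's replicate directions are summarized by their mean pairwise
cosine distance; the null distribution of that statistic is built by
repeatedly drawing the same number of directions at random from the pooled
replicate directions of the whole batch. The score is the negative log10 of
the lower-tail empirical probability (with an add-one pseudo-count so the
log is always defined), so a score of 1.3 marks the 5% tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientReplicatesError

logger = logging.getLogger(__name__)

#: Default consistency filter: score > 1.3 <=> empirical p < 0.05.
SCS_CUTOFF = 1.3

DEFAULT_N_NULL = 10_000


@dataclass
class NullDistribution:
    values: np.ndarray
    J: int
    pool_size: int
    seed: int | None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("null distribution is empty")
        if self.values.min() < -1e-9 or self.values.max() > 2 + 1e-9:
            raise ValueError("null values outside [0, 2]")

    @property
    def n_null(self) -> int:
        return self.values.size


@dataclass
class ConsistencyResult:
    condition_key: tuple
    S_i: float
    p_value: float
    SCS: float
    n_null: int


def replicate_dispersion(replicates: list[np.ndarray]) -> float:
    """Mean pairwise cosine distance among J >= 2 unit replicate directions."""
    J = len(replicates)
    if J < 2:
        raise InsufficientReplicatesError(
            f"dispersion needs >= 2 replicates, got {J}"
        )
    mat = np.asarray(replicates, dtype=float)
    mat = mat / np.linalg.norm(mat, axis=1, keepdims=True)
    gram = mat @ mat.T
    iu = np.triu_indices(J, k=1)
    return float(1.0 - gram[iu].mean())


def build_null(
    pool: np.ndarray,
    J: int,
    n_null: int = DEFAULT_N_NULL,
    seed: int | None = None,
    plates: list | None = None,
) -> NullDistribution:
    """Empirical null of the dispersion statistic.

    Each draw samples ``J`` directions without replacement from ``pool``
    (a P x G matrix of all replicate directions in the batch) and records
    their mean pairwise cosine distance.

    When ``plates`` gives the source plate of each pool vector, draws are
    stratified: one vector from each of J distinct plates. This matches the
    structure of the observed statistic (one replicate per plate) — replicate
    directions from the same plate share the subtracted control-mean noise
    and are therefore slightly correlated, which would otherwise bias the
    null low.
    """
    pool = np.asarray(pool, dtype=float)
    if pool.ndim != 2:
        raise ValueError("pool must be a P x G matrix")
    P = pool.shape[0]
    if J < 2:
        raise ValueError(f"J must be >= 2, got {J}")
    if P < J:
        raise ValueError(f"pool of size {P} cannot supply J={J} draws")
    by_plate: list[np.ndarray] | None = None
    if plates is not None:
        if len(plates) != P:
            raise ValueError("one plate label required per pool vector")
        unique = sorted(set(plates))
        if len(unique) < J:
            raise ValueError(
                f"{len(unique)} distinct plates cannot supply J={J} "
                "stratified draws"
            )
        plate_arr = np.asarray(plates)
        by_plate = [np.flatnonzero(plate_arr == u) for u in unique]
    unit = pool / np.linalg.norm(pool, axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(J, k=1)
    values = np.empty(n_null)
    for t in range(n_null):
        if by_plate is None:
            idx = rng.choice(P, size=J, replace=False)
        else:
            chosen = rng.choice(len(by_plate), size=J, replace=False)
            idx = np.array(
                [by_plate[c][rng.integers(len(by_plate[c]))] for c in chosen]
            )
        sub = unit[idx]
        values[t] = 1.0 - (sub @ sub.T)[iu].mean()
    return NullDistribution(values=values, J=J, pool_size=P, seed=seed)


def score_scs(
    S_i: float,
    null: NullDistribution,
    condition_key: tuple = (),
) -> ConsistencyResult:
    """Lower-tail empirical p-value of ``S_i`` and its negative log10 score.

    ``p = (1 + #{null <= S_i}) / (n_null + 1)``; ties are counted
    inclusively (the conservative direction).
    """
    n = null.n_null
    count = int(np.count_nonzero(null.values <= S_i))
    p = (1 + count) / (n + 1)
    return ConsistencyResult(
        condition_key=condition_key,
        S_i=float(S_i),
        p_value=p,
        SCS=float(-np.log10(p)),
        n_null=n,
    )


def score_batch(
    replicate_dirs: dict[tuple, list[np.ndarray]],
    n_null: int = DEFAULT_N_NULL,
    seed: int | None = None,
    plate_labels: dict[tuple, list] | None = None,
) -> dict[tuple, ConsistencyResult]:
    """Score every scoreable condition in a batch against a shared null.

    The pool contains all replicate directions of all conditions (a
    condition's own replicates are not excluded). Conditions with a single
    replicate are skipped. ``plate_labels`` (condition key -> plate id per
    replicate, aligned with ``replicate_dirs``) enables plate-stratified
    null draws; see :func:`build_null`.
    """
    scoreable = {k: v for k, v in replicate_dirs.items() if len(v) >= 2}
    if not scoreable:
        return {}
    n_skipped = len(replicate_dirs) - len(scoreable)
    if n_skipped:
        logger.info("score_batch: skipping %d condition(s) with J < 2", n_skipped)
    Js = {len(v) for v in scoreable.values()}
    pool = np.vstack([d for dirs in replicate_dirs.values() for d in dirs])
    plates = None
    if plate_labels is not None:
        plates = [
            p for key, dirs in replicate_dirs.items()
            for p in plate_labels[key][: len(dirs)]
        ]
    nulls = {
        J: build_null(pool, J, n_null=n_null, seed=seed, plates=plates)
        for J in sorted(Js)
    }
    results = {}
    for key, dirs in scoreable.items():
        S_i = replicate_dispersion(dirs)
        results[key] = score_scs(S_i, nulls[len(dirs)], condition_key=key)
    return results
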