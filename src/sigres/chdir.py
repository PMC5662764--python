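"""Characteristic-direction signatures.

Each treated replicate is contrasted against the vehicle-control wells of its
own plate to yield a unit direction in gene space; replicate directions are
averaged and re-normalized into the condition signature, whose pre-
normalization magnitude ("amplitude") measures effect size.

The discriminant uses a shrinkage-regularized control covariance:
``sigma_hat = (1 - gamma) * S + gamma * nu * I + ridge * I`` with
``nu = trace(S) / G``. At ``gamma = 1`` the direction reduces to the
normalized mean-difference vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .errors import (
    DegenerateConsistencyError,
    DegenerateSignalError,
    InsufficientControlsError,
)
from .io_core import PlateBatch

logger = logging.getLogger(__name__)

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class ShrinkageParams:
    """Regularization of the control covariance estimate.

    gamma: weight on the scaled-identity target, in [0, 1].
    ridge: small positive diagonal constant for rank safety.
    """

    gamma: float = 0.5
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.ridge <= 0:
            raise ValueError(f"ridge must be > 0, got {self.ridge}")


@dataclass
class CharacteristicDirection:
    """Batch-averaged unit signature for one experimental condition."""

    condition_key: tuple[str, str, float, float]
    vector: np.ndarray
    amplitude: float
    J_used: int

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.vector))
        if abs(norm - 1.0) > _UNIT_TOL:
            raise ValueError(f"signature is not unit norm (|v| = {norm})")
        if not 0.0 <= self.amplitude <= 1.0 + _UNIT_TOL:
            raise ValueError(
                f"amplitude {self.amplitude} outside [0, 1] (mean of unit vectors)"
            )


def characteristic_direction(
    controls: np.ndarray,
    treated: np.ndarray,
    params: ShrinkageParams = ShrinkageParams(),
) -> np.ndarray:
    """Direction separating one treated profile from same-plate controls.

    Parameters
    ----------
    controls : (G, N) array
        Vehicle-control profiles on the plate, N >= 2.
    treated : (G,) array
        The treated replicate profile.

    Returns
    -------
    (G,) unit vector with non-negative projection on the raw difference
    ``treated - mean(controls)``.
    """
    controls = np.asarray(controls, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if controls.ndim != 2:
        raise ValueError("controls must be a G x N matrix")
    G, N = controls.shape
    if N < 2:
        raise InsufficientControlsError(
            f"need >= 2 control wells to estimate covariance, got {N}"
        )
    if G < 2 or treated.shape != (G,):
        raise ValueError(f"treated must be a vector of length G={G} (G >= 2)")

    diff = treated - controls.mean(axis=1)
    if np.linalg.norm(diff) < 1e-12:
        raise DegenerateSignalError(
            "treated profile equals the control mean; no direction exists"
        )

    if params.gamma == 1.0:
        # Identity-covariance limit: solve is a scalar multiple of diff.
        b = diff
    else:
        S = np.cov(controls, rowvar=True, ddof=1)
        nu = np.trace(S) / G
        sigma = (1.0 - params.gamma) * S
        idx = np.diag_indices(G)
        sigma[idx] += params.gamma * nu + params.ridge
        b = linalg.solve(sigma, diff, assume_a="pos")

    b = b / np.linalg.norm(b)
    if float(b @ diff) < 0:  # sign ambiguity of discriminant directions
        b = -b
    return b


def batch_average_cd(
    replicates: list[np.ndarray],
    condition_key: tuple[str, str, float, float] = ("", "", 0.0, 0.0),
) -> CharacteristicDirection:
    """Average replicate unit directions into the condition signature.

    The returned vector is ``mean(D_j) / ||mean(D_j)||`` and the amplitude is
    ``||mean(D_j)||`` (1 when replicates agree perfectly, smaller as they
    disperse).
    """
    if len(replicates) < 1:
        raise ValueError("need at least one replicate direction")
    mat = np.asarray(replicates, dtype=float)
    norms = np.linalg.norm(mat, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("replicate directions must be unit norm")
    mean = mat.mean(axis=0)
    amplitude = float(np.linalg.norm(mean))
    if amplitude < 1e-12:
        raise DegenerateConsistencyError(
            f"replicate directions cancel for condition {condition_key}"
        )
    return CharacteristicDirection(
        condition_key=condition_key,
        vector=mean / amplitude,
        amplitude=min(amplitude, 1.0),
        J_used=len(replicates),
    )


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - cos(a, b); ranges over [0, 2]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - (a @ b) / (na * nb))


def batch_directions(
    batch: PlateBatch,
    params: ShrinkageParams = ShrinkageParams(),
) -> tuple[dict[tuple, list[np.ndarray]], dict[tuple, CharacteristicDirection]]:
    """Per-replicate and batch-averaged directions for every condition.

    Returns ``(replicate_dirs, signatures)``; conditions whose signal is
    degenerate are dropped with a warning.
    """
    replicate_dirs: dict[tuple, list[np.ndarray]] = {}
    signatures: dict[tuple, CharacteristicDirection] = {}
    n_dropped = 0
    for key, cond in batch.conditions.items():
        dirs = []
        try:
            for plate_id, vec in zip(cond.plate_ids, cond.vectors):
                dirs.append(
                    characteristic_direction(batch.controls[plate_id], vec, params)
                )
            signatures[key] = batch_average_cd(dirs, condition_key=key)
        except (DegenerateSignalError, DegenerateConsistencyError) as exc:
            logger.warning("dropping condition %s: %s", key, exc)
            n_dropped += 1
            continue
        replicate_dirs[key] = dirs
    logger.info(
        "batch_directions: %s @ %s h: %d conditions in, %d signatures out "
        "(%d degenerate)",
        batch.cell_line, batch.time_h, batch.M, len(signatures), n_dropped,
    )
    return replicate_dirs, signatures
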