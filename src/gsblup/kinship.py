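"""Realized additive genomic relationship matrix (VanRaden / A.mat scaling).

K = theta * Mc Mc' with Mc the dosage matrix centered by twice the allele
frequency and theta = 1 / (2 * sum_k p_k (1 - p_k)).  Under this scaling the
expected diagonal is 1 + f for inbreeding coefficient f and full sibs have
expected relationship ~0.5, matching the pedigree numerator relationship.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .markers import MarkerMatrix

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    """Symmetric genet x genet realized relationship matrix."""

    genet_ids: list[str]
    values: np.ndarray
    theta: float
    bend_applied: bool = False
    bend_magnitude: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genet_ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"kinship shape {self.values.shape} does not match {n} genets"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValidationError("kinship matrix is not symmetric")
        self._pos = {g: i for i, g in enumerate(self.genet_ids)}

    @property
    def n(self) -> int:
        return len(self.genet_ids)

    def indices(self, ids) -> np.ndarray:
        try:
            return np.array([self._pos[g] for g in ids])
        except KeyError as exc:
            missing = [g for g in ids if g not in self._pos]
            raise KeyError(f"genets absent from kinship matrix: {missing[:10]}") from exc

    def subset(self, ids) -> "KinshipMatrix":
        idx = self.indices(ids)
        return replace(
            self, genet_ids=list(ids), values=self.values[np.ix_(idx, idx)]
        )


def compute_grm(m: MarkerMatrix) -> KinshipMatrix:
    """Compute the VanRaden genomic relationship matrix from imputed dosages.

    Columns are centered by 2 p_k; K = Mc Mc' / (2 sum p_k (1 - p_k)).
    Monomorphic columns (p in {0, 1}) carry no relationship information and
    are excluded from both the product and the normalizing sum, with a
    logged count.  Allele frequencies are taken from the matrix itself.
    """
    if not m.is_imputed:
        raise ValidationError("impute the marker matrix before computing the GRM")
    p = m.dosage.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("excluding %d monomorphic marker(s) from the GRM", n_mono)
    if not poly.any():
        raise ValidationError("all markers monomorphic; GRM undefined")
    pk = p[poly]
    mc = m.dosage[:, poly] - 2.0 * pk
    denom = 2.0 * float(np.sum(pk * (1.0 - pk)))
    theta = 1.0 / denom
    values = (mc @ mc.T) * theta
    values = 0.5 * (values + values.T)
    return KinshipMatrix(genet_ids=list(m.genet_ids), values=values, theta=theta)


def bend_to_psd(
    k: KinshipMatrix, eps: float = 1e-6, strategy: str = "ridge"
) -> KinshipMatrix:
    """Repair a non-positive-definite kinship matrix.

    ``ridge`` adds max(0, eps - lambda_min) * I to the diagonal; by the
    interlacing bound the smallest eigenvalue then reaches eps exactly.
    ``eigen_floor`` clips eigenvalues at eps and reconstructs, which keeps
    the trace closer to the original but perturbs every entry.  When the
    smallest eigenvalue is already >= eps the matrix is returned unchanged.
    """
    eigvals = np.linalg.eigvalsh(k.values)
    lam_min = float(eigvals[0])
    if lam_min >= eps:
        return replace(k, bend_applied=False, bend_magnitude=0.0)
    if strategy == "ridge":
        shift = eps - lam_min
        values = k.values + shift * np.eye(k.n)
        magnitude = shift
    elif strategy == "eigen_floor":
        w, v = np.linalg.eigh(k.values)
        w_clip = np.maximum(w, eps)
        values = (v * w_clip) @ v.T
        values = 0.5 * (values + values.T)
        magnitude = float(np.abs(values - k.values).max())
    else:
        raise ValueError(f"unknown bending strategy {strategy!r}")
    logger.info("bent kinship to PSD (%s, magnitude %.3g)", strategy, magnitude)
    return replace(k, values=values, bend_applied=True, bend_magnitude=magnitude)
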