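"""Stage 2: GBLUP on per-genet adjusted values (kin.blup-equivalent).

Fits  y = 1 mu + g + e  with  g ~ N(0, sigma2_g * K)  on the training
genets by exact REML over the single variance ratio
lambda = sigma2_e / sigma2_g (eigen-rotation of the training kinship
submatrix), then predicts genomic estimated breeding values (GEBVs) for
every genet in K:

    g_hat = K[:, train] (K[train, train] + lambda I)^-1 (y - mu_hat).

Genomic heritability is sigma2_g / (sigma2_g + sigma2_e) from the fitted
components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize_scalar

from .errors import ValidationError
from .kinship import KinshipMatrix, bend_to_psd

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-8
#: Variance-ratio ceiling; above this the genetic variance is treated as 0.
MAX_LAMBDA = 1e8


@dataclass
class GSFit:
    """A fitted genomic-selection model and its GEBVs for all genets in K."""

    trait: str
    training_ids: list[str]
    sigma2_g: float
    sigma2_e: float
    h2: float
    mu: float
    gebv: pd.Series  # indexed by genet_id, all genets in K
    loglik: float
    converged: bool

    def predict(self, ids) -> pd.Series:
        return predict(self, ids)


def genomic_heritability(sigma2_g: float, sigma2_e: float) -> float:
    """Narrow-sense genomic heritability sigma2_g / (sigma2_g + sigma2_e)."""
    if sigma2_g < 0 or sigma2_e < 0:
        raise ValidationError("variance components must be non-negative")
    total = sigma2_g + sigma2_e
    if total == 0:
        raise ValidationError("heritability undefined: both components zero")
    return sigma2_g / total


def fit_gblup(
    blups: pd.DataFrame,
    k: KinshipMatrix,
    training_ids=None,
    trait: str | None = None,
) -> GSFit:
    """Fit the GBLUP model on training genets and predict all genets in K.

    ``blups`` is a table with columns genet_id and value (trait/cycle
    columns are carried through if present).  When a genet has several
    records for the trait they are averaged with a log message.  The sole
    fixed effect is an intercept, since stage-1 values are already adjusted
    for site and spatial trend.
    """
    df = blups
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    elif trait is None and "trait" in df.columns:
        traits = df["trait"].unique()
        if len(traits) > 1:
            raise ValidationError(
                f"blup table holds several traits {list(traits)}; pass trait="
            )
        trait = str(traits[0]) if len(traits) else "trait"
    df = df.dropna(subset=["value"])
    if df["genet_id"].duplicated().any():
        logger.info("averaging duplicate stage-1 records per genet")
        df = df.groupby("genet_id", as_index=False)["value"].mean()

    avail = set(df["genet_id"])
    if training_ids is None:
        training_ids = [g for g in k.genet_ids if g in avail]
    else:
        training_ids = list(training_ids)
        missing = sorted(set(training_ids) - avail)
        if missing:
            raise ValidationError(
                f"training genets without records: {missing[:10]}"
            )
        missing_k = sorted(set(training_ids) - set(k.genet_ids))
        if missing_k:
            raise ValidationError(
                f"training genets absent from K: {missing_k[:10]}"
            )
    if len(training_ids) < 2:
        raise ValidationError("at least 2 training genets required")

    y = df.set_index("genet_id").loc[training_ids, "value"].to_numpy(float)
    t_idx = k.indices(training_ids)
    Ktt = k.values[np.ix_(t_idx, t_idx)]

    lam, s2g, s2e, mu, ll = _reml_ratio(y, Ktt)

    if s2g <= VARIANCE_FLOOR * 10 or lam >= MAX_LAMBDA:
        gebv = np.zeros(k.n)
    else:
        try:
            A = sla.cho_factor(Ktt + lam * np.eye(len(y)), lower=True)
        except np.linalg.LinAlgError:
            warnings.warn("singular training kinship; bending then refitting",
                          stacklevel=2)
            kb = bend_to_psd(k.subset(training_ids), eps=1e-6)
            Ktt = kb.values
            lam, s2g, s2e, mu, ll = _reml_ratio(y, Ktt)
            A = sla.cho_factor(Ktt + lam * np.eye(len(y)), lower=True)
        alpha = sla.cho_solve(A, y - mu)
        gebv = k.values[:, t_idx] @ alpha

    h2 = genomic_heritability(s2g, s2e) if (s2g + s2e) > 0 else 0.0
    return GSFit(
        trait=trait or "trait",
        training_ids=list(training_ids),
        sigma2_g=float(s2g),
        sigma2_e=float(s2e),
        h2=float(h2),
        mu=float(mu),
        gebv=pd.Series(gebv, index=k.genet_ids, name="gebv"),
        loglik=float(ll),
        converged=True,
    )


def _reml_ratio(y: np.ndarray, Ktt: np.ndarray):
    """Exact REML for y = 1 mu + g + e via eigen-rotation of Ktt.

    Profiles the restricted likelihood over delta = sigma2_e / sigma2_g.
    Returns (lambda, sigma2_g, sigma2_e, mu_gls, loglik) with loglik on the
    convention -2l = log|V| + log|X'V^-1 X| + r'V^-1 r (constants dropped).
    """
    n = y.size
    X = np.ones((n, 1))
    Q = sla.null_space(X.T)  # n x (n-1)
    A = Q.T @ Ktt @ Q
    xi, U = np.linalg.eigh(0.5 * (A + A.T))
    xi = np.maximum(xi, 0.0)
    eta = U.T @ (Q.T @ y)
    eta2 = eta**2
    logdet_xtx = np.log(float(n))

    def neg2(log_delta: float):
        d = np.exp(log_delta)
        w = xi + d
        s2g = max(float(np.mean(eta2 / w)), VARIANCE_FLOOR)
        val = (n - 1) * np.log(s2g) + float(np.sum(np.log(w))) + (n - 1) + logdet_xtx
        return val, s2g

    grid = np.linspace(-16.0, np.log(MAX_LAMBDA), 57)
    vals = np.array([neg2(g)[0] for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(lambda g: neg2(g)[0], bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-8})
    best = float(res.x) if res.fun <= vals[i] else float(grid[i])
    val, s2g = neg2(best)
    lam = float(np.exp(best))
    s2e = lam * s2g
    # GLS intercept at the optimum
    Vw = s2g * (Ktt + lam * np.eye(n))
    cf = sla.cho_factor(Vw, lower=True)
    Vi_1 = sla.cho_solve(cf, np.ones(n))
    mu = float(Vi_1 @ y / Vi_1.sum())
    return lam, s2g, s2e, mu, -0.5 * val


def predict(fit: GSFit, ids) -> pd.Series:
    """GEBVs for the requested genets (phenotyped or not).

    Every id must be present in the kinship matrix the fit was built on.
    """
    ids = list(ids)
    unknown = [g for g in ids if g not in fit.gebv.index]
    if unknown:
        raise KeyError(f"unknown genet id(s): {unknown[:10]}")
    return fit.gebv.loc[ids]
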