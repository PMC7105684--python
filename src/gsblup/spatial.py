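"""Stage 1: spatially corrected genomic BLUPs per cycle and trait-year.

The model is the standard field-trial mixed model

    y = X b + Z u + e,   u ~ N(0, sigma2_A * K),
    e ~ N(0, blockdiag_s  sigma2_e[s] * (Sigma_c(rho_c[s]) (x) Sigma_r(rho_r[s])))

with a separable first-order autoregressive (AR1 x AR1) residual correlation
on each site's row/column grid and an independent error variance per site.
Estimation is by REML:

* the autocorrelations are profiled by coordinate search on a coarse grid
  (-0.9 .. 0.9 step 0.1) followed by one-dimensional quadratic refinement;
* for a single site, the variance components at fixed (rho_r, rho_c) are
  found exactly by whitening the residual with the Cholesky factor of the
  AR1 x AR1 correlation and eigen-rotating Z K Z' in the whitened metric,
  then profiling the restricted likelihood over the ratio
  delta = sigma2_e / sigma2_A (the EMMA device);
* with several sites (separate residual variances) the restricted
  likelihood is maximized numerically over log-variances.

Missing plots (grid gaps) are handled by subsetting the Kronecker
correlation to observed plots, an approximation to full separable-residual
handling that is exact when every plot is observed.

Reported log-likelihoods use the convention
``-2 l_R = log|V| + log|X'V^-1 X| + r' V^-1 r`` with constants dropped,
so values are comparable across autocorrelation candidates of the same fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize

from .errors import ConvergenceWarning, ValidationError
from .kinship import KinshipMatrix

logger = logging.getLogger(__name__)

#: Lower bound applied to variance components to keep V invertible.
VARIANCE_FLOOR = 1e-8

#: Observations required for a cycle-trait combination to feed stage 2.
MIN_CYCLE_OBSERVATIONS = 350


def build_ar1(n: int, rho: float) -> np.ndarray:
    """AR1 correlation matrix: entry (i, j) = rho ** |i - j|.

    Positive definite for |rho| < 1; |rho| >= 1 is a domain error.
    """
    if n < 1:
        raise ValidationError("AR1 dimension must be >= 1")
    if abs(rho) >= 1:
        raise ValidationError(f"AR1 correlation must satisfy |rho| < 1, got {rho}")
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def ar1_chol(n: int, rho: float) -> np.ndarray:
    """Lower Cholesky factor of the AR1 correlation matrix, closed form."""
    if abs(rho) >= 1:
        raise ValidationError(f"|rho| must be < 1, got {rho}")
    L = np.zeros((n, n))
    L[:, 0] = rho ** np.arange(n)
    s = np.sqrt(1.0 - rho**2)
    for j in range(1, n):
        L[j:, j] = s * rho ** np.arange(n - j)
    return L


@dataclass
class FieldDesign:
    """Row/column grid of one trial site."""

    site: str
    n_rows: int
    n_cols: int
    occupancy: dict | None = None  # (row, col) -> genet_id

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("grid extents must be >= 1")


@dataclass
class SiteBlock:
    site: str
    n_rows: int
    n_cols: int
    obs_slice: slice  # rows of y belonging to this site
    plot_idx: np.ndarray  # column-major linear plot index per observation
    full_grid: bool = False


@dataclass
class ModelSpec:
    """Assembled design for one cycle x trait(-year) stage-1 fit."""

    trait: str
    cycle: str
    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    genet_ids: list[str]
    site_blocks: list[SiteBlock]
    fixed_names: list[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return self.y.size


def assemble_model(
    records: pd.DataFrame,
    k: KinshipMatrix,
    trait: str,
    cycle: str,
    year: int | None = None,
    designs: list[FieldDesign] | None = None,
    fixed_factors: list[str] | None = None,
) -> ModelSpec:
    """Build y, X, Z and the per-site residual blocks for one fit.

    Observations are ordered site-major, then column-major within site, so
    each site's residual block is a row/column subset of
    ``Sigma_c (x) Sigma_r``.  Fixed effects are an intercept, a site main
    effect when the cycle spans more than one site, and any extra
    categorical columns named in ``fixed_factors``.
    """
    df = records[(records["trait"] == trait) & (records["cycle"] == cycle)]
    if year is not None:
        df = df[df["year"] == year]
    df = df.dropna(subset=["value"])
    if df.empty:
        raise ValidationError(f"no records for trait={trait!r} cycle={cycle!r}")
    dup = df.duplicated(subset=["site", "year", "row", "col"])
    if dup.any():
        bad = df.loc[dup, ["site", "row", "col"]].iloc[0]
        raise ValidationError(
            f"duplicate plot at site={bad['site']} row={bad['row']} col={bad['col']}"
        )
    missing = sorted(set(df["genet_id"]) - set(k.genet_ids))
    if missing:
        raise ValidationError(
            f"{len(missing)} genet(s) absent from kinship matrix: {missing[:10]}"
        )

    df = df.sort_values(["site", "col", "row"], kind="mergesort").reset_index(drop=True)
    sites = list(dict.fromkeys(df["site"]))
    design_map = {d.site: d for d in (designs or [])}

    blocks: list[SiteBlock] = []
    start = 0
    for s in sites:
        sub = df[df["site"] == s]
        d = design_map.get(s)
        n_rows = d.n_rows if d else int(sub["row"].max())
        n_cols = d.n_cols if d else int(sub["col"].max())
        if (sub["row"] > n_rows).any() or (sub["col"] > n_cols).any():
            raise ValidationError(f"plot outside the {s} grid extents")
        plot_idx = ((sub["col"].to_numpy() - 1) * n_rows
                    + (sub["row"].to_numpy() - 1))
        blocks.append(
            SiteBlock(
                site=s,
                n_rows=n_rows,
                n_cols=n_cols,
                obs_slice=slice(start, start + len(sub)),
                plot_idx=plot_idx,
                full_grid=len(sub) == n_rows * n_cols,
            )
        )
        start += len(sub)

    y = df["value"].to_numpy(float)
    n = y.size

    cols = [np.ones(n)]
    names = ["intercept"]
    if len(sites) > 1:
        for s in sites[1:]:
            cols.append((df["site"] == s).to_numpy(float))
            names.append(f"site[{s}]")
    for f in fixed_factors or []:
        levels = list(dict.fromkeys(df[f]))
        for lv in levels[1:]:
            cols.append((df[f] == lv).to_numpy(float))
            names.append(f"{f}[{lv}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("singular fixed-effect design matrix")

    genet_ids = [g for g in k.genet_ids if g in set(df["genet_id"])]
    pos = {g: j for j, g in enumerate(genet_ids)}
    Z = np.zeros((n, len(genet_ids)))
    for i, g in enumerate(df["genet_id"]):
        Z[i, pos[g]] = 1.0

    return ModelSpec(
        trait=trait, cycle=cycle, y=y, X=X, Z=Z,
        genet_ids=genet_ids, site_blocks=blocks, fixed_names=names,
    )


@dataclass
class StageOneResult:
    """Variance components, autocorrelations and per-genet BLUPs of one fit."""

    trait: str
    cycle: str
    genet_ids: list[str]
    blups: np.ndarray
    sigma2_a: float
    sigma2_e: dict[str, float]
    rho_row: dict[str, float]
    rho_col: dict[str, float]
    fixed_effects: np.ndarray
    fixed_names: list[str]
    loglik: float
    converged: bool
    n_obs: int


def _site_corr_chol(block: SiteBlock, rho_r: float, rho_c: float) -> np.ndarray:
    """Lower Cholesky of the site's residual correlation on observed plots."""
    if block.full_grid:
        # chol(A (x) B) = chol(A) (x) chol(B); ordering is column-major
        return np.kron(ar1_chol(block.n_cols, rho_c), ar1_chol(block.n_rows, rho_r))
    C = np.kron(build_ar1(block.n_cols, rho_c), build_ar1(block.n_rows, rho_r))
    C = C[np.ix_(block.plot_idx, block.plot_idx)]
    return np.linalg.cholesky(C)


def residual_correlation(block: SiteBlock, rho_r: float, rho_c: float) -> np.ndarray:
    """Residual correlation matrix of one site's observed plots."""
    C = np.kron(build_ar1(block.n_cols, rho_c), build_ar1(block.n_rows, rho_r))
    return C[np.ix_(block.plot_idx, block.plot_idx)]


def _whiten(spec: ModelSpec, rhos: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Transform (y, X, Z) by the blockwise inverse residual Cholesky.

    Returns the whitened arrays and ``2 * sum(log diag L)``, the residual
    correlation log-determinant needed to compare likelihoods across rho.
    """
    y = np.empty_like(spec.y)
    X = np.empty_like(spec.X)
    Z = np.empty_like(spec.Z)
    logdet = 0.0
    for b in spec.site_blocks:
        rr, rc = rhos[b.site]
        L = _site_corr_chol(b, rr, rc)
        sl = b.obs_slice
        stacked = np.column_stack([spec.y[sl], spec.X[sl], spec.Z[sl]])
        sol = sla.solve_triangular(L, stacked, lower=True)
        y[sl] = sol[:, 0]
        X[sl] = sol[:, 1 : 1 + spec.X.shape[1]]
        Z[sl] = sol[:, 1 + spec.X.shape[1] :]
        logdet += 2.0 * float(np.sum(np.log(np.diag(L))))
    return y, X, Z, logdet


def _profile_single_site(yt, Xt, H, corr_logdet):
    """Exact REML for V = s2a * H + s2e * I by eigen-rotation.

    Profiles the restricted likelihood over delta = s2e / s2a on a log grid
    with parabolic refinement.  Returns (loglik, s2a, s2e) where loglik is
    on the comparable convention (includes corr_logdet and log|X'X| terms).
    """
    n, p = Xt.shape
    Q = sla.null_space(Xt.T)
    A = Q.T @ H @ Q
    xi, U = np.linalg.eigh(0.5 * (A + A.T))
    xi = np.maximum(xi, 0.0)
    eta = U.T @ (Q.T @ yt)
    eta2 = eta**2
    sign, logdet_xtx = np.linalg.slogdet(Xt.T @ Xt)
    const = corr_logdet + logdet_xtx

    def neg2_loglik(log_delta: float) -> tuple[float, float, float]:
        d = np.exp(log_delta)
        w = xi + d
        s2a = max(float(np.mean(eta2 / w)), VARIANCE_FLOOR)
        val = (n - p) * np.log(s2a) + float(np.sum(np.log(w))) + (n - p) + const
        return val, s2a, d * s2a

    grid = np.linspace(-14.0, 14.0, 57)
    vals = np.array([neg2_loglik(g)[0] for g in grid])
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    # golden-section refinement on log delta
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda g: neg2_loglik(g)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    best = res.x if res.fun <= vals[i] else grid[i]
    val, s2a, s2e = neg2_loglik(float(best))
    return -0.5 * val, s2a, s2e


def dense_neg2_restricted_loglik(y, X, V) -> float:
    """-2 * restricted log-likelihood, dense evaluation (constants dropped)."""
    cf = sla.cho_factor(V, lower=True)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Vi_y = sla.cho_solve(cf, y)
    Vi_X = sla.cho_solve(cf, X)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    b = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ b
    Vi_r = sla.cho_solve(cf, r)
    return logdet_v + logdet_x + float(r @ Vi_r)


def _inner_fit(spec: ModelSpec, K: np.ndarray, rhos: dict):
    """REML variance components at fixed autocorrelations.

    Returns (loglik, sigma2_a, sigma2_e dict).  Single-site fits use the
    exact eigen profile; multi-site fits optimize log-variances numerically.
    """
    yt, Xt, Zt, corr_logdet = _whiten(spec, rhos)
    if len(spec.site_blocks) == 1:
        H = Zt @ K @ Zt.T
        ll, s2a, s2e = _profile_single_site(yt, Xt, H, corr_logdet)
        return ll, s2a, {spec.site_blocks[0].site: s2e}

    sites = [b.site for b in spec.site_blocks]
    ZKZ = spec.Z @ K @ spec.Z.T
    Cs = {
        b.site: residual_correlation(b, *rhos[b.site]) for b in spec.site_blocks
    }
    vy = float(np.var(spec.y))

    def neg2(logv: np.ndarray) -> float:
        s2a = np.exp(logv[0])
        V = s2a * ZKZ
        for j, b in enumerate(spec.site_blocks):
            sl = b.obs_slice
            V[sl.start:sl.stop, sl.start:sl.stop] += np.exp(logv[1 + j]) * Cs[b.site]
        try:
            return dense_neg2_restricted_loglik(spec.y, spec.X, V)
        except np.linalg.LinAlgError:
            return np.inf

    x0 = np.log(np.full(1 + len(sites), max(vy / 2.0, VARIANCE_FLOOR)))
    res = minimize(neg2, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    s2a = max(float(np.exp(res.x[0])), VARIANCE_FLOOR)
    s2e = {s: max(float(np.exp(res.x[1 + j])), VARIANCE_FLOOR)
           for j, s in enumerate(sites)}
    return -0.5 * float(res.fun), s2a, s2e


#: Coarse autocorrelation search grid.
RHO_GRID = np.round(np.arange(-0.9, 0.91, 0.1), 10)


def fit_reml(
    spec: ModelSpec,
    k: KinshipMatrix,
    rho_grid: np.ndarray | None = None,
    tol: float = 1e-6,
    estimate_rho: bool = True,
    fixed_rho: tuple[float, float] | None = None,
    max_sweeps: int = 4,
) -> StageOneResult:
    """REML fit of the stage-1 spatial genomic model.

    Autocorrelations are searched by coordinate descent over ``rho_grid``
    per site and axis, with quadratic refinement of the final grid optimum;
    variance components at each candidate come from the inner exact or
    numeric REML solver.  Set ``fixed_rho`` (or ``estimate_rho=False`` for
    rho = 0) to skip the search.
    """
    grid = RHO_GRID if rho_grid is None else np.asarray(rho_grid)
    K = k.subset(spec.genet_ids).values
    sites = [b.site for b in spec.site_blocks]

    if fixed_rho is not None:
        rhos = {s: (fixed_rho[0], fixed_rho[1]) for s in sites}
        ll, s2a, s2e = _inner_fit(spec, K, rhos)
        return _finalize(spec, k, K, rhos, ll, s2a, s2e, converged=True)
    if not estimate_rho:
        rhos = {s: (0.0, 0.0) for s in sites}
        ll, s2a, s2e = _inner_fit(spec, K, rhos)
        return _finalize(spec, k, K, rhos, ll, s2a, s2e, converged=True)

    # Coordinate ascent alternating between (a) a grid scan of one rho
    # parameter at the current variance components (cheap dense restricted
    # likelihood, one Cholesky per candidate) and (b) the full inner
    # variance-component solve at the accepted autocorrelations.
    G0 = spec.Z @ K @ spec.Z.T

    def scan_ll(rhos: dict, s2a: float, s2e: dict) -> float:
        V = s2a * G0
        for b in spec.site_blocks:
            sl = b.obs_slice
            C = residual_correlation(b, *rhos[b.site])
            V[sl.start:sl.stop, sl.start:sl.stop] += s2e[b.site] * C
        try:
            return -0.5 * dense_neg2_restricted_loglik(spec.y, spec.X, V)
        except np.linalg.LinAlgError:
            return -np.inf

    cache: dict[tuple, tuple] = {}

    def full_fit(rhos: dict) -> tuple:
        key = tuple((s, round(rhos[s][0], 6), round(rhos[s][1], 6)) for s in sites)
        if key not in cache:
            cache[key] = _inner_fit(spec, K, rhos)
        return cache[key]

    def candidate(rhos: dict, s: str, axis: int, r: float) -> dict:
        cand = {q: tuple(v) for q, v in rhos.items()}
        cv = list(cand[s])
        cv[axis] = float(r)
        cand[s] = tuple(cv)
        return cand

    rhos = {s: [0.0, 0.0] for s in sites}
    best_ll, s2a, s2e = full_fit({s: tuple(v) for s, v in rhos.items()})
    converged = False
    for _ in range(max_sweeps):
        improved = False
        for s in sites:
            for axis in (0, 1):
                lls = [scan_ll(candidate(rhos, s, axis, r), s2a, s2e)
                       for r in grid]
                j = int(np.argmax(lls))
                if float(grid[j]) == rhos[s][axis]:
                    continue
                ll_j, s2a_j, s2e_j = full_fit(candidate(rhos, s, axis, grid[j]))
                if ll_j > best_ll + tol:
                    rhos[s][axis] = float(grid[j])
                    best_ll, s2a, s2e = ll_j, s2a_j, s2e_j
                    improved = True
        if not improved:
            converged = True
            break
    # quadratic refinement around the grid optimum, one pass per parameter
    step = float(np.median(np.diff(grid)))
    for s in sites:
        for axis in (0, 1):
            r0 = rhos[s][axis]
            pts = [max(r0 - step, -0.95), r0, min(r0 + step, 0.95)]
            vals = [scan_ll(candidate(rhos, s, axis, r), s2a, s2e)
                    for r in pts]
            r_hat = _parabola_vertex(pts, vals)
            if r_hat is not None and abs(r_hat - r0) > 1e-9:
                ll_r, s2a_r, s2e_r = full_fit(candidate(rhos, s, axis, r_hat))
                if ll_r > best_ll:
                    rhos[s][axis] = r_hat
                    best_ll, s2a, s2e = ll_r, s2a_r, s2e_r

    final = {s: tuple(v) for s, v in rhos.items()}
    ll, s2a, s2e = full_fit(final)
    if not converged:
        warnings.warn(
            f"autocorrelation search did not settle in {max_sweeps} sweeps "
            f"for {spec.trait}/{spec.cycle}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return _finalize(spec, k, K, final, ll, s2a, s2e, converged=converged)


def _parabola_vertex(x, y):
    """Vertex of the parabola through three points, clipped to (-0.95, 0.95)."""
    x0, x1, x2 = x
    y0, y1, y2 = y
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    if denom == 0:
        return None
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # not a maximum
        return None
    return float(np.clip(-b / (2 * a), -0.95, 0.95))


def _finalize(spec, k, K, rhos, ll, s2a, s2e, converged) -> StageOneResult:
    n = spec.n_obs
    V = s2a * (spec.Z @ K @ spec.Z.T)
    for b in spec.site_blocks:
        sl = b.obs_slice
        C = residual_correlation(b, *rhos[b.site])
        V[sl.start:sl.stop, sl.start:sl.stop] += s2e[b.site] * C
    cf = sla.cho_factor(V, lower=True)
    Vi_X = sla.cho_solve(cf, spec.X)
    XtViX = spec.X.T @ Vi_X
    beta = np.linalg.solve(XtViX, spec.X.T @ sla.cho_solve(cf, spec.y))
    r = spec.y - spec.X @ beta
    u = s2a * (K @ (spec.Z.T @ sla.cho_solve(cf, r)))
    return StageOneResult(
        trait=spec.trait,
        cycle=spec.cycle,
        genet_ids=list(spec.genet_ids),
        blups=u,
        sigma2_a=float(s2a),
        sigma2_e={s: float(v) for s, v in s2e.items()},
        rho_row={s: float(rhos[s][0]) for s in s2e},
        rho_col={s: float(rhos[s][1]) for s in s2e},
        fixed_effects=beta,
        fixed_names=list(spec.fixed_names),
        loglik=float(ll),
        converged=bool(converged),
        n_obs=n,
    )


def extract_blups(
    result: StageOneResult,
    min_observations: int = MIN_CYCLE_OBSERVATIONS,
    override: bool = False,
) -> pd.DataFrame:
    """Per-genet adjusted-value table for stage 2.

    A cycle-trait combination with fewer than ``min_observations`` recorded
    plots is ineligible for genomic selection and yields an empty table
    unless ``override`` is set.
    """
    if result.n_obs < min_observations and not override:
        warnings.warn(
            f"{result.trait}/{result.cycle}: {result.n_obs} observations "
            f"< floor {min_observations}; excluded from stage 2",
            stacklevel=2,
        )
        return pd.DataFrame(columns=["genet_id", "cycle", "trait", "value"])
    return pd.DataFrame(
        {
            "genet_id": result.genet_ids,
            "cycle": result.cycle,
            "trait": result.trait,
            "value": result.blups,
        }
    )
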