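"""Training-set designs and prediction-ability metrics.

Prediction ability is the Pearson correlation between GEBVs and the
phenotypic (stage-1) BLUPs of held-out genets.  Schemes: within-cycle
fivefold cross-validation repeated 100 times, across-cycle prediction,
leave-one-cycle-out, and training subsets defined by PCA similarity groups
or breeding program.  95% confidence intervals use the Fisher z transform;
a candidate training design beats the reference only when their intervals
do not overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EligibilityError, ValidationError
from .gblup import fit_gblup
from .kinship import KinshipMatrix
from .markers import PcaResult

logger = logging.getLogger(__name__)

#: Minimum training-set size for any prediction model.
MIN_TRAIN_GENETS = 100


@dataclass
class TrainingSpec:
    """A resolved training/prediction design for one model."""

    scheme: str  # within_cv | across_cycle | leave_one_out | pca_subset | program_subset
    train_ids: list[str]
    predict_ids: list[str]
    min_train: int = MIN_TRAIN_GENETS
    label: str = ""

    def __post_init__(self) -> None:
        if self.scheme != "within_cv":
            overlap = set(self.train_ids) & set(self.predict_ids)
            if overlap:
                raise ValidationError(
                    f"train/predict overlap in {self.scheme}: "
                    f"{sorted(overlap)[:5]}"
                )

    @property
    def eligible(self) -> bool:
        return len(self.train_ids) >= self.min_train


@dataclass
class PredictionResult:
    """Prediction ability of one model for one trait and predicted cycle."""

    trait: str
    predict_cycle: str
    train_label: str
    scheme: str
    r: float
    ci_low: float
    ci_high: float
    n: int
    sd_over_reps: float | None = None
    flags: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "trait": self.trait,
            "predict_cycle": self.predict_cycle,
            "train_label": self.train_label,
            "scheme": self.scheme,
            "r": self.r,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
            "sd_over_reps": self.sd_over_reps,
        }


def correlation_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z confidence interval for a Pearson correlation.

    z = atanh(r) with standard error 1/sqrt(n - 3); the interval is
    tanh(z -+ z_crit / sqrt(n - 3)).
    """
    if n < 4:
        raise ValidationError(f"need n >= 4 pairs for a Fisher CI, got {n}")
    if abs(r) >= 1.0:
        warnings.warn("|r| = 1: degenerate confidence interval", stacklevel=2)
        return (r, r)
    zcrit = 1.96 if level == 0.95 else stats.norm.ppf(0.5 + level / 2.0)
    half = zcrit / np.sqrt(n - 3)
    z = np.arctanh(r)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _cycle_table(blups: pd.DataFrame, trait: str, cycle: str | None = None):
    df = blups[blups["trait"] == trait].dropna(subset=["value"])
    if cycle is not None:
        df = df[df["cycle"] == cycle]
    if df["genet_id"].duplicated().any():
        df = df.groupby(["genet_id"], as_index=False).agg(
            cycle=("cycle", "first"), trait=("trait", "first"),
            value=("value", "mean"),
        )
    return df


def within_cycle_cv(
    blups: pd.DataFrame,
    k: KinshipMatrix,
    trait: str,
    cycle: str,
    folds: int = 5,
    reps: int = 100,
    seed: int = 0,
    pooling: str = "rep",
) -> PredictionResult:
    """Fivefold cross-validation within one cycle, repeated ``reps`` times.

    Each repetition partitions the cycle's genets into ``folds`` folds by
    random sampling without replacement; each fold is predicted from a model
    trained on the remaining genets.  With ``pooling='rep'`` (default) the
    correlation is computed per repetition over all pooled held-out
    predictions; ``pooling='fold'`` averages per-fold correlations instead.
    Full and half sibs may fall on both sides of a split; nothing prevents
    that, mirroring how cross-validation is usually reported for breeding
    populations.
    """
    df = _cycle_table(blups, trait, cycle)
    ids = [g for g in k.genet_ids if g in set(df["genet_id"])]
    if len(ids) < folds:
        raise ValidationError(
            f"{len(ids)} genets in {cycle} < {folds} folds"
        )
    values = df.set_index("genet_id").loc[ids, "value"]
    rng = np.random.default_rng(seed)
    rs = []
    for _ in range(reps):
        perm = rng.permutation(len(ids))
        fold_of = np.empty(len(ids), int)
        for f, chunk in enumerate(np.array_split(perm, folds)):
            fold_of[chunk] = f
        pooled_pred, pooled_obs, fold_rs = [], [], []
        for f in range(folds):
            test = [ids[i] for i in np.flatnonzero(fold_of == f)]
            train = [ids[i] for i in np.flatnonzero(fold_of != f)]
            fit = fit_gblup(df, k, training_ids=train, trait=trait)
            pred = fit.gebv.loc[test].to_numpy()
            obs = values.loc[test].to_numpy()
            pooled_pred.append(pred)
            pooled_obs.append(obs)
            if pooling == "fold":
                fold_rs.append(_pearson(pred, obs))
        if pooling == "rep":
            rs.append(_pearson(np.concatenate(pooled_pred),
                               np.concatenate(pooled_obs)))
        else:
            rs.append(float(np.nanmean(fold_rs)))
    rs_arr = np.asarray(rs, float)
    mean_r = float(np.nanmean(rs_arr))
    sd_r = float(np.nanstd(rs_arr, ddof=1)) if reps > 1 else 0.0
    lo, hi = correlation_ci(np.clip(mean_r, -0.999999, 0.999999), len(ids))
    return PredictionResult(
        trait=trait, predict_cycle=cycle, train_label=f"{cycle} (CV)",
        scheme="within_cv", r=mean_r, ci_low=lo, ci_high=hi,
        n=len(ids), sd_over_reps=sd_r,
    )


def across_cycle(
    blups: pd.DataFrame,
    k: KinshipMatrix,
    trait: str,
    train_cycle: str,
    predict_cycles,
    min_train: int = MIN_TRAIN_GENETS,
    cv_seed: int = 0,
) -> list[PredictionResult]:
    """Train on one cycle, predict every listed cycle.

    A predicted cycle equal to the training cycle is routed through
    within-cycle CV and flagged, rather than reporting an in-sample
    correlation.  Predicted cycles lacking the trait are skipped with a log
    entry.
    """
    train_df = _cycle_table(blups, trait, train_cycle)
    train_ids = [g for g in k.genet_ids if g in set(train_df["genet_id"])]
    if len(train_ids) < min_train:
        raise EligibilityError(
            f"{train_cycle}: {len(train_ids)} training genets < {min_train}"
        )
    fit = fit_gblup(train_df, k, training_ids=train_ids, trait=trait)
    out = []
    for pc in predict_cycles:
        if pc == train_cycle:
            res = within_cycle_cv(blups, k, trait, pc, seed=cv_seed)
            res.flags.append("self-prediction routed to within-cycle CV")
            out.append(res)
            continue
        pdf = _cycle_table(blups, trait, pc)
        if pdf.empty:
            logger.info("cycle %s lacks trait %s; skipped", pc, trait)
            continue
        ids = [g for g in k.genet_ids if g in set(pdf["genet_id"])]
        pred = fit.gebv.loc[ids].to_numpy()
        obs = pdf.set_index("genet_id").loc[ids, "value"].to_numpy()
        r = _pearson(pred, obs)
        lo, hi = correlation_ci(np.clip(r, -0.999999, 0.999999), len(ids))
        out.append(
            PredictionResult(
                trait=trait, predict_cycle=pc, train_label=train_cycle,
                scheme="across_cycle", r=r, ci_low=lo, ci_high=hi, n=len(ids),
            )
        )
    return out


def leave_one_cycle_out(
    blups: pd.DataFrame,
    k: KinshipMatrix,
    trait: str,
    predict_cycle: str,
    min_train: int = MIN_TRAIN_GENETS,
    train_filter_ids=None,
    train_label: str | None = None,
) -> PredictionResult:
    """Predict one cycle from the union of all other cycles with the trait.

    ``train_filter_ids`` restricts the training union to a similarity group
    (PCA split or breeding program), implementing the subset training
    designs.  A union consisting of a single cycle degenerates to plain
    across-cycle prediction and is flagged.
    """
    df = blups[blups["trait"] == trait].dropna(subset=["value"])
    train_df = df[df["cycle"] != predict_cycle]
    if train_filter_ids is not None:
        allowed = set(train_filter_ids)
        train_df = train_df[train_df["genet_id"].isin(allowed)]
    train_cycles = sorted(train_df["cycle"].unique())
    if not train_cycles:
        raise EligibilityError(f"no other cycle carries trait {trait}")
    agg = train_df.groupby("genet_id", as_index=False)["value"].mean()
    agg["trait"] = trait
    train_ids = [g for g in k.genet_ids if g in set(agg["genet_id"])]
    if len(train_ids) < min_train:
        raise EligibilityError(
            f"training union has {len(train_ids)} genets < {min_train}"
        )
    fit = fit_gblup(agg, k, training_ids=train_ids, trait=trait)
    pdf = _cycle_table(blups, trait, predict_cycle)
    ids = [g for g in k.genet_ids
           if g in set(pdf["genet_id"]) and g not in set(train_ids)]
    if len(ids) < 3:
        raise EligibilityError(
            f"{predict_cycle}: fewer than 3 held-out genets to predict"
        )
    pred = fit.gebv.loc[ids].to_numpy()
    obs = pdf.set_index("genet_id").loc[ids, "value"].to_numpy()
    r = _pearson(pred, obs)
    lo, hi = correlation_ci(np.clip(r, -0.999999, 0.999999), len(ids))
    res = PredictionResult(
        trait=trait, predict_cycle=predict_cycle,
        train_label=train_label or "all other cycles",
        scheme="leave_one_out", r=r, ci_low=lo, ci_high=hi, n=len(ids),
    )
    if len(train_cycles) == 1:
        res.flags.append(
            f"single training cycle {train_cycles[0]}: degenerates to "
            "across-cycle prediction"
        )
    return res


def pca_split(
    pca: PcaResult, component: int = 2, threshold: float = 0.0
) -> tuple[list[str], list[str]]:
    """Partition genets into two similarity groups by a PC score threshold.

    Returns (low, high) groups: scores <= threshold and scores > threshold.
    The default threshold 0 is the centroid line of the centered scores; on
    structured material a leading component separates breeding programs.
    """
    scores = pca.component(component)
    low = [g for g, s in zip(pca.genet_ids, scores) if s <= threshold]
    high = [g for g, s in zip(pca.genet_ids, scores) if s > threshold]
    if not low or not high:
        warnings.warn(
            f"PCA split on component {component} at {threshold} puts all "
            "genets on one side",
            stacklevel=2,
        )
    return low, high


def best_model(
    results: list[PredictionResult], reference: PredictionResult
) -> pd.DataFrame:
    """Rank candidate training designs against a reference by CI overlap.

    A candidate is 'better' ('worse') than the reference only when the two
    95% intervals do not overlap; otherwise the pair is statistically
    indistinguishable.  Rows are sorted by r, best first.
    """
    rows = []
    for res in results:
        if res.trait != reference.trait or res.predict_cycle != reference.predict_cycle:
            raise ValidationError(
                "all results must share trait and predicted cycle with the reference"
            )
        if res.ci_low > reference.ci_high:
            verdict = "better"
        elif res.ci_high < reference.ci_low:
            verdict = "worse"
        else:
            verdict = "indistinguishable"
        row = res.as_row()
        row["vs_reference"] = verdict
        rows.append(row)
    ref_row = reference.as_row()
    ref_row["vs_reference"] = "reference"
    rows.append(ref_row)
    out = pd.DataFrame(rows).sort_values("r", ascending=False, kind="mergesort")
    return out.reset_index(drop=True)
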