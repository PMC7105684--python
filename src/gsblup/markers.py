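"""Genotype calls, GBS-style quality filters, dosage coding, imputation and PCA.

Genotype calls are held genet x marker with the integer coding

    0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate,
    -1 = missing,

which doubles as the alt-allele dosage for non-missing calls.  Filters follow
standard genotyping-by-sequencing practice for heterozygous outcrossing
material: depth-aware call correction (a homozygote supported by too few
reads, or a heterozygote without enough reads of *both* alleles, is set to
missing), then marker-level MAF / call-rate / biallelic filters, then a
genet-level missingness filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DepthUnavailableError, NonBiallelicError, ValidationError

logger = logging.getLogger(__name__)

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1


@dataclass
class GenotypeCallSet:
    """Raw per-genet, per-marker genotype calls with read-depth evidence.

    Parameters
    ----------
    genet_ids, marker_ids
        Unique identifiers for rows and columns of ``calls``.
    alleles
        Per-marker ``(ref, alt)`` strings; a comma in ``alt`` marks a
        multiallelic site.
    calls
        ``(n_genets, n_markers)`` int8 array in {0, 1, 2, -1}.
    depth
        Total read depth per call, or ``None`` when the source has no depth.
    ref_depth, alt_depth
        Optional per-allele read counts (e.g. from a VCF ``AD`` field).
    metadata
        Optional frame indexed by genet ID; recognised columns are ``cycle``
        and ``program``.
    """

    genet_ids: list[str]
    marker_ids: list[str]
    alleles: list[tuple[str, str]]
    calls: np.ndarray
    depth: np.ndarray | None = None
    ref_depth: np.ndarray | None = None
    alt_depth: np.ndarray | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(set(self.genet_ids)) != len(self.genet_ids):
            dupes = pd.Series(self.genet_ids).value_counts()
            raise ValidationError(
                f"duplicate genet IDs: {sorted(dupes[dupes > 1].index)}"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValidationError("duplicate marker IDs")
        if self.calls.shape != (len(self.genet_ids), len(self.marker_ids)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.genet_ids)} genets x {len(self.marker_ids)} markers"
            )
        if not np.isin(self.calls, [HOM_REF, HET, HOM_ALT, MISSING]).all():
            raise ValidationError("calls must be coded {0, 1, 2, -1}")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if (self.depth < 0).any():
                raise ValidationError("read depths must be non-negative")

    @property
    def n_genets(self) -> int:
        return len(self.genet_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def has_depth(self) -> bool:
        return self.depth is not None

    @property
    def has_allele_depth(self) -> bool:
        return self.ref_depth is not None and self.alt_depth is not None

    def is_biallelic(self) -> np.ndarray:
        """Boolean mask over markers: exactly one ref and one alt allele."""
        return np.array(
            [("," not in alt) and alt not in (".", "") for _, alt in self.alleles]
        )

    def subset(self, genet_idx=None, marker_idx=None) -> "GenotypeCallSet":
        gi = np.arange(self.n_genets) if genet_idx is None else np.asarray(genet_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)

        def _take(a):
            return None if a is None else a[np.ix_(gi, mi)]

        meta = None
        if self.metadata is not None:
            keep = [self.genet_ids[i] for i in gi]
            meta = self.metadata.loc[self.metadata.index.intersection(keep)]
        return GenotypeCallSet(
            genet_ids=[self.genet_ids[i] for i in gi],
            marker_ids=[self.marker_ids[i] for i in mi],
            alleles=[self.alleles[i] for i in mi],
            calls=self.calls[np.ix_(gi, mi)],
            depth=_take(self.depth),
            ref_depth=_take(self.ref_depth),
            alt_depth=_take(self.alt_depth),
            metadata=meta,
        )


@dataclass
class FilterSpec:
    """Thresholds for call-, marker- and genet-level genotype filtering.

    Defaults reproduce common GBS practice for heterozygous outcrossing
    populations: MAF strictly above 0.01, marker call rate of at least 30%,
    biallelic SNPs only, homozygotes supported by at least 4 reads,
    heterozygotes by at least 2 reads of each allele, and genets with
    strictly more than 95% missing calls discarded.
    """

    min_maf: float = 0.01
    min_marker_call_rate: float = 0.30
    biallelic_only: bool = True
    min_hom_depth: int = 4
    min_het_contrasting: int = 2
    max_genet_missing: float = 0.95

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_marker_call_rate", "max_genet_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.min_hom_depth < 1 or self.min_het_contrasting < 1:
            raise ValidationError("depth thresholds must be >= 1")


@dataclass
class FilterReport:
    """Counts of what each filtering stage removed."""

    n_genets_in: int = 0
    n_markers_in: int = 0
    calls_set_missing_hom_depth: int = 0
    calls_set_missing_het_contrast: int = 0
    markers_removed_non_biallelic: int = 0
    markers_removed_maf: int = 0
    markers_removed_call_rate: int = 0
    genets_removed_missing: int = 0
    removed_genet_ids: list[str] = field(default_factory=list)
    n_genets_out: int = 0
    n_markers_out: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def marker_call_rate(calls: GenotypeCallSet) -> np.ndarray:
    """Fraction of genets with a non-missing call, per marker."""
    return (calls.calls != MISSING).mean(axis=0)


def minor_allele_freq(calls: GenotypeCallSet) -> np.ndarray:
    """MAF per marker from non-missing calls; 0 where nothing is called."""
    obs = calls.calls != MISSING
    n_called = obs.sum(axis=0)
    alt = np.where(obs, calls.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), 0.0)
    return np.minimum(p, 1.0 - p)


def apply_depth_rules(calls: GenotypeCallSet, spec: FilterSpec) -> GenotypeCallSet:
    """Set under-supported calls to missing based on read depth.

    Homozygous calls with total depth below ``spec.min_hom_depth`` become
    missing.  Heterozygous calls need at least ``spec.min_het_contrasting``
    reads of *each* allele; this requires per-allele depths (``AD``).  When
    only total depth is present the heterozygote rule is skipped with a
    warning, since contrasting read counts cannot be reconstructed.
    """
    if not calls.has_depth:
        raise DepthUnavailableError(
            "no read depth in this call set; skip the depth-rule stage "
            "(e.g. plain GT-only VCF)"
        )
    new = calls.calls.copy()
    report = FilterReport()

    hom = (new == HOM_REF) | (new == HOM_ALT)
    low = hom & (calls.depth < spec.min_hom_depth)
    report.calls_set_missing_hom_depth = int(low.sum())
    new[low] = MISSING

    het = new == HET
    if calls.has_allele_depth:
        contrast = np.minimum(calls.ref_depth, calls.alt_depth)
        weak = het & (contrast < spec.min_het_contrasting)
        report.calls_set_missing_het_contrast = int(weak.sum())
        new[weak] = MISSING
    elif het.any():
        warnings.warn(
            "per-allele depths unavailable; heterozygote contrasting-read "
            "rule skipped",
            stacklevel=2,
        )
    out = replace(calls, calls=new)
    out.last_report = report  # type: ignore[attr-defined]
    return out


def filter_markers(
    calls: GenotypeCallSet, spec: FilterSpec
) -> tuple[GenotypeCallSet, FilterReport]:
    """Keep biallelic markers with MAF > min_maf and call rate >= threshold.

    The MAF bound is strict and the call-rate bound inclusive.  Returns the
    filtered set and a report of counts removed per criterion (each marker is
    charged to the first criterion it fails, in the order biallelic, MAF,
    call rate).
    """
    report = FilterReport(n_genets_in=calls.n_genets, n_markers_in=calls.n_markers)
    bi = calls.is_biallelic() if spec.biallelic_only else np.ones(calls.n_markers, bool)
    maf_ok = minor_allele_freq(calls) > spec.min_maf
    rate_ok = marker_call_rate(calls) >= spec.min_marker_call_rate

    report.markers_removed_non_biallelic = int((~bi).sum())
    report.markers_removed_maf = int((bi & ~maf_ok).sum())
    report.markers_removed_call_rate = int((bi & maf_ok & ~rate_ok).sum())

    keep = np.flatnonzero(bi & maf_ok & rate_ok)
    if keep.size == 0:
        warnings.warn("all markers removed by marker filters", stacklevel=2)
    out = calls.subset(marker_idx=keep)
    report.n_genets_out = out.n_genets
    report.n_markers_out = out.n_markers
    return out, report


def filter_genets(
    calls: GenotypeCallSet, spec: FilterSpec
) -> tuple[GenotypeCallSet, FilterReport]:
    """Drop genets whose missing-call fraction strictly exceeds the threshold."""
    report = FilterReport(n_genets_in=calls.n_genets, n_markers_in=calls.n_markers)
    missing_frac = (calls.calls == MISSING).mean(axis=1)
    keep = np.flatnonzero(missing_frac <= spec.max_genet_missing)
    removed = np.flatnonzero(missing_frac > spec.max_genet_missing)
    report.genets_removed_missing = removed.size
    report.removed_genet_ids = [calls.genet_ids[i] for i in removed]
    out = calls.subset(genet_idx=keep)
    report.n_genets_out = out.n_genets
    report.n_markers_out = out.n_markers
    return out, report


def apply_filters(
    calls: GenotypeCallSet, spec: FilterSpec
) -> tuple[GenotypeCallSet, FilterReport]:
    """Run the full filter pipeline in its fixed order.

    Order: depth rules (when depth is available) -> marker filters -> genet
    filter.  Marker statistics (MAF, call rate) are recomputed downstream
    whenever the dosage matrix is built, so a single pass is performed here.
    """
    report = FilterReport(n_genets_in=calls.n_genets, n_markers_in=calls.n_markers)
    if calls.has_depth:
        calls = apply_depth_rules(calls, spec)
        dr = calls.last_report  # type: ignore[attr-defined]
        report.calls_set_missing_hom_depth = dr.calls_set_missing_hom_depth
        report.calls_set_missing_het_contrast = dr.calls_set_missing_het_contrast
    else:
        logger.warning("input has no read depth; depth rules skipped")
    calls, mrep = filter_markers(calls, spec)
    report.markers_removed_non_biallelic = mrep.markers_removed_non_biallelic
    report.markers_removed_maf = mrep.markers_removed_maf
    report.markers_removed_call_rate = mrep.markers_removed_call_rate
    calls, grep_ = filter_genets(calls, spec)
    report.genets_removed_missing = grep_.genets_removed_missing
    report.removed_genet_ids = grep_.removed_genet_ids
    report.n_genets_out = calls.n_genets
    report.n_markers_out = calls.n_markers
    return calls, report


@dataclass
class MarkerMatrix:
    """Alt-allele dosage matrix (genets x markers) on the {0, 1, 2} scale.

    Missing entries are ``NaN`` until imputation.  ``allele_freq`` holds the
    per-marker alt-allele frequency from non-missing calls; ``call_rate``
    the pre-imputation fraction of non-missing calls (used by the PCA
    marker-subset rule after imputation has filled the matrix).
    """

    genet_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray
    allele_freq: np.ndarray
    call_rate: np.ndarray
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        ok = np.isnan(self.dosage) | (
            (self.dosage >= 0.0) & (self.dosage <= 2.0)
        )
        if not ok.all():
            raise ValidationError("dosages must lie in [0, 2] or be NaN")
        if not ((self.allele_freq >= 0) & (self.allele_freq <= 1)).all():
            raise ValidationError("allele frequencies outside [0, 1]")

    @property
    def n_genets(self) -> int:
        return len(self.genet_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def is_imputed(self) -> bool:
        return not np.isnan(self.dosage).any()

    def subset_genets(self, ids: list[str]) -> "MarkerMatrix":
        pos = {g: i for i, g in enumerate(self.genet_ids)}
        idx = [pos[g] for g in ids]
        m = MarkerMatrix(
            genet_ids=list(ids),
            marker_ids=self.marker_ids,
            dosage=self.dosage[idx],
            allele_freq=self.allele_freq,
            call_rate=self.call_rate,
            metadata=self.metadata,
        )
        return m


def _recompute_freq(dosage: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(dosage, axis=0) / 2.0
    return np.nan_to_num(p, nan=0.0)


def to_dosage(calls: GenotypeCallSet) -> MarkerMatrix:
    """Code biallelic calls as alt-allele dosage {0, 1, 2} with NaN missing."""
    bad = np.flatnonzero(~calls.is_biallelic())
    if bad.size:
        names = [calls.marker_ids[i] for i in bad[:5]]
        raise NonBiallelicError(
            f"{bad.size} non-biallelic marker(s) present, e.g. {names}; "
            "filter them first"
        )
    d = calls.calls.astype(float)
    d[calls.calls == MISSING] = np.nan
    return MarkerMatrix(
        genet_ids=list(calls.genet_ids),
        marker_ids=list(calls.marker_ids),
        dosage=d,
        allele_freq=_recompute_freq(d),
        call_rate=(calls.calls != MISSING).mean(axis=0),
        metadata=calls.metadata,
    )


def impute_naive(
    m: MarkerMatrix,
    method: Literal["marker_mean", "random_hwe"] = "marker_mean",
    seed: int | None = None,
) -> MarkerMatrix:
    """Fill missing dosages from per-marker allele frequencies.

    ``marker_mean`` fills with the expected dosage 2p (continuous values are
    allowed after imputation); ``random_hwe`` draws Binomial(2, p) genotypes
    with the given seed.  This is a deliberately simple stand-in for
    haplotype-based imputation: kinship built from common variants is
    insensitive to the difference, and the choice is recorded in run logs.
    """
    all_missing = np.isnan(m.dosage).all(axis=0)
    if all_missing.any():
        names = [m.marker_ids[i] for i in np.flatnonzero(all_missing)[:5]]
        raise ValidationError(
            f"marker(s) with no observed calls, e.g. {names}: allele "
            "frequency undefined; filter before imputing"
        )
    d = m.dosage.copy()
    miss = np.isnan(d)
    p = m.allele_freq
    if method == "marker_mean":
        fill = np.broadcast_to(2.0 * p, d.shape)
        d[miss] = fill[miss]
    elif method == "random_hwe":
        rng = np.random.default_rng(seed)
        draws = rng.binomial(2, np.broadcast_to(p, d.shape)).astype(float)
        d[miss] = draws[miss]
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return replace(m, dosage=d)


@dataclass
class PcaResult:
    """Principal components of the centered dosage matrix."""

    genet_ids: list[str]
    scores: np.ndarray
    var_explained: np.ndarray
    loadings: np.ndarray | None = None

    def component(self, k: int) -> np.ndarray:
        """Scores on component ``k`` (1-based, as in 'PC2')."""
        if not 1 <= k <= self.scores.shape[1]:
            raise ValidationError(f"component {k} not computed")
        return self.scores[:, k - 1]


def pca(
    m: MarkerMatrix,
    n_components: int = 10,
    maf_subset: float = 0.05,
    call_rate_subset: float = 0.50,
    standardize: bool = False,
) -> PcaResult:
    """PCA of the imputed dosage matrix for population-structure inspection.

    Markers are subset to MAF strictly above ``maf_subset`` and
    pre-imputation call rate strictly above ``call_rate_subset`` (the
    structure subset is deliberately stricter than the analysis filter).
    Columns are centered; standardization to unit variance is off by
    default.  Signs follow the convention that each component's largest-
    magnitude loading is positive, so results do not depend on genet order.
    """
    if not m.is_imputed:
        raise ValidationError("impute the marker matrix before PCA")
    maf = np.minimum(m.allele_freq, 1.0 - m.allele_freq)
    keep = (maf > maf_subset) & (m.call_rate > call_rate_subset)
    x = m.dosage[:, keep]
    if x.shape[1] == 0:
        raise ValidationError("no markers pass the PCA subset thresholds")
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    max_rank = min(x.shape)
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank bound {max_rank}; "
            "truncating",
            stacklevel=2,
        )
        n_components = max_rank
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest |loading| positive per component
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    total_var = float((s**2).sum())
    var_exp = (s[:n_components] ** 2) / total_var if total_var > 0 else s[:n_components] * 0
    return PcaResult(
        genet_ids=list(m.genet_ids),
        scores=u[:, :n_components] * s[:n_components],
        var_explained=var_exp,
        loadings=vt[:n_components].T,
    )
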