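"""Synthetic multi-cycle outcrossing breeding programs with full ground truth.

The generator emulates the structure of a perennial-grain domestication
study: heterozygous genets descended from common founders over several
cycles of recurrent phenotypic selection, biallelic SNP genotypes, traits
with contrasting architectures (few large-effect QTL versus many small
ones), genotype-by-environment interaction expressed as a between-site
genetic correlation, spatially autocorrelated plot error on row/column
grids, and genotyping-by-sequencing style missingness with depth-dependent
calling error.  Every run emits the true breeding values, QTL effects,
realized heritabilities and pedigree so that each pipeline stage can be
checked by parameter recovery.

All randomness flows from the mandatory ``seed`` through one
``numpy.random.Generator``; a run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil, sqrt

import numpy as np
import pandas as pd

from .errors import ValidationError
from .markers import GenotypeCallSet, MarkerMatrix
from .spatial import ar1_chol


@dataclass
class SimConfig:
    """Parameters of one simulated breeding program.

    Defaults describe a mid-sized program: 50 heterozygous founders, 2,000
    unlinked biallelic SNPs, a moderately polygenic trait (100 QTL),
    single-plant plot heritability 0.5, three cycles of 500 genets with the
    top 20% intermated each cycle, high cross-site genetic correlation, and
    moderate spatial autocorrelation (rho 0.4 both axes) carrying half of
    the plot-error variance.  GBS read depth averages 8x.
    """

    seed: int
    n_founders: int = 50
    n_markers: int = 2000
    n_qtl: int = 100
    h2_target: float = 0.5
    n_cycles: int = 3
    genets_per_cycle: int = 500
    selection_fraction: float = 0.2
    mating: str = "random_intermating"  # or "open_pollination_halfsib"
    ge_correlation: float = 0.9
    rho_row: float = 0.4
    rho_col: float = 0.4
    spatial_variance_fraction: float = 0.5
    mean_depth: float = 8.0
    founder_freq_low: float = 0.05
    founder_freq_high: float = 0.95
    linkage_blocks: int | None = None
    trait: str = "trait"
    program: str = "P1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        for name in ("h2_target", "selection_fraction", "ge_correlation"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name}={v} outside (0, 1]")
        if not 0.0 <= self.spatial_variance_fraction <= 1.0:
            raise ValidationError("spatial_variance_fraction outside [0, 1]")
        if self.n_qtl > self.n_markers:
            raise ValidationError("n_qtl cannot exceed n_markers")
        if self.mating not in ("random_intermating", "open_pollination_halfsib"):
            raise ValidationError(f"unknown mating scheme {self.mating!r}")


def domestication_like(seed: int, **overrides) -> SimConfig:
    """Preset for a domestication-syndrome trait.

    Few QTL of large effect and near-unit cross-site genetic correlation,
    the architecture class for which selection models transfer well across
    cycles and environments.
    """
    kw = dict(n_qtl=10, ge_correlation=0.95, trait="domestication")
    kw.update(overrides)
    return SimConfig(seed=seed, **kw)


def agronomic_like(seed: int, **overrides) -> SimConfig:
    """Preset for a polygenic agronomic trait.

    Many small-effect QTL and a low cross-site genetic correlation (0.3),
    producing the within- versus across-environment prediction gap typical
    of yield-type traits.
    """
    kw = dict(n_qtl=500, ge_correlation=0.3, trait="agronomic")
    kw.update(overrides)
    return SimConfig(seed=seed, **kw)


@dataclass
class Population:
    """One cycle's genets as phased haplotypes (n, 2, m)."""

    cycle: str
    genet_ids: list[str]
    haplotypes: np.ndarray
    parents: list[tuple[str, str] | None]
    program: str = "P1"

    @property
    def n(self) -> int:
        return len(self.genet_ids)

    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1).astype(float)


@dataclass
class TraitArchitecture:
    """QTL positions and per-site additive effects for one trait."""

    trait: str
    qtl_idx: np.ndarray
    shared_effects: np.ndarray
    site_effects: dict[str, np.ndarray]

    def breeding_values(self, pop: Population, site: str) -> np.ndarray:
        d = pop.haplotypes[:, :, self.qtl_idx].sum(axis=1).astype(float)
        return d @ self.site_effects[site]

    def shared_breeding_values(self, pop: Population) -> np.ndarray:
        d = pop.haplotypes[:, :, self.qtl_idx].sum(axis=1).astype(float)
        return d @ self.shared_effects


@dataclass
class SimTruth:
    """Ground truth emitted by the generator for recovery tests."""

    breeding_values: pd.DataFrame  # genet_id, cycle, site, bv
    qtl_idx: np.ndarray
    site_effects: dict[str, np.ndarray]
    realized_h2: dict[tuple[str, str], float]  # (cycle, trait) -> h2
    rho_row: float
    rho_col: float
    pedigree: pd.DataFrame  # genet_id, parent1, parent2


def simulate_founders(cfg: SimConfig, rng: np.random.Generator | None = None) -> Population:
    """Draw founder haplotypes at Hardy-Weinberg equilibrium.

    Allele frequencies are Uniform(founder_freq_low, founder_freq_high) per
    marker; the two haplotypes of a genet are independent Bernoulli(p)
    draws, so founders are unrelated and maximally heterozygous for their
    frequencies.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    p = rng.uniform(cfg.founder_freq_low, cfg.founder_freq_high, cfg.n_markers)
    haps = (rng.random((cfg.n_founders, 2, cfg.n_markers)) < p).astype(np.uint8)
    ids = [f"{cfg.program}-F{i:04d}" for i in range(cfg.n_founders)]
    return Population(
        cycle=f"{cfg.program}-C0", genet_ids=ids, haplotypes=haps,
        parents=[None] * cfg.n_founders, program=cfg.program,
    )


def sample_architecture(
    cfg: SimConfig, sites: list[str], rng: np.random.Generator
) -> TraitArchitecture:
    """Draw QTL positions and correlated per-site effect vectors.

    Site effects follow a compound-symmetry model:
    a_s = sqrt(rho_ge) * a_shared + sqrt(1 - rho_ge) * a_s_specific with all
    components iid normal, so cor(bv_s, bv_s') ~ rho_ge between any two
    sites.
    """
    qtl = np.sort(rng.choice(cfg.n_markers, size=cfg.n_qtl, replace=False))
    scale = 1.0 / sqrt(cfg.n_qtl)
    shared = rng.normal(0.0, scale, cfg.n_qtl)
    rho = cfg.ge_correlation
    site_effects = {
        s: sqrt(rho) * shared + sqrt(1.0 - rho) * rng.normal(0.0, scale, cfg.n_qtl)
        for s in sites
    }
    return TraitArchitecture(
        trait=cfg.trait, qtl_idx=qtl, shared_effects=shared,
        site_effects=site_effects,
    )


def _gametes(pop: Population, parent_idx: np.ndarray, rng, blocks: int | None):
    """Mendelian gamete per parent index, free recombination or block linkage."""
    m = pop.haplotypes.shape[2]
    n = parent_idx.size
    if blocks:
        bounds = np.linspace(0, m, blocks + 1).astype(int)
        pick = rng.integers(0, 2, size=(n, blocks))
        choose = np.repeat(pick, np.diff(bounds), axis=1)
    else:
        choose = rng.integers(0, 2, size=(n, m))
    haps = pop.haplotypes[parent_idx]  # (n, 2, m)
    return np.take_along_axis(haps, choose[:, None, :], axis=1)[:, 0, :]


def advance_cycles(
    founders: Population,
    cfg: SimConfig,
    rng: np.random.Generator,
    architecture: TraitArchitecture | None = None,
) -> list[Population]:
    """Produce successive cycles by truncation selection and mating.

    Selection acts on a noisy phenotype of the shared genetic value
    (heritability ``h2_target``) and keeps the top ``selection_fraction``;
    selected parents are mated per the configured scheme, each progeny from
    two distinct parents via Mendelian gamete sampling.  In half-sib mode
    one maternal parent is fixed per family, as in open pollination of
    selected mother plants.
    """
    populations = []
    current = founders
    for c in range(1, cfg.n_cycles + 1):
        if architecture is not None:
            crit = architecture.shared_breeding_values(current)
            vg = np.var(crit)
            if vg > 0 and cfg.h2_target < 1.0:
                crit = crit + rng.normal(
                    0.0, sqrt(vg * (1 - cfg.h2_target) / cfg.h2_target), crit.size
                )
        else:
            crit = rng.normal(size=current.n)  # drift only
        n_sel = max(int(round(cfg.selection_fraction * current.n)), 0)
        if n_sel < 2:
            raise ValidationError(
                f"selection keeps {n_sel} < 2 parents in cycle {c}"
            )
        selected = np.argsort(crit)[::-1][:n_sel]

        n_off = cfg.genets_per_cycle
        if cfg.mating == "random_intermating":
            # second parent drawn as a nonzero shift, so always distinct
            j1 = rng.integers(0, n_sel, n_off)
            j2 = (j1 + rng.integers(1, n_sel, n_off)) % n_sel
            p1 = selected[j1]
            p2 = selected[j2]
        else:  # open_pollination_halfsib
            family_size = max(n_off // n_sel, 1)
            j1 = np.repeat(np.arange(n_sel), family_size)[:n_off]
            if j1.size < n_off:  # top up with random mothers
                extra = rng.integers(0, n_sel, n_off - j1.size)
                j1 = np.concatenate([j1, extra])
            j2 = (j1 + rng.integers(1, n_sel, n_off)) % n_sel
            p1 = selected[j1]
            p2 = selected[j2]

        g1 = _gametes(current, p1, rng, cfg.linkage_blocks)
        g2 = _gametes(current, p2, rng, cfg.linkage_blocks)
        haps = np.stack([g1, g2], axis=1)
        label = f"{cfg.program}-C{c}"
        ids = [f"{label}-{i:04d}" for i in range(n_off)]
        parents = [
            (current.genet_ids[a], current.genet_ids[b])
            for a, b in zip(p1, p2)
        ]
        current = Population(
            cycle=label, genet_ids=ids, haplotypes=haps,
            parents=parents, program=cfg.program,
        )
        populations.append(current)
    return populations


def _spatial_field(n_rows: int, n_cols: int, rho_r: float, rho_c: float, rng):
    """Unit-variance Gaussian field with separable AR1 x AR1 correlation."""
    Lr = ar1_chol(n_rows, rho_r)
    Lc = ar1_chol(n_cols, rho_c)
    return Lr @ rng.standard_normal((n_rows, n_cols)) @ Lc.T


def simulate_phenotypes(
    populations: list[Population],
    cfg: SimConfig,
    rng: np.random.Generator,
    architecture: TraitArchitecture,
    sites: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Phenotype every cycle on its own field grid, with ground truth.

    Each cycle is grown at one site (``sites`` maps cycle label to site
    label; default one site per cycle), genets are placed randomly on a
    near-square row/column grid, and the plot error is the sum of a
    separable AR1 x AR1 spatial field and white noise, scaled so the
    realized single-site heritability matches ``h2_target``.
    """
    sites = sites or {p.cycle: f"S{i + 1}" for i, p in enumerate(populations)}
    records = []
    bv_rows = []
    realized = {}
    ped_rows = []
    for i, pop in enumerate(populations):
        site = sites[pop.cycle]
        if site not in architecture.site_effects:
            raise ValidationError(f"no effects drawn for site {site!r}")
        bv = architecture.breeding_values(pop, site)
        bv = bv - bv.mean()
        n = pop.n
        n_rows = ceil(sqrt(n))
        n_cols = ceil(n / n_rows)
        if n_rows * n_cols < n:
            raise ValidationError("grid smaller than population")
        var_bv = float(np.var(bv))
        var_err = (
            var_bv * (1.0 - cfg.h2_target) / cfg.h2_target
            if cfg.h2_target < 1.0 else 0.0
        )
        field = _spatial_field(n_rows, n_cols, cfg.rho_row, cfg.rho_col, rng)
        spatial = sqrt(cfg.spatial_variance_fraction * var_err) * field
        plot_order = rng.permutation(n_rows * n_cols)[:n]
        rows = plot_order % n_rows + 1
        cols = plot_order // n_rows + 1
        iid = rng.normal(0.0, sqrt((1 - cfg.spatial_variance_fraction) * var_err), n)
        values = bv + spatial[rows - 1, cols - 1] + iid
        year = 2001 + i
        for j, g in enumerate(pop.genet_ids):
            records.append(
                dict(genet_id=g, cycle=pop.cycle, program=pop.program,
                     site=site, year=year, row=int(rows[j]),
                     col=int(cols[j]), trait=cfg.trait, value=values[j])
            )
            bv_rows.append(dict(genet_id=g, cycle=pop.cycle, site=site, bv=bv[j]))
            par = pop.parents[j]
            ped_rows.append(
                dict(genet_id=g,
                     parent1=par[0] if par else None,
                     parent2=par[1] if par else None)
            )
        vv = float(np.var(values))
        realized[(pop.cycle, cfg.trait)] = var_bv / vv if vv > 0 else 1.0
    truth = SimTruth(
        breeding_values=pd.DataFrame(bv_rows),
        qtl_idx=architecture.qtl_idx,
        site_effects=architecture.site_effects,
        realized_h2=realized,
        rho_row=cfg.rho_row,
        rho_col=cfg.rho_col,
        pedigree=pd.DataFrame(ped_rows),
    )
    return pd.DataFrame(records), truth


def dosage_matrix(populations: list[Population]) -> MarkerMatrix:
    """Stack populations into one complete MarkerMatrix with metadata."""
    dos = np.vstack([p.dosage() for p in populations])
    ids = [g for p in populations for g in p.genet_ids]
    meta = pd.DataFrame(
        {
            "cycle": [p.cycle for p in populations for _ in p.genet_ids],
            "program": [p.program for p in populations for _ in p.genet_ids],
        },
        index=ids,
    )
    m = dos.shape[1]
    return MarkerMatrix(
        genet_ids=ids,
        marker_ids=[f"M{j:05d}" for j in range(m)],
        dosage=dos,
        allele_freq=dos.mean(axis=0) / 2.0,
        call_rate=np.ones(m),
        metadata=meta,
    )


def degrade_genotypes(
    m: MarkerMatrix, cfg: SimConfig, rng: np.random.Generator
) -> GenotypeCallSet:
    """Re-observe clean genotypes through a GBS-like read-depth model.

    Per call: depth ~ Poisson(mean_depth); alt reads ~ Binomial(depth, g/2)
    for true dosage g.  Depth 0 is missing; a heterozygote whose reads all
    come from one allele is miscalled homozygous, which is exactly the
    error mode the depth filters are designed to catch.
    """
    n, mm = m.dosage.shape
    true_g = np.rint(m.dosage).astype(int)
    depth = rng.poisson(cfg.mean_depth, size=(n, mm))
    alt = rng.binomial(depth, true_g / 2.0)
    ref = depth - alt
    calls = np.full((n, mm), -1, dtype=np.int8)
    called = depth > 0
    calls[called & (alt == 0)] = 0
    calls[called & (alt == depth) & (alt > 0)] = 2
    calls[called & (alt > 0) & (alt < depth)] = 1
    return GenotypeCallSet(
        genet_ids=list(m.genet_ids),
        marker_ids=list(m.marker_ids),
        alleles=[("A", "B")] * mm,
        calls=calls,
        depth=depth.astype(float),
        ref_depth=ref.astype(float),
        alt_depth=alt.astype(float),
        metadata=m.metadata,
    )


@dataclass
class SimStudy:
    """A complete simulated data set plus its generating truth."""

    config: SimConfig
    populations: list[Population]
    markers: MarkerMatrix
    phenotypes: pd.DataFrame
    truth: SimTruth
    architecture: TraitArchitecture


def simulate_study(
    cfg: SimConfig, include_founders: bool = False
) -> SimStudy:
    """Run the full generator: founders -> cycles -> phenotypes -> truth."""
    rng = np.random.default_rng(cfg.seed)
    founders = simulate_founders(cfg, rng)
    site_labels = [f"S{i + 1}" for i in range(cfg.n_cycles)]
    arch = sample_architecture(cfg, site_labels, rng)
    cycles = advance_cycles(founders, cfg, rng, arch)
    phenos, truth = simulate_phenotypes(cycles, cfg, rng, arch)
    pops = ([founders] + cycles) if include_founders else cycles
    markers = dosage_matrix(pops)
    return SimStudy(
        config=cfg, populations=pops, markers=markers,
        phenotypes=phenos, truth=truth, architecture=arch,
    )


def simulate_two_programs(
    cfg: SimConfig, drift_cycles: int | None = None
) -> tuple[list[Population], MarkerMatrix]:
    """Two programs diverging from common founders, for structure tests.

    Both programs descend from the same founder pool but are advanced
    independently (separate random streams, independent selection), so
    allele-frequency drift accumulates between them and a leading principal
    component separates the programs.
    """
    rng = np.random.default_rng(cfg.seed)
    founders = simulate_founders(cfg, rng)
    sites = [f"S{i + 1}" for i in range(cfg.n_cycles)]
    pops = []
    for prog in ("UMN", "TLI"):
        sub_cfg = replace(cfg, program=prog,
                          n_cycles=drift_cycles or cfg.n_cycles)
        sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        arch = sample_architecture(sub_cfg, sites, sub_rng)
        f = replace(founders, program=prog,
                    cycle=f"{prog}-C0",
                    genet_ids=[g.replace(cfg.program, prog) for g in founders.genet_ids])
        pops.extend(advance_cycles(f, sub_cfg, sub_rng, arch))
    return pops, dosage_matrix(pops)
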