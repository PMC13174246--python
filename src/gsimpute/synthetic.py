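"""Synthetic LD-structured genotype panels, populations and phenotypes.

A haplotype-copying mosaic (Li-Stephens flavoured) generates diploid
panels with realistic marker-marker correlation: each haplotype copies a
founder haplotype, switching to a random founder between adjacent markers
with a small probability and flipping alleles at a small mutation rate.
Populations derived from the same founders are imputable from the panel;
an ``unrelated`` switch draws fresh founders as a negative control.

Phenotypes follow a purely additive model y = sum_q beta_q z_q + e with
marker codes z in {-1, 0, 1}, QTL effects standard normal and the residual
variance set from the realized genetic variance to hit a target
narrow-sense heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genotype_io import GenotypeMatrix, MarkerRecord, PositionSet

__all__ = [
    "SimulationConfig",
    "PhenotypeSimConfig",
    "simulate_panel",
    "derive_populations",
    "simulate_phenotypes",
    "duplicated_marker_panel",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Conditions of the simulated study system.

    Defaults emulate a desk-scale diversity panel: 200 panel samples over
    1000 markers copied from 20 founder haplotypes with a 2% per-marker
    switch rate (tight local LD), 0.5% mutation rate and a 5% floor on
    founder allele frequencies.
    """

    n_panel: int = 200
    n_pop1: int = 100
    n_pop2: int = 100
    p: int = 1000
    n_founder_haplotypes: int = 20
    switch_rate: float = 0.02
    mutation_rate: float = 0.005
    maf_floor: float = 0.05
    chrom: str = "1"
    pos_step: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_panel", "n_pop1", "n_pop2", "p", "n_founder_haplotypes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("switch_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in [0, 0.5)")


@dataclass
class PhenotypeSimConfig:
    """Additive trait architecture: number of QTL and target heritability."""

    n_qtl: int = 50
    h2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("heritability must be in (0, 1)")
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be >= 1")


def _markers(cfg: SimulationConfig, rng: np.random.Generator) -> list[MarkerRecord]:
    ref_idx = rng.integers(0, 4, size=cfg.p)
    alt_idx = (ref_idx + rng.integers(1, 4, size=cfg.p)) % 4
    return [
        MarkerRecord(cfg.chrom, (j + 1) * cfg.pos_step, f"snp{j + 1}",
                     str(_BASES[ref_idx[j]]), str(_BASES[alt_idx[j]]))
        for j in range(cfg.p)
    ]


def _founders(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    freq = rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, size=cfg.p)
    return (rng.random((cfg.n_founder_haplotypes, cfg.p)) < freq).astype(np.int8)


def _mosaic_haplotypes(
    founders: np.ndarray, n_hap: int, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Copy n_hap haplotypes from the founders with switching and mutation."""
    n_f, p = founders.shape
    out = np.empty((n_hap, p), dtype=np.int8)
    for h in range(n_hap):
        switch = rng.random(p) < cfg.switch_rate
        switch[0] = True  # initial founder draw
        draws = rng.integers(0, n_f, size=p)
        # forward-fill the founder index between switch points
        seg = np.where(switch, np.arange(p), -1)
        seg = np.maximum.accumulate(seg)
        idx = draws[seg]
        hap = founders[idx, np.arange(p)]
        flips = rng.random(p) < cfg.mutation_rate
        out[h] = np.where(flips, 1 - hap, hap)
    return out


def _diploids(
    founders: np.ndarray,
    n: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sample_ids: list[str],
    markers: list[MarkerRecord],
) -> GenotypeMatrix:
    haps = _mosaic_haplotypes(founders, 2 * n, cfg, rng)
    codes = (haps[0::2] + haps[1::2] + 1).astype(np.int8)  # alt dosage -> codes 1/2/3
    return GenotypeMatrix(sample_ids, markers, codes, validate=False)


def simulate_panel(cfg: SimulationConfig) -> GenotypeMatrix:
    """Simulate a missing-free reference panel; the founder haplotypes are
    attached (``.founders``) so related populations can be derived."""
    rng = np.random.default_rng(cfg.seed)
    markers = _markers(cfg, rng)
    founders = _founders(cfg, rng)
    ids = [f"P{i + 1}" for i in range(cfg.n_panel)]
    g = _diploids(founders, cfg.n_panel, cfg, rng, ids, markers)
    g.founders = founders
    g.sim_config = cfg
    return g


def derive_populations(
    panel: GenotypeMatrix,
    cfg: SimulationConfig | None = None,
    size_a: int | None = None,
    size_b: int | None = None,
    overlap: float | int = 0.0,
    unrelated: bool = False,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Derive two chip-genotyped populations from a simulated panel.

    Population 1 is genotyped on marker subset A (size_a markers) and
    population 2 on subset B (size_b markers); ``overlap`` fixes |A ∩ B|
    (an int is a count, a float a fraction of min(|A|, |B|)). Samples are
    drawn by the same copying mosaic from the panel's founders, or from
    fresh founders when ``unrelated`` (the negative control).
    """
    if not hasattr(panel, "founders"):
        raise ValueError("panel was not produced by simulate_panel (no founders attached)")
    cfg = cfg if cfg is not None else panel.sim_config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    p = panel.n_markers
    size_a = p if size_a is None else size_a
    size_b = p if size_b is None else size_b
    if size_a > p or size_b > p:
        raise ValueError("requested subset sizes exceed the panel's marker count")
    n_shared = int(overlap) if isinstance(overlap, (int, np.integer)) else int(
        round(overlap * min(size_a, size_b))
    )
    if n_shared > min(size_a, size_b) or size_a + size_b - n_shared > p:
        raise ValueError("requested overlap is infeasible for the subset sizes")

    perm = rng.permutation(p)
    shared = perm[:n_shared]
    only_a = perm[n_shared : n_shared + size_a - n_shared]
    only_b = perm[size_a : size_a + size_b - n_shared]
    idx_a = np.sort(np.concatenate([shared, only_a]))
    idx_b = np.sort(np.concatenate([shared, only_b]))

    founders = panel.founders
    if unrelated:
        founders = _founders(cfg, rng)
    ids1 = [f"I{i + 1}" for i in range(cfg.n_pop1)]
    ids2 = [f"J{i + 1}" for i in range(cfg.n_pop2)]
    pop1_full = _diploids(founders, cfg.n_pop1, cfg, rng, ids1, panel.markers)
    pop2_full = _diploids(founders, cfg.n_pop2, cfg, rng, ids2, panel.markers)
    pop1 = pop1_full.subset_markers(idx_a)
    pop2 = pop2_full.subset_markers(idx_b)
    pop1.truth_full = pop1_full
    pop2.truth_full = pop2_full
    return pop1, pop2


def simulate_phenotypes(
    g: GenotypeMatrix, cfg: PhenotypeSimConfig
) -> tuple[np.ndarray, dict]:
    """Simulate an additive trait on a missing-free genotype matrix.

    Returns (y, info) where info records the QTL indices, effects and the
    realized heritability.
    """
    if g.has_missing():
        raise ValueError("phenotype simulation needs missing-free genotypes")
    if cfg.n_qtl > g.n_markers:
        raise ValueError("more QTL requested than markers available")
    rng = np.random.default_rng(cfg.seed)
    qtl = np.sort(rng.choice(g.n_markers, size=cfg.n_qtl, replace=False))
    beta = rng.standard_normal(cfg.n_qtl)
    z = g.codes[:, qtl].astype(float) - 2.0  # codes 1/2/3 -> -1/0/1
    gvals = z @ beta
    var_g = float(np.var(gvals))
    var_e = var_g * (1.0 - cfg.h2) / cfg.h2 if var_g > 0 else 1.0
    e = rng.normal(0.0, np.sqrt(var_e), size=g.n_samples)
    y = gvals + e
    realized = var_g / float(np.var(y)) if np.var(y) > 0 else 0.0
    return y, {"qtl": qtl, "beta": beta, "h2_realized": realized, "var_g": var_g, "var_e": var_e}


def duplicated_marker_panel(
    n: int, p: int, seed: int, maf_floor: float = 0.1
) -> GenotypeMatrix:
    """A panel whose markers come in perfectly duplicated adjacent pairs.

    Column 2j+1 equals column 2j for every j, giving maximal local LD: a
    masked member of any pair is exactly recoverable from its twin. Used
    to probe the denoising skill of the autoencoder.
    """
    if p % 2:
        raise ValueError("p must be even (markers are duplicated in pairs)")
    rng = np.random.default_rng(seed)
    half = p // 2
    freq = rng.uniform(maf_floor, 1.0 - maf_floor, size=half)
    dose = (
        (rng.random((n, half)) < freq).astype(np.int8)
        + (rng.random((n, half)) < freq).astype(np.int8)
    )
    codes = np.repeat(dose + 1, 2, axis=1).astype(np.int8)
    markers = [
        MarkerRecord("1", j + 1, f"dup{j + 1}", "A", "G") for j in range(p)
    ]
    ids = [f"S{i + 1}" for i in range(n)]
    return GenotypeMatrix(ids, markers, codes, validate=False)
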