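"""Synthetic breeding populations for end-to-end testing and benchmarking.

Genotypes are unlinked biallelic markers with dosages drawn
Binomial(2, p) at per-marker frequencies uniform over a MAF range
(Hardy-Weinberg, no LD).  Phenotypes follow a purely additive
architecture: a random subset of markers act as QTL with standard-normal
effects, and Gaussian noise is calibrated against the *realized*
true-breeding-value variance so the target heritability is exact per
dataset.  Field trials lay each genotype out once per replication, with
random block intercepts (per replication for RCBD, per incomplete block
nested in replication for alpha-lattice/augmented layouts) and plot
noise.  Every function is fully deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import FormatError
from .io_formats import Design, Encoding, GenotypeMatrix, PhenotypeTable


@dataclass
class SimulatedPopulation:
    """A simulated genotype panel with its additive trait architecture.

    phenotype_i = tbv_i + N(0, sigma_e2) with sigma_e2 chosen so that
    var(tbv) / (var(tbv) + sigma_e2) equals the requested h2 exactly on
    the realized tbv variance.
    """

    genotypes: GenotypeMatrix
    qtl_ids: list[str]
    qtl_effects: dict[str, float]
    true_breeding_values: dict[str, float]
    phenotypes: dict[str, float]
    realized_h2: float
    seed: int


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> GenotypeMatrix:
    """n individuals x m unlinked markers, dosages ~ Binomial(2, p) with
    p ~ Uniform(maf_range) per marker, on the [0, 2] encoding."""
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise FormatError(f"invalid maf_range {maf_range}: need 0 < lo <= hi <= 0.5")
    if n < 2 or m < 1:
        raise FormatError("need n >= 2 individuals and m >= 1 markers")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=m)
    dosage = rng.binomial(2, p, size=(n, m)).astype(float)
    width = max(3, len(str(n)))
    individual_ids = [f"ind{i + 1:0{width}d}" for i in range(n)]
    marker_ids = [f"m{j + 1:0{max(4, len(str(m)))}d}" for j in range(m)]
    return GenotypeMatrix(individual_ids, marker_ids, dosage, Encoding.ZERO_1_2)


def simulate_phenotypes(
    g: GenotypeMatrix,
    n_qtl: int,
    h2: float,
    seed: int = 0,
) -> SimulatedPopulation:
    """Additive trait on an existing genotype panel with exact realized h2.

    n_qtl markers are drawn without replacement as QTL with N(0,1)
    effects; tbv_i = sum_j effect_j * dosage_ij.  Noise variance is
    var(tbv) (1 - h2) / h2, so the variance ratio identity holds to
    machine precision.  h2 = 0 gives a pure-noise N(0, 1) trait with all
    breeding values zero; h2 = 1 is rejected (degenerate noise).
    """
    if not (0.0 <= h2 < 1.0):
        raise FormatError(f"h2 must lie in [0, 1); got {h2}")
    if not (1 <= n_qtl <= g.n_markers):
        raise FormatError(f"n_qtl must lie in [1, {g.n_markers}]; got {n_qtl}")
    if g.has_missing():
        raise FormatError("phenotype simulation requires a complete matrix")
    rng = np.random.default_rng(seed)
    qtl_idx = np.sort(rng.choice(g.n_markers, size=n_qtl, replace=False))
    qtl_ids = [g.marker_ids[j] for j in qtl_idx]
    if h2 == 0.0:
        effects = np.zeros(n_qtl)
        tbv = np.zeros(g.n_individuals)
        sigma_e2 = 1.0
    else:
        effects = rng.standard_normal(n_qtl)
        tbv = g.dosage[:, qtl_idx] @ effects
        var_tbv = float(tbv.var(ddof=1))
        sigma_e2 = var_tbv * (1.0 - h2) / h2
    noise = rng.normal(0.0, np.sqrt(sigma_e2), size=g.n_individuals)
    pheno = tbv + noise
    return SimulatedPopulation(
        genotypes=g,
        qtl_ids=qtl_ids,
        qtl_effects={m: float(e) for m, e in zip(qtl_ids, effects)},
        true_breeding_values={
            i: float(v) for i, v in zip(g.individual_ids, tbv)
        },
        phenotypes={i: float(v) for i, v in zip(g.individual_ids, pheno)},
        realized_h2=h2,
        seed=seed,
    )


def simulate_trial(
    genotype_values: dict[str, float],
    design: Design | str = Design.RCBD,
    n_reps: int = 2,
    block_sd: float = 0.0,
    plot_sd: float = 0.0,
    seed: int = 0,
    trial_id: str = "trial1",
    trait: str = "trait1",
    block_size: int = 10,
) -> PhenotypeTable:
    """Lay genotypes out in a replicated field trial and add block and
    plot noise.

    Each genotype appears once per replication.  RCBD draws one random
    intercept per replication; ALPHA_LATTICE and AUGMENTED draw one per
    incomplete block of ``block_size`` genotypes nested in each
    replication; UNKNOWN adds no block structure (completely randomized).
    observation = genotype value + block effect + N(0, plot_sd^2).
    """
    if isinstance(design, str):
        try:
            design = Design(design)
        except ValueError:
            raise FormatError(f"unknown design label {design!r}") from None
    if not isinstance(design, Design):
        raise FormatError(f"unknown design label {design!r}")
    if n_reps < 1:
        raise FormatError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    genotypes = list(genotype_values)
    rows = []
    for rep in range(1, n_reps + 1):
        if design is Design.RCBD:
            rep_effect = rng.normal(0.0, block_sd)
        order = rng.permutation(len(genotypes)) if design in (
            Design.ALPHA_LATTICE, Design.AUGMENTED
        ) else np.arange(len(genotypes))
        block_effects: dict[int, float] = {}
        for pos, gi in enumerate(order):
            genotype = genotypes[gi]
            if design is Design.RCBD:
                block = None
                effect = rep_effect
            elif design in (Design.ALPHA_LATTICE, Design.AUGMENTED):
                block = pos // block_size + 1
                if block not in block_effects:
                    block_effects[block] = rng.normal(0.0, block_sd)
                effect = block_effects[block]
            else:  # UNKNOWN: completely randomized
                block = None
                effect = 0.0
            value = genotype_values[genotype] + effect + rng.normal(0.0, plot_sd)
            rows.append(
                {
                    "trial": trial_id,
                    "genotype": genotype,
                    "replication": str(rep) if design is not Design.UNKNOWN else pd.NA,
                    "block": f"{rep}.{block}" if block is not None else pd.NA,
                    "design": design,
                    trait: value,
                }
            )
    return PhenotypeTable(pd.DataFrame(rows))
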