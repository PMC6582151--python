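"""Selection acting on segregant pools.

Three forces are modelled:

* a toxin-antidote selfish element (peel-1/zeel-1-like): a sperm-delivered
  toxin with a zygotically expressed antidote, so a zygote dies (with
  probability ``s``, the element's penetrance) iff its father carries at
  least one element allele and the zygote itself inherits none;
* fitness loci that weight a male's probability of being chosen to mate,
  multiplicatively across loci;
* truncation selection on a quantitative score ``S = g + d`` where ``g`` is
  the 0/1/2 causal genotype and ``d`` Gaussian noise scaled so the locus
  explains a target fraction Ve of the score variance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ALLELE_A, ALLELE_B, AlleleCountTable, MarkerGrid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DriveElement:
    """A toxin-antidote drive locus.

    ``element_allele`` is the allele carrying the linked toxin+antidote
    pair (allele A by default, as for the N2 peel-1/zeel-1 haplotype);
    ``s`` is the penetrance of the toxin: the fitness of a poisoned
    zygote without the antidote is 1 - s.
    """

    chrom: str
    pos: int
    s: float = 1.0
    element_allele: int = ALLELE_A

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= 1.0):
            raise ValueError("penetrance s must be in [0,1]")

    def with_s(self, s: float) -> "DriveElement":
        return DriveElement(self.chrom, self.pos, s, self.element_allele)


@dataclass(frozen=True)
class FitnessLocus:
    """Per-genotype male mating weights (w_AA, w_AB, w_BB), all > 0."""

    chrom: str
    pos: int
    w_aa: float = 1.0
    w_ab: float = 1.0
    w_bb: float = 1.0

    def __post_init__(self) -> None:
        for w in (self.w_aa, self.w_ab, self.w_bb):
            if not (w > 0 and np.isfinite(w)):
                raise ValueError("fitness weights must be positive and finite")

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.w_aa, self.w_ab, self.w_bb])


@dataclass(frozen=True)
class EffectSizeModel:
    """Truncation-selection model for a causal locus explaining Ve of variance.

    The score is S = g + d with g the allele-B dosage (0/1/2) and
    d ~ Normal(0, sigma^2). Two sigma^2 conventions are available:
    'variance-consistent' (default) uses sigma^2 = Vl (1 - Ve) / Ve, which
    makes Var(g)/Var(S) equal Ve for any genotype variance Vl; 'as-printed'
    uses sigma^2 = (1 - Ve) / (Ve Vl). They agree when Vl = 1.
    """

    chrom: str
    pos: int
    ve: float
    truncation: float = 0.05
    variant: str = "variance-consistent"
    causal_allele: int = ALLELE_B

    def __post_init__(self) -> None:
        if not (0.0 < self.ve < 1.0):
            raise ValueError("Ve must be in (0,1)")
        if not (0.0 < self.truncation < 1.0):
            raise ValueError("truncation fraction must be in (0,1)")
        if self.variant not in ("variance-consistent", "as-printed"):
            raise ValueError(f"unknown sigma^2 variant {self.variant!r}")

    def sigma2(self, vl: float) -> float:
        if vl <= 0:
            raise ValueError("causal locus is monomorphic (Vl = 0)")
        if self.variant == "variance-consistent":
            return vl * (1.0 - self.ve) / self.ve
        return (1.0 - self.ve) / (self.ve * vl)


def drive_lethality(mother_gt: int, father_gt: int, zygote_gt: int,
                    element: DriveElement, rng: np.random.Generator) -> bool:
    """Whether one zygote survives the toxin-antidote interaction.

    Genotypes are element-allele copy numbers. The toxin is strictly
    paternal: the zygote is at risk iff the father carries >= 1 element
    allele; the zygotic antidote rescues any zygote with >= 1 copy. At-risk
    zygotes die with probability ``s``. The maternal genotype never
    triggers lethality (it only shapes zygote genotype frequencies).
    """
    at_risk = father_gt >= 1 and zygote_gt == 0
    return not (at_risk and rng.random() < element.s)


def male_fitness_weights(pop, male_idx: np.ndarray,
                         loci: list[FitnessLocus] | None) -> np.ndarray:
    """Mating weight per male: product of per-locus genotype weights, 1 with
    no loci. Hemizygous-X genotypes map 0 -> w_AA and 1 -> w_BB."""
    w = np.ones(male_idx.size)
    for locus in loci or []:
        j = pop.markers.index_of(locus.chrom, locus.pos)
        g = pop.dosage(j)[male_idx].astype(int)
        if pop._is_x_marker(j):
            g = g * 2  # hemizygous: one B copy behaves as the BB class
        w *= locus.weights[g]
    return w


def male_fitness_weight(individual, loci: list[FitnessLocus] | None) -> float:
    """Object-layer counterpart of :func:`male_fitness_weights`."""
    w = 1.0
    for locus in loci or []:
        g = individual.genotype_at(locus.chrom, locus.pos)
        if locus.chrom == individual.hap1.gmap.x_name and locus.chrom not in individual.hap2.segments:
            g *= 2
        w *= float(locus.weights[g])
    return w


def truncation_select(pool, model: EffectSizeModel, rng: np.random.Generator,
                      control_size: int | None = None):
    """Split a pool into a phenotype-selected and a random control population.

    Every individual receives a score S = g + d at the causal locus; the
    top ``model.truncation`` fraction by S forms the selected population,
    and an independent uniform subset (default: same size) the control.
    Boundary ties are broken uniformly at random under the run's seed.
    """
    j = pool.markers.index_of(model.chrom, model.pos)
    g = pool.dosage(j).astype(float)
    if model.causal_allele == ALLELE_A:
        g = 2.0 - g
    vl = float(np.var(g))
    sigma2 = model.sigma2(vl)  # raises on monomorphic locus
    s_score = g + rng.normal(0.0, np.sqrt(sigma2), size=len(pool))
    n_sel = max(1, int(round(model.truncation * len(pool))))
    shuffle = rng.permutation(len(pool))  # uniform tie-break at the cut
    order = shuffle[np.argsort(-s_score[shuffle], kind="stable")]
    selected = pool.subset(np.sort(order[:n_sel]))
    if control_size is None:
        control_size = n_sel
    ctrl_idx = np.sort(rng.choice(len(pool), size=control_size, replace=False))
    control = pool.subset(ctrl_idx)
    return selected, control


def simulate_pool_counts(selected, control, markers: MarkerGrid, coverage: int,
                         rng: np.random.Generator) -> AlleleCountTable:
    """Binomial sequencing of two pools at fixed depth.

    Per marker and pool, the allele-B read count is Binomial(C, pool
    frequency of B) and the allele-A count its complement, mimicking
    pooled short-read genotyping at C-fold coverage.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    f_high = selected.freq_b()
    f_low = control.freq_b()
    n3 = rng.binomial(coverage, f_high)
    n4 = rng.binomial(coverage, f_low)
    df = pd.DataFrame({
        "chrom": markers.chrom, "pos": markers.pos,
        "n1": coverage - n3, "n2": coverage - n4, "n3": n3, "n4": n4,
    })
    return AlleleCountTable(df, markers)
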