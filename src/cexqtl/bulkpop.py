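"""Forward simulator of two-parent, outcrossing-only segregant pools.

The model follows obligate-outcrossing C. elegans crosses (selfing
abolished): non-overlapping generations, at most one crossover per
chromosome per meiosis (probability ``p_xo``, default 0.5), crossover
position uniform in genetic-map units, X/0 sex determination (males
hemizygous for X; the paternal gamete decides offspring sex), every female
mates once, males sampled with replacement weighted by their fitness, each
mated female leaving a fixed number of progeny, and the population
down-sampled uniformly to a cap after drive lethality.

Two representations are provided. ``Haplotype``/``Individual`` keep exact
breakpoint segments and are convenient for small crosses and invariants;
``Population`` stores parental origin at the marker grid as dense int8
arrays so that meiosis over hundreds of thousands of gametes is a handful
of vectorised numpy operations. Both implement the same meiosis rule and a
test pins them against each other draw-for-draw.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import ALLELE_A, ALLELE_B, GeneticMap, MarkerGrid
from .selection import DriveElement, FitnessLocus, male_fitness_weights

logger = logging.getLogger(__name__)

FEMALE = 0
MALE = 1


class ExtinctionError(RuntimeError):
    """Raised when a generation leaves no viable offspring (or a single sex)."""

    def __init__(self, message: str, generation: int | None = None):
        super().__init__(message)
        self.generation = generation


@dataclass
class SimConfig:
    """Run parameters of a segregant-pool simulation.

    Defaults reproduce the standard design: 1,000 F1 founders, cap 50,000,
    10 progeny per mated female, crossover probability 0.5 per chromosome.
    """

    pop_cap: int = 50_000
    progeny_per_female: int = 10
    f1_founders: int = 1_000
    generations: int = 10
    p_xo: float = 0.5
    seed: int | None = None
    fitness_loci: list[FitnessLocus] = field(default_factory=list)
    drive: DriveElement | None = None
    sex_ratio: float = 0.5  # probability an offspring is female

    def __post_init__(self) -> None:
        if self.pop_cap < self.f1_founders:
            raise ValueError("population cap must be >= founder count")
        if not (0.0 <= self.p_xo <= 1.0):
            raise ValueError("crossover probability must be in [0,1]")
        if not (0.0 < self.sex_ratio < 1.0):
            raise ValueError("sex ratio must be in (0,1)")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Breakpoint-segment object layer
# ---------------------------------------------------------------------------

class Haplotype:
    """One gametic genome as parental-origin segments per chromosome.

    ``segments[chrom]`` is an ordered list of ``(end_bp, origin)`` pairs
    tiling the chromosome's map span ``[start_bp, end_bp]``; origin is
    ALLELE_A (parent 1) or ALLELE_B (parent 2). A male individual's second
    haplotype simply lacks the X entry.
    """

    def __init__(self, segments: dict[str, list[tuple[int, int]]], gmap: GeneticMap):
        self.segments = segments
        self.gmap = gmap
        self.validate()

    @classmethod
    def pure(cls, origin: int, gmap: GeneticMap, chroms: list[str] | None = None) -> "Haplotype":
        chroms = gmap.names if chroms is None else chroms
        return cls({c: [(gmap[c].bp_span[1], origin)] for c in chroms}, gmap)

    def validate(self) -> None:
        for chrom, segs in self.segments.items():
            span = self.gmap[chrom].bp_span
            ends = [e for e, _ in segs]
            if any(b <= a for a, b in zip(ends, ends[1:])):
                raise ValueError(f"{chrom}: segment ends not strictly increasing")
            if ends[-1] != span[1]:
                raise ValueError(f"{chrom}: segments do not tile the chromosome span")

    def origin_at(self, chrom: str, bp: int) -> int:
        lo, hi = self.gmap[chrom].bp_span
        if not (lo <= bp <= hi):
            raise ValueError(f"{chrom}:{bp} outside map span")
        for end, origin in self.segments[chrom]:
            if bp <= end:
                return origin
        raise AssertionError("unreachable: segments tile the span")

    def n_breakpoints(self, chrom: str) -> int:
        return len(self.segments[chrom]) - 1

    def to_vector(self, markers: MarkerGrid) -> np.ndarray:
        """Parental origin at every grid marker present in this haplotype."""
        out = np.empty(len(markers), dtype=np.int8)
        out.fill(-1)
        for chrom, sl in markers.chrom_slices().items():
            if chrom not in self.segments:
                continue
            pos = markers.pos[sl]
            ends = np.array([e for e, _ in self.segments[chrom]])
            origins = np.array([o for _, o in self.segments[chrom]], dtype=np.int8)
            out[sl] = origins[np.searchsorted(ends, pos)]
        return out


def _join_at(h_first: Haplotype, h_second: Haplotype, chrom: str, xo_bp: float) -> list[tuple[int, int]]:
    """Single-crossover product: h_first up to xo_bp, h_second after."""
    segs: list[tuple[int, int]] = []
    for end, origin in h_first.segments[chrom]:
        if end < xo_bp:
            segs.append((end, origin))
        else:
            segs.append((int(np.floor(xo_bp)), origin))
            break
    for end, origin in h_second.segments[chrom]:
        if end > xo_bp:
            if segs and segs[-1][1] == origin:
                segs[-1] = (end, origin)  # merge same-origin neighbours
            elif not segs or end > segs[-1][0]:
                segs.append((end, origin))
    return segs


@dataclass
class Individual:
    """Diploid individual: two haplotypes and a sex label.

    Males are X/0 hemizygous: ``hap2`` has no X entry.
    """

    hap1: Haplotype
    hap2: Haplotype
    sex: int

    def __post_init__(self) -> None:
        x = self.hap1.gmap.x_name
        if x is not None:
            if self.sex == MALE and x in self.hap2.segments:
                raise ValueError("male individuals carry a single X haplotype")
            if self.sex == FEMALE and x not in self.hap2.segments:
                raise ValueError("female individuals need two X haplotypes")

    def genotype_at(self, chrom: str, bp: int) -> int:
        """Allele-B dosage at a position (male X counted once)."""
        g = int(self.hap1.origin_at(chrom, bp) == ALLELE_B)
        if chrom in self.hap2.segments:
            g += int(self.hap2.origin_at(chrom, bp) == ALLELE_B)
        return g


def make_gamete(parent: Individual, gmap: GeneticMap, rng: np.random.Generator,
                p_xo: float = 0.5, chroms: list[str] | None = None) -> Haplotype:
    """Simulate one meiosis.

    Per chromosome, with probability ``1 - p_xo`` one parental haplotype is
    copied whole (chosen uniformly); otherwise a single crossover is placed
    uniformly in cM, converted to bp through the map, and one of the two
    reciprocal products is returned uniformly. Chromosomes present in only
    one haplotype (the male X) are transmitted as-is.
    """
    chroms = list(parent.hap1.segments) if chroms is None else chroms
    segs: dict[str, list[tuple[int, int]]] = {}
    for chrom in chroms:
        if chrom not in gmap:
            raise KeyError(f"chromosome {chrom!r} absent from genetic map")
        haps = [h for h in (parent.hap1, parent.hap2) if chrom in h.segments]
        if len(haps) == 1:
            segs[chrom] = list(haps[0].segments[chrom])
            continue
        start = int(rng.integers(2))
        if rng.random() < p_xo:
            lo, hi = gmap[chrom].cm_span
            xo_cm = lo + rng.random() * (hi - lo)
            xo_bp = gmap[chrom].cm_to_bp(xo_cm)
            segs[chrom] = _join_at(haps[start], haps[1 - start], chrom, xo_bp)
        else:
            segs[chrom] = list(haps[start].segments[chrom])
    return Haplotype(segs, gmap)


def mate(mother: Individual, father: Individual, n_progeny: int,
         gmap: GeneticMap, rng: np.random.Generator, p_xo: float = 0.5) -> list[Individual]:
    """Produce progeny from one female x male pairing.

    Each progeny combines an independent maternal and paternal gamete. Sex
    follows the paternal gamete: X-bearing sperm give females, nullo-X
    sperm give males (males therefore inherit their X from the mother).
    Drive lethality is applied downstream, not here.
    """
    if mother.sex != FEMALE or father.sex != MALE:
        raise ValueError("mate() requires a female mother and a male father")
    x = gmap.x_name
    autosomes = [c for c in gmap.names if c != x]
    out = []
    for _ in range(n_progeny):
        egg = make_gamete(mother, gmap, rng, p_xo)
        sperm_auto = make_gamete(father, gmap, rng, p_xo, chroms=autosomes)
        x_bearing = x is not None and rng.random() < 0.5
        if x is None:
            sex = FEMALE if rng.random() < 0.5 else MALE
            out.append(Individual(egg, sperm_auto, sex))
        elif x_bearing:
            sperm = Haplotype({**sperm_auto.segments, x: list(father.hap1.segments[x])}, gmap)
            out.append(Individual(egg, sperm, FEMALE))
        else:
            out.append(Individual(egg, sperm_auto, MALE))
    return out


# ---------------------------------------------------------------------------
# Vectorised population engine
# ---------------------------------------------------------------------------

class Population:
    """A generation of diploids as dense parental-origin arrays.

    ``haps`` has shape (n, 2, n_markers) with int8 origins (0 = allele A
    parent, 1 = allele B parent); row 0 is the maternal, row 1 the paternal
    gamete. Males carry one X: their row-1 X columns mirror row 0 and are
    counted once in all dosage/frequency computations.
    """

    def __init__(self, haps: np.ndarray, sex: np.ndarray, markers: MarkerGrid):
        if haps.ndim != 3 or haps.shape[1] != 2 or haps.shape[2] != len(markers):
            raise ValueError("haps must have shape (n, 2, n_markers)")
        self.haps = haps
        self.sex = np.asarray(sex, dtype=np.int8)
        self.markers = markers
        self._slices = markers.chrom_slices()

    # -- construction -------------------------------------------------------

    @classmethod
    def f1_founders(cls, n: int, markers: MarkerGrid, rng: np.random.Generator,
                    sex_ratio: float = 0.5) -> "Population":
        """F1 of an (A female) x (B male) cross: all autosomes heterozygous;
        F1 males carry the maternal (A) X only."""
        m = len(markers)
        haps = np.zeros((n, 2, m), dtype=np.int8)
        haps[:, 0, :] = ALLELE_A
        haps[:, 1, :] = ALLELE_B
        sex = np.where(rng.random(n) < sex_ratio, FEMALE, MALE).astype(np.int8)
        x = markers.map.x_name
        if x is not None:
            sl = markers.chrom_slices().get(x)
            if sl is not None:
                haps[sex == MALE, 1, sl] = ALLELE_A  # mirror of maternal X
        return cls(haps, sex, markers)

    @classmethod
    def from_individuals(cls, individuals: list[Individual], markers: MarkerGrid) -> "Population":
        n, m = len(individuals), len(markers)
        haps = np.zeros((n, 2, m), dtype=np.int8)
        sex = np.zeros(n, dtype=np.int8)
        x = markers.map.x_name
        sl_x = markers.chrom_slices().get(x) if x is not None else None
        for i, ind in enumerate(individuals):
            haps[i, 0] = ind.hap1.to_vector(markers)
            v2 = ind.hap2.to_vector(markers)
            if ind.sex == MALE and sl_x is not None:
                v2[sl_x] = haps[i, 0, sl_x]
            haps[i, 1] = v2
            sex[i] = ind.sex
        return cls(haps, sex, markers)

    # -- basic queries -------------------------------------------------------

    def __len__(self) -> int:
        return self.haps.shape[0]

    @property
    def n_females(self) -> int:
        return int((self.sex == FEMALE).sum())

    @property
    def n_males(self) -> int:
        return int((self.sex == MALE).sum())

    def subset(self, idx: np.ndarray) -> "Population":
        return Population(self.haps[idx], self.sex[idx], self.markers)

    def dosage(self, marker_index: int) -> np.ndarray:
        """Allele-B copy number per individual at one marker (male X: 0/1)."""
        j = marker_index
        g = (self.haps[:, :, j] == ALLELE_B).sum(axis=1).astype(np.int8)
        if self._is_x_marker(j):
            male = self.sex == MALE
            g[male] = (self.haps[male, 0, j] == ALLELE_B).astype(np.int8)
        return g

    def freq_b(self) -> np.ndarray:
        """Frequency of allele B per marker (male X chromosomes counted once)."""
        n = len(self)
        s = (self.haps == ALLELE_B).sum(axis=(0, 1)).astype(float)
        denom = np.full(len(self.markers), 2.0 * n)
        x = self.markers.map.x_name
        if x is not None and x in self._slices:
            sl = self._slices[x]
            male = self.sex == MALE
            n_m = int(male.sum())
            # male row-1 X mirrors row 0: subtract the duplicate copies
            dup = (self.haps[male, 1, sl] == ALLELE_B).sum(axis=0)
            s[sl] -= dup
            denom[sl] = 2.0 * (n - n_m) + n_m
        return s / denom

    def _is_x_marker(self, j: int) -> bool:
        x = self.markers.map.x_name
        return x is not None and x in self._slices and self._slices[x].start <= j < self._slices[x].stop


def _draw_meiosis(n: int, length_cm: float, cm_lo: float, p_xo: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised meiosis draws for one chromosome: starting haplotype and
    crossover position in cM (+inf when no crossover occurs)."""
    start = rng.integers(0, 2, size=n).astype(np.int8)
    has_xo = rng.random(n) < p_xo
    xo_cm = np.where(has_xo, cm_lo + rng.random(n) * length_cm, np.inf)
    return start, xo_cm


def _transmit(parent_haps: np.ndarray, start: np.ndarray, xo_cm: np.ndarray,
              marker_cm: np.ndarray) -> np.ndarray:
    """Gamete origins at markers given meiosis draws for one chromosome.

    Markers with cM <= crossover position come from the starting haplotype,
    the rest from the other; xo_cm = inf copies the starting haplotype.
    """
    k = parent_haps.shape[0]
    rows = np.arange(k)
    h_start = parent_haps[rows, start]
    h_other = parent_haps[rows, 1 - start]
    return np.where(marker_cm[None, :] <= xo_cm[:, None], h_start, h_other)


def _transmit_single_marker(haps: np.ndarray, idx: np.ndarray, j: int, cm_j: float,
                            start: np.ndarray, xo_cm: np.ndarray) -> np.ndarray:
    """Transmitted origin at one marker, without materialising gametes."""
    rows = np.arange(idx.size)
    which = np.where(cm_j <= xo_cm, start, 1 - start).astype(np.intp)
    return haps[idx, which, j]


def propagate(pop: Population, config: SimConfig, gmap: GeneticMap,
              rng: np.random.Generator, generation: int | None = None) -> Population:
    """Advance one non-overlapping generation.

    Every female mates exactly once with a male drawn with replacement with
    probability proportional to his fitness weight (uniform with no fitness
    loci); each mating yields ``progeny_per_female`` zygotes; toxin-antidote
    lethality removes susceptible zygotes; survivors are down-sampled
    uniformly without replacement to the population cap.
    """
    females = np.flatnonzero(pop.sex == FEMALE)
    males = np.flatnonzero(pop.sex == MALE)
    if females.size == 0 or males.size == 0:
        raise ExtinctionError("population lost one sex entirely", generation)

    w = male_fitness_weights(pop, males, config.fitness_loci)
    fathers = males[rng.choice(males.size, size=females.size, p=w / w.sum())]
    k = config.progeny_per_female
    mother_idx = np.repeat(females, k)
    father_idx = np.repeat(fathers, k)
    n_off = mother_idx.size

    x = gmap.x_name
    slices = pop.markers.chrom_slices()
    # meiosis draws for every putative zygote, both gametes, all chromosomes
    draws: dict[str, tuple] = {}
    for chrom in gmap.names:
        if chrom not in slices:
            continue
        cmap = gmap[chrom]
        m_start, m_xo = _draw_meiosis(n_off, cmap.length_cm, cmap.cm_span[0], config.p_xo, rng)
        if chrom == x:
            draws[chrom] = (m_start, m_xo, None, None)
        else:
            p_start, p_xo_cm = _draw_meiosis(n_off, cmap.length_cm, cmap.cm_span[0], config.p_xo, rng)
            draws[chrom] = (m_start, m_xo, p_start, p_xo_cm)

    sex_off = np.where(rng.random(n_off) < config.sex_ratio, FEMALE, MALE).astype(np.int8)

    alive = np.ones(n_off, dtype=bool)
    drive = config.drive
    if drive is not None and drive.s > 0:
        j = pop.markers.index_of(drive.chrom, drive.pos)
        if pop._is_x_marker(j):
            raise ValueError("drive element must sit on an autosome")
        cm_j = float(pop.markers.cm[j])
        elem = drive.element_allele
        m_start, m_xo, p_start, p_xo_cm = draws[drive.chrom]
        mat = _transmit_single_marker(pop.haps, mother_idx, j, cm_j, m_start, m_xo)
        pat = _transmit_single_marker(pop.haps, father_idx, j, cm_j, p_start, p_xo_cm)
        zyg_cnt = (mat == elem).astype(np.int8) + (pat == elem).astype(np.int8)
        father_carrier = (pop.haps[father_idx, :, j] == elem).any(axis=1)
        susceptible = father_carrier & (zyg_cnt == 0)
        dies = susceptible & (rng.random(n_off) < drive.s)
        alive = ~dies

    surv = np.flatnonzero(alive)
    if surv.size == 0:
        raise ExtinctionError("all offspring died of drive lethality", generation)
    if surv.size > config.pop_cap:
        surv = surv[np.sort(rng.choice(surv.size, size=config.pop_cap, replace=False))]

    # materialise only the kept offspring; gather parent rows once
    m_total = len(pop.markers)
    new = np.empty((surv.size, 2, m_total), dtype=np.int8)
    mk, fk, sk = mother_idx[surv], father_idx[surv], sex_off[surv]
    mh_all = pop.haps[mk]
    fh_all = pop.haps[fk]
    for chrom, sl in slices.items():
        cm = pop.markers.cm[sl]
        m_start, m_xo, p_start, p_xo_cm = draws[chrom]
        new[:, 0, sl] = _transmit(mh_all[:, :, sl], m_start[surv], m_xo[surv], cm)
        if chrom == x:
            # X-bearing sperm (female offspring) deliver the father's single X
            new[:, 1, sl] = np.where((sk == FEMALE)[:, None],
                                     fh_all[:, 0, sl], new[:, 0, sl])
        else:
            new[:, 1, sl] = _transmit(fh_all[:, :, sl], p_start[surv], p_xo_cm[surv], cm)
    return Population(new, sk, pop.markers)


def expand_pool(pop: Population, target: int, config: SimConfig, gmap: GeneticMap,
                rng: np.random.Generator) -> Population:
    """One additional random-mating generation without a cap, sized to target.

    Mothers are drawn uniformly with replacement from females and fathers
    with fitness weighting, so the expansion preserves the source
    population's allele frequencies up to sampling noise. Drive lethality
    still applies; the loop tops up until the target size is reached.
    """
    chunks, have = [], 0
    grow = config.with_(pop_cap=max(target, 1), progeny_per_female=1)
    while have < target:
        need = target - have
        females = np.flatnonzero(pop.sex == FEMALE)
        if females.size == 0:
            raise ExtinctionError("no females available for expansion")
        mothers = females[rng.integers(0, females.size, size=need)]
        sub = Population(np.concatenate([pop.haps[mothers], pop.haps[pop.sex == MALE]]),
                         np.concatenate([np.zeros(need, np.int8),
                                         np.ones(int((pop.sex == MALE).sum()), np.int8)]),
                         pop.markers)
        out = propagate(sub, grow, gmap, rng)
        chunks.append(out)
        have += len(out)
    haps = np.concatenate([c.haps for c in chunks])[:target]
    sex = np.concatenate([c.sex for c in chunks])[:target]
    return Population(haps, sex, pop.markers)


def trajectory_frame(freqs: dict[int, np.ndarray], markers: MarkerGrid) -> pd.DataFrame:
    """Long-format per-generation marker frequencies with deviation from 0.5."""
    rows = []
    for gen, f in freqs.items():
        rows.append(pd.DataFrame({
            "generation": gen, "chrom": markers.chrom, "pos": markers.pos,
            "freq_b": f, "deviation": f - 0.5,
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_cross(config: SimConfig, gmap: GeneticMap, markers: MarkerGrid,
                   rng: np.random.Generator | None = None,
                   record_generations: bool = True) -> tuple[pd.DataFrame, Population]:
    """Found an A x B cross and propagate it for ``config.generations``
    non-overlapping generations, recording per-generation B-allele
    frequencies. Generation 1 is the F1; with ``generations=1`` nothing is
    propagated. Deterministic given ``config.seed`` (or a supplied rng).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = Population.f1_founders(config.f1_founders, markers, rng, config.sex_ratio)
    freqs: dict[int, np.ndarray] = {}
    if record_generations:
        freqs[1] = pop.freq_b()
    for gen in range(2, config.generations + 1):
        try:
            pop = propagate(pop, config, gmap, rng, generation=gen)
        except ExtinctionError as err:
            raise ExtinctionError(f"generation {gen}: {err}", gen) from err
        if record_generations:
            freqs[gen] = pop.freq_b()
    traj = trajectory_frame(freqs, markers) if record_generations else pd.DataFrame()
    return traj, pop
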