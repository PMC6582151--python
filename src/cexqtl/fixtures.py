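"""Synthetic genome and experiment generators.

These build everything the rest of the package consumes without any
external data: a worm-like genome (6 chromosomes, ~100 Mb total, one X,
~50 cM each, with recombination concentrated on the chromosome arms as in
C. elegans), marker grids, and end-to-end simulated pooled-sequencing
experiments with a ground-truth record for testing.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .bulkpop import SimConfig, simulate_cross
from .genome import ChromosomeMap, GeneticMap, MarkerGrid
from .selection import DriveElement, EffectSizeModel, simulate_pool_counts, truncation_select

logger = logging.getLogger(__name__)

DEFAULT_CHROM_BP = 17_000_000  # ~100 Mb over six chromosomes
DEFAULT_CHROM_CM = 50.0


def make_fixture_genome(n_chrom: int = 6, bp_length: int = DEFAULT_CHROM_BP,
                        map_profile: str = "arm-biased", n_markers: int = 2_000,
                        seed: int | None = None, cm_length: float = DEFAULT_CHROM_CM,
                        out_dir=None) -> tuple[GeneticMap, MarkerGrid]:
    """Generate a genetic map and marker grid emulating a worm-like genome.

    'uniform' makes cM strictly proportional to bp. 'arm-biased' puts 45 of
    the 50 cM on the outer thirds of each chromosome (the arms), matching
    the strongly nonuniform recombination landscape of C. elegans where
    crossovers are rare in chromosome centres. Markers are placed uniformly
    in bp; the last chromosome is flagged as X. Deterministic given seed.
    """
    if n_markers < 2 * n_chrom:
        raise ValueError("need at least 2 markers per chromosome")
    rng = np.random.default_rng(seed)
    chroms: dict[str, ChromosomeMap] = {}
    names = [f"chr{i + 1}" for i in range(n_chrom - 1)] + ["chrX"]
    for i, name in enumerate(names):
        if map_profile == "uniform":
            bp = np.array([1, bp_length])
            cm = np.array([0.0, cm_length])
        elif map_profile == "arm-biased":
            third = bp_length // 3
            bp = np.array([1, third, 2 * third, bp_length])
            arm_cm = 0.45 * cm_length
            cm = np.array([0.0, arm_cm, cm_length - arm_cm, cm_length])
        else:
            raise ValueError(f"unknown map profile {map_profile!r}")
        chroms[name] = ChromosomeMap(name, bp, cm, is_x=(name == "chrX"))
    gmap = GeneticMap(chroms)

    per = np.full(n_chrom, n_markers // n_chrom)
    per[: n_markers % n_chrom] += 1
    rows = []
    for name, k in zip(names, per):
        pos = np.sort(rng.choice(np.arange(2, bp_length), size=k, replace=False))
        for p in pos:
            rows.append((name, int(p)))
    markers = MarkerGrid(pd.DataFrame(rows, columns=["chrom", "pos"]), gmap)

    if out_dir is not None:
        from . import io
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io.write_genetic_map(gmap, out_dir / "genetic_map.tsv")
        io.write_marker_grid(markers, out_dir / "markers.tsv")
    return gmap, markers


def nearest_marker(markers: MarkerGrid, chrom: str, frac: float = 0.5) -> tuple[str, int]:
    """Marker nearest a fractional position along a chromosome's bp span."""
    cmap = markers.map[chrom]
    target = cmap.bp_span[0] + frac * (cmap.bp_span[1] - cmap.bp_span[0])
    sl = markers.chrom_slices()[chrom]
    pos = markers.pos[sl]
    return chrom, int(pos[np.argmin(np.abs(pos - target))])


def make_fixture_experiment(design: str, gmap: GeneticMap, markers: MarkerGrid,
                            seed: int, config: SimConfig | None = None,
                            effect: EffectSizeModel | None = None,
                            drive: DriveElement | None = None,
                            coverage: int = 100, pool_size: int | None = None,
                            out_dir=None):
    """Simulate a complete pooled experiment and (optionally) write its files.

    Designs:
      'drug-selection'     one tail (truncation survivors) vs a random control;
      'two-tail-sort'      top tail vs bottom tail of the score distribution;
      'neutral-timecourse' no causal locus: two random subsets as high/low.

    Returns (counts, truth, trajectory); truth is a JSON-serialisable dict
    with the causal loci, Ve, and drive penetrance used.
    """
    from .selection import ALLELE_A  # local, trivial

    rng = np.random.default_rng(seed)
    cfg = (config or SimConfig()).with_(seed=None, drive=drive)
    traj, pop = simulate_cross(cfg, gmap, markers, rng=rng)
    truth: dict = {"design": design, "seed": seed, "drive": None, "causal": []}
    if drive is not None:
        truth["drive"] = {"chrom": drive.chrom, "pos": drive.pos, "s": drive.s}

    n_half = pool_size or max(1, int(round(0.05 * len(pop))))
    if design == "neutral-timecourse":
        idx = rng.permutation(len(pop))
        selected = pop.subset(np.sort(idx[:n_half]))
        control = pop.subset(np.sort(idx[n_half:2 * n_half]))
    elif design in ("drug-selection", "two-tail-sort"):
        if effect is None:
            raise ValueError(f"{design} design needs an EffectSizeModel")
        truth["causal"] = [{"chrom": effect.chrom, "pos": effect.pos, "ve": effect.ve}]
        if design == "drug-selection":
            selected, control = truncation_select(pop, effect, rng,
                                                  control_size=n_half)
        else:
            j = pop.markers.index_of(effect.chrom, effect.pos)
            g = pop.dosage(j).astype(float)
            if effect.causal_allele == ALLELE_A:
                g = 2.0 - g
            score = g + rng.normal(0.0, np.sqrt(effect.sigma2(float(np.var(g)))), len(pop))
            order = np.argsort(-score)
            k = max(1, int(round(effect.truncation * len(pop))))
            selected = pop.subset(np.sort(order[:k]))
            control = pop.subset(np.sort(order[-k:]))
    else:
        raise ValueError(f"unknown experiment design {design!r}")

    counts = simulate_pool_counts(selected, control, markers, coverage, rng)

    if out_dir is not None:
        from . import io
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io.write_allele_counts(counts, out_dir / "counts.tsv")
        io.write_trajectory(traj, out_dir / "trajectory.tsv")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return counts, truth, traj
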