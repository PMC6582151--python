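"""Genetic map, marker grid, and pooled allele-count containers.

Coordinates are 1-based inclusive (VCF convention) throughout. Allele A is
the parent-1 (reference / N2-like) allele and allele B the parent-2
(CB4856-like) allele; frequencies are reported as frequency of allele B
unless a function says otherwise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALLELE_A = 0
ALLELE_B = 1


class MapFormatError(ValueError):
    """Raised when a genetic-map file is malformed."""


class MapValidationError(ValueError):
    """Raised when map anchors violate monotonicity or span constraints."""


class MapRangeError(ValueError):
    """Raised when a bp/cM query falls outside the anchored span."""


@dataclass(frozen=True)
class ChromosomeMap:
    """Piecewise-linear bp<->cM map for a single chromosome.

    Anchors must be strictly increasing in both bp and cM; the anchored
    span defines the chromosome for every downstream operation.
    """

    name: str
    bp: np.ndarray  # int, strictly increasing, >= 1
    cm: np.ndarray  # float, strictly increasing, >= 0
    is_x: bool = False

    def __post_init__(self) -> None:
        bp = np.asarray(self.bp, dtype=np.int64)
        cm = np.asarray(self.cm, dtype=np.float64)
        object.__setattr__(self, "bp", bp)
        object.__setattr__(self, "cm", cm)
        if bp.size < 2:
            raise MapValidationError(f"chromosome {self.name}: need >= 2 anchors")
        if bp[0] < 1:
            raise MapValidationError(f"chromosome {self.name}: bp anchors must be >= 1")
        if np.any(np.diff(bp) <= 0):
            raise MapValidationError(f"chromosome {self.name}: bp anchors not strictly increasing")
        if np.any(np.diff(cm) <= 0):
            raise MapValidationError(f"chromosome {self.name}: cM anchors not strictly increasing")
        if cm[-1] - cm[0] <= 0:
            raise MapValidationError(f"chromosome {self.name}: total map length must be > 0")

    @property
    def bp_span(self) -> tuple[int, int]:
        return int(self.bp[0]), int(self.bp[-1])

    @property
    def cm_span(self) -> tuple[float, float]:
        return float(self.cm[0]), float(self.cm[-1])

    @property
    def length_cm(self) -> float:
        return float(self.cm[-1] - self.cm[0])

    def bp_to_cm(self, bp) -> np.ndarray | float:
        """Interpolate cM at bp position(s); raises MapRangeError outside the span."""
        arr = np.asarray(bp, dtype=np.float64)
        if np.any(arr < self.bp[0]) or np.any(arr > self.bp[-1]):
            raise MapRangeError(
                f"chromosome {self.name}: bp query outside anchored span {self.bp_span}"
            )
        out = np.interp(arr, self.bp, self.cm)
        return float(out) if np.isscalar(bp) else out

    def cm_to_bp(self, cm) -> np.ndarray | float:
        """Inverse interpolation: bp at cM position(s)."""
        arr = np.asarray(cm, dtype=np.float64)
        if np.any(arr < self.cm[0]) or np.any(arr > self.cm[-1]):
            raise MapRangeError(
                f"chromosome {self.name}: cM query outside anchored span {self.cm_span}"
            )
        out = np.interp(arr, self.cm, self.bp.astype(np.float64))
        return float(out) if np.isscalar(cm) else out


@dataclass
class GeneticMap:
    """Ordered collection of per-chromosome maps.

    The chromosome order given at construction is the canonical genome
    order used by the simulator and the scan.
    """

    chromosomes: dict[str, ChromosomeMap] = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = [c for c in self.chromosomes.values() if c.is_x]
        if len(x) > 1:
            raise MapValidationError("at most one chromosome may be flagged as X")

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    @property
    def x_name(self) -> str | None:
        for c in self.chromosomes.values():
            if c.is_x:
                return c.name
        return None

    def __getitem__(self, name: str) -> ChromosomeMap:
        try:
            return self.chromosomes[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} absent from genetic map") from None

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def bp_to_cm(self, chrom: str, bp):
        return self[chrom].bp_to_cm(bp)

    def cm_to_bp(self, chrom: str, cm):
        return self[chrom].cm_to_bp(cm)


class MarkerGrid:
    """Ordered biallelic SNV markers: (chromosome, 1-based bp) with A/B alleles.

    Backed by a DataFrame with columns chrom, pos, allele_a, allele_b,
    sorted by genome order of the supplied map. Marker cM positions are
    interpolated once at construction.
    """

    def __init__(self, df: pd.DataFrame, genetic_map: GeneticMap):
        required = {"chrom", "pos"}
        if not required.issubset(df.columns):
            raise MapFormatError(f"marker table missing columns {required - set(df.columns)}")
        df = df.copy()
        if "allele_a" not in df.columns:
            df["allele_a"] = "A"
        if "allele_b" not in df.columns:
            df["allele_b"] = "B"
        for chrom in df["chrom"].unique():
            if chrom not in genetic_map:
                raise MapValidationError(f"marker chromosome {chrom!r} absent from genetic map")
        order = {name: i for i, name in enumerate(genetic_map.names)}
        df["_order"] = df["chrom"].map(order)
        df = df.sort_values(["_order", "pos"], kind="mergesort").drop(columns="_order")
        df = df.reset_index(drop=True)
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise MapValidationError("duplicate (chromosome, bp) marker keys")
        cm = np.empty(len(df))
        for chrom, sub in df.groupby("chrom", sort=False):
            cmap = genetic_map[chrom]
            lo, hi = cmap.bp_span
            pos = sub["pos"].to_numpy()
            if pos.min() < lo or pos.max() > hi:
                raise MapValidationError(
                    f"markers on {chrom} fall outside the map span {cmap.bp_span}"
                )
            cm[sub.index] = cmap.bp_to_cm(pos)
        df["cm"] = cm
        self.df = df
        self.map = genetic_map

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def cm(self) -> np.ndarray:
        return self.df["cm"].to_numpy()

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice per chromosome (markers are genome-ordered)."""
        out: dict[str, slice] = {}
        chrom = self.df["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[start]:
                out[chrom[start]] = slice(start, i)
                start = i
        return out

    def index_of(self, chrom: str, pos: int) -> int:
        """Row index of an exact marker; KeyError if absent."""
        hit = self.df.index[(self.df["chrom"] == chrom) & (self.df["pos"] == pos)]
        if len(hit) == 0:
            raise KeyError(f"no marker at {chrom}:{pos}")
        return int(hit[0])


class AlleleCountTable:
    """Per-marker pooled allele counts for a high/treatment and low/control pool.

    n1/n3 are A/B counts in the high pool; n2/n4 are A/B counts in the low
    pool. Derived columns: per-pool depths, coverage C, and the baseline
    frequency q of allele A estimated from the control pool. Markers with a
    monomorphic or empty control pool (q outside (0,1)) are flagged and
    excluded from scans rather than clamped.
    """

    COUNT_COLS = ("n1", "n2", "n3", "n4")

    def __init__(self, df: pd.DataFrame, markers: MarkerGrid | None = None):
        missing = set(self.COUNT_COLS) - set(df.columns)
        if missing:
            raise MapFormatError(f"allele-count table missing columns {sorted(missing)}")
        df = df.copy()
        counts = df[list(self.COUNT_COLS)].to_numpy()
        if np.any(counts < 0):
            raise ValueError("negative allele counts")
        self.df = df.reset_index(drop=True)
        self.markers = markers

    def __len__(self) -> int:
        return len(self.df)

    @property
    def depth_high(self) -> np.ndarray:
        return (self.df["n1"] + self.df["n3"]).to_numpy()

    @property
    def depth_low(self) -> np.ndarray:
        return (self.df["n2"] + self.df["n4"]).to_numpy()

    def q_and_coverage(self, convention: str = "mean") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-marker baseline frequency q (allele A, control pool), coverage C,
        and a boolean mask of markers retained for the scan.

        convention selects the coverage definition: 'mean' (default) averages
        the two pools' depths, 'min' takes the smaller, 'control' the control
        pool depth.
        """
        d_low = self.depth_low.astype(float)
        d_high = self.depth_high.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(d_low > 0, self.df["n2"].to_numpy() / np.where(d_low > 0, d_low, 1), np.nan)
        if convention == "mean":
            cov = (d_high + d_low) / 2.0
        elif convention == "min":
            cov = np.minimum(d_high, d_low)
        elif convention == "control":
            cov = d_low
        else:
            raise ValueError(f"unknown coverage convention {convention!r}")
        keep = np.isfinite(q) & (q > 0) & (q < 1) & (cov > 0)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("excluding %d/%d markers with q outside (0,1) or zero coverage",
                        n_dropped, len(self.df))
        return q, cov, keep
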