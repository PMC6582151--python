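"""Pooled bulk-segregant QTL scan: modified G statistic, tri-cube smoothing,
robust log-normal null, peak calling, and simulation-based confidence
intervals.

For a SNV with counts n1/n3 (alleles A/B, high pool) and n2/n4 (A/B, low
pool), baseline allele-A frequency q from the control pool and coverage C,
the modified statistic contrasts the observed counts with the expectation
under the control-pool allele frequencies:

    N = (1 - q)(n2 - n1) + q(n3 - n4)
    G = N^2 / (2 C q (1 - q))          (default, chi-square-like)
    G = N   / (2 C q (1 - q))          (signed linear form, optional)

The linear form can be negative, which no chi-square-type statistic and no
log-normal null admits; the squared numerator is therefore the default and
reduces to (n2 - n1)^2 / (2 C q (1 - q)) when pool depths are equal. Raw G
is smoothed along the genetic map with a tri-cube kernel over a +-12.5 cM
window (W = 25 cM), the null distribution of the smoothed G' is fitted
robustly as log-normal (median / MAD of log G'), and p-values are its
upper-tail probabilities.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import AlleleCountTable, GeneticMap, MarkerGrid

logger = logging.getLogger(__name__)

DEFAULT_HALF_WIDTH_CM = 12.5


class NullFitError(RuntimeError):
    """Raised when the log-normal null cannot be fitted stably."""


def g_statistic(n1, n2, n3, n4, q, c, variant: str = "squared"):
    """Modified G statistic for one or many SNVs.

    Parameters are broadcastable arrays; ``q`` must lie in (0,1) and ``c``
    be positive (filter markers upstream). ``variant`` selects the squared
    (default) or the signed linear form.
    """
    n1, n2, n3, n4 = (np.asarray(x, dtype=float) for x in (n1, n2, n3, n4))
    q = np.asarray(q, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("q must be in (0,1); filter monomorphic markers first")
    if np.any(c <= 0):
        raise ValueError("coverage must be positive")
    num = (1.0 - q) * (n2 - n1) + q * (n3 - n4)
    denom = 2.0 * c * q * (1.0 - q)
    if variant == "squared":
        return num * num / denom
    if variant == "as-printed-linear":
        return num / denom
    raise ValueError(f"unknown G variant {variant!r}")


def estimate_q_and_c(table: AlleleCountTable, convention: str = "mean"):
    """Per-marker baseline frequency q (allele A from the control pool),
    coverage C under the chosen convention, and the retained-marker mask."""
    return table.q_and_coverage(convention)


def tricube_weights(d: np.ndarray) -> np.ndarray:
    """Raw tri-cube kernel (1 - D^3)^3 for normalized distances D in [0,1]."""
    d = np.asarray(d, dtype=float)
    w = (1.0 - d ** 3) ** 3
    return np.where(d <= 1.0, w, 0.0)


def tricube_smooth(g: np.ndarray, cm: np.ndarray, chrom: np.ndarray,
                   half_width: float = DEFAULT_HALF_WIDTH_CM) -> np.ndarray:
    """Smooth per-marker G along the genetic map with a tri-cube kernel.

    For focal marker s the window holds same-chromosome markers within
    ``half_width`` cM; each contributes weight (1 - D^3)^3 with
    D = |cM_j - cM_s| / half_width, normalised to sum to one. A marker
    alone in its window keeps its raw G.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    g = np.asarray(g, dtype=float)
    cm = np.asarray(cm, dtype=float)
    out = np.empty_like(g)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        cc = cm[idx]
        gg = g[idx]
        order = np.argsort(cc, kind="mergesort")
        cs, gs = cc[order], gg[order]
        lo = np.searchsorted(cs, cs - half_width, side="left")
        hi = np.searchsorted(cs, cs + half_width, side="right")
        sm = np.empty_like(gs)
        for i in range(len(cs)):
            w = tricube_weights(np.abs(cs[lo[i]:hi[i]] - cs[i]) / half_width)
            sm[i] = np.dot(w, gs[lo[i]:hi[i]]) / w.sum()
        buf = np.empty_like(sm)
        buf[order] = sm
        out[idx] = buf
    return out


def fit_null_lognormal(g_smoothed: np.ndarray, min_markers: int = 100) -> tuple[float, float]:
    """Robust log-normal null for smoothed G': location and scale of log G'.

    Uses the median and the normal-consistent MAD (x 1.4826) of log G', so
    that the minority of true-signal markers does not inflate the null.
    Non-positive values (possible only under the linear statistic) are
    excluded before taking logs.
    """
    x = np.asarray(g_smoothed, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < min_markers:
        raise NullFitError(f"only {x.size} positive G' values; need >= {min_markers}")
    logx = np.log(x)
    mu = float(np.median(logx))
    sigma = float(stats.median_abs_deviation(logx, scale="normal"))
    if sigma <= 0:
        raise NullFitError("degenerate null: MAD of log G' is zero")
    return mu, sigma


def p_values(g_smoothed: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Upper-tail log-normal p-values; non-positive G' map to p = 1."""
    x = np.asarray(g_smoothed, dtype=float)
    p = np.ones_like(x)
    pos = x > 0
    p[pos] = stats.norm.sf((np.log(x[pos]) - mu) / sigma)
    return p


@dataclass(frozen=True)
class Peak:
    """A called QTL peak with its simulation-based confidence interval."""

    chrom: str
    pos: int
    p: float
    ci_lo: int | None = None
    ci_hi: int | None = None
    method: str = "simulation"

    def to_dict(self) -> dict:
        return {"chrom": self.chrom, "pos": int(self.pos), "p": float(self.p),
                "ci_lo": self.ci_lo, "ci_hi": self.ci_hi, "method": self.method}


def call_peaks(table: pd.DataFrame, alpha: float) -> list[Peak]:
    """Merge contiguous runs of markers with p < alpha per chromosome; the
    minimum-p marker of each run (leftmost on ties) is the peak."""
    peaks: list[Peak] = []
    for chrom, sub in table.groupby("chrom", sort=False):
        sig = (sub["p"].to_numpy() < alpha)
        if not sig.any():
            continue
        pos = sub["pos"].to_numpy()
        pv = sub["p"].to_numpy()
        start = None
        for i in range(len(sig) + 1):
            if i < len(sig) and sig[i]:
                if start is None:
                    start = i
            elif start is not None:
                run = slice(start, i)
                j = start + int(np.argmin(pv[run]))  # argmin is leftmost on ties
                peaks.append(Peak(str(chrom), int(pos[j]), float(pv[j])))
                start = None
    return peaks


def nearest_rank_ci(positions: np.ndarray, level: float = 0.95) -> tuple[int, int]:
    """Central nearest-rank interval enclosing ``level`` of the positions."""
    x = np.sort(np.asarray(positions))
    n = x.size
    tail = (1.0 - level) / 2.0
    lo = x[int(np.floor(tail * n))]
    hi = x[int(np.ceil((1.0 - tail) * n)) - 1]
    return int(lo), int(hi)


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class GScan:
    """Pooled-scan model over an allele-count table and a genetic map.

    Parameters
    ----------
    counts : AlleleCountTable
        Pooled counts keyed to a marker grid.
    genetic_map : GeneticMap
        Supplies cM positions for smoothing windows.
    half_width : float
        Tri-cube window half-width in cM (window = 2 x half_width).
    variant : str
        'squared' (default) or 'as-printed-linear'.
    coverage : str
        Coverage convention: 'mean', 'min', or 'control'.
    """

    def __init__(self, counts: AlleleCountTable, genetic_map: GeneticMap,
                 half_width: float = DEFAULT_HALF_WIDTH_CM,
                 variant: str = "squared", coverage: str = "mean"):
        if counts.markers is None:
            raise ValueError("counts must be keyed to a MarkerGrid")
        self.counts = counts
        self.map = genetic_map
        self.half_width = float(half_width)
        self.variant = variant
        self.coverage = coverage

    @classmethod
    def from_files(cls, counts_path, map_path, markers_path=None, **kw) -> "GScan":
        from . import io
        gmap = io.read_genetic_map(map_path)
        markers = io.read_marker_grid(markers_path, gmap) if markers_path else None
        counts = io.read_allele_counts(counts_path, markers=markers)
        if markers is None:
            counts = AlleleCountTable(counts.df, MarkerGrid(counts.df[["chrom", "pos"]], gmap))
            counts.df = counts.markers.df.merge(counts.df, on=["chrom", "pos"])
        return cls(counts, gmap, **kw)

    def fit(self, alpha: float = 1e-5, min_markers: int = 100) -> "GScanResults":
        """Run the full scan: filter, G, tri-cube G', log-normal null, p,
        peaks. Fully deterministic."""
        df = self.counts.df.copy()
        q, cov, keep = self.counts.q_and_coverage(self.coverage)
        df = df.loc[keep].reset_index(drop=True)
        q, cov = q[keep], cov[keep]
        mk = self.counts.markers
        cm = mk.cm[keep] if mk is not None and len(mk) == len(keep) else \
            np.array([self.map.bp_to_cm(c, p) for c, p in zip(df["chrom"], df["pos"])])
        g = g_statistic(df["n1"], df["n2"], df["n3"], df["n4"], q, cov, self.variant)
        gs = tricube_smooth(np.asarray(g), cm, df["chrom"].to_numpy(), self.half_width)
        mu, sigma = fit_null_lognormal(gs, min_markers=min_markers)
        p = p_values(gs, mu, sigma)
        table = pd.DataFrame({
            "chrom": df["chrom"], "pos": df["pos"], "cm": cm,
            "q": q, "coverage": cov, "G": np.asarray(g), "G_smoothed": gs, "p": p,
        })
        peaks = call_peaks(table, alpha)
        return GScanResults(self, table, peaks, mu, sigma, alpha)


@dataclass
class GScanResults:
    """Fitted scan: per-marker statistics, null parameters, and peaks."""

    model: GScan
    table: pd.DataFrame
    peaks: list[Peak]
    null_mu: float
    null_sigma: float
    alpha: float

    @property
    def half_width(self) -> float:
        return self.model.half_width

    @property
    def variant(self) -> str:
        return self.model.variant

    def top_marker(self) -> tuple[str, int]:
        """Position of the strongest association (maximum smoothed G')."""
        i = int(self.table["G_smoothed"].idxmax())
        return str(self.table.at[i, "chrom"]), int(self.table.at[i, "pos"])

    def summary(self) -> str:
        lines = [
            "Pooled bulk-segregant scan",
            "=" * 60,
            f"markers retained      {len(self.table)}",
            f"statistic variant     {self.variant}",
            f"smoothing half-width  {self.half_width:g} cM",
            f"null (log G')         mu = {self.null_mu:.4f}, sigma = {self.null_sigma:.4f}",
            f"alpha                 {self.alpha:g}",
            f"peaks                 {len(self.peaks)}",
        ]
        for pk in self.peaks:
            ci = f" CI [{pk.ci_lo}, {pk.ci_hi}]" if pk.ci_lo is not None else ""
            lines.append(f"  {pk.chrom}:{pk.pos}  p = {pk.p:.3g}{ci}")
        return "\n".join(lines)

    def to_tsv(self, path, peaks_path=None) -> None:
        from . import io
        io.write_scan(self, path, peaks_path)

    def plot(self, ax=None):
        """Genome-wide -log10(p) scatter, one panel, chromosomes concatenated."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        offset = 0.0
        for chrom, sub in self.table.groupby("chrom", sort=False):
            x = sub["cm"].to_numpy() - sub["cm"].min() + offset
            ax.scatter(x, -np.log10(sub["p"]), s=4, label=str(chrom))
            offset = x.max() + 5
        ax.set_xlabel("genetic position (cM, chromosomes concatenated)")
        ax.set_ylabel("-log10 p")
        return ax


def run_scan(counts: AlleleCountTable, gmap: GeneticMap,
             half_width: float = DEFAULT_HALF_WIDTH_CM, variant: str = "squared",
             coverage: str = "mean", alpha: float = 1e-5,
             min_markers: int = 100) -> GScanResults:
    """Functional wrapper: ``GScan(counts, gmap, ...).fit(alpha)``."""
    return GScan(counts, gmap, half_width, variant, coverage).fit(alpha, min_markers)


def ci_by_simulation(peak_chrom: str, peak_pos: int, gmap: GeneticMap,
                     markers: MarkerGrid, sim_config, rng: np.random.Generator,
                     ve_range: tuple[float, float] = (0.15, 0.25),
                     truncation: float = 0.05, coverage: int = 100,
                     iterations: int = 1300, level: float = 0.95,
                     min_markers: int = 100) -> tuple[int, int, np.ndarray]:
    """Simulation-based confidence interval for a QTL peak position.

    Each iteration re-simulates the whole experiment with the causal
    variant planted at the observed peak and an effect size drawn
    uniformly from ``ve_range``: propagate a segregant pool, truncation-
    select survivors, sequence both pools at ``coverage``, scan, and record
    the top-associated (maximum G') marker position. The interval is the
    central nearest-rank span of the recorded positions. Returns
    (ci_lo, ci_hi, positions).
    """
    from .bulkpop import simulate_cross  # local import to avoid a cycle
    from .selection import EffectSizeModel, simulate_pool_counts, truncation_select

    positions = np.empty(iterations, dtype=np.int64)
    for it in range(iterations):
        try:
            ve = rng.uniform(*ve_range)
            model = EffectSizeModel(peak_chrom, peak_pos, ve=ve, truncation=truncation)
            _, pool = simulate_cross(sim_config, gmap, markers, rng=rng,
                                     record_generations=False)
            selected, control = truncation_select(pool, model, rng)
            counts = simulate_pool_counts(selected, control, markers, coverage, rng)
            res = run_scan(counts, gmap, min_markers=min_markers)
            sub = res.table[res.table["chrom"] == peak_chrom]
            top = sub if len(sub) else res.table
            positions[it] = int(top.loc[top["G_smoothed"].idxmax(), "pos"])
        except Exception as err:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"CI simulation failed at iteration {it}: {err}") from err
    lo, hi = nearest_rank_ci(positions, level)
    return lo, hi, positions
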