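"""Expression-QTL mapping by Pearson correlation and LOD transform.

Probes observed in fewer than 2/3 of samples are removed; expression and
genotype matrices are normalised to mean zero, variance one; each probe is
correlated with every marker and the squared correlation converted to a LOD
score, LOD = -n ln(1 - R^2) / (2 ln 10). Genome-wide significance comes
from permutations of the expression sample labels: the false-discovery rate
at a threshold t is the average permuted number of probes whose best LOD
reaches t divided by the observed number, and the chosen cutoff is the
smallest t with FDR at or below the target (5% by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def filter_probes(expr: pd.DataFrame, min_presence: float = 2.0 / 3.0) -> pd.DataFrame:
    """Drop probes (rows) observed in less than ``min_presence`` of samples.

    'Present' means non-missing; a probe exactly at the threshold is kept.
    """
    if expr.empty:
        raise ValueError("empty expression matrix")
    frac = expr.notna().mean(axis=1)
    kept = expr.loc[frac >= min_presence]
    removed = len(expr) - len(kept)
    if removed:
        logger.info("removed %d/%d probes below %.3f presence", removed, len(expr), min_presence)
    if kept.empty:
        raise ValueError("all probes removed by the presence filter")
    return kept


def normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to mean 0, variance 1 over its non-missing samples.

    Idempotent; constant rows are dropped with a logged count (they carry
    no mappable signal and would divide by zero).
    """
    centred = mat.sub(mat.mean(axis=1, skipna=True), axis=0)
    sd = centred.std(axis=1, ddof=0, skipna=True)
    keep = sd > 0
    if (~keep).any():
        logger.info("dropped %d constant rows during normalization", int((~keep).sum()))
    return centred.loc[keep].div(sd[keep], axis=0)


def lod_from_r2(r2, n):
    """LOD score from a squared Pearson correlation at sample size n.

    LOD = -n ln(1 - R^2) / (2 ln 10); strictly increasing in both R^2 and n.
    """
    r2 = np.asarray(r2, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((r2 < 0) | (r2 >= 1)):
        raise ValueError("R^2 must be in [0, 1)")
    if np.any(n < 3):
        raise ValueError("need n >= 3 samples")
    return -n * np.log1p(-r2) / (2.0 * np.log(10.0))


def _lod_matrix(expr: pd.DataFrame, geno: pd.DataFrame) -> np.ndarray:
    """Probe x marker LOD scores with pairwise-complete correlation.

    Probes with complete data go through one matrix product; probes with
    missing samples are correlated pairwise with a per-pair n in the LOD
    transform.
    """
    e = expr.to_numpy(dtype=float)
    g = geno.to_numpy(dtype=float)
    n_samples = e.shape[1]
    lod = np.zeros((e.shape[0], g.shape[0]))
    complete = ~np.isnan(e).any(axis=1)
    if complete.any():
        ec = e[complete]
        ez = (ec - ec.mean(axis=1, keepdims=True))
        ez /= np.sqrt((ez ** 2).sum(axis=1, keepdims=True))
        gz = g - g.mean(axis=1, keepdims=True)
        gz /= np.sqrt((gz ** 2).sum(axis=1, keepdims=True))
        r2 = np.clip(ez @ gz.T, -1.0, 1.0) ** 2
        lod[complete] = lod_from_r2(np.minimum(r2, 1.0 - 1e-12), n_samples)
    for i in np.flatnonzero(~complete):
        ok = ~np.isnan(e[i])
        n_i = int(ok.sum())
        if n_i < 3:
            continue
        ei = e[i, ok]
        ei = ei - ei.mean()
        denom_e = np.sqrt((ei ** 2).sum())
        if denom_e == 0:
            continue
        gi = g[:, ok]
        gi = gi - gi.mean(axis=1, keepdims=True)
        denom_g = np.sqrt((gi ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (gi @ ei) / (denom_g * denom_e)
        r2 = np.clip(np.nan_to_num(r), -1.0, 1.0) ** 2
        lod[i] = lod_from_r2(np.minimum(r2, 1.0 - 1e-12), n_i)
    return lod


def permutation_fdr(expr: pd.DataFrame, geno: pd.DataFrame, n_perm: int = 100,
                    target_fdr: float = 0.05, grid_step: float = 0.1,
                    rng: np.random.Generator | None = None):
    """Choose a genome-wide LOD cutoff by sample-label permutation.

    Only the expression matrix's sample labels are shuffled, preserving the
    genotype LD structure. Returns (cutoff, curve) where curve is a
    DataFrame of candidate thresholds, observed and mean permuted discovery
    counts, and the FDR estimate; cutoff is NaN when no threshold attains
    the target (flagged no-signal result).
    """
    if list(expr.columns) != list(geno.columns):
        raise ValueError("expression and genotype matrices must share sample order")
    rng = rng or np.random.default_rng()
    obs_max = _lod_matrix(expr, geno).max(axis=1)
    if not np.any(obs_max > 0):
        return float("nan"), pd.DataFrame()
    thresholds = np.arange(grid_step, obs_max.max() + grid_step, grid_step)
    perm_counts = np.zeros((n_perm, thresholds.size))
    cols = np.arange(expr.shape[1])
    for p in range(n_perm):
        perm = rng.permutation(cols)
        shuffled = pd.DataFrame(expr.to_numpy()[:, perm], index=expr.index,
                                columns=expr.columns)
        pm = _lod_matrix(shuffled, geno).max(axis=1)
        perm_counts[p] = (pm[:, None] >= thresholds[None, :]).sum(axis=0)
    obs_counts = (obs_max[:, None] >= thresholds[None, :]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(obs_counts > 0, perm_counts.mean(axis=0) / obs_counts, np.nan)
    curve = pd.DataFrame({"lod": thresholds, "observed": obs_counts,
                          "permuted_mean": perm_counts.mean(axis=0), "fdr": fdr})
    ok = np.flatnonzero((obs_counts > 0) & (fdr <= target_fdr))
    cutoff = float(thresholds[ok[0]]) if ok.size else float("nan")
    if not ok.size:
        logger.info("no LOD threshold attains FDR <= %.3f", target_fdr)
    return cutoff, curve


@dataclass
class EqtlResults:
    """Per-probe best markers with LODs, the chosen cutoff, and the FDR curve."""

    lod: np.ndarray  # probes x markers
    probes: pd.Index
    markers: pd.Index
    best: pd.DataFrame  # per probe: best marker, best LOD, significant flag
    cutoff: float
    fdr_curve: pd.DataFrame
    target_fdr: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.best[self.best["significant"]]

    def summary(self) -> str:
        n_sig = int(self.best["significant"].sum())
        lines = [
            "eQTL scan",
            "=" * 60,
            f"probes x markers   {self.lod.shape[0]} x {self.lod.shape[1]}",
            f"LOD cutoff         {self.cutoff:.2f} (target FDR {self.target_fdr:g})",
            f"significant probes {n_sig}",
        ]
        return "\n".join(lines)


class EqtlModel:
    """Probe-by-marker eQTL scan over aligned expression/genotype matrices.

    Rows are probes/markers, columns are shared sample IDs. Construction
    applies the presence filter and mean-0/variance-1 normalisation.
    """

    def __init__(self, expr: pd.DataFrame, geno: pd.DataFrame,
                 min_presence: float = 2.0 / 3.0):
        if list(expr.columns) != list(geno.columns):
            raise ValueError("expression and genotype matrices must share sample order")
        self.expr = normalize(filter_probes(expr, min_presence))
        self.geno = normalize(geno)

    def fit(self, n_perm: int = 100, target_fdr: float = 0.05,
            grid_step: float = 0.1,
            seed: int | np.random.Generator | None = None) -> EqtlResults:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        cutoff, curve = permutation_fdr(self.expr, self.geno, n_perm, target_fdr,
                                        grid_step, rng)
        lod = _lod_matrix(self.expr, self.geno)
        best_idx = lod.argmax(axis=1)
        best_lod = lod[np.arange(lod.shape[0]), best_idx]
        best = pd.DataFrame({
            "probe": self.expr.index,
            "marker": self.geno.index[best_idx],
            "lod": best_lod,
            "significant": best_lod >= cutoff if np.isfinite(cutoff) else False,
        }).set_index("probe")
        return EqtlResults(lod, self.expr.index, self.geno.index, best,
                           cutoff, curve, target_fdr)


def map_eqtls(expr: pd.DataFrame, geno: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """All probe LODs against a fixed cutoff (inputs already normalised)."""
    lod = _lod_matrix(expr, geno)
    best_idx = lod.argmax(axis=1)
    best_lod = lod[np.arange(lod.shape[0]), best_idx]
    return pd.DataFrame({
        "probe": expr.index, "marker": geno.index[best_idx], "lod": best_lod,
        "significant": best_lod >= cutoff,
    }).set_index("probe")
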