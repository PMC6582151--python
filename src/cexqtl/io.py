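"""Readers and writers for maps, marker grids, allele counts, and scan output.

All files are plain TSV/JSON. Coordinates are 1-based inclusive; file
headers carry a comment line documenting this.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    AlleleCountTable,
    ChromosomeMap,
    GeneticMap,
    MapFormatError,
    MarkerGrid,
)

logger = logging.getLogger(__name__)

_COORD_COMMENT = "# coordinates: 1-based inclusive\n"


def read_genetic_map(path) -> GeneticMap:
    """Read a genetic map TSV with columns chrom, bp, cM (header required).

    An optional boolean column ``is_x`` flags the sex chromosome. Anchors
    must be strictly increasing in both bp and cM within each chromosome.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    for need in ("chrom", "bp", "cm"):
        if need not in cols:
            raise MapFormatError(f"genetic map file missing column {need!r}")
    chroms: dict[str, ChromosomeMap] = {}
    for chrom, sub in df.groupby(cols["chrom"], sort=False):
        is_x = bool(sub[cols["is_x"]].iloc[0]) if "is_x" in cols else False
        chroms[str(chrom)] = ChromosomeMap(
            name=str(chrom),
            bp=sub[cols["bp"]].to_numpy(),
            cm=sub[cols["cm"]].to_numpy(),
            is_x=is_x,
        )
    return GeneticMap(chroms)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    rows = []
    for name, cmap in gmap.chromosomes.items():
        for b, c in zip(cmap.bp, cmap.cm):
            rows.append((name, int(b), float(c), cmap.is_x))
    df = pd.DataFrame(rows, columns=["chrom", "bp", "cM", "is_x"])
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        df.to_csv(fh, sep="\t", index=False)


def read_marker_grid(path, gmap: GeneticMap) -> MarkerGrid:
    """Read a marker grid TSV (chrom, pos, allele_a, allele_b)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return MarkerGrid(df, gmap)


def write_marker_grid(markers: MarkerGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        markers.df[["chrom", "pos", "allele_a", "allele_b"]].to_csv(fh, sep="\t", index=False)


def read_marker_grid_vcf(path, gmap: GeneticMap) -> MarkerGrid:
    """Build a marker grid from biallelic SNV records of a VCF.

    REF becomes allele A (parent 1), the first ALT allele B. Non-SNV and
    multiallelic records are skipped with a logged count.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    rows, skipped = [], 0
    for rec in VCF(str(path)):
        if not rec.is_snp or len(rec.ALT) != 1:
            skipped += 1
            continue
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    if skipped:
        logger.info("skipped %d non-SNV/multiallelic VCF records", skipped)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "allele_a", "allele_b"])
    return MarkerGrid(df, gmap)


_SIMPLE_COLS = ["chrom", "pos", "refA_high", "altB_high", "refA_low", "altB_low"]


def read_allele_counts(path, dialect: str = "simple-tsv",
                       markers: MarkerGrid | None = None) -> AlleleCountTable:
    """Read pooled allele counts.

    dialect 'simple-tsv': one file with columns chrom, pos, refA_high,
    altB_high, refA_low, altB_low.

    dialect 'bam-readcount': ``path`` must be a (high, low) pair of
    bam-readcount output files; only the two expected alleles of each
    marker are read (requires ``markers``), other bases are ignored.

    When ``markers`` is given, file rows absent from the grid are dropped
    with a logged count and the table is keyed to grid order.
    """
    if dialect == "simple-tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = set(_SIMPLE_COLS) - set(df.columns)
        if missing:
            raise MapFormatError(f"allele-count TSV missing columns {sorted(missing)}")
        out = pd.DataFrame({
            "chrom": df["chrom"].astype(str),
            "pos": df["pos"].astype(int),
            "n1": df["refA_high"].astype(int),
            "n3": df["altB_high"].astype(int),
            "n2": df["refA_low"].astype(int),
            "n4": df["altB_low"].astype(int),
        })
    elif dialect == "bam-readcount":
        if markers is None:
            raise ValueError("bam-readcount dialect requires a marker grid")
        try:
            high_path, low_path = path
        except (TypeError, ValueError):
            raise ValueError(
                "bam-readcount dialect requires a (high, low) pair of paths"
            ) from None
        high = _read_bam_readcount(high_path, markers)
        low = _read_bam_readcount(low_path, markers)
        out = pd.DataFrame({
            "chrom": markers.chrom, "pos": markers.pos,
            "n1": high[:, 0], "n3": high[:, 1],
            "n2": low[:, 0], "n4": low[:, 1],
        })
    else:
        raise ValueError(f"unknown allele-count dialect {dialect!r}")

    if markers is not None:
        key = pd.MultiIndex.from_frame(markers.df[["chrom", "pos"]])
        out = out.set_index(pd.MultiIndex.from_frame(out[["chrom", "pos"]]))
        n_before = len(out)
        out = out[out.index.isin(key)]
        if len(out) < n_before:
            logger.info("dropped %d count rows absent from the marker grid",
                        n_before - len(out))
        out = out.reindex(key).dropna().reset_index(drop=True)
        out[["pos", "n1", "n2", "n3", "n4"]] = out[["pos", "n1", "n2", "n3", "n4"]].astype(int)
    return AlleleCountTable(out.reset_index(drop=True), markers)


def _read_bam_readcount(path, markers: MarkerGrid) -> np.ndarray:
    """Parse bam-readcount lines into per-marker (A count, B count)."""
    want: dict[tuple[str, int], int] = {
        (c, int(p)): i for i, (c, p) in enumerate(zip(markers.chrom, markers.pos))
    }
    alleles = markers.df[["allele_a", "allele_b"]].to_numpy()
    counts = np.zeros((len(markers), 2), dtype=np.int64)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            key = (fields[0], int(fields[1]))
            idx = want.get(key)
            if idx is None:
                continue
            per_base = {}
            for cell in fields[4:]:
                parts = cell.split(":")
                if len(parts) >= 2:
                    per_base[parts[0]] = int(parts[1])
            a, b = alleles[idx]
            counts[idx, 0] = per_base.get(a, 0)
            counts[idx, 1] = per_base.get(b, 0)
    return counts


def write_allele_counts(table: AlleleCountTable, path) -> None:
    df = table.df
    out = pd.DataFrame({
        "chrom": df["chrom"], "pos": df["pos"],
        "refA_high": df["n1"], "altB_high": df["n3"],
        "refA_low": df["n2"], "altB_low": df["n4"],
    })
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        out.to_csv(fh, sep="\t", index=False)


def write_scan(result, path, peaks_path=None) -> None:
    """Write a scan as TSV (chrom, pos, G, G_smoothed, p) plus a JSON peak sidecar.

    ``result`` is a GScanResults; peaks_path defaults to <path>.peaks.json.
    """
    path = Path(path)
    df = result.table[["chrom", "pos", "G", "G_smoothed", "p"]]
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    if peaks_path is None:
        peaks_path = path.with_suffix(path.suffix + ".peaks.json")
    payload = {
        "alpha": result.alpha,
        "half_width_cm": result.half_width,
        "variant": result.variant,
        "null": {"mu": result.null_mu, "sigma": result.null_sigma},
        "peaks": [p.to_dict() for p in result.peaks],
    }
    with open(peaks_path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_scan(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_population(pop, path) -> None:
    """Snapshot a population as text for later reload.

    One row per individual: sex (F/M) and the two haplotypes' parental
    origins at the marker grid as 0/1 strings (marker order as in the
    grid; a male's second X entries mirror the first). The marker grid
    itself is not embedded and must be supplied on reload.
    """
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        fh.write(f"# n_markers: {pop.haps.shape[2]}\n")
        fh.write("sex\thap0\thap1\n")
        for i in range(len(pop)):
            h0 = "".join(map(str, pop.haps[i, 0]))
            h1 = "".join(map(str, pop.haps[i, 1]))
            fh.write(f"{'FM'[pop.sex[i]]}\t{h0}\t{h1}\n")


def read_population(path, markers):
    """Reload a population snapshot written by :func:`write_population`."""
    from .bulkpop import Population

    sexes, rows0, rows1 = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("sex\t") or not line.strip():
                continue
            sex, h0, h1 = line.rstrip("\n").split("\t")
            sexes.append(0 if sex == "F" else 1)
            rows0.append(np.frombuffer(h0.encode(), dtype=np.uint8) - ord("0"))
            rows1.append(np.frombuffer(h1.encode(), dtype=np.uint8) - ord("0"))
    haps = np.stack([np.stack(rows0), np.stack(rows1)], axis=1).astype(np.int8)
    return Population(haps, np.array(sexes, dtype=np.int8), markers)


def read_sim_config(path):
    """Load a simulation config from YAML.

    Schema (all keys optional, defaults as in SimConfig):

        pop_cap: 50000
        progeny_per_female: 10
        f1_founders: 1000
        generations: 10
        p_xo: 0.5
        seed: 1
        sex_ratio: 0.5
        drive: {chrom: chr1, pos: 123456, s: 1.0}
        fitness_loci:
          - {chrom: chr2, pos: 99999, w_aa: 1.0, w_ab: 1.5, w_bb: 2.0}
    """
    import yaml

    from .bulkpop import SimConfig
    from .selection import DriveElement, FitnessLocus

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    drive = raw.pop("drive", None)
    loci = raw.pop("fitness_loci", None) or []
    cfg = SimConfig(**raw)
    if drive is not None:
        cfg = cfg.with_(drive=DriveElement(**drive))
    if loci:
        cfg = cfg.with_(fitness_loci=[FitnessLocus(**l) for l in loci])
    return cfg


def write_sim_config(cfg, path) -> None:
    import yaml
    from dataclasses import asdict

    raw = asdict(cfg)
    if raw.get("drive") is None:
        raw.pop("drive", None)
    if not raw.get("fitness_loci"):
        raw.pop("fitness_loci", None)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def write_trajectory(traj: pd.DataFrame, path) -> None:
    """Write a trajectory table (generation, chrom, pos, freq_b, deviation)."""
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        traj.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
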