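"""Readers and writers for the exchange formats.

* snapshot haplotype matrices: tab-separated, header row of 1-based
  positions, one row of 0/1 states per sequence, plus a JSON sidecar with
  the sampling metadata;
* SweepFinder-style allele-frequency files: ``position\\tx\\tn\\tfolded``;
* minimal VCF (CHROM POS REF ALT GT) read through pysam, diploid genotypes
  split into two sequences;
* tab genotype tables (scaffold, position, one diploid GT column per
  sample);
* tidy result tables (trajectories, window statistics, scan output).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clr_scan import CLRResult, FreqRecord
from .simcore import SampleSnapshot, Trajectory
from .sumstats import HaplotypeMatrix, WindowStat

__all__ = [
    "write_snapshot",
    "read_snapshot",
    "write_freq_file",
    "read_freq_file",
    "read_vcf",
    "write_vcf",
    "read_genotype_table",
    "write_genotype_table",
    "write_trajectory",
    "write_window_stats",
    "write_scan_results",
    "read_scan_results",
    "write_sfs",
    "read_sfs",
]


# -- snapshots -------------------------------------------------------------

def write_snapshot(snapshot: SampleSnapshot, prefix: str | Path, extra_meta: dict | None = None) -> None:
    """Matrix to ``<prefix>.haps.tsv`` (1-based position header), metadata to
    ``<prefix>.json``."""
    prefix = Path(prefix)
    m = snapshot.matrix
    with open(f"{prefix}.haps.tsv", "w") as fh:
        fh.write("\t".join(str(int(p) + 1) for p in m.positions) + "\n")
        for row in m.states:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")
    meta = {
        "time_gens": snapshot.time_gens,
        "time_scaled": snapshot.time_scaled,
        "population_label": snapshot.population_label,
        "chrom_len": m.chrom_len,
        "substitution_positions": [int(p) + 1 for p in m.positions[m.substitution]],
    }
    meta.update(extra_meta or {})
    with open(f"{prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=str)


def read_snapshot(prefix: str | Path) -> SampleSnapshot:
    prefix = Path(prefix)
    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    rows = []
    with open(f"{prefix}.haps.tsv") as fh:
        header = fh.readline().split()
        positions = np.array([int(p) - 1 for p in header], dtype=np.int64)
        for line in fh:
            if line.strip():
                rows.append([int(v) for v in line.split()])
    matrix = HaplotypeMatrix(
        positions=positions,
        states=np.array(rows, dtype=np.uint8) if rows else np.zeros((0, len(positions)), np.uint8),
        chrom_len=meta.get("chrom_len"),
        metadata={k: meta[k] for k in meta if k not in ("time_gens", "time_scaled", "population_label")},
    )
    return SampleSnapshot(
        time_gens=int(meta["time_gens"]),
        time_scaled=float(meta["time_scaled"]),
        population_label=meta["population_label"],
        matrix=matrix,
    )


# -- freq files ------------------------------------------------------------

def write_freq_file(records: Iterable[FreqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tx\tn\tfolded\n")
        for r in sorted(records, key=lambda r: r.position):
            fh.write(f"{r.position}\t{r.x}\t{r.n}\t{int(r.folded)}\n")


def read_freq_file(path: str | Path) -> list[FreqRecord]:
    df = pd.read_csv(path, sep="\t")
    expected = ["position", "x", "n", "folded"]
    if list(df.columns) != expected:
        raise ValueError(f"freq file must have columns {expected}")
    return [
        FreqRecord(position=int(r.position), x=int(r.x), n=int(r.n), folded=bool(r.folded))
        for r in df.itertuples()
    ]


# -- VCF and genotype tables ----------------------------------------------

def read_vcf(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Positions (1-based), allele matrix (2·n_samples x n_sites; 0/1/-1)
    and sample names from a minimal uncompressed VCF."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        positions, cols = [], []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            col = []
            for s in samples:
                gt = rec.samples[s].get("GT", (None, None))
                for allele in gt:
                    col.append(-1 if allele is None else int(allele))
            positions.append(rec.pos)
            cols.append(col)
    pos = np.array(positions, dtype=np.int64)
    mat = np.array(cols, dtype=np.int8).T if cols else np.zeros((2 * len(samples), 0), np.int8)
    return pos, mat, samples


def write_vcf(
    positions: Sequence[int],
    alleles: np.ndarray,
    path: str | Path,
    chrom: str = "chr1",
    contig_len: int | None = None,
) -> None:
    """Minimal diploid VCF from an allele matrix (2·n_samples x n_sites)."""
    alleles = np.asarray(alleles)
    n_samples = alleles.shape[0] // 2
    names = [f"s{i}" for i in range(n_samples)]
    clen = contig_len or (int(max(positions)) + 1 if len(positions) else 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={clen}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n")
        for j, pos in enumerate(positions):
            gts = []
            for i in range(n_samples):
                a, b = alleles[2 * i, j], alleles[2 * i + 1, j]
                gts.append(f"{'.' if a < 0 else int(a)}/{'.' if b < 0 else int(b)}")
            fh.write(f"{chrom}\t{int(pos)}\t.\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def write_genotype_table(
    positions: Sequence[int],
    alleles: np.ndarray,
    path: str | Path,
    scaffold: str = "chr1",
) -> None:
    """Tab table: scaffold, position, one diploid GT column per sample."""
    alleles = np.asarray(alleles)
    n_samples = alleles.shape[0] // 2
    with open(path, "w") as fh:
        fh.write("scaffold\tposition\t" + "\t".join(f"s{i}" for i in range(n_samples)) + "\n")
        for j, pos in enumerate(positions):
            gts = []
            for i in range(n_samples):
                a, b = alleles[2 * i, j], alleles[2 * i + 1, j]
                gts.append(f"{'.' if a < 0 else int(a)}/{'.' if b < 0 else int(b)}")
            fh.write(f"{scaffold}\t{int(pos)}\t" + "\t".join(gts) + "\n")


def read_genotype_table(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    samples = list(df.columns[2:])
    positions = df["position"].astype(int).to_numpy()
    cols = []
    for _, row in df.iterrows():
        col = []
        for s in samples:
            a, b = str(row[s]).split("/")
            col.append(-1 if a == "." else int(a))
            col.append(-1 if b == "." else int(b))
        cols.append(col)
    mat = np.array(cols, dtype=np.int8).T if cols else np.zeros((2 * len(samples), 0), np.int8)
    return positions, mat, samples


# -- tidy result tables ----------------------------------------------------

def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame(
        {"generation": traj.generations, "freq_p1": traj.freq_p1, "freq_p2": traj.freq_p2}
    ).to_csv(path, sep="\t", index=False)


def write_window_stats(
    stats: Sequence[WindowStat], path: str | Path, population: str = "p1", scaffold: str = "chr1"
) -> None:
    rows = [
        {
            "population": population,
            "scaffold": scaffold,
            "start": w.window_start,
            "end": w.window_end,
            "n_sites": w.n_sites_genotyped,
            "S": w.S,
            "pi": w.pi_per_site,
            "tajD": "" if w.tajimas_d is None else w.tajimas_d,
            "ZnS": "" if w.kellys_zns is None else w.kellys_zns,
        }
        for w in stats
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_scan_results(results: Sequence[CLRResult], path: str | Path) -> None:
    """SweepFinder-style output: location, LR, alpha."""
    pd.DataFrame(
        {
            "location": [r.grid_position for r in results],
            "LR": [r.clr for r in results],
            "alpha": [r.alpha_hat for r in results],
        }
    ).to_csv(path, sep="\t", index=False)


def write_sfs(sfs: "SiteFrequencySpectrum", path: str | Path) -> None:
    """Spectrum as a two-column table: derived count, probability."""
    pd.DataFrame({"count": np.arange(sfs.n + 1), "prob": sfs.probs}).to_csv(
        path, sep="\t", index=False
    )


def read_sfs(path: str | Path, folded: bool = False):
    from .sumstats import SiteFrequencySpectrum

    df = pd.read_csv(path, sep="\t")
    return SiteFrequencySpectrum(
        n=int(df["count"].max()), probs=df["prob"].to_numpy(), folded=folded
    )


def read_scan_results(path: str | Path) -> list[CLRResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        CLRResult(grid_position=int(r.location), clr=float(r.LR), alpha_hat=float(r.alpha))
        for r in df.itertuples()
    ]
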