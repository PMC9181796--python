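"""Plain-TSV readers and writers for every pipeline artifact.

Counts: first column gene_id, one integer column per sample. Sample sheet:
sample, group (or tissue+condition from which the group is derived),
replicate. Gene lengths: gene_id, length (bp). Everything round-trips
through the simulator's writers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import CountMatrix

_TISSUE_SUFFIX = {"shoot": "Sh", "root": "R"}


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"replicate": "Int64"})
    if "sample" not in df.columns:
        raise ValueError(f"{path}: sample sheet needs a 'sample' column")
    if "group" not in df.columns:
        if not {"tissue", "condition"} <= set(df.columns):
            raise ValueError(
                f"{path}: sample sheet needs 'group' or 'tissue'+'condition' columns"
            )
        bad = set(df["tissue"]) - set(_TISSUE_SUFFIX)
        if bad:
            raise ValueError(f"{path}: unknown tissue value(s) {sorted(bad)}")
        df["group"] = df["condition"] + "_" + df["tissue"].map(_TISSUE_SUFFIX)
    if "tissue" not in df.columns:
        df["tissue"] = df["group"].map(
            lambda g: "shoot" if str(g).endswith("_Sh") else "root"
        )
    return df


def read_gene_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0]
    s.name = "length"
    return s


def load_count_matrix(
    counts_path: str | Path, sheet_path: str | Path, lengths_path: str | Path
) -> CountMatrix:
    counts = read_counts(counts_path)
    samples = read_sample_sheet(sheet_path)
    lengths = read_gene_lengths(lengths_path)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(
            f"gene length table is missing {len(missing)} gene(s), "
            f"e.g. {list(missing[:5])}"
        )
    return CountMatrix(counts=counts, samples=samples, gene_lengths=lengths.loc[counts.index])


def write_count_matrix(cm: CountMatrix, outdir: str | Path, truth: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write counts / sample sheet / lengths (and truth) TSVs; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "lengths": outdir / "gene_lengths.tsv",
    }
    cm.counts.to_csv(paths["counts"], sep="\t")
    cm.samples.to_csv(paths["samples"], sep="\t", index=False)
    cm.gene_lengths.rename("length").to_frame().to_csv(paths["lengths"], sep="\t")
    if truth is not None:
        paths["truth"] = outdir / "truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path
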