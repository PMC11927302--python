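"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as TSV (genes x samples) or MatrixMarket triplets; gene-set
collections as GMT; MS2 spectra as MGF (via pyteomics); everything tabular
as CSV/TSV through pandas.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from pyteomics import mgf as _mgf


# ---------------------------------------------------------------- counts

def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_mtx(counts: pd.DataFrame, prefix) -> None:
    """Write counts as <prefix>.mtx plus <prefix>.genes.tsv / <prefix>.samples.tsv."""
    prefix = str(prefix)
    scipy.io.mmwrite(prefix + ".mtx", scipy.sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(prefix + ".genes.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.columns).to_csv(prefix + ".samples.tsv", sep="\t", index=False, header=False)


def read_counts_mtx(prefix) -> pd.DataFrame:
    prefix = str(prefix)
    mat = scipy.io.mmread(prefix + ".mtx").toarray()
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t", header=None)[0].tolist()
    samples = pd.read_csv(prefix + ".samples.tsv", sep="\t", header=None)[0].tolist()
    return pd.DataFrame(mat, index=genes, columns=samples)


# ---------------------------------------------------------------- gene sets

def write_gmt(sets: dict, path) -> None:
    """Write a gene-set collection: one line per set, name TAB description TAB genes..."""
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([str(name), "na", *sorted(map(str, genes))]) + "\n")


def read_gmt(path) -> dict:
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


# ---------------------------------------------------------------- spectra

def write_mgf(spectra: dict, path, precursor_mz: dict | None = None) -> None:
    """Write {id -> (n, 2) peak array} as MGF with TITLE = id."""
    entries = []
    for sid, peaks in spectra.items():
        peaks = np.asarray(peaks, dtype=float)
        params = {"title": str(sid)}
        if precursor_mz and sid in precursor_mz:
            params["pepmass"] = float(precursor_mz[sid])
        entries.append(
            {"m/z array": peaks[:, 0], "intensity array": peaks[:, 1], "params": params}
        )
    if os.path.exists(path):
        os.remove(path)
    _mgf.write(entries, output=str(path))


def read_mgf(path) -> dict:
    """Read MGF into {TITLE -> (n, 2) peak array}."""
    out = {}
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            title = spec["params"]["title"]
            out[title] = np.column_stack([spec["m/z array"], spec["intensity array"]])
    return out


# ---------------------------------------------------------------- misc tables

def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=index_col)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
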