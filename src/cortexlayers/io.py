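"""Plain-text readers and writers for the pipeline's tabular interfaces.

All matrices and tables travel as TSV (missing abundances as empty cells),
gene sets as standard GMT, and ground truth as JSON.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="protein_id", na_rep="")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="protein_id")


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", keep_default_na=False,
                           dtype={"exclusion_reason": str})
    manifest["excluded"] = manifest["excluded"].astype(str).str.lower().isin(
        ("true", "1"))
    manifest["layer_index"] = manifest["layer_index"].astype(int)
    return manifest


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path,
              descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term, members in gene_sets.items():
            desc = descriptions.get(term, "na")
            fh.write("\t".join([term, desc, *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_cells(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, sep="\t", index=False)


def read_cells(path) -> pd.DataFrame:
    cells = pd.read_csv(path, sep="\t")
    for col in ("BrdU", "Ki67", "pHH3", "Reelin"):
        if col in cells.columns:
            cells[col] = cells[col].astype(str).str.lower().isin(("true", "1"))
    return cells


def write_term_table(rep: pd.DataFrame, path) -> None:
    rep.to_csv(path, sep="\t", index=False)


def read_term_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
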