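"""Readers and writers for the plain-text formats the pipeline consumes.

All tabular data travel as TSV.  Intensity matrices are features (rows) x
samples (columns) with an empty cell meaning "missing"; designs are one row
per sample; gene sets are GMT or two-column TSV; PPI edge lists are SIF
("A pp B") or two-column TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

DESIGN_COLUMNS = [
    "sample_id",
    "dataset_kind",
    "compound",
    "dose",
    "timepoint_h",
    "replicate",
    "patient_group",
]

PEPTIDE_META_COLUMNS = ["peptide", "protein", "charge", "modification"]


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a feature x sample matrix; NaN becomes an empty cell."""
    matrix.to_csv(path, sep="\t", index=True, na_rep="")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False, columns=DESIGN_COLUMNS, na_rep="")


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return df[DESIGN_COLUMNS]


def write_peptides(peptides: pd.DataFrame, path: str | Path) -> None:
    peptides.to_csv(path, sep="\t", index=False, na_rep="")


def read_peptides(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PEPTIDE_META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    return df


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read GMT (name, description, members...) or two-column TSV (set, member)."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first and len(first.rstrip("\n").split("\t")) == 2:
            for line in fh:
                if not line.strip():
                    continue
                name, member = line.rstrip("\n").split("\t")
                sets.setdefault(name, set()).add(member)
        else:
            for line in fh:
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                sets[fields[0]] = set(f for f in fields[2:] if f)
    return sets


def write_gene_sets(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tsynthetic\t{members}\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a SIF ("A pp B") or two-column TSV edge list.

    Raises ValueError with the offending line number on malformed input.
    """
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").replace(" ", "\t").split("\t")
            fields = [f for f in fields if f]
            if len(fields) == 3:  # SIF: node relation node
                a, _, b = fields
            elif len(fields) == 2:
                a, b = fields
            else:
                raise ValueError(f"malformed edge line {lineno}: {line.rstrip()}")
            edges.append((a, b))
    return edges


def write_edge_list(edges, path: str | Path, sif: bool = True) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a} pp {b}\n" if sif else f"{a}\t{b}\n")


def linkage_to_newick(Z, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string; branch lengths are
    the height differences between a node and its parent merge."""
    import numpy as np

    Z = np.asarray(Z, dtype=float)
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    for i in range(Z.shape[0]):
        height[n + i] = float(Z[i, 2])

    def render(node: int, parent_height: float) -> str:
        length = parent_height - height[node]
        if node < n:
            return f"{labels[node]}:{length:.6g}"
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = height[node]
        return f"({render(a, h)},{render(b, h)}):{length:.6g}"

    root = n + Z.shape[0] - 1
    return f"({render(int(Z[-1, 0]), height[root])},{render(int(Z[-1, 1]), height[root])});"


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
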