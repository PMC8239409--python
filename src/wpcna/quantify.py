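"""Peptide-to-protein quantification: consolidation, parsimonious protein
inference, and Hi3 (Top3) intensities.

The input is a linear-intensity peptide table with columns ``peptide``,
``protein``, ``charge``, ``modification`` and one column per sample.  The
output is a proteins x samples log2 matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import PEPTIDE_META_COLUMNS


def _sample_columns(peptides: pd.DataFrame) -> list[str]:
    return [c for c in peptides.columns if c not in PEPTIDE_META_COLUMNS]


def consolidate_peptides(peptides: pd.DataFrame) -> pd.DataFrame:
    """Sum charge-state and modification variants into one row per
    (peptide, protein); a consolidated cell is missing only when every
    variant is missing in that sample."""
    if len(peptides) == 0:
        raise ValueError("peptide table is empty")
    samples = _sample_columns(peptides)
    if (peptides[samples].to_numpy(dtype=float) < 0).any():
        raise ValueError("negative peptide intensities")
    grouped = peptides.groupby(["peptide", "protein"], sort=True)[samples].sum(min_count=1)
    out = grouped.reset_index()
    out.insert(2, "charge", 0)
    out.insert(3, "modification", "consolidated")
    return out


def infer_proteins(peptides: pd.DataFrame) -> pd.DataFrame:
    """Parsimonious protein inference on a consolidated table.

    Proteins whose peptide set is contained in another protein's set are
    redundant and removed (Occam's razor; equal sets keep the
    lexicographically smaller accession).  Peptides still shared between
    retained proteins are discarded, and proteins left with fewer than two
    peptides are dropped.
    """
    pep_sets: dict[str, frozenset[str]] = {
        acc: frozenset(grp["peptide"]) for acc, grp in peptides.groupby("protein", sort=True)
    }
    accs = sorted(pep_sets)
    removed: set[str] = set()
    for a in accs:
        if a in removed:
            continue
        for b in accs:
            if a == b or b in removed:
                continue
            if pep_sets[a] < pep_sets[b]:
                removed.add(a)
                break
            if pep_sets[a] == pep_sets[b] and a > b:
                removed.add(a)
                break
    retained = peptides[~peptides["protein"].isin(removed)]
    counts = retained.groupby("peptide")["protein"].nunique()
    shared = set(counts[counts > 1].index)
    unique = retained[~retained["peptide"].isin(shared)]
    n_pep = unique.groupby("protein")["peptide"].nunique()
    keep = set(n_pep[n_pep >= 2].index)
    return unique[unique["protein"].isin(keep)].reset_index(drop=True)


def hi3_quantify(peptides: pd.DataFrame, agg: str = "mean") -> pd.DataFrame:
    """Hi3 protein intensities: per protein, the up-to-3 peptides with the
    highest mean intensity across samples (mean over present cells; ties
    broken lexicographically by peptide) are averaged per sample and
    log2-transformed.  ``agg='sum'`` totals the top peptides instead.

    Returns a proteins x samples log2 matrix with a ``n_peptides_used``
    attribute in ``DataFrame.attrs``.
    """
    if agg not in ("mean", "sum"):
        raise ValueError("agg must be 'mean' or 'sum'")
    samples = _sample_columns(peptides)
    rows = {}
    n_used = {}
    for acc, grp in peptides.groupby("protein", sort=True):
        values = grp[samples].astype(float)
        rank = pd.DataFrame(
            {"mean": values.mean(axis=1, skipna=True), "peptide": grp["peptide"].to_numpy()},
            index=grp.index,
        ).sort_values(["mean", "peptide"], ascending=[False, True])
        top = values.loc[rank.index[:3]]
        if agg == "mean":
            linear = top.mean(axis=0, skipna=True)
        else:
            linear = top.sum(axis=0, min_count=1)
        with np.errstate(divide="ignore"):
            rows[acc] = np.log2(linear.to_numpy(dtype=float))
        n_used[acc] = len(top)
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    matrix[~np.isfinite(matrix)] = np.nan
    matrix.attrs["n_peptides_used"] = n_used
    return matrix


def quantify(peptides: pd.DataFrame, agg: str = "mean") -> pd.DataFrame:
    """consolidate -> infer -> Hi3 in one call."""
    return hi3_quantify(infer_proteins(consolidate_peptides(peptides)), agg=agg)
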