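"""Treatment-affected module selection, disease annotation and
over-representation analysis (ORA).

Module selection quantifies what is usually judged from eigengene bar plots
and PCA scatter: a standardized eigengene contrast (treated vs control) and
a silhouette-style separation score on the first two principal components of
the module submatrix.  ORA is a hypergeometric upper-tail test with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .coexnet import GREY, EigengeneSet, _standardize_rows


@dataclass
class ContrastReport:
    module: str
    effect: float
    pca_separation: float
    pooled_sd_defined: bool = True


def treated_mask(design: pd.DataFrame) -> pd.Series:
    """Treated = any non-control condition (drug-exposed in vitro sample or
    cancer-treated patient)."""
    invitro = design["dataset_kind"] == "invitro"
    is_control = np.where(
        invitro,
        design["compound"].fillna("none").eq("none"),
        design["patient_group"].fillna("control").eq("control"),
    )
    return pd.Series(~is_control, index=design["sample_id"].to_numpy())


def eigengene_contrast(
    eigengenes: EigengeneSet,
    design: pd.DataFrame,
    matrix: pd.DataFrame | None = None,
    partition: pd.Series | None = None,
) -> list[ContrastReport]:
    """Standardized treated-vs-control eigengene difference per module, plus
    (when the protein matrix is supplied) a PCA separation score."""
    treated = treated_mask(design)
    samples = eigengenes.eigengenes.index
    t_mask = treated.reindex(samples).to_numpy(dtype=bool)
    reports = []
    for module in eigengenes.modules():
        me = eigengenes.eigengenes[module].to_numpy()
        a, b = me[t_mask], me[~t_mask]
        defined = len(a) >= 2 and len(b) >= 2
        if defined:
            pooled = np.sqrt(
                ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                / (len(a) + len(b) - 2)
            )
        else:
            pooled = np.nan
        diff = a.mean() - b.mean() if len(a) and len(b) else np.nan
        effect = float(diff / pooled) if defined and pooled > 0 else (0.0 if diff == 0 else np.nan)
        sep = np.nan
        if matrix is not None and partition is not None:
            sep = pca_separation(matrix, partition, module, t_mask)
        reports.append(
            ContrastReport(
                module=module,
                effect=effect if np.isfinite(effect) else float(diff),
                pca_separation=sep,
                pooled_sd_defined=defined,
            )
        )
    return reports


def pca_separation(
    matrix: pd.DataFrame, partition: pd.Series, module: str, t_mask: np.ndarray
) -> float:
    """Silhouette of treated vs control samples on the first two principal
    components of the module's standardized submatrix."""
    sub = matrix.loc[partition[partition == module].index]
    x = _standardize_rows(sub)
    if x.shape[0] < 2 or len(set(t_mask)) < 2:
        return np.nan
    comps = PCA(n_components=min(2, x.shape[0]), svd_solver="full").fit_transform(x.T)
    return float(silhouette_score(comps, t_mask.astype(int)))


def select_affected(
    contrasts: list[ContrastReport],
    effect_threshold: float = 1.0,
    pca_threshold: float = 0.25,
) -> list[str]:
    """Modules whose |standardized effect| or PCA separation clears its
    threshold, ordered by decreasing |effect|."""
    selected = [
        c
        for c in contrasts
        if c.module != GREY
        and (
            (np.isfinite(c.effect) and abs(c.effect) >= effect_threshold)
            or (np.isfinite(c.pca_separation) and c.pca_separation >= pca_threshold)
        )
    ]
    selected.sort(key=lambda c: -abs(c.effect) if np.isfinite(c.effect) else 0.0)
    return [c.module for c in selected]


def annotate_disease(
    partition: pd.Series, weighted: set[str], disease_set: set[str]
) -> pd.DataFrame:
    """Per-module counts table: total proteins, disease overlap, weighted
    proteins, weighted-and-disease — with a leading whole-matrix column."""
    if not disease_set:
        raise ValueError("disease_set is empty")
    modules = sorted(set(partition) - {GREY}, key=lambda m: (-int((partition == m).sum()), m))
    table = pd.DataFrame(
        index=["n_proteins", "n_disease", "n_weighted", "n_weighted_disease"],
        columns=["total"] + modules,
        dtype=int,
    )
    all_prot = set(partition.index)
    table.loc[:, "total"] = [
        len(all_prot),
        len(all_prot & disease_set),
        len(all_prot & weighted),
        len(all_prot & weighted & disease_set),
    ]
    for m in modules:
        members = set(partition[partition == m].index)
        table.loc[:, m] = [
            len(members),
            len(members & disease_set),
            len(members & weighted),
            len(members & weighted & disease_set),
        ]
    return table


@dataclass
class EnrichmentResult:
    pathway_id: str
    size: int
    overlap: int
    p_value: float
    q_value: float
    passes: bool


def ora(
    query: set[str],
    background: set[str],
    pathways: dict[str, set[str]],
    p_cut: float = 0.01,
    q_cut: float = 0.01,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` within ``background``
    against each pathway (intersected with the background), with BH-adjusted
    q-values; ``passes`` requires p < p_cut and q < q_cut."""
    if not query <= background:
        raise ValueError("query must be a subset of background")
    names = sorted(pathways)
    M, N = len(background), len(query)
    results = []
    pvals = []
    for name in names:
        members = pathways[name] & background
        K = len(members)
        k = len(members & query)
        # P[X >= k], X ~ Hypergeom(M, K, N)
        p = float(hypergeom.sf(k - 1, M, K, N))
        pvals.append(min(max(p, 0.0), 1.0))
        results.append((name, K, k))
    if not results:
        return []
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = []
    for (name, K, k), p, q in zip(results, pvals, qvals):
        out.append(
            EnrichmentResult(
                pathway_id=name,
                size=K,
                overlap=k,
                p_value=p,
                q_value=float(q),
                passes=bool(p < p_cut and q < q_cut),
            )
        )
    return out


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.pathway_id, r.size, r.overlap, r.p_value, r.q_value, r.passes)
            for r in results
        ],
        columns=["pathway_id", "size", "overlap", "p", "q", "passes"],
    )
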