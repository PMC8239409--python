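"""Cross-dataset integration: overlap sets, weighted-in-either/both
proteins, log2 fold-change tables, and the high-expression filter.

Integration is deliberately set algebra plus per-dataset statistics — no
cross-dataset renormalization is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class IntegrationResult:
    common: set[str]
    weighted_either: set[str]
    weighted_both: set[str]
    pct_weighted_either: float | None
    module_labels: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_common": len(self.common),
            "n_weighted_either": len(self.weighted_either),
            "n_weighted_both": len(self.weighted_both),
            "pct_weighted_either": self.pct_weighted_either,
        }


def overlap_datasets(
    set_a: set[str],
    set_b: set[str],
    weighted_a: set[str],
    weighted_b: set[str],
    partition_a: dict[str, str] | None = None,
    partition_b: dict[str, str] | None = None,
) -> IntegrationResult:
    """Proteins present in both datasets, those weighted in at least one and
    in both, and the weighted-in-either percentage (1 decimal)."""
    if not weighted_a <= set_a or not weighted_b <= set_b:
        raise ValueError("weighted sets must be subsets of their parent sets")
    common = set_a & set_b
    weighted_either = (weighted_a | weighted_b) & common
    weighted_both = weighted_a & weighted_b & common
    pct = round(100.0 * len(weighted_either) / len(common), 1) if common else None
    labels = {
        p: (
            partition_a.get(p) if partition_a else None,
            partition_b.get(p) if partition_b else None,
        )
        for p in sorted(common)
    }
    return IntegrationResult(
        common=common,
        weighted_either=weighted_either,
        weighted_both=weighted_both,
        pct_weighted_either=pct,
        module_labels=labels,
    )


def log2fc_invitro(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per protein and (compound, dose, timepoint): mean over treated
    replicates minus mean over same-timepoint controls (missing cells
    ignored; a cell is empty when either group has no present value)."""
    d = design.set_index("sample_id")
    d = d.loc[[s for s in matrix.columns]]
    controls = d[d["compound"].fillna("none") == "none"]
    treated = d[d["compound"].fillna("none") != "none"]
    columns = {}
    for (compound, dose, t), grp in treated.groupby(
        ["compound", "dose", "timepoint_h"], sort=True
    ):
        tp_controls = controls[controls["timepoint_h"] == t]
        if len(tp_controls) == 0:
            raise ValueError(f"no control samples at timepoint {t}")
        t_mean = matrix[list(grp.index)].mean(axis=1, skipna=True)
        c_mean = matrix[list(tp_controls.index)].mean(axis=1, skipna=True)
        columns[f"{compound}:{dose}:{int(t)}"] = t_mean - c_mean
    return pd.DataFrame(columns, index=matrix.index)


def log2fc_biopsy(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Treated patient-group means minus the control-group mean; columns are
    ant_treated_vs_control and nonant_treated_vs_control."""
    d = design.set_index("sample_id")
    d = d.loc[[s for s in matrix.columns]]
    groups = {g: list(grp.index) for g, grp in d.groupby("patient_group")}
    if not groups.get("control"):
        raise ValueError("empty control patient group")
    c_mean = matrix[groups["control"]].mean(axis=1, skipna=True)
    columns = {}
    for g in ("ant_treated", "nonant_treated"):
        if groups.get(g):
            columns[f"{g}_vs_control"] = matrix[groups[g]].mean(axis=1, skipna=True) - c_mean
    return pd.DataFrame(columns, index=matrix.index)


def high_expression_filter(matrix: pd.DataFrame, floor: float = 10.0) -> set[str]:
    """Proteins observed in every sample with log2 expression strictly above
    ``floor`` everywhere."""
    values = matrix.to_numpy(dtype=float)
    complete = ~np.isnan(values).any(axis=1)
    with np.errstate(invalid="ignore"):
        high = np.nanmin(values, axis=1) > floor
    return set(matrix.index[complete & high])


def pct(numerator: int, denominator: int, decimals: int = 1) -> float | None:
    """Report-style percentage with explicit rounding; None when undefined."""
    if denominator == 0:
        return None
    return round(100.0 * numerator / denominator, decimals)
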