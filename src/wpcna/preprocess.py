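"""Protein-matrix preprocessing: identifier filtering, missingness filtering,
the two median-shift normalization schemes, and decimal standardization.

Both normalizations are purely additive per sample on the log2 scale, so
within-sample differences between proteins are preserved exactly.

* in vitro: control samples are shifted to the median of the control-sample
  medians over the set of proteins present in every control sample; each
  (compound, dose, timepoint) treatment group is then shifted to the median
  of the same-timepoint normalized controls' medians over the protein set
  common to that group and those controls.
* biopsy: every sample is shifted to a common median computed over the
  proteins present in all samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class NormalizationReport:
    scheme: str
    reference_set_size: int
    shifts: dict[str, float]
    targets: dict[str, float] = field(default_factory=dict)
    common_set_sizes: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.shifts), "shift": list(self.shifts.values())}
        )


def drop_ambiguous_ids(matrix: pd.DataFrame, id_map: dict[str, int]) -> pd.DataFrame:
    """Keep only proteins mapping to a single UniProt ID."""
    missing = [acc for acc in matrix.index if acc not in id_map]
    if missing:
        raise ValueError(f"accessions absent from id_map: {missing[:5]}")
    keep = [acc for acc in matrix.index if id_map[acc] == 1]
    if not keep:
        warnings.warn("all proteins matched multiple UniProt IDs; empty matrix")
    return matrix.loc[keep]


def filter_missing(matrix: pd.DataFrame, max_missing_fraction: float = 0.5) -> pd.DataFrame:
    """Drop proteins missing in strictly more than ``max_missing_fraction``
    of samples, and zero-variance proteins (the cited filter's default)."""
    if len(matrix) == 0:
        raise ValueError("matrix is empty")
    values = matrix.to_numpy(dtype=float)
    frac_missing = np.isnan(values).mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        variance = np.nanvar(values, axis=1)
    keep = (frac_missing <= max_missing_fraction) & (variance > 0)
    return matrix.loc[keep]


def _median_over(matrix: pd.DataFrame, proteins: pd.Index, sample: str) -> float:
    return float(matrix.loc[proteins, sample].median())


def normalize_invitro(
    matrix: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, NormalizationReport]:
    """Treatment/control median normalization for the microtissue design."""
    design = design.set_index("sample_id")
    samples = [s for s in matrix.columns]
    controls = [s for s in samples if design.loc[s, "compound"] in ("none", None)]
    if not controls:
        raise ValueError("design contains no control samples")

    out = matrix.copy().astype(float)
    shifts: dict[str, float] = {}
    targets: dict[str, float] = {}
    common_sizes: dict[str, int] = {}

    ref_set = out.index[out[controls].notna().all(axis=1)]
    if len(ref_set) == 0:
        raise ValueError("empty reference set: no protein present in all control samples")
    ctl_medians = {s: _median_over(out, ref_set, s) for s in controls}
    target = float(np.median(list(ctl_medians.values())))
    targets["controls"] = target
    for s in controls:
        shift = target - ctl_medians[s]
        out[s] = out[s] + shift
        shifts[s] = shift

    treated = design.loc[[s for s in samples if s not in controls]]
    for (compound, dose, t), grp in treated.groupby(
        ["compound", "dose", "timepoint_h"], sort=True
    ):
        group_samples = list(grp.index)
        tp_controls = [s for s in controls if design.loc[s, "timepoint_h"] == t]
        if not tp_controls:
            raise ValueError(f"no control samples at timepoint {t} for group {compound}:{dose}")
        cols = group_samples + tp_controls
        common = out.index[out[cols].notna().all(axis=1)]
        key = f"{compound}:{dose}:{int(t)}"
        if len(common) == 0:
            raise ValueError(f"empty common protein set for group {key}")
        common_sizes[key] = len(common)
        group_target = float(np.median([_median_over(out, common, s) for s in tp_controls]))
        targets[key] = group_target
        for s in group_samples:
            shift = group_target - _median_over(out, common, s)
            out[s] = out[s] + shift
            shifts[s] = shift

    report = NormalizationReport(
        scheme="invitro",
        reference_set_size=len(ref_set),
        shifts=shifts,
        targets=targets,
        common_set_sizes=common_sizes,
    )
    return out, report


def normalize_biopsy(matrix: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationReport]:
    """Shift every sample to the common median of the core protein set
    (proteins present in all samples)."""
    out = matrix.copy().astype(float)
    core = out.index[out.notna().all(axis=1)]
    if len(core) == 0:
        raise ValueError("empty core set: no protein present in all samples")
    medians = {s: _median_over(out, core, s) for s in out.columns}
    target = float(np.median(list(medians.values())))
    shifts = {}
    for s in out.columns:
        shift = target - medians[s]
        out[s] = out[s] + shift
        shifts[s] = shift
    report = NormalizationReport(
        scheme="biopsy",
        reference_set_size=len(core),
        shifts=shifts,
        targets={"common": target},
    )
    return out, report


def standardize_decimals(matrix: pd.DataFrame, digits: int = 6) -> pd.DataFrame:
    """Round present values half-to-even to ``digits`` decimals."""
    return matrix.round(digits)
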