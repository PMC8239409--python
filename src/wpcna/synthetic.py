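"""Synthetic study generator with full ground truth.

Emulates the structure of an anthracycline cardiotoxicity proteomics study:

* an in vitro design of 3 drugs (DOX, EPI, IDA) x 2 doses (therapeutic,
  toxic) x 7 harvest timepoints with ~3 replicates, where the toxic dose of
  idarubicin is truncated at 168 h (cell death) and reduced to 2 replicates
  at the 2 h and 24 h harvests — with 3 replicates this yields exactly 139
  samples (21 control + 42 DOX + 42 EPI + 34 IDA);
* a 16-biopsy patient design (control / anthracycline-treated /
  non-anthracycline-treated);
* log-normal peptide intensities layered on planted co-expression modules
  with per-protein module-membership targets and treatment effects;
* intensity-dependent (or MCAR) missingness;
* a protein-protein interaction graph with planted hubs;
* a disease gene set overlapping the planted modules.

Every generated object carries its ground truth so downstream stages
(quantification, normalization, network construction, module selection,
integration, hub calling) can be tested offline against what was planted.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DESIGN_COLUMNS, PEPTIDE_META_COLUMNS

TIMEPOINTS_H = (2, 8, 24, 72, 168, 240, 336)
COMPOUNDS = ("DOX", "EPI", "IDA")
DOSES = ("therapeutic", "toxic")
IDA_TOXIC_MAX_H = 168
IDA_TOXIC_REDUCED_H = (2, 24)

BACKGROUND_LABEL = "background"


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a synthetic dataset."""

    planted_partition: dict[str, str]
    planted_kme: dict[str, float]
    effect_profile: dict[str, dict[str, float]]
    planted_hubs: list[str] = field(default_factory=list)
    disease_set: set[str] = field(default_factory=set)

    def module_labels(self) -> list[str]:
        labels = sorted({m for m in self.planted_partition.values() if m != BACKGROUND_LABEL})
        return labels


def generate_invitro_design(n_replicates: int = 3, seed: int = 0) -> pd.DataFrame:
    """Full-factorial microtissue harvest design.

    Controls at every timepoint, each compound x dose x timepoint, the toxic
    IDA arm truncated at 168 h and reduced to at most 2 replicates at 2 h and
    24 h.  ``n_replicates=3`` reproduces the 139-sample study layout.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []

    def add(compound: str, dose: str, t: int, n: int) -> None:
        for r in range(1, n + 1):
            sid = f"ivt_{compound}_{dose}_{t}h_r{r}"
            rows.append((sid, "invitro", compound, dose, t, r, None))

    for t in TIMEPOINTS_H:
        add("none", "none", t, n_replicates)
    for compound in COMPOUNDS:
        for dose in DOSES:
            for t in TIMEPOINTS_H:
                if compound == "IDA" and dose == "toxic":
                    if t > IDA_TOXIC_MAX_H:
                        continue
                    n = min(n_replicates, 2) if t in IDA_TOXIC_REDUCED_H else n_replicates
                else:
                    n = n_replicates
                add(compound, dose, t, n)
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    _check_design(design)
    return design


def generate_biopsy_design(
    n_control: int = 8, n_ant: int = 6, n_nonant: int = 2, seed: int = 0
) -> pd.DataFrame:
    """Heart-failure biopsy design: control, ANT-treated and non-ANT-treated
    cancer patients (defaults give the 16-sample analysis set)."""
    rows = []
    for group, n in (
        ("control", n_control),
        ("ant_treated", n_ant),
        ("nonant_treated", n_nonant),
    ):
        for r in range(1, n + 1):
            sid = f"bx_{group}_r{r}"
            rows.append((sid, "biopsy", None, None, None, r, group))
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    _check_design(design)
    return design


def _check_design(design: pd.DataFrame) -> None:
    if design["sample_id"].duplicated().any():
        raise ValueError("sample_ids are not unique")


def _condition_key(row: pd.Series) -> str | None:
    """Condition label used by effect profiles: compound:dose:timepoint for
    treated in vitro samples, patient_group for treated biopsies, None for
    controls."""
    if row["dataset_kind"] == "invitro":
        if row["compound"] in (None, "none") or pd.isna(row["compound"]):
            return None
        return f"{row['compound']}:{row['dose']}:{int(row['timepoint_h'])}"
    group = row["patient_group"]
    return None if group == "control" else str(group)


def build_effect_profile(
    design: pd.DataFrame,
    module_labels: list[str],
    effect_size: float,
    affected_modules: list[str] | None = None,
    min_timepoint_h: int = 72,
) -> dict[str, dict[str, float]]:
    """Per-module additive log2 shifts for treated conditions.

    In vitro, shifts apply to treated conditions at ``min_timepoint_h`` or
    later (an intermediate/chronic response); set ``min_timepoint_h=0`` for
    an effect across all exposures.  Biopsy shifts apply to both treated
    patient groups.  Sign alternates between affected modules.
    """
    if affected_modules is None:
        affected_modules = module_labels
    conditions = sorted(
        {k for k in (_condition_key(r) for _, r in design.iterrows()) if k is not None}
    )
    profile: dict[str, dict[str, float]] = {m: {} for m in module_labels}
    for i, module in enumerate(module_labels):
        if module not in affected_modules:
            continue
        sign = 1.0 if i % 2 == 0 else -1.0
        for cond in conditions:
            parts = cond.split(":")
            if len(parts) == 3 and int(parts[2]) < min_timepoint_h:
                continue
            profile[module][cond] = sign * effect_size
    return profile


def generate_protein_profiles(
    design: pd.DataFrame,
    module_sizes: list[int],
    effect_size: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    *,
    n_background: int = 0,
    kme_range: tuple[float, float] = (0.85, 0.97),
    baseline_range: tuple[float, float] = (8.0, 14.0),
    affected_modules: list[str] | None = None,
    effect_min_timepoint_h: int = 72,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Plant co-expression modules on top of a sample design.

    Each module m has a latent unit-variance per-sample template T_m; treated
    conditions in the module's effect profile shift the template additively
    (log2 units).  Protein p of module m is

        x_p = baseline_p + a_p * T_m + noise_sd * eps,
        a_p = noise_sd * r_p / sqrt(1 - r_p^2),

    so its expected correlation with the template (its planted module
    membership) is exactly the drawn target r_p ~ U(kme_range).  Background
    proteins are pure noise.  Baselines are U(baseline_range) log2 units so a
    "log2 expression > 10" high-expression filter is exercised nontrivially.
    """
    if len(design) == 0:
        raise ValueError("design is empty")
    if any(s <= 0 for s in module_sizes):
        raise ValueError("module_sizes must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_samples = len(design)
    module_labels = [f"M{i + 1}" for i in range(len(module_sizes))]
    profile = build_effect_profile(
        design, module_labels, effect_size, affected_modules, effect_min_timepoint_h
    )
    condition_keys = [_condition_key(r) for _, r in design.iterrows()]

    templates = {}
    for m in module_labels:
        t = rng.standard_normal(n_samples)
        shift = np.array([profile[m].get(c, 0.0) if c else 0.0 for c in condition_keys])
        templates[m] = t + shift

    rows = []
    accs = []
    partition: dict[str, str] = {}
    kme: dict[str, float] = {}
    idx = 0
    for m, size in zip(module_labels, module_sizes):
        for _ in range(size):
            acc = f"SYN{idx:04d}"
            idx += 1
            baseline = rng.uniform(*baseline_range)
            r = rng.uniform(*kme_range)
            eps = rng.standard_normal(n_samples)
            if noise_sd == 0.0:
                x = baseline + templates[m]
                r = 1.0
            else:
                a = noise_sd * r / np.sqrt(1.0 - r**2)
                x = baseline + a * templates[m] + noise_sd * eps
            rows.append(x)
            accs.append(acc)
            partition[acc] = m
            kme[acc] = float(r)
    for _ in range(n_background):
        acc = f"SYN{idx:04d}"
        idx += 1
        baseline = rng.uniform(*baseline_range)
        x = baseline + max(noise_sd, 1e-12) * rng.standard_normal(n_samples)
        rows.append(x)
        accs.append(acc)
        partition[acc] = BACKGROUND_LABEL
        kme[acc] = 0.0

    matrix = pd.DataFrame(rows, index=accs, columns=list(design["sample_id"]))
    truth = SyntheticTruth(planted_partition=partition, planted_kme=kme, effect_profile=profile)
    return matrix, truth


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def generate_peptides(
    proteins: pd.DataFrame,
    peptides_per_protein: tuple[int, int] = (3, 6),
    seed: int = 0,
    *,
    response_sd: float = 0.5,
    variant_fraction: float = 0.3,
) -> pd.DataFrame:
    """Expand a log2 protein matrix into a linear-scale peptide table.

    Each protein gets k ~ U{peptides_per_protein} tryptic-looking peptides
    with multiplicative log-normal response factors; a ``variant_fraction``
    of peptides is split across charge states (2+/3+/4+) and modification
    variants whose intensities sum back to the peptide's total, so
    consolidation followed by Hi3 is an exact round trip on noise-free data.
    """
    lo, hi = peptides_per_protein
    if lo < 1:
        raise ValueError("peptides_per_protein minimum must be >= 1")
    rng = np.random.default_rng(seed)
    sample_cols = list(proteins.columns)
    linear = np.power(2.0, proteins.to_numpy(dtype=float))
    mods = ["carbamidomethyl", "deamidated", "oxidation"]
    seen: set[str] = set()
    records = []
    for i, acc in enumerate(proteins.index):
        k = int(rng.integers(lo, hi + 1))
        for _ in range(k):
            while True:
                seq = "".join(rng.choice(_AA, size=int(rng.integers(8, 15)))) + "K"
                if seq not in seen:
                    seen.add(seq)
                    break
            f = float(rng.lognormal(mean=0.0, sigma=response_sd))
            total = f * linear[i]
            if rng.uniform() < variant_fraction:
                n_var = int(rng.integers(2, 4))
                w = rng.uniform(0.2, 1.0, size=n_var)
                w = w / w.sum()
                charges = [2, 3, 4][:n_var]
                variants = [
                    (charges[j], "none" if j == 0 else mods[j - 1], w[j]) for j in range(n_var)
                ]
            else:
                variants = [(2, "none", 1.0)]
            for charge, mod, weight in variants:
                records.append([seq, acc, charge, mod] + list(weight * total))
    table = pd.DataFrame(records, columns=PEPTIDE_META_COLUMNS + sample_cols)
    return table


def inject_missingness(
    matrix: pd.DataFrame,
    mechanism: str = "intensity_dependent",
    target_rate: float = 0.2,
    seed: int = 0,
    *,
    steepness: float = 4.0,
) -> pd.DataFrame:
    """Censor cells MCAR or preferentially at low intensity.

    The realized overall missing fraction equals ``target_rate`` up to
    rounding (cells are drawn without replacement).  In intensity-dependent
    mode the censoring weight decays exponentially with the cell's intensity
    rank, mimicking left-censored label-free LC-MS data.
    """
    if not 0 <= target_rate < 1:
        raise ValueError("target_rate must be in [0, 1)")
    if mechanism not in ("MCAR", "intensity_dependent"):
        raise ValueError(f"unknown mechanism: {mechanism}")
    out = matrix.copy()
    value_cols = [c for c in out.columns if c not in PEPTIDE_META_COLUMNS]
    values = out[value_cols].to_numpy(dtype=float)
    flat = values.ravel()
    n_cells = flat.size
    n_target = int(round(target_rate * n_cells))
    present = np.flatnonzero(~np.isnan(flat))
    n_new = n_target - (n_cells - present.size)
    if n_new <= 0 or target_rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    if mechanism == "MCAR":
        chosen = rng.choice(present, size=n_new, replace=False)
    else:
        ranks = np.argsort(np.argsort(flat[present])) / max(present.size - 1, 1)
        logw = -steepness * ranks
        # Gumbel top-k = weighted sampling without replacement
        keys = logw + rng.gumbel(size=present.size)
        chosen = present[np.argsort(keys)[::-1][:n_new]]
    flat[chosen] = np.nan
    out[value_cols] = flat.reshape(values.shape)
    return out


def generate_ppi(
    proteins: list[str],
    hub_count: int,
    hub_degree: int,
    background_degree_mean: float,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Simple undirected graph with ``hub_count`` planted hubs of degree
    >= ``hub_degree`` over a Poisson-degree background; returns (edges, hubs)."""
    n = len(proteins)
    if hub_degree >= n:
        raise ValueError("hub_degree must be smaller than the number of proteins")
    if hub_count > n:
        raise ValueError("hub_count exceeds number of proteins")
    rng = np.random.default_rng(seed)
    edges: set[tuple[str, str]] = set()

    def add_edge(a: str, b: str) -> None:
        if a != b:
            edges.add((a, b) if a < b else (b, a))

    p = background_degree_mean / max(n - 1, 1)
    if p > 0:
        upper = rng.uniform(size=(n, n))
        ii, jj = np.where(np.triu(upper < p, k=1))
        for i, j in zip(ii, jj):
            add_edge(proteins[i], proteins[j])
    hubs = [proteins[i] for i in rng.choice(n, size=hub_count, replace=False)]
    degree: dict[str, int] = {}
    for a, b in edges:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    for hub in hubs:
        others = [q for q in proteins if q != hub]
        rng.shuffle(others)
        k = 0
        while degree.get(hub, 0) < hub_degree and k < len(others):
            before = len(edges)
            add_edge(hub, others[k])
            if len(edges) > before:
                degree[hub] = degree.get(hub, 0) + 1
                degree[others[k]] = degree.get(others[k], 0) + 1
            k += 1
    return sorted(edges), sorted(hubs)


def make_disease_set(
    truth: SyntheticTruth,
    modules: list[str],
    fraction: float = 0.3,
    n_background: int = 0,
    seed: int = 0,
) -> set[str]:
    """Disease gene set overlapping the given planted modules (plus optional
    background proteins), stored back onto the truth object."""
    rng = np.random.default_rng(seed)
    disease: set[str] = set()
    for m in modules:
        members = sorted(p for p, lab in truth.planted_partition.items() if lab == m)
        k = int(round(fraction * len(members)))
        if k:
            disease.update(rng.choice(members, size=k, replace=False))
    if n_background:
        bg = sorted(
            p for p, lab in truth.planted_partition.items() if lab == BACKGROUND_LABEL
        )
        k = min(n_background, len(bg))
        if k:
            disease.update(rng.choice(bg, size=k, replace=False))
    truth.disease_set = disease
    return disease
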