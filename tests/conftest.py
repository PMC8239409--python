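import numpy as np
import pandas as pd
import pytest

from wpcna import coexnet, preprocess, synthetic


@pytest.fixture
def invitro_design():
    return synthetic.generate_invitro_design(n_replicates=1)


@pytest.fixture
def small_peptides():
    """Four peptides over two proteins, three samples, with charge variants."""
    return pd.DataFrame(
        {
            "peptide": ["AAAK", "AAAK", "CCCK", "DDDK", "EEEK"],
            "protein": ["P1", "P1", "P1", "P2", "P2"],
            "charge": [2, 3, 2, 2, 2],
            "modification": ["none", "oxidation", "none", "none", "none"],
            "s1": [100.0, 40.0, 50.0, 10.0, 20.0],
            "s2": [80.0, np.nan, 60.0, 12.0, 24.0],
            "s3": [np.nan, np.nan, 70.0, 14.0, 28.0],
        }
    )


def planted_pipeline(seed, module_sizes, effect_size=1.0, n_background=0,
                     affected_modules=None, effect_min_timepoint_h=72,
                     n_replicates=1, missing_rate=0.2):
    """Run the synthetic generator and the module-detection stack once,
    returning everything downstream tests need."""
    design = synthetic.generate_invitro_design(n_replicates)
    matrix, truth = synthetic.generate_protein_profiles(
        design,
        module_sizes,
        effect_size=effect_size,
        seed=seed,
        n_background=n_background,
        affected_modules=affected_modules,
        effect_min_timepoint_h=effect_min_timepoint_h,
    )
    matrix = synthetic.inject_missingness(
        matrix, "intensity_dependent", missing_rate, seed=seed + 7919
    )
    normalized, _ = preprocess.normalize_invitro(matrix, design)
    normalized = preprocess.filter_missing(normalized)
    params = coexnet.NetworkParams()
    adjacency = coexnet.signed_adjacency(normalized, params.power)
    diss = coexnet.tom_dissimilarity(adjacency)
    tree = coexnet.cluster_tree(diss)
    partition = coexnet.dynamic_cut(tree, diss, params)
    eigengenes = coexnet.module_eigengenes(normalized, partition)
    partition, eigengenes = coexnet.merge_modules(
        normalized, partition, eigengenes, params.merge_cut_height
    )
    return design, normalized, truth, partition, eigengenes
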