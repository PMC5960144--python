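import io as _io

import numpy as np
import pytest
from skbio import TreeNode

from fastkit.recovery import EngraftmentRecovery, RecoveryConfig
from fastkit.simulate import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def toy_tree() -> TreeNode:
    """The 3-leaf tree used by the worked UniFrac examples."""
    return TreeNode.read(_io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture(scope="session")
def small_bundle():
    """A scaled-down synthetic study for fast integration tests."""
    return generate_study(
        SyntheticConfig(
            n_subjects=4,
            n_mice_per_subject=2,
            n_otus=120,
            reads_per_sample=3000,
            rng_seed=11,
        )
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic study at the full default design (8 subjects, 800 OTUs)."""
    return generate_study(SyntheticConfig(rng_seed=1))


@pytest.fixture(scope="session")
def engraftment_replicates():
    """Mean OTU-level S2->mouse recovery across 20 replicate default studies."""
    means = []
    for seed in range(1, 21):
        bundle = generate_study(SyntheticConfig(rng_seed=seed))
        results = EngraftmentRecovery(
            bundle.table, bundle.taxonomy, bundle.manifest,
            RecoveryConfig(ranks=("OTU",)),
        ).fit()
        means.append(results.mean_recovery("S2_vs_mouse", "OTU", "any_mouse"))
    return np.asarray(means)
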