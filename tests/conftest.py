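import numpy as np
import pandas as pd
import pytest

from metacohort import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def signal_cohort():
    """Six mid-size studies with SMD + survival signal, correlated pair,
    and a mutated driver gene; the workhorse fixture."""
    rng = np.random.default_rng(0)
    genes = 120
    cfg = SyntheticConfig(
        n_studies=6, genes=genes, samples_per_study=(60, 120),
        true_smd=rng.normal(0, 0.5, genes),
        true_loghr=rng.normal(0, 0.2, genes),
        corr_pairs=[(0, 1, 0.8)],
        mutation_genes=[("EGFR", 0.3, np.r_[0.8, np.zeros(genes - 1)])],
        seed=42,
    )
    bundles, truth = generate_cohort(cfg)
    return cfg, bundles, truth


@pytest.fixture(scope="session")
def null_cohort():
    """No signal, no heterogeneity, no batch structure."""
    cfg = SyntheticConfig(n_studies=6, genes=400, true_smd=0.0, tau2_smd=0.0,
                          batch_shift_sd=0.0, batch_scale_range=(1.0, 1.0),
                          seed=7)
    bundles, truth = generate_cohort(cfg)
    return cfg, bundles, truth


@pytest.fixture()
def tiny_bundle():
    """Hand-built 3-gene x 6-sample study for exact-value tests."""
    from metacohort import StudyBundle
    expr = pd.DataFrame(
        [[3.0, 4.0, 5.0, 6.0, 1.0, 2.0],
         [1.0, 1.0, 2.0, 2.0, 1.5, 1.5],
         [5.0, 5.0, 5.0, 5.0, 5.0, 5.0]],
        index=["gA", "gB", "gConst"],
        columns=[f"s{i}" for i in range(6)],
    )
    samples = pd.DataFrame(
        {
            "tissue": ["tumor"] * 4 + ["normal"] * 2,
            "histology": "ADC",
            "os_time": [5.0, 10.0, 15.0, 20.0, np.nan, np.nan],
            "os_event": [1.0, 0.0, 1.0, 1.0, np.nan, np.nan],
        },
        index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"),
    )
    return StudyBundle("tiny", expr, samples)
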