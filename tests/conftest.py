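import numpy as np
import pandas as pd
import pytest

from cfmir.io import CountMatrix


def make_count_matrix(counts, groups=None, fraction="WP", rna_types=None,
                      features=None, samples=None) -> CountMatrix:
    """Wrap a 2-D array of counts into a CountMatrix with minimal metadata."""
    counts = np.asarray(counts)
    n_feat, n_samp = counts.shape
    features = features or [f"f{i}" for i in range(n_feat)]
    samples = samples or [f"s{j}" for j in range(n_samp)]
    if groups is None:
        half = n_samp // 2
        groups = ["PTSD-"] * half + ["PTSD+"] * (n_samp - half)
    rna_types = rna_types or ["miRNA"] * n_feat
    df = pd.DataFrame(counts, index=features, columns=samples)
    meta = pd.DataFrame(
        {"subject": [f"S{j}" for j in range(n_samp)], "group": groups,
         "fraction": [fraction] * n_samp},
        index=pd.Index(samples, name="sample"),
    )
    return CountMatrix(df, pd.Series(rna_types, index=features, name="rna_type"), meta)


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 3-fraction cohort with one planted marker per EV and EVD."""
    import cfmir as m

    cfg = m.SimConfig(
        n_per_group=12,
        n_mirna=200,
        lib_size_mean=1e5,
        de_spec=[
            m.PlantedEffect("miR-sim-0100", "EV", 4.0, "up"),
            m.PlantedEffect("miR-sim-0150", "EVD", 3.0, "down"),
        ],
        seed=11,
    )
    tables, samples, gt = m.simulate_cohort(cfg)
    return cfg, tables, samples, gt
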