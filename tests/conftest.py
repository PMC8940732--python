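import numpy as np
import pandas as pd
import pytest

import morphosim as ms


@pytest.fixture(scope="session")
def small_cohort():
    """Null cohort (no planted effect), 20 regions, 15 + 15 subjects."""
    cfg = ms.MorphSimConfig(n_cases=15, n_controls=15, n_regions=20, seed=101)
    subjects, truth = ms.simulate_cohort(cfg)
    return subjects, truth


@pytest.fixture(scope="session")
def toy_subject():
    rng = np.random.default_rng(7)
    return ms.SubjectMorphometry(
        subject_id="s1",
        group="control",
        age=40.0,
        sex=0,
        icv=1.5e6,
        features=rng.standard_normal((6, 5)),
        region_labels=[f"r{i}" for i in range(6)],
    )


@pytest.fixture(scope="session")
def toy_donor_tables():
    """Three-donor toy expression set over 10 regions, 30 genes."""
    cfg = ms.ExpressionSimConfig(
        n_genes=30, n_regions=10, n_donors=3, n_signal_pos=5, n_signal_neg=5,
        alignment_strength=0.8, donor_noise_sd=0.3, seed=11)
    target = np.random.default_rng(3).standard_normal(10)
    tables, geometry, truth = ms.simulate_expression(cfg, target)
    return tables, geometry, truth, target


@pytest.fixture(scope="session")
def left_geometry():
    """34-parcel synthetic left-hemisphere spherical geometry."""
    from morphosim.parcellation import synthetic_dk_geometry

    frame = synthetic_dk_geometry(whole_cortex=False)
    return ms.ParcelGeometry.from_frame(frame)
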