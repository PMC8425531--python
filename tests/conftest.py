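import numpy as np
import pandas as pd
import pytest

from repeatsig.synthetic import CohortSpec, generate_cohort
from tests.helpers import profile_of


@pytest.fixture(scope="session")
def small_cohort():
    """3-class cohort with a planted m-shift in the third class."""
    spec = CohortSpec(
        n_classes=3,
        samples_per_class=(20, 20, 20),
        n_regions=30,
        signal_regions=frozenset(range(5)),
        effect_class=2,
        m_shift=3.0,
        d_shift=0.0,
        seed=101,
    )
    return generate_cohort(spec, keep_histories=True)


@pytest.fixture(scope="session")
def perfect_cohort():
    """Zero-mutation cohort: every region is a perfect tandem repeat."""
    spec = CohortSpec(
        n_classes=2,
        samples_per_class=(8, 8),
        n_regions=40,
        pattern_length_range=(2, 8),
        base_mutation_rate=0.0,
        pattern_noise_rate=0.0,
        dropout_rate=0.0,
        signal_regions=frozenset(),
        effect_class=0,
        m_shift=0.0,
        seed=202,
    )
    return generate_cohort(spec, keep_histories=True)


@pytest.fixture
def paper_profiles():
    """The worked alignment example: query (A, CG) vs reference (A, CGTA, CG)."""
    query = profile_of("patient1", [("A", 0, 7), ("CG", 1, 4)])
    reference = profile_of(
        "reference", [("A", 0, 8), ("CGTA", 0, 3), ("CG", 1, 3)]
    )
    return query, reference


@pytest.fixture(scope="session")
def labeled_matrix():
    """Synthetic aligned matrix with a strong planted shift in one class."""
    from repeatsig.align import AlignedMatrix

    rng = np.random.default_rng(7)
    n, n_regions = 96, 30
    X = rng.poisson(2.0, size=(n, 2 * n_regions)).astype(float)
    y = np.array(["alpha"] * 32 + ["beta"] * 32 + ["gamma"] * 32)
    X[y == "gamma", :6] += 4.0
    ids = [f"s{i:03d}" for i in range(n)]
    regions = [f"chr1:{100 * i}-{100 * i + 10}" for i in range(n_regions)]
    cols = [f"{r}_{s}" for r in regions for s in ("m", "d")]
    return AlignedMatrix(
        reference_regions=regions,
        values=pd.DataFrame(X, index=pd.Index(ids, name="sample_id"), columns=cols),
        labels=pd.Series(y, index=ids, name="class"),
    )
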