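import numpy as np
import pandas as pd
import pytest

from myomethix.formats_io import BetaMatrix, ExpressionMatrix, SampleSheet
from myomethix.synthetic_cohort import SimulationConfig, simulate_cohort

# de_effect_log2 is raised because the scaled-down cohort (n=10 per
# group, 300 genes) otherwise lacks power for cross-state recovery tests
SMALL_KWARGS = dict(
    n_per_group=10, n_genes=300, n_probes=1500, n_candidate_genes=3,
    n_opposite_sites=10, n_random_sets=5, promoter_length=300,
    de_effect_log2=1.5,
)


@pytest.fixture(scope="session")
def small_sim():
    """A scaled-down simulated cohort shared by fast unit tests."""
    return simulate_cohort(SimulationConfig(seed=42, **SMALL_KWARGS))


@pytest.fixture(scope="session")
def small_bundle(small_sim):
    return small_sim.bundle


def make_sample_sheet(n_per_group=2, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for group, prefix in (("NGT", "N"), ("T2D", "D")):
        for i in range(n_per_group):
            subject = f"{prefix}{i:02d}"
            for state in ("myoblast", "myotube"):
                rows.append({
                    "sample_id": f"{subject}_{state}", "subject_id": subject,
                    "group": group, "state": state,
                    "age": float(rng.integers(40, 70)),
                    "bmi": float(rng.uniform(20, 32)),
                    "sex": "male" if i % 2 == 0 else "female",
                })
    return SampleSheet(pd.DataFrame(rows))


def make_matrices(sheet, n_features=5, seed=0, kind="expression"):
    rng = np.random.default_rng(seed)
    ids = [f"F{i:03d}" for i in range(n_features)]
    samples = tuple(sheet.sample_ids)
    if kind == "expression":
        values = rng.normal(8, 1, (n_features, len(samples)))
        return ExpressionMatrix(tuple(ids), samples, values)
    values = rng.uniform(0.05, 0.95, (n_features, len(samples)))
    return BetaMatrix(tuple(ids), samples, values)
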