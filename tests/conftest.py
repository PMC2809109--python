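import numpy as np
import pandas as pd
import pytest

from priorihap import simulate
from priorihap.genio import GenotypeMatrix


@pytest.fixture
def small_cohort():
    """Modest case-control cohort with a planted OR-4 haplotype (two blocks)."""
    cfg = simulate.SimConfig(
        n_cases=68,
        n_controls=830,
        n_blocks=2,
        founder_freqs=[[0.05, 0.35, 0.30, 0.30], [0.25, 0.25, 0.25, 0.25]],
        risk_block_index=0,
        risk_haplotype_index=0,
        risk_or=4.0,
        missing_rate=0.02,
        seed=11,
    )
    return simulate.simulate_cohort(cfg)


@pytest.fixture
def null_cohort():
    """Cohort with no genetic effect (risk OR 1), no missingness."""
    cfg = simulate.SimConfig(
        n_cases=68,
        n_controls=830,
        n_blocks=4,
        markers_per_block=5,
        risk_or=1.0,
        missing_rate=0.0,
        seed=5,
    )
    return simulate.simulate_cohort(cfg)


def make_genotypes(dosage, individual_ids=None, marker_ids=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    ind = individual_ids or [f"i{k}" for k in range(n)]
    mk = marker_ids or [f"m{k}" for k in range(m)]
    return GenotypeMatrix(ind, mk, dosage)


def make_phenos(statuses, sexes=None, individual_ids=None):
    n = len(statuses)
    ind = individual_ids or [f"i{k}" for k in range(n)]
    return pd.DataFrame(
        {
            "family_id": ind,
            "individual_id": ind,
            "sex": sexes or ["male"] * n,
            "status": statuses,
        }
    )
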