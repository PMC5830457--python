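import io

import numpy as np
import pytest

from hccscreen import (
    Cohort,
    default_study_spec,
    generate_cohort,
    read_cohort,
)


TINY_CSV = """subject_id,disease_group,tp53_249t,mrassf1a,mgstp1,serum_afp,age,gender,hbv,hcv
A1,HCC,1.5,0.0,2.0,250.0,61,male,positive,negative
B1,hepatitis,0.0,0.3,0.0,4.2,55,female,negative,
"""


@pytest.fixture()
def tiny_csv():
    return io.StringIO(TINY_CSV)


@pytest.fixture(scope="session")
def study_cohort():
    """Default synthetic study cohort (137 HCC / 207 cirrhosis / 224 hepatitis)."""
    return generate_cohort(default_study_spec(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort for fast model fits (60 HCC / 140 controls)."""
    spec = default_study_spec(seed=7)
    spec.n_hcc, spec.n_cirrhosis, spec.n_hepatitis = 60, 70, 70
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20180228)


def brute_force_auc(scores, labels):
    """O(n^2) Mann-Whitney oracle: P(s1 > s0) + 0.5 P(s1 = s0)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))
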