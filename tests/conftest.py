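import numpy as np
import pytest

import naivegate as ng
from naivegate.simulate import NAIVE_SUBSET_OF


@pytest.fixture(scope="session")
def cohort_config():
    return ng.default_cohort_config(seed=12345)


@pytest.fixture(scope="session")
def donor_20k(cohort_config):
    """One young-donor synthetic sample at demonstration scale (20k events)."""
    return ng.simulate_donor(("A001", 30.0, "A"), cohort_config,
                             n_events=20_000, seed=42)


@pytest.fixture(scope="session")
def donor_20k_asinh(donor_20k, cohort_config):
    return ng.asinh_transform(donor_20k.events, cohort_config.cofactor)


@pytest.fixture(scope="session")
def gating_20k(donor_20k_asinh):
    """Full default gating tree run on the 20k donor (shared: it is the
    expensive end-to-end object several suites interrogate)."""
    return ng.run_gating_tree(donor_20k_asinh, seed=7)


def coarse_truth(truth):
    """Collapse naive-subset leaf labels to their parent population."""
    return np.array([NAIVE_SUBSET_OF.get(t, t) for t in truth])


def f1_score(pred_mask, truth_mask):
    tp = int(np.sum(pred_mask & truth_mask))
    fp = int(np.sum(pred_mask & ~truth_mask))
    fn = int(np.sum(~pred_mask & truth_mask))
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return precision, recall, 2 * precision * recall / (precision + recall)
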