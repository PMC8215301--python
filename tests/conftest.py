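import numpy as np
import pandas as pd
import pytest

from schoolineq.synthetic import (ConfounderSpec, COMPREHENSIVE, SELECTIVE,
                                  generate_cohort, planted_continuous_outcome)


def make_ordered(labels_per_record, categories):
    """Ordered categorical helper (disadvantaged -> advantaged)."""
    return pd.Categorical(labels_per_record, categories=categories, ordered=True)


def exact_two_arm_table(ci_comp: float, ci_sel: float, n_per_arm: int = 2500,
                        noise_sd: float = 0.0, seed: int = 0):
    """Two-system cohort with deterministic class shares per arm and a
    noise-free (by default) outcome exactly linear in the population class
    rank, so arm-wise concentration indices equal their planted values at
    machine precision."""
    spec = ConfounderSpec()
    arms = []
    for label, ci in ((COMPREHENSIVE, ci_comp), (SELECTIVE, ci_sel)):
        out = planted_continuous_outcome("y", ci, ci, noise_sd=noise_sd,
                                         spec=spec)
        t, _ = generate_cohort(spec, outs=[out], n=n_per_arm,
                               seed=seed + (0 if label == COMPREHENSIVE else 1),
                               exact_class_counts=True)
        t["system"] = pd.Categorical([label] * n_per_arm,
                                     categories=[COMPREHENSIVE, SELECTIVE])
        arms.append(t)
    table = pd.concat(arms, ignore_index=True)
    table.attrs["outcome_meta"] = {
        "y": {"kind": "continuous", "higher_is_better": True, "bounds": [0, 1]}}
    table.attrs["outcome_names"] = ["y"]
    return table


@pytest.fixture(scope="session")
def default_cohort():
    """One moderately sized confounded cohort shared across read-only tests."""
    table, truth = generate_cohort(n=20_000, seed=11)
    return table, truth
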