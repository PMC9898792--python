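import numpy as np
import pandas as pd
import pytest

import cellfie as cf


@pytest.fixture
def toy_matrix():
    """3 genes × 2 samples, handcrafted."""
    return cf.ExpressionMatrix(pd.DataFrame(
        [[2.0, 4.0], [10.0, 1.0], [0.0, 6.0]],
        index=["101", "102", "103"], columns=["s1", "s2"],
    ))


@pytest.fixture
def toy_model():
    """Two tasks sharing gene 101 (promiscuous), one AND rule, one empty rule."""
    tasks = [
        cf.TaskInfo("T1", "task one", "SYS1", "SUB1"),
        cf.TaskInfo("T2", "task two", "SYS1", "SUB2"),
    ]
    rules = {
        "R1": cf.parse_gpr("101 and 102"),
        "R2": cf.parse_gpr("103"),
        "R3": cf.parse_gpr("101 or 103"),
        "R4": cf.parse_gpr(""),
    }
    model = cf.TaskModel(
        tasks=tasks,
        task_reactions={"T1": ["R1", "R2"], "T2": ["R3", "R4"]},
        gpr_rules=rules,
    )
    model.validate()
    return model


@pytest.fixture
def default_design():
    return cf.FixtureDesign(seed=7)


@pytest.fixture
def noise_free_design():
    return cf.FixtureDesign(seed=7, noise_sd=0.0)


@pytest.fixture
def seeded_fixture(default_design):
    model = cf.generate_model(default_design)
    m, props = cf.generate_expression(model, default_design)
    return model, m, props


def mixed_planted_design(seed=11, noise_sd=0.0):
    """8 tasks, 2 groups: T01/T02 active in both groups, T03/T04 inactive in
    both, T05–T08 differ between groups — so 'designed different' is a strict
    subset of all tasks. A large background gene pool keeps the pooled
    percentile bounds inside the background component, so the min-max-mean
    clamp can call uniformly high/low genes (local thresholding has no
    across-sample contrast for them otherwise)."""
    planted = {}
    patterns = {
        "T01": ("high", "high"), "T02": ("high", "high"),
        "T03": ("low", "low"), "T04": ("low", "low"),
        "T05": ("high", "low"), "T06": ("low", "high"),
        "T07": ("high", "low"), "T08": ("low", "high"),
    }
    for tid, (a, b) in patterns.items():
        planted[(tid, "A")] = a
        planted[(tid, "B")] = b
    return cf.FixtureDesign(seed=seed, noise_sd=noise_sd, n_genes=120,
                            planted_activity=planted), {
        tid for tid, (a, b) in patterns.items() if a != b
    }
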