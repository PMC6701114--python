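import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import omescreen as om

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# --- frozen numeric fixtures -------------------------------------------------

# 10 samples, 2 cohorts; hand-picked values with nonzero slopes in both
# cohorts, used against the normal-equations + quadrature oracle
PAIR10 = dict(
    y=np.array([0.10, 0.22, 0.31, 0.38, 0.52, 0.05, 0.12, 0.35, 0.41, 0.60]),
    x=np.array([1.0, 2.0, 3.1, 4.2, 5.0, 0.8, 1.6, 3.5, 4.4, 6.0]),
    cohorts=np.array(["A", "A", "A", "A", "A", "B", "B", "B", "B", "B"]),
    reference="A",
)

# 12 points, 2 cohorts, slight curvature so residuals are non-trivial
PAIR12 = dict(
    y=np.array([0.11, 0.19, 0.33, 0.36, 0.50, 0.47,
                0.08, 0.15, 0.24, 0.39, 0.44, 0.58]),
    x=np.array([0.9, 1.8, 3.0, 4.1, 5.2, 5.9,
                0.7, 1.5, 2.6, 3.8, 4.9, 6.1]),
    cohorts=np.array(["A"] * 6 + ["B"] * 6),
    reference="A",
)


@pytest.fixture
def pair10():
    return {k: (v.copy() if isinstance(v, np.ndarray) else v)
            for k, v in PAIR10.items()}


@pytest.fixture
def pair12():
    return {k: (v.copy() if isinstance(v, np.ndarray) else v)
            for k, v in PAIR12.items()}


@pytest.fixture
def fit10(pair10):
    return om.fit_pair(pair10["y"], pair10["x"], pair10["cohorts"],
                       pair10["reference"], microbe="Mb_1", immune="IR_1")


@pytest.fixture
def fit12(pair12):
    return om.fit_pair(pair12["y"], pair12["x"], pair12["cohorts"],
                       pair12["reference"], microbe="Mb_1", immune="IR_1")


# --- table fixtures ----------------------------------------------------------

@pytest.fixture
def tiny_table():
    """4 samples, 2 cohorts, 2 microbes + 1 cytokine."""
    values = pd.DataFrame(
        {
            "Mb_1": [0.1, 0.0, 0.3, 0.5],
            "Mb_2": [0.0, 0.2, 0.0, 0.4],
            "IL6": [10.0, 12.0, 8.0, 15.0],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    cohorts = pd.Series(["HC", "HC", "CD", "CD"], index=values.index,
                        name="cohort")
    features = [
        om.FeatureMeta("Mb_1", "microbe", "relative abundance"),
        om.FeatureMeta("Mb_2", "microbe", "relative abundance"),
        om.FeatureMeta("IL6", "immune", "pg/ml"),
    ]
    return om.MergedTable(values=values, cohorts=cohorts, features=features)


@pytest.fixture
def tiny_csv(tmp_path):
    """The tiny table written in the documented CSV dialect."""
    table = tmp_path / "merged.csv"
    table.write_text(
        "sample_id,cohort,Mb_1,Mb_2,IL6\n"
        "s1,HC,0.1,0.0,10\n"
        "s2,HC,0.0,0.2,12\n"
        "s3,CD,0.3,0.0,8\n"
        "s4,CD,0.5,0.4,15\n"
    )
    manifest = tmp_path / "manifest.csv"
    manifest.write_text(
        "feature,ome,units\n"
        "Mb_1,microbe,relative abundance\n"
        "Mb_2,microbe,relative abundance\n"
        "IL6,immune,pg/ml\n"
    )
    return table, manifest


@pytest.fixture
def screened():
    """A small screen with planted structure, for export-level tests."""
    spec = om.SyntheticSpec(
        cohorts={"A": 18, "B": 17}, n_microbes=6, n_immune=4,
        planted=[om.PlantedPair(0, 0, {"A": 0.4, "B": 0.0}),
                 om.PlantedPair(1, 1, {"A": -0.3, "B": 0.3})],
        seed=7,
    )
    table, truth = om.generate_dataset(spec)
    config = om.RunConfig(
        reference_cohort="A", threshold_type="fdr_p", threshold_value=0.05,
        metric_columns=("F", "p", "pAdj", "interaction_p", "max_influence"),
        seed=7,
    )
    result, top = om.run_screen(table, config)
    return dict(table=table, truth=truth, config=config, result=result, top=top)
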