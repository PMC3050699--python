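import numpy as np
import pandas as pd
import pytest

from gmoequiv.mixed_model import fit_model
from gmoequiv.simulation import (
    SimulationSpec,
    example_field_design,
    generate_trial,
    generate_trial_from_design,
)


@pytest.fixture(scope="session")
def balanced_spec():
    return SimulationSpec(seed=20240915)


@pytest.fixture(scope="session")
def balanced_dataset(balanced_spec):
    """One balanced 8x4x8 synthetic trial on the ln scale."""
    return generate_trial(balanced_spec, iteration=3)


@pytest.fixture(scope="session")
def balanced_fits(balanced_dataset):
    """REML fits of both model variants on the balanced trial."""
    return (
        fit_model(balanced_dataset, 1),
        fit_model(balanced_dataset, 2),
    )


@pytest.fixture(scope="session")
def unbalanced_dataset():
    """Synthetic trial on the 67-plot four-site example layout."""
    return generate_trial_from_design(
        example_field_design(), m_gmo=-0.08, seed=11, analyte="protein"
    )


@pytest.fixture(scope="session")
def unbalanced_fits(unbalanced_dataset):
    return (
        fit_model(unbalanced_dataset, 1),
        fit_model(unbalanced_dataset, 2),
    )


@pytest.fixture()
def trial_csv(tmp_path):
    """Write a small long-format trial table (2 analytes, 67 plots each)."""
    frames = []
    for k, analyte in enumerate(["protein", "zinc"]):
        ds = generate_trial_from_design(
            example_field_design(), seed=100 + k, analyte=analyte
        )
        d = ds.data.copy()
        d["value"] = np.exp(d["y"]) * 10.0
        d["analyte"] = analyte
        frames.append(d[["site", "block", "genotype", "group", "analyte", "value"]])
    path = tmp_path / "trial.csv"
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path
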