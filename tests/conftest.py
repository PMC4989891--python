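import numpy as np
import pandas as pd
import pytest

from mirnetppi.io_formats import ExpressionMatrix
from mirnetppi.synth_fixtures import SynthConfig, generate_study


def make_matrix(values, feature_ids, samples, labels, mode="intensity"):
    frame = pd.DataFrame(values, index=feature_ids, columns=samples, dtype=float)
    return ExpressionMatrix(frame, pd.Series(labels, index=samples), mode=mode)


@pytest.fixture
def two_class_matrix():
    """4 vs 4 matrix with two obviously shifted features."""
    rng = np.random.default_rng(3)
    samples = [f"WT{i}" for i in range(1, 5)] + [f"KO{i}" for i in range(1, 5)]
    labels = ["WT"] * 4 + ["KO"] * 4
    values = rng.normal(8, 1, size=(20, 8))
    values[0, 4:] += 6.0  # up in KO
    values[1, 4:] -= 6.0  # down in KO
    return make_matrix(values, [f"f{i}" for i in range(20)], samples, labels)


@pytest.fixture(scope="session")
def default_study():
    return generate_study(SynthConfig())


@pytest.fixture
def study_dir(tmp_path, default_study):
    from mirnetppi.synth_fixtures import write_study

    return write_study(default_study, tmp_path / "study")
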