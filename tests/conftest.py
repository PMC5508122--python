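import numpy as np
import pandas as pd
import pytest

from ciber.data_io import QuestionnaireDataset


@pytest.fixture
def write_csv(tmp_path):
    """Write a CSV from rows of strings and return its path."""

    def _write(name: str, lines: list[str]):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20270929)


@pytest.fixture
def small_dataset(rng):
    """80 respondents, three correlated items plus one target, no missing."""
    n = 80
    t = rng.standard_normal(n)
    frame = pd.DataFrame(
        {
            "item_a": np.round(4 + 1.2 * (0.6 * t + 0.8 * rng.standard_normal(n))).clip(1, 7),
            "item_b": np.round(4 + 1.2 * (0.3 * t + 0.95 * rng.standard_normal(n))).clip(1, 7),
            "item_c": np.round(4 + 1.2 * rng.standard_normal(n)).clip(1, 7),
            "outcome": np.round(4 + 1.2 * t).clip(1, 7),
        }
    )
    return QuestionnaireDataset(frame)
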