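import numpy as np
import pandas as pd
import pytest

from comorbidx import SyntheticConfig, generate_registry, load_condition_maps
from comorbidx.codes import load_chapter_bands


@pytest.fixture(scope="session")
def condition_maps():
    return load_condition_maps()


@pytest.fixture(scope="session")
def chapter_bands():
    return load_chapter_bands()


@pytest.fixture(scope="session")
def small_cohort():
    """A 4,000-patient synthetic cohort shared by model-level tests."""
    return generate_registry(SyntheticConfig(n=4000, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_codes_in_bands(bands: pd.DataFrame, rng: np.random.Generator, n: int):
    """Syntactically valid codes drawn uniformly from the chapter bands."""
    rows = bands.sample(n=n, replace=True, random_state=int(rng.integers(2**31)))
    out = []
    for low, high in zip(rows["low"], rows["high"]):
        letter = chr(rng.integers(ord(low[0]), ord(high[0]) + 1))
        lo = int(low[1:]) if letter == low[0] else 0
        hi = int(high[1:]) if letter == high[0] else 99
        num = rng.integers(lo, hi + 1)
        code = f"{letter}{num:02d}"
        # random extra granularity
        for _ in range(rng.integers(0, 3)):
            if len(code) < 5:
                code += str(rng.integers(0, 10))
        out.append(code)
    return out
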