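import numpy as np
import pytest

from noisefield.cohort import expand_from_counts, load_study_fixture
from noisefield.prng import Xorshift32
from noisefield.stimulus import StimulusConfig, render_sequence
from noisefield.visual_field import (LAYOUT, Laterality, PDCategory, VFResult)


@pytest.fixture(scope="session")
def study_records():
    """Per-eye records expanded from the packaged study count fixture."""
    return expand_from_counts(load_study_fixture())


@pytest.fixture
def small_config():
    """A 30x30-cell stimulus, cheap enough for repeated rendering."""
    return StimulusConfig(width_px=210, height_px=210, dot_px=7, n_frames=4)


@pytest.fixture
def small_sequence(small_config):
    return render_sequence(small_config, Xorshift32(20240520))


def random_vf(rng: np.random.Generator, p_sig: float = 0.25) -> VFResult:
    """Random 30-2 pattern-deviation map (for oracle comparisons)."""
    cats = {}
    for p in LAYOUT:
        if rng.random() < p_sig:
            cats[(p.x_deg, p.y_deg)] = PDCategory(
                int(rng.integers(1, 5)))
    return VFResult.from_categories(Laterality.OD, cats, md_db=-3.0)
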