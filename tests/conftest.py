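import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from renoct import phantom, pipeline
from renoct.features import ExtractionConfig


def random_region(rng, shape=(7, 6, 5), n_levels=5, fill=0.6):
    """A random discretized region: (level volume, boolean mask)."""
    mask = rng.random(shape) < fill
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return levels, mask


@pytest.fixture(scope="session")
def cohort_stats():
    """Truth table of a 200-patient default cohort plus DSC for 50 kidneys.

    Streams patients so volumes are never held simultaneously.
    """
    from renoct.imaging import dice_coefficient, PARENCHYMA

    rows, dice = [], []
    params = phantom.PhantomParams(n_patients=200, seed=123)
    for i, pt in enumerate(phantom.iter_cohort(params)):
        for k in pt.kidneys.values():
            rows.append(
                dict(
                    patient_id=pt.patient_id,
                    age=pt.age,
                    true_gfr=k.true_gfr,
                    true_srf=k.true_srf,
                    rpv_ml=k.rpv_ml,
                    rhv_ml=k.rhv_ml,
                )
            )
            if i < 25:
                dice.append(dice_coefficient(k.manual_mask, k.auto_mask, PARENCHYMA))
    import pandas as pd

    return pd.DataFrame(rows), np.array(dice)


SMALL_N = 12
SMALL_SEED = 42


@pytest.fixture(scope="session")
def small_dataset():
    """Fully extracted 12-patient default-configuration dataset."""
    params = phantom.PhantomParams(n_patients=SMALL_N, seed=SMALL_SEED)
    return pipeline.build_phantom_dataset(params, pipeline.PipelineConfig(seed=SMALL_SEED))


@pytest.fixture(scope="session")
def small_training(small_dataset):
    return pipeline.run_training(small_dataset, pipeline.PipelineConfig(seed=SMALL_SEED))


@pytest.fixture()
def fast_config():
    """Trimmed extraction (no wavelet/square/log) for cheap pipeline tests."""
    return pipeline.PipelineConfig(
        extraction=ExtractionConfig(filters=("original", "gradient")), seed=0
    )
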