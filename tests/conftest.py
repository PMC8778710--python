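import numpy as np
import pandas as pd
import pytest

from dimsqc.core_io import PeakMatrix
from dimsqc.synthetic import StudyConfig, generate_study


def make_pm(values: dict[str, list], classes: list[str] | None = None,
            mz: list[float] | None = None, plates: list[str] | None = None,
            wells: list[str] | None = None, transformed: bool = False
            ) -> PeakMatrix:
    """Build a small PeakMatrix from a {sample_id: column} dict.

    ``values`` columns are per-sample intensity lists (np.nan = MISSING);
    all features get synthetic ids F1.. and evenly spaced m/z unless given.
    """
    intens = pd.DataFrame(values, dtype=float)
    n_feat = len(intens)
    intens.index = [f"F{i + 1}" for i in range(n_feat)]
    mz = mz or [100.0 + 10.0 * i for i in range(n_feat)]
    sample_ids = list(values)
    n = len(sample_ids)
    classes = classes or ["biological"] * n
    wells = wells or ["B2"] * n
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "class": classes,
        "plate_id": plates or ["TP1"] * n,
        "well": wells,
        "batch_id": ["B1"] * n,
        "acquisition_order": range(1, n + 1),
        "extraction_day": 1,
        "plate_extraction_order": 1,
        "deck_position": "a",
    })
    return PeakMatrix(intensities=intens,
                      mz=pd.Series(mz, index=intens.index), samples=samples,
                      transformed=transformed)


@pytest.fixture(scope="session")
def small_cfg() -> StudyConfig:
    """Desk-scale study used across unit tests (fast to generate)."""
    return StudyConfig(n_features=60, n_plates=2, wells_per_plate=12,
                       n_qc=6, n_blank=2, seed=11)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return generate_study(small_cfg)
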