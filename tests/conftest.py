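import numpy as np
import pandas as pd
import pytest

from nirscreen.spectra import SpectraSet


def make_meta(sample_ids, **overrides):
    n = len(sample_ids)
    data = {
        "sample_id": list(sample_ids),
        "batch_id": overrides.get("batch_id", ["default"] * n),
        "line_id": overrides.get("line_id", [""] * n),
        "replicate": overrides.get("replicate", [0] * n),
        "role": overrides.get("role", ["unknown"] * n),
    }
    return pd.DataFrame(data)


def make_set(absorbance, grid=None, sample_ids=None, **meta_overrides) -> SpectraSet:
    absorbance = np.atleast_2d(np.asarray(absorbance, float))
    n, p = absorbance.shape
    if grid is None:
        grid = 4000.0 + 8.0 * np.arange(p)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return SpectraSet(
        grid=np.asarray(grid, float),
        absorbance=absorbance,
        meta=make_meta(sample_ids, **meta_overrides),
    )


@pytest.fixture
def small_set() -> SpectraSet:
    rng = np.random.default_rng(42)
    return make_set(0.5 + 0.1 * rng.random((4, 50)))


@pytest.fixture
def wide_csv(tmp_path):
    """A 4-sample, 10-channel wide-matrix CSV on disk."""
    rng = np.random.default_rng(7)
    grid = 4000.0 + 8.0 * np.arange(10)
    vals = 0.2 + rng.random((10, 4))
    lines = ["wavenumber,a,b,c,d"]
    for i, w in enumerate(grid):
        lines.append(",".join([f"{w:.1f}"] + [f"{v:.10f}" for v in vals[i]]))
    path = tmp_path / "spectra.csv"
    path.write_text("\n".join(lines) + "\n")
    return path, grid, vals.T  # absorbance as samples x channels
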