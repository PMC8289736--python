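import numpy as np
import pandas as pd
import pytest

from sedsip.gradient import AbundanceTable


def make_table(values, sample_meta, asv_ids=None, mode="counts"):
    """Build an AbundanceTable from a matrix and a list of metadata dicts.

    ``values`` is (n_asv, n_sample); ``sample_meta`` is a list of dicts with
    at least sample_id; treatment/timepoint/density default sensibly.
    """
    values = np.asarray(values, dtype=float)
    asv_ids = asv_ids or [f"asv{i + 1}" for i in range(values.shape[0])]
    rows = []
    for j, m in enumerate(sample_meta):
        rows.append(
            {
                "sample_id": m.get("sample_id", f"s{j + 1}"),
                "gradient_id": m.get("gradient_id", "g1"),
                "treatment": m.get("treatment", "C13"),
                "timepoint_days": m.get("timepoint_days", 4),
                "density": m.get("density", float("nan")),
                "replicate": m.get("replicate", ""),
            }
        )
    meta = pd.DataFrame(rows).set_index("sample_id")
    data = pd.DataFrame(values, index=asv_ids, columns=meta.index)
    return AbundanceTable(data=data, meta=meta, mode=mode)


@pytest.fixture
def toy_gradient_table():
    """Two ASVs across a small two-treatment gradient at one time point."""
    densities = [1.715, 1.727, 1.731, 1.735, 1.739]
    meta = []
    for tr in ("C13", "C12"):
        for d in densities:
            meta.append(
                {
                    "sample_id": f"{tr}_{d:.3f}",
                    "gradient_id": f"{tr}_d4",
                    "treatment": tr,
                    "timepoint_days": 4,
                    "density": d,
                }
            )
    rng = np.random.default_rng(0)
    values = rng.integers(10, 100, size=(2, len(meta)))
    return make_table(values, meta)
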