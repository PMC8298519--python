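import numpy as np
import pandas as pd
import pytest

from surgforce import FEATURE_CATALOG, extract_all, make_fixture
from surgforce.segment_io import ForceSegment, SegmentTable


def make_segment(
    x,
    fs=100.0,
    segment_id="seg-0",
    task="Coagulation",
    experience="Expert",
    surgeon_id="EXP01",
    case_id="C01",
    left=None,
):
    """Build a single-channel test segment (left mirrors right unless given)."""
    x = np.asarray(x, dtype=float)
    return ForceSegment(
        segment_id=segment_id,
        case_id=case_id,
        sampling_rate=fs,
        left_force=np.asarray(left, dtype=float) if left is not None else x.copy(),
        right_force=x,
        task=task,
        surgeon_id=surgeon_id,
        experience=experience,
    )


def make_table(arrays, fs=100.0, **kwargs):
    segs = [
        make_segment(x, fs=fs, segment_id=f"seg-{i}", **kwargs) for i, x in enumerate(arrays)
    ]
    return SegmentTable(segs)


def random_feature_table(rng, n_per_cell=15, effect_feature=None, effect_size=0.0):
    """Feature-table-shaped frame with iid N(0,1) features, optional Expert
    vs Novice mean shift on one feature."""
    rows = []
    tasks = ("Retracting", "Manipulation", "Dissecting", "Pulling", "Coagulation")
    i = 0
    for task in tasks:
        for exp in ("Expert", "Novice"):
            for _ in range(n_per_cell):
                row = {
                    "segment_id": f"s{i}",
                    "case_id": "C01",
                    "task": task,
                    "surgeon_id": "EXP01" if exp == "Expert" else "NOV01",
                    "experience": exp,
                }
                vals = rng.normal(size=len(FEATURE_CATALOG))
                row.update(dict(zip(FEATURE_CATALOG, vals)))
                if effect_feature and exp == "Novice":
                    row[effect_feature] += effect_size
                rows.append(row)
                i += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def tiny_dataset():
    return make_fixture("tiny", seed=7)


@pytest.fixture(scope="session")
def tiny_features(tiny_dataset):
    return extract_all(tiny_dataset.table)


@pytest.fixture(scope="session")
def mid_dataset():
    """50 segments per (task, experience) cell: enough statistical power for
    model-recovery checks while staying desk-scale."""
    from surgforce.synthetic import default_study_spec, generate, with_counts

    return generate(with_counts(default_study_spec(), 50), seed=7)


@pytest.fixture(scope="session")
def mid_features(mid_dataset):
    return extract_all(mid_dataset.table)
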