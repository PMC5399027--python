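import numpy as np
import pandas as pd
import pytest

from metaboeval.containers import PeakTable


def make_table(intensities, groups=None, days=None, sample_types=None, platforms=None):
    """Build a PeakTable from a dict/DataFrame of intensities plus metadata lists."""
    df = pd.DataFrame(intensities)
    n = df.shape[0]
    if df.index.dtype.kind in "iu":
        df.index = [f"S{i}" for i in range(n)]
    groups = groups or ["G1"] * n
    days = days if days is not None else [0] * n
    sample_types = sample_types or ["study"] * n
    meta = pd.DataFrame(
        {
            "group": groups,
            "animal_id": [f"A{i}" for i in range(n)],
            "day": days,
            "sample_type": sample_types,
        },
        index=df.index,
    )
    fmeta = pd.DataFrame(
        {"platform": platforms or ["lcms_pos"] * df.shape[1]}, index=df.columns
    )
    return PeakTable(df, meta, fmeta)


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared across tests (seed fixed)."""
    from metaboeval.synthetic import generate_study

    return generate_study(seed=11)


@pytest.fixture(scope="session")
def preprocessed(study):
    from metaboeval.config import PipelineConfig
    from metaboeval.pipeline import stage_preprocess

    table, phenotypes, truth = study
    clean, reports = stage_preprocess(table, PipelineConfig(seed=11))
    return clean, phenotypes, truth, reports
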