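import numpy as np
import pandas as pd
import pytest

from ric_activity.tables import IntensityTable, SampleMeta


def make_table(values: dict[str, list[float]], metas: list[tuple], proteins=None):
    """Build an IntensityTable from {sample_id: column} and metadata tuples.

    metas entries are (sample_id, fraction, genotype, replicate, batch).
    NaN encodes missing cells.
    """
    samples = [SampleMeta(*m) for m in metas]
    n = len(next(iter(values.values())))
    proteins = proteins or [f"P{i:03d}" for i in range(1, n + 1)]
    frame = pd.DataFrame(values, index=proteins, dtype=float)
    frame = frame[[s.sample_id for s in samples]]
    return IntensityTable(frame, samples)


@pytest.fixture
def paired_metas():
    """Triplicate RIC + WCE design in one batch."""
    metas = []
    for rep in (1, 2, 3):
        metas.append((f"RIC_{rep}", "RIC", "WT", rep, "B1"))
        metas.append((f"WCE_{rep}", "WCE", "WT", rep, "B1"))
    return metas


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def tiny_tsv(tmp_path):
    """3-protein x 2-sample intensity TSV (one empty cell) plus metadata."""
    intensities = tmp_path / "intensities.tsv"
    intensities.write_text(
        "protein_id\tS1\tS2\n"
        "P001\t20.5\t21.0\n"
        "P002\t\t19.0\n"
        "P003\t22.25\t18.5\n"
    )
    meta = tmp_path / "meta.tsv"
    meta.write_text(
        "sample_id\tfraction\tgenotype\treplicate\tbatch\n"
        "S1\tRIC\tWT\t1\tB1\n"
        "S2\tWCE\tWT\t1\tB1\n"
    )
    return intensities, meta
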