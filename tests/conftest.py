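import numpy as np
import pandas as pd
import pytest

from xenoduct.annotation import TranscriptModel, TransporterCatalogue
from xenoduct.mirna import CtMatrix
from xenoduct.rnaseq import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20160426)


@pytest.fixture
def transcripts():
    return [
        TranscriptModel("TX1", "GENEA", "chr1", "+", 9_999, 15_000),
        TranscriptModel("TX2", "GENEB", "chr1", "-", 30_000, 43_424_501),
        TranscriptModel("TX3", "GENEA", "chr1", "+", 10_499, 15_500),
    ]


def _paired_ct(values: dict, donors=("d1", "d2", "d3", "d4", "d5", "d6", "d7")):
    """Build a merged (per-sample) CtMatrix from {feature: {col: ct}} dicts."""
    cols = [f"{d}_{t}" for d in donors for t in ("rifampin", "vehicle")]
    frame = pd.DataFrame(values, index=cols).T
    samples = pd.DataFrame(
        [{"donor": c.split("_")[0], "treatment": c.split("_")[1]} for c in cols],
        index=pd.Index(cols, name="sample"),
    )
    return CtMatrix(values=frame, samples=samples)


@pytest.fixture
def make_merged_ct():
    return _paired_ct


@pytest.fixture
def raw_duplicate_ct():
    """2 donors x 2 treatments x 2 technical replicates, 3 features, with
    one undetected-in-one-replicate and one undetected-in-both case."""
    cols = [
        f"{d}_{t}_r{r}"
        for d in ("d1", "d2")
        for t in ("rifampin", "vehicle")
        for r in (1, 2)
    ]
    values = pd.DataFrame(
        {
            # d1_rif: (34.1, 35.3) -> 34.7 ; d1_veh: one undetected -> 33.0
            "miR-1": [34.1, 35.3, 33.0, np.nan, 30.0, 30.4, 31.0, 31.2],
            # d1_rif both undetected -> 40
            "miR-2": [np.nan, np.nan, 28.0, 28.2, 29.0, 29.2, 28.5, 28.7],
            "U6": [20.0, 20.2, 20.1, 20.3, 20.0, 20.4, 20.2, 20.2],
        },
        index=cols,
    ).T
    samples = pd.DataFrame(
        [
            {
                "donor": c.split("_")[0],
                "treatment": c.split("_")[1],
                "replicate": int(c.rsplit("_r", 1)[1]),
            }
            for c in cols
        ],
        index=pd.Index(cols, name="sample"),
    )
    return CtMatrix(values=values, samples=samples)


@pytest.fixture
def small_catalogue():
    return TransporterCatalogue(
        pd.DataFrame(
            {
                "gene_symbol": ["A1", "A2", "B1", "B2"],
                "family": ["A", "A", "B", "B"],
                "clinically_relevant": [True, False, True, False],
            }
        )
    )


@pytest.fixture
def paired_counts():
    """7 paired donors, 4 genes incl. a zero-in-vehicle gene."""
    donors = [f"d{i}" for i in range(1, 8)]
    cols = [f"{d}_{t}" for d in donors for t in ("rifampin", "vehicle")]
    rows = {
        "A1": [1600 if "rifampin" in c else 800 for c in cols],   # 2-fold up
        "A2": [500] * len(cols),                                   # null
        "B1": [50 if "rifampin" in c else 400 for c in cols],      # 8-fold down
        "B2": [120 if "rifampin" in c else 0 for c in cols],       # zero in vehicle
    }
    counts = pd.DataFrame(rows, index=cols).T
    samples = pd.DataFrame(
        [{"donor": c.split("_")[0], "treatment": c.split("_")[1]} for c in cols],
        index=pd.Index(cols, name="sample"),
    )
    libs = pd.Series(1e6, index=cols)
    return CountMatrix(counts=counts, samples=samples, library_sizes=libs)
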