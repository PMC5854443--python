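import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ssmprone import GeneModel

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def two_exon_plus() -> GeneModel:
    """Exons [100,200) and [300,400) on +: donor boundary 200, acceptor 300."""
    return GeneModel("gp", "chr1", "+", ((100, 200), (300, 400)))


@pytest.fixture
def two_exon_minus() -> GeneModel:
    """Same intervals on -: transcript runs right-to-left."""
    return GeneModel("gm", "chr1", "-", ((100, 200), (300, 400)))


@pytest.fixture
def four_exon_minus() -> GeneModel:
    return GeneModel(
        "g4m", "chr2", "-",
        ((1000, 1100), (1300, 1400), (1600, 1700), (1900, 2000)),
    )


@pytest.fixture
def toy_fraction_counts():
    """One wt/mt pair over all spliceosomal fractions (flat wild type)."""
    def make(mt_sel: dict[str, int]) -> pd.DataFrame:
        rows = []
        for frac in ("E", "A", "B/C", "mRNA", "lariat"):
            rows.append(("wt", frac, 100, 100))
            rows.append(("mt", frac, mt_sel.get(frac, 100), 100))
        return pd.DataFrame(rows, columns=["allele", "fraction", "sel", "inp"])
    return make
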