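import numpy as np
import pandas as pd
import pytest

from isofodder.sources import DietSource, SpacingTable
from isofodder.synthetic import synthetic_haplotype_panel


@pytest.fixture(scope="session")
def sources():
    """Well-separated C3/C4 end-members used across tests."""
    return (
        DietSource("C3_steppe", -24.0, 1.2, 30),
        DietSource("C4_millet", -12.0, 0.4, 10),
    )


@pytest.fixture(scope="session")
def tight_sources():
    """Nearly point-mass sources for boundary-identification checks."""
    return (
        DietSource("C3_steppe", -24.0, 0.3, 30),
        DietSource("C4_millet", -12.0, 0.3, 10),
    )


@pytest.fixture(scope="session")
def spacing():
    return SpacingTable()


@pytest.fixture(scope="session")
def panel():
    return synthetic_haplotype_panel(seed=0)


def make_tooth_frame(positions, d18O, d13C=None, **meta):
    """Assemble a minimal enamel-band table in the analysis schema."""
    positions = np.asarray(positions, dtype=float)
    if d13C is None:
        d13C = np.full_like(positions, -9.9)
    base = {
        "tooth_id": meta.get("tooth_id", "T001"),
        "specimen": meta.get("specimen", "S001"),
        "taxon": meta.get("taxon", "Ovis aries"),
        "site": meta.get("site", "TestSite"),
        "period": meta.get("period", "P1"),
        "molar": meta.get("molar", "M2"),
    }
    return pd.DataFrame(
        {**base, "position_mm": positions, "d13C_apa": d13C, "d18O_apa": d18O}
    )
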