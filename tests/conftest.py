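import numpy as np
import pandas as pd
import pytest

from kinomescreen import (
    GuideLibrary,
    SampleSheet,
    ScreenSimConfig,
    ScRNASimConfig,
    simulate_screen,
    simulate_scrna,
)


@pytest.fixture(scope="session")
def tiny_library() -> GuideLibrary:
    """Two targeting genes x 2 guides + 2 NTCs with short-but-valid protospacers."""
    rows = [
        ("KIN1_g1", "KIN1", "A" * 19 + "C", False),
        ("KIN1_g2", "KIN1", "A" * 19 + "G", False),
        ("KIN2_g1", "KIN2", "C" * 19 + "A", False),
        ("KIN2_g2", "KIN2", "C" * 19 + "G", False),
        ("NTC_g1", "NTC", "G" * 19 + "A", True),
        ("NTC_g2", "NTC", "G" * 19 + "C", True),
    ]
    return GuideLibrary(pd.DataFrame(rows, columns=["guide_id", "gene", "protospacer", "is_ntc"]))


@pytest.fixture(scope="session")
def tiny_sheet() -> SampleSheet:
    rows = [
        ("WT_late_m1", "WT", "late", "m1", "AAAAACCC"),
        ("WT_late_m2", "WT", "late", "m2", "AAAAAGGG"),
        ("CD8KO_late_m1", "CD8KO", "late", "m3", "CCCCCAAA"),
        ("CD8KO_late_m2", "CD8KO", "late", "m4", "CCCCCGGG"),
    ]
    return SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "genotype", "stage", "mouse_id", "barcode"])
    )


@pytest.fixture(scope="session")
def planted_screen():
    """Default study-condition screen with one planted WT-depleted gene."""
    cfg = ScreenSimConfig(
        seed=20240901,
        n_genes=100,
        guides_per_gene=4,
        n_ntc=20,
        selection={"G0001": (-1.0, 0.0)},
    )
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def coupled_scrna():
    """Default coupled single-cell simulation (planted low-sample signature)."""
    return simulate_scrna(ScRNASimConfig(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
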