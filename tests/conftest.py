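import numpy as np
import pandas as pd
import pytest

from evmeth.preprocess import PairedDesign, SamplePair

# Hand-enumerable single-group fixture: treated/control beta pairs chosen so
# the npCV ranking, the Q3 cut and the delta-beta filter can all be verified
# on paper.  npCV (MAD/median) values, in row order:
#   0.4/1.4, 0.4/0.6, 0.05/1.05, 0, 0.02/1.02, 0.02/0.98, 0.05/0.95, 0.05/0.95
EIGHT_PROBE_PAIRS = [
    ("p1", 0.90, 0.50),
    ("p2", 0.10, 0.50),
    ("p3", 0.55, 0.50),
    ("p4", 0.50, 0.50),
    ("p5", 0.52, 0.50),
    ("p6", 0.48, 0.50),
    ("p7", 0.45, 0.50),
    ("p8", 0.50, 0.45),
]


@pytest.fixture
def eight_probe_beta() -> pd.DataFrame:
    probes, treated, control = zip(*EIGHT_PROBE_PAIRS)
    return pd.DataFrame(
        {"EVs_a": treated, "Ctrl_a": control},
        index=pd.Index(probes, name="probe_id"),
        dtype=float,
    )


@pytest.fixture
def one_group_design() -> PairedDesign:
    return PairedDesign(groups=(SamplePair("a", "EVs_a", "Ctrl_a"),))


def toy_manifest(rows: dict[str, tuple[str, str, str]]) -> pd.DataFrame:
    """Manifest from {probe: (chromosome, gene_region, island_relation)}."""
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["chromosome", "gene_region", "island_relation"]
    ).rename_axis("probe_id")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
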