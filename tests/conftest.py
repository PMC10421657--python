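import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ighrep import Cohort, PhyloTree, RepertoireSample, SyntheticConfig, simulate_cohort


def make_sample(sample_id, group, isotype, rows):
    """rows: list of (cdr3_aa, v_call, j_call, count). Frequencies derived."""
    df = pd.DataFrame(
        [
            {
                "cdr3_aa": aa, "cdr3_nt": None, "v_call": v, "d_call": None,
                "j_call": j, "c_call": isotype, "count": c, "frequency": 0.0,
            }
            for aa, v, j, c in rows
        ]
    )
    df["frequency"] = df["count"] / df["count"].sum()
    return RepertoireSample(sample_id, group, isotype, df)


@pytest.fixture
def toy_tree():
    return PhyloTree.from_newick("((A:1,B:2):0.5,C:3);")


@pytest.fixture
def tiny_cohort():
    """Two patients + two endemic controls, IGHG, hand-sized repertoires."""
    samples = [
        make_sample("NT1", "nontreated", "IGHG",
                    [("CARDW", "IGHV3-30", "IGHJ4", 6),
                     ("CAKDW", "IGHV3-23", "IGHJ4", 3),
                     ("CYYYW", "IGHV1-69", "IGHJ6", 1)]),
        make_sample("NT2", "nontreated", "IGHG",
                    [("CARDW", "IGHV3-30", "IGHJ4", 5),
                     ("CWWWW", "IGHV5-51", "IGHJ2", 5)]),
        make_sample("EC1", "endemic_control", "IGHG",
                    [("CARDY", "IGHV3-23", "IGHJ4", 4),
                     ("CHHHW", "IGHV1-69", "IGHJ1", 6)]),
        make_sample("EC2", "endemic_control", "IGHG",
                    [("CARDW", "IGHV3-30", "IGHJ4", 2),
                     ("CMMMW", "IGHV4-34", "IGHJ3", 8)]),
    ]
    meta = {"NT1": "nontreated", "NT2": "nontreated",
            "EC1": "endemic_control", "EC2": "endemic_control"}
    return Cohort(samples, meta)


@pytest.fixture(scope="session")
def small_synthetic():
    """Default study structure at ~2% richness (fast but non-trivial)."""
    return simulate_cohort(SyntheticConfig(seed=11).scaled_richness(0.02))
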