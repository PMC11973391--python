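import numpy as np
import pytest

from ystrkit.io import AlleleCall, build_table
from ystrkit.loci import PANEL_Y23
from ystrkit.simulate import SimulationConfig, simulate_tribe


def make_record(sample_id, clan="Kerderi", haplogroup="R1a1a", tribe="Zhetiru",
                overrides=None):
    """One sample record with mid-range alleles at every panel locus."""
    rec = {"id": sample_id, "tribe": tribe, "clan": clan,
           "haplogroup": haplogroup}
    for d in PANEL_Y23:
        mid = int((d.min_repeats + d.max_repeats) // 2)
        if d.multi_copy:
            rec[d.name] = AlleleCall.duplicated(mid, mid + 2)
        else:
            rec[d.name] = AlleleCall.value(mid)
    if overrides:
        rec.update(overrides)
    return rec


@pytest.fixture
def tiny_table():
    """Three samples over the full 23-locus panel, with one null, one
    duplication and one microvariant."""
    recs = [
        make_record("K001"),
        make_record("K002", clan="Kereit", haplogroup="N1a2",
                    overrides={"DYS448": AlleleCall.null(),
                               "DYS458": AlleleCall.value(17.2)}),
        make_record("K003", clan="Tama", haplogroup="C2a1a3",
                    overrides={"DYS19": AlleleCall.duplicated(15, 14)}),
    ]
    return build_table(recs)


@pytest.fixture(scope="session")
def sim_tribe():
    """Default-condition simulated tribe: 7 clans at the study's sample
    sizes, one founder each, T = 1000 y."""
    return simulate_tribe(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_tribe():
    """Small 3-clan simulation for fast end-to-end tests."""
    cfg = SimulationConfig(seed=11, n_clans=3, samples_per_clan=(8, 9, 10))
    return simulate_tribe(cfg)


def rng(seed=0):
    return np.random.default_rng(seed)
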