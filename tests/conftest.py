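import numpy as np
import pytest

from panmosaic import synthetic_panel as sp
from panmosaic.pipeline import PanelAnalysis


def small_config(seed=3):
    """1-Mb two-chromosome panel: fast enough for unit tests, large enough
    to carry every event class."""
    return sp.PanelConfig(
        genome_length=1_000_000, ancestral_te_count=10, te_insertion_rate=3,
        knob_seed_sites=3, gene_count=50, gene_gain_rate=2,
        ibd_tracts=[sp.IbdTractSpec(("fl1", "fl2", "fl3", "fl4"), 90_000),
                    sp.IbdTractSpec(("fl1", "dt1"), 70_000),
                    sp.IbdTractSpec(("dt1", "dt2"), 60_000)],
        rng_seed=seed)


@pytest.fixture(scope="session")
def small_panel():
    return sp.simulate_panel(small_config())


@pytest.fixture(scope="session")
def small_analysis(small_panel):
    panel, truth = small_panel
    return PanelAnalysis(panel, truth, reference="fl1", both_strands=False)


@pytest.fixture(scope="session")
def default_analysis():
    """The default study conditions: 6 lines, 2x5 Mb, 20 IBD tracts."""
    panel, truth = sp.simulate_panel(sp.PanelConfig(rng_seed=0))
    return PanelAnalysis(panel, truth, reference="fl1", both_strands=False)


@pytest.fixture(scope="session")
def subs_only_analysis():
    """Substitution-only panel (no TEs/knobs/IBD): the clean regime for
    SNP-recovery checks."""
    cfg = sp.PanelConfig(genome_length=4_000_000, ancestral_te_count=0,
                         te_insertion_rate=0, knob_seed_sites=0,
                         gene_count=0, gene_gain_rate=0, ibd_tracts=[],
                         rng_seed=21)
    panel, truth = sp.simulate_panel(cfg)
    return PanelAnalysis(panel, truth, reference="fl1", both_strands=False)
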