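import numpy as np
import pandas as pd
import pytest

from msy_seg.pipeline import analyze_panel, demo_config
from msy_seg.simulate import simulate_panel


@pytest.fixture(scope="session")
def demo_panel():
    """The packaged demo panel (fixed seed), simulated once per session."""
    return simulate_panel(demo_config().simulation)


@pytest.fixture(scope="session")
def demo_summary(demo_panel):
    """Full analysis of the demo panel (no file I/O)."""
    return analyze_panel(demo_panel, demo_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(20160203)


def make_table(rows, samples):
    """Hand-build a VariantTable from (chrom, pos, ref, alt, [(r, a), ...]) rows."""
    from msy_seg.segregation import VariantTable

    sites = pd.DataFrame(
        [(r[0], r[1], r[2], r[3]) for r in rows], columns=["chrom", "pos", "ref", "alt"]
    )
    refs = pd.DataFrame([[c[0] for c in r[4]] for r in rows], columns=samples)
    alts = pd.DataFrame([[c[1] for c in r[4]] for r in rows], columns=samples)
    return VariantTable(sites, refs, alts)
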