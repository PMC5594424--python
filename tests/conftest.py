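import numpy as np
import pytest

from twosample_mr.harmonize import HarmonizedPair, InstrumentSet


def make_instrument_set(gammas, se_gammas, Gammas, se_Gammas, **kw) -> InstrumentSet:
    pairs = [
        HarmonizedPair(
            snp_id=f"rs{i + 1:04d}",
            gamma=float(g),
            se_gamma=float(sg),
            Gamma=float(G),
            se_Gamma=float(sG),
        )
        for i, (g, sg, G, sG) in enumerate(zip(gammas, se_gammas, Gammas, se_Gammas))
    ]
    defaults = dict(exposure_name="exposure", outcome_name="outcome")
    defaults.update(kw)
    return InstrumentSet(pairs=pairs, **defaults)


@pytest.fixture
def toy_s4() -> InstrumentSet:
    """Four-SNP worked example: three SNPs with Wald ratio 0.5, one with 1.5.

    Exposure SEs 0.01, outcome SEs 0.01 throughout, so IVW weights differ
    (gamma^2/se^2) but the Egger regression weights (1/se_Gamma^2) are equal.
    """
    return make_instrument_set(
        gammas=[0.10, 0.20, 0.15, 0.10],
        se_gammas=[0.01] * 4,
        Gammas=[0.050, 0.100, 0.075, 0.150],
        se_Gammas=[0.01] * 4,
    )


@pytest.fixture
def homogeneous_set() -> InstrumentSet:
    """Every Wald ratio exactly 0.5; zero heterogeneity."""
    g = np.array([0.05, 0.10, 0.20])
    return make_instrument_set(g, [0.01] * 3, 0.5 * g, [0.02] * 3)


def random_instrument_set(rng: np.random.Generator, L: int) -> InstrumentSet:
    g = rng.uniform(0.02, 0.3, L)
    seg = rng.uniform(0.005, 0.05, L)
    G = rng.normal(0.0, 0.1, L)
    seG = rng.uniform(0.005, 0.05, L)
    return make_instrument_set(g, seg, G, seG)
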