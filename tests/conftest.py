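import warnings

import numpy as np
import pandas as pd
import pytest

from methexpr import (
    DegThresholds,
    DmpThresholds,
    IntegrationParams,
    SimConfig,
    call_degs,
    call_dmps,
    correlate_dmps,
    estimate_size_factors,
    filter_low_expression,
    filter_probes,
    overlap_with_degs,
    simulate,
)

# the Welch t on probes that are nearly constant in both groups triggers a
# harmless precision warning inside scipy
warnings.filterwarnings("ignore", message="Precision loss occurred")


@pytest.fixture(scope="session")
def default_sim():
    """Default study conditions: 32+5 samples, planted DMPs/DEGs/couplings."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def null_sim():
    """Nothing planted: no DMPs, no DEGs, coupling disabled."""
    return simulate(
        SimConfig(
            seed=5,
            frac_dmp=0.0,
            frac_deg=0.0,
            frac_coupled_among_dmp=0.0,
            coupling_strength=0.0,
        )
    )


@pytest.fixture(scope="session")
def default_calls(default_sim):
    """Full pipeline outputs on the default simulation."""
    ds = default_sim
    dmp_th = DmpThresholds()
    filtered = filter_probes(ds.meth, ds.annotation, dmp_th)
    dmps = call_dmps(filtered, ds.annotation, dmp_th)
    deg_th = DegThresholds()
    expr = estimate_size_factors(filter_low_expression(ds.expr, deg_th))
    degs = call_degs(expr, deg_th)
    corr = correlate_dmps(dmps, filtered, expr, ds.annotation, IntegrationParams())
    quadrants = overlap_with_degs(corr, dmps, degs)
    return {
        "filtered": filtered,
        "dmps": dmps,
        "expr": expr,
        "degs": degs,
        "corr": corr,
        "quadrants": quadrants,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_sheet(n_tumor, n_normal):
    from methexpr import SampleSheet

    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": [f"T{i}" for i in range(n_tumor)]
                + [f"N{i}" for i in range(n_normal)],
                "group": ["tumor"] * n_tumor + ["normal"] * n_normal,
            }
        )
    )
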