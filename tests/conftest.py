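import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

STRAINS = ("HMS174", "RV308", "BL21")


@pytest.fixture(scope="session")
def samples():
    """Sample id -> strain for 3 strains x 3 replicate cultivations."""
    return {f"{s}_r{i + 1}": s for s in STRAINS for i in range(3)}


@pytest.fixture(scope="session")
def default_array_analysis(samples):
    """Full default-design microarray simulation + DE analysis (shared)."""
    from fermscope import transcriptome as tr
    from fermscope.synthetic_data import (
        make_array_truth,
        reference_design,
        simulate_microarray,
    )

    truth = make_array_truth(seed=11)
    scans = simulate_microarray(truth, reference_design(samples))
    universe = tr.intersect_platforms(
        truth.platform_genes["K12"], truth.platform_genes["B"]
    )
    results, flags, venn = tr.analyze_scans(scans, samples, universe=universe)
    return {
        "truth": truth,
        "universe": universe,
        "results": results,
        "flags": flags,
        "venn": venn,
    }


@pytest.fixture()
def exponential_series():
    """Exact exponential growth cdm(t) = 0.4 exp(0.5 t)."""
    from fermscope.process_metrics import PROCESS_COLUMNS, ProcessTimeSeries

    t = np.linspace(0.0, 6.0, 25)
    frame = pd.DataFrame(0.0, index=range(len(t)), columns=PROCESS_COLUMNS)
    frame["time_h"] = t
    frame["cdm_g_per_L"] = 0.4 * np.exp(0.5 * t)
    frame["glucose_g_per_L"] = 40.0
    return ProcessTimeSeries(frame)
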