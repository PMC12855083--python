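import numpy as np
import pytest

from fibrocyto.design import AcquisitionModel, build_default_design
from fibrocyto.simulate import simulate_sample


@pytest.fixture(scope="session")
def design():
    return build_default_design()


@pytest.fixture(scope="session")
def small_acq():
    return AcquisitionModel(target_events=20_000)


@pytest.fixture(scope="session")
def ra_sample(design, small_acq):
    """One default RA whole-blood acquisition at reduced bulk size."""
    return simulate_sample(design, small_acq, group="RA", seed=11, sample_id="RA-fix")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


def patient_truth(n_detectable: int, n_without: int):
    """Minimal truth scaffold: patient samples with/without CDH11+ fibroblasts,
    for exercising the NPX arm without simulating event tables."""
    import pandas as pd

    from fibrocyto.simulate import SyntheticTruth

    ids = [f"P{i:02d}" for i in range(n_detectable + n_without)]
    samples = pd.DataFrame({"sample_id": ids, "group": "RA", "tissue": "blood",
                            "timepoint": "baseline", "effective_volume_ml": 0.27})
    rows = [
        {"sample_id": s, "event_index": 0, "cell_class": "fibroblast",
         "phenotype_code": 2, "CDH11": True, "PDPN": True, "CD34": False,
         "CD90": False, "Notch3": False, "HLA-DR": False,
         "CCR4": False, "CCR6": True, "CCR7": False, "CXCR3": False, "CXCR5": False}
        for s in ids[:n_detectable]
    ]
    return SyntheticTruth(samples=samples, event_labels={}, records=pd.DataFrame(rows))
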