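import numpy as np
import pytest

from netscope.cohort import BALFCytology, HorseRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(
    neut=1.0,
    eos=0.0,
    mast=0.5,
    labored=False,
    auscultation=False,
    group="unknown",
    subject_id="X1",
    **kwargs,
):
    """Record with a cytology balanced to sum to 100."""
    rest = 100.0 - neut - eos - mast
    cyt = BALFCytology(
        macrophages_pct=rest / 2,
        lymphocytes_pct=rest / 2,
        neutrophils_pct=neut,
        eosinophils_pct=eos,
        mast_cells_pct=mast,
    )
    return HorseRecord(
        subject_id=subject_id,
        group_label=group,
        labored_breathing_at_rest=labored,
        abnormal_lung_auscultation=auscultation,
        cytology=cyt,
        **kwargs,
    )
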