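import pytest
from hypothesis import settings

from pcbrisk import MeasurementRecord
from pcbrisk.refdata import RESIDUE_SUMMARY_LW

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def survey_mean_records() -> list[MeasurementRecord]:
    """One pseudo-bird per (species, tissue) carrying the published
    lipid-weight congener means."""
    return [
        MeasurementRecord(
            sample_id=f"{species}_{tissue}_mean",
            species=species,
            tissue=tissue,
            congener=congener,
            concentration=mean,
            basis="lipid_weight",
        )
        for (species, tissue, congener), (mean, _sd) in sorted(
            RESIDUE_SUMMARY_LW.items()
        )
    ]
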