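import pytest
from hypothesis import settings

from phosphoquad.model import Arm, Axis, ChannelDesign, PhosphopeptideRecord, PipelineParameters

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

TREATED = ("126", "127", "128")
CONTROL = ("129", "130", "131")


def make_design(experiment_id="ATRI_1", axis=Axis.ATRI, replicate_id="r1"):
    channel_to_arm = {c: Arm.TREATED for c in TREATED}
    channel_to_arm.update({c: Arm.CONTROL for c in CONTROL})
    return ChannelDesign(
        experiment_id=experiment_id,
        perturbation_axis=axis,
        replicate_id=replicate_id,
        channel_to_arm=channel_to_arm,
    )


def make_record(
    peptide="AASQPK",
    protein="P1",
    start=1,
    offsets=(3,),
    probs=(0.99,),
    treated=(100.0, 100.0, 100.0),
    control=(100.0, 100.0, 100.0),
    experiment_id="ATRI_1",
    replicate_id="r1",
):
    intensities = dict(zip(TREATED, treated))
    intensities.update(dict(zip(CONTROL, control)))
    return PhosphopeptideRecord(
        peptide_sequence=peptide,
        protein_accession=protein,
        peptide_start=start,
        site_offsets=list(offsets),
        site_probabilities=list(probs),
        reporter_intensities=intensities,
        experiment_id=experiment_id,
        replicate_id=replicate_id,
    )


@pytest.fixture
def design():
    return make_design()


@pytest.fixture
def params():
    return PipelineParameters()
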