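import pytest
from hypothesis import HealthCheck, settings

from cladescan.alignment_io import LabeledAlignment
from cladescan.simulate import simulate_survey_bundle

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_alignment() -> LabeledAlignment:
    """Six sequences, two groups, with gaps and a clear signature column.

    Column 3 is fixed A in the in-group and fixed G in the out-group;
    column 5 is gapped in 4 of 6 sequences (gap fraction 2/3 > 0.5).
    """
    ids = ["in1", "in2", "in3", "out1", "out2", "out3"]
    seqs = [
        "ACAGU",
        "ACAG-",
        "AUAG-",
        "ACGG-",
        "AUGGU",
        "-CGG-",
    ]
    groups = {i: ("IN" if i.startswith("in") else "OUT") for i in ids}
    return LabeledAlignment(ids, seqs, groups)


@pytest.fixture(scope="session")
def survey_bundle(tmp_path_factory):
    """The seeded synthetic two-clade survey fixture used across modules."""
    outdir = tmp_path_factory.mktemp("survey")
    return simulate_survey_bundle(outdir, seed=42)
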