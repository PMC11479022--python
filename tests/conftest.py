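import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import germeval as g

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    return g.default_scheme()


@pytest.fixture(scope="session")
def survey_table(scheme):
    """A fixed 288-accession synthetic collection at the default conditions."""
    return g.sample_accessions(g.SyntheticConfig(n_accessions=288, seed=42))


@pytest.fixture(scope="session")
def survey_matrix(survey_table, scheme):
    return g.encode_indicators(survey_table, scheme)


@pytest.fixture
def tiny_table(scheme):
    """Three hand-written accessions covering both trait kinds."""
    rows = {
        "Height of the plant": ["2-3 m", ">3 m", "<2 m"],
        "Number of stems per plant": ["<15", "16-30", ">45"],
        "Stem color": ["Light green", "Green", "Yellow"],
        "Rhizome color": ["White", "Light purple", "Light green"],
        "Shape of the leaf": ["Oblong", "Oblong", "Lanceolate"],
        "Pubescence of the leaf": ["Glabra", "Dense", "Spaced"],
        "Panicle type": ["Semi-erect", "Semi-erect", "Erect"],
        "Number of panicles per stem": ["2", "1", ">3"],
        "Number of panicles per plant": ["<10", "21-30", ">31"],
        "Panicle length": ["<50 cm", "51-75 cm", ">100 cm"],
        "Number of clusters per panicle": ["<20", "20-30", "30-40"],
        "Cluster internodal length": [1.5, 2.8, 4.0],
        "Panicle branching": ["Absence", "Absence", "Presence"],
        "Panicle branching pattern": ["Not branching pattern",
                                      "Not branching pattern", "Proximal"],
        "Number of capsules per cluster": [8, 12, 20],
        "Capsule form": ["Ovoid", "Globose", "Ellipsoid"],
        "Capsule color": ["Green", "Light green", "Yellow"],
    }
    frame = pd.DataFrame(rows, index=["GTM-A", "GTM-B", "GTM-C"])
    frame.index.name = "accession_id"
    return g.validate_table(frame, scheme)
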