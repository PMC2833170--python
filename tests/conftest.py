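import numpy as np
import pytest

from crthedge import Corpus, Citation, GoldLabels, Identifiability, LabelRecord

# Gold-standard pool structure: yearly CRT totals and clearly identified
# counts, with the non-clear mass split 46 UNIT / 38 NONE overall.
TREND_COUNTS = [
    (2000, 4, 14),
    (2001, 1, 16),
    (2002, 1, 9),
    (2003, 10, 19),
    (2004, 8, 15),
    (2005, 13, 20),
    (2006, 30, 52),
    (2007, 11, 17),
]
N_GOLD_CRT = 162
N_GOLD_TOTAL = 25707
N_UNIT = 46
N_NONE = 38


def build_gold_labels() -> GoldLabels:
    """GoldLabels mirroring the gold-standard pool's class structure."""
    labels = GoldLabels()
    uid = 20000001
    unit_left = N_UNIT
    for year, clear, total in TREND_COUNTS:
        for j in range(total):
            if j < clear:
                cls = Identifiability.CLEAR
            elif unit_left > 0:
                cls = Identifiability.UNIT
                unit_left -= 1
            else:
                cls = Identifiability.NONE
            labels.add(f"{uid:08d}", LabelRecord(True, cls, year))
            uid += 1
    return labels


@pytest.fixture(scope="session")
def gold_labels() -> GoldLabels:
    return build_gold_labels()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20100216)


@pytest.fixture
def tiny_corpus() -> Corpus:
    return Corpus(
        [
            Citation(
                uid="11111111",
                title="A cluster randomised controlled trial of hand hygiene",
                abstract="Wards were randomised to feedback or usual practice.",
                mesh_terms=["Humans", "*Cluster Analysis/methods"],
                pub_types=["Journal Article", "Randomized Controlled Trial"],
                journal="Test Journal",
                year=2005,
            ),
            Citation(
                uid="22222222",
                title="Metformin for type 2 diabetes",
                abstract="Patients were randomly assigned to metformin or placebo.",
                mesh_terms=["Humans"],
                pub_types=["Journal Article", "Randomized Controlled Trial"],
                journal="Test Journal",
                year=2004,
            ),
            Citation(
                uid="33333333",
                title="Outcomes of cataract surgery",
                abstract="A retrospective review of consecutive cases.",
                mesh_terms=["Humans", "Program Evaluation"],
                pub_types=["Journal Article"],
                journal="Other Journal",
                year=2003,
            ),
        ]
    )
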