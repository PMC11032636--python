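import numpy as np
import pytest

from formtyp.synthetic_data import SyntheticConfig, generate_study

TINY_DICT = """\
;;; tiny fixture lexicon
TALL  T AO1 L
TEENSY  T IY1 N Z IY0
PILL  P IH1 L
ELEPHANT  EH1 L AH0 F AH0 N T
BANANA  B AH0 N AE1 N AH0
BANANA(2)  B AH0 N AA1 N AH0
GIRAFFE  JH ER0 AE1 F
TRUTH  T R UW1 TH
HUMBLE  HH AH1 M B AH0 L
OYSTER  OY1 S T ER0
WOLF  W UH1 L F
YACHT  Y AA1 T
"""


@pytest.fixture()
def tiny_dict_path(tmp_path):
    path = tmp_path / "tiny.dict"
    path.write_text(TINY_DICT)
    return path


@pytest.fixture(scope="session")
def small_study():
    """One seeded synthetic study, shared read-only across tests."""
    return generate_study(SyntheticConfig(n_words=400, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20250930)
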