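import warnings

import pytest

warnings.filterwarnings("ignore", category=DeprecationWarning)

from ighrep.fixtures import load_expanded_clone_table
from ighrep.hcdr3 import canonicalize_clones
from ighrep.pipeline import annotate_and_correct
from ighrep.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def table1():
    """Transcribed expanded-clone table (per-tissue observations)."""
    return load_expanded_clone_table()


@pytest.fixture(scope="session")
def canonical(table1):
    return canonicalize_clones(table1)


@pytest.fixture(scope="session")
def expanded(canonical):
    return [c for c in canonical if c.is_expanded]


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic cohort with stereotypes and F1 recipients."""
    cfg = SimConfig(seed=11, n_mice_per_genotype=5, n_stereotype_mice=3,
                    n_f1_recipients=2)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def annotated_cohort(cohort):
    """(rearrangement frame, ssp table, annotated pairs) for the session cohort."""
    return annotate_and_correct(cohort.records, cohort.base_germline)
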