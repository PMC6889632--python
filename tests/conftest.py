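import numpy as np
import pytest

from paleopgls.specimens import SpecimenRecord
from paleopgls.trees import parse_newick

# 10-tip non-ultrametric fossil tree used by the cross-implementation
# oracle tests (frozen alongside independently computed GLS results).
ORACLE_NEWICK = (
    "((((sp004:7.733387957301261,((sp005:0.14822528279933778,"
    "((sp008:1.0771120009093238,(sp010:30.81789345684409,"
    "sp009:0.08130675542226129):2.352003595536999):20.2713613678088,"
    "sp007:2.264077315051914):3.869805224553204):8.40855065598226,"
    "sp003:0.6061138502546015):0.39429039442622127):6.839557272111591,"
    "sp006:16.787239595472798):15.741293462898454,"
    "sp001:3.724770553092693):9.172157691824058,sp002:25.09405706958869);"
)

ORACLE_DATA = {
    # species: (log_fl, log_hl)
    "sp004": (1.9702373160, 1.8937753611),
    "sp005": (2.0817468877, 1.9204403721),
    "sp008": (2.0915952902, 2.0044996143),
    "sp010": (1.7410907757, 1.5813215794),
    "sp009": (2.0878936320, 1.9431497819),
    "sp007": (2.0487015307, 1.8508283875),
    "sp003": (1.9910280800, 1.8369686132),
    "sp006": (2.0349071054, 1.9378682126),
    "sp001": (2.0875417630, 1.8126884972),
    "sp002": (2.1266315080, 1.9393766641),
}


@pytest.fixture
def oracle_tree():
    return parse_newick(ORACLE_NEWICK)


@pytest.fixture
def oracle_xy(oracle_tree):
    order = [leaf.taxon.label for leaf in oracle_tree.leaf_node_iter()]
    x = np.array([ORACLE_DATA[s][0] for s in order])
    y = np.array([ORACLE_DATA[s][1] for s in order])
    return x, y


def make_record(specimen_id="s1", species="Alpha one", genus="Alpha",
                clades=frozenset(), fl=100.0, hl=80.0, lo=70.0, hi=75.0,
                status="adult"):
    return SpecimenRecord(
        specimen_id=specimen_id, species=species, genus=genus,
        clade_labels=frozenset(clades), fl_mm=fl, hl_mm=hl,
        age_min_ma=lo, age_max_ma=hi, onto_status=status,
    )


@pytest.fixture
def record_factory():
    return make_record


def random_fossil_tree(rng, n_tips=8):
    """Small random fossil tree for property tests (not the unit under test
    in the tests that use it)."""
    from paleopgls.simulate import SimulationConfig, simulate_birth_death_tree

    cfg = SimulationConfig(n_species=n_tips, birth_rate=0.12,
                           death_rate=0.05, seed=0)
    return simulate_birth_death_tree(cfg, rng)


@pytest.fixture
def fossil_tree_factory():
    return random_fossil_tree
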