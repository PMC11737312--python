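import math

import dendropy
import numpy as np
import pytest

from parrotbite import biomech


@pytest.fixture
def hand_tree():
    """((A:1,B:1):1,C:2); — ultrametric, depth 2, built by hand."""
    return dendropy.Tree.get(
        data="((A:1,B:1):1,C:2);", schema="newick", preserve_underscores=True
    )


@pytest.fixture
def five_tip_tree():
    """A fixed 5-tip ultrametric tree with unequal internal structure."""
    return dendropy.Tree.get(
        data="(((A:1,B:1):1.5,C:2.5):0.5,(D:2,E:2):1);",
        schema="newick",
        preserve_underscores=True,
    )


def make_muscle(
    name="EM",
    role=biomech.ADDUCTOR,
    wet_mass=1.06,
    surface_area=100.0,
    pennation_angle=0.0,
    loa_angle=math.pi / 2,
    moment_arms=(10.0, 10.0, 10.0),
    **kw,
):
    return biomech.MuscleObservation(
        name=name,
        role=role,
        wet_mass=wet_mass,
        surface_area=surface_area,
        pennation_angle=pennation_angle,
        loa_angle=loa_angle,
        moment_arms=moment_arms,
        **kw,
    )


def make_specimen(muscles, out_lever=50.0, physical_ref=30.0, digital_ref=30.0,
                  constants=None):
    return biomech.SpecimenRecord(
        specimen_id="spec01",
        species="Testus_parrotus",
        geometry=biomech.JawGeometry(
            out_lever=out_lever,
            physical_ref_distance=physical_ref,
            digital_ref_distance=digital_ref,
        ),
        muscles=tuple(muscles),
        constants=constants or biomech.ModelConstants(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240924)
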