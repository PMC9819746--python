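import numpy as np
import pytest

from ly6orient.synthetic import (
    ObservableProcess, SyntheticSpec, default_groups_config,
    generate_trajectory, three_finger_template,
)


@pytest.fixture(scope="session")
def template():
    return three_finger_template()


@pytest.fixture(scope="session")
def groups():
    return default_groups_config()


@pytest.fixture(scope="session")
def small_traj():
    """60-frame default-conditions trajectory with ground truth."""
    spec = SyntheticSpec(n_frames=60, seed=7)
    return generate_trajectory(spec)


@pytest.fixture(scope="session")
def calm_spec():
    """Elevated, low-noise pose used for contact-planting fixtures: contact
    presence is then controlled solely by the planted lipid."""
    def make(n_frames=100, seed=5):
        return SyntheticSpec(
            n_frames=n_frames, seed=seed,
            z_process=ObservableProcess(means=[2.2], sds=[0.05]),
            alpha_process=ObservableProcess(means=[-31.5], sds=[8.7]),
        )
    return make


def measure_pose(template, coords):
    """Independent measurement of a posed template: group COMs -> A, B,
    sheet-normal F -> (Z above z=0, alpha, beta)."""
    from ly6orient.orientation import (
        ReferenceVectors, rotation_angle, tilt_angle,
    )

    m = template.masses
    resnums = np.asarray(template.resnums)

    def gcom(res):
        idx = np.flatnonzero(np.isin(resnums, res))
        return np.average(coords[idx], axis=0, weights=m[idx])

    A = gcom(template.loop2_tip) - gcom(template.head)
    B = gcom(template.loop1_tip) - gcom(template.loop3_tip)
    F = np.cross(A, B)
    F = F / np.linalg.norm(F)
    v = ReferenceVectors(A=A, B=B, F=F)
    Z = float(np.average(coords[:, 2], weights=m))
    return Z, tilt_angle(v), rotation_angle(v)
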