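import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def templates():
    from shellcargo.state import default_templates
    return default_templates()


@pytest.fixture(scope="session")
def blueprint():
    from shellcargo.geometry import build_shell_blueprint
    return build_shell_blueprint()


@pytest.fixture(scope="session")
def table():
    from shellcargo.interactions import InteractionTable
    return InteractionTable(eps_ss=2.0, eps_sc=6.0, eps_rr=1.3, eps_gg=1.3,
                            eps_rg=1.3)


@pytest.fixture(scope="session")
def random_soup(table):
    """Small random system of bodies + cargo used by force/energy checks."""
    from shellcargo.dynamics import init_random
    return init_random(4, 6, 15, 15, box=12.0, seed=11, table=table)


def rigid_perturb(state, rng, scale):
    """Random rigid perturbation of every body (and cargo) by <= scale."""
    from scipy.spatial.transform import Rotation as Rot
    st = state.copy()
    st.body_pos += rng.uniform(-scale, scale, st.body_pos.shape)
    if st.n_bodies:
        rv = rng.uniform(-scale, scale, (st.n_bodies, 3))
        q = st.body_quat[:, [1, 2, 3, 0]]
        st.body_quat = (Rot.from_rotvec(rv) * Rot.from_quat(q)
                        ).as_quat()[:, [3, 0, 1, 2]]
    if st.n_cargo:
        st.cargo_pos += rng.uniform(-scale, scale, st.cargo_pos.shape)
    return st
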