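import numpy as np
import pytest
from hypothesis import settings

import bundledissect as bd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec() -> bd.PhantomSpec:
    """Desk-scale phantom conditions shared across tests."""
    return bd.PhantomSpec(n_streamlines=600, seed=11)


@pytest.fixture(scope="session")
def subject(spec) -> bd.PhantomSubject:
    return bd.make_subject(spec, seed=11)


@pytest.fixture(scope="session")
def labels(spec) -> bd.LabelVolume:
    return bd.make_phantom_parcellation(spec)


@pytest.fixture(scope="session")
def selected(subject):
    return bd.select_slmfb(subject.tractogram)


def brute_force_visits_sphere(points, center, radius, ds=0.05):
    """Oracle: dense resampling + vertex distances (no segment projection)."""
    p = bd.subdivide_polyline(np.asarray(points, float), ds)
    return bool((np.linalg.norm(p - np.asarray(center), axis=1) <= radius).any())


def brute_force_select(points, criteria=None):
    """Independent per-streamline evaluation of the three selection rules.

    Returns the hemisphere the streamline belongs to, or None.
    """
    c = criteria or bd.SelectionCriteria()
    p = np.asarray(points, float)
    x = p[:, 0]
    if np.all(x > 0):
        hemi = "right"
    elif np.all(x < 0):
        hemi = "left"
    else:
        return None
    e0, e1 = p[0], p[-1]
    frontal_basal = ((e0[1] > c.y_front and e1[2] < c.z_base)
                     or (e1[1] > c.y_front and e0[2] < c.z_base))
    if not frontal_basal:
        return None
    if not brute_force_visits_sphere(p, c.center(hemi), c.sphere_radius):
        return None
    return hemi
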