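"""Shared study conditions for the analysis drivers.

Every driver regenerates the phantom cohort deterministically from this
spec, so the scripts can be run independently and in any order.
"""

import os

import bundledissect as bd

COHORT_SEED = 7
N_SUBJECTS = 5
SPEC = bd.PhantomSpec(n_streamlines=2000, seed=COHORT_SEED)
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def results_dir(name: str) -> str:
    path = os.path.abspath(os.path.join(RESULTS, name))
    os.makedirs(path, exist_ok=True)
    return path


def cohort() -> list:
    return bd.make_cohort(SPEC, N_SUBJECTS)
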