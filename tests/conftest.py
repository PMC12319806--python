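import warnings

import numpy as np
import pytest

from tractgr.phantom import (
    orthogonal_crossing_spec,
    single_bundle_spec,
    two_bundle_spec,
)
from tractgr.pipeline import run_phantom_pipeline


@pytest.fixture(scope="session")
def corridor_result():
    """Full pipeline on the default two-bundle partial-volume phantom."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_phantom_pipeline(two_bundle_spec(seed=0))


@pytest.fixture(scope="session")
def orthogonal_result():
    """Full pipeline on the clean single-crossing phantom."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_phantom_pipeline(orthogonal_crossing_spec(seed=0))


@pytest.fixture(scope="session")
def single_result():
    """Full pipeline on a single-bundle (crossing-free) phantom."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_phantom_pipeline(single_bundle_spec(seed=0))


def enumerate_nnls(A, y):
    """Exhaustive active-set oracle for small NNLS problems.

    Tries every support set, keeps the feasible least-squares solution whose
    KKT conditions hold, and returns the one with the smallest objective.
    Independent of the package solver.
    """
    from itertools import combinations

    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    n = A.shape[1]
    best_obj, best_x = np.inf, np.zeros(n)
    for k in range(n + 1):
        for support in combinations(range(n), k):
            s = list(support)
            x = np.zeros(n)
            if s:
                sol, *_ = np.linalg.lstsq(A[:, s], y, rcond=None)
                if np.any(sol < -1e-12):
                    continue
                x[s] = np.maximum(sol, 0.0)
            grad = A.T @ (A @ x - y)
            if np.all(grad >= -1e-9):
                obj = float(np.sum((A @ x - y) ** 2))
                if obj < best_obj:
                    best_obj, best_x = obj, x
    return best_x
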