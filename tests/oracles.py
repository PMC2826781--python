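"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: occupancy is
computed by exhaustive enumeration of state paths weighted by path
probability, so matrix-power results can be checked against first
principles on small instances.
"""

import itertools

import numpy as np

N_STATES = 4


def enumerate_occupancy(matrix: np.ndarray, n_cycles: int) -> np.ndarray:
    """State occupancy after each cycle by exhaustive path enumeration.

    Returns an array of shape (n_cycles + 1, 4); row 0 is the start
    distribution (everyone in state 0).
    """
    occupancy = np.zeros((n_cycles + 1, N_STATES))
    occupancy[0, 0] = 1.0
    # cycle c occupancy: enumerate all length-c path prefixes
    for c in range(1, n_cycles + 1):
        for path in itertools.product(range(N_STATES), repeat=c):
            prob = 1.0
            prev = 0
            for state in path:
                prob *= matrix[prev, state]
                prev = state
            occupancy[c, path[-1]] += prob
    return occupancy


def enumerate_expected_alive_years(
    matrix: np.ndarray, n_cycles: int, cycle_length: float
) -> float:
    """Undiscounted expected alive time, membership at cycle start."""
    occ = enumerate_occupancy(matrix, n_cycles)
    return float(sum(occ[c, :3].sum() * cycle_length for c in range(n_cycles)))
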