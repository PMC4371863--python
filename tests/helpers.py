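"""Independent oracles used by the test suite.

These deliberately avoid the library's convolution / NNLS code paths:
the isotopologue oracle enumerates element isotope-count vectors with
multinomial weights, and the amplitude oracle minimizes the least-squares
objective by dense grid search.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# exact masses and natural abundances, duplicated on purpose (oracle
# independence); nitrogen abundance is replaced by the enrichment
ORACLE_ISOTOPES = {
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "O": [(15.99491461956, 0.99757), (16.99913170, 0.00038), (17.9991610, 0.00205)],
    "S": [
        (31.97207100, 0.9499),
        (32.97145876, 0.0075),
        (33.96786690, 0.0425),
        (35.96708076, 0.0001),
    ],
}
ORACLE_NEUTRON_OFFSETS = {
    "H": [0, 1],
    "C": [0, 1],
    "O": [0, 1, 2],
    "S": [0, 1, 2, 4],
}
N14 = (14.0030740048, 0)
N15 = (15.0001088989, 1)


def _element_count_vectors(n_atoms: int, isotopes):
    """All (count per isotope) vectors for n_atoms i.i.d. atoms, with
    multinomial probability and total (mass, neutron offset)."""
    k = len(isotopes)
    for counts in itertools.product(range(n_atoms + 1), repeat=k - 1):
        rest = n_atoms - sum(counts)
        if rest < 0:
            continue
        full = (rest,) + counts
        prob = math.factorial(n_atoms)
        mass = 0.0
        for c, (m, p) in zip(full, isotopes):
            prob = prob / math.factorial(c) * (p**c)
            mass += c * m
        yield full, prob, mass


def enumerate_isotopologues(counts: dict[str, int], e: float) -> dict[int, tuple[float, float]]:
    """Aggregate isotopologues by total neutron offset.

    Returns {offset: (probability, probability-weighted mass)} for a
    composition given as element -> atom count, with 15N enrichment ``e``.
    """
    element_tables = []
    for el, n in counts.items():
        if n == 0:
            continue
        if el == "N":
            isotopes = [(N14[0], 1.0 - e), (N15[0], e)]
            offsets = [0, 1]
        else:
            isotopes = ORACLE_ISOTOPES[el]
            offsets = ORACLE_NEUTRON_OFFSETS[el]
        table = []
        for full, prob, mass in _element_count_vectors(n, isotopes):
            if prob == 0.0:
                continue
            off = sum(c * o for c, o in zip(full, offsets))
            table.append((off, prob, mass))
        element_tables.append(table)

    agg: dict[int, list[float]] = {}
    for combo in itertools.product(*element_tables):
        off = sum(c[0] for c in combo)
        prob = math.prod(c[1] for c in combo)
        mass = sum(c[2] for c in combo)
        slot = agg.setdefault(off, [0.0, 0.0])
        slot[0] += prob
        slot[1] += prob * mass
    return {off: (p, pm) for off, (p, pm) in sorted(agg.items())}


def grid_search_amplitudes(
    design: np.ndarray, observed: np.ndarray, hi: float = 2.0, coarse: float = 0.05
) -> np.ndarray:
    """Dense grid search minimizing ||observed - design @ a||^2 over a >= 0,
    refined once around the coarse optimum."""

    def objective(a):
        r = observed - design @ a
        return float(r @ r)

    def search(lo_v, hi_v, step):
        best, best_obj = None, np.inf
        axes = [np.arange(lo_v[i], hi_v[i] + step / 2, step) for i in range(3)]
        for a in itertools.product(*axes):
            a = np.asarray(a)
            obj = objective(a)
            if obj < best_obj:
                best, best_obj = a, obj
        return best

    a0 = search(np.zeros(3), np.full(3, hi), coarse)
    lo = np.clip(a0 - coarse, 0, None)
    return search(lo, a0 + coarse, coarse / 10)
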