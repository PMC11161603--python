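"""Independent brute-force oracles used to check the fast implementations.

These deliberately avoid the package's convolution path: envelopes are
computed by exhaustive enumeration over every isotope assignment of every
atom, and the binomial tail by summing all outcome counts.
"""

import itertools
from math import comb

import numpy as np

from fluxprot.isotopes import isotope_table


def enumerate_envelope(formula, k=4, labeled_sites=0, p=0.0):
    """Envelope M0..M(k-1) by enumerating all isotope assignments.

    ``labeled_sites`` hydrogens use the two-point (1-p, p) distribution in
    place of natural H abundance.  Only tractable for tiny formulas.
    """
    table = isotope_table()
    atoms = []
    for el in sorted(formula):
        count = formula[el]
        if el == "H":
            count -= labeled_sites
        atoms.extend([table[el]] * count)
    atoms.extend([((0, 1.0 - p), (1, p))] * labeled_sites)
    probs = np.zeros(k)
    for combo in itertools.product(*atoms):
        shift = 0
        pr = 1.0
        for s, a in combo:
            shift += s
            pr *= a
        if shift < k:
            probs[shift] += pr
    return probs / probs.sum()


def all_formulas_up_to(total_atoms, elements=("C", "H", "N", "O", "S")):
    """Every non-empty elemental composition with at most ``total_atoms``."""
    out = []
    for counts in itertools.product(range(total_atoms + 1), repeat=len(elements)):
        t = sum(counts)
        if 0 < t <= total_atoms:
            out.append({el: c for el, c in zip(elements, counts) if c})
    return out


def binomial_upper_tail(n_majority, n_total):
    """P(X >= n_majority | n_total, 1/2) by exact outcome counting."""
    favorable = sum(comb(n_total, j) for j in range(n_majority, n_total + 1))
    return favorable / 2.0**n_total


def bh_step_up(p_values):
    """Hand implementation of the Benjamini-Hochberg step-up adjustment."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * p[i] / rank_from_top)
        adjusted[i] = running_min
    return adjusted
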