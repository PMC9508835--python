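"""Brute-force structure enumeration: the reference the folding DPs answer to.

Enumerates every nested structure over a short sequence (practical up to
~14 nt), scores each with :func:`utrfold.energy.evaluate_energy`, and
derives the exact minimum free energy and Boltzmann pair probabilities.
Nothing here shares code with the dynamic programs in :mod:`utrfold.fold`
beyond the energy function itself, which is the quantity under test.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Optional

import numpy as np

from .energy import EnergyModel, evaluate_energy, load_default_model
from .structure import SecondaryStructure, WATSON_CRICK_WOBBLE

__all__ = ["enumerate_structures", "brute_force_mfe", "brute_force_pair_probs"]


def enumerate_structures(seq: str, model: Optional[EnergyModel] = None):
    """All nested pair sets (1-based tuples) obeying the model's constraints."""
    model = model or load_default_model()
    n = len(seq)
    min_sep = model.min_hairpin + 1
    max_sep = model.max_pairing_dist

    def can(i: int, j: int) -> bool:
        return (
            min_sep <= j - i <= max_sep
            and (seq[i], seq[j]) in WATSON_CRICK_WOBBLE
        )

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        """Structures over the closed 0-based interval [i, j]."""
        if j - i < min_sep:
            return (() ,)
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + min_sep, j + 1):
            if can(i, k):
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append(((i, k),) + left + right)
        return tuple(out)

    for struct in rec(0, n - 1):
        yield tuple(sorted((i + 1, j + 1) for i, j in struct))


def brute_force_mfe(
    seq: str,
    profile: Optional[np.ndarray] = None,
    model: Optional[EnergyModel] = None,
) -> SecondaryStructure:
    """Exact MFE by enumeration; ties resolved toward fewer pairs then
    lexicographically smaller pair lists."""
    model = model or load_default_model()
    best_e, best_pairs = math.inf, ()
    for pairs in enumerate_structures(seq, model):
        e = evaluate_energy(SecondaryStructure(seq, pairs), profile, model)
        key = (e, len(pairs), pairs)
        if key < (best_e, len(best_pairs), best_pairs):
            best_e, best_pairs = e, pairs
    return SecondaryStructure(sequence=seq, pairs=best_pairs, energy=best_e)


def brute_force_pair_probs(
    seq: str,
    profile: Optional[np.ndarray] = None,
    model: Optional[EnergyModel] = None,
) -> np.ndarray:
    """Exact Boltzmann pair-probability matrix (symmetric, 0-based array)."""
    model = model or load_default_model()
    n = len(seq)
    rt = model.rt
    num = np.zeros((n, n))
    z = 0.0
    for pairs in enumerate_structures(seq, model):
        e = evaluate_energy(SecondaryStructure(seq, pairs), profile, model)
        w = math.exp(-e / rt)
        z += w
        for i, j in pairs:
            num[i - 1, j - 1] += w
    p = num / z
    return p + p.T
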