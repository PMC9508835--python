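"""Reduced nearest-neighbor energy model and structure energy evaluation.

The model covers Watson-Crick and GU-wobble dinucleotide stacks, hairpin /
bulge / internal-loop initiation penalties with Jacobson-Stockmayer
extrapolation, and an affine multibranch penalty.  Parameters live in a
versioned YAML data file shipped with the package; swapping the file
changes numbers but none of the structural invariants.

SHAPE reactivities enter as pseudo-free-energy terms
``dG_SHAPE(S) = m * ln(S + 1) + b`` added once per paired nucleotide per
helix stack it participates in, the standard convention for data-directed
folding.  ``evaluate_energy`` is the single source of truth for the energy
of a fixed structure; the dynamic programs in :mod:`utrfold.fold` and the
brute-force enumeration in :mod:`utrfold.exhaustive` must agree with it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import yaml

from .structure import SecondaryStructure, StructureError, WATSON_CRICK_WOBBLE

__all__ = ["EnergyModel", "load_default_model", "shape_pseudo_energy", "evaluate_energy"]

log = logging.getLogger(__name__)

GAS_CONSTANT = 0.0019872  # kcal / (mol K)
JS_COEFF = 1.75  # Jacobson-Stockmayer prefactor, dG += 1.75 * R * T * ln(n / n_max)


@dataclass
class EnergyModel:
    """Nearest-neighbor parameter set (kcal/mol at ``temperature_k``)."""

    stack: dict
    hairpin: list
    bulge: list
    internal: list
    multibranch_offset: float
    multibranch_per_branch: float
    multibranch_per_unpaired: float
    temperature_k: float = 310.15
    min_hairpin: int = 3
    max_internal: int = 30
    max_pairing_dist: int = 600
    shape_slope: float = 1.8
    shape_intercept: float = -0.6
    source: str = field(default="", repr=False)

    @property
    def rt(self) -> float:
        return GAS_CONSTANT * self.temperature_k

    def can_pair(self, a: str, b: str) -> bool:
        return (a, b) in WATSON_CRICK_WOBBLE

    def stack_energy(self, outer: str, inner: str) -> float:
        """Energy of pair ``outer`` (5'X...Y3' as "XY") stacked over ``inner``."""
        return float(self.stack[outer][inner])

    def _js(self, table: list, n_min: int, n: int) -> float:
        n_max = n_min + len(table) - 1
        if n <= n_max:
            return float(table[n - n_min])
        return float(table[-1]) + JS_COEFF * self.rt * math.log(n / n_max)

    def hairpin_energy(self, size: int) -> float:
        if size < self.min_hairpin:
            raise StructureError(f"hairpin loop of size {size} below minimum {self.min_hairpin}")
        return self._js(self.hairpin, 3, size)

    def bulge_energy(self, size: int) -> float:
        return self._js(self.bulge, 1, size)

    def internal_energy(self, size: int) -> float:
        return self._js(self.internal, 2, size)

    def loop_energy(self, n1: int, n2: int) -> float:
        """Bulge/internal penalty for a 2x2 loop with n1, n2 unpaired on each side."""
        if n1 == 0 and n2 == 0:
            raise StructureError("size-0 loop is a stack, not a bulge/internal loop")
        if n1 == 0 or n2 == 0:
            return self.bulge_energy(n1 + n2)
        return self.internal_energy(n1 + n2)

    def multibranch_energy(self, branches: int, unpaired: int) -> float:
        """Closing penalty: ``branches`` counts inner helices plus the closing pair."""
        return (
            self.multibranch_offset
            + self.multibranch_per_branch * branches
            + self.multibranch_per_unpaired * unpaired
        )


def load_default_model(**overrides) -> EnergyModel:
    """Load the packaged parameter file; keyword overrides replace fields."""
    with resources.files("utrfold.data").joinpath("energy_params.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    model = EnergyModel(
        stack=raw["stack"],
        hairpin=raw["hairpin"],
        bulge=raw["bulge"],
        internal=raw["internal"],
        multibranch_offset=raw["multibranch"]["offset"],
        multibranch_per_branch=raw["multibranch"]["per_branch"],
        multibranch_per_unpaired=raw["multibranch"]["per_unpaired"],
        temperature_k=raw["temperature_k"],
        min_hairpin=raw["min_hairpin"],
        max_internal=raw["max_internal"],
        max_pairing_dist=raw["max_pairing_dist"],
        shape_slope=raw["shape_slope"],
        shape_intercept=raw["shape_intercept"],
        source="energy_params.yaml",
    )
    for key, val in overrides.items():
        if not hasattr(model, key):
            raise TypeError(f"unknown EnergyModel field {key!r}")
        setattr(model, key, val)
    return model


def shape_pseudo_energy(reactivity: float, model: EnergyModel) -> float:
    """Per-nucleotide pseudo-free-energy ``m * ln(S + 1) + b`` in kcal/mol.

    Missing data (NaN) contributes 0.  Reactivities at or below -1 make the
    logarithm undefined and are treated as missing, with a warning.
    Negative reactivities above -1 are evaluated as written, so the term
    can fall below the intercept.
    """
    if reactivity is None or (isinstance(reactivity, float) and math.isnan(reactivity)):
        return 0.0
    s = float(reactivity)
    if s <= -1.0:
        log.warning("reactivity %.3f <= -1 treated as no-data", s)
        return 0.0
    return model.shape_slope * math.log(s + 1.0) + model.shape_intercept


def pseudo_energy_array(values: Optional[np.ndarray], n: int, model: EnergyModel) -> np.ndarray:
    """Vector of per-nucleotide pseudo-energies (index 0 = position 1)."""
    ps = np.zeros(n)
    if values is None:
        return ps
    if len(values) != n:
        raise ValueError(f"profile length {len(values)} != sequence length {n}")
    for idx in range(n):
        ps[idx] = shape_pseudo_energy(float(values[idx]), model)
    return ps


def _loop_children(pairs: tuple, n: int):
    """Yield (closing pair or None, direct children) for every loop.

    The exterior loop is reported with closing pair ``None``.
    """
    # Sort by opening position; use a stack to build the nesting tree.
    children: dict = {None: []}
    stack: list = [None]
    events = []
    for i, j in pairs:
        events.append((i, 0, (i, j)))
        events.append((j, 1, (i, j)))
    events.sort()
    for _, kind, pair in events:
        if kind == 0:
            children[pair] = []
            children[stack[-1]].append(pair)
            stack.append(pair)
        else:
            if stack[-1] != pair:
                raise StructureError("pairs are not nested (pseudoknot)")
            stack.pop()
    return children


def evaluate_energy(
    structure: SecondaryStructure,
    profile: Optional[np.ndarray] = None,
    model: Optional[EnergyModel] = None,
) -> float:
    """Free energy (kcal/mol) of a fixed structure by loop decomposition.

    ``profile`` is an optional vector of per-nucleotide reactivities (NaN
    for missing); when given, SHAPE pseudo-energies are added on every
    helix stack.  Passing ``None`` gives the purely thermodynamic value
    used for unfolding-cost calculations.
    """
    model = model or load_default_model()
    seq = structure.sequence
    n = len(seq)
    structure.validate(min_hairpin=model.min_hairpin,
                       max_pairing_dist=model.max_pairing_dist)
    ps = pseudo_energy_array(profile, n, model) if profile is not None else None

    children = _loop_children(structure.pairs, n)
    total = 0.0
    for closing, kids in children.items():
        if closing is None:
            continue  # exterior loop contributes nothing in this model
        i, j = closing
        if not kids:
            total += model.hairpin_energy(j - i - 1)
        elif len(kids) == 1:
            k, l = kids[0]
            if k == i + 1 and l == j - 1:
                outer = seq[i - 1] + seq[j - 1]
                inner = seq[k - 1] + seq[l - 1]
                total += model.stack_energy(outer, inner)
                if ps is not None:
                    total += ps[i - 1] + ps[j - 1] + ps[k - 1] + ps[l - 1]
            else:
                total += model.loop_energy(k - i - 1, j - l - 1)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            total += model.multibranch_energy(branches=len(kids) + 1, unpaired=unpaired)
    return total
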