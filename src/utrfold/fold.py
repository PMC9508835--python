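"""SHAPE-directed thermodynamic folding: MFE structure and pair probabilities.

Dynamic programs over the reduced nearest-neighbor model in
:mod:`utrfold.energy`:

* :func:`mfe_fold` - Zuker-style minimum free energy structure with a
  deterministic traceback.
* :func:`partition_pair_probs` - McCaskill inside/outside partition
  function yielding base-pair probabilities at 37 C.
* Both accept an optional reactivity profile whose values enter as
  pseudo-free-energy terms on helix stacks, so folding with an all-missing
  profile coincides exactly with folding without one.

The decomposition used by both DPs is identical to the loop decomposition
scored by :func:`utrfold.energy.evaluate_energy`; exhaustive enumeration
(:mod:`utrfold.exhaustive`) is the reference implementation both are
validated against.

Structures are nested, obey a minimum hairpin loop of 3 nt, a maximum pair
span (``maxPairingDist``, default 600 nt) and a maximum bulge/internal
loop size.  Sequences longer than 1200 nt are refused: the engine folds a
single partition window and does not implement multi-window stitching.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .energy import EnergyModel, load_default_model, pseudo_energy_array
from .structure import SecondaryStructure

__all__ = ["PairProbabilityMatrix", "mfe_fold", "partition_pair_probs"]

log = logging.getLogger(__name__)

INF = float("inf")
MAX_FOLD_LENGTH = 1200


@dataclass
class PairProbabilityMatrix:
    """Symmetric base-pairing probability matrix over 1-based positions."""

    sequence: str
    p: np.ndarray  # (n, n), p[i-1, j-1] = P(i paired with j)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if self.p.shape != (n, n):
            raise ValueError(f"matrix shape {self.p.shape} != ({n}, {n})")

    @property
    def n(self) -> int:
        return len(self.sequence)

    @property
    def q(self) -> np.ndarray:
        """Per-position probability of being paired (to anything)."""
        return self.p.sum(axis=1)

    def prob(self, i: int, j: int) -> float:
        return float(self.p[i - 1, j - 1])


def _profile_values(profile) -> Optional[np.ndarray]:
    if profile is None:
        return None
    if hasattr(profile, "values") and not isinstance(profile, np.ndarray):
        return np.asarray(profile.values, dtype=float)
    return np.asarray(profile, dtype=float)


def _sequence_of(record) -> str:
    return record if isinstance(record, str) else record.sequence


class _FoldContext:
    """Shared precomputation for the MFE and partition DPs (0-based)."""

    def __init__(self, seq: str, profile, model: EnergyModel):
        if len(seq) > MAX_FOLD_LENGTH:
            raise ValueError(
                f"sequence of {len(seq)} nt exceeds the single-window limit of "
                f"{MAX_FOLD_LENGTH} nt; this engine does not stitch windows"
            )
        self.model = model
        self.seq = seq
        self.n = n = len(seq)
        values = _profile_values(profile)
        self.ps = pseudo_energy_array(values, n, model) if values is not None else np.zeros(n)

        enc = np.array([{"A": 0, "C": 1, "G": 2, "U": 3}[c] for c in seq], dtype=int)
        can = np.zeros((4, 4), dtype=bool)
        for a, b in (("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")):
            can["ACGU".index(a), "ACGU".index(b)] = True
        span_ok = np.zeros((n, n), dtype=bool)
        for i in range(n):
            lo = i + model.min_hairpin + 1
            hi = min(n - 1, i + model.max_pairing_dist)
            if lo <= hi:
                span_ok[i, lo:hi + 1] = True
        self.pairable = span_ok & can[enc[:, None], enc[None, :]]

        # stack transition energy for pair (i, j) over (i+1, j-1), with the
        # four per-stack pseudo-energy terms folded in
        self.stack_e = np.full((n, n), INF)
        for i in range(n - 1):
            js = np.nonzero(self.pairable[i])[0]
            for j in js:
                if j - 1 > i + 1 and self.pairable[i + 1, j - 1]:
                    outer = seq[i] + seq[j]
                    inner = seq[i + 1] + seq[j - 1]
                    self.stack_e[i, j] = (
                        model.stack_energy(outer, inner)
                        + self.ps[i] + self.ps[j] + self.ps[i + 1] + self.ps[j - 1]
                    )

        # bulge/internal initiation penalties indexed by (n1, n2)
        mi = model.max_internal
        lp = np.full((mi + 1, mi + 1), INF)
        for n1 in range(mi + 1):
            for n2 in range(mi + 1 - n1):
                if n1 + n2 >= 1:
                    lp[n1, n2] = model.loop_energy(n1, n2)
        self.loop_pen = lp

        self.hairpin_e = np.array(
            [model.hairpin_energy(s) if s >= model.min_hairpin else INF
             for s in range(n + 1)]
        )
        self.a = model.multibranch_offset
        self.b = model.multibranch_per_branch
        self.c = model.multibranch_per_unpaired


def _internal_candidates(ctx: _FoldContext, i: int, j: int):
    """Index windows for bulge/internal-loop transitions of cell (i, j).

    Returns (k0, k1, l0, l1, penalty_submatrix) covering inner pairs (k, l)
    with k in [k0, k1), l in [l0, l1); or None when no candidate exists.
    """
    mi = ctx.model.max_internal
    k0, k1 = i + 1, min(i + 1 + mi, j - 4) + 1
    l1 = j  # exclusive; l <= j - 1
    l0 = max(i + 2, j - 1 - mi)
    if k1 <= k0 or l1 <= l0:
        return None
    pen = ctx.loop_pen[0:k1 - k0 - 0, 0:l1 - l0][:, ::-1]
    # row r -> n1 = (k0 + r) - i - 1 = r ; col c -> n2 = (j - 1) - (l0 + c)
    return k0, k1, l0, l1, pen


def _mfe_tables(ctx: _FoldContext):
    n = ctx.n
    V = np.full((n, n), INF)
    FM = np.full((n, n), INF)
    FM1 = np.full((n, n), INF)
    b, c = ctx.b, ctx.c

    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            if ctx.pairable[i, j]:
                best = ctx.hairpin_e[j - i - 1]
                cand = _internal_candidates(ctx, i, j)
                if cand is not None:
                    k0, k1, l0, l1, pen = cand
                    sub = V[k0:k1, l0:l1] + pen
                    m = sub.min()
                    if m < best:
                        best = m
                if ctx.stack_e[i, j] < INF:
                    v = ctx.stack_e[i, j] + V[i + 1, j - 1]
                    if v < best:
                        best = v
                if span >= 11:
                    mm = FM[i + 1, i + 2:j - 1] + FM1[i + 3:j, j - 1]
                    if mm.size:
                        m = mm.min() + ctx.a + b
                        if m < best:
                            best = m
                V[i, j] = best
            # FM1: branch starts exactly at i, trailing unpaired
            f1 = V[i, j] + b if np.isfinite(V[i, j]) else INF
            if j - 1 >= i + 4:
                f1 = min(f1, FM1[i, j - 1] + c)
            FM1[i, j] = f1
            # FM: >= 1 branch anywhere in [i, j]
            ks = np.arange(i, j - 3)
            pref = c * (ks - i)
            if ks.size > 1:
                prev = FM[i, ks[1:] - 1]
                pref = np.minimum(pref, np.concatenate(([INF], prev)))
            fm = (pref + FM1[ks, j]).min() if ks.size else INF
            FM[i, j] = fm

    W = np.zeros(n + 1)  # W[j+1] = best over prefix 0..j ; W[0] = 0
    for j in range(n):
        best = W[j]
        iv = V[: j + 1, j]
        cand = W[np.arange(j + 1)] + iv
        m = cand.min() if cand.size else INF
        if m < best:
            best = m
        W[j + 1] = best
    return V, FM, FM1, W


def _traceback(ctx: _FoldContext, V, FM, FM1, W) -> list[tuple[int, int]]:
    """Deterministic traceback; unpaired/hairpin options are preferred on ties."""
    n = ctx.n
    tol = 1e-9
    pairs: list[tuple[int, int]] = []
    b, c = ctx.b, ctx.c

    ext: list[tuple[int, int]] = []
    j = n - 1
    while j >= 0:
        if abs(W[j + 1] - W[j]) <= tol:
            j -= 1
            continue
        hit = None
        for i in range(0, j + 1):
            if np.isfinite(V[i, j]) and abs(W[i] + V[i, j] - W[j + 1]) <= tol:
                hit = i
                break
        assert hit is not None, "traceback failed in exterior loop"
        ext.append((hit, j))
        j = hit - 1

    stack: list[tuple[str, int, int]] = [("V", i, j) for i, j in ext]
    while stack:
        kind, i, j = stack.pop()
        if kind == "V":
            pairs.append((i + 1, j + 1))
            target = V[i, j]
            if abs(ctx.hairpin_e[j - i - 1] - target) <= tol:
                continue
            found = False
            cand = _internal_candidates(ctx, i, j)
            if cand is not None:
                k0, k1, l0, l1, pen = cand
                sub = V[k0:k1, l0:l1] + pen
                locs = np.argwhere(np.abs(sub - target) <= tol)
                if locs.size:
                    r, cc = locs[0]
                    stack.append(("V", k0 + int(r), l0 + int(cc)))
                    found = True
            if not found and ctx.stack_e[i, j] < INF and \
                    abs(ctx.stack_e[i, j] + V[i + 1, j - 1] - target) <= tol:
                stack.append(("V", i + 1, j - 1))
                found = True
            if not found:
                for x in range(i + 2, j - 1):
                    if abs(ctx.a + b + FM[i + 1, x] + FM1[x + 1, j - 1] - target) <= tol:
                        stack.append(("FM", i + 1, x))
                        stack.append(("FM1", x + 1, j - 1))
                        found = True
                        break
            assert found, f"traceback failed at V({i},{j})"
        elif kind == "FM1":
            target = FM1[i, j]
            if j - 1 >= i + 4 and abs(FM1[i, j - 1] + c - target) <= tol:
                stack.append(("FM1", i, j - 1))
            else:
                assert abs(V[i, j] + b - target) <= tol, f"traceback failed at FM1({i},{j})"
                stack.append(("V", i, j))
        else:  # FM
            target = FM[i, j]
            found = False
            for k in range(i, j - 3):
                if abs(c * (k - i) + FM1[k, j] - target) <= tol:
                    stack.append(("FM1", k, j))
                    found = True
                    break
                if k > i and abs(FM[i, k - 1] + FM1[k, j] - target) <= tol:
                    stack.append(("FM", i, k - 1))
                    stack.append(("FM1", k, j))
                    found = True
                    break
            assert found, f"traceback failed at FM({i},{j})"
    return sorted(pairs)


def mfe_fold(
    record: Union[str, "object"],
    profile=None,
    model: Optional[EnergyModel] = None,
) -> SecondaryStructure:
    """Minimum free energy structure, optionally SHAPE-directed.

    Parameters
    ----------
    record
        Sequence string or any object with a ``sequence`` attribute.
    profile
        Optional per-nucleotide reactivities (NaN = no data): an ndarray or
        an object exposing ``values``.
    model
        Energy model; the packaged defaults when omitted.
    """
    model = model or load_default_model()
    seq = _sequence_of(record)
    ctx = _FoldContext(seq, profile, model)
    if ctx.n < 5:
        return SecondaryStructure(sequence=seq, pairs=(), energy=0.0)
    V, FM, FM1, W = _mfe_tables(ctx)
    energy = float(W[ctx.n])
    pairs = _traceback(ctx, V, FM, FM1, W)
    return SecondaryStructure(sequence=seq, pairs=tuple(pairs), energy=energy)


def partition_pair_probs(
    record: Union[str, "object"],
    profile=None,
    model: Optional[EnergyModel] = None,
) -> PairProbabilityMatrix:
    """Boltzmann base-pair probabilities under the same energy function as
    :func:`mfe_fold`.

    Uses uniform per-nucleotide rescaling (anchored to the MFE energy) to
    keep the inside/outside recursions within float64 range on long,
    strongly SHAPE-stabilized folds.
    """
    model = model or load_default_model()
    seq = _sequence_of(record)
    ctx = _FoldContext(seq, profile, model)
    n = ctx.n
    if n < 5 or not ctx.pairable.any():
        return PairProbabilityMatrix(sequence=seq, p=np.zeros((n, n)))

    rt = model.rt
    # per-nucleotide scale factor: full-weight structures end up O(1)
    V, _, _, W = _mfe_tables(ctx)
    e_min = min(0.0, float(W[n]))
    u = math.exp(e_min / (n * rt))

    def bw(e):
        return np.exp(-np.asarray(e, dtype=float) / rt)

    cwu = math.exp(-ctx.c / rt) * u
    bwb = math.exp(-ctx.b / rt)
    bwab = math.exp(-(ctx.a + ctx.b) / rt)

    with np.errstate(over="raise"):
        wlp = np.zeros_like(ctx.loop_pen)
        finite = np.isfinite(ctx.loop_pen)
        sizes = np.add.outer(np.arange(wlp.shape[0]), np.arange(wlp.shape[1]))
        wlp[finite] = np.exp(-ctx.loop_pen[finite] / rt) * (u ** sizes[finite])

        Zb = np.zeros((n, n))
        Zm = np.zeros((n, n))
        Zm1 = np.zeros((n, n))
        for span in range(4, n):
            for i in range(0, n - span):
                j = i + span
                if ctx.pairable[i, j]:
                    acc = math.exp(-ctx.hairpin_e[j - i - 1] / rt) * u ** (j - i + 1)
                    if ctx.stack_e[i, j] < INF:
                        acc += math.exp(-ctx.stack_e[i, j] / rt) * u * u * Zb[i + 1, j - 1]
                    cand = _internal_candidates(ctx, i, j)
                    if cand is not None:
                        k0, k1, l0, l1, pen = cand
                        wsub = wlp[0:k1 - k0, 0:l1 - l0][:, ::-1]
                        acc += u * u * float(np.sum(wsub * Zb[k0:k1, l0:l1]))
                    if span >= 11:
                        mm = float(np.dot(Zm[i + 1, i + 2:j - 1], Zm1[i + 3:j, j - 1]))
                        acc += bwab * u * u * mm
                    Zb[i, j] = acc
                z1 = Zb[i, j] * bwb
                if j - 1 >= i + 4:
                    z1 += Zm1[i, j - 1] * cwu
                Zm1[i, j] = z1
                ks = np.arange(i, j - 3)
                pref = cwu ** (ks - i)
                if ks.size > 1:
                    pref = pref + np.concatenate(([0.0], Zm[i, ks[1:] - 1]))
                zm = float(np.dot(pref, Zb[ks, j])) * bwb
                if j - 1 >= i + 4:
                    zm += Zm[i, j - 1] * cwu
                Zm[i, j] = zm

        Ze = np.ones(n + 1)  # Ze[j+1] over prefix 0..j, Ze[0] = 1 (empty)
        for j in range(n):
            Ze[j + 1] = Ze[j] * u + float(np.dot(Ze[: j + 1], Zb[: j + 1, j]))
        ZeR = np.ones(n + 1)  # ZeR[i] over suffix i..n-1, ZeR[n] = 1
        for i in range(n - 1, -1, -1):
            ZeR[i] = ZeR[i + 1] * u + float(np.dot(Zb[i, i:], ZeR[i + 1:]))
        Z = Ze[n]
        if not np.isfinite(Z) or Z <= 0:
            raise FloatingPointError("partition function out of range")

        Zhb = np.zeros((n, n))
        Zhm = np.zeros((n, n))
        Zhm1 = np.zeros((n, n))
        mi = model.max_internal
        for span in range(n - 1, 3, -1):
            for i in range(0, n - span):
                j = i + span
                # outside of Zm1(i, j)
                z = 0.0
                if j + 1 < n:
                    z += Zhm1[i, j + 1] * cwu
                if i >= 2 and j + 1 < n:
                    ks = np.arange(0, i - 1)
                    z += bwab * u * u * float(np.dot(Zhb[ks, j + 1], Zm[ks + 1, i - 1]))
                Zhm1[i, j] = z
                # outside of Zm(i, j)
                z = 0.0
                if j + 1 < n:
                    z += Zhm[i, j + 1] * cwu
                if i >= 1 and j + 2 < n:
                    ls = np.arange(j + 2, n)
                    z += bwab * u * u * float(np.dot(Zhb[i - 1, ls], Zm1[j + 1, ls - 1]))
                if j + 1 < n:
                    jps = np.arange(j + 1, n)
                    z += bwb * float(np.dot(Zhm[i, jps], Zb[j + 1, jps]))
                Zhm[i, j] = z
                # outside of Zb(i, j)
                if not ctx.pairable[i, j]:
                    continue
                acc = Ze[i] * ZeR[j + 1]
                if i >= 1 and j + 1 < n and ctx.stack_e[i - 1, j + 1] < INF:
                    acc += Zhb[i - 1, j + 1] * math.exp(-ctx.stack_e[i - 1, j + 1] / rt) * u * u
                k0 = max(0, i - 1 - mi)
                l1 = min(n, j + 2 + mi)
                if i >= 1 and l1 > j + 1:
                    ksub = Zhb[k0:i, j + 1:l1]
                    if ksub.size:
                        wsub = wlp[0:i - k0, 0:l1 - j - 1][::-1, :]
                        acc += u * u * float(np.sum(ksub * wsub))
                ips = np.arange(0, i + 1)
                coef = cwu ** (i - ips)
                if i >= 1:
                    coef = coef + np.concatenate((Zm[ips[:-1], i - 1], [0.0]))
                acc += bwb * float(np.dot(Zhm[ips, j], coef))
                acc += Zhm1[i, j] * bwb
                Zhb[i, j] = acc

        P = Zb * Zhb / Z
    P = np.where(P > 0, P, 0.0)
    np.clip(P, 0.0, 1.0, out=P)
    P = P + P.T
    return PairProbabilityMatrix(sequence=seq, p=P)
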