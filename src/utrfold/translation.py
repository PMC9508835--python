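"""Start-codon accessibility, relative translation, and uORF scanning.

The accessibility score is the non-equilibrium unfolding cost

    dG_unfold = dG_constrained - dG_reference

where the constrained structure is the reference minus every base pair
with an endpoint inside a window of +-w nucleotides (w in 13..16, default
15) around the adenosine of the start codon; the RNA is not allowed to
refold.  Energies are evaluated thermodynamics-only by default (no SHAPE
pseudo-energies), even when the reference is a SHAPE-directed model.

Translation is read out as nanoluciferase normalized to co-transfected
firefly (NL/FF) per replicate, expressed relative to the native construct,
and classified as increase / no_effect / decrease with a 15% boundary
(a change of exactly 15% counts as an effect).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .energy import EnergyModel, evaluate_energy, load_default_model
from .structure import SecondaryStructure

__all__ = [
    "UnfoldResult",
    "TranslationRecord",
    "UorfCall",
    "constrain_structure",
    "delta_g_unfold",
    "relative_translation",
    "classify_effect",
    "group_ttest",
    "scan_uorfs",
    "structure_translation_report",
]

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 15
WINDOW_SWEEP = (13, 14, 15, 16)
EFFECT_THRESHOLD = 0.15
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})
DEFAULT_START_CODONS = frozenset({"AUG", "CUG"})


@dataclass
class UnfoldResult:
    label: str
    a_position: int
    window: int
    dg_reference: float
    dg_constrained: float
    pairs_removed: int

    @property
    def dg_unfold(self) -> float:
        return self.dg_constrained - self.dg_reference


@dataclass
class TranslationRecord:
    label: str
    ratios: np.ndarray            # per-replicate NL/FF
    relative: float               # mean ratio / native mean ratio
    relative_sd: float
    n: int
    effect: str = ""

    def __post_init__(self) -> None:
        if not self.effect:
            self.effect = classify_effect(self.relative)


@dataclass
class UorfCall:
    start: int
    codon: str
    stop: Optional[int]           # 1-based first nt of the in-frame stop, None if stop-less
    length: int                   # nt from start codon through last pre-stop nt
    cug_g: bool                   # codon followed by G ("CUG/G"-style context)


def constrain_structure(
    reference: SecondaryStructure,
    a_position: int,
    window: int = DEFAULT_WINDOW,
) -> SecondaryStructure:
    """Remove every pair with an endpoint within +-window of ``a_position``.

    All other pairs are untouched (no refolding).  Windows running off
    either end of the sequence are clipped with a warning.
    """
    n = len(reference.sequence)
    if not 1 <= a_position <= n:
        raise ValueError(f"start position {a_position} outside sequence of length {n}")
    lo, hi = a_position - window, a_position + window
    if lo < 1 or hi > n:
        log.warning("unfolding window [%d, %d] clipped to [1, %d]", lo, hi, n)
        lo, hi = max(1, lo), min(n, hi)
    drop = [(i, j) for i, j in reference.pairs if lo <= i <= hi or lo <= j <= hi]
    return reference.remove_pairs(drop)


def delta_g_unfold(
    reference: SecondaryStructure,
    a_position: int,
    window: int = DEFAULT_WINDOW,
    model: Optional[EnergyModel] = None,
    label: str = "",
    profile=None,
) -> UnfoldResult:
    """Non-equilibrium unfolding cost of the start-codon window.

    ``profile`` is normally left ``None`` (thermodynamics-only evaluation
    of both structures, mirroring energy-function re-evaluation of
    data-directed models); pass reactivities to include pseudo-energies
    in both terms instead.
    """
    model = model or load_default_model()
    constrained = constrain_structure(reference, a_position, window)
    vals = None if profile is None else (
        profile.values if hasattr(profile, "values") and not isinstance(profile, np.ndarray)
        else np.asarray(profile, dtype=float))
    dg_ref = evaluate_energy(reference, vals, model)
    dg_con = evaluate_energy(constrained, vals, model)
    return UnfoldResult(
        label=label,
        a_position=a_position,
        window=window,
        dg_reference=dg_ref,
        dg_constrained=dg_con,
        pairs_removed=len(reference.pairs) - len(constrained.pairs),
    )


def delta_g_unfold_sweep(reference, a_position, windows=WINDOW_SWEEP, **kwargs):
    """Window sweep across w in {13, 14, 15, 16}."""
    return [delta_g_unfold(reference, a_position, window=w, **kwargs) for w in windows]


def relative_translation(
    luminescence: pd.DataFrame,
    native_label: str,
) -> list[TranslationRecord]:
    """Per-construct relative translation from raw dual-luciferase readouts.

    ``luminescence`` needs columns ``construct``, ``nl``, ``ff`` (one row
    per replicate well).  Each replicate's NL/FF ratio is computed, each
    construct's mean ratio is divided by the native construct's mean
    ratio, and the SD is propagated across the replicate-level relative
    values.  Replicates with non-positive firefly signal are dropped with
    a warning.  The native construct's relative translation is exactly 1.
    """
    required = {"construct", "nl", "ff"}
    if not required <= set(luminescence.columns):
        raise ValueError(f"luminescence table needs columns {sorted(required)}")
    if native_label not in set(luminescence["construct"]):
        raise ValueError(f"native construct {native_label!r} not in table")

    ratios: dict = {}
    for construct, grp in luminescence.groupby("construct", sort=False):
        ff = grp["ff"].to_numpy(float)
        nl = grp["nl"].to_numpy(float)
        keep = ff > 0
        if not keep.all():
            log.warning("construct %s: dropped %d replicate(s) with FF <= 0",
                        construct, int((~keep).sum()))
        if not keep.any():
            raise ValueError(f"construct {construct!r}: all replicates dropped (FF <= 0)")
        ratios[construct] = nl[keep] / ff[keep]

    native_mean = float(np.mean(ratios[native_label]))
    records = []
    for construct, r in ratios.items():
        rel_values = r / native_mean
        if construct == native_label:
            rel, sd = 1.0, float(np.std(rel_values, ddof=1)) if len(r) > 1 else 0.0
        else:
            rel = float(np.mean(rel_values))
            sd = float(np.std(rel_values, ddof=1)) if len(r) > 1 else 0.0
        records.append(TranslationRecord(
            label=construct, ratios=r, relative=rel, relative_sd=sd, n=len(r),
        ))
    return records


def classify_effect(relative: float) -> str:
    """increase / no_effect / decrease with the 15% boundary counted as an effect."""
    if relative <= 0:
        raise ValueError("relative translation must be positive")
    if relative <= 1 - EFFECT_THRESHOLD:
        return "decrease"
    if relative >= 1 + EFFECT_THRESHOLD:
        return "increase"
    return "no_effect"


def group_ttest(values_a: Sequence[float], values_b: Sequence[float],
                welch: bool = True) -> tuple[float, float]:
    """Two-sample two-tailed t-test (Welch by default) -> (t, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def scan_uorfs(
    record,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
    min_len: int = 30,
) -> list[UorfCall]:
    """Upstream ORFs initiating 5' of the annotated main start codon.

    Every occurrence of a start codon (canonical AUG or near-cognate,
    e.g. CUG) strictly 5' of the main start that opens an in-frame
    stretch of at least ``min_len`` nt is reported, running to its first
    in-frame stop codon or flagged stop-less.  The call notes whether the
    start codon is followed by G (the efficient "CUG/G" context).
    """
    seq = record.sequence
    main_start = record.annotations.get("start_codon")
    if main_start is None:
        raise ValueError("record must annotate the main start codon")
    starts = {c.upper().replace("T", "U") for c in start_codons}
    calls = []
    for pos in range(1, main_start):
        codon = seq[pos - 1:pos + 2]
        if codon not in starts:
            continue
        stop = None
        for cpos in range(pos + 3, len(seq) - 1, 3):
            if seq[cpos - 1:cpos + 2] in STOP_CODONS:
                stop = cpos
                break
        length = (stop - pos) if stop is not None else (len(seq) - pos + 1)
        if length < min_len:
            continue
        calls.append(UorfCall(
            start=pos,
            codon=codon,
            stop=stop,
            length=length,
            cug_g=(seq[pos + 2:pos + 3] == "G"),
        ))
    return calls


def structure_translation_report(
    unfold: Sequence[UnfoldResult],
    translation: Sequence[TranslationRecord],
    grouping=None,
) -> dict:
    """Joint structure-translation summary.

    Returns per-group distributions of relative translation and unfolding
    cost, pairwise Welch t-tests between groups on both quantities, and
    the overall Spearman correlation between dG_unfold and relative
    translation.  Labels present on one side only are listed, not
    silently dropped.
    """
    dg = {u.label: u.dg_unfold for u in unfold}
    tr = {t.label: t.relative for t in translation}
    shared = sorted(set(dg) & set(tr), key=str)
    missing = sorted((set(dg) ^ set(tr)), key=str)
    if not shared:
        raise ValueError("no shared construct labels")

    x = np.array([dg[l] for l in shared])
    y = np.array([tr[l] for l in shared])
    if len(shared) >= 3 and np.std(x) > 0 and np.std(y) > 0:
        rho, rho_p = stats.spearmanr(x, y)
        pearson_r, pearson_p = stats.pearsonr(x, y)
    else:
        rho = rho_p = pearson_r = pearson_p = float("nan")

    groups_table = None
    pairwise = []
    if grouping is not None:
        glab = dict(zip(grouping.labels, grouping.group))
        rows = []
        for g in sorted(set(glab.values())):
            members = [l for l in shared if glab.get(l) == g]
            if not members:
                continue
            ty = np.array([tr[l] for l in members])
            tx = np.array([dg[l] for l in members])
            rows.append({
                "group": g,
                "n": len(members),
                "translation_median": float(np.median(ty)),
                "translation_iqr": float(np.subtract(*np.percentile(ty, [75, 25]))),
                "dg_unfold_median": float(np.median(tx)),
                "dg_unfold_iqr": float(np.subtract(*np.percentile(tx, [75, 25]))),
            })
        groups_table = pd.DataFrame(rows)
        gs = sorted({glab[l] for l in shared if l in glab})
        for ia in range(len(gs)):
            for ib in range(ia + 1, len(gs)):
                ga = [l for l in shared if glab.get(l) == gs[ia]]
                gb = [l for l in shared if glab.get(l) == gs[ib]]
                if len(ga) < 2 or len(gb) < 2:
                    continue
                t_tr, p_tr = group_ttest([tr[l] for l in ga], [tr[l] for l in gb])
                t_dg, p_dg = group_ttest([dg[l] for l in ga], [dg[l] for l in gb])
                pairwise.append({
                    "group_a": gs[ia], "group_b": gs[ib],
                    "t_translation": t_tr, "p_translation": p_tr,
                    "t_dg_unfold": t_dg, "p_dg_unfold": p_dg,
                })
    return {
        "n_shared": len(shared),
        "missing_labels": missing,
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "pearson_r": float(pearson_r),
        "pearson_p": float(pearson_p),
        "groups": groups_table,
        "pairwise_tests": pd.DataFrame(pairwise) if pairwise else None,
    }
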