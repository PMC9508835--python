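"""Synthetic study inputs: mutant panels, planted structures, simulated
MaP rate tables and dual-luciferase panels.

The simulators generate every input the downstream analysis needs, so the
full pipeline is testable without sequencing data.  They emulate the study
conditions: a G/C-rich 5'-UTR (58% G+C), non-overlapping 6-nt UUAUUA
substitution windows named by their 3'-most substituted position, MaP
mutation counts drawn per read at ~20 000x depth with higher modification
probabilities at unpaired nucleotides, and reporter translation whose
mutant-to-native ratio decays as exp(-beta * dG_unfold) with multiplicative
log-normal noise over n = 6 replicates (two plasmid x three biological).

Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .fold import PairProbabilityMatrix
from .io import TranscriptRecord
from .reactivity import MapRateTable
from .structure import SecondaryStructure
from .translation import TranslationRecord

__all__ = [
    "SimulationConfig",
    "MutantConstruct",
    "tile_mutants",
    "random_structured_sequence",
    "simulate_map_rates",
    "simulate_translation_panel",
    "simulate_luciferase_table",
    "planted_structure",
    "simulate_structure_archetypes",
]

log = logging.getLogger(__name__)

SUBSTITUTION = "UUAUUA"
WINDOW = len(SUBSTITUTION)
REPLICATES = 6  # two plasmid replicates x three biological replicates


@dataclass
class SimulationConfig:
    """Study-condition defaults for all simulators.

    ``depth`` echoes the median sequencing depth of the probing
    experiments (> 20 000 reads per position).  The per-read modification
    probabilities place the unpaired/paired rate separation well above the
    untreated background while keeping rates realistically small.
    """

    seed: int = 0
    depth: int = 20000
    p_mod_unpaired: float = 0.03
    p_mod_paired: float = 0.004
    p_background: float = 0.002
    translation_sigma: float = 0.1   # log-normal sigma on replicate ratios
    beta: float = 0.1                # translation ~ exp(-beta * dG_unfold)

    def __post_init__(self) -> None:
        for name in ("p_mod_unpaired", "p_mod_paired", "p_background"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.p_mod_unpaired > self.p_mod_paired >= self.p_background:
            raise ValueError("need p_mod_unpaired > p_mod_paired >= p_background")
        if self.depth < 0 or self.beta < 0 or self.translation_sigma < 0:
            raise ValueError("depth, beta and sigma must be non-negative")


@dataclass
class MutantConstruct:
    """A 6-nt UUAUUA substitution variant, named by its 3'-most substituted
    position."""

    name: int
    window: tuple[int, int]
    sequence: str
    is_degenerate: bool = False

    def __post_init__(self) -> None:
        start, end = self.window
        if end - start + 1 != WINDOW:
            raise ValueError("substitution window must span 6 nt")
        if self.sequence[start - 1:end] != SUBSTITUTION:
            raise ValueError("window residues must spell UUAUUA")


def tile_mutants(native: TranscriptRecord, region_end: int) -> list[MutantConstruct]:
    """Tile consecutive, non-overlapping UUAUUA windows over [1, region_end].

    Windows are [1..6], [7..12], ...; mutants are named 6, 12, ... by the
    3'-most substituted position.  A trailing partial window is dropped
    with a warning, as is a region shorter than one window.  A window
    where the native sequence already reads UUAUUA yields a construct
    flagged degenerate.
    """
    seq = native.sequence
    if region_end > len(seq):
        raise ValueError(f"region_end {region_end} beyond sequence length {len(seq)}")
    if region_end < WINDOW:
        log.warning("region_end %d shorter than one 6-nt window: empty panel", region_end)
        return []
    if region_end % WINDOW != 0:
        log.warning("region_end %d not divisible by 6; dropping trailing partial window",
                    region_end)
    mutants = []
    for end in range(WINDOW, region_end + 1, WINDOW):
        start = end - WINDOW + 1
        mutated = seq[:start - 1] + SUBSTITUTION + seq[end:]
        mutants.append(MutantConstruct(
            name=end,
            window=(start, end),
            sequence=mutated,
            is_degenerate=(mutated == seq),
        ))
    return mutants


def random_structured_sequence(length: int, gc_fraction: float = 0.58,
                               seed: int = 0) -> TranscriptRecord:
    """Random RNA with expected G+C content ``gc_fraction`` (study UTR: 58%)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [
        (1 - gc_fraction) / 2,  # A
        gc_fraction / 2,        # C
        gc_fraction / 2,        # G
        (1 - gc_fraction) / 2,  # U
    ]
    seq = "".join(rng.choice(list("ACGU"), size=length, p=probs))
    return TranscriptRecord(id=f"random_gc{gc_fraction:.2f}_seed{seed}", sequence=seq)


def simulate_map_rates(structure: SecondaryStructure,
                       config: Optional[SimulationConfig] = None) -> MapRateTable:
    """Per-read binomial MaP counts from a planted structure.

    Untreated counts ~ Binomial(depth, p_background); modified counts use
    p_background + p_mod_unpaired at unpaired positions and
    p_background + p_mod_paired at paired ones.  Zero depth yields zero
    rates that the depth filter masks downstream.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n = len(structure.sequence)
    partner = structure.partner()
    paired = np.array([partner[i] != 0 for i in range(1, n + 1)])

    p_mod = np.where(paired,
                     config.p_background + config.p_mod_paired,
                     config.p_background + config.p_mod_unpaired)
    depth = np.full(n, config.depth, dtype=int)
    counts_mod = rng.binomial(depth, p_mod)
    counts_unt = rng.binomial(depth, config.p_background)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate_mod = np.where(depth > 0, counts_mod / np.maximum(depth, 1), 0.0)
        rate_unt = np.where(depth > 0, counts_unt / np.maximum(depth, 1), 0.0)
    return MapRateTable(rate_mod=rate_mod, rate_unt=rate_unt,
                        depth_mod=depth.copy(), depth_unt=depth.copy())


def simulate_translation_panel(
    dg_unfold: Mapping[str, float],
    config: Optional[SimulationConfig] = None,
    n_replicates: int = REPLICATES,
) -> list[TranslationRecord]:
    """Relative-translation panel coupled to unfolding cost.

    Each replicate draws exp(-beta * dG_unfold) * LogNormal(0, sigma); the
    anti-correlation between accessibility cost and translation is the
    generative truth recovery tests check against.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    records = []
    for label in dg_unfold:
        base = np.exp(-config.beta * dg_unfold[label])
        noise = (rng.lognormal(0.0, config.translation_sigma, size=n_replicates)
                 if config.translation_sigma > 0 else np.ones(n_replicates))
        reps = base * noise
        records.append(TranslationRecord(
            label=label,
            ratios=reps,
            relative=float(np.mean(reps)),
            relative_sd=float(np.std(reps, ddof=1)) if n_replicates > 1 else 0.0,
            n=n_replicates,
        ))
    return records


def simulate_luciferase_table(
    dg_unfold: Mapping[str, float],
    native_label: str,
    config: Optional[SimulationConfig] = None,
    n_replicates: int = REPLICATES,
) -> pd.DataFrame:
    """Raw dual-luciferase wells (construct, replicate, nl, ff).

    Firefly signal varies well-to-well (transfection efficiency);
    nanoluciferase tracks firefly times the construct's translation output,
    so NL/FF normalization recovers the planted coupling.
    """
    config = config or SimulationConfig()
    if native_label not in dg_unfold:
        raise ValueError(f"native label {native_label!r} missing from panel")
    rng = np.random.default_rng(config.seed)
    rows = []
    for label, dg in dg_unfold.items():
        out = np.exp(-config.beta * dg)
        for rep in range(1, n_replicates + 1):
            ff = rng.lognormal(np.log(1e5), 0.2)
            noise = rng.lognormal(0.0, config.translation_sigma) \
                if config.translation_sigma > 0 else 1.0
            rows.append({
                "construct": label,
                "replicate": rep,
                "nl": ff * 0.05 * out * noise,
                "ff": ff,
            })
    return pd.DataFrame(rows)


def planted_structure(
    n_hairpins: int = 3,
    stem: int = 8,
    loop: int = 5,
    linker: int = 6,
    seed: int = 0,
) -> tuple[TranscriptRecord, SecondaryStructure]:
    """A designed multi-hairpin RNA with its ground-truth structure.

    Stems are G/C-heavy random duplexes (distinct between hairpins), so
    the planted fold is strongly favored; linkers and loops are A-rich.
    Used as the planted truth for probing-and-recovery simulations.
    """
    rng = np.random.default_rng(seed)
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
    seq_parts: list[str] = []
    pairs: list[tuple[int, int]] = []
    pos = 0

    def extend(s: str) -> None:
        nonlocal pos
        seq_parts.append(s)
        pos += len(s)

    extend("A" * linker)
    for _ in range(n_hairpins):
        stem_seq = "".join(rng.choice(list("GCGCAU"), size=stem))
        open_start = pos + 1
        extend(stem_seq)
        extend("A" * (loop - 1) + "C")
        close_start = pos + 1
        extend("".join(comp[c] for c in reversed(stem_seq)))
        for k in range(stem):
            pairs.append((open_start + k, close_start + stem - 1 - k))
        extend("A" * linker)

    sequence = "".join(seq_parts)
    record = TranscriptRecord(id=f"planted_seed{seed}", sequence=sequence)
    structure = SecondaryStructure(sequence=sequence, pairs=tuple(sorted(pairs)))
    structure.validate()
    return record, structure


def _random_nested_pairs(rng: np.random.Generator, n_positions: int,
                         n_helices: int, helix_len: int) -> frozenset:
    """Disjoint hairpin helices at random offsets: a structural archetype."""
    block = n_positions // n_helices
    pairs = set()
    for h in range(n_helices):
        base = h * block
        width = 2 * helix_len + 4
        off = int(rng.integers(0, max(1, block - width)))
        s = base + off + 1
        e = s + width - 1
        for k in range(helix_len):
            pairs.add((s + k, e - k))
    return frozenset(pairs)


def simulate_structure_archetypes(
    seed: int = 0,
    group_sizes: Sequence[int] = (26, 6, 6, 5),
    n_positions: int = 270,
    drop_prob: float = 0.05,
    n_spurious: int = 2,
) -> tuple[list[str], list[PairProbabilityMatrix], np.ndarray]:
    """A simulated construct panel drawn from planted structural archetypes.

    The default sizes mirror a 43-construct panel: the native construct
    plus 25 native-like mutants share the first archetype, and 17 mutants
    split across three alternative archetypes.  Each construct's pairing-probability
    matrix is its archetype's pair set with high probabilities, a few
    pairs dropped, and a few spurious low-probability pairs added.

    Returns (labels, matrices, true group indices).
    """
    rng = np.random.default_rng(seed)
    archetypes = [
        _random_nested_pairs(rng, n_positions, n_helices=4 + g % 2, helix_len=8)
        for g in range(len(group_sizes))
    ]
    labels: list[str] = []
    matrices: list[PairProbabilityMatrix] = []
    truth: list[int] = []
    seq = "A" * n_positions
    counter = 0
    for g, size in enumerate(group_sizes):
        for _ in range(size):
            label = "native" if counter == 0 else f"mut{counter * 6}"
            counter += 1
            p = np.zeros((n_positions, n_positions))
            for i, j in archetypes[g]:
                if rng.random() < drop_prob:
                    continue
                v = rng.uniform(0.75, 0.95)
                p[i - 1, j - 1] = p[j - 1, i - 1] = v
            for _ in range(n_spurious):
                i = int(rng.integers(1, n_positions - 4))
                j = int(rng.integers(i + 4, n_positions + 1))
                v = rng.uniform(0.1, 0.25)
                p[i - 1, j - 1] = p[j - 1, i - 1] = v
            labels.append(label)
            matrices.append(PairProbabilityMatrix(sequence=seq, p=p))
            truth.append(g)
    return labels, matrices, np.array(truth)
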