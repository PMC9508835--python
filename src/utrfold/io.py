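"""On-disk formats: FASTA, .shape, CT, dot-bracket and pairing-probability tables.

Conventions
-----------
* Coordinates are 1-based and inclusive over the analyzed transcript
  string.  Transcript-level "+1" numbering is recovered through the
  ``numbering_offset`` annotation (reporter constructs prepend 45 nt of
  promoter sequence, hence offset -45).
* Sequences are RNA internally (T converted to U on input, upper-cased);
  ambiguity codes are rejected because the folding engine defines
  energies only over A, C, G, U.
* ``.shape`` files are whitespace-delimited ``position reactivity stderr``
  rows with -999 marking missing data in both value columns.
* Pairing-probability tables are TSV of ``i  j  probability`` for
  probabilities >= 0.001.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reactivity import NO_DATA, ReactivityProfile
from .structure import SecondaryStructure

__all__ = [
    "TranscriptRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_shape",
    "write_shape",
    "read_ct",
    "write_ct",
    "read_pairprob",
    "write_pairprob",
    "read_config",
    "configure_logging",
]

log = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
PAIRPROB_MIN = 0.001


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class TranscriptRecord:
    """An RNA sequence with optional feature annotations.

    Annotations understood downstream: ``utr5_end`` (1-based last 5'-UTR
    nucleotide), ``start_codon`` (1-based A of the AUG) and
    ``numbering_offset`` (added to internal positions to obtain
    transcript-level numbering).
    """

    id: str
    sequence: str
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        if not seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-nucleotide character(s) {sorted(bad)}"
            )
        self.sequence = seq
        start = self.annotations.get("start_codon")
        if start is not None:
            codon = seq[start - 1:start + 2]
            if codon != "AUG":
                raise FormatError(
                    f"record {self.id!r}: start_codon={start} spells {codon!r}, not AUG"
                )
            utr_end = self.annotations.get("utr5_end")
            if utr_end is not None and not utr_end < start:
                raise FormatError(
                    f"record {self.id!r}: utr5_end ({utr_end}) must precede start_codon ({start})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def to_transcript_coords(self, position: int) -> int:
        return position + int(self.annotations.get("numbering_offset", 0))


def read_fasta(path: Union[str, Path]) -> list[TranscriptRecord]:
    """Read a FASTA file into transcript records (T -> U, upper-cased)."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(TranscriptRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path: Union[str, Path]) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(Path(path)), "fasta")


def read_shape(path: Union[str, Path]) -> ReactivityProfile:
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                rows.append((int(parts[0]), float(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise FormatError(f"{path}: empty .shape file")
    positions = [r[0] for r in rows]
    if positions != list(range(1, len(rows) + 1)):
        raise FormatError(f"{path}: positions must be contiguous from 1")
    vals = np.array([r[1] for r in rows])
    errs = np.array([r[2] for r in rows])
    missing = vals == NO_DATA
    vals[missing] = np.nan
    errs[missing | (errs == NO_DATA)] = np.nan
    return ReactivityProfile(values=vals, stderr=errs)


def write_shape(profile: ReactivityProfile, path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        for idx in range(len(profile)):
            v, e = profile.values[idx], profile.stderr[idx]
            if np.isnan(v):
                fh.write(f"{idx + 1}\t{NO_DATA:.0f}\t{NO_DATA:.0f}\n")
            else:
                e_out = 0.0 if np.isnan(e) else e
                fh.write(f"{idx + 1}\t{v:.6f}\t{e_out:.6f}\n")


def write_ct(structure: SecondaryStructure, path: Union[str, Path],
             title: str = "structure") -> None:
    """Write connect (CT) format; partner column 0 means unpaired."""
    n = len(structure.sequence)
    partner = structure.partner()
    energy = structure.energy
    header = f"{n}\t{title}"
    if energy is not None:
        header = f"{n}\tENERGY = {energy:.2f}\t{title}"
    lines = [header]
    for pos in range(1, n + 1):
        lines.append(
            f"{pos}\t{structure.sequence[pos - 1]}\t{pos - 1}\t"
            f"{(pos + 1) if pos < n else 0}\t{partner[pos]}\t{pos}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_ct(path: Union[str, Path]) -> SecondaryStructure:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty CT file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError(f"{path}: malformed CT header") from None
    energy = None
    if "ENERGY" in lines[0].upper():
        try:
            energy = float(lines[0].upper().split("ENERGY")[1].lstrip(" =").split()[0])
        except (ValueError, IndexError):
            energy = None
    if len(lines) - 1 < n:
        raise FormatError(f"{path}: expected {n} body rows, found {len(lines) - 1}")
    seq = []
    partner = [0] * (n + 1)
    for row in lines[1:n + 1]:
        parts = row.split()
        pos, res, pair = int(parts[0]), parts[1], int(parts[4])
        seq.append(res)
        partner[pos] = pair
    for pos in range(1, n + 1):
        mate = partner[pos]
        if mate and partner[mate] != pos:
            raise FormatError(f"{path}: pairing column not involutive at position {pos}")
    pairs = tuple((i, partner[i]) for i in range(1, n + 1) if partner[i] > i)
    sequence = "".join(seq).upper().replace("T", "U")
    return SecondaryStructure(sequence=sequence, pairs=pairs, energy=energy)


def write_pairprob(matrix, path: Union[str, Path], min_prob: float = PAIRPROB_MIN) -> None:
    """TSV of (i, j, probability) for the upper triangle, thresholded."""
    p = matrix.p
    n = p.shape[0]
    with Path(path).open("w") as fh:
        fh.write(f"# length={n}\n")
        fh.write("i\tj\tprobability\n")
        iu, ju = np.triu_indices(n, k=1)
        keep = p[iu, ju] >= min_prob
        for i, j, v in zip(iu[keep] + 1, ju[keep] + 1, p[iu, ju][keep]):
            fh.write(f"{i}\t{j}\t{v:.6f}\n")


def read_pairprob(path: Union[str, Path], sequence: Optional[str] = None):
    """Read a pairing-probability TSV back into a matrix.

    The sequence is not stored in the TSV; supply it, or a run of N's of
    the right length is used as a placeholder label.
    """
    from .fold import PairProbabilityMatrix

    path = Path(path)
    n = None
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#") and "length=" in first:
            n = int(first.split("length=")[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    if n is None:
        n = int(max(df["i"].max(), df["j"].max()))
    if sequence is None:
        sequence = "A" * n
    p = np.zeros((n, n))
    for _, row in df.iterrows():
        i, j = int(row["i"]) - 1, int(row["j"]) - 1
        p[i, j] = p[j, i] = float(row["probability"])
    return PairProbabilityMatrix(sequence=sequence, p=p)


def read_config(path: Union[str, Path]) -> dict:
    """Flat key=value configuration (YAML subset); later keys win."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a flat mapping")
    for key, val in raw.items():
        if isinstance(val, (dict, list)):
            raise FormatError(f"{path}: nested values not allowed (key {key!r})")
    return raw


def configure_logging(level: str = "INFO") -> None:
    """Log to stderr with levels; CLI commands record parameters here."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
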