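"""From MaP mutation rates to normalized SHAPE reactivity profiles.

The measurement chain implemented here starts where read alignment ends:
per-nucleotide mutation rates and read depths in the reagent-treated
(modified) and untreated channels.  Raw reactivity is the rate difference
(modified minus untreated, the two-condition design without a denatured
control); positions with fewer than 4000 reads in either channel are
masked.  Normalization uses the field-standard 2%/8% rule: the top 2% of
raw values are treated as outliers and the remaining values are divided by
the mean of the next 8%.  Replicate averaging masks nucleotides whose
standard error of the mean reaches 50% of the absolute mean, flagging high
inter-replicate variability.  Direct reactivity, ln(rateMod/rateUnt), is
provided as a model-free alternative readout.

Missing data is NaN in memory and the -999 sentinel on disk.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NO_DATA",
    "MapRateTable",
    "ReactivityProfile",
    "raw_reactivity",
    "normalize_profile",
    "direct_reactivity",
    "average_replicates",
    "MIN_DEPTH",
]

log = logging.getLogger(__name__)

NO_DATA = -999.0
MIN_DEPTH = 4000  # read-depth exclusion threshold
SEM_MASK_FRACTION = 0.5  # mask where SEM >= 50% of |mean|

MASK_NONE = ""
MASK_LOW_DEPTH = "low_depth"
MASK_HIGH_VARIABILITY = "high_replicate_variability"
MASK_PRIMER = "primer_region"


@dataclass
class MapRateTable:
    """Per-position MaP mutation rates and depths for both channels."""

    rate_mod: np.ndarray
    rate_unt: np.ndarray
    depth_mod: np.ndarray
    depth_unt: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.rate_mod, self.rate_unt)]
        depths = [np.asarray(a, dtype=int) for a in (self.depth_mod, self.depth_unt)]
        n = len(arrays[0])
        if any(len(a) != n for a in arrays + depths):
            raise ValueError("rate/depth columns differ in length")
        for a in arrays:
            with np.errstate(invalid="ignore"):
                if np.any((a < 0) | (a > 1)):
                    raise ValueError("mutation rates must lie in [0, 1]")
        if any(np.any(d < 0) for d in depths):
            raise ValueError("read depths must be non-negative")
        self.rate_mod, self.rate_unt = arrays
        self.depth_mod, self.depth_unt = depths

    def __len__(self) -> int:
        return len(self.rate_mod)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self) + 1),
                "rate_mod": self.rate_mod,
                "rate_unt": self.rate_unt,
                "depth_mod": self.depth_mod,
                "depth_unt": self.depth_unt,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MapRateTable":
        df = df.sort_values("position")
        pos = df["position"].to_numpy()
        if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ValueError("positions must be contiguous from 1")
        return cls(
            rate_mod=df["rate_mod"].to_numpy(float),
            rate_unt=df["rate_unt"].to_numpy(float),
            depth_mod=df["depth_mod"].to_numpy(int),
            depth_unt=df["depth_unt"].to_numpy(int),
        )


@dataclass
class ReactivityProfile:
    """Per-nucleotide reactivities over positions 1..n.

    ``values`` holds the working reactivity (raw straight out of
    :func:`raw_reactivity`, normalized after :func:`normalize_profile`);
    NaN marks missing data.  ``mask_reason`` records why a position was
    excluded; masked positions always carry NaN values.
    """

    values: np.ndarray
    stderr: Optional[np.ndarray] = None
    mask_reason: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        n = len(self.values)
        if self.stderr is None:
            self.stderr = np.full(n, np.nan)
        else:
            self.stderr = np.asarray(self.stderr, dtype=float).copy()
            if len(self.stderr) != n:
                raise ValueError("stderr length mismatch")
        if self.mask_reason is None:
            self.mask_reason = np.array([MASK_NONE] * n, dtype=object)
        else:
            self.mask_reason = np.asarray(self.mask_reason, dtype=object).copy()
            if len(self.mask_reason) != n:
                raise ValueError("mask_reason length mismatch")
        # invariant: a masked position carries no value
        masked = self.mask_reason != MASK_NONE
        self.values[masked] = np.nan
        self.stderr[masked] = np.nan

    def __len__(self) -> int:
        return len(self.values)

    @property
    def masked(self) -> np.ndarray:
        return np.isnan(self.values)

    def mask(self, positions: Sequence[int], reason: str) -> "ReactivityProfile":
        """New profile with the given 1-based positions masked."""
        out = ReactivityProfile(self.values, self.stderr, self.mask_reason)
        for p in positions:
            out.mask_reason[p - 1] = reason
            out.values[p - 1] = np.nan
            out.stderr[p - 1] = np.nan
        return out


def raw_reactivity(rates: MapRateTable) -> ReactivityProfile:
    """Raw reactivity = rateMod - rateUnt, depth-filtered.

    Positions where either channel has depth below 4000 reads are masked
    ``low_depth`` (masking, never failure).
    """
    vals = rates.rate_mod - rates.rate_unt
    reasons = np.array([MASK_NONE] * len(rates), dtype=object)
    low = (rates.depth_mod < MIN_DEPTH) | (rates.depth_unt < MIN_DEPTH)
    vals = vals.astype(float)
    vals[low] = np.nan
    reasons[low] = MASK_LOW_DEPTH
    if low.any():
        log.info("masked %d/%d positions below %d reads", int(low.sum()), len(rates), MIN_DEPTH)
    return ReactivityProfile(values=vals, mask_reason=reasons)


def normalize_profile(profile: ReactivityProfile, min_positions: int = 20) -> ReactivityProfile:
    """2%/8% normalization of raw reactivities.

    Unmasked values are ranked descending; the top 2% are set aside as
    outliers and every value is divided by the mean of the next 8%, so the
    mean of that band becomes 1.  Negative raw values are retained (the
    folding engine decides their pseudo-energy treatment).  Masked
    positions pass through untouched.
    """
    vals = profile.values
    data = vals[~np.isnan(vals)]
    if len(data) < min_positions:
        raise ValueError(
            f"too few unmasked positions to normalize ({len(data)} < {min_positions})"
        )
    order = np.sort(data)[::-1]
    n = len(order)
    n_out = int(n * 0.02)
    n_band = max(1, int(n * 0.08))
    band = order[n_out:n_out + n_band]
    scale = float(band.mean())
    if scale <= 0:
        raise ValueError("normalization scale is non-positive (all-zero or negative profile)")
    return ReactivityProfile(
        values=vals / scale,
        stderr=None if profile.stderr is None else profile.stderr / scale,
        mask_reason=profile.mask_reason,
    )


def direct_reactivity(rates: MapRateTable) -> ReactivityProfile:
    """Direct reactivity ln(rateMod/rateUnt).

    Masked wherever either depth is below 4000 reads or either rate is 0
    (the ratio is undefined).
    """
    n = len(rates)
    vals = np.full(n, np.nan)
    reasons = np.array([MASK_NONE] * n, dtype=object)
    for idx in range(n):
        if rates.depth_mod[idx] < MIN_DEPTH or rates.depth_unt[idx] < MIN_DEPTH:
            reasons[idx] = MASK_LOW_DEPTH
        elif rates.rate_mod[idx] == 0 or rates.rate_unt[idx] == 0:
            reasons[idx] = "zero_rate"
        else:
            vals[idx] = math.log(rates.rate_mod[idx] / rates.rate_unt[idx])
    return ReactivityProfile(values=vals, mask_reason=reasons)


def average_replicates(profiles: Sequence[ReactivityProfile]) -> ReactivityProfile:
    """Arithmetic mean and SEM across biological replicates, per nucleotide.

    Positions whose SEM reaches 50% of the absolute mean are masked as
    highly variable between replicates.  With a single replicate the SEM
    is undefined and the rule cannot fire.  A position masked in every
    replicate stays masked; masks never shrink along the pipeline.
    """
    if not profiles:
        raise ValueError("need at least one replicate")
    n = len(profiles[0])
    if any(len(p) != n for p in profiles):
        raise ValueError("replicate profiles differ in length")
    stacked = np.vstack([p.values for p in profiles])
    count = (~np.isnan(stacked)).sum(axis=0)
    import warnings

    with warnings.catch_warnings():
        # all-NaN columns (positions masked in every replicate) are expected
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stacked, axis=0)
        sd = np.nanstd(stacked, axis=0, ddof=1)
    sem = np.where(count >= 2, sd / np.sqrt(np.maximum(count, 1)), np.nan)

    vals = mean.copy()
    errs = sem.copy()
    reasons = np.array([MASK_NONE] * n, dtype=object)
    for idx in range(n):
        if count[idx] == 0:
            # inherit the first recorded reason from the replicates
            for p in profiles:
                if p.mask_reason[idx] != MASK_NONE:
                    reasons[idx] = p.mask_reason[idx]
                    break
            else:
                reasons[idx] = MASK_LOW_DEPTH
            vals[idx] = np.nan
            continue
        if count[idx] >= 2 and not np.isnan(sem[idx]):
            m = abs(mean[idx])
            if sem[idx] >= SEM_MASK_FRACTION * m:
                reasons[idx] = MASK_HIGH_VARIABILITY
                vals[idx] = np.nan
                errs[idx] = np.nan
    return ReactivityProfile(values=vals, stderr=errs, mask_reason=reasons)
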