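"""Per-column residue frequencies and the mean-plus-SD consensus statistic.

A residue is part of the consensus of a column when its frequency f is at
least f_mean + SD, where f_mean and SD are the mean and population standard
deviation of the frequency vector over the 20 canonical residues (zeros
included; f_mean is then exactly 1/20).  With the alternative "observed"
denominator both moments are taken over the residues actually present in the
column.  The threshold is inclusive, so a perfectly uniform column (SD = 0)
returns all residues present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .anchoring import GAP, CoreAlignment
from .errors import InputError
from .records import CANONICAL_RESIDUES

#: Placeholder emitted for a core column with no residue observations.
UNDEFINED_COLUMN = "·"  # middle dot


@dataclass(frozen=True)
class ColumnProfile:
    """Residue counts and frequencies of one alignment column.

    Gaps and ``X`` are excluded from both numerator and denominator, so the
    20 canonical frequencies sum to 1 whenever ``n_non_gap > 0``.
    """

    column: int
    counts: dict[str, int]
    n_non_gap: int

    @property
    def frequencies(self) -> dict[str, float]:
        if self.n_non_gap == 0:
            raise InputError(f"column {self.column}: all-gap column has no frequencies")
        return {aa: self.counts.get(aa, 0) / self.n_non_gap for aa in CANONICAL_RESIDUES}

    @property
    def defined(self) -> bool:
        return self.n_non_gap > 0


@dataclass(frozen=True)
class ConsensusCall:
    """Consensus residues of one column under the f >= f_mean + SD rule,
    ordered by descending frequency (ties alphabetical)."""

    column: int
    threshold: float
    consensus: tuple[tuple[str, float], ...]  # (residue, frequency)

    @property
    def residues(self) -> tuple[str, ...]:
        return tuple(aa for aa, _ in self.consensus)


def column_frequencies(alignment: CoreAlignment, column: int) -> ColumnProfile:
    """Tally one alignment column over the 20 canonical residues."""
    residues = alignment.column(column)
    counts: dict[str, int] = {}
    for aa in residues:
        if aa == GAP or aa == "X":
            continue
        counts[aa] = counts.get(aa, 0) + 1
    return ColumnProfile(column=column, counts=counts, n_non_gap=sum(counts.values()))


def call_consensus(profile: ColumnProfile, denominator: str = "all20") -> ConsensusCall:
    """Apply the mean-plus-SD rule to one column profile.

    ``denominator="all20"`` computes f_mean and SD over the full canonical
    frequency vector (population SD, divide by 20); ``"observed"`` restricts
    both to residues with nonzero frequency.
    """
    if not profile.defined:
        raise InputError(f"column {profile.column}: consensus undefined for all-gap column")
    freqs = profile.frequencies
    if denominator == "all20":
        values = [freqs[aa] for aa in CANONICAL_RESIDUES]
    elif denominator == "observed":
        values = [f for f in freqs.values() if f > 0]
    else:
        raise InputError(f"unknown consensus denominator {denominator!r}")
    mean = sum(values) / len(values)
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / len(values))
    threshold = mean + sd
    # inclusive comparison with a float-roundoff guard so that exact-tie
    # columns (e.g. perfectly uniform: SD = 0, every f == f_mean) qualify
    hits = sorted(
        ((aa, f) for aa, f in freqs.items() if f >= threshold - 1e-12),
        key=lambda item: (-item[1], item[0]),
    )
    return ConsensusCall(column=profile.column, threshold=threshold, consensus=tuple(hits))


def consensus_string(
    alignment: CoreAlignment,
    denominator: str = "all20",
    columns: tuple[int, ...] | None = None,
) -> str:
    """Render the per-position consensus of the core columns.

    Single-residue consensus prints bare (``E``); multi-residue prints
    bracketed and slash-separated in order of abundance (``[R/K]``); a column
    without observations prints the placeholder dot.
    """
    parts = []
    for col in columns if columns is not None else alignment.core_columns:
        profile = column_frequencies(alignment, col)
        if not profile.defined:
            parts.append(UNDEFINED_COLUMN)
            continue
        residues = call_consensus(profile, denominator).residues
        parts.append(residues[0] if len(residues) == 1 else "[" + "/".join(residues) + "]")
    return " ".join(parts)


def frequency_matrix(alignment: CoreAlignment, columns: tuple[int, ...] | None = None) -> pd.DataFrame:
    """20-row frequency matrix (rows = residues, columns = core positions 1..k).

    Undefined (all-gap) columns hold NaN.
    """
    cols = columns if columns is not None else alignment.core_columns
    data = {}
    for pos, col in enumerate(cols, start=1):
        profile = column_frequencies(alignment, col)
        if profile.defined:
            freqs = profile.frequencies
            data[pos] = [freqs[aa] for aa in CANONICAL_RESIDUES]
        else:
            data[pos] = [float("nan")] * 20
    return pd.DataFrame(data, index=list(CANONICAL_RESIDUES))
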