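"""Amino-acid composition tables for single sequences and record collections.

Reported over the 20 standard residues plus Sec (U) and Pyl (O); ambiguity
codes (B/Z/J/X) are tallied in a single ``ambiguous`` bucket so frequencies
stay biologically interpretable while totals are conserved.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io import ProteinRecord
from .motifs import AMBIGUOUS_AA, STANDARD_AA

#: Reporting alphabet, in fixed output order.
REPORT_ALPHABET = tuple(STANDARD_AA) + ("U", "O")
AMBIGUOUS_KEY = "ambiguous"


@dataclass(frozen=True)
class CompositionTable:
    counts: Mapping[str, int]
    total: int

    @property
    def frequencies(self) -> dict[str, float]:
        """Fractions per reporting key; empty when total is 0."""
        if self.total == 0:
            return {}
        return {k: v / self.total for k, v in self.counts.items()}

    def __add__(self, other: "CompositionTable") -> "CompositionTable":
        counts = {k: self.counts[k] + other.counts[k] for k in self.counts}
        return CompositionTable(counts, self.total + other.total)

    def to_frame(self) -> pd.DataFrame:
        freqs = self.frequencies
        return pd.DataFrame(
            {
                "residue": list(self.counts),
                "count": list(self.counts.values()),
                "frequency": [freqs.get(k, 0.0) for k in self.counts],
            }
        )


def _empty_counts() -> dict[str, int]:
    counts = {aa: 0 for aa in REPORT_ALPHABET}
    counts[AMBIGUOUS_KEY] = 0
    return counts


def composition(sequence: str) -> CompositionTable:
    """Exact residue counts of one cleaned sequence.

    Absent residues are reported with count 0 across the full reporting
    alphabet; an empty sequence yields total 0 and no defined frequencies.
    """
    counts = _empty_counts()
    for aa, n in Counter(sequence).items():
        if aa in AMBIGUOUS_AA:
            counts[AMBIGUOUS_KEY] += n
        else:
            counts[aa] += n
    return CompositionTable(counts, len(sequence))


def aggregate_composition(records: Iterable[ProteinRecord]) -> CompositionTable:
    """Elementwise sum of per-record compositions (order-invariant)."""
    total = CompositionTable(_empty_counts(), 0)
    for rec in records:
        total = total + composition(rec.sequence)
    return total
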