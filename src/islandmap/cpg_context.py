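"""Cytosine site enumeration and CpG/CHG/CHH context classification.

Every cytosine that can carry methylation is enumerated on both strands: a C
on the plus strand, and a G on the plus strand (which reads as C on the minus
strand). The context is decided by the two bases immediately downstream in
the strand's own 5'->3' direction:

* next base G                      -> CpG
* next base H, base after that G   -> CHG
* next base H, base after that H   -> CHH   (H = A, C or T)

A site whose context window runs off the sequence end or touches an N is
labeled ``ambiguous`` and excluded from the three-way tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .genome_io import SequenceRecord

CONTEXTS = ("CpG", "CHG", "CHH", "ambiguous")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CSite:
    """One cytosine site.

    ``pos`` is always given in plus-strand (reference) coordinates: for a
    minus-strand site it is the coordinate of the G whose paired base is the
    methylatable C.
    """

    chrom: str
    pos: int
    strand: str  # "+" or "-"
    context: str


def _context_codes(seq_bytes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plus-strand C positions and context labels for a byte-encoded sequence."""
    C, G, N = ord("C"), ord("G"), ord("N")
    n = len(seq_bytes)
    pos = np.nonzero(seq_bytes == C)[0]
    contexts = np.empty(len(pos), dtype=object)
    for k, i in enumerate(pos):
        if i + 1 >= n or seq_bytes[i + 1] == N:
            contexts[k] = "ambiguous"
        elif seq_bytes[i + 1] == G:
            contexts[k] = "CpG"
        elif i + 2 >= n or seq_bytes[i + 2] == N:
            contexts[k] = "ambiguous"
        elif seq_bytes[i + 2] == G:
            contexts[k] = "CHG"
        else:
            contexts[k] = "CHH"
    return pos, contexts


def enumerate_c_sites(record: SequenceRecord) -> list[CSite]:
    """Enumerate every methylatable cytosine on both strands with its context."""
    seq = record.sequence
    fwd = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    sites: list[CSite] = []

    pos, ctx = _context_codes(fwd)
    for p, c in zip(pos, ctx):
        sites.append(CSite(record.name, int(p), "+", c))

    rev = np.frombuffer(reverse_complement(seq).encode("ascii"), dtype=np.uint8)
    n = len(seq)
    pos, ctx = _context_codes(rev)
    for p, c in zip(pos, ctx):
        # position i on the reverse complement is reference position n-1-i
        sites.append(CSite(record.name, n - 1 - int(p), "-", c))

    sites.sort(key=lambda s: (s.pos, s.strand))
    return sites


def cpg_positions(record: SequenceRecord | str) -> np.ndarray:
    """0-based start positions of plus-strand CG dinucleotides, increasing.

    CpG dinucleotides are palindromic, so plus-strand starts enumerate every
    CpG once; downstream island math uses these exclusively.
    """
    seq = record if isinstance(record, str) else record.sequence
    b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if len(b) < 2:
        return np.empty(0, dtype=np.int64)
    mask = (b[:-1] == ord("C")) & (b[1:] == ord("G"))
    return np.nonzero(mask)[0].astype(np.int64)


def count_contexts(records: Iterable[SequenceRecord]) -> pd.DataFrame:
    """Per chromosome x context x strand counts of cytosine sites.

    Returns a tidy DataFrame with columns (chrom, context, strand, count),
    one row per combination, zeros included.
    """
    rows = []
    for rec in records:
        tallies = {(c, s): 0 for c in CONTEXTS for s in "+-"}
        for site in enumerate_c_sites(rec):
            tallies[(site.context, site.strand)] += 1
        for (c, s), n in tallies.items():
            rows.append({"chrom": rec.name, "context": c, "strand": s, "count": n})
    return pd.DataFrame(rows, columns=["chrom", "context", "strand", "count"])


def write_context_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
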