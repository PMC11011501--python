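"""Minimal sequence support: FASTA reading and motif-pattern search.

Positions are 1-based, matching the biological convention used for
residue labels such as R427 throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

#: twenty standard amino acids plus X (unknown)
_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class SequenceRecord:
    identifier: str
    residues: str

    def __post_init__(self):
        self.residues = self.residues.upper()
        for i, c in enumerate(self.residues):
            if c not in _ALPHABET:
                raise ValueError(
                    f"illegal residue character {c!r} at position {i + 1} "
                    f"in {self.identifier}")

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """All records of a FASTA file; empty files are an error."""
    path = Path(path)
    records = [
        SequenceRecord(identifier=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def find_motif(record: SequenceRecord, pattern: str) -> list[int]:
    """1-based start positions of all (possibly overlapping) motif matches.

    The pattern uses one-letter residue codes with X as a wildcard, e.g.
    the catalytic motif HXXXXD or the structural motif XXXXPXXX.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    pattern = pattern.upper()
    for c in pattern:
        if c not in _ALPHABET:
            raise ValueError(f"pattern contains non-residue character {c!r}")
    regex = "".join("." if c == "X" else re.escape(c) for c in pattern)
    # lookahead so overlapping occurrences are all reported
    return [m.start() + 1
            for m in re.finditer(f"(?=({regex}))", record.residues)]
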