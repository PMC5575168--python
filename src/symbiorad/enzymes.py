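"""Restriction enzymes with IUPAC-ambiguity recognition motifs.

A :class:`RestrictionEnzyme` is a named motif plus the 0-based offset of the
top-strand cut within the motif (ApeKI = G|CWGC: motif ``GCWGC``, offset 1).
The built-in table covers the enzymes commonly surveyed for fungal-scale
(~40 Mb) GBS library design; ApeKI, a 5-cutter with one ambiguous position,
is the workhorse for small genomes because the W doubles its site density.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import product

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def expand_motif(motif: str) -> set[str]:
    """Expand an IUPAC motif into the set of concrete A/C/G/T motifs.

    The cardinality of the result is the product of per-position degeneracies
    (``GCWGC`` -> {``GCAGC``, ``GCTGC``}).

    Raises
    ------
    ValueError
        If the motif contains a non-IUPAC character; the offending 0-based
        position is reported.
    """
    for i, ch in enumerate(motif):
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} at position {i} in motif {motif!r}")
    return {"".join(combo) for combo in product(*(IUPAC[c] for c in motif))}


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: recognition motif + top-strand cut offset."""

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not 4 <= len(self.motif) <= 10:
            raise ValueError(f"{self.name}: motif length must be in [4, 10]")
        if not 0 <= self.cut_offset <= len(self.motif):
            raise ValueError(f"{self.name}: cut_offset outside motif")
        expand_motif(self.motif)  # validates characters

    @property
    def expanded(self) -> tuple[str, ...]:
        return tuple(sorted(expand_motif(self.motif)))

    def is_palindromic_set(self) -> bool:
        """True when the expanded motif set is closed under reverse complement
        (all type-II enzymes in the built-in table are)."""
        from .seqs import revcomp

        exp = set(self.expanded)
        return {revcomp(m) for m in exp} == exp


#: Enzymes surveyed for GBS library design on small fungal genomes.
BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {
    e.name: e
    for e in [
        RestrictionEnzyme("ApeKI", "GCWGC", 1),
        RestrictionEnzyme("SbfI", "CCTGCAGG", 2),
        RestrictionEnzyme("PstI", "CTGCAG", 1),
        RestrictionEnzyme("NsiI", "ATGCAT", 1),
        RestrictionEnzyme("BclI", "TGATCA", 1),
        RestrictionEnzyme("BstYI", "RGATCY", 1),
    ]
}


def get_enzyme(name: str) -> RestrictionEnzyme:
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; built-ins: {sorted(BUILTIN_ENZYMES)}"
        ) from None


def load_enzyme_table(path) -> dict[str, RestrictionEnzyme]:
    """Load a user enzyme panel from a TSV with columns name/motif/cut_offset."""
    out: dict[str, RestrictionEnzyme] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["name"]] = RestrictionEnzyme(
                row["name"], row["motif"].upper(), int(row["cut_offset"])
            )
    return out
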