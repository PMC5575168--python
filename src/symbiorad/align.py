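"""Pairwise identity and star-alignment helpers built on edlib.

Identity between two loci is defined as ``1 − editDistance / max(|a|, |b|)``
(global alignment, Levenshtein distance). For near-equal-length RAD loci this
coincides with column-identity measures; normalising by the longer sequence
makes a short read compared with a long merged locus score low, which is the
desired behaviour for an identity threshold. RAD loci are unstranded (GBS
reads come from either fragment end), so all public comparisons take the
better of the two orientations.
"""

from __future__ import annotations

import re

import edlib

from .seqs import revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def identity(a: str, b: str) -> float:
    """Global-alignment identity of two sequences in the given orientation."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def oriented_identity(a: str, b: str) -> tuple[float, str]:
    """Best identity over both orientations of ``b``; returns (identity, '+'|'-')."""
    fwd = identity(a, b)
    rev = identity(a, revcomp(b))
    return (fwd, "+") if fwd >= rev else (rev, "-")


def project_onto(query: str, target: str) -> str:
    """Project ``query`` onto ``target`` coordinates via global alignment.

    Returns a string of length ``len(target)``: the query base aligned to
    each target column, '-' where the query has a deletion. Query insertions
    (bases between target columns) are dropped — adequate for the ≥90%-
    identical short loci this package stacks into star alignments.
    """
    cigar = edlib.align(query, target, mode="NW", task="path")["cigar"]
    out: list[str] = []
    qi = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        if op in "=XM":
            out.append(query[qi : qi + n])
            qi += n
        elif op == "I":  # insertion in query: consumes query only
            qi += n
        else:  # 'D': target column with no query base
            out.append("-" * n)
    row = "".join(out)
    assert len(row) == len(target)
    return row
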