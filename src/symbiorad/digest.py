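"""In-silico restriction digestion and RAD-locus extraction.

The simulation mirrors the standard GBS library design workflow: digest each
genome with an (ambiguity-coded) restriction enzyme, keep fragments inside a
size-selection window, then read the first and last ``read_len`` bases of each
fragment as single-end loci. Fragments shorter than ``merge_len`` would yield
two reads overlapping by more than ~30%, which RAD assembly pipelines merge —
so those fragments contribute a single whole-fragment locus instead.

Defaults follow common practice for small fungal genomes: ApeKI digestion,
200–500 bp size selection, 143 bp loci (150 bp Illumina single-end reads minus
adapter/barcode), 243 bp merge threshold (2·143 − 243 = 43 bp ≈ 30% overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .enzymes import RestrictionEnzyme
from .loci import ConsensusLocus, SampleLociSet
from .seqs import read_fasta, revcomp


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive fragment size-selection window in bp."""

    min_len: int = 200
    max_len: int = 500

    def __post_init__(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("require 0 < min_len <= max_len")

    def __contains__(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len


@dataclass(frozen=True)
class Fragment:
    """A digestion product; ``[start, end)`` on the source sequence."""

    source_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("fragment coordinates inconsistent with sequence length")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SimReadParams:
    """Locus-extraction parameters.

    read_len: usable read length after adapter/barcode removal (143 for a
    150 bp single-end run). merge_len: fragments shorter than this yield one
    whole-fragment locus because their two end-reads would overlap by more
    than ~30% and be merged downstream.
    """

    read_len: int = 143
    merge_len: int = 243

    def __post_init__(self) -> None:
        if self.merge_len >= 2 * self.read_len:
            raise ValueError("merge_len must be < 2*read_len")


def find_cut_positions(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """All cut coordinates of ``enzyme`` on a linear sequence, sorted.

    Both strands are scanned: a bottom-strand recognition site at ``s`` (a
    reverse-complemented motif on the top strand) cuts the top strand at
    ``s + len(motif) − cut_offset``. For enzymes whose expanded motif set is
    closed under reverse complement (all built-ins) forward scanning alone is
    complete and the bottom-strand scan only re-finds the same cuts, which are
    de-duplicated. N never matches; overlapping occurrences each yield a cut.
    """
    seq = sequence.upper()
    k = len(enzyme.motif)
    cuts: set[int] = set()
    forward = set(enzyme.expanded)
    for motif in forward:
        start = seq.find(motif)
        while start != -1:
            cuts.add(start + enzyme.cut_offset)
            start = seq.find(motif, start + 1)
    for motif in {revcomp(m) for m in forward} - forward:
        start = seq.find(motif)
        while start != -1:
            cuts.add(start + k - enzyme.cut_offset)
            start = seq.find(motif, start + 1)
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(sequence: str, enzyme: RestrictionEnzyme, source_id: str = "seq") -> list[Fragment]:
    """Digest a linear sequence into fragments tiling it end to end.

    With cuts c1<…<ck the fragments are [0,c1), [c1,c2), …, [ck,L); their
    concatenation equals the input. Zero-length fragments (coincident cuts)
    are dropped.
    """
    if not sequence:
        return []
    seq = sequence.upper()
    cuts = find_cut_positions(seq, enzyme)
    bounds = [0, *cuts, len(seq)]
    return [
        Fragment(source_id, a, b, seq[a:b])
        for a, b in zip(bounds, bounds[1:])
        if b > a
    ]


def size_select(fragments: list[Fragment], window: SizeWindow) -> list[Fragment]:
    """Keep fragments whose length falls in the inclusive window, order kept."""
    return [f for f in fragments if len(f) in window]


def extract_loci(
    fragment: Fragment, params: SimReadParams, sample_id: str = "sample"
) -> list["SimLocus"]:
    """Extract 1 or 2 RAD loci from a size-selected fragment.

    Fragments shorter than ``merge_len`` give one whole-fragment locus;
    otherwise the first and last ``read_len`` bases are taken. The 3' (suffix)
    locus is stored reverse-complemented so both loci read inward from a cut
    site, as GBS sequencing from either fragment end would produce them;
    downstream comparisons are therefore orientation-insensitive.
    """
    n = len(fragment)
    if n < params.read_len:
        raise ValueError(f"fragment length {n} < read_len {params.read_len}")
    base = f"{fragment.source_id}:{fragment.start}-{fragment.end}"
    if n < params.merge_len:
        return [
            SimLocus(sample_id, f"{base}:whole", fragment.sequence, "whole_fragment",
                     fragment.source_id, fragment.start, fragment.end)
        ]
    return [
        SimLocus(sample_id, f"{base}:start", fragment.sequence[: params.read_len],
                 "fragment_start", fragment.source_id, fragment.start, fragment.end),
        SimLocus(sample_id, f"{base}:end", revcomp(fragment.sequence[-params.read_len:]),
                 "fragment_end", fragment.source_id, fragment.start, fragment.end),
    ]


@dataclass(frozen=True)
class SimLocus:
    """A simulated RAD locus with its source-fragment coordinates."""

    sample_id: str
    locus_id: str
    sequence: str
    origin: str  # fragment_start | fragment_end | whole_fragment
    source_id: str
    frag_start: int
    frag_end: int


def simulate_rad_sample(
    genome,
    enzyme: RestrictionEnzyme,
    window: SizeWindow = SizeWindow(),
    params: SimReadParams = SimReadParams(),
    sample_id: str = "sample",
) -> SampleLociSet:
    """Deterministic digestion → size selection → locus extraction per contig.

    ``genome`` may be a FASTA path or a list of ``(contig_id, sequence)``.
    The result enters the pipeline at the consensus-locus stage, i.e. as if
    reads had already been clustered and consensus-called per sample.
    """
    contigs = genome if isinstance(genome, list) else read_fasta(genome)
    if not contigs:
        raise ValueError("genome has no sequences")
    loci: list[ConsensusLocus] = []
    for contig_id, seq in contigs:
        for frag in size_select(digest(seq, enzyme, contig_id), window):
            for sl in extract_loci(frag, params, sample_id):
                loci.append(ConsensusLocus(sl.locus_id, sl.sequence, depth=1))
    if not loci:
        warnings.warn(f"sample {sample_id}: no fragments in the size window", stacklevel=2)
    return SampleLociSet(sample_id, "simulated", loci)


def enzyme_survey(
    genome, enzymes: list[RestrictionEnzyme], window: SizeWindow = SizeWindow()
) -> pd.DataFrame:
    """Count in-window fragments per enzyme — the screen used to pick the
    enzyme whose site density fits the genome size (one row per enzyme)."""
    if not enzymes:
        raise ValueError("need at least one enzyme")
    contigs = genome if isinstance(genome, list) else read_fasta(genome)
    rows = []
    for enz in enzymes:
        total = in_window = 0
        for contig_id, seq in contigs:
            frags = digest(seq, enz, contig_id)
            total += len(frags)
            in_window += len(size_select(frags, window))
        rows.append(
            {"enzyme": enz.name, "motif": enz.motif,
             "fragments_total": total, "fragments_in_window": in_window}
        )
    return pd.DataFrame(rows)
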