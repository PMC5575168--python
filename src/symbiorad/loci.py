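"""Per-sample locus containers.

A :class:`SampleLociSet` holds the consensus loci recovered for one sample —
either simulated directly from a genome (they enter the pipeline at the stage
where real data has been demultiplexed, filtered, within-sample clustered and
consensus-called) or produced by :func:`symbiorad.clustering.within_sample_cluster`
from reads. It is the unit the reference filter classifies and the input to
across-sample clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqs import write_fasta


@dataclass
class ConsensusLocus:
    locus_id: str
    sequence: str
    depth: int = 1
    #: ground-truth source label when known (synthetic data), else None
    provenance: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SampleLociSet:
    sample_id: str
    origin: str = "simulated"  # "simulated" | "empirical"
    loci: list[ConsensusLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [l.locus_id for l in self.loci]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate locus ids in sample {self.sample_id}")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def to_fasta(self, path) -> None:
        """Write loci with structured headers ``sample|locus|origin|depth``."""
        write_fasta(
            path,
            (
                (f"{self.sample_id}|{l.locus_id}|{self.origin}|depth={l.depth}", l.sequence)
                for l in self.loci
            ),
        )

    @classmethod
    def from_fasta(cls, path, sample_id: str | None = None) -> "SampleLociSet":
        from .seqs import read_fasta

        loci = []
        sid, origin = sample_id, "empirical"
        for name, seq in read_fasta(path):
            parts = name.split("|")
            if len(parts) >= 4:
                sid = sid or parts[0]
                origin = parts[2]
                depth = int(parts[3].split("=")[1])
                loci.append(ConsensusLocus(parts[1], seq, depth))
            else:
                sid = sid or "sample"
                loci.append(ConsensusLocus(name, seq))
        return cls(sid or "sample", origin, loci)
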