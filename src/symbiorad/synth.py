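"""Synthetic holobiont genomes and reads.

This module generates everything the pipeline consumes, at desk scale:
a haploid target genome (a stand-in for a ~40 Mb lichen-fungus assembly,
scaled down, typically to ~0.2–1 Mb), congeneric genomes diverged along a
dated tree (branch lengths in Myr, substitutions at a per-site-per-Myr rate),
contaminant genomes (algal / bacterial symbionts of the holobiont), and
error-bearing single-end reads.

Two read protocols are available:

* ``"rad"`` (default) — each source genome is digested, size-selected and
  its extracted loci sequenced at Poisson depth, emulating a GBS library
  built from total metagenomic DNA. Reads span whole loci (the >30% overlap
  merge is realized at extraction time), so read length ranges from
  ``read_len`` up to ``merge_len − 1``.
* ``"shotgun"`` — fixed-length reads with uniform start positions, for
  coverage-style simulations.

Every operation is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .digest import SimReadParams, SizeWindow, simulate_rad_sample
from .enzymes import RestrictionEnzyme, get_enzyme
from .seqs import revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_genome(length: int, gc_content: float = 0.5, seed=0) -> str:
    """An i.i.d. random genome with P(G)=P(C)=gc/2, P(A)=P(T)=(1−gc)/2."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must be in [0, 1]")
    rng = _as_rng(seed)
    at, gc = (1 - gc_content) / 2, gc_content / 2
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return _BASES[idx].tobytes().decode()


def evolve_genome(
    genome: str,
    branch_length_myr: float,
    substitution_rate: float,
    indel_rate: float = 0.0,
    seed=0,
) -> str:
    """Evolve a genome along one branch.

    Substitutions: each site mutates with probability
    ``min(rate·t, 0.75)`` to a uniformly chosen *different* base (a
    Jukes–Cantor-like uniform model — adequate for identity-threshold
    behaviour, which depends on overall divergence, not on the exact
    substitution process). Indels: events at ``indel_rate·t`` per site,
    insertion or deletion with equal probability, lengths uniform on 1–5.
    """
    if substitution_rate < 0 or indel_rate < 0 or branch_length_myr < 0:
        raise ValueError("rates and branch lengths must be non-negative")
    rng = _as_rng(seed)
    p_sub = min(substitution_rate * branch_length_myr, 0.75)
    arr = np.frombuffer(genome.encode(), dtype="S1").copy()
    if p_sub > 0:
        hits = np.nonzero(rng.random(arr.size) < p_sub)[0]
        if hits.size:
            old = np.array([_BASE_INDEX[b] for b in arr[hits].tobytes().decode()])
            # shift by 1–3 mod 4 => always a different base, uniform over the other three
            new = (old + rng.integers(1, 4, size=hits.size)) % 4
            arr[hits] = _BASES[new]
    seq = arr.tobytes().decode()
    p_indel = min(indel_rate * branch_length_myr, 0.5)
    if p_indel > 0:
        n_events = rng.binomial(len(seq), p_indel)
        if n_events:
            positions = np.sort(rng.integers(0, len(seq) + 1, size=n_events))[::-1]
            for pos in positions:  # right-to-left keeps earlier coordinates valid
                size = int(rng.integers(1, 6))
                if rng.random() < 0.5:
                    ins = _BASES[rng.integers(0, 4, size=size)].tobytes().decode()
                    seq = seq[:pos] + ins + seq[pos:]
                else:
                    seq = seq[:pos] + seq[pos + size:]
    return seq


def simulate_tree_genomes(
    root_genome: str,
    tree_newick: str,
    substitution_rate: float,
    indel_rate: float = 0.0,
    seed=0,
) -> dict[str, str]:
    """Evolve a root genome along a Newick tree (branch lengths in Myr).

    Sister tips share the mutations accumulated on their common ancestral
    branches, so the tip genomes carry genuine phylogenetic signal. Returns
    ``{tip_label: genome}``. Deterministic under seed.
    """
    import dendropy

    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    rng = _as_rng(seed)
    out: dict[str, str] = {}

    def walk(node, genome: str) -> None:
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            child_seed = int(rng.integers(0, 2**31 - 1))
            g = evolve_genome(genome, bl, substitution_rate, indel_rate, child_seed)
            if child.is_leaf():
                out[child.taxon.label.replace(" ", "_")] = g
            else:
                walk(child, g)

    walk(tree.seed_node, root_genome)
    return out


@dataclass
class Contaminant:
    """A non-target genome in the metagenomic pool (alga, bacterium, ...)."""

    label: str
    genome: str
    weight: float


@dataclass
class MetagenomeReads:
    reads: list[tuple[str, str]]  # (name, sequence); name = label|locus|index
    #: per-source read counts (ground truth for filter benchmarking)
    source_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)


def default_contaminants(target_len: int, seed=0) -> list[Contaminant]:
    """A realistic holobiont mixture: the target fungus contributes ~50% of
    the pool, an algal photobiont ~30% and a bacterial fraction ~20% — chosen
    to echo metagenomic GBS libraries where only about half the loci derive
    from the target fungus."""
    rng = _as_rng(seed)
    return [
        Contaminant("alga", random_genome(target_len, 0.6, rng), 0.3),
        Contaminant("bacteria", random_genome(max(target_len // 2, 1000), 0.5, rng), 0.2),
    ]


def simulate_metagenome_reads(
    target_genome: str,
    contaminants: list[Contaminant],
    coverage: float = 30.0,
    read_len: int = 150,
    error_rate: float = 0.001,
    seed=0,
    protocol: str = "rad",
    enzyme: RestrictionEnzyme | None = None,
    window: SizeWindow = SizeWindow(),
    sim_params: SimReadParams = SimReadParams(),
) -> MetagenomeReads:
    """Simulate a single-end metagenomic sequencing pool.

    The per-read source is chosen by weight (the target's weight is
    1 − Σ contaminant weights); each read is reverse-complemented with
    probability 1/2 and sequencing errors substitute bases i.i.d. at
    ``error_rate``. Read names record the true source (``label|locus|i``),
    giving ground truth for filter benchmarking. ``coverage`` is the expected
    depth per target locus (rad) or per target base (shotgun).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    w_cont = sum(c.weight for c in contaminants)
    if w_cont >= 1.0 + 1e-9:
        raise ValueError("contaminant weights must sum to < 1")
    w_target = 1.0 - w_cont
    rng = _as_rng(seed)
    enzyme = enzyme or get_enzyme("ApeKI")

    sources: list[tuple[str, float, list[tuple[str, str]]]] = []
    if protocol == "rad":
        tgt = simulate_rad_sample([("target", target_genome)], enzyme, window, sim_params, "target")
        tgt_pool = [(l.locus_id, l.sequence) for l in tgt]
        if not tgt_pool:
            raise ValueError("target genome yields no in-window loci")
        sources.append(("target", w_target, tgt_pool))
        for c in contaminants:
            cs = simulate_rad_sample([(c.label, c.genome)], enzyme, window, sim_params, c.label)
            pool = [(l.locus_id, l.sequence) for l in cs] or [(f"{c.label}:none", c.genome[:read_len])]
            sources.append((c.label, c.weight, pool))
        n_reads = int(round(coverage * len(tgt_pool) / w_target))
    elif protocol == "shotgun":
        sources.append(("target", w_target, [("target", target_genome)]))
        for c in contaminants:
            sources.append((c.label, c.weight, [(c.label, c.genome)]))
        n_reads = int(round(coverage * len(target_genome) / read_len / w_target))
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    weights = np.array([w for _, w, _ in sources])
    weights = weights / weights.sum()
    choice = rng.choice(len(sources), size=n_reads, p=weights)
    reads: list[tuple[str, str]] = []
    counts = {label: 0 for label, _, _ in sources}
    for i in range(n_reads):
        label, _, pool = sources[choice[i]]
        counts[label] += 1
        if protocol == "rad":
            locus_id, seq = pool[int(rng.integers(0, len(pool)))]
        else:
            locus_id, src = pool[0]
            start = int(rng.integers(0, max(len(src) - read_len, 0) + 1))
            seq = src[start : start + read_len]
            locus_id = f"{locus_id}:{start}"
        if rng.random() < 0.5:
            seq = revcomp(seq)
        if error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
            if hits.size:
                old = np.array([_BASE_INDEX.get(b, 0) for b in arr[hits].tobytes().decode()])
                arr[hits] = _BASES[(old + rng.integers(1, 4, size=hits.size)) % 4]
            seq = arr.tobytes().decode()
        reads.append((f"{label}|{locus_id}|{i}", seq))
    return MetagenomeReads(reads, counts)
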