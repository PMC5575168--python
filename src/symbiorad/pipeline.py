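"""End-to-end workflows: the simulated arm, the empirical arm, and hybrids.

Two workflows mirror how reference-guided RAD studies of holobionts are run:

* **simulated arm** — genomes (real assemblies or synthetic congeners
  evolved along a dated tree) are digested in silico; the extracted loci
  enter across-sample clustering directly, as if per-sample consensus
  calling had already happened.
* **empirical arm** — single-end reads per sample are within-sample
  clustered to consensus loci, the loci are filtered against a reference
  genome to keep the target symbiont's share of the metagenomic pool, and
  (in hybrid mode) merged with simulated samples before across-sample
  clustering.

Both arms end with sample filtering (two-pass), unlinked-SNP extraction,
summary statistics, a shared-loci matrix and an NJ topology check; every run
writes a machine-readable manifest sufficient to re-run bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import analysis, clustering, io, reffilter, synth
from .digest import SimReadParams, SizeWindow, simulate_rad_sample
from .enzymes import get_enzyme
from .loci import SampleLociSet


@dataclass
class PipelineConfig:
    """One configuration object for every stage; defaults are the standard
    parameter set for this protocol (ApeKI, 200–500 bp window, 143/243 bp
    read/merge, Wclust 0.90, Mindepth 4, MinCov 4, <5000-loci sample
    removal, 20% missing-data cutoff, 5 PCs)."""

    mode: str = "simulated"  # simulated | empirical | hybrid
    outdir: str = "symbiorad_out"
    seed: int = 0
    # digestion
    enzyme: str = "ApeKI"
    min_len: int = 200
    max_len: int = 500
    read_len: int = 143
    merge_len: int = 243
    # clustering
    identity_threshold: float = 0.90
    min_depth: int = 4
    min_samples: int = 4
    min_loci_per_sample: int = 5000
    # synthetic genomes (used when no genome/reads paths are given)
    genome_len: int = 200_000
    gc_content: float = 0.5
    tree: str | None = None
    substitution_rate: float = 0.005
    indel_rate: float = 0.0
    n_samples: int = 6
    # read simulation / empirical inputs
    genome_paths: list[str] = field(default_factory=list)
    fastq_paths: dict[str, str] = field(default_factory=dict)
    reference_path: str | None = None
    coverage: float = 30.0
    error_rate: float = 0.001
    contaminant_weight: float = 0.5
    # reference filter
    min_identity: float = 0.85
    min_locus_coverage: float = 0.50
    # DAPC
    dapc_groups: dict[str, str] = field(default_factory=dict)
    max_missing: float = 0.20
    n_pcs: int = 5

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @property
    def window(self) -> SizeWindow:
        return SizeWindow(self.min_len, self.max_len)

    @property
    def sim_params(self) -> SimReadParams:
        return SimReadParams(self.read_len, self.merge_len)

    @property
    def cluster_params(self) -> clustering.ClusterParams:
        return clustering.ClusterParams(
            self.identity_threshold, self.min_depth, self.min_samples, self.min_loci_per_sample
        )

    @property
    def filter_params(self) -> reffilter.RefFilterParams:
        return reffilter.RefFilterParams(
            min_identity=self.min_identity, min_locus_coverage=self.min_locus_coverage
        )

    @property
    def dapc_config(self) -> analysis.DapcConfig:
        return analysis.DapcConfig(self.max_missing, self.n_pcs)


@dataclass
class ArmResult:
    samples: list[SampleLociSet]
    clusters: list[clustering.LocusCluster]
    snps: clustering.SnpMatrix
    stats: dict
    report: pd.DataFrame | None = None
    newick: str | None = None
    outdir: str | None = None


def _synthesize_genomes(config: PipelineConfig) -> dict[str, str]:
    """Root genome + congeners along the configured tree (or identical
    copies when no tree is given)."""
    root = synth.random_genome(config.genome_len, config.gc_content, config.seed)
    if config.tree:
        return synth.simulate_tree_genomes(
            root, config.tree, config.substitution_rate, config.indel_rate, config.seed + 1
        )
    return {f"S{i}": root for i in range(config.n_samples)}


def _load_genomes(config: PipelineConfig) -> dict[str, str]:
    from .seqs import read_fasta

    if config.genome_paths:
        out = {}
        for p in config.genome_paths:
            contigs = read_fasta(p)
            out[Path(p).stem] = "".join(seq for _, seq in contigs)
        return out
    return _synthesize_genomes(config)


def _finish(
    config: PipelineConfig,
    samples: list[SampleLociSet],
    report: pd.DataFrame | None = None,
) -> ArmResult:
    """Shared tail of both arms: cluster, filter samples (two-pass), extract
    SNPs, stats, and the NJ topology check."""
    retained, clusters = clustering.filter_samples(samples, config.cluster_params)
    sample_ids = [s.sample_id for s in retained]
    snps = clustering.extract_unlinked_snps(clusters, sample_ids, config.seed)
    stats = clustering.dataset_stats(clusters, snps)
    newick = None
    if len(sample_ids) >= 3 and snps.shape[1] > 0:
        try:
            newick = analysis.nj_tree(snps)
        except ValueError:
            newick = None
    return ArmResult(retained, clusters, snps, stats, report, newick)


def _write_outputs(config: PipelineConfig, result: ArmResult, stage_counts: dict) -> None:
    """Write the artifact set + a manifest that suffices to re-run
    bit-identically (parameters, seed, per-stage counts)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample_ids = [s.sample_id for s in result.samples]
    for s in result.samples:
        s.to_fasta(outdir / f"{s.sample_id}.loci.fasta")
    io.export_matrices(result.snps, result.clusters, result.newick, outdir)
    shared = analysis.shared_loci_matrix(result.clusters, sample_ids)
    io.write_tsv(shared.to_frame().round(6), outdir / "shared_loci.tsv")
    flat_stats = {k: v for k, v in result.stats.items() if k != "loci_per_sample"}
    pd.DataFrame([flat_stats]).to_csv(outdir / "stats.tsv", sep="\t", index=False)
    if result.report is not None:
        result.report.to_csv(outdir / "report.tsv", sep="\t", index=False)
    if config.dapc_groups:
        dapc = analysis.dapc_fit(result.snps, config.dapc_groups, config.dapc_config)
        dapc.membership.round(8).to_csv(outdir / "dapc_membership.tsv", sep="\t")
    manifest = {
        "config": asdict(config),
        "stage_counts": stage_counts,
        "final": flat_stats | {"loci_per_sample": result.stats["loci_per_sample"]},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    result.outdir = str(outdir)


def run_simulated_arm(
    config: PipelineConfig, genomes: dict[str, str] | None = None, write: bool = True
) -> ArmResult:
    """Digest each genome in silico and run the shared clustering tail."""
    genomes = genomes if genomes is not None else _load_genomes(config)
    if not genomes:
        raise ValueError("no genomes to digest")
    enzyme = get_enzyme(config.enzyme)
    samples = [
        simulate_rad_sample([(sid, g)], enzyme, config.window, config.sim_params, sid)
        for sid, g in sorted(genomes.items())
    ]
    counts = {"simulated_loci_per_sample": {s.sample_id: len(s) for s in samples}}
    result = _finish(config, samples)
    if write:
        _write_outputs(config, result, counts)
    return result


def run_empirical_arm(
    config: PipelineConfig,
    reads_by_sample: dict[str, list[tuple[str, str]]] | None = None,
    reference: list[tuple[str, str]] | None = None,
    simulated_samples: list[SampleLociSet] | None = None,
    write: bool = True,
) -> ArmResult:
    """Reads → within-sample consensus loci → reference filter → clustering.

    ``reads_by_sample`` maps sample id to (name, sequence) reads (loaded
    from the configured FASTQ paths when omitted); ``reference`` is the
    target-genome contig list (or loaded from ``reference_path``). In hybrid
    mode the filtered empirical samples are merged with ``simulated_samples``
    before across-sample clustering. The per-sample report carries the four
    diagnostic columns: raw reads, within-sample clusters, mapped (target)
    loci, final loci.
    """
    from .seqs import read_fasta, read_fastq

    if reads_by_sample is None:
        if not config.fastq_paths:
            raise ValueError("empirical arm requires reads")
        reads_by_sample = {
            sid: list(read_fastq(path)) for sid, path in sorted(config.fastq_paths.items())
        }
    if reference is None:
        if not config.reference_path:
            raise ValueError("empirical arm requires a reference genome")
        reference = read_fasta(config.reference_path)
    index = reffilter.build_reference_index(reference)
    fparams = config.filter_params
    cparams = config.cluster_params

    rows = []
    filtered: list[SampleLociSet] = []
    for sid in sorted(reads_by_sample):
        reads = reads_by_sample[sid]
        sample = clustering.within_sample_cluster(reads, cparams, sid, origin="empirical")
        target, _off, frac, _assign = reffilter.filter_loci(sample, index, fparams)
        filtered.append(target)
        rows.append(
            {"sample": sid, "origin": "empirical", "raw_reads": len(reads),
             "within_sample_clusters": len(sample), "mapped_loci": len(target),
             "mapped_fraction": round(frac, 6) if frac is not None else None}
        )
    pool = [s for s in filtered if len(s) > 0]
    if simulated_samples:
        for s in simulated_samples:
            rows.append(
                {"sample": s.sample_id, "origin": "simulated", "raw_reads": None,
                 "within_sample_clusters": None, "mapped_loci": len(s),
                 "mapped_fraction": None}
            )
        pool = pool + list(simulated_samples)
    result = _finish(config, pool)
    final_counts = result.stats["loci_per_sample"]
    for r in rows:
        r["final_loci"] = final_counts.get(r["sample"], 0)
    result.report = pd.DataFrame(rows)
    if write:
        _write_outputs(config, result, {"per_sample": rows})
    return result
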