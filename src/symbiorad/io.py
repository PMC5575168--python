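"""Flat-file export/import: relaxed PHYLIP, ``.loci`` cluster files, TSV.

All writers are deterministic (stable ordering, no timestamps) so that
re-running a pipeline with the same configuration and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import numpy as np

from .clustering import LocusCluster, SnpMatrix


def write_phylip(snps: SnpMatrix, path) -> None:
    """Relaxed PHYLIP: names of any length, separated from sites by spaces."""
    width = max((len(s) for s in snps.samples), default=0) + 2
    with open(path, "w") as fh:
        fh.write(f"{len(snps.samples)} {snps.shape[1]}\n")
        for i, name in enumerate(snps.samples):
            fh.write(name.ljust(width) + "".join(snps.data[i]) + "\n")


def read_phylip(path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        n, m = map(int, fh.readline().split())
        names, rows = [], []
        for _ in range(n):
            name, seq = fh.readline().split(maxsplit=1)
            names.append(name)
            rows.append(list(seq.strip()))
    data = np.array(rows, dtype="<U1") if rows else np.empty((n, m), dtype="<U1")
    return names, data


def write_snp_tsv(snps: SnpMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(f"{c}:{col}" for c, col in snps.site_ids) + "\n")
        for i, name in enumerate(snps.samples):
            fh.write(name + "\t" + "\t".join(snps.data[i]) + "\n")


def write_loci_file(clusters: list[LocusCluster], path) -> None:
    """pyRAD-like ``.loci`` flat text: per cluster, one aligned row per
    sample and a closing annotation line marking variable columns with '*'."""
    with open(path, "w") as fh:
        for cl in clusters:
            width = max(len(s) for s in cl.alignment) + 2
            for sample in sorted(cl.alignment):
                fh.write(sample.ljust(width) + cl.alignment[sample] + "\n")
            marks = ["-"] * cl.aligned_length
            for col in cl.variable_columns:
                marks[col] = "*"
            flag = " paralog" if cl.paralog_flagged else ""
            fh.write("//".ljust(width) + "".join(marks) + f"|{cl.cluster_id}{flag}|\n")


def write_tsv(df, path) -> None:
    df.to_csv(path, sep="\t")


def export_matrices(snps: SnpMatrix, clusters: list[LocusCluster], newick: str | None, outdir) -> dict:
    """Write the standard artifact set; returns {name: path}."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phylip": outdir / "unlinked_snps.phy",
        "snps_tsv": outdir / "unlinked_snps.tsv",
        "loci": outdir / "clusters.loci",
    }
    write_phylip(snps, paths["phylip"])
    write_snp_tsv(snps, paths["snps_tsv"])
    write_loci_file(clusters, paths["loci"])
    if newick is not None:
        paths["newick"] = outdir / "nj_tree.nwk"
        with open(paths["newick"], "w") as fh:
            fh.write(newick.strip() + "\n")
    return {k: str(v) for k, v in paths.items()}
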