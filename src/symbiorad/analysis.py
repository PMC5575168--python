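"""Comparative analytics over clustered RAD loci.

Covers the downstream questions this kind of dataset is built for:

* how many loci pairs of samples share (:func:`shared_loci_matrix`);
* whether locus/fragment recovery decays with divergence time from the
  reference, tested by ordinary least squares
  (:func:`regress_counts_vs_divergence`);
* a neighbor-joining topology check on the unlinked-SNP matrix using
  p-distances with pairwise deletion (:func:`nj_tree`) — an internal
  substitute for external maximum-likelihood inference;
* DAPC — discriminant analysis of principal components — for population
  structure: PCA reduction of the 0/1-coded haploid SNP matrix followed by a
  linear discriminant analysis on the retained PC scores, yielding
  per-sample group-membership probabilities (:func:`dapc_fit`,
  :func:`predict_membership`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import LocusCluster, SnpMatrix, per_sample_locus_counts


# ---------------------------------------------------------------------------
# shared loci


@dataclass
class SharedLociMatrix:
    samples: list[str]
    proportions: np.ndarray  # symmetric, diagonal 1 for non-empty samples
    totals: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.samples, columns=self.samples)


def shared_loci_matrix(clusters: list[LocusCluster], samples: list[str]) -> SharedLociMatrix:
    """Pairwise proportion of shared loci.

    entry(i, j) = |clusters containing both| / min(|loci_i|, |loci_j|) —
    min-normalisation keeps the value at 1.0 for nested locus sets. Samples
    with no loci get NaN rows/columns (flagged missing).
    """
    totals = per_sample_locus_counts(clusters)
    membership = {s: set() for s in samples}
    for cl in clusters:
        for s in cl.members:
            if s in membership:
                membership[s].add(cl.cluster_id)
    n = len(samples)
    mat = np.full((n, n), np.nan)
    for i, a in enumerate(samples):
        for j, b in enumerate(samples):
            na, nb = len(membership[a]), len(membership[b])
            if na == 0 or nb == 0:
                continue
            mat[i, j] = len(membership[a] & membership[b]) / min(na, nb)
    return SharedLociMatrix(list(samples), mat, {s: totals.get(s, 0) for s in samples})


# ---------------------------------------------------------------------------
# divergence regression


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def regress_counts_vs_divergence(counts, times) -> RegressionResult:
    """OLS of per-sample locus/fragment counts on divergence time (Myr).

    Accepts aligned sequences of y (counts) and x (times), or two dicts
    keyed by sample. Returns slope, intercept, R² and the two-sided p-value
    of the slope.
    """
    if isinstance(counts, dict):
        keys = sorted(set(counts) & set(times))
        y = np.array([counts[k] for k in keys], dtype=float)
        x = np.array([times[k] for k in keys], dtype=float)
    else:
        y = np.asarray(counts, dtype=float)
        x = np.asarray(times, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in divergence times")
    res = stats.linregress(x, y)
    return RegressionResult(res.slope, res.intercept, res.rvalue**2, res.pvalue, len(x))


# ---------------------------------------------------------------------------
# neighbor joining


def p_distance_matrix(snps: SnpMatrix) -> tuple[np.ndarray, list[str]]:
    """Pairwise p-distances with pairwise deletion of missing sites.

    A site contributes to a pair only when both samples have a base (not 'N'
    and not '-'). A pair with zero overlapping sites is an error naming the
    pair — the matrix would otherwise be silently undefined.
    """
    ok = (snps.data != "N") & (snps.data != "-")
    n = len(snps.samples)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no overlapping sites for pair ({snps.samples[i]}, {snps.samples[j]})"
                )
            diff = int((snps.data[i][both] != snps.data[j][both]).sum())
            dist[i, j] = dist[j, i] = diff / m
    return dist, list(snps.samples)


def nj_tree(snps_or_matrix, labels: list[str] | None = None) -> str:
    """Canonical neighbor-joining; returns an unrooted Newick string.

    Accepts a SnpMatrix (p-distances computed with pairwise deletion) or a
    precomputed square distance matrix + labels. Negative branch lengths are
    clamped to 0.
    """
    if isinstance(snps_or_matrix, SnpMatrix):
        dist, labels = p_distance_matrix(snps_or_matrix)
    else:
        dist = np.asarray(snps_or_matrix, dtype=float).copy()
        if labels is None:
            raise ValueError("labels required with a raw distance matrix")
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 samples")
    nodes = [f"{lab}" for lab in labels]
    d = dist.copy()
    active = list(range(n))
    newick = {i: nodes[i] for i in active}
    while len(active) > 2:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best, best_q = None, np.inf
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        k = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for x in active:
            if x not in (i, j):
                d[k, x] = d[x, k] = 0.5 * (d[i, x] + d[j, x] - d[i, j])
        newick[k] = f"({newick[i]}:{li:.6f},{newick[j]}:{lj:.6f})"
        active = [x for x in active if x not in (i, j)] + [k]
    i, j = active
    return f"({newick[i]}:{max(d[i, j], 0.0):.6f},{newick[j]}:0.0);"


def tree_splits(newick: str) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each as the smaller
    taxon side — for topology comparisons."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    all_taxa = {t.label for t in tree.taxon_namespace}
    out = set()
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        side = {
            t.label
            for t in tree.taxon_namespace
            if edge.bipartition.leafset_bitmask & tree.taxon_namespace.taxon_bitmask(t)
        }
        if 1 < len(side) < len(all_taxa) - 1:
            out.add(frozenset(min(side, all_taxa - side, key=lambda s: (len(s), sorted(s)))))
    return out


# ---------------------------------------------------------------------------
# DAPC


@dataclass(frozen=True)
class DapcConfig:
    """DAPC settings: drop sites with more than ``max_missing_per_locus``
    missing data, impute the rest with per-site means, retain ``n_pcs``
    principal components and ``n_da`` discriminant axes (default: one fewer
    than the number of groups)."""

    max_missing_per_locus: float = 0.20
    n_pcs: int = 5
    n_da: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing_per_locus < 1:
            raise ValueError("max_missing in [0, 1)")
        if self.n_pcs < 1:
            raise ValueError("n_pcs >= 1")


@dataclass
class DapcResult:
    retained_sites: list[tuple[str, int]]
    groups: list[str]
    sample_ids: list[str]
    pc_mean: np.ndarray
    pc_components: np.ndarray  # (n_pcs, n_sites)
    da_axes: np.ndarray  # (n_pcs, n_da)
    class_means_da: np.ndarray  # (n_groups, n_da)
    pooled_cov_da: np.ndarray  # (n_da, n_da)
    coords: np.ndarray  # per-sample DA coordinates
    membership: pd.DataFrame  # samples × groups, rows sum to 1
    site_means: np.ndarray = field(default=None)  # training imputation means
    major_alleles: list[str] = field(default_factory=list)


def _encode_sites(
    snps: SnpMatrix, max_missing: float
) -> tuple[np.ndarray, list[tuple[str, int]], np.ndarray, list[str]]:
    """0/1 haploid coding by major allele; multi-allelic sites collapse to
    most-frequent-alternate (flagged via warning). Gaps and 'N' are missing.
    Sites above the missing-fraction cutoff are dropped."""
    data = snps.data
    n_samples = len(snps.samples)
    cols, sites, means, majors = [], [], [], []
    multi = 0
    for j in range(data.shape[1]):
        col = data[:, j]
        observed = col[(col != "N") & (col != "-")]
        if n_samples and (n_samples - len(observed)) / n_samples > max_missing:
            continue
        alleles = pd.Series(observed).value_counts()
        if len(alleles) < 2:
            continue
        if len(alleles) > 2:
            multi += 1
        major = alleles.index[0]
        coded = np.full(n_samples, np.nan)
        mask = (col != "N") & (col != "-")
        coded[mask] = (col[mask] != major).astype(float)
        cols.append(coded)
        sites.append(snps.site_ids[j])
        means.append(np.nanmean(coded))
        majors.append(str(major))
    if multi:
        warnings.warn(f"{multi} multi-allelic sites collapsed to 0/1", stacklevel=3)
    X = np.column_stack(cols) if cols else np.empty((n_samples, 0))
    return X, sites, np.asarray(means), majors


def dapc_fit(
    snps: SnpMatrix, labels: dict[str, str] | list[str], config: DapcConfig = DapcConfig()
) -> DapcResult:
    """Fit a DAPC: PCA on the imputed, centered 0/1 matrix, then LDA on the
    retained PC scores.

    The discriminant step maximises between-group over within-group scatter
    on the PC scores (pooled covariance); membership probabilities come from
    Gaussian class-conditional densities on the discriminant axes with equal
    priors, so each row of ``membership`` sums to 1.
    """
    from sklearn.decomposition import PCA

    if isinstance(labels, dict):
        y = [labels[s] for s in snps.samples]
    else:
        y = list(labels)
    groups = sorted(set(y))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    X, sites, site_means, majors = _encode_sites(snps, config.max_missing_per_locus)
    if X.shape[1] == 0:
        raise ValueError("no usable sites after missing-data filtering")
    for g in groups:
        rows = [i for i, lab in enumerate(y) if lab == g]
        if np.all(np.isnan(X[rows])):
            raise ValueError(f"group {g} has no observed data")
    # mean imputation per site, then centering
    nan_mask = np.isnan(X)
    X_imp = np.where(nan_mask, site_means, X)

    n_pcs = min(config.n_pcs, min(X_imp.shape) - 1, np.linalg.matrix_rank(X_imp - X_imp.mean(0)))
    if n_pcs < config.n_pcs:
        warnings.warn(f"n_pcs reduced to available rank {n_pcs}", stacklevel=2)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(X_imp)

    n_da = config.n_da if config.n_da is not None else len(groups) - 1
    n_da = min(n_da, len(groups) - 1, n_pcs)
    axes, class_means, pooled = _lda_axes(scores, y, groups, n_da)
    coords = scores @ axes
    member = _gaussian_membership(coords, class_means, pooled, groups)
    membership = pd.DataFrame(member, index=snps.samples, columns=groups)
    return DapcResult(
        sites, groups, list(snps.samples), pca.mean_, pca.components_,
        axes, class_means, pooled, coords, membership, site_means, majors,
    )


def _lda_axes(scores, y, groups, n_da):
    """Discriminant axes from within/between scatter with pooled covariance."""
    n, p = scores.shape
    overall = scores.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    class_scores = {}
    for g in groups:
        rows = scores[[i for i, lab in enumerate(y) if lab == g]]
        class_scores[g] = rows
        mu = rows.mean(axis=0)
        centered = rows - mu
        Sw += centered.T @ centered
        diff = (mu - overall)[:, None]
        Sb += len(rows) * (diff @ diff.T)
    Sw += np.eye(p) * 1e-9 * max(np.trace(Sw), 1.0)  # guard against singular Sw
    eigvals, eigvecs = np.linalg.eig(np.linalg.solve(Sw, Sb))
    order = np.argsort(eigvals.real)[::-1][:n_da]
    axes = eigvecs[:, order].real
    axes /= np.linalg.norm(axes, axis=0, keepdims=True)
    class_means = np.vstack([class_scores[g].mean(axis=0) @ axes for g in groups])
    pooled = np.zeros((n_da, n_da))
    for g in groups:
        proj = class_scores[g] @ axes
        centered = proj - proj.mean(axis=0)
        pooled += centered.T @ centered
    pooled /= max(n - len(groups), 1)
    pooled += np.eye(n_da) * 1e-9 * max(np.trace(pooled), 1.0)
    return axes, class_means, pooled


def _gaussian_membership(coords, class_means, pooled, groups):
    inv = np.linalg.inv(pooled)
    log_dens = np.empty((coords.shape[0], len(groups)))
    for gi in range(len(groups)):
        diff = coords - class_means[gi]
        log_dens[:, gi] = -0.5 * np.einsum("ij,jk,ik->i", diff, inv, diff)
    log_dens -= log_dens.max(axis=1, keepdims=True)
    dens = np.exp(log_dens)
    return dens / dens.sum(axis=1, keepdims=True)


def predict_membership(result: DapcResult, snps: SnpMatrix) -> pd.DataFrame:
    """Project new samples through the stored PCA + DA and return membership
    probabilities. Sites missing from the new matrix (or unobserved in a
    sample) are imputed with the training means, with a warning."""
    site_pos = {site: k for k, site in enumerate(result.retained_sites)}
    col_of = {site: j for j, site in enumerate(snps.site_ids)}
    n = len(snps.samples)
    X = np.tile(result.site_means, (n, 1))
    imputed_any = False
    for site, k in site_pos.items():
        j = col_of.get(site)
        if j is None:
            imputed_any = True
            continue
        col = snps.data[:, j]
        mask = (col != "N") & (col != "-")
        imputed_any = imputed_any or not mask.all()
        X[mask, k] = (col[mask] != result.major_alleles[k]).astype(float)
    if imputed_any:
        warnings.warn("missing retained sites imputed with training means", stacklevel=2)
    scores = (X - result.pc_mean) @ result.pc_components.T
    coords = scores @ result.da_axes
    member = _gaussian_membership(coords, result.class_means_da, result.pooled_cov_da, result.groups)
    return pd.DataFrame(member, index=snps.samples, columns=result.groups)
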