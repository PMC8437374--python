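"""Alpha/beta diversity, rarefaction, ordination and PERMANOVA.

Distance matrices are square pandas DataFrames (sample x sample) with zero
diagonal; UniFrac distances are delegated to scikit-bio, while PERMANOVA and
principal-coordinate analysis are implemented directly so permutations are
seeded and the pseudo-F bookkeeping is explicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import beta_diversity

logger = logging.getLogger("guildscope")


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # over positive eigenvalues only


def shannon(abundances, base: float = 2.0) -> float:
    """Shannon diversity -sum p_i log_base p_i of one sample's composition."""
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("cannot compute Shannon diversity of an all-zero sample")
    p = p[p > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def observed_features(counts) -> int:
    """Number of taxa present (count > 0) in one sample."""
    c = np.asarray(counts)
    return int((c > 0).sum())


def rarefy(counts: pd.DataFrame, depth: int, seed: int = 0) -> pd.DataFrame:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped (logged).  Raises if
    no sample survives.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=0)
    keep = totals.index[totals >= depth]
    dropped = totals.index.difference(keep).tolist()
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s", len(dropped), depth, dropped)
    if len(keep) == 0:
        raise ValueError(f"rarefaction depth {depth} drops every sample")
    out = {}
    for sample in keep:
        col = counts[sample].to_numpy(dtype=np.int64)
        out[sample] = rng.multivariate_hypergeometric(col, depth)
    return pd.DataFrame(out, index=counts.index)


def _as_distance_frame(matrix: np.ndarray, ids) -> pd.DataFrame:
    return pd.DataFrame(matrix, index=ids, columns=ids)


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples (columns) of a table."""
    if table.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = table.to_numpy(dtype=float).T
    d = squareform(pdist(x, metric="braycurtis"))
    return _as_distance_frame(np.nan_to_num(d), table.columns)


def unifrac(counts: pd.DataFrame, tree, weighted: bool = False, normalized: bool = True) -> pd.DataFrame:
    """Unweighted or (normalised) weighted UniFrac between samples.

    All table taxa must be tree leaves; extra tree leaves are tolerated
    (scikit-bio shears the tree internally).
    """
    leaf_names = {t.name for t in tree.tips()}
    missing = [t for t in counts.index if t not in leaf_names]
    if missing:
        raise ValueError(f"taxa missing from the tree: {missing}")
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    kwargs = {"normalized": normalized} if weighted else {}
    dm = beta_diversity(
        metric,
        counts.to_numpy(dtype=float).T,
        ids=list(counts.columns),
        taxa=list(counts.index),
        tree=tree,
        validate=True,
        **kwargs,
    )
    return _as_distance_frame(dm.data, counts.columns)


def pcoa(d: pd.DataFrame) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centres -d^2/2, eigendecomposes, and reports coordinates for
    positive eigenvalues; negative eigenvalues are retained in
    ``eigenvalues`` but excluded from proportions explained.
    """
    m = np.asarray(d, dtype=float)
    if m.shape[0] != m.shape[1] or m.shape[0] < 3:
        raise ValueError("need a square distance matrix over >= 3 samples")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    n = m.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (m**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12 if evals.max() > 0 else np.zeros_like(evals, bool)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    ids = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(n)
    frame = pd.DataFrame(coords, index=ids, columns=[f"PC{i+1}" for i in range(coords.shape[1])])
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    return PcoaResult(frame, evals, prop)


def _permanova_stats(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(pseudo-F, R^2) from squared distances and integer labels."""
    n = d2.shape[0]
    k = len(groups)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    if ss_total <= 0:
        return 0.0, 0.0
    if ss_within <= 0:
        return np.inf, 1.0
    f = (ss_among / (k - 1)) / (ss_within / (n - k))
    return float(f), float(ss_among / ss_total)


def permanova(
    d: pd.DataFrame,
    labels,
    n_permutations: int = 9999,
    seed: int | None = 0,
    min_group_size: int = 2,
) -> PermanovaResult:
    """One-factor PERMANOVA with a seeded label-permutation p-value.

    Pseudo-F follows the among/within sum-of-squared-distances formulation;
    p = (1 + #{permuted F >= observed F}) / (n_permutations + 1), so p is
    never zero.
    """
    m = np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    if m.shape[0] != len(labels):
        raise ValueError("label length must match the distance matrix")
    groups, labels_int = np.unique(labels, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    sizes = np.bincount(labels_int)
    if (sizes < min_group_size).any():
        raise ValueError(f"every group needs >= {min_group_size} samples (sizes {sizes.tolist()})")
    d2 = m**2
    group_ids = np.arange(len(groups))
    f_obs, r2 = _permanova_stats(d2, labels_int, group_ids)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels_int)
        f_perm, _ = _permanova_stats(d2, perm, group_ids)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return PermanovaResult(f_obs, r2, float(p), n_permutations, seed)


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when both groups have <= 20 observations and no ties;
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(a) <= 20 and len(b) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
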