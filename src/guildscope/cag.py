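"""Co-abundance group (guild) discovery and sparse partial-correlation networks.

Taxa are clustered hierarchically (Ward linkage by default) on the distance
1 - Spearman rho between their abundance profiles.  The number of groups is
chosen by significance testing: for every candidate k, every pair of
clusters is tested with PERMANOVA on the Kendall-correlation distance
matrix D = 1 - tau restricted to the pair's taxa; the chosen k is the
largest candidate for which every pairwise test is significant (p < alpha).
If no candidate qualifies, the k with maximal mean between-cluster
PERMANOVA R^2 is used (logged prominently).

The sparse network is a graphical-lasso fit over a log-spaced penalty path
with extended-BIC model selection (EBIC = -2*loglik + E*log n + 4*E*gamma*log p),
mirroring the EBICglasso approach popularised by qgraph; edges carry partial
correlations -w_ij / sqrt(w_ii * w_jj) from the selected precision matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.covariance import graphical_lasso

from .diversity import permanova

logger = logging.getLogger("guildscope")


@dataclass
class CAGAssignment:
    labels: dict[str, int]  # taxon -> CAG label (1..k)
    k: int
    diagnostics: pd.DataFrame  # columns: k, cluster_a, cluster_b, p, r_squared
    linkage_method: str
    fallback_used: bool = False

    def members(self, label: int) -> list[str]:
        return [t for t, c in self.labels.items() if c == label]


@dataclass
class PartialCorrelationNetwork:
    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (i, j, partial correlation)
    regularization: float
    ebic: float
    ebic_gamma: float
    precision: np.ndarray = field(repr=False, default=None)

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"source": i, "target": j, "weight": w, "sign": "+" if w > 0 else "-"}
                for i, j, w in self.edges
            ]
        )


def select_top_taxa(table: pd.DataFrame, n: int = 99) -> list[str]:
    """Top-n taxa by mean relative abundance; ties broken lexicographically."""
    means = table.mean(axis=1)
    if len(means) < n:
        logger.warning("table has only %d taxa (< %d); using all", len(means), n)
        n = len(means)
    order = sorted(means.index, key=lambda t: (-means[t], str(t)))
    chosen = order[:n]
    if n < len(means) and means[order[n - 1]] == means[order[n]]:
        logger.info("tie at the top-%d boundary broken lexicographically (%s kept)", n, order[n - 1])
    return chosen


def kendall_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise tie-corrected Kendall tau-b between taxa (rows of ``table``).

    Constant taxa have undefined tau; their correlations are set to 0 with a
    warning (diagonal stays 1).
    """
    if table.shape[1] < 3:
        raise ValueError("need at least three samples")
    x = table.to_numpy(dtype=float)
    p = x.shape[0]
    constant = np.array([np.all(row == row[0]) for row in x])
    if constant.any():
        logger.warning("constant taxa in Kendall matrix set to 0 correlation: %s",
                       list(table.index[constant]))
    tau = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            if constant[i] or constant[j]:
                t = 0.0
            else:
                t = stats.kendalltau(x[i], x[j]).statistic
                if np.isnan(t):
                    t = 0.0
            tau[i, j] = tau[j, i] = t
    return pd.DataFrame(tau, index=table.index, columns=table.index)


def _spearman_distance(table: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Spearman rho distance between taxon rows."""
    rho = stats.spearmanr(table.to_numpy(dtype=float), axis=1).statistic
    rho = np.atleast_2d(rho)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    return squareform(d, checks=False)


def cluster_cags(
    table: pd.DataFrame,
    k_range=range(2, 13),
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    linkage_method: str = "ward",
    cluster_on: str = "abundance",
) -> CAGAssignment:
    """Cluster taxa into co-abundance groups with permutation-based k selection.

    ``cluster_on='abundance'`` clusters on 1 - Spearman between abundance
    profiles (default); ``'kendall_rows'`` clusters rows of the Kendall
    correlation matrix instead.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if table.shape[0] < max(k_range) + 1:
        raise ValueError("need more taxa than the largest candidate k")
    taxa = list(table.index)
    tau = kendall_matrix(table)
    d_tau = 1.0 - tau.to_numpy()
    np.fill_diagonal(d_tau, 0.0)

    if cluster_on == "abundance":
        condensed = _spearman_distance(table)
    elif cluster_on == "kendall_rows":
        rho = stats.spearmanr(tau.to_numpy(), axis=1).statistic
        d = 1.0 - np.atleast_2d(rho)
        np.fill_diagonal(d, 0.0)
        condensed = squareform(np.clip((d + d.T) / 2, 0.0, None), checks=False)
    else:
        raise ValueError("cluster_on must be 'abundance' or 'kendall_rows'")
    z = linkage(condensed, method=linkage_method)

    rng = np.random.default_rng(seed)
    diag_rows = []
    per_k = {}
    d_frame = pd.DataFrame(d_tau, index=taxa, columns=taxa)
    for k in k_range:
        labels = fcluster(z, t=k, criterion="maxclust")
        per_k[k] = labels
        all_sig = True
        r2s = []
        for a in range(1, k + 1):
            for b in range(a + 1, k + 1):
                idx = np.flatnonzero((labels == a) | (labels == b))
                pair_labels = labels[idx]
                sub = d_tau[np.ix_(idx, idx)]
                try:
                    res = permanova(
                        pd.DataFrame(sub),
                        pair_labels,
                        n_permutations=n_permutations,
                        seed=int(rng.integers(2**31)),
                    )
                    p, r2 = res.p_value, res.r_squared
                except ValueError:  # singleton cluster: separation not testable
                    p, r2 = np.nan, np.nan
                diag_rows.append({"k": k, "cluster_a": a, "cluster_b": b, "p": p, "r_squared": r2})
                if not (p < alpha):
                    all_sig = False
                if np.isfinite(r2):
                    r2s.append(r2)
        per_k[k] = (labels, all_sig, float(np.mean(r2s)) if r2s else np.nan)
    diagnostics = pd.DataFrame(diag_rows)

    valid = [k for k, (_, ok, _) in per_k.items() if ok]
    fallback = not valid
    if valid:
        chosen = max(valid)
    else:
        mean_r2 = {k: v[2] for k, v in per_k.items() if np.isfinite(v[2])}
        chosen = max(mean_r2, key=mean_r2.get) if mean_r2 else min(k_range)
        logger.warning(
            "no candidate k had all pairwise cluster separations significant; "
            "falling back to k=%d (maximal mean between-cluster R^2)", chosen
        )
    labels = per_k[chosen][0]
    return CAGAssignment(
        labels=dict(zip(taxa, (int(c) for c in labels))),
        k=int(chosen),
        diagnostics=diagnostics,
        linkage_method=linkage_method,
        fallback_used=fallback,
    )


def cag_abundance(
    table: pd.DataFrame,
    assignment: CAGAssignment,
    include_remainder: bool = True,
) -> pd.DataFrame:
    """Summed relative abundance per CAG (rows CAG1..CAGk [, unassigned]).

    ``table`` must be a relative-abundance table containing every assigned
    taxon; taxa not in the assignment are pooled into an ``unassigned`` row
    when ``include_remainder`` is set.
    """
    missing = [t for t in assignment.labels if t not in table.index]
    if missing:
        raise ValueError(f"assigned taxa missing from the table: {missing}")
    rows = {}
    for label in sorted(set(assignment.labels.values())):
        members = assignment.members(label)
        rows[f"CAG{label}"] = table.loc[members].sum(axis=0)
    out = pd.DataFrame(rows).T
    if include_remainder:
        rest = table.index.difference(list(assignment.labels))
        out.loc["unassigned"] = table.loc[rest].sum(axis=0) if len(rest) else 0.0
    out.columns = table.columns
    return out


def _glasso_ebic(s: np.ndarray, n: int, lam: float, gamma: float) -> tuple[np.ndarray, float, int]:
    cov, prec = graphical_lasso(s, alpha=lam, max_iter=500, tol=1e-6, enet_tol=1e-8)
    p = s.shape[0]
    off = prec[np.triu_indices(p, 1)]
    n_edges = int((np.abs(off) > 1e-8).sum())
    sign, logdet = np.linalg.slogdet(prec)
    if sign <= 0:
        return prec, np.inf, n_edges
    loglik = (n / 2.0) * (logdet - np.trace(s @ prec))
    ebic = -2.0 * loglik + n_edges * np.log(n) + 4.0 * n_edges * gamma * np.log(p)
    return prec, float(ebic), n_edges


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix -w_ij / sqrt(w_ii w_jj) from a precision."""
    d = np.sqrt(np.diag(precision))
    pc = -precision / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


def sparse_partial_network(
    data: pd.DataFrame,
    ebic_gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    sample_axis: str = "columns",
    threshold: float | None = None,
) -> PartialCorrelationNetwork:
    """Lasso-regularised partial-correlation network with EBIC selection.

    ``data`` holds variables x samples (``sample_axis='columns'``, the
    package's table orientation) or samples x variables.  The penalty path
    runs log-spaced from the smallest lambda giving an empty graph down by
    ``lambda_min_ratio``; the lambda minimising EBIC is selected.

    Because the lasso shrinks strong edges, the EBIC-optimal precision can
    carry tiny spurious edges that absorb the residual marginal correlation;
    edges with |partial correlation| below ``threshold`` are therefore
    pruned after selection.  The default threshold is the detection bound
    sqrt(log(p(p-1)/2) / n) (Jankova & van de Geer), as popularised by
    qgraph's ``threshold`` option; pass ``threshold=0`` to disable.
    """
    x = data.to_numpy(dtype=float)
    names = list(data.index) if sample_axis == "columns" else list(data.columns)
    if sample_axis == "columns":
        x = x.T  # samples x variables
    n, p = x.shape
    if n < p + 1:
        logger.warning("fewer samples (%d) than variables+1 (%d); estimates may be unstable", n, p + 1)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant variables: {[names[i] for i in np.flatnonzero(sd == 0)]}")
    s = np.corrcoef(x, rowvar=False)
    # guard against numerical non-PSD input
    min_eig = np.linalg.eigvalsh(s).min()
    if min_eig < 1e-10:
        s = s + np.eye(p) * (1e-10 - min_eig)
        logger.warning("correlation matrix regularised on the diagonal (min eigenvalue %.3g)", min_eig)

    lam_max = np.max(np.abs(s - np.eye(p)))
    if lam_max <= 0:
        lam_max = 1e-3
    lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambda)
    best = None
    for lam in lambdas:
        try:
            prec, ebic, n_edges = _glasso_ebic(s, n, lam, ebic_gamma)
        except FloatingPointError:
            continue
        if best is None or ebic < best[1]:
            best = (prec, ebic, lam)
    if best is None:
        raise RuntimeError("graphical lasso failed along the whole penalty path")
    prec, ebic, lam = best
    pc = partial_correlations(prec)
    if threshold is None:
        n_pairs = p * (p - 1) / 2
        threshold = np.sqrt(np.log(n_pairs) / n) if n_pairs > 1 else 0.0
    edges = [
        (names[i], names[j], float(pc[i, j]))
        for i in range(p)
        for j in range(i + 1, p)
        if abs(prec[i, j]) > 1e-8 and abs(pc[i, j]) >= threshold
    ]
    return PartialCorrelationNetwork(names, edges, float(lam), float(ebic), ebic_gamma, prec)
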