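"""Taxon-clinical association structure with covariate adjustment.

Partial Spearman correlations are computed by rank-transforming each
variable, residualising the ranks on the covariate design by least squares,
and correlating the residuals; p-values use the t approximation with
n - 2 - #covariates degrees of freedom and BH correction across the whole
taxa x indices grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffabund import benjamini_hochberg, build_design

logger = logging.getLogger("guildscope")


@dataclass
class AssocEdge:
    source: str
    target: str
    value: float  # correlation (or coefficient) on [-1, 1] scale for correlations
    q: float
    sign: str


def adjusted_index_difference(
    clinical: pd.DataFrame,
    group,
    covariates: pd.DataFrame | None = None,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-index group difference adjusted for covariates.

    OLS of each clinical index on group (1 = alphabetically last group) plus
    covariates, complete cases per index; BH across indices.  Returns a
    DataFrame with columns coefficient, p, q.
    """
    group = pd.Series(np.asarray(group), index=clinical.index)
    groups = sorted(group.dropna().unique())
    if len(groups) != 2:
        raise ValueError("expected exactly two groups")
    if covariates is not None and covariate_names is not None:
        design = build_design(covariates.loc[clinical.index], covariate_names)
    elif covariates is not None:
        design = covariates.loc[clinical.index].astype(float)
        design.insert(0, "Intercept", 1.0)
    else:
        design = pd.DataFrame({"Intercept": np.ones(len(clinical))}, index=clinical.index)

    rows = []
    for index_name in clinical.columns:
        y = clinical[index_name]
        mask = y.notna() & group.notna() & design.notna().all(axis=1)
        n = int(mask.sum())
        if n < design.shape[1] + 2:
            raise ValueError(f"too few complete cases for {index_name} ({n})")
        g = (group[mask] == groups[1]).astype(float).to_numpy()
        x = np.column_stack([g, design.loc[mask].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError(f"rank-deficient design for {index_name}")
        yv = y[mask].to_numpy(dtype=float)
        beta, _, _, _ = np.linalg.lstsq(x, yv, rcond=None)
        resid = yv - x @ beta
        dof = n - x.shape[1]
        sigma2 = resid @ resid / dof
        xtx_inv = np.linalg.inv(x.T @ x)
        se = np.sqrt(sigma2 * xtx_inv[0, 0])
        t = beta[0] / se if se > 0 else 0.0
        p = 2 * stats.t.sf(abs(t), dof) if se > 0 else 1.0
        rows.append({"index": index_name, "coefficient": float(beta[0]), "p": float(p), "n": n})
    out = pd.DataFrame(rows).set_index("index")
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def _rank_residuals(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(values)
    beta, _, _, _ = np.linalg.lstsq(design, ranks, rcond=None)
    return ranks - design @ beta


def _rank_design(design_df: pd.DataFrame) -> np.ndarray:
    """Rank-transform non-intercept design columns (Spearman-consistent).

    Residualising ranks on raw covariates leaves monotone leakage; ranking
    the covariates too makes the adjustment consistent with the rank scale
    (binary/dummy columns are unaffected up to an affine map).
    """
    design = design_df.to_numpy(dtype=float).copy()
    for j, col in enumerate(design_df.columns):
        if col != "Intercept":
            design[:, j] = stats.rankdata(design[:, j])
    return design


def partial_spearman(
    taxa: pd.DataFrame,
    clinical: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    covariate_names: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partial Spearman correlations between taxa (rows) and clinical indices.

    Returns (rho, p, q) DataFrames of shape taxa x indices; BH is applied
    jointly across the whole grid.  With no covariates this reduces to
    ordinary Spearman correlation.
    """
    samples = clinical.index.intersection(taxa.columns)
    if covariates is not None and covariate_names is not None:
        design_df = build_design(covariates.loc[samples], covariate_names)
    elif covariates is not None:
        design_df = covariates.loc[samples].astype(float)
        design_df.insert(0, "Intercept", 1.0)
    else:
        design_df = pd.DataFrame({"Intercept": np.ones(len(samples))}, index=samples)
    design = _rank_design(design_df)
    n = len(samples)
    n_cov = design.shape[1] - 1
    dof = n - 2 - n_cov
    if dof < 1:
        raise ValueError(f"too few samples (n={n}) for {n_cov} covariates")

    taxa_resid = np.stack([_rank_residuals(taxa.loc[t, samples].to_numpy(float), design) for t in taxa.index])
    clin_resid = np.stack([_rank_residuals(clinical.loc[samples, c].to_numpy(float), design) for c in clinical.columns])

    def _norm(m):
        m = m - m.mean(axis=1, keepdims=True)
        s = np.linalg.norm(m, axis=1, keepdims=True)
        s[s == 0] = 1.0
        return m / s

    rho = _norm(taxa_resid) @ _norm(clin_resid).T
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(dof / (1.0 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), dof)
    p = np.where(np.isnan(p), 0.0, p)  # |rho| == 1
    q = benjamini_hochberg(p.ravel()).reshape(p.shape)
    idx, cols = taxa.index, clinical.columns
    return (
        pd.DataFrame(rho, index=idx, columns=cols),
        pd.DataFrame(p, index=idx, columns=cols),
        pd.DataFrame(q, index=idx, columns=cols),
    )


def point_biserial(labels, values) -> tuple[float, float]:
    """Point-biserial correlation between a binary label and continuous values."""
    labels = np.asarray(labels)
    values = np.asarray(values, dtype=float)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    binary = (labels == classes[1]).astype(float)
    res = stats.pointbiserialr(binary, values)
    return float(res.statistic), float(res.pvalue)


def sankey_edges(
    taxon_index_q: pd.DataFrame,
    taxon_index_rho: pd.DataFrame,
    index_outcome: pd.DataFrame,
    fdr: float = 0.05,
) -> list[AssocEdge]:
    """Two-layer (taxon -> index -> outcome) edge list at FDR < ``fdr``.

    ``index_outcome`` must have columns ``value`` (signed association with
    the outcome) and ``q`` indexed by clinical index.  Each layer is
    filtered independently at q < fdr; signs are preserved.
    """
    edges: list[AssocEdge] = []
    sig_indices = set(index_outcome.index[index_outcome["q"] < fdr])
    for index_name in taxon_index_q.columns:
        for taxon in taxon_index_q.index:
            q = taxon_index_q.loc[taxon, index_name]
            if q < fdr:
                rho = float(taxon_index_rho.loc[taxon, index_name])
                edges.append(AssocEdge(str(taxon), str(index_name), rho, float(q), "+" if rho > 0 else "-"))
    for index_name in sorted(sig_indices):
        val = float(index_outcome.loc[index_name, "value"])
        edges.append(
            AssocEdge(str(index_name), "outcome", val, float(index_outcome.loc[index_name, "q"]), "+" if val > 0 else "-")
        )
    return edges


def edges_frame(edges: list[AssocEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"source": e.source, "target": e.target, "value": e.value, "q": e.q, "sign": e.sign} for e in edges]
    )
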