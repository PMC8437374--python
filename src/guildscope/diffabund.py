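"""Differential-abundance testing.

Two complementary routes, mirroring common 16S practice:

* ``lefse_lite`` — a deterministic LEfSe-style screen: per-taxon
  Kruskal-Wallis, Benjamini-Hochberg FDR across taxa, then a linear
  discriminant effect size on abundances rescaled to counts-per-million;
  a taxon is retained when q < fdr and |LDA| exceeds the threshold
  (conventionally 2).  Unlike classic LEfSe there is no bootstrap
  subsampling, so results are exactly reproducible.

* ``adjusted_linear_models`` — MaAsLin-style confirmation: per-taxon
  ordinary least squares of transformed relative abundance on group plus
  covariates (arcsine-square-root transform by default), BH across taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("guildscope")

#: counts-per-million rescaling used for the LDA effect size, after LEfSe's
#: convention of mapping relative abundances onto ~[1, 1e6].
CPM = 1e6


@dataclass
class TaxonTestResult:
    taxon: str
    direction: str | None  # enriched group, defined only when significant
    p: float
    q: float
    effect: float  # signed LDA score or model coefficient
    test: str


def kruskal_wallis_per_taxon(table: pd.DataFrame, labels) -> pd.Series:
    """Tie-corrected Kruskal-Wallis p-value per taxon (rows of ``table``).

    Constant taxa get p = 1 with a warning.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    masks = [labels == g for g in groups]
    pvals = {}
    for taxon, row in table.iterrows():
        x = row.to_numpy(dtype=float)
        if np.all(x == x[0]):
            logger.warning("taxon %s constant across samples; p set to 1", taxon)
            pvals[taxon] = 1.0
            continue
        try:
            _, p = stats.kruskal(*[x[m] for m in masks])
        except ValueError:  # all values identical within the test
            p = 1.0
        pvals[taxon] = float(p)
    return pd.Series(pvals, name="p")


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def lda_effect_size(table: pd.DataFrame, labels, taxa=None) -> pd.Series:
    """Signed LDA effect score per taxon between two groups.

    Abundances are rescaled to counts-per-million; for a single feature the
    linear discriminant axis is the feature itself, so the discriminant-
    projected between-class difference is the difference of class means.
    Score = log10(1 + |difference in CPM|), signed positive when the first
    group (alphabetically) is enriched.  Identical class means give 0.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("LDA effect size is defined for exactly two groups")
    g0, g1 = groups
    taxa = list(table.index) if taxa is None else list(taxa)
    sub = table.loc[taxa].to_numpy(dtype=float) * CPM
    m0 = sub[:, labels == g0].mean(axis=1)
    m1 = sub[:, labels == g1].mean(axis=1)
    diff = m0 - m1
    scores = np.sign(diff) * np.log10(1.0 + np.abs(diff))
    return pd.Series(scores, index=taxa, name="lda")


def lefse_lite(
    table: pd.DataFrame,
    labels,
    fdr: float = 0.05,
    lda_threshold: float = 2.0,
) -> list[TaxonTestResult]:
    """Kruskal-Wallis -> BH FDR -> LDA effect-size pipeline for two groups.

    Returns results for taxa with q < fdr and |LDA| > lda_threshold.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("lefse_lite expects exactly two groups")
    p = kruskal_wallis_per_taxon(table, labels)
    q = pd.Series(benjamini_hochberg(p.to_numpy()), index=p.index)
    screened = q.index[q < fdr]
    results: list[TaxonTestResult] = []
    if len(screened) == 0:
        return results
    lda = lda_effect_size(table, labels, screened)
    for taxon in screened:
        score = lda[taxon]
        if abs(score) > lda_threshold:
            direction = groups[0] if score > 0 else groups[1]
            results.append(
                TaxonTestResult(str(taxon), str(direction), float(p[taxon]), float(q[taxon]), float(score), "lefse_lite")
            )
    return results


def arcsine_sqrt(x: np.ndarray) -> np.ndarray:
    """Variance-stabilising transform for proportions: arcsin(sqrt(x))."""
    x = np.asarray(x, dtype=float)
    if ((x < 0) | (x > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(x))


def log10_halfmin(x: np.ndarray) -> np.ndarray:
    """log10 with half-minimum-positive pseudocount (per feature vector)."""
    x = np.asarray(x, dtype=float)
    positive = x[x > 0]
    pseudo = positive.min() / 2 if positive.size else 1e-6
    return np.log10(x + pseudo)


_TRANSFORMS = {"arcsin_sqrt": arcsine_sqrt, "log10": log10_halfmin, "none": lambda x: np.asarray(x, float)}


def build_design(meta: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Intercept + dummy-encoded covariate design matrix.

    Categorical covariates are dummy-encoded against the alphabetically
    first level; constant columns are dropped with a warning.
    """
    design = pd.DataFrame({"Intercept": np.ones(len(meta))}, index=meta.index)
    for cov in covariates:
        if cov not in meta.columns:
            raise ValueError(f"covariate {cov!r} not in metadata")
        col = meta[cov]
        if pd.api.types.is_numeric_dtype(col):
            if col.nunique() <= 1:
                logger.warning("covariate %r constant; dropped", cov)
                continue
            design[cov] = col.astype(float)
        else:
            levels = sorted(col.astype(str).unique())
            if len(levels) <= 1:
                logger.warning("covariate %r constant; dropped", cov)
                continue
            for level in levels[1:]:
                design[f"{cov}[{level}]"] = (col.astype(str) == level).astype(float)
    return design


def adjusted_linear_models(
    table: pd.DataFrame,
    labels,
    covariates: pd.DataFrame | None = None,
    covariate_names: list[str] | None = None,
    transform: str = "arcsin_sqrt",
    fdr: float = 0.05,
) -> list[TaxonTestResult]:
    """Covariate-adjusted per-taxon linear models (MaAsLin-style).

    Fits OLS of transformed relative abundance on group (coded 1 for the
    alphabetically last group) plus covariates; reports the group
    coefficient, its t-test p and BH q across taxa.  Significant taxa
    (q < fdr) get a direction.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("expected exactly two groups")
    tfm = _TRANSFORMS[transform]
    y_group = (labels == groups[1]).astype(float)

    if covariates is None:
        design = pd.DataFrame({"Intercept": np.ones(table.shape[1])}, index=table.columns)
    elif covariate_names is not None:
        design = build_design(covariates.loc[table.columns], covariate_names)
    else:
        design = covariates.loc[table.columns].astype(float)
        design.insert(0, "Intercept", 1.0)
    x = np.column_stack([y_group, design.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify a collinear column by leave-one-out rank probing
        bad = [
            design.columns[j - 1]
            for j in range(1, x.shape[1])
            if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    n, k = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    hat = xtx_inv @ x.T
    dof = n - k
    results = []
    for taxon, row in table.iterrows():
        y = tfm(row.to_numpy())
        beta = hat @ y
        resid = y - x @ beta
        sigma2 = resid @ resid / dof
        se = np.sqrt(max(sigma2 * xtx_inv[0, 0], 1e-300))
        t = beta[0] / se
        p = 2 * stats.t.sf(abs(t), dof)
        results.append((taxon, float(beta[0]), float(p)))
    pvals = np.array([r[2] for r in results])
    qvals = benjamini_hochberg(pvals)
    out = []
    for (taxon, coef, p), q in zip(results, qvals):
        direction = None
        if q < fdr:
            direction = str(groups[1] if coef > 0 else groups[0])
        out.append(TaxonTestResult(str(taxon), direction, p, float(q), coef, "adjusted_lm"))
    return out


def results_frame(results: list[TaxonTestResult]) -> pd.DataFrame:
    """Tidy DataFrame view of a list of taxon test results."""
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "p": r.p,
                "q": r.q,
                "effect": r.effect,
                "direction": r.direction,
                "test": r.test,
            }
            for r in results
        ]
    )
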