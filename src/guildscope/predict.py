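"""Prospective case/control prediction: splits, feature sets, ROC and DeLong CIs.

The classifier is ridge-penalised logistic regression (the minimal standard
for ROC biomarker panels; the ridge stabilises correlated guild features).
All feature selection (differential genera, CAG membership) is performed on
the discovery split only, and validation features are standardised with
discovery means/SDs, so the validation AUC is leakage-free.

AUC uses the pairwise (Mann-Whitney) definition with half-credit for ties;
confidence intervals use DeLong's placement-value variance estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from . import cag as cagmod
from . import diffabund, tabio

logger = logging.getLogger("guildscope")

FEATURE_SET_NAMES = ("clinical", "maaslin_genera", "lefse_genera", "cag", "cag_plus_clinical")


@dataclass
class ROCResult:
    auc: float
    ci_lower: float | None
    ci_upper: float | None
    n_cases: int
    n_controls: int
    curve: pd.DataFrame | None = field(default=None, repr=False)  # threshold/sensitivity/specificity
    method: str = "delong"


def split_cohort(
    meta: pd.DataFrame,
    discovery_fraction: float = 0.6,
    seed: int = 0,
    stratify: str = "group",
    discovery_counts: dict | None = None,
) -> tuple[pd.Index, pd.Index]:
    """Stratified random discovery/validation split of samples.

    Default draws ``discovery_fraction`` of each class; ``discovery_counts``
    (class -> exact discovery n) overrides the fraction per class.
    """
    if stratify not in meta.columns:
        raise ValueError(f"stratification column {stratify!r} missing")
    rng = np.random.default_rng(seed)
    discovery = []
    for level, sub in meta.groupby(stratify, sort=True):
        ids = sub.index.to_numpy()
        if len(ids) < 2:
            raise ValueError(f"class {level!r} too small to stratify")
        n_disc = (
            int(discovery_counts[level])
            if discovery_counts is not None
            else int(round(discovery_fraction * len(ids)))
        )
        if not 0 < n_disc < len(ids):
            raise ValueError(f"discovery count {n_disc} infeasible for class {level!r} (n={len(ids)})")
        take = rng.permutation(len(ids))[:n_disc]
        discovery.extend(ids[take])
    discovery_idx = meta.index[meta.index.isin(discovery)]
    validation_idx = meta.index[~meta.index.isin(discovery)]
    return discovery_idx, validation_idx


class RidgeLogitScorer:
    """Ridge-penalised logistic model with discovery-set standardisation."""

    def __init__(self, C: float = 1.0):
        self.C = C
        self.features_: list[str] | None = None

    def fit(self, x: pd.DataFrame, y) -> "RidgeLogitScorer":
        y = np.asarray(y)
        if len(np.unique(y)) != 2:
            raise ValueError("need exactly two classes")
        if min(np.bincount(pd.factorize(y)[0])) < 2:
            raise ValueError("need at least two samples per class")
        sd = x.std(axis=0, ddof=0)
        keep = sd.index[sd > 0]
        dropped = sd.index.difference(keep).tolist()
        if dropped:
            logger.warning("constant features dropped: %s", dropped)
        if len(keep) == 0:
            raise ValueError("no non-constant features to fit")
        self.features_ = list(keep)
        self.mean_ = x[keep].mean(axis=0)
        self.sd_ = sd[keep]
        z = (x[keep] - self.mean_) / self.sd_
        self.model_ = LogisticRegression(C=self.C, solver="lbfgs", max_iter=2000)
        self.model_.fit(z.to_numpy(), y)
        return self

    def score_samples(self, x: pd.DataFrame) -> np.ndarray:
        z = (x[self.features_] - self.mean_) / self.sd_
        return self.model_.decision_function(z.to_numpy())


def fit_classifier(features: pd.DataFrame, labels, C: float = 1.0) -> RidgeLogitScorer:
    """Fit the ridge-logistic scoring model on standardised features."""
    return RidgeLogitScorer(C=C).fit(features, labels)


def _case_mask(labels, positive) -> np.ndarray:
    labels = np.asarray(labels)
    if positive is None:
        classes = np.unique(labels)
        if len(classes) != 2:
            raise ValueError("need exactly two classes")
        positive = classes[1]
    return labels == positive


def roc_auc(scores, labels, positive=None) -> ROCResult:
    """ROC curve and AUC by the pairwise Mann-Whitney definition.

    AUC = (#{case > control} + 0.5 * #{ties}) / (n_case * n_control),
    computed via mid-ranks; the curve enumerates sorted unique score
    thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    case = _case_mask(labels, positive)
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    auc = (ranks[case].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(scores))[::-1]])
    sens = [(scores[case] >= t).mean() for t in thresholds]
    spec = [(scores[~case] < t).mean() for t in thresholds]
    curve = pd.DataFrame({"threshold": thresholds, "sensitivity": sens, "specificity": spec})
    return ROCResult(float(auc), None, None, n1, n0, curve, method="mann-whitney")


def delong_ci(scores, labels, level: float = 0.95, positive=None) -> tuple[float, float, float]:
    """AUC with DeLong normal-approximation confidence interval.

    Variance = var(case placements)/n_case + var(control placements)/n_control,
    where a case's placement is the fraction of controls scoring below it
    (ties count half), and symmetrically for controls.
    """
    scores = np.asarray(scores, dtype=float)
    case = _case_mask(labels, positive)
    x, y = scores[case], scores[~case]
    m, n = len(x), len(y)
    if m < 2 or n < 2:
        raise ValueError("need at least two samples per class")
    # placement values via mid-ranks (tie-aware, O((m+n) log(m+n)))
    all_ranks = stats.rankdata(np.concatenate([x, y]))
    rank_x_within = stats.rankdata(x)
    rank_y_within = stats.rankdata(y)
    v10 = (all_ranks[:m] - rank_x_within) / n  # per-case fraction of controls below
    v01 = 1.0 - (all_ranks[m:] - rank_y_within) / m  # per-control fraction of cases above... see below
    auc = v10.mean()
    var = np.var(v10, ddof=1) / m + np.var(1.0 - v01, ddof=1) / n
    if var <= 0:
        logger.warning("degenerate DeLong variance (AUC=%.3f); CI collapses to a point", auc)
        return float(auc), float(auc), float(auc)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def _roc_with_ci(scores, labels, positive=None) -> ROCResult:
    res = roc_auc(scores, labels, positive)
    auc, lo, hi = delong_ci(scores, labels, positive=positive)
    res.ci_lower, res.ci_upper = lo, hi
    res.method = "delong"
    return res


def assemble_feature_sets(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    clinical: pd.DataFrame,
    discovery: pd.Index,
    group_col: str = "group",
    top_n: int = 99,
    k_range=range(2, 9),
    n_permutations: int = 199,
    seed: int = 0,
    fdr: float = 0.05,
    covariate_names: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Build the five benchmark feature sets, selecting on discovery only.

    Returns name -> samples x features DataFrame over all samples; sets
    that come out empty (no significant genera) are omitted with a warning.
    """
    rel = tabio.to_relative(counts)
    labels_disc = meta.loc[discovery, group_col].to_numpy()
    sets: dict[str, pd.DataFrame] = {"clinical": clinical.copy()}

    maaslin = diffabund.adjusted_linear_models(
        rel[discovery],
        labels_disc,
        covariates=meta.loc[discovery] if covariate_names else None,
        covariate_names=covariate_names,
        fdr=fdr,
    )
    maaslin_taxa = [r.taxon for r in maaslin if r.q < fdr]
    if maaslin_taxa:
        sets["maaslin_genera"] = rel.loc[maaslin_taxa].T
    else:
        logger.warning("no covariate-adjusted differential genera on discovery; set skipped")

    lefse = diffabund.lefse_lite(rel[discovery], labels_disc, fdr=fdr)
    lefse_taxa = [r.taxon for r in lefse]
    if lefse_taxa:
        sets["lefse_genera"] = rel.loc[lefse_taxa].T
    else:
        logger.warning("no LEfSe-retained genera on discovery; set skipped")

    top = cagmod.select_top_taxa(rel[discovery], n=min(top_n, rel.shape[0]))
    assignment = cagmod.cluster_cags(
        rel.loc[top, discovery], k_range=k_range, n_permutations=n_permutations, seed=seed
    )
    cag_table = cagmod.cag_abundance(rel, assignment, include_remainder=False)
    sets["cag"] = cag_table.T
    sets["cag_plus_clinical"] = pd.concat([cag_table.T, clinical], axis=1)
    return sets


def evaluate_feature_sets(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    clinical: pd.DataFrame,
    seed: int = 0,
    group_col: str = "group",
    positive: str = "GA",
    discovery_fraction: float = 0.6,
    discovery_counts: dict | None = None,
    **assemble_kwargs,
) -> dict[str, dict[str, ROCResult]]:
    """Discovery/validation ROC evaluation of every constructible feature set."""
    discovery, validation = split_cohort(
        meta, discovery_fraction=discovery_fraction, seed=seed, stratify=group_col,
        discovery_counts=discovery_counts,
    )
    sets = assemble_feature_sets(
        counts, meta, clinical, discovery, group_col=group_col, seed=seed, **assemble_kwargs
    )
    # encode the outcome as 1 = positive class so classifier scores and AUC agree
    y_disc = (meta.loc[discovery, group_col] == positive).astype(int).to_numpy()
    y_val = (meta.loc[validation, group_col] == positive).astype(int).to_numpy()
    out: dict[str, dict[str, ROCResult]] = {}
    for name, features in sets.items():
        try:
            model = fit_classifier(features.loc[discovery], y_disc)
        except ValueError as err:
            logger.warning("feature set %r unusable (%s); skipped", name, err)
            continue
        out[name] = {
            "discovery": _roc_with_ci(model.score_samples(features.loc[discovery]), y_disc, 1),
            "validation": _roc_with_ci(model.score_samples(features.loc[validation]), y_val, 1),
        }
    return out


def summary_frame(results: dict[str, dict[str, ROCResult]]) -> pd.DataFrame:
    rows = []
    for name, splits in results.items():
        for split, res in splits.items():
            rows.append(
                {
                    "feature_set": name,
                    "split": split,
                    "auc": res.auc,
                    "ci_lower": res.ci_lower,
                    "ci_upper": res.ci_upper,
                    "n_cases": res.n_cases,
                    "n_controls": res.n_controls,
                }
            )
    return pd.DataFrame(rows)
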