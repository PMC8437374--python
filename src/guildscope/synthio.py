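"""Synthetic cohort generator with known ground truth.

Emulates a prospective pregnancy cohort with genus-level 16S compositional
data: two outcome groups (gestational anemia vs. healthy control), up to two
stool-sampling timepoints, block-correlated taxon abundances (co-abundance
"guilds"), a configurable set of planted differential taxa, thirteen
epidemiological covariates, and clinical blood indices tied to the outcome.

The generative model is a latent log-normal factor model: each sample draws
one standard-normal factor per block, taxon log-abundances are
``sqrt(rho) * block_factor + sqrt(1-rho) * noise + baseline``, shifted by the
group effect for planted differential taxa, exponentiated, normalised, and
read counts are drawn multinomially at a log-normally distributed depth.
When per-block outcome log-odds are supplied, case/control labels are drawn
from a logistic model on the standardised true block relative abundances
with the intercept calibrated so the expected case fraction matches
``n_case / (n_case + n_control)``.

One global seed expands deterministically into per-stage child generators
via ``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

logger = logging.getLogger("guildscope")

# fixed stage indices for seed expansion (documented rule; order is frozen)
_STAGES = {
    "baseline": 0,
    "community": 1,
    "depths": 2,
    "labels": 3,
    "covariates": 4,
    "clinical": 5,
    "registry": 6,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for a named pipeline stage of a global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES[stage],)))


#: Thirteen covariates mirroring a typical pregnancy-cohort questionnaire:
#: (name, kind, parameters).  Continuous -> (mean, sd); categorical ->
#: dict level -> probability; binary -> probability of 1.
DEFAULT_COVARIATES: tuple = (
    ("maternal_age", "continuous", (29.0, 3.2)),
    ("pre_bmi", "continuous", (22.3, 5.6)),
    ("parity", "binary", 0.24),
    ("gravidity", "binary", 0.41),
    ("family_income", "categorical", {"low": 0.12, "mid": 0.70, "high": 0.18}),
    ("education", "categorical", {"college_or_below": 0.30, "university": 0.52, "graduate": 0.18}),
    ("passive_smoking", "categorical", {"never": 0.42, "seldom": 0.49, "always": 0.09}),
    ("antibiotic_use", "binary", 0.57),
    ("supplement_use", "binary", 0.94),
    ("alcohol_pre", "binary", 0.07),
    ("caffeine_pre", "binary", 0.43),
    ("alcohol_pregnancy", "binary", 0.0),
    ("caffeine_pregnancy", "binary", 0.15),
)

#: Clinical indices: (name, control mean, SD, GA shift in SD units).
#: Units: Hb g/L, RBC 10^12/L, ALB g/L, DB/TB/serum iron umol/L, FT4 pmol/L,
#: ferritin ug/L.  Negative shifts mirror indices observed lower in anemia.
DEFAULT_CLINICAL: tuple = (
    ("Hb", 121.0, 9.0, -0.8),
    ("RBC", 4.1, 0.35, -0.6),
    ("ALB", 38.5, 2.8, -0.5),
    ("DB", 3.6, 1.1, -0.4),
    ("TB", 10.5, 3.0, -0.4),
    ("FT4", 15.2, 2.0, -0.5),
    ("serum_iron", 18.0, 5.5, 0.0),
    ("serum_ferritin", 34.0, 14.0, -0.3),
)


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study: 156 anemia cases and 402 controls,
    ~100 genera in 8 co-abundance blocks, mean sequencing depth 40,000 reads
    (above a typical rarefaction depth of ~31,000).
    """

    n_case: int = 156
    n_control: int = 402
    n_taxa: int = 100
    n_blocks: int = 8
    within_block_corr: float = 0.7
    depth_mean: float = 40000.0
    depth_dispersion: float = 0.25  # sigma of log-normal depth
    differential_taxa: tuple = ()  # (taxon index, log2 fold change in cases)
    outcome_coefficients: dict | None = None  # block index -> log-odds per SD
    covariate_spec: tuple = DEFAULT_COVARIATES
    clinical_spec: tuple = DEFAULT_CLINICAL
    timepoints: tuple = ("T2", "T3")
    t3_shift_sd: float = 0.3  # per-taxon log-abundance shift between timepoints
    baseline_log_sd: float = 1.5  # spread of taxon baselines (rank-abundance)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_case, self.n_control, self.n_taxa, self.n_blocks) <= 0:
            raise ValueError("n_case, n_control, n_taxa and n_blocks must be positive")
        if self.n_blocks > self.n_taxa:
            raise ValueError("n_blocks must not exceed n_taxa")
        if not 0 <= self.within_block_corr < 1:
            raise ValueError("within_block_corr must lie in [0, 1)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        for idx, _ in self.differential_taxa:
            if not 0 <= idx < self.n_taxa:
                raise ValueError(f"differential taxon index {idx} out of range")
        if self.outcome_coefficients:
            for b in self.outcome_coefficients:
                if not 0 <= b < self.n_blocks:
                    raise ValueError(f"outcome coefficient references unknown block {b}")


@dataclass
class SynthTruth:
    """Planted ground truth accompanying a generated cohort."""

    block_assignment: dict[str, int]
    differential_taxa: tuple
    outcome_model: dict | None
    block_abundance: pd.DataFrame | None = field(default=None, repr=False)


def _draw_covariates(rng: np.random.Generator, n: int, spec) -> pd.DataFrame:
    cols = {}
    for name, kind, params in spec:
        if kind == "continuous":
            mu, sd = params
            cols[name] = rng.normal(mu, sd, n)
        elif kind == "binary":
            cols[name] = rng.binomial(1, params, n)
        elif kind == "categorical":
            levels = list(params)
            probs = np.asarray(list(params.values()), dtype=float)
            probs = probs / probs.sum()
            cols[name] = rng.choice(levels, size=n, p=probs)
        else:
            raise ValueError(f"unknown covariate kind {kind!r}")
    return pd.DataFrame(cols)


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept alpha with mean sigmoid(alpha + eta) == target."""

    def gap(alpha):
        return np.mean(1.0 / (1.0 + np.exp(-(alpha + eta)))) - target

    return brentq(gap, -30.0, 30.0)


def generate_community(config: SynthConfig):
    """Generate (counts, metadata, truth) for one synthetic cohort.

    Returns a taxa x samples integer count table, per-sample metadata
    (subject, timepoint, group, covariates) and the planted truth.
    """
    config.validate()
    n_subjects = config.n_case + config.n_control
    rho = config.within_block_corr

    rng_base = stage_rng(config.seed, "baseline")
    baseline = rng_base.normal(0.0, config.baseline_log_sd, config.n_taxa)
    # round-robin block assignment keeps block sizes balanced
    blocks = np.arange(config.n_taxa) % config.n_blocks
    t3_shift = rng_base.normal(0.0, config.t3_shift_sd, config.n_taxa)

    taxa = [f"g__Taxon{i:03d}" for i in range(config.n_taxa)]
    diff = dict(config.differential_taxa)

    rng_comm = stage_rng(config.seed, "community")
    rng_depth = stage_rng(config.seed, "depths")
    rng_lab = stage_rng(config.seed, "labels")

    # latent block factors at the outcome-relevant timepoint (first one)
    factors = {tp: rng_comm.standard_normal((n_subjects, config.n_blocks)) for tp in config.timepoints}
    noise = {tp: rng_comm.standard_normal((n_subjects, config.n_taxa)) for tp in config.timepoints}

    # group labels
    base_tp = config.timepoints[0]
    target = config.n_case / n_subjects
    if config.outcome_coefficients:
        logits = np.zeros(n_subjects)
        # true block relative abundance at the base timepoint drives the outcome
        loga = (
            baseline
            + np.sqrt(rho) * factors[base_tp][:, blocks]
            + np.sqrt(1 - rho) * noise[base_tp]
        )
        comp = np.exp(loga)
        comp /= comp.sum(axis=1, keepdims=True)
        block_ab = np.stack([comp[:, blocks == b].sum(axis=1) for b in range(config.n_blocks)], axis=1)
        for b, coef in config.outcome_coefficients.items():
            z = (block_ab[:, b] - block_ab[:, b].mean()) / block_ab[:, b].std(ddof=0)
            logits += coef * z
        alpha = _calibrate_intercept(logits, target)
        p_case = 1.0 / (1.0 + np.exp(-(alpha + logits)))
        is_case = rng_lab.random(n_subjects) < p_case
        outcome_model = {"intercept": alpha, "coefficients": dict(config.outcome_coefficients)}
    else:
        is_case = np.zeros(n_subjects, dtype=bool)
        is_case[rng_lab.permutation(n_subjects)[: config.n_case]] = True
        outcome_model = None

    subjects = [f"S{i:04d}" for i in range(n_subjects)]
    columns, meta_rows, count_cols = [], [], []
    block_ab_rows = {}
    for tp in config.timepoints:
        loga = (
            baseline
            + np.sqrt(rho) * factors[tp][:, blocks]
            + np.sqrt(1 - rho) * noise[tp]
        )
        if tp != base_tp:
            loga = loga + t3_shift
        if diff:
            idx = np.fromiter(diff.keys(), dtype=int)
            lfc = np.fromiter(diff.values(), dtype=float)
            loga[np.ix_(is_case, idx)] += np.log(2.0) * lfc
        comp = np.exp(loga)
        comp /= comp.sum(axis=1, keepdims=True)
        depths = np.maximum(
            1, rng_depth.lognormal(np.log(config.depth_mean), config.depth_dispersion, n_subjects)
        ).astype(np.int64)
        counts = np.empty((n_subjects, config.n_taxa), dtype=np.int64)
        for i in range(n_subjects):
            counts[i] = rng_comm.multinomial(depths[i], comp[i])
        for i, subj in enumerate(subjects):
            sid = f"{subj}_{tp}"
            columns.append(sid)
            meta_rows.append(
                {
                    "sample": sid,
                    "subject": subj,
                    "timepoint": tp,
                    "group": "GA" if is_case[i] else "control",
                }
            )
        count_cols.append(counts.T)
        block_ab_rows[tp] = comp

    count_table = pd.DataFrame(np.hstack(count_cols), index=taxa, columns=columns)
    meta = pd.DataFrame(meta_rows).set_index("sample")

    rng_cov = stage_rng(config.seed, "covariates")
    cov = _draw_covariates(rng_cov, n_subjects, config.covariate_spec)
    cov.index = pd.Index(subjects, name="subject")
    meta = meta.join(cov, on="subject")

    comp_base = block_ab_rows[base_tp]
    block_df = pd.DataFrame(
        np.stack([comp_base[:, blocks == b].sum(axis=1) for b in range(config.n_blocks)], axis=1),
        index=[f"{s}_{base_tp}" for s in subjects],
        columns=[f"block{b}" for b in range(config.n_blocks)],
    )
    truth = SynthTruth(
        block_assignment={taxa[i]: int(blocks[i]) for i in range(config.n_taxa)},
        differential_taxa=tuple(config.differential_taxa),
        outcome_model=outcome_model,
        block_abundance=block_df,
    )
    return count_table, meta, truth


def generate_cohort_registry(n_enrolled: int, exclusion_counts: dict[str, int], seed: int) -> pd.DataFrame:
    """Registry of enrolled subjects with mutually exclusive exclusion flags.

    ``exclusion_counts`` maps criterion name -> exact number of subjects to
    flag; flags are assigned to disjoint random subsets so the flow-chart
    subtraction is exact.
    """
    counts = {k: int(v) for k, v in exclusion_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("exclusion counts must be non-negative")
    total = sum(counts.values())
    if total > n_enrolled:
        raise ValueError(f"exclusion counts ({total}) exceed n_enrolled ({n_enrolled})")
    rng = stage_rng(seed, "registry")
    order = rng.permutation(n_enrolled)
    registry = pd.DataFrame(
        {crit: np.zeros(n_enrolled, dtype=bool) for crit in counts},
        index=pd.Index([f"P{i:04d}" for i in range(n_enrolled)], name="subject"),
    )
    start = 0
    for crit, k in counts.items():
        registry.iloc[order[start : start + k], registry.columns.get_loc(crit)] = True
        start += k
    return registry


def generate_clinical(
    meta: pd.DataFrame,
    spec=DEFAULT_CLINICAL,
    seed: int = 0,
    anemia_threshold: float = 100.0,
) -> pd.DataFrame:
    """Gaussian clinical indices per sample with group shifts.

    For case (GA) samples at the outcome timepoint (the last timepoint
    present), Hb is drawn from a normal truncated below the anemia threshold
    so the diagnostic definition holds by construction.
    """
    if "group" not in meta.columns:
        raise ValueError("metadata must contain a 'group' column")
    rng = stage_rng(seed, "clinical")
    n = len(meta)
    is_case = (meta["group"] == "GA").to_numpy()
    out = {}
    for name, mu, sd, shift in spec:
        values = rng.normal(mu, sd, n)
        values[is_case] += shift * sd
        out[name] = values
    clinical = pd.DataFrame(out, index=meta.index)

    if "Hb" in clinical.columns:
        tps = meta["timepoint"].unique().tolist() if "timepoint" in meta.columns else []
        outcome_tp = sorted(tps)[-1] if tps else None
        mask = is_case.copy()
        if outcome_tp is not None:
            mask &= (meta["timepoint"] == outcome_tp).to_numpy()
        if mask.any():
            row = next(r for r in spec if r[0] == "Hb")
            _, mu, sd, shift = row
            mu_case = mu + shift * sd
            a = (0.0 - mu_case) / sd
            b = (anemia_threshold - mu_case) / sd
            clinical.loc[mask, "Hb"] = truncnorm.rvs(
                a, b, loc=mu_case, scale=sd, size=int(mask.sum()), random_state=rng
            )
    neg = clinical.lt(0).any(axis=0)
    if neg.any():
        clinical[clinical < 0] = 0.0
        logger.warning("clipped negative clinical values in %s", list(clinical.columns[neg]))
    return clinical


def write_truth(truth: SynthTruth, path) -> None:
    """Persist planted truth as a plain-text key/value sidecar."""
    with open(path, "w") as fh:
        for taxon, block in truth.block_assignment.items():
            fh.write(f"block.{taxon} = {block}\n")
        for idx, lfc in truth.differential_taxa:
            fh.write(f"differential.{idx} = {lfc}\n")
        if truth.outcome_model:
            fh.write(f"outcome.intercept = {truth.outcome_model['intercept']}\n")
            for b, c in truth.outcome_model["coefficients"].items():
                fh.write(f"outcome.block{b} = {c}\n")
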