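"""Synthetic metabolomics data generation.

Simulated datasets mimic targeted / nontargeted metabolomics panels:
metabolite levels are multivariate normal on the standardized (post
log-transform) scale with a clustered correlation structure whose
off-diagonal entries scatter around a configurable mean (+0.40 by
default), and a small set of "true positive" metabolites carries a
direct (conditional) association with a continuous or binary clinical
outcome.  A separate generator produces cohort-style raw feature tables
(right-skewed positive intensities with age / sex / batch covariates)
for exercising the preprocessing and cohort-analysis stages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "ConfigurationError",
    "CorrelationSpec",
    "ScenarioConfig",
    "SimulatedDataset",
    "FeatureTable",
    "build_correlation_matrix",
    "cluster_labels",
    "nearest_psd_correlation",
    "simulate_dataset",
    "calibrate_binary_intercept",
    "generate_cohort_table",
    "default_effect_sizes",
]


class ConfigurationError(ValueError):
    """A generator specification violates one of its feasibility constraints."""


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationSpec:
    """Specification of the between-metabolite correlation matrix.

    The matrix is block compound-symmetric: metabolites are partitioned
    into ``n_clusters`` near-equal clusters with correlation
    ``within_cluster_rho`` inside a cluster and ``between_cluster_rho``
    across clusters, plus zero-mean Gaussian jitter of standard
    deviation ``jitter_sd`` so pairwise correlations are *distributed
    around* their block value rather than constant.  When
    ``between_cluster_rho`` is None it is solved in closed form so the
    mean off-diagonal correlation equals ``target_mean_rho``.

    ``negative_block_fraction`` flips the sign of the between-cluster
    correlation for that fraction of cluster pairs (a secondary design
    with negative correlations); ``paired_high_rho`` plants one highly
    intercorrelated metabolite pair per cluster at the given value.
    The jitter and any random block choices are driven by ``corr_seed``
    so the correlation structure is a fixed dataset attribute: every
    replicate of a scenario shares the same matrix.
    """

    n_metabolites: int
    n_clusters: int = 10
    within_cluster_rho: float = 0.7
    between_cluster_rho: Optional[float] = None
    target_mean_rho: float = 0.40
    jitter_sd: float = 0.005
    negative_block_fraction: float = 0.0
    paired_high_rho: Optional[float] = None
    corr_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_metabolites < 1:
            raise ConfigurationError("n_metabolites must be a positive integer")
        if not 1 <= self.n_clusters <= self.n_metabolites:
            raise ConfigurationError("n_clusters must be in [1, n_metabolites]")
        if not 0.0 <= self.within_cluster_rho < 1.0:
            raise ConfigurationError("within_cluster_rho must lie in [0, 1)")
        if self.between_cluster_rho is not None and not -1.0 < self.between_cluster_rho < 1.0:
            raise ConfigurationError("between_cluster_rho must lie in (-1, 1)")
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter_sd must be nonnegative")
        if not 0.0 <= self.negative_block_fraction <= 1.0:
            raise ConfigurationError("negative_block_fraction must lie in [0, 1]")
        if self.paired_high_rho is not None and not 0.0 < self.paired_high_rho < 1.0:
            raise ConfigurationError("paired_high_rho must lie in (0, 1)")


def cluster_labels(spec: CorrelationSpec) -> np.ndarray:
    """Cluster membership (0-based) of each metabolite; near-equal sizes."""
    return np.sort(np.arange(spec.n_metabolites) % spec.n_clusters)


def _solve_between_rho(spec: CorrelationSpec) -> float:
    """Closed-form between-cluster correlation hitting the target mean.

    mean_offdiag = (w_pairs * rho_w + b_pairs * rho_b) / total_pairs,
    solved for rho_b.  Sign-flipped blocks (negative_block_fraction)
    are accounted for by scaling the effective between-pair weight.
    """
    labels = cluster_labels(spec)
    m = spec.n_metabolites
    total_pairs = m * (m - 1) // 2
    sizes = np.bincount(labels, minlength=spec.n_clusters)
    w_pairs = int(np.sum(sizes * (sizes - 1) // 2))
    b_pairs = total_pairs - w_pairs
    if b_pairs == 0:
        if abs(spec.within_cluster_rho - spec.target_mean_rho) > 1e-12:
            raise ConfigurationError(
                "single-cluster spec cannot reach target_mean_rho "
                f"{spec.target_mean_rho} with within_cluster_rho {spec.within_cluster_rho}"
            )
        return 0.0
    # fraction f of between pairs flipped to -rho_b: effective weight (1 - 2f)
    eff = 1.0 - 2.0 * spec.negative_block_fraction
    if abs(eff) < 1e-12:
        raise ConfigurationError(
            "negative_block_fraction = 0.5 makes the between-cluster mean "
            "vanish; target_mean_rho is unreachable — set between_cluster_rho explicitly"
        )
    rho_b = (spec.target_mean_rho * total_pairs - w_pairs * spec.within_cluster_rho) / (
        b_pairs * eff
    )
    if not -1.0 < rho_b < 1.0:
        raise ConfigurationError(
            f"solved between_cluster_rho = {rho_b:.4f} falls outside (-1, 1); "
            "target_mean_rho is unreachable with this cluster layout"
        )
    return rho_b


def nearest_psd_correlation(a: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone and restore unit diagonal.

    Eigenvalue clipping at zero followed by diagonal re-normalization;
    adequate for jitter-scale repairs (the input is close to PSD).
    """
    vals, vecs = np.linalg.eigh((a + a.T) / 2.0)
    if vals[0] >= 0:
        out = a.copy()
    else:
        vals = np.clip(vals, 0.0, None)
        out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def build_correlation_matrix(spec: CorrelationSpec) -> np.ndarray:
    """Build the M x M metabolite correlation matrix for ``spec``.

    Block compound symmetry with Gaussian jitter, followed by a
    nearest-PSD repair (eigenvalue clipping, unit-diagonal rescale).
    """
    labels = cluster_labels(spec)
    rho_b = (
        spec.between_cluster_rho
        if spec.between_cluster_rho is not None
        else _solve_between_rho(spec)
    )
    same = labels[:, None] == labels[None, :]
    sigma = np.where(same, spec.within_cluster_rho, rho_b).astype(float)

    rng = np.random.default_rng(spec.corr_seed)
    if spec.negative_block_fraction > 0 and spec.n_clusters > 1:
        pairs = [(i, j) for i in range(spec.n_clusters) for j in range(i + 1, spec.n_clusters)]
        n_flip = int(round(spec.negative_block_fraction * len(pairs)))
        flip_idx = rng.choice(len(pairs), size=n_flip, replace=False)
        for k in flip_idx:
            ci, cj = pairs[k]
            mask = np.outer(labels == ci, labels == cj)
            sigma[mask] = -rho_b
            sigma[mask.T] = -rho_b

    if spec.jitter_sd > 0:
        noise = rng.normal(0.0, spec.jitter_sd, size=sigma.shape)
        noise = (noise + noise.T) / np.sqrt(2.0)
        sigma = sigma + noise
        sigma = np.clip(sigma, -0.99, 0.99)

    if spec.paired_high_rho is not None:
        for c in range(spec.n_clusters):
            members = np.flatnonzero(labels == c)
            if len(members) >= 2:
                i, j = members[0], members[1]
                sigma[i, j] = sigma[j, i] = spec.paired_high_rho

    np.fill_diagonal(sigma, 1.0)
    sigma = nearest_psd_correlation(sigma)
    if np.linalg.eigvalsh(sigma)[0] < -1e-8:
        raise ConfigurationError("PSD repair failed to produce a valid correlation matrix")
    return sigma


@lru_cache(maxsize=16)
def _cached_factor(spec: CorrelationSpec) -> tuple[np.ndarray, np.ndarray]:
    """(Sigma, L) with L L' = Sigma; cached because the matrix is fixed per scenario."""
    sigma = build_correlation_matrix(spec)
    vals, vecs = np.linalg.eigh(sigma)
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return sigma, factor


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------


def default_effect_sizes(n_true: int = 10, low: float = 0.05, high: float = 0.5) -> tuple:
    """Alternating-sign geometric grid of effect sizes (outcome-SD per metabolite-SD).

    Magnitudes span [low, high] geometrically; signs alternate so that
    metabolites both raise and lower the outcome.  With an everywhere-
    positive correlation structure, same-sign effects would make the
    outcome nearly proportional to the common metabolite factor and
    every null metabolite marginally associated at any sample size;
    mixed signs keep marginal null associations cluster-local, the
    regime the benchmark is about.
    """
    mags = np.geomspace(low, high, n_true)
    return tuple(m * (1.0 if i % 2 == 0 else -1.0) for i, m in enumerate(mags))


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one simulated study."""

    n_subjects: int
    correlation: CorrelationSpec
    outcome_type: str = "continuous"
    prevalence: Optional[float] = None
    n_true: int = 10
    effect_sizes: tuple = field(default_factory=default_effect_sizes)
    noise_sd: float = 1.0
    seed: int = 0
    truth_placement: str = "spread"  # or "same_cluster"
    case_control: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be positive")
        if self.outcome_type not in ("continuous", "binary"):
            raise ConfigurationError("outcome_type must be 'continuous' or 'binary'")
        if self.outcome_type == "binary":
            if self.prevalence is None or not 0.0 < self.prevalence < 1.0:
                raise ConfigurationError("binary outcomes require prevalence in (0, 1)")
        elif self.prevalence is not None:
            raise ConfigurationError("prevalence is only meaningful for binary outcomes")
        if not 1 <= self.n_true <= self.correlation.n_metabolites:
            raise ConfigurationError("n_true must lie in [1, n_metabolites]")
        if len(self.effect_sizes) != self.n_true:
            raise ConfigurationError("effect_sizes must have length n_true")
        if any(e == 0 for e in self.effect_sizes):
            raise ConfigurationError("effect_sizes must be nonzero")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.truth_placement not in ("spread", "same_cluster"):
            raise ConfigurationError("truth_placement must be 'spread' or 'same_cluster'")
        object.__setattr__(self, "effect_sizes", tuple(float(e) for e in self.effect_sizes))

    # --- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["correlation"] = dataclasses.asdict(self.correlation)
        d["effect_sizes"] = list(self.effect_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        corr = d.pop("correlation")
        if isinstance(corr, dict):
            corr = CorrelationSpec(**corr)
        d["effect_sizes"] = tuple(d.get("effect_sizes", default_effect_sizes(d.get("n_true", 10))))
        return cls(correlation=corr, **d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        return cls.from_dict(json.loads(text))


@dataclass
class SimulatedDataset:
    """One simulated study: metabolite matrix, outcome, and planted truth."""

    X: np.ndarray
    y: np.ndarray
    beta: np.ndarray
    truth_set: np.ndarray
    config: ScenarioConfig

    @property
    def cluster_labels(self) -> np.ndarray:
        return cluster_labels(self.config.correlation)

    @property
    def sigma(self) -> np.ndarray:
        return _cached_factor(self.config.correlation)[0]


# ---------------------------------------------------------------------------
# outcome generation
# ---------------------------------------------------------------------------


def calibrate_binary_intercept(
    linear_predictor_sample: np.ndarray, target_prevalence: float
) -> float:
    """Intercept c with mean(expit(c + lp)) == target_prevalence over the sample.

    The mean fitted probability is strictly increasing in c, so the root
    is unique; solved by bracketed root-finding to 1e-12.
    """
    lp = np.asarray(linear_predictor_sample, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor sample contains non-finite values")
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must lie in (0, 1)")

    def f(c: float) -> float:
        return float(np.mean(expit(c + lp))) - target_prevalence

    lo = float(logit(target_prevalence) - np.max(np.abs(lp)) - 1.0)
    hi = float(logit(target_prevalence) + np.max(np.abs(lp)) + 1.0)
    return float(brentq(f, lo, hi, xtol=1e-13, rtol=1e-14))


def _place_truth(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    labels = cluster_labels(config.correlation)
    n_clusters = config.correlation.n_clusters
    if config.truth_placement == "same_cluster":
        pool = np.flatnonzero(labels == 0)
        if len(pool) < config.n_true:
            raise ConfigurationError("cluster 0 too small for same_cluster truth placement")
        return np.sort(rng.choice(pool, size=config.n_true, replace=False))
    # spread: round-robin over clusters, one random member per visit
    chosen: list[int] = []
    taken = np.zeros(config.correlation.n_metabolites, dtype=bool)
    for i in range(config.n_true):
        c = i % n_clusters
        pool = np.flatnonzero((labels == c) & ~taken)
        if len(pool) == 0:
            pool = np.flatnonzero(~taken)
        j = int(rng.choice(pool))
        chosen.append(j)
        taken[j] = True
    return np.sort(np.array(chosen))


def simulate_dataset(config: ScenarioConfig) -> SimulatedDataset:
    """Draw one dataset: X ~ MVN(0, Sigma), outcome from a linear / logistic model.

    The truth set is placed first (seeded), then X, then outcome noise,
    so regeneration with the same config is bit-identical.
    """
    rng = np.random.default_rng(config.seed)
    sigma, factor = _cached_factor(config.correlation)
    m = config.correlation.n_metabolites
    n = config.n_subjects

    truth = _place_truth(config, rng)
    beta = np.zeros(m)
    beta[truth] = np.asarray(config.effect_sizes, dtype=float)

    z = rng.standard_normal((n, m))
    X = z @ factor.T
    lp = X @ beta

    if config.outcome_type == "continuous":
        y = lp + rng.normal(0.0, config.noise_sd, size=n)
    else:
        c = calibrate_binary_intercept(lp, config.prevalence)
        y = rng.binomial(1, expit(c + lp)).astype(float)
        if config.case_control:
            X, y = _case_control_subsample(X, y, rng)
            lp = X @ beta
    return SimulatedDataset(X=X, y=y, beta=beta, truth_set=truth, config=config)


def _case_control_subsample(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample to an exact 1:1 case/control ratio (n preserved when possible)."""
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    k = min(len(cases), len(controls))
    keep = np.sort(
        np.concatenate(
            [rng.choice(cases, k, replace=False), rng.choice(controls, k, replace=False)]
        )
    )
    return X[keep], y[keep]


# ---------------------------------------------------------------------------
# cohort-style raw feature tables
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Cohort-style raw intensity table with sample covariates.

    Intensities are strictly positive (log-normal scale) with no
    missing values; covariates carry at least age (years), sex (0/1)
    and batch (categorical).
    """

    sample_ids: list
    metabolite_ids: list
    intensities: np.ndarray
    covariates: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        df = self.covariates.copy()
        df.insert(0, "sample_id", self.sample_ids)
        inten = pd.DataFrame(self.intensities, columns=self.metabolite_ids)
        return pd.concat([df.reset_index(drop=True), inten], axis=1)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        covar_cols = ["age", "sex", "batch"]
        met_cols = [c for c in df.columns if c not in ["sample_id"] + covar_cols]
        return cls(
            sample_ids=df["sample_id"].tolist(),
            metabolite_ids=met_cols,
            intensities=df[met_cols].to_numpy(dtype=float),
            covariates=df[covar_cols].copy(),
        )


def generate_cohort_table(
    n_samples: int,
    n_metabolites: int,
    planted_age_set: Sequence[int] = (),
    planted_sex_set: Sequence[int] = (),
    n_batches: int = 3,
    seed: int = 0,
    age_effect: float = 0.3,
    sex_effect: float = 0.5,
    batch_sd: float = 0.1,
    correlation: Optional[CorrelationSpec] = None,
) -> FeatureTable:
    """Generate a right-skewed cohort feature table with planted covariate effects.

    Log-intensities are a correlated Gaussian field plus covariate
    effects, so raw intensities are log-normal (strictly positive,
    right-skewed).  ``age_effect`` / ``sex_effect`` are log-scale shifts
    per SD of age / per sex class on the planted metabolite sets;
    ``batch_sd`` is the SD of random per-batch, per-metabolite shifts.
    """
    planted_age = np.asarray(sorted(planted_age_set), dtype=int)
    planted_sex = np.asarray(sorted(planted_sex_set), dtype=int)
    for s in (planted_age, planted_sex):
        if len(s) and (s.min() < 0 or s.max() >= n_metabolites):
            raise ValueError("planted index set out of range")
    if n_batches < 1:
        raise ValueError("n_batches must be positive")

    if correlation is None:
        correlation = CorrelationSpec(
            n_metabolites=n_metabolites,
            n_clusters=min(n_metabolites, max(2, n_metabolites // 20)),
            jitter_sd=0.005,
            corr_seed=seed,
        )
    rng = np.random.default_rng(seed)
    _, factor = _cached_factor(correlation)

    age = rng.normal(55.0, 10.0, size=n_samples)
    sex = rng.integers(0, 2, size=n_samples).astype(float)
    batch = rng.integers(0, n_batches, size=n_samples)

    base = rng.normal(5.0, 1.0, size=n_metabolites)  # baseline log-abundance
    log_x = base + rng.standard_normal((n_samples, n_metabolites)) @ factor.T
    age_z = (age - age.mean()) / age.std()
    if len(planted_age):
        log_x[:, planted_age] += np.outer(age_z, np.full(len(planted_age), age_effect))
    if len(planted_sex):
        log_x[:, planted_sex] += np.outer(sex, np.full(len(planted_sex), sex_effect))
    batch_shift = rng.normal(0.0, batch_sd, size=(n_batches, n_metabolites))
    log_x += batch_shift[batch]

    covar = pd.DataFrame({"age": age, "sex": sex, "batch": [f"B{b+1}" for b in batch]})
    return FeatureTable(
        sample_ids=[f"S{i+1:04d}" for i in range(n_samples)],
        metabolite_ids=[f"met{j+1:04d}" for j in range(n_metabolites)],
        intensities=np.exp(log_x),
        covariates=covar,
    )
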