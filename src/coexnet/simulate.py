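"""Seeded synthetic RNA-seq data with planted co-expression modules.

The generator emulates the statistical structure the analysis assumes:
negative-binomial counts over log-normal gene baselines, a handful of
planted gene modules driven by latent per-sample factors whose means
shift with the experimental condition, log-normal library sizes,
additive (log-scale) batch offsets, and optional outlier samples whose
profiles are destroyed by permutation. Companion generators plant
module-specific annotation enrichments and an external clustering that
is a noisy refinement of the planted modules — everything needed to
exercise ingest, network construction, module detection and the
interpretation statistics end to end.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coexnet.interpret import AnnotationTable, ExternalClustering
from coexnet.types import CountMatrix


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic count generator.

    Defaults describe a desk-scale analogue of a multi-study bulk
    RNA-seq compendium: 1,200 genes x 36 samples over 3 nutrient-style
    conditions and 2 sequencing batches, with 5 planted modules of
    40-80 genes whose members correlate at ~0.7 on the log scale.
    """

    n_genes: int = 1200
    n_samples: int = 36
    n_conditions: int = 3
    n_batches: int = 2
    n_modules: int = 5
    module_size_range: tuple[int, int] = (40, 80)
    within_module_correlation: float = 0.7  # target pairwise log-scale correlation
    cross_module_correlation: float = 0.1  # correlation between module factors
    signal_log_sd: float = 1.0  # log-scale sd of the per-gene dynamic range
    condition_effect_sd: float = 1.0  # sd of module-factor mean shifts per condition
    base_log_mean: float = 5.0  # natural-log mean count (~150 reads)
    base_log_sd: float = 1.0
    nb_dispersion: float = 0.1  # var = mu + dispersion * mu^2
    library_size_sigma: float = 0.25  # log-normal spread of library scaling
    batch_effect_sd: float = 0.5  # log-scale additive per-gene batch offsets
    n_outlier_samples: int = 1
    annotation_odds_ratio: float = 8.0
    annotation_baseline_prevalence: float = 0.1
    n_null_features: int = 3
    external_refinement_factor: int = 3
    external_noise_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.within_module_correlation < 1):
            raise ValueError("within_module_correlation must be in (0, 1)")
        if self.nb_dispersion <= 0 or self.library_size_sigma <= 0:
            raise ValueError("noise parameters must be positive")
        if min(self.n_genes, self.n_samples, self.n_modules) <= 0:
            raise ValueError("sizes must be positive")


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside a generated count matrix."""

    membership: pd.Series  # gene -> "M1".."Mk" or "none"
    factors: pd.DataFrame  # module x sample latent factors
    condition_shifts: pd.DataFrame  # module x condition factor means
    outlier_samples: list[str]
    batch_offsets: pd.DataFrame  # gene x batch log-scale offsets
    config: GeneratorConfig

    @property
    def module_labels(self) -> list[str]:
        return [m for m in self.membership.unique() if m != "none"]


def generate_expression(cfg: GeneratorConfig) -> tuple[CountMatrix, PlantedTruth]:
    """Simulate a raw count matrix with planted correlated modules.

    Module gene i in module m has log-mean
    ``base_i + s * (sqrt(rho) * f_m(sample) + sqrt(1-rho) * eps)`` so
    any two members correlate at ``rho`` on the log scale before count
    noise; background genes carry independent variation of the same
    magnitude. Factors receive condition-specific mean shifts, counts
    are negative-binomial with log-normal library sizes, batch offsets
    are added pre-sampling, and outlier samples are gene-permuted
    post-hoc.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.module_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_modules)
    if sizes.sum() > cfg.n_genes:
        raise ValueError(
            f"module sizes sum to {sizes.sum()} > n_genes={cfg.n_genes}"
        )
    gene_ids = [f"g{i + 1:05d}" for i in range(cfg.n_genes)]
    sample_ids = [f"s{j + 1:03d}" for j in range(cfg.n_samples)]
    conditions = [f"cond{j % cfg.n_conditions + 1}" for j in range(cfg.n_samples)]
    batches = [f"batch{(j // cfg.n_conditions) % cfg.n_batches + 1}" for j in range(cfg.n_samples)]
    meta = pd.DataFrame(
        {"condition": conditions, "batch": batches}, index=pd.Index(sample_ids, name="sample_id")
    )

    membership = pd.Series("none", index=pd.Index(gene_ids, name="gene_id"))
    start = 0
    for m, size in enumerate(sizes):
        membership.iloc[start : start + size] = f"M{m + 1}"
        start += size

    # latent module factors: cross-correlated noise + condition mean shifts
    shifts = pd.DataFrame(
        rng.normal(0.0, cfg.condition_effect_sd, size=(cfg.n_modules, cfg.n_conditions)),
        index=[f"M{m + 1}" for m in range(cfg.n_modules)],
        columns=[f"cond{c + 1}" for c in range(cfg.n_conditions)],
    )
    cov = np.full((cfg.n_modules, cfg.n_modules), cfg.cross_module_correlation)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    z = chol @ rng.standard_normal((cfg.n_modules, cfg.n_samples))
    factors = pd.DataFrame(z, index=shifts.index, columns=sample_ids)
    for j, cond in enumerate(conditions):
        factors.iloc[:, j] += shifts[cond].to_numpy()

    base = rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=cfg.n_genes)
    rho = cfg.within_module_correlation
    eps = rng.standard_normal((cfg.n_genes, cfg.n_samples))
    signal = np.sqrt(1.0 - rho) * eps
    for m, mod in enumerate(shifts.index):
        rows = np.flatnonzero((membership == mod).to_numpy())
        signal[rows] = np.sqrt(rho) * factors.loc[mod].to_numpy()[None, :] + signal[rows]
    bg = np.flatnonzero((membership == "none").to_numpy())
    signal[bg] = eps[bg]  # background: fully independent, unit-sd variation

    batch_levels = sorted(set(batches))
    offsets = pd.DataFrame(
        rng.normal(0.0, cfg.batch_effect_sd, size=(cfg.n_genes, len(batch_levels))),
        index=gene_ids,
        columns=batch_levels,
    )
    batch_term = offsets[batches].to_numpy()

    lib = rng.lognormal(0.0, cfg.library_size_sigma, size=cfg.n_samples)
    log_mu = base[:, None] + cfg.signal_log_sd * signal + batch_term + np.log(lib)[None, :]
    mu = np.exp(log_mu)
    r_nb = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))

    outliers: list[str] = []
    if cfg.n_outlier_samples > 0:
        chosen = rng.choice(cfg.n_samples, size=cfg.n_outlier_samples, replace=False)
        for j in sorted(chosen):
            counts[:, j] = rng.permutation(counts[:, j])
            outliers.append(sample_ids[j])

    cm = CountMatrix(
        counts=pd.DataFrame(counts.astype("int64"), index=gene_ids, columns=sample_ids),
        sample_meta=meta,
    )
    truth = PlantedTruth(
        membership=membership,
        factors=factors,
        condition_shifts=shifts,
        outlier_samples=outliers,
        batch_offsets=offsets,
        config=cfg,
    )
    return cm, truth


def generate_annotations(
    truth: PlantedTruth,
    odds_ratios: dict[str, float] | None = None,
    baseline_prevalence: float | None = None,
    n_null_features: int | None = None,
    seed: int | None = None,
) -> AnnotationTable:
    """Plant one enriched binary feature per module, plus null features.

    Feature ``feat_M`` is Bernoulli with baseline odds for every gene
    and odds multiplied by the module's odds ratio for members of M
    (default from the generator config). Null features use the baseline
    everywhere. Each feature forms its own predictor group.
    """
    cfg = truth.config
    p0 = cfg.annotation_baseline_prevalence if baseline_prevalence is None else baseline_prevalence
    n_null = cfg.n_null_features if n_null_features is None else n_null_features
    if odds_ratios is None:
        odds_ratios = {m: cfg.annotation_odds_ratio for m in truth.module_labels}
    if any(v < 0 for v in odds_ratios.values()):
        raise ValueError("odds ratios must be >= 0")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    genes = truth.membership.index
    cols = {}
    base_odds = p0 / (1.0 - p0)
    for mod, odds_ratio in odds_ratios.items():
        odds = np.where(
            (truth.membership == mod).to_numpy(), base_odds * odds_ratio, base_odds
        )
        p = odds / (1.0 + odds)
        cols[f"feat_{mod}"] = rng.random(len(genes)) < p
    for i in range(n_null):
        cols[f"null_{i + 1}"] = rng.random(len(genes)) < p0
    return AnnotationTable(features=pd.DataFrame(cols, index=genes))


def generate_external_clustering(
    truth: PlantedTruth,
    refinement_factor: int | None = None,
    noise_rate: float | None = None,
    seed: int | None = None,
) -> ExternalClustering:
    """A noisy refinement of the planted modules, as an external partition.

    Each planted module is split into ``refinement_factor`` sub-clusters
    (emulating a finer-grained legacy clustering of the same genes),
    after which a ``noise_rate`` fraction of covered genes is reassigned
    to uniformly random clusters. Background genes are absent from the
    mapping.
    """
    cfg = truth.config
    factor = cfg.external_refinement_factor if refinement_factor is None else refinement_factor
    noise = cfg.external_noise_rate if noise_rate is None else noise_rate
    if factor < 1:
        raise ValueError("refinement_factor must be >= 1")
    if not (0.0 <= noise <= 1.0):
        raise ValueError("noise_rate must be in [0, 1]")
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    labels: dict[str, str] = {}
    all_clusters: list[str] = []
    for mod in truth.module_labels:
        members = list(truth.membership.index[truth.membership == mod])
        chunks = np.array_split(np.arange(len(members)), factor)
        for j, chunk in enumerate(chunks):
            if len(chunk) == 0:
                continue
            cluster = f"{mod}_c{j + 1}"
            all_clusters.append(cluster)
            for idx in chunk:
                labels[members[idx]] = cluster
    series = pd.Series(labels)
    if noise > 0 and len(series):
        flip = rng.random(len(series)) < noise
        series[flip] = rng.choice(all_clusters, size=int(flip.sum()))
    return ExternalClustering(labels=series)
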