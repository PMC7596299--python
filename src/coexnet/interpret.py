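"""Module-interpretation statistics.

Four families of statistics connect a module partition to external
knowledge:

* chi-squared enrichment/depletion of categorical gene annotations
  within each module, aggregated into integer scores (+1/-1 at
  p < 0.05, +2/-2 at p < 1e-5) and summed over the predictors of a
  condition;
* concordance with an external gene clustering via two counting
  statistics (shared-module co-membership and plurality membership)
  with permutation and chi-squared nulls;
* the preferential distribution of external clusters over modules;
* repartition (cross-tabulation) of curated gene sets over modules.

The gene universe throughout is the set of genes carrying a module
assignment, with grey treated as a module of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from coexnet.types import ModulePartition

P_WEAK = 0.05
P_STRONG = 1e-5


@dataclass
class AnnotationTable:
    """Binary gene features grouped into named conditions.

    ``features`` is a boolean gene x feature DataFrame; ``groups`` maps
    a condition name to the features whose scores are summed for it
    (e.g. several chloroplast-targeting predictors forming one
    "chloroplast" condition). Ungrouped features form singleton groups.
    """

    features: pd.DataFrame
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.features.index.duplicated().any():
            raise ValueError("duplicate gene IDs in annotation table")
        if not self.groups:
            self.groups = {f: [f] for f in self.features.columns}
        for name, feats in self.groups.items():
            if not feats:
                raise ValueError(f"empty predictor group {name!r}")
            unknown = set(feats) - set(self.features.columns)
            if unknown:
                raise ValueError(f"group {name!r} references unknown features {unknown}")


def enrichment_test(
    part: ModulePartition,
    genes_with_feature: set[str],
    module: str,
    fisher: bool = False,
) -> tuple[float, float, str]:
    """2x2 chi-squared test of a feature's concentration in one module.

    The contingency table crosses module membership with feature
    presence over all genes in the partition (grey counts as a module).
    No continuity correction is applied; ``fisher=True`` switches to
    Fisher's exact test for small tables. Returns (statistic, p,
    direction) where direction is "enriched" when the in-module feature
    count exceeds its expectation, else "depleted"; degenerate tables
    (empty module or feature) return (0, 1, "none").
    """
    universe = set(part.assignment.index)
    feature = genes_with_feature & universe
    in_module = set(part.assignment.index[part.assignment == module])
    a = len(in_module & feature)
    b = len(in_module - feature)
    c = len(feature - in_module)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return 0.0, 1.0, "none"
    expected_a = (a + b) * (a + c) / table.sum()
    direction = "enriched" if a > expected_a else "depleted"
    if a == expected_a:
        direction = "none"
    if fisher:
        stat, p = stats.fisher_exact(table)
        return float(stat), float(p), direction
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), direction


def _score(p: float, direction: str) -> int:
    if direction == "none":
        return 0
    sign = 1 if direction == "enriched" else -1
    if p < P_STRONG:
        return 2 * sign
    if p < P_WEAK:
        return sign
    return 0


@dataclass
class EnrichmentScore:
    """Aggregated module x condition scores with per-predictor detail."""

    scores: pd.DataFrame  # module x condition, integer
    detail: pd.DataFrame  # module, condition, feature, chi2, p, direction, score


def score_conditions(
    part: ModulePartition,
    ann: AnnotationTable,
    fisher: bool = False,
    bh_correct: bool = False,
) -> EnrichmentScore:
    """Score every module against every annotation condition.

    Each predictor contributes +1 (enriched, p < 0.05), +2 (enriched,
    p < 1e-5), -1/-2 for depletions, 0 otherwise; a condition's score is
    the sum over its predictors. Raw p-values are used by default, as is
    conventional for this scoring scheme; ``bh_correct`` applies
    Benjamini-Hochberg across all (module, feature) tests first.
    """
    modules = list(part.modules)
    if "grey" in set(part.assignment):
        modules = modules + ["grey"]
    records = []
    for module in modules:
        for cond, feats in ann.groups.items():
            for feat in feats:
                genes = set(ann.features.index[ann.features[feat].astype(bool)])
                chi2, p, direction = enrichment_test(part, genes, module, fisher=fisher)
                records.append(
                    {
                        "module": module,
                        "condition": cond,
                        "feature": feat,
                        "statistic": chi2,
                        "p_value": p,
                        "direction": direction,
                    }
                )
    detail = pd.DataFrame(records)
    if bh_correct and len(detail):
        from statsmodels.stats.multitest import multipletests

        detail["p_value"] = multipletests(detail["p_value"], method="fdr_bh")[1]
    detail["score"] = [
        _score(p, d) for p, d in zip(detail["p_value"], detail["direction"])
    ]
    scores = (
        detail.pivot_table(
            index="module", columns="condition", values="score", aggfunc="sum"
        )
        .reindex(index=modules, columns=list(ann.groups))
        .fillna(0)
        .astype(int)
    )
    return EnrichmentScore(scores=scores, detail=detail)


@dataclass
class ExternalClustering:
    """Gene -> external cluster label; genes absent from the map allowed."""

    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        if (self.labels == "").any():
            raise ValueError("external cluster labels must be non-empty")


def _assessable(part: ModulePartition, ext: ExternalClustering) -> pd.DataFrame:
    genes = part.assignment.index.intersection(ext.labels.index)
    if len(genes) == 0:
        raise ValueError("no genes shared between partition and external clustering")
    return pd.DataFrame(
        {"module": part.assignment.loc[genes], "cluster": ext.labels.loc[genes]}
    )


def concordance_same_module(
    part: ModulePartition, ext: ExternalClustering
) -> tuple[int, float]:
    """Genes sharing a module with another gene from their external cluster.

    Counts assessable genes g for which some other gene has both the
    same external cluster and the same module assignment. Returns
    (count, fraction of assessable genes).
    """
    df = _assessable(part, ext)
    pair_sizes = df.groupby(["cluster", "module"], observed=True)["module"].transform("size")
    count = int((pair_sizes >= 2).sum())
    return count, count / len(df)


def concordance_plurality(
    part: ModulePartition, ext: ExternalClustering
) -> tuple[int, float]:
    """Genes inside their external cluster's single best-represented module.

    For each external cluster, the module holding the greatest number of
    the cluster's genes is found; genes in that module are counted only
    when the maximizer is unique (ties disqualify the whole cluster).
    """
    df = _assessable(part, ext)
    count = 0
    for _, sub in df.groupby("cluster", observed=True):
        sizes = sub["module"].value_counts()
        if len(sizes) > 1 and sizes.iloc[0] == sizes.iloc[1]:
            continue
        count += int(sizes.iloc[0])
    return count, count / len(df)


def preferential_distribution(
    part: ModulePartition, ext: ExternalClustering
) -> pd.DataFrame:
    """Preferred module of each external cluster.

    For each cluster with at least one assessable gene, reports the
    module with unique plurality of its genes ("tied" when the maximum
    is shared), the cluster size, and whether the cluster is
    preferentially distributed (unique plurality exists).
    """
    df = _assessable(part, ext)
    records = []
    for cluster, sub in df.groupby("cluster", observed=True):
        sizes = sub["module"].value_counts()
        tied = len(sizes) > 1 and sizes.iloc[0] == sizes.iloc[1]
        records.append(
            {
                "cluster": cluster,
                "n_assessable": len(sub),
                "preferred_module": "tied" if tied else sizes.index[0],
                "preferred_count": int(sizes.iloc[0]),
                "preferential": not tied,
            }
        )
    return pd.DataFrame(records).set_index("cluster")


@dataclass
class ConcordanceReport:
    """Both concordance statistics with permutation and chi-squared nulls."""

    n_assessable: int
    same_module: int
    same_module_fraction: float
    plurality: int
    plurality_fraction: float
    p_perm_same_module: float | None = None
    p_perm_plurality: float | None = None
    p_chi2_same_module: float | None = None
    p_chi2_plurality: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def concordance_null(
    part: ModulePartition,
    ext: ExternalClustering,
    n_perm: int = 999,
    seed: int = 0,
) -> ConcordanceReport:
    """Permutation and chi-squared nulls for both concordance statistics.

    Module labels are permuted over the assessable genes ``n_perm``
    times; the empirical one-tailed p is (1 + #{perm >= observed}) /
    (n_perm + 1). A one-tailed chi-squared approximation compares the
    observed count with the permutation-mean expectation on a
    concordant/non-concordant 2-cell table.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    df = _assessable(part, ext)
    n = len(df)
    obs_same, frac_same = concordance_same_module(part, ext)
    obs_plur, frac_plur = concordance_plurality(part, ext)

    rng = np.random.default_rng(seed)
    modules = df["module"].to_numpy()
    clusters = df["cluster"]
    genes = df.index
    same_null = np.empty(n_perm)
    plur_null = np.empty(n_perm)
    for i in range(n_perm):
        perm = pd.Series(rng.permutation(modules), index=genes)
        perm_part = ModulePartition(assignment=perm, provenance=part.provenance)
        sub_ext = ExternalClustering(labels=clusters)
        same_null[i], _ = concordance_same_module(perm_part, sub_ext)
        plur_null[i], _ = concordance_plurality(perm_part, sub_ext)

    def _pchi2(obs: float, null: np.ndarray) -> float:
        expected = max(null.mean(), 1e-12)
        if expected >= n:
            return 1.0
        chi2 = (obs - expected) ** 2 / expected + (obs - expected) ** 2 / (n - expected)
        p_two = stats.chi2.sf(chi2, df=1)
        return float(p_two / 2 if obs > expected else 1 - p_two / 2)

    return ConcordanceReport(
        n_assessable=n,
        same_module=obs_same,
        same_module_fraction=frac_same,
        plurality=obs_plur,
        plurality_fraction=frac_plur,
        p_perm_same_module=float((1 + (same_null >= obs_same).sum()) / (n_perm + 1)),
        p_perm_plurality=float((1 + (plur_null >= obs_plur).sum()) / (n_perm + 1)),
        p_chi2_same_module=_pchi2(obs_same, same_null),
        p_chi2_plurality=_pchi2(obs_plur, plur_null),
    )


def repartition_table(
    part: ModulePartition, curated: pd.DataFrame, category_col: str = "pathway"
) -> tuple[pd.DataFrame, list[str]]:
    """Cross-tabulate curated gene categories against module assignment.

    ``curated`` is indexed by gene ID with a categorical column (e.g.
    organelle pathway or TF family). Genes absent from the partition are
    returned separately rather than counted. Row sums equal category
    sizes among module-assigned genes.
    """
    in_part = curated.index.intersection(part.assignment.index)
    missing = [g for g in curated.index if g not in set(in_part)]
    sub = curated.loc[in_part]
    table = pd.crosstab(sub[category_col], part.assignment.loc[in_part])
    table.columns.name = "module"
    return table, missing
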