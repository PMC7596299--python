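"""Interpret the merged modules against annotations and an external clustering.

Computes the +/-1, +/-2 chi-squared enrichment score matrix over the
planted annotation features, both concordance statistics against the
external clustering with permutation and chi-squared nulls, the
preferential distribution of external clusters over modules, and a
repartition table treating the planted features as curated categories.

Run after 03:  python analysis/04_interpret.py
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from coexnet import export, interpret

parser = argparse.ArgumentParser()
parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
parser.add_argument("--mod-dir", type=Path, default=Path("results/modules"))
parser.add_argument("--out-dir", type=Path, default=Path("results/interpret"))
parser.add_argument("--n-perm", type=int, default=999)
parser.add_argument("--seed", type=int, default=7)
args = parser.parse_args()

part = export.read_partition(args.mod_dir / "modules_merged.tsv")
features = pd.read_csv(args.data_dir / "annotations.tsv", sep="\t", index_col=0).astype(bool)
ext_labels = pd.read_csv(args.data_dir / "external_clusters.tsv", sep="\t", index_col=0)["cluster"]

out = args.out_dir
out.mkdir(parents=True, exist_ok=True)

score = interpret.score_conditions(part, interpret.AnnotationTable(features=features))
export.write_table(score.scores, out / "enrichment_scores.tsv")
score.detail.to_csv(out / "enrichment_detail.tsv", sep="\t", index=False)
strong = (score.scores.abs() >= 2).to_numpy().sum()
print(
    f"enrichment: scored {score.scores.shape[0]} modules x "
    f"{score.scores.shape[1]} features; {strong} cells at strength |2| "
    f"(planted features should light up their own module)"
)

ext = interpret.ExternalClustering(labels=ext_labels)
report = interpret.concordance_null(part, ext, n_perm=args.n_perm, seed=args.seed)
(out / "concordance.json").write_text(json.dumps(report.to_dict(), indent=2))
pref = interpret.preferential_distribution(part, ext)
pref.to_csv(out / "preferential_distribution.tsv", sep="\t")
n_pref = int(pref.preferential.sum())
print(
    f"concordance over {report.n_assessable} assessable genes: "
    f"{report.same_module} ({report.same_module_fraction:.0%}) share a module "
    f"with a cluster-mate (perm p={report.p_perm_same_module:.3g}); "
    f"{report.plurality} ({report.plurality_fraction:.0%}) sit in their "
    f"cluster's plurality module (perm p={report.p_perm_plurality:.3g})"
)
print(f"preferential distribution: {n_pref}/{len(pref)} clusters prefer a single module")

annotated = features.index[features.any(axis=1)]
curated = pd.DataFrame(
    {"pathway": [features.columns[features.loc[g].to_numpy()][0] for g in annotated]},
    index=annotated,
)
table, missing = interpret.repartition_table(part, curated)
table.to_csv(out / "repartition.tsv", sep="\t")
print(
    f"repartition: {table.to_numpy().sum()} annotated genes cross-tabulated "
    f"over {table.shape[1]} modules ({len(missing)} genes outside the partition)"
)
print(f"wrote scores, concordance, preferential and repartition tables to {out}/")
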