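"""Generate the synthetic RNA-seq compendium used by the downstream steps.

Writes a raw count matrix with planted co-expression modules, sample
metadata (condition x batch), a binary annotation table with planted
module enrichments, an external clustering that noisily refines the
planted modules, and the ground-truth record.

Run from the repository root:  python analysis/01_simulate.py [--seed 7]
"""

import argparse
import json
from pathlib import Path

from coexnet import simulate
from coexnet.simulate import GeneratorConfig

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=7)
parser.add_argument("--out-dir", type=Path, default=Path("results/data"))
args = parser.parse_args()

cfg = GeneratorConfig(seed=args.seed)
cm, truth = simulate.generate_expression(cfg)
ann = simulate.generate_annotations(truth)
ext = simulate.generate_external_clustering(truth)

out = args.out_dir
out.mkdir(parents=True, exist_ok=True)
cm.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene_id")
cm.sample_meta.to_csv(out / "samples.tsv", sep="\t", index_label="sample_id")
ann.features.astype(int).to_csv(out / "annotations.tsv", sep="\t", index_label="gene_id")
ext.labels.rename("cluster").to_csv(out / "external_clusters.tsv", sep="\t", index_label="gene_id")
(out / "truth.json").write_text(
    json.dumps(
        {
            "seed": args.seed,
            "membership": truth.membership.to_dict(),
            "outlier_samples": truth.outlier_samples,
            "module_sizes": truth.membership.value_counts().to_dict(),
        },
        indent=2,
    )
)

sizes = truth.membership.value_counts()
print(f"simulated {cm.shape[0]} genes x {cm.shape[1]} samples (seed {args.seed})")
print(f"planted modules: {sizes.drop('none').to_dict()}; background genes: {sizes['none']}")
print(f"outlier samples planted: {truth.outlier_samples}")
print(f"wrote counts, metadata, annotations, external clusters, truth to {out}/")
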