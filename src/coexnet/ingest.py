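"""Count ingestion, normalization, filtering, outlier and batch handling.

The ingest stage turns a raw gene x sample count table into the
log-scale expression matrix the network consumes:

1. median-of-ratios size factors (the DESeq2 estimator),
2. low-expression filtering (gene dropped only if its median raw count
   is below threshold in *every* condition group),
3. log2(count / size_factor + 1) transform,
4. outlier-sample flagging from mean pairwise Spearman correlation,
5. per-batch gene-mean centering with the global gene mean restored.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from coexnet.types import CountMatrix, ExpressionMatrix

DEFAULT_MEDIAN_THRESHOLD = 10
DEFAULT_OUTLIER_Z = -2.5


def read_counts(path, meta_path) -> CountMatrix:
    """Read a delimited count table and a sample metadata table.

    The count file has gene IDs in the first column and sample IDs in
    the header; the metadata file must have ``sample_id``, ``condition``
    and ``batch`` columns covering every sample. Separator is sniffed
    from the extension (TSV default, CSV for ``.csv``).
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, index_col=0)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene ID: {dup!r}")
    # integer check with location reporting
    for col in raw.columns:
        vals = raw[col]
        as_int = vals.astype("float64")
        frac = as_int != np.floor(as_int)
        if frac.any():
            gene = vals.index[frac.to_numpy()][0]
            raise ValueError(
                f"non-integer count {vals[gene]!r} at gene {gene!r}, sample {col!r}"
            )
    counts = raw.astype("int64")

    msep = "," if str(meta_path).endswith(".csv") else "\t"
    meta = pd.read_csv(meta_path, sep=msep)
    if "sample_id" not in meta.columns:
        raise ValueError("metadata must have a sample_id column")
    meta = meta.set_index("sample_id")
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    return CountMatrix(counts=counts, sample_meta=meta)


def compute_size_factors(cm: CountMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios library size factors.

    For each gene with a strictly positive geometric mean across
    samples, the ratio count/geomean is formed; each sample's size
    factor is the median of its ratios. Size factors are invariant to a
    global rescaling of all counts (both counts and the reference
    scale). With ``pseudo_reference`` the per-gene reference is the
    geometric mean over *nonzero* counts only, rescuing datasets where
    every gene has a zero somewhere.
    """
    x = cm.counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    if pseudo_reference:
        nonzero = x > 0
        n_nz = nonzero.sum(axis=1)
        usable = n_nz > 0
        log_ref = np.full(x.shape[0], -np.inf)
        log_ref[usable] = (
            np.where(nonzero, logx, 0.0).sum(axis=1)[usable] / n_nz[usable]
        )
    else:
        log_ref = logx.mean(axis=1)  # -inf when any sample has a zero
        usable = np.isfinite(log_ref)
        if not usable.any():
            raise ValueError(
                "no gene has nonzero counts in every sample; "
                "re-run with pseudo_reference=True to use a nonzero-count "
                "geometric-mean reference"
            )
    log_ratios = logx[usable] - log_ref[usable, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=cm.sample_ids, name="size_factor")


def filter_low_expression(
    cm: CountMatrix, threshold: float = DEFAULT_MEDIAN_THRESHOLD
) -> tuple[CountMatrix, dict]:
    """Drop genes whose median raw count is below threshold in every condition.

    A gene survives if its within-condition median count is >= threshold
    in at least one condition group, which keeps genes expressed only
    under specific conditions. Returns the filtered matrix and a report
    listing removed genes.
    """
    conditions = cm.sample_meta["condition"]
    medians = pd.concat(
        {
            cond: cm.counts.loc[:, conditions.index[conditions == cond]].median(axis=1)
            for cond in conditions.unique()
        },
        axis=1,
    )
    keep = (medians >= threshold).any(axis=1)
    removed = list(cm.counts.index[~keep])
    if keep.sum() == 0:
        warnings.warn("low-expression filter removed every gene")
    filtered = CountMatrix(
        counts=cm.counts.loc[keep], sample_meta=cm.sample_meta
    )
    report = {
        "removed_genes": removed,
        "n_removed_genes": len(removed),
        "n_retained_genes": int(keep.sum()),
        "median_threshold": threshold,
    }
    return filtered, report


def detect_outlier_samples(
    em: ExpressionMatrix, z_cutoff: float = DEFAULT_OUTLIER_Z
) -> list[str]:
    """Flag samples poorly correlated with the rest of the dataset.

    Each sample's mean pairwise Spearman correlation with all other
    samples is standardized across samples; samples scoring below
    ``z_cutoff`` (default -2.5) are flagged. Spearman makes the flagging
    invariant to per-sample monotone transforms.
    """
    n = em.shape[1]
    if n < 4:
        raise ValueError(f"need at least 4 samples to flag outliers, got {n}")
    ranks = np.apply_along_axis(rankdata, 0, em.values.to_numpy())
    rho = np.corrcoef(ranks.T)
    mean_rho = (rho.sum(axis=1) - 1.0) / (n - 1)
    sd = mean_rho.std(ddof=0)
    if sd == 0:
        return []
    z = (mean_rho - mean_rho.mean()) / sd
    return [s for s, zi in zip(em.sample_ids, z) if zi < z_cutoff]


def remove_batch_effects(em: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene, per-batch mean centering with the global gene mean restored.

    After correction every batch has the same per-gene mean (the
    original global mean), removing additive batch offsets while leaving
    within-batch structure untouched. Batches with a single sample are
    left uncorrected with a warning. A single batch is an identity
    transform.
    """
    batches = em.sample_meta["batch"]
    if batches.nunique() < 2:
        return ExpressionMatrix(
            values=em.values.copy(),
            sample_meta=em.sample_meta,
            size_factors=em.size_factors,
            qc_report={**em.qc_report, "batch_correction": "skipped (single batch)"},
        )
    vals = em.values.to_numpy().copy()
    global_mean = vals.mean(axis=1, keepdims=True)
    skipped = []
    for batch in batches.unique():
        cols = np.flatnonzero((batches == batch).to_numpy())
        if len(cols) < 2:
            skipped.append(str(batch))
            continue
        batch_mean = vals[:, cols].mean(axis=1, keepdims=True)
        vals[:, cols] += global_mean - batch_mean
    if skipped:
        warnings.warn(f"batches with a single sample left uncorrected: {skipped}")
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=em.gene_ids, columns=em.sample_ids),
        sample_meta=em.sample_meta,
        size_factors=em.size_factors,
        qc_report={
            **em.qc_report,
            "batch_correction": "per-batch gene-mean centering",
            "uncorrected_batches": skipped,
        },
    )


def normalize(
    cm: CountMatrix,
    median_threshold: float = DEFAULT_MEDIAN_THRESHOLD,
    outlier_z: float = DEFAULT_OUTLIER_Z,
    correct_batches: bool = True,
    drop_outliers: bool = True,
    pseudo_reference: bool = False,
) -> ExpressionMatrix:
    """Full ingest: filter genes, normalize, flag outliers, correct batches.

    Composition: low-expression filter on raw counts -> median-of-ratios
    size factors on the filtered matrix -> log2(count/s + 1) ->
    Spearman outlier flagging (flagged samples dropped when
    ``drop_outliers``) -> batch centering. The qc_report records every
    removal with its reason. The output is *not* a count matrix;
    re-normalizing it is meaningless and prevented by type.
    """
    filtered, gene_report = filter_low_expression(cm, median_threshold)
    sf = compute_size_factors(filtered, pseudo_reference=pseudo_reference)
    logvals = np.log2(
        filtered.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0
    )
    em = ExpressionMatrix(
        values=pd.DataFrame(
            logvals, index=filtered.gene_ids, columns=filtered.sample_ids
        ),
        sample_meta=filtered.sample_meta,
        size_factors=sf,
        qc_report={**gene_report, "removed_samples": []},
    )
    if drop_outliers and em.shape[1] >= 4:
        flagged = detect_outlier_samples(em, z_cutoff=outlier_z)
        if flagged:
            keep = [s for s in em.sample_ids if s not in flagged]
            em = ExpressionMatrix(
                values=em.values.loc[:, keep],
                sample_meta=em.sample_meta.loc[keep],
                size_factors=em.size_factors.loc[keep],
                qc_report={
                    **em.qc_report,
                    "removed_samples": [
                        {"sample_id": s, "reason": "low mean Spearman correlation"}
                        for s in flagged
                    ],
                },
            )
    if correct_batches:
        em = remove_batch_effects(em)
    return em
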