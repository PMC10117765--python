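"""Per-feature read counts, RPKM and translation efficiency (TE).

The counting rule mirrors featureCounts' permissive overlap: a read is
assigned to every same-strand feature it overlaps by at least one
nucleotide.  RPKM = count x 10^9 / (feature length in nt x total mapped
reads of the sample).  TE is the per-replicate Ribo/RNA RPKM ratio,
defined only where the RNA RPKM is positive; undefined values propagate
as NaN and are excluded (never zeroed) from class means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome_io import FeatureRecord

__all__ = [
    "count_reads",
    "count_features",
    "rpkm",
    "translation_efficiency",
    "quantify_features",
    "class_te_summary",
]


class _ReadIndex:
    """Sorted per-(replicon, strand) read-boundary arrays for fast
    same-strand >=1 nt overlap counting."""

    def __init__(self, reads: pd.DataFrame):
        self.groups = {}
        for (rep, strand), grp in reads.groupby(["replicon_id", "strand"],
                                                sort=False):
            starts = np.sort(grp["start"].to_numpy(dtype=np.int64))
            ends = np.sort(grp["end"].to_numpy(dtype=np.int64))
            self.groups[(rep, strand)] = (starts, ends)

    def count(self, replicon_id: str, strand: str, start: int, end: int) -> int:
        entry = self.groups.get((replicon_id, strand))
        if entry is None:
            return 0
        starts, ends = entry
        # overlap iff read.start < end and read.end > start
        n_start_ok = np.searchsorted(starts, end, side="left")
        n_end_bad = np.searchsorted(ends, start, side="right")
        return int(n_start_ok - n_end_bad)


def count_reads(feature: FeatureRecord, reads: pd.DataFrame) -> int:
    """Number of same-strand reads overlapping the feature by >= 1 nt.

    A read may count toward several overlapping features.
    """
    return _ReadIndex(reads).count(
        feature.replicon_id, feature.strand, feature.start, feature.end
    )


def count_features(features, reads: pd.DataFrame) -> pd.Series:
    """Vectorised count_reads over many features (one shared index)."""
    index = _ReadIndex(reads)
    return pd.Series(
        {
            f.feature_id: index.count(f.replicon_id, f.strand, f.start, f.end)
            for f in features
        },
        dtype=int,
    )


def rpkm(count: int, feature_length_nt: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_length_nt <= 0:
        raise ValueError("feature length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    return count * 1e9 / (feature_length_nt * total_mapped_reads)


def translation_efficiency(rpkm_ribo, rpkm_rna):
    """Per-replicate TE values and their mean.

    TE[r] = rpkm_ribo[r] / rpkm_rna[r], defined only where the RNA RPKM is
    positive; undefined replicates are NaN and the mean is over defined
    values only (NaN when none are defined).
    """
    ribo = np.asarray(rpkm_ribo, dtype=float)
    rna = np.asarray(rpkm_rna, dtype=float)
    te = np.where(rna > 0, ribo / np.where(rna > 0, rna, 1.0), np.nan)
    mean_te = float(np.nanmean(te)) if np.any(~np.isnan(te)) else float("nan")
    return te, mean_te


def quantify_features(
    features,
    reads: pd.DataFrame,
    sample_pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Quantification table: counts, RPKM and TE per replicate plus mean TE.

    ``sample_pairs`` pairs each Ribo-seq sample with its RNA-seq partner
    explicitly, e.g. ``[("ribo_1", "rna_1"), ("ribo_2", "rna_2")]``;
    pairing is never inferred from sample names.
    """
    features = list(features)
    rows = {f.feature_id: {"feature_id": f.feature_id,
                           "feature_class": f.feature_class,
                           "replicon_id": f.replicon_id,
                           "length_nt": f.length}
            for f in features}
    n_rep = len(sample_pairs)
    for r, (ribo_sample, rna_sample) in enumerate(sample_pairs, start=1):
        for library, sample in (("ribo", ribo_sample), ("rna", rna_sample)):
            sel = reads[reads["sample_id"] == sample]
            total = len(sel)
            counts = count_features(features, sel)
            for f in features:
                c = int(counts[f.feature_id])
                rows[f.feature_id][f"count_{library}_{r}"] = c
                rows[f.feature_id][f"rpkm_{library}_{r}"] = rpkm(
                    c, f.length, total
                ) if total > 0 else float("nan")
    table = pd.DataFrame(rows.values())
    ribo_cols = [f"rpkm_ribo_{r}" for r in range(1, n_rep + 1)]
    rna_cols = [f"rpkm_rna_{r}" for r in range(1, n_rep + 1)]
    te = np.full((len(table), n_rep), np.nan)
    for r in range(n_rep):
        te[:, r], _ = translation_efficiency(
            table[ribo_cols[r]].to_numpy(), table[rna_cols[r]].to_numpy()
        )
    for r in range(n_rep):
        table[f"te_{r + 1}"] = te[:, r]
    with np.errstate(invalid="ignore"):
        defined = ~np.isnan(te)
        mean_te = np.where(defined.any(axis=1),
                           np.nansum(np.where(defined, te, 0.0), axis=1)
                           / np.maximum(defined.sum(axis=1), 1),
                           np.nan)
    table["mean_te"] = mean_te
    return table


def class_te_summary(quants: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of defined mean-TE values per feature class.

    Classes with no feature (or no defined TE) are absent from the
    result, never reported as zero.
    """
    defined = quants[~quants["mean_te"].isna()]
    summary = defined.groupby("feature_class")["mean_te"].mean()
    return summary.dropna()
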