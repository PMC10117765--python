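"""Translation-filter cascades, curation heuristics and sORF summaries.

Annotated sORFs are called translated when mean TE >= 0.5 and both
Ribo-seq and RNA-seq RPKM are >= 10 (inclusive boundaries).  Novel
predictor candidates additionally need the RPKM rule satisfied in every
replicate and a DeepRibo-like score strictly greater than -0.5.  On top
of the cascade, four quantitative curation flags emulate visual
inspection of paired coverage: footprint signal confined to the ORF
+/- 16 nt, exclusion from residual UTRs, evenness of coverage, and a
Ribo >= RNA signal ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .genome_io import FeatureRecord, Replicon, feature_sequence

__all__ = [
    "Thresholds",
    "CurationParams",
    "filter_annotated_sorfs",
    "filter_novel_candidates",
    "curation_flags",
    "apply_curation",
    "select_primary_candidates",
    "classify_context",
    "summarize_sorfs",
    "candidate_codons",
]


@dataclass
class Thresholds:
    """Expression cut-offs of the translation filter.

    ``te_min`` and ``rpkm_min`` are inclusive (>=); ``deepribo_min`` is a
    strict lower bound (>).  ``rpkm_rule`` selects whether the RPKM rule
    applies to the replicate mean or to each replicate separately.
    """

    te_min: float = 0.5
    rpkm_min: float = 10.0
    deepribo_min: float = -0.5
    rpkm_rule: str = "mean"  # or "each_replicate"

    def __post_init__(self) -> None:
        if self.te_min < 0 or self.rpkm_min < 0:
            raise ValueError("te_min and rpkm_min must be non-negative")
        if self.rpkm_rule not in ("mean", "each_replicate"):
            raise ValueError(f"unknown rpkm_rule {self.rpkm_rule!r}")


@dataclass
class CurationParams:
    """Constants of the four curation proxies (all exposed, all tunable)."""

    boundary_fraction: float = 0.8  # signal share inside [start-16, stop+16]
    utr_max_ratio: float = 0.3  # residual-UTR vs in-ORF mean density
    max_position_share: float = 0.5  # evenness part 1
    max_codon_cv: float = 2.0  # evenness part 2
    min_signal_ratio: float = 1.0  # in-ORF Ribo vs RNA mean
    pileup_extent: int = 16
    default_flank: int = 50  # locus flank when no transcript is annotated


def _rpkm_pass(row: pd.Series, thresholds: Thresholds, rule: str) -> bool:
    ribo = [v for k, v in row.items() if k.startswith("rpkm_ribo_")]
    rna = [v for k, v in row.items() if k.startswith("rpkm_rna_")]
    if rule == "mean":
        return (np.nanmean(ribo) >= thresholds.rpkm_min
                and np.nanmean(rna) >= thresholds.rpkm_min)
    return (all(v >= thresholds.rpkm_min for v in ribo)
            and all(v >= thresholds.rpkm_min for v in rna))


def filter_annotated_sorfs(
    quants: pd.DataFrame,
    sorf_ids,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """TE/RPKM cascade over annotated sORFs.

    Returns one row per sORF with pass flags and a verdict
    (``filtered_pass`` or ``fail``); an undefined mean TE fails with the
    reason recorded.
    """
    indexed = quants.set_index("feature_id")
    rows = []
    for fid in sorf_ids:
        row = indexed.loc[fid]
        mean_te = row["mean_te"]
        if np.isnan(mean_te):
            rows.append(dict(candidate_id=fid, pass_te=False, pass_rpkm=False,
                             verdict="fail", reason="undefined mean TE"))
            continue
        pass_te = bool(mean_te >= thresholds.te_min)
        pass_rpkm = bool(_rpkm_pass(row, thresholds, thresholds.rpkm_rule))
        verdict = "filtered_pass" if (pass_te and pass_rpkm) else "fail"
        rows.append(dict(candidate_id=fid, pass_te=pass_te,
                         pass_rpkm=pass_rpkm, verdict=verdict, reason=""))
    return pd.DataFrame(rows)


def filter_novel_candidates(
    quants: pd.DataFrame,
    candidates: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Cascade for novel predictor candidates.

    The RPKM rule is applied per replicate ("in both replicates") and the
    DeepRibo score must be strictly greater than the threshold; a missing
    score fails with the reason recorded.  ``candidates`` must carry a
    ``quant_id`` or ``candidate_id`` column matching the quant table.
    """
    indexed = quants.set_index("feature_id")
    rows = []
    for cand in candidates.itertuples():
        cid = cand.candidate_id
        qid = getattr(cand, "quant_id", cid)
        row = indexed.loc[qid]
        score = getattr(cand, "deepribo_score", None)
        if score is None or (isinstance(score, float) and np.isnan(score)):
            rows.append(dict(candidate_id=cid, pass_te=False, pass_rpkm=False,
                             pass_score=False, verdict="fail",
                             reason="missing DeepRibo score"))
            continue
        mean_te = row["mean_te"]
        pass_te = bool(not np.isnan(mean_te) and mean_te >= thresholds.te_min)
        pass_rpkm = bool(_rpkm_pass(row, thresholds, "each_replicate"))
        pass_score = bool(score > thresholds.deepribo_min)
        verdict = ("filtered_pass" if (pass_te and pass_rpkm and pass_score)
                   else "fail")
        rows.append(dict(candidate_id=cid, pass_te=pass_te,
                         pass_rpkm=pass_rpkm, pass_score=pass_score,
                         verdict=verdict,
                         reason="" if verdict != "fail" else "below cut-off"))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# curation proxies


def curation_flags(
    feature: FeatureRecord,
    ribo_track: CoverageTrack,
    rna_track: CoverageTrack,
    params: CurationParams = CurationParams(),
    transcript: tuple[int, int] | None = None,
    exclude: list | None = None,
) -> dict:
    """Quantitative stand-ins for visual coverage curation.

    * ``boundary``: fraction of locus Ribo signal inside
      ``[start - extent, stop + extent]``;
    * ``utr_exclusion``: mean Ribo density in the residual transcript
      flanks relative to in-ORF density;
    * ``evenness``: largest single-position share of in-ORF signal and
      per-codon coefficient of variation;
    * ``signal_ratio``: in-ORF mean Ribo over in-ORF mean RNA (both
      tracks must be min-normalized so the scales are comparable).

    ``transcript`` bounds the locus; without one, the ORF plus a default
    flank is used.  ``exclude`` intervals (other annotated ORFs on a
    shared transcript, each widened by the pile-up extent) are masked out
    of the locus before the boundary and flank statistics, emulating how
    a curator discounts neighbouring genes in an operon.  Zero in-ORF
    Ribo coverage turns all flags off.
    """
    key = (feature.replicon_id, feature.strand)
    ribo = ribo_track.arrays[key]
    rna = rna_track.arrays[key]
    if exclude:
        ribo = ribo.copy()
        pe = params.pileup_extent
        for lo, hi in exclude:
            if (lo, hi) == (feature.start, feature.end):
                continue
            ribo[max(lo - pe, 0): hi + pe] = 0.0
        w_lo, w_hi = max(feature.start - pe, 0), feature.end + pe
        ribo[w_lo:w_hi] = ribo_track.arrays[key][w_lo:w_hi]
    ext = params.pileup_extent
    if transcript is None:
        t_lo = max(feature.start - params.default_flank, 0)
        t_hi = min(feature.end + params.default_flank, len(ribo))
    else:
        t_lo, t_hi = transcript
    win_lo = max(feature.start - ext, t_lo, 0)
    win_hi = min(feature.end + ext, t_hi, len(ribo))

    in_orf = ribo[feature.start: feature.end]
    flags = dict.fromkeys(
        ("boundary", "utr_exclusion", "evenness", "signal_ratio"), False)
    scores = dict(boundary_score=0.0, utr_ratio=np.inf,
                  max_position_share=1.0, codon_cv=np.inf, signal_ratio_value=0.0)
    if in_orf.sum() == 0:
        return {**flags, **scores}

    locus = ribo[t_lo:t_hi]
    window = ribo[win_lo:win_hi]
    locus_sum = float(locus.sum())
    boundary_score = float(window.sum()) / locus_sum if locus_sum else 0.0
    flags["boundary"] = boundary_score >= params.boundary_fraction
    scores["boundary_score"] = boundary_score

    flank = np.concatenate([ribo[t_lo:win_lo], ribo[win_hi:t_hi]])
    in_orf_mean = float(in_orf.mean())
    if len(flank):
        utr_ratio = float(flank.mean()) / in_orf_mean
    else:
        utr_ratio = 0.0
    flags["utr_exclusion"] = utr_ratio <= params.utr_max_ratio
    scores["utr_ratio"] = utr_ratio

    share = float(in_orf.max()) / float(in_orf.sum())
    codons = in_orf[: 3 * (len(in_orf) // 3)].reshape(-1, 3).sum(axis=1)
    cv = float(codons.std() / codons.mean()) if codons.mean() > 0 else np.inf
    flags["evenness"] = (share <= params.max_position_share
                         and cv <= params.max_codon_cv)
    scores["max_position_share"] = share
    scores["codon_cv"] = cv

    rna_mean = float(rna[feature.start: feature.end].mean())
    ratio = in_orf_mean / rna_mean if rna_mean > 0 else np.inf
    flags["signal_ratio"] = ratio >= params.min_signal_ratio
    scores["signal_ratio_value"] = 0.0 if ratio == np.inf else ratio
    if rna_mean == 0:
        flags["signal_ratio"] = True  # no transcript signal to outcompete
        scores["signal_ratio_value"] = float("inf")
    return {**flags, **scores}


def apply_curation(
    calls: pd.DataFrame,
    features_by_id: dict,
    ribo_track: CoverageTrack,
    rna_track: CoverageTrack,
    params: CurationParams = CurationParams(),
    transcripts: dict | None = None,
    exclusions: dict | None = None,
) -> pd.DataFrame:
    """Attach curation flags and upgrade passing calls.

    Rows whose cascade verdict is ``filtered_pass`` and whose four flags
    are all true become ``translated_high_confidence``.
    """
    flag_names = ("boundary", "utr_exclusion", "evenness", "signal_ratio")
    out = calls.copy()
    records = []
    for row in out.itertuples():
        feature = features_by_id[row.candidate_id]
        transcript = (transcripts or {}).get(row.candidate_id)
        exclude = (exclusions or {}).get(row.candidate_id)
        records.append(curation_flags(feature, ribo_track, rna_track,
                                      params, transcript, exclude))
    flag_df = pd.DataFrame(records, index=out.index)
    out = pd.concat([out, flag_df], axis=1)
    all_flags = out[list(flag_names)].all(axis=1)
    out["verdict"] = np.where(
        (out["verdict"] == "filtered_pass") & all_flags,
        "translated_high_confidence", out["verdict"],
    )
    return out


def select_primary_candidates(candidates: pd.DataFrame) -> pd.DataFrame:
    """Resolve nested/overlapping candidates that share a stop codon.

    Within each (replicon, strand, stop) group the highest-scoring
    candidate is kept (ties to the longest); the rest are flagged
    ``shadowed`` and excluded from downstream calling.
    """
    out = candidates.copy()
    stop = np.where(out["strand"] == "+", out["end"] - 1, out["start"])
    out["_stop"] = stop
    out["_len"] = out["end"] - out["start"]
    ranked = out.sort_values(["deepribo_score", "_len"],
                             ascending=[False, False], kind="mergesort")
    first = ranked.drop_duplicates(subset=["replicon_id", "strand", "_stop"])
    out["shadowed"] = ~out.index.isin(first.index)
    return out.drop(columns=["_stop", "_len"])


# ---------------------------------------------------------------------------
# genomic context and summaries


def _contains(outer: FeatureRecord, start: int, end: int, strand: str,
              same_strand: bool) -> bool:
    if same_strand and outer.strand != strand:
        return False
    if not same_strand and outer.strand == strand:
        return False
    return outer.start <= start and end <= outer.end


def classify_context(
    feature: FeatureRecord,
    annotation,
    transcripts: list | None = None,
) -> str:
    """Genomic-context label for an sORF.

    Precedence: same-strand containment in an annotated 5'-UTR, then
    3'-UTR, then sRNA/hkRNA; then operon-internal (inside a same-strand
    multi-CDS transcript between CDS); then antisense (>= 1 nt
    opposite-strand overlap with anything annotated); else intergenic.
    ``transcripts`` are optional (replicon, strand, start, end) tuples of
    multi-gene transcripts.
    """
    s, e, strand = feature.start, feature.end, feature.strand
    for cls, label in (("five_prime_UTR", "five_prime_UTR"),
                       ("three_prime_UTR", "three_prime_UTR")):
        for other in annotation:
            if other.feature_class == cls and \
                    other.replicon_id == feature.replicon_id and \
                    _contains(other, s, e, strand, same_strand=True):
                return label
    for other in annotation:
        if other.feature_class in ("sRNA", "hkRNA") and \
                other.replicon_id == feature.replicon_id and \
                _contains(other, s, e, strand, same_strand=True):
            return "sRNA_hosted"
    if transcripts:
        for (rep, t_strand, t_s, t_e) in transcripts:
            if rep == feature.replicon_id and t_strand == strand and \
                    t_s <= s and e <= t_e:
                cds = [o for o in annotation
                       if o.feature_class in ("CDS", "sORF")
                       and o.replicon_id == rep and o.strand == strand
                       and o.start >= t_s and o.end <= t_e
                       and not (o.start == s and o.end == e)]
                left = any(o.end <= s for o in cds)
                right = any(o.start >= e for o in cds)
                if left and right:
                    return "operon_internal"
    for other in annotation:
        if other.replicon_id == feature.replicon_id and \
                other.strand != strand and other.start < e and other.end > s:
            return "antisense"
    if transcripts:
        for (rep, t_strand, t_s, t_e) in transcripts:
            if rep == feature.replicon_id and t_strand != strand and \
                    t_s < e and t_e > s:
                return "antisense"
    return "intergenic"


def candidate_codons(feature: FeatureRecord, replicon: Replicon) -> tuple[str, str]:
    """Start and stop codon read from the genome at the feature's
    coordinates (authoritative over any predictor annotation)."""
    seq = feature_sequence(feature, replicon)
    return seq[:3], seq[-3:]


AA_LENGTH_BINS = (0, 20, 30, 40, 50, 60, 71)


def summarize_sorfs(features, replicons) -> dict:
    """Start/stop codon tallies, replicon distribution (percent) and
    aa-length histogram for a set of called sORFs."""
    by_id = {r.id: r for r in replicons}
    starts, stops, reps, aas = [], [], [], []
    for f in features:
        start, stop = candidate_codons(f, by_id[f.replicon_id])
        starts.append(start if start in ("ATG", "GTG", "TTG") else "other")
        stops.append(stop)
        reps.append(f.replicon_id)
        aas.append(f.length // 3 - 1)
    start_tally = pd.Series(starts).value_counts()
    stop_tally = pd.Series(stops).value_counts()
    rep_counts = pd.Series(reps).value_counts()
    rep_percent = 100.0 * rep_counts / rep_counts.sum()
    hist = pd.cut(pd.Series(aas), bins=list(AA_LENGTH_BINS),
                  right=False).value_counts().sort_index()
    return {
        "start_codons": start_tally,
        "stop_codons": stop_tally,
        "replicon_percent": rep_percent,
        "aa_length_histogram": hist,
    }
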