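"""Translation-filter cascades, curation proxies, context and summaries."""

import numpy as np
import pandas as pd
import pytest

from riboseep.coverage import CoverageTrack
from riboseep.genome_io import AnnotationSet, FeatureRecord, Replicon
from riboseep.sorf_call import (
    CurationParams,
    Thresholds,
    candidate_codons,
    classify_context,
    curation_flags,
    filter_annotated_sorfs,
    filter_novel_candidates,
    select_primary_candidates,
    summarize_sorfs,
)


def quant_row(fid, te, ribo=(100.0, 100.0), rna=(100.0, 100.0)):
    return dict(feature_id=fid, feature_class="sORF",
                rpkm_ribo_1=ribo[0], rpkm_ribo_2=ribo[1],
                rpkm_rna_1=rna[0], rpkm_rna_2=rna[1], mean_te=te)


class TestAnnotatedFilter:
    def test_inclusive_boundaries_pass(self):
        quants = pd.DataFrame([quant_row("a", 0.5, (10.0, 10.0), (10.0, 10.0))])
        calls = filter_annotated_sorfs(quants, ["a"])
        assert calls.iloc[0]["verdict"] == "filtered_pass"

    def test_just_below_te_fails(self):
        quants = pd.DataFrame([quant_row("a", 0.49)])
        calls = filter_annotated_sorfs(quants, ["a"])
        assert calls.iloc[0]["verdict"] == "fail"

    def test_undefined_te_fails_with_reason(self):
        quants = pd.DataFrame([quant_row("a", np.nan)])
        calls = filter_annotated_sorfs(quants, ["a"])
        assert calls.iloc[0]["verdict"] == "fail"
        assert "undefined" in calls.iloc[0]["reason"]

    def test_mean_rpkm_rule_default(self):
        # replicate RPKMs 8 and 12 average to 10 -> passes under "mean"
        quants = pd.DataFrame([quant_row("a", 1.0, (8.0, 12.0), (8.0, 12.0))])
        assert filter_annotated_sorfs(quants, ["a"]).iloc[0]["verdict"] == \
            "filtered_pass"

    def test_matches_brute_force_on_randomized_records(self, rng):
        n = 259
        quants = pd.DataFrame([
            quant_row(f"f{i}", te=float(rng.uniform(0, 1.5)),
                      ribo=(float(rng.uniform(0, 30)),) * 2,
                      rna=(float(rng.uniform(0, 30)),) * 2)
            for i in range(n)
        ])
        calls = filter_annotated_sorfs(quants, quants["feature_id"])
        got = (calls["verdict"] == "filtered_pass").sum()
        expected = sum(
            1 for r in quants.itertuples()
            if r.mean_te >= 0.5
            and (r.rpkm_ribo_1 + r.rpkm_ribo_2) / 2 >= 10
            and (r.rpkm_rna_1 + r.rpkm_rna_2) / 2 >= 10
        )
        assert got == expected


class TestNovelFilter:
    def _candidates(self, score):
        return pd.DataFrame([dict(candidate_id="c", quant_id="c",
                                  deepribo_score=score)])

    def test_boundary_pass(self):
        quants = pd.DataFrame([quant_row("c", 0.5, (10.0, 10.0), (10.0, 10.0))])
        calls = filter_novel_candidates(quants, self._candidates(-0.4))
        assert calls.iloc[0]["verdict"] == "filtered_pass"

    def test_score_threshold_is_strict(self):
        quants = pd.DataFrame([quant_row("c", 0.5, (10.0, 10.0), (10.0, 10.0))])
        calls = filter_novel_candidates(quants, self._candidates(-0.5))
        assert calls.iloc[0]["verdict"] == "fail"
        assert not calls.iloc[0]["pass_score"]

    def test_rpkm_required_in_each_replicate(self):
        quants = pd.DataFrame([quant_row("c", 1.0, (10.0, 9.0), (20.0, 20.0))])
        calls = filter_novel_candidates(quants, self._candidates(1.0))
        assert calls.iloc[0]["verdict"] == "fail"

    def test_missing_score_fails_with_reason(self):
        quants = pd.DataFrame([quant_row("c", 1.0)])
        calls = filter_novel_candidates(
            quants, pd.DataFrame([dict(candidate_id="c", quant_id="c",
                                       deepribo_score=np.nan)]))
        assert calls.iloc[0]["verdict"] == "fail"
        assert "score" in calls.iloc[0]["reason"]

    def test_threshold_monotonicity(self, rng):
        quants = pd.DataFrame([
            quant_row(f"f{i}", te=float(rng.uniform(0, 2)),
                      ribo=(float(rng.uniform(0, 40)),
                            float(rng.uniform(0, 40))),
                      rna=(float(rng.uniform(0, 40)),
                           float(rng.uniform(0, 40))))
            for i in range(200)
        ])
        candidates = pd.DataFrame([
            dict(candidate_id=f"f{i}", quant_id=f"f{i}",
                 deepribo_score=float(rng.normal(0, 1)))
            for i in range(200)
        ])
        grid = [(te, rp) for te in (0.0, 0.25, 0.5, 0.75, 1.0)
                for rp in (0.0, 5.0, 10.0, 15.0, 20.0)]
        passes = {}
        for te_min, rpkm_min in grid:
            thresholds = Thresholds(te_min=te_min, rpkm_min=rpkm_min)
            calls = filter_novel_candidates(quants, candidates, thresholds)
            passes[(te_min, rpkm_min)] = set(
                calls.loc[calls["verdict"] == "filtered_pass", "candidate_id"])
        for (te1, rp1), set1 in passes.items():
            for (te2, rp2), set2 in passes.items():
                if te2 >= te1 and rp2 >= rp1:
                    assert set2 <= set1

    def test_output_invariant_to_candidate_order(self, rng):
        quants = pd.DataFrame([
            quant_row(f"f{i}", te=float(rng.uniform(0, 2))) for i in range(30)
        ])
        candidates = pd.DataFrame([
            dict(candidate_id=f"f{i}", quant_id=f"f{i}",
                 deepribo_score=float(rng.normal(0, 1)))
            for i in range(30)
        ])
        forward = filter_novel_candidates(quants, candidates)
        backward = filter_novel_candidates(quants, candidates.iloc[::-1])
        merged = forward.merge(backward, on="candidate_id",
                               suffixes=("_f", "_b"))
        assert (merged["verdict_f"] == merged["verdict_b"]).all()


def _track(ribo_array, rna_array=None):
    arrays = {("chr", "+"): np.asarray(ribo_array, dtype=float)}
    ribo = CoverageTrack("s", "RIBO", "global", arrays, 100, "min")
    rna_arrays = {("chr", "+"): np.asarray(
        rna_array if rna_array is not None else np.zeros_like(ribo_array),
        dtype=float)}
    rna = CoverageTrack("s", "RNA", "global", rna_arrays, 100, "min")
    return ribo, rna


class TestCuration:
    def test_clean_planted_sorf_passes_all_flags(self, pipeline_out):
        calls = pd.read_csv(pipeline_out / "novel_sorf_calls.tsv", sep="\t")
        cand = pd.read_csv(pipeline_out / "candidates.tsv", sep="\t")
        merged = calls.merge(cand, on="candidate_id")
        clean = merged[merged["truth_translated"]
                       & merged["candidate_id"].str.contains("cand_sorf_")]
        assert len(clean) > 0
        flags = clean[["boundary", "utr_exclusion", "evenness",
                       "signal_ratio"]]
        assert flags.all(axis=None)

    def test_single_position_artifact_fails_evenness(self):
        ribo = np.zeros(200)
        ribo[100:130] = 1.0
        ribo[110] = 200.0  # ~90 % of the locus signal at one position
        rna = np.full(200, 1.0)
        ribo_t, rna_t = _track(ribo, rna)
        feature = FeatureRecord("f", "chr", "+", 100, 130,
                                feature_class="other")
        flags = curation_flags(feature, ribo_t, rna_t)
        assert not flags["evenness"]

    def test_rna_only_coverage_fails_signal_ratio(self):
        ribo = np.zeros(200)
        ribo[100:130] = 0.2
        rna = np.zeros(200)
        rna[80:150] = 5.0
        ribo_t, rna_t = _track(ribo, rna)
        feature = FeatureRecord("f", "chr", "+", 100, 130,
                                feature_class="other")
        flags = curation_flags(feature, ribo_t, rna_t)
        assert not flags["signal_ratio"]

    def test_zero_ribo_coverage_turns_all_flags_off(self):
        ribo_t, rna_t = _track(np.zeros(200), np.full(200, 3.0))
        feature = FeatureRecord("f", "chr", "+", 100, 130,
                                feature_class="other")
        flags = curation_flags(feature, ribo_t, rna_t)
        assert not any(flags[k] for k in
                       ("boundary", "utr_exclusion", "evenness",
                        "signal_ratio"))

    def test_utr_coverage_fails_exclusion(self):
        ribo = np.zeros(400)
        ribo[200:230] = 2.0  # ORF
        ribo[100:180] = 1.5  # heavy residual 5'-UTR signal
        rna = np.full(400, 1.0)
        ribo_t, rna_t = _track(ribo, rna)
        feature = FeatureRecord("f", "chr", "+", 200, 230,
                                feature_class="other")
        flags = curation_flags(feature, ribo_t, rna_t, transcript=(100, 280))
        assert not flags["utr_exclusion"]
        assert not flags["boundary"]


class TestContext:
    def _annotation(self):
        return AnnotationSet("ann", 1, [
            FeatureRecord("utr5", "chr", "+", 100, 200,
                          feature_class="five_prime_UTR"),
            FeatureRecord("cds1", "chr", "+", 200, 500, feature_class="CDS"),
            FeatureRecord("utr3", "chr", "+", 500, 560,
                          feature_class="three_prime_UTR"),
            FeatureRecord("srna", "chr", "-", 700, 900, feature_class="sRNA"),
        ])

    def test_five_prime_utr_containment(self):
        sorf = FeatureRecord("s", "chr", "+", 120, 180, feature_class="other")
        assert classify_context(sorf, self._annotation()) == "five_prime_UTR"

    def test_antisense_overlap(self):
        sorf = FeatureRecord("s", "chr", "-", 300, 360, feature_class="other")
        assert classify_context(sorf, self._annotation()) == "antisense"

    def test_srna_hosted(self):
        sorf = FeatureRecord("s", "chr", "-", 720, 780, feature_class="other")
        assert classify_context(sorf, self._annotation()) == "sRNA_hosted"

    def test_intergenic_default(self):
        sorf = FeatureRecord("s", "chr", "+", 950, 1010,
                             feature_class="other")
        assert classify_context(sorf, self._annotation()) == "intergenic"

    def test_operon_internal_needs_flanking_cds(self):
        annotation = AnnotationSet("ann", 1, [
            FeatureRecord("g1", "chr", "+", 100, 400, feature_class="CDS"),
            FeatureRecord("g2", "chr", "+", 600, 900, feature_class="CDS"),
        ])
        sorf = FeatureRecord("s", "chr", "+", 450, 540, feature_class="other")
        context = classify_context(sorf, annotation,
                                   transcripts=[("chr", "+", 50, 950)])
        assert context == "operon_internal"

    def test_simulation_contexts_match_truth_labels(self, study):
        _, annotation, truth, _ = study
        expectations = {"uORF": "five_prime_UTR", "decoy_sORF": "sRNA_hosted",
                        "antisense_sORF": "antisense"}
        transcripts = [
            ("chr", "+", 0, 0)  # placeholder replaced below
        ]
        transcripts = [
            (r.replicon_id, r.strand, r.transcript_start, r.transcript_end)
            for r in truth[truth["feature_class"] == "CDS"].itertuples()
        ]
        for truth_class, expected in expectations.items():
            subset = truth[truth["feature_class"] == truth_class]
            assert len(subset) > 0
            for row in subset.itertuples():
                feature = FeatureRecord("x", row.replicon_id, row.strand,
                                        row.start, row.end,
                                        feature_class="other")
                assert classify_context(feature, annotation,
                                        transcripts) == expected


class TestDedupAndSummaries:
    def test_shared_stop_keeps_best_score(self):
        candidates = pd.DataFrame([
            dict(candidate_id="long", replicon_id="chr", strand="+",
                 start=100, end=190, deepribo_score=0.5),
            dict(candidate_id="short", replicon_id="chr", strand="+",
                 start=130, end=190, deepribo_score=1.5),
            dict(candidate_id="other", replicon_id="chr", strand="+",
                 start=300, end=390, deepribo_score=0.0),
        ])
        out = select_primary_candidates(candidates)
        shadowed = set(out.loc[out["shadowed"], "candidate_id"])
        assert shadowed == {"long"}

    def test_codons_read_from_genome(self):
        replicon = Replicon("chr", "ATGAAATAA" + "C" * 10)
        feature = FeatureRecord("f", "chr", "+", 0, 9, feature_class="sORF")
        assert candidate_codons(feature, replicon) == ("ATG", "TAA")

    def test_summaries(self):
        seqs = {"ATG": "ATGAAATAA", "GTG": "GTGAAATGA"}
        replicon = Replicon("chr", seqs["ATG"] + seqs["ATG"] + seqs["GTG"])
        rep2 = Replicon("pA", seqs["ATG"])
        features = [
            FeatureRecord("a", "chr", "+", 0, 9, feature_class="sORF"),
            FeatureRecord("b", "chr", "+", 9, 18, feature_class="sORF"),
            FeatureRecord("c", "chr", "+", 18, 27, feature_class="sORF"),
            FeatureRecord("d", "pA", "+", 0, 9, feature_class="sORF"),
        ]
        out = summarize_sorfs(features, [replicon, rep2])
        assert out["start_codons"]["ATG"] == 3
        assert out["start_codons"]["GTG"] == 1
        assert out["stop_codons"]["TAA"] == 3
        assert out["replicon_percent"]["chr"] == pytest.approx(75.0)
        assert out["replicon_percent"]["pA"] == pytest.approx(25.0)
        assert out["aa_length_histogram"].sum() == 4

    def test_histogram_matches_brute_force(self, rng):
        from riboseep.sorf_call import AA_LENGTH_BINS

        aas = rng.integers(10, 71, size=100)
        replicon = Replicon("chr", "A" * 50_000)
        features = []
        pos = 0
        for i, aa in enumerate(aas):
            length = 3 * (int(aa) + 1)
            features.append(FeatureRecord(f"f{i}", "chr", "+", pos,
                                          pos + length,
                                          feature_class="other"))
            pos += length + 10
        out = summarize_sorfs(features, [replicon])
        hist = out["aa_length_histogram"]
        edges = list(AA_LENGTH_BINS)
        for lo, hi, count in zip(edges[:-1], edges[1:], hist):
            assert count == ((aas >= lo) & (aas < hi)).sum()
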