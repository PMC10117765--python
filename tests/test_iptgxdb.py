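"""Six-frame ORF prediction, hierarchical clustering and minimally
redundant protein entries."""

import numpy as np
import pytest
from Bio.Seq import Seq

from riboseep.genome_io import AnnotationSet, FeatureRecord, Replicon
from riboseep.iptgxdb import (
    AnnotationCluster,
    Proteoform,
    cluster_summary,
    generate_entries,
    integrate_annotations,
    predict_insilico_orfs,
    write_iptgxdb,
)
from riboseep.peptide_evidence import digest


def _brute_force_orfs(seq, min_aa, starts=("ATG", "GTG", "TTG"),
                      max_alt=10**9):
    """Independent six-frame scanner: walk every frame codon by codon."""
    stops = {"TAA", "TAG", "TGA"}
    found = set()
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        L = len(seq)
        for frame in range(3):
            codons = [s[i: i + 3] for i in range(frame, len(s) - 2, 3)]
            prev = -1
            for idx, codon in enumerate(codons):
                if codon not in stops:
                    continue
                n_emitted = 0
                for j in range(prev + 1, idx):
                    if codons[j] in starts and idx - j >= min_aa:
                        lo = frame + 3 * j
                        hi = frame + 3 * (idx + 1)
                        if strand == "-":
                            lo, hi = L - hi, L - lo
                        n_emitted += 1
                        if n_emitted <= max_alt:
                            found.add((strand, lo, hi))
                prev = idx
    return found


class TestInsilicoOrfs:
    def test_minimal_orf(self):
        replicon = Replicon("chr", "ATGAAATAA")
        annotation = predict_insilico_orfs([replicon], min_aa=2,
                                           max_alt_starts=5)
        plus = [f for f in annotation if f.strand == "+"]
        assert len(plus) == 1
        assert (plus[0].start, plus[0].end) == (0, 9)

    def test_alternative_starts_share_stop(self):
        replicon = Replicon("chr", "ATGCCCATGAAATAA")
        annotation = predict_insilico_orfs([replicon], min_aa=2,
                                           max_alt_starts=2)
        plus = [f for f in annotation if f.strand == "+" and f.end == 15]
        assert {f.start for f in plus} == {0, 6}

    def test_max_alt_starts_limits_most_upstream_first(self):
        replicon = Replicon("chr", "ATGCCCATGCCCATGAAATAA")
        annotation = predict_insilico_orfs([replicon], min_aa=2,
                                           max_alt_starts=2)
        plus = [f for f in annotation if f.strand == "+" and f.end == 21]
        assert {f.start for f in plus} == {0, 6}

    def test_matches_brute_force_scanner(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        replicon = Replicon("chr", seq)
        annotation = predict_insilico_orfs([replicon], min_aa=10,
                                           max_alt_starts=10**9)
        got = {(f.strand, f.start, f.end) for f in annotation}
        expected = _brute_force_orfs(seq, min_aa=10)
        assert got == expected


def _cds(fid, rep, strand, start, end, source=""):
    return FeatureRecord(fid, rep, strand, start, end, feature_class="CDS"
                         if (end - start) // 3 - 1 > 70 else "sORF",
                         source=source)


@pytest.fixture()
def toy_genome():
    # + strand ORF at [10, 40) with an internal ATG at 19 sharing the stop
    seq = list("C" * 60)
    orf = "ATGCCCGCAATGAAAGAAACCGCAGCCTAA"
    seq[10:40] = orf
    return Replicon("chr", "".join(seq))


class TestIntegration:
    def test_agreeing_sources_merge_tags(self, toy_genome):
        a = AnnotationSet("A", 1, [_cds("fa", "chr", "+", 10, 40)])
        b = AnnotationSet("B", 2, [_cds("fb", "chr", "+", 10, 40)])
        (cluster,) = integrate_annotations([a, b], None, [toy_genome])
        assert len(cluster.proteoforms) == 1
        assert cluster.proteoforms[0].sources == {("A", "fa"), ("B", "fb")}

    def test_shared_stop_different_starts_one_cluster(self, toy_genome):
        a = AnnotationSet("A", 1, [_cds("long", "chr", "+", 10, 40)])
        b = AnnotationSet("B", 2, [_cds("short", "chr", "+", 19, 40)])
        (cluster,) = integrate_annotations([a, b], None, [toy_genome])
        assert len(cluster.proteoforms) == 2
        assert cluster.proteoforms[0].start == 10  # most upstream first
        assert cluster.stop_coordinate == 39

    def test_cluster_count_equals_distinct_stop_triples(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        replicon = Replicon("chr", seq)
        annotation = predict_insilico_orfs([replicon], min_aa=15,
                                           max_alt_starts=3)
        clusters = integrate_annotations(
            [AnnotationSet("A", 1, list(annotation))], None, [replicon])
        triples = {("chr", f.strand, f.end - 1 if f.strand == "+" else f.start)
                   for f in annotation}
        assert len(clusters) == len(triples)

    def test_feature_without_stop_codon_rejected(self, toy_genome):
        bad = AnnotationSet("A", 1, [_cds("bad", "chr", "+", 10, 37)])
        clusters = integrate_annotations([bad], None, [toy_genome])
        assert clusters == []

    def test_idempotent_reintegration(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        replicon = Replicon("chr", seq)
        annotation = predict_insilico_orfs([replicon], min_aa=12,
                                           max_alt_starts=3)
        clusters = integrate_annotations(
            [AnnotationSet("A", 1, list(annotation))], None, [replicon])

        def signature(cs):
            return {(c.replicon_id, c.strand, c.stop_coordinate,
                     tuple(p.start for p in c.proteoforms)) for c in cs}

        regenerated = [
            FeatureRecord(f"r{i}", c.replicon_id, c.strand, *p.interval,
                          feature_class="CDS" if
                          (p.interval[1] - p.interval[0]) // 3 - 1 > 70
                          else "sORF")
            for i, (c, p) in enumerate(
                (c, p) for c in clusters for p in c.proteoforms)
        ]
        again = integrate_annotations(
            [AnnotationSet("A", 1, regenerated)], None, [replicon])
        assert signature(again) == signature(clusters)

    def test_equal_rank_permutation_invariance(self, toy_genome):
        a = AnnotationSet("A", 1, [_cds("fa", "chr", "+", 10, 40)])
        b = AnnotationSet("B", 1, [_cds("fb", "chr", "+", 19, 40)])
        forward = integrate_annotations([a, b], None, [toy_genome])
        backward = integrate_annotations([b, a], None, [toy_genome])
        key = lambda cs: {(c.stop_coordinate,
                           tuple(sorted(p.start for p in c.proteoforms)))
                          for c in cs}
        assert key(forward) == key(backward)

    def test_category_from_best_rank(self, toy_genome):
        annotated = AnnotationSet("A", 1, [_cds("fa", "chr", "+", 10, 40)],
                                  category="annotated")
        insilico = AnnotationSet("I", 100, [_cds("fi", "chr", "+", 19, 40)],
                                 category="in_silico")
        (cluster,) = integrate_annotations([annotated], insilico, [toy_genome])
        assert cluster.category == "annotated"


def _toy_cluster(parent="MAKTTTKGGGK", child="TTKGGGK"):
    return AnnotationCluster(
        replicon_id="chr", strand="+", stop_coordinate=99,
        proteoforms=[
            Proteoform(start=0, interval=(0, 36), protein_sequence=parent,
                       sources={("A", "p")}, rank=1, category="annotated"),
            Proteoform(start=12, interval=(12, 36), protein_sequence=child,
                       sources={("B", "c")}, rank=2, category="annotated"),
        ],
    )


class TestEntries:
    def test_child_truncated_after_required_cleavage_sites(self):
        entries = generate_entries(_toy_cluster(), "trypsin",
                                   max_missed_cleavages=0)
        assert entries[0].sequence == "MAKTTTKGGGK"
        assert entries[1].sequence == "TTK"

    def test_child_kept_full_when_too_few_sites(self):
        entries = generate_entries(_toy_cluster(), "trypsin",
                                   max_missed_cleavages=2)
        assert entries[1].sequence == "TTKGGGK"

    def test_no_protease_emits_full_sequences(self):
        entries = generate_entries(_toy_cluster(), "none")
        assert [e.sequence for e in entries] == ["MAKTTTKGGGK", "TTKGGGK"]

    def test_unknown_protease_rejected(self):
        with pytest.raises(ValueError):
            generate_entries(_toy_cluster(), "gluC")

    @pytest.mark.parametrize("protease", ["trypsin", "lysC"])
    def test_completeness_on_random_clusters(self, rng, protease):
        """Every peptide (<= max_missed) of every proteoform occurs in at
        least one emitted entry of its cluster."""
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(50):
            length = int(rng.integers(30, 120))
            parent = "M" + "".join(rng.choice(alphabet, size=length))
            offset = int(rng.integers(1, length - 10))
            child = "M" + parent[offset + 1:]
            cluster = AnnotationCluster(
                replicon_id="chr", strand="+", stop_coordinate=0,
                proteoforms=[
                    Proteoform(0, (0, 0), parent, {("A", "p")}, 1, "annotated"),
                    Proteoform(3 * offset, (0, 0), child, {("B", "c")}, 2,
                               "annotated"),
                ])
            entries = generate_entries(cluster, protease,
                                       max_missed_cleavages=2)
            sequences = [e.sequence for e in entries]
            for proteoform in cluster.proteoforms:
                for pep in digest(proteoform.protein_sequence, protease,
                                  max_missed=2):
                    assert any(pep in s for s in sequences), (pep, sequences)

    def test_minimality_of_truncated_entry(self):
        """Dropping the last residue of a truncated child entry loses a
        child-specific peptide (the child's initiator Met makes its
        N-terminal peptide distinct from the parent)."""
        cluster = _toy_cluster(parent="MAKTTTKGGGK", child="MTKGGGK")
        entries = generate_entries(cluster, "trypsin", max_missed_cleavages=0)
        child_entry = entries[1].sequence  # "TTK"
        trimmed = child_entry[:-1]
        child_peptides = digest(cluster.proteoforms[1].protein_sequence,
                                "trypsin", max_missed=0)
        parent_entry = entries[0].sequence
        lost = [p for p in child_peptides
                if p in child_entry and p not in trimmed
                and p not in parent_entry]
        assert lost, "truncation is not minimal"


class TestWriteDb:
    def test_round_trip_sequences_and_coordinates(self, tmp_path, toy_genome):
        from Bio import SeqIO

        a = AnnotationSet("A", 1, [_cds("long", "chr", "+", 10, 40)])
        b = AnnotationSet("B", 2, [_cds("short", "chr", "+", 19, 40)])
        clusters = integrate_annotations([a, b], None, [toy_genome])
        fasta, gff = tmp_path / "db.fasta", tmp_path / "db.gff3"
        n = write_iptgxdb(clusters, "trypsin", fasta, gff)
        records = list(SeqIO.parse(str(fasta), "fasta"))
        assert len(records) == n == 2
        gff_rows = [line.split("\t") for line in gff.read_text().splitlines()
                    if not line.startswith("#")]
        coords = {(int(r[3]) - 1, int(r[4])) for r in gff_rows}
        assert coords == {(10, 40), (19, 40)}

    def test_entry_count_is_sum_of_proteoforms(self, rng, tmp_path):
        seq = "".join(rng.choice(list("ACGT"), size=15_000))
        replicon = Replicon("chr", seq)
        annotation = predict_insilico_orfs([replicon], min_aa=12,
                                           max_alt_starts=3)
        clusters = integrate_annotations(
            [AnnotationSet("A", 1, list(annotation))], None, [replicon])
        n = write_iptgxdb(clusters, "none", tmp_path / "db.fasta",
                          tmp_path / "db.gff3")
        assert n == sum(len(c.proteoforms) for c in clusters)
        summary = cluster_summary(clusters)
        assert summary["n_proteoforms"].sum() == n

    def test_custom_db_strictly_smaller_than_standard(self, study, sim_config):
        from riboseep.synthetic_data import split_annotation_sources

        replicons, _, truth = study[0], study[1], study[2]
        sources = split_annotation_sources(truth, replicons, sim_config)
        insilico = predict_insilico_orfs(replicons)
        riboseq = AnnotationSet("riboseq", 50, [
            FeatureRecord(r.feature_id, r.replicon_id, r.strand, r.start,
                          r.end, feature_class="sORF")
            for r in truth[truth["translated"]
                           & (truth["feature_class"] == "sORF")].itertuples()
        ], category="riboseq")
        standard = integrate_annotations(sources, insilico, replicons)
        custom = integrate_annotations(sources, riboseq, replicons)
        n_standard = sum(len(c.proteoforms) for c in standard)
        n_custom = sum(len(c.proteoforms) for c in custom)
        assert n_custom < n_standard
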