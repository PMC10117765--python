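"""Build standard and custom proteogenomic search databases.

The standard database integrates two imperfect annotation releases with
a six-frame in-silico ORF scan; the custom database replaces the
in-silico tier with the (much smaller) set of Ribo-seq-supported sORFs,
shrinking the search space dramatically.
"""

from riboseep.genome_io import AnnotationSet, FeatureRecord
from riboseep.iptgxdb import (generate_all_entries, integrate_annotations,
                              predict_insilico_orfs)
from riboseep.synthetic_data import (SimConfig, make_genome,
                                     split_annotation_sources)

config = SimConfig(seed=1)
replicons, annotation, truth = make_genome(config)
sources = split_annotation_sources(truth, replicons, config)
insilico = predict_insilico_orfs(replicons, min_aa=10, max_alt_starts=5)
print(f"six-frame scan: {len(insilico)} candidate ORFs "
      f"(alternative starts included)")

riboseq = AnnotationSet("riboseq", 50, [
    FeatureRecord(r.feature_id, r.replicon_id, r.strand, r.start, r.end,
                  feature_class="sORF")
    for r in truth[truth["translated"]
                   & (truth["feature_class"] == "sORF")].itertuples()
], category="riboseq")

standard = integrate_annotations(sources, insilico, replicons)
custom = integrate_annotations(sources, riboseq, replicons)
n_std = len(generate_all_entries(standard, "trypsin"))
n_cus = len(generate_all_entries(custom, "trypsin"))
print(f"standard database: {len(standard)} clusters, {n_std} protein entries")
print(f"custom database:   {len(custom)} clusters, {n_cus} protein entries")
print(f"-> the Ribo-seq-informed database is {n_std / n_cus:.0f}-fold smaller,")
print("   which improves search statistics and protein-level FDR control.")
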