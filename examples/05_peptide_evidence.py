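"""Classify peptides against a proteoform database and apply the tiered
PSM acceptance rules.

Peptide classes: 1a unique to one protein entry; 2a a proper subset of a
cluster's proteoforms; 2b all proteoforms (gene-level); 3a a unique
sequence encoded by identical gene copies.  Acceptance tiers require
more PSM evidence the less trusted the annotation category is.
"""

import pandas as pd

from riboseep.genome_io import AnnotationSet, FeatureRecord
from riboseep.iptgxdb import integrate_annotations
from riboseep.peptide_evidence import accept_protein, classify_peptides
from riboseep.synthetic_data import (SimConfig, make_genome, simulate_psms,
                                     split_annotation_sources)

config = SimConfig(seed=1)
replicons, annotation, truth = make_genome(config)
sources = split_annotation_sources(truth, replicons, config)
riboseq = AnnotationSet("riboseq", 50, [
    FeatureRecord(r.feature_id, r.replicon_id, r.strand, r.start, r.end,
                  feature_class="sORF")
    for r in truth[truth["translated"]
                   & (truth["feature_class"] == "sORF")].itertuples()
], category="riboseq")
clusters = integrate_annotations(sources, riboseq, replicons)

psms = pd.concat([simulate_psms(truth, protease, config)
                  for protease in ("trypsin", "lysC", "none")],
                 ignore_index=True)
classes = classify_peptides(psms["peptide"], clusters)
print("peptide ambiguity classes:")
print(pd.Series(classes).value_counts().to_string())

decisions = [accept_protein(c, psms, classes) for c in clusters]
accepted = sum(d.accepted for d in decisions)
print(f"\naccepted {accepted} of {len(decisions)} clusters with PSM support "
      "under the tiered rules")
for d in decisions[:3]:
    print(f"  {d.cluster_id.split('|')[0]:>6} {d.category:<10} "
          f"{d.mass_kda:5.1f} kDa  unique={d.unique_peptides} "
          f"PSMs={d.total_psms}  accepted={d.accepted}")
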