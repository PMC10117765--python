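"""Simulate a paired Ribo-seq/RNA-seq study and quantify translation.

Builds the default synthetic genome (three replicons, planted CDS,
sORFs, sRNAs...), simulates aligned reads, computes per-feature RPKM and
translation efficiency (TE), and prints the per-class mean TE.
"""

from riboseep.genome_io import FeatureRecord
from riboseep.quantify import class_te_summary, quantify_features
from riboseep.synthetic_data import SimConfig, make_genome, simulate_reads

config = SimConfig(seed=1)
replicons, annotation, truth = make_genome(config)
reads = simulate_reads(truth, config, {r.id: r.length for r in replicons})
print(f"genome: {[(r.id, r.length) for r in replicons]}")
print(f"reads simulated: {len(reads):,} "
      f"({(reads['library'] == 'RIBO').sum():,} Ribo-seq)")

features = [FeatureRecord(r.feature_id, r.replicon_id, r.strand, r.start,
                          r.end, feature_class=r.feature_class)
            for r in truth.itertuples()
            if r.feature_class in ("CDS", "sORF", "sRNA", "hkRNA")]
quants = quantify_features(features, reads,
                           [("ribo_1", "rna_1"), ("ribo_2", "rna_2")])
print("\nmean TE per feature class (Ribo-seq RPKM / RNA-seq RPKM):")
print(class_te_summary(quants).round(2).to_string())
print("\nTranslated classes sit well above 1; untranslated RNA classes at 0:")
print("that separation is what the translation filters exploit.")
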