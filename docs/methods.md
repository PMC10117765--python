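# Methods

This note documents the models, conventions and design choices behind
`riboseep`, and what the synthetic studies do and do not establish.

## Coordinates and genome I/O

Internally all intervals are 0-based half-open on the forward strand;
GFF3 (1-based inclusive) is converted at the I/O boundary in both
directions, and round trips are exact.  CDS/sORF intervals include the
stop codon; `aa_length = length/3 − 1` excludes it, so a 153 nt CDS
encodes 50 aa.  An sORF is a coding feature of ≤ 70 aa.  Features
wrapping the origin of a circular replicon are rejected: none of the
implemented statistics needs them, and supporting them would complicate
every interval operation.  Annotation dialects differ in how they mark
non-coding RNA subtypes, so the GFF reader takes a configurable
type map and attribute key (`rna_class` by default) instead of guessing.

## Coverage and normalization

Four read-assignment modes are supported.  `global` increments every
covered position; `five_prime`/`three_prime` increment only the
biological read end (strand-aware: the 5′ end of a minus-strand read is
its rightmost base).  `centered` is defined here as trimming `k` nt
(default 5) from both read ends, with sub-`2k+1` reads contributing
their midpoint — the term is used in the field without a fixed
definition, so this convention is stated rather than assumed.

`mil` scales a track by `10⁶ / total_mapped_reads`; `min` scales each
of a set of samples by `min(totals) / own_total`, leaving the shallowest
library unchanged — the natural choice when several samples must share
one genome-browser scale.  Both are scalar per-sample factors, so
within-sample position ratios are invariant, and TE (a ratio of
per-sample-normalized quantities) is identical whether computed from
raw, mil- or min-scaled data.

## Quantification

Counting is permissive: a read counts toward every same-strand feature
it overlaps by ≥ 1 nt, and may count several times.  Fractional
assignment was rejected for reproducibility — permissive counting is
deterministic and matches common featureCounts-style practice.
Replicate pairing of Ribo and RNA samples is explicit configuration,
never inferred from names.  Undefined TEs (zero RNA RPKM) propagate as
NaN; class summaries average only defined values and report empty
classes as absent, never as zero.

## Metagene profiles

Each gene's window (default −30..+30 nt around the first nucleotide of
the start codon, oriented so negative = upstream on both strands) is
normalized to sum 1 before equal-weight averaging; otherwise a handful
of highly expressed genes dominates the profile.  Genes with zero
window signal or windows leaving the replicon are dropped and counted.
The per-length initiation score is the mean density in [−16, 0]
divided by the mean ORF-body density; it is a declared proxy — the
qualitative claim it supports ("which footprint lengths carry the
strongest start-codon signal") does not depend on the exact statistic.

## sORF calling

The expression cascade uses mean TE ≥ 0.5 and RPKM ≥ 10 with inclusive
boundaries; for novel candidates the RPKM rule applies to each
replicate separately and the predictor score bound (> −0.5) is strict.
For annotated sORFs the RPKM rule defaults to the replicate mean — the
per-replicate wording is attached to novel candidates only.  The mean-TE
rule is taken literally for novel candidates as well (no per-replicate
TE requirement).

Manual curation of coverage shapes is inherently visual; the four flags
are quantitative stand-ins with every constant exposed:

* **boundary** — fraction of locus Ribo signal inside
  [start−16, stop+16] ≥ 0.8;
* **utr_exclusion** — mean Ribo density in residual transcript flanks
  ≤ 0.3 × in-ORF density;
* **evenness** — no single position holds > 0.5 of the in-ORF signal
  and the per-codon coefficient of variation is ≤ 2.0 (a two-part proxy
  for "no peaks with plateau");
* **signal_ratio** — in-ORF Ribo mean ≥ 1.0 × in-ORF RNA mean on
  min-normalized tracks.

Zero in-ORF Ribo coverage turns all flags off.  When a candidate sits
on a shared (operon) transcript, intervals of other annotated ORFs are
masked (widened by the 16 nt pile-up extent) before the boundary and
flank statistics — a curator likewise discounts the neighbouring genes'
coverage.  A candidate passing the cascade alone is `filtered_pass`;
passing all four flags upgrades it to `translated_high_confidence`.
Nested candidates sharing a stop keep the best-scoring (tie: longest)
representative; the rest are reported as shadowed.  Start/stop codons
are always re-read from the genome; disagreement with a predictor table
is an error, not silently corrected.

Context classification precedence is containment in a same-strand
5′-UTR, then 3′-UTR, then sRNA; then operon-internal (inside a
same-strand multi-CDS transcript, CDS on both sides); then antisense
(≥ 1 nt opposite-strand overlap); else intergenic.

## Proteogenomic databases

Clusters are keyed by (replicon, strand, last base of the stop codon);
proteoforms are the distinct start sites, ordered most upstream first.
Sources are integrated in rank order (default: first reference release >
second release > ab initio > in-silico/Ribo-seq, fully configurable);
lower ranks can only add proteoforms or source tags, never move a
higher-ranked start.  Coding features whose genomic sequence lacks a
valid stop codon (pseudogenes, frameshifts) are rejected and logged.
The composite cluster identifier lists every source-qualified feature
id exactly once; its exact format is this package's own convention.

The six-frame scan emits, per stop-to-stop segment and frame, up to 5
alternative starts (ATG/GTG/TTG, most upstream first) of ≥ 10 aa.  The
10 aa floor leaves margin below the shortest products one expects to
detect by MS (~12 aa proteolysis-tag peptides).

Entry generation: the most upstream proteoform is written in full; each
shorter proteoform is truncated after cleavage site 1 + max_missed
(default 2) downstream of its start.  Rationale: a proteoform-specific
peptide must cover the proteoform's first residue, and with ≤ m missed
cleavages it cannot extend past the (1+m)-th site; everything further
downstream is a suffix of the full parent entry.  This is the package's
reconstruction of "minimally redundant"; completeness and minimality
are enforced by digestion oracles in the test suite.  Trypsin cleaves
after K/R except before P (declared convention); LysC after every
lysine; the no-protease dialect cannot truncate, so every proteoform is
written in full.  Contaminant sequences are appended from a
user-supplied FASTA only — which contaminants to include is a
laboratory decision, not a package constant.

## Peptide evidence

Classification matches peptides against full proteoform sequences by
substring containment: one single-proteoform cluster → 1a; a proper
subset of one cluster's proteoforms → 2a; all of them → 2b (gene-level
evidence); several clusters with identical matched sequences → 3a
(identical gene copies); anything else ambiguous, and absent peptides
are reported unmatched rather than erroring.  "Unique peptide" for
acceptance means class 1a/2a/3a (2a inclusion is configurable — it
identifies a proteoform subset, which is protein-level evidence); 2b
PSMs add to the cluster total without counting as unique.  Exactly
15 kDa falls in the two-unique-peptide regime, i.e. the mass boundary
is implemented as ≥ 15 kDa.  Cluster mass is taken from the
best-ranked proteoform.  PSMs are pooled across sample-preparation
approaches within one database build.  Protein masses are average
(isotope-abundance-weighted) masses including one water, via pyteomics.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
at a scale a laptop handles in seconds: three replicons (120, 60 and
40 kb — a chromosome plus two plasmid-like replicons, scaled down),
~40 translated CDS, 20 translated sORFs (10–70 aa, ~20 % leaderless,
one identical-copy pair to exercise class 3a), 20 untranslated sRNAs
each hiding an ORF-shaped decoy, 5 uORFs, 3 antisense sORFs, 4
housekeeping RNAs, and one operon with 14/12 nt intergenic gaps.  Two
replicates at 2 × 10⁵ RNA-seq reads per sample are simulated with
Poisson counts.

Footprints are 27–33 nt with modal length 30; each footprint is an
initiation footprint (5′ end pinned at start−16) with probability 0.18
(0.38 for 32 nt reads, so the length-stratified enrichment has a known
ordering), a termination footprint (3′ end at stop+16) with probability
0.10 — the relative magnitude of termination pile-ups is a free
parameter — or an elongation footprint uniform inside
[start−16, stop+16].  RNA fragments (26–34 nt) tile whole transcripts.
Translated features carry a planted TE drawn from 1.5–4.0 — the regime
of clearly translated bacterial genes, and comfortably above the 0.5
cut-off so the recovery test measures the pipeline, not threshold
luck — and log-uniform abundances (0.3–3).

Two calibration details make the planted TE identifiable from the
RPKM ratio: read-sampling weights are exact fragment-start-position
counts (so the permissive ≥ 1 nt overlap counting is unbiased for short
features), and "background" transcripts — unannotated, untranslated RNA
mass standing in for rRNA remnants and unannotated transcription — are
planted so the Ribo and RNA libraries have equal expected totals.
Without that mass balance TE is only identifiable up to a global
factor.  The calibration is exact when planted ribosome-occupancy mass
exceeds annotated RNA mass (true for the defaults); configurations with
planted TE ≪ 1 everywhere would recover inflated values.

Predictor emulation assigns DeepRibo-like scores N(2.0, 0.6) to planted
translated sORFs and N(−0.5, 0.8) to decoys: the score cleanly ranks
true positives, while decoys straddle the −0.5 bound so that the
expression filters — not the score alone — must reject them.  PSM
tables draw up to 3 peptides per expressed protein from the in-silico
digest (tryptic/LysC peptides of 7–40 aa with ≤ 2 missed cleavages, or
arbitrary 7–30 aa substrings without protease), with 1 + Poisson(2)
PSMs spread over three MS replicates.

**What passing the recovery tests shows — and what it does not.** The
generator plants clean, isolated signals: no sequencing error, no
multimapping, no rRNA contamination, no coverage artifacts from
structure or library preparation, no condition-dependent expression,
and a noise-free footprint background (a uniform background rate
exists but defaults to 0).  Perfect sensitivity/specificity on this
material demonstrates that the filter logic, coordinate arithmetic and
evidence tiers are implemented correctly — not that real data would
yield those rates.  On real libraries the curation flags in particular
will reject genuine sORFs with artifact-laden coverage, which is their
purpose.

## Numerical and degenerate-input conventions

Zero-read samples cannot be mil/min-normalized (error, not silent NaN).
Empty metagene gene sets and windows not containing the start position
are errors.  Ties in the nested-candidate resolution break to the
longest candidate, then input order (stable sort).  All randomness runs
through `numpy` integer-seeded generator streams with fixed derivation
constants per stage, so outputs are reproducible across platforms; the
pipeline manifest records the seed, the full configuration echo and
SHA-256 hashes of every output.

## Known limitations

P-site offset calibration and codon-resolution (3 nt phasing) analyses
are out of scope — the fixed-end mapping used here does not attempt
codon resolution.  Differential translation across conditions, spectral
search/FDR estimation, conservation analysis and structure prediction
are upstream or downstream of this package and are consumed or emitted
as plain tables.  Origin-wrapping features on circular replicons are
unsupported.  The published per-feature supplementary tables of real
studies can be fed through the same filter functions, but they ship
with the journal article and are not redistributed here.
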