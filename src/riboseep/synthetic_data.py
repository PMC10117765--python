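"""Synthetic Ribo-seq/RNA-seq study generator.

Builds a toy multi-replicon bacterial genome with planted transcripts and
coding features, then simulates pre-aligned ribosome footprints and RNA-seq
fragments with the signal structure the downstream analysis assumes:

* footprints of 27-33 nt (modal length 30 nt) whose protection extends
  ~16 nt beyond start and stop codons, with initiation/termination
  pile-ups at those offsets;
* RNA-seq fragments uniformly tiling whole transcripts including UTRs;
* translated CDS, sORFs (including leaderless ones), uORFs inside
  5'-UTRs, antisense sORFs, and untranslated sRNAs/housekeeping RNAs;
* per-feature translation-efficiency levels, Poisson read counts, and a
  zero (configurable) background footprint rate.

Every planted feature is recorded in a truth table so recovery tests can
score the pipeline against ground truth.  All randomness flows from a
single integer seed; equal seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import (
    AnnotationSet,
    FeatureRecord,
    Replicon,
    feature_sequence,
    translate_cds,
)

__all__ = [
    "SimConfig",
    "AlignedRead",
    "make_genome",
    "simulate_reads",
    "simulate_psms",
    "make_candidate_table",
    "split_annotation_sources",
    "write_reads_tsv",
    "read_reads_tsv",
]

READ_COLUMNS = ["replicon_id", "strand", "start", "end", "library", "sample_id"]

_START_CODONS = ("ATG", "GTG", "TTG")
_START_WEIGHTS = (0.70, 0.20, 0.10)
_STOP_CODONS = ("TGA", "TAA", "TAG")
_STOP_WEIGHTS = (0.40, 0.35, 0.25)
_EDGE_MARGIN = 100  # nt kept free at replicon ends so footprints never clip


@dataclass
class SimConfig:
    """Parameters of the simulated study.

    Defaults describe a scaled-down three-replicon genome (chromosome plus
    two plasmid-like replicons) sequenced to ~2x10^5 RNA-seq reads per
    sample in two replicates.  ``te_range`` is the planted translation
    efficiency of translated features; untranslated features receive no
    ribosome footprints unless ``ribo_noise_rate`` is raised above zero.
    """

    seed: int = 0
    replicon_lengths: tuple[int, ...] = (120_000, 60_000, 40_000)
    n_translated_cds: int = 40
    n_translated_sorfs: int = 20
    n_untranslated_srnas: int = 20
    n_uorfs: int = 5
    n_antisense_sorfs: int = 3
    n_hkrnas: int = 4
    include_operon: bool = True
    # footprint lengths 27..33 nt; modal length 30 nt
    footprint_length_distribution: tuple[float, ...] = (
        0.05, 0.10, 0.18, 0.30, 0.17, 0.13, 0.07,
    )
    initiation_pileup_extent: int = 16
    # probability that a footprint of a given length is an initiation
    # footprint pinned at start-16; strongest for 32 nt reads
    initiation_prob: dict = field(
        default_factory=lambda: {27: 0.18, 28: 0.18, 29: 0.18, 30: 0.18,
                                 31: 0.18, 32: 0.38, 33: 0.18}
    )
    termination_prob: float = 0.10
    te_range: tuple[float, float] = (1.5, 4.0)
    abundance_range: tuple[float, float] = (0.3, 3.0)
    library_size: int = 200_000  # RNA-seq reads per sample
    n_replicates: int = 2
    ribo_noise_rate: float = 0.0  # background RIBO reads per nt per sample
    # mass-spec simulation
    n_ms_replicates: int = 3
    peptides_per_protein: int = 3
    mean_extra_psms: float = 2.0
    nonspecific_peptide_bounds: tuple[int, int] = (7, 30)

    def __post_init__(self) -> None:
        counts = (
            self.n_translated_cds, self.n_translated_sorfs,
            self.n_untranslated_srnas, self.n_uorfs,
            self.n_antisense_sorfs, self.n_hkrnas,
        )
        if any(c < 0 for c in counts):
            raise ValueError("feature counts must be non-negative")
        weights = np.asarray(self.footprint_length_distribution, dtype=float)
        if len(weights) != 7 or not np.isclose(weights.sum(), 1.0):
            raise ValueError("footprint weights must cover 27..33 nt and sum to 1")
        if self.library_size <= 0 or self.n_replicates < 1:
            raise ValueError("library_size and n_replicates must be positive")


@dataclass
class AlignedRead:
    """One aligned read; 0-based half-open genomic interval."""

    replicon_id: str
    strand: str
    start: int
    end: int
    library: str  # RIBO or RNA
    sample_id: str


TRUTH_COLUMNS = [
    "feature_id", "replicon_id", "strand", "start", "end", "feature_class",
    "transcript_start", "transcript_end", "abundance", "te", "translated",
    "protein", "host_id",
]


class _Builder:
    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.sequences = {}
        self.occupied = {}  # replicon_id -> list of (start, end)
        self.rows = []
        self.features = []
        names = ["chr", "pA", "pB", *(f"rep{i}" for i in range(3, 99))]
        for name, length in zip(names, config.replicon_lengths):
            self.sequences[name] = rng.integers(0, 4, size=length)
            self.occupied[name] = []

    # -- sequence helpers ---------------------------------------------------
    _NT = np.frombuffer(b"ACGT", dtype=np.uint8)

    def _codon_ints(self, codon: str) -> list[int]:
        return ["ACGT".index(c) for c in codon]

    def _random_orf(self, aa_length: int) -> tuple[np.ndarray, str, str]:
        """Codon-int array for an ORF of aa_length residues plus stop."""
        rng = self.rng
        start = rng.choice(_START_CODONS, p=_START_WEIGHTS)
        stop = rng.choice(_STOP_CODONS, p=_STOP_WEIGHTS)
        non_stop = [c for c in _all_codons() if c not in _STOP_CODONS]
        idx = rng.integers(0, len(non_stop), size=aa_length - 1)
        body = [non_stop[i] for i in idx]
        nt = "".join([start, *body, stop])
        return np.array(self._codon_ints(nt), dtype=np.int64), start, stop

    def _write(self, replicon_id: str, pos: int, codon_ints: np.ndarray,
               strand: str) -> None:
        seq = self.sequences[replicon_id]
        if strand == "+":
            seq[pos: pos + len(codon_ints)] = codon_ints
        else:
            seq[pos: pos + len(codon_ints)] = (3 - codon_ints)[::-1]

    def _place(self, length: int, margin: int = 30) -> tuple[str, int]:
        rng = self.rng
        names = list(self.sequences)
        sizes = np.array([len(self.sequences[n]) for n in names], dtype=float)
        for _ in range(500):
            rep = names[rng.choice(len(names), p=sizes / sizes.sum())]
            limit = len(self.sequences[rep]) - length - _EDGE_MARGIN
            if limit <= _EDGE_MARGIN:
                continue
            pos = int(rng.integers(_EDGE_MARGIN, limit))
            if all(pos - margin >= e or pos + length + margin <= s
                   for s, e in self.occupied[rep]):
                self.occupied[rep].append((pos, pos + length))
                return rep, pos
        raise RuntimeError(
            "could not place a feature without forbidden overlap; "
            "reduce counts or enlarge replicons"
        )

    # -- feature planting ---------------------------------------------------
    def add_transcript_feature(self, fid, rep, strand, orf_start, orf_end,
                               t_start, t_end, fclass, te, abundance,
                               translated, protein, host_id=""):
        self.rows.append(dict(
            feature_id=fid, replicon_id=rep, strand=strand, start=orf_start,
            end=orf_end, feature_class=fclass, transcript_start=t_start,
            transcript_end=t_end, abundance=abundance, te=te,
            translated=translated, protein=protein, host_id=host_id,
        ))

    def plant_coding(self, fid, aa_length, utr5, utr3, fclass,
                     orf_ints=None, host_interval=None):
        """Plant one transcript with a single ORF; returns the truth row."""
        cfg, rng = self.config, self.rng
        orf_len = 3 * (aa_length + 1)
        t_len = utr5 + orf_len + utr3
        if host_interval is None:
            rep, t_start = self._place(t_len)
        else:
            rep, t_start = host_interval
        if orf_ints is None:
            orf_ints, _, _ = self._random_orf(aa_length)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            orf_start = t_start + utr5
        else:
            orf_start = t_start + utr3
        orf_end = orf_start + orf_len
        self._write(rep, orf_start, orf_ints, strand)
        abundance = float(np.exp(rng.uniform(*np.log(cfg.abundance_range))))
        te = float(rng.uniform(*cfg.te_range))
        protein = _ints_to_protein(orf_ints)
        self.add_transcript_feature(
            fid, rep, strand, orf_start, orf_end, t_start, t_start + t_len,
            fclass, te, abundance, True, protein,
        )
        return self.rows[-1]


def _all_codons():
    return ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]


_INT_TO_NT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _ints_to_seq(arr: np.ndarray) -> str:
    return _INT_TO_NT[arr].tobytes().decode()


def _ints_to_protein(orf_ints: np.ndarray) -> str:
    return translate_cds(_ints_to_seq(orf_ints))


def make_genome(config: SimConfig):
    """Generate genome, truth annotation and truth table.

    Returns ``(replicons, truth_annotation, truth)`` where ``truth`` is a
    DataFrame with one row per planted feature (coordinates, class,
    transcript bounds, planted abundance and TE, translation status,
    protein sequence).  Feature classes in the truth table are finer than
    the annotation classes: uORF, antisense_sORF and decoy_sORF (an
    ORF-shaped but untranslated sequence inside an sRNA) are recorded
    explicitly.
    """
    rng = np.random.default_rng([config.seed, 101])
    b = _Builder(config, rng)
    cfg = config

    # translated CDS (some with long 5'-UTRs to host uORFs later)
    long_utr = set(rng.choice(max(cfg.n_translated_cds, 1),
                              size=min(cfg.n_uorfs, cfg.n_translated_cds),
                              replace=False)) if cfg.n_uorfs else set()
    asense_hosts = []
    for i in range(cfg.n_translated_cds):
        aa = int(rng.integers(80, 250))
        utr5 = int(rng.integers(90, 140)) if i in long_utr else int(rng.integers(20, 60))
        # some hosts get long 3'-UTRs so antisense sORFs can nest there
        wants_asense = len(asense_hosts) < cfg.n_antisense_sorfs
        utr3 = int(rng.integers(110, 150)) if wants_asense else int(rng.integers(20, 60))
        row = b.plant_coding(f"cds_{i:03d}", aa, utr5, utr3, "CDS")
        if wants_asense:
            asense_hosts.append(row)

    # one operon: three CDS on a single transcript with 14 / 12 nt gaps
    if cfg.include_operon:
        aa_sizes = [int(rng.integers(60, 120)) for _ in range(2)] + [50]
        gaps = [14, 12]
        orf_lens = [3 * (aa + 1) for aa in aa_sizes]
        utr5, utr3 = 40, 40
        t_len = utr5 + sum(orf_lens) + sum(gaps) + utr3
        rep, t_start = b._place(t_len)
        abundance = float(np.exp(rng.uniform(*np.log(cfg.abundance_range))))
        pos = t_start + utr5
        for j, (aa, olen) in enumerate(zip(aa_sizes, orf_lens)):
            ints, _, _ = b._random_orf(aa)
            b._write(rep, pos, ints, "+")
            te = float(rng.uniform(*cfg.te_range))
            fclass = "CDS" if aa > 70 else "sORF"
            b.add_transcript_feature(
                f"operon_g{j}", rep, "+", pos, pos + olen, t_start,
                t_start + t_len, fclass, te, abundance, True,
                _ints_to_protein(ints),
            )
            pos += olen + (gaps[j] if j < len(gaps) else 0)

    # standalone translated sORFs; ~20 % leaderless; one duplicated pair
    dup_ints = None
    for i in range(cfg.n_translated_sorfs):
        aa = int(rng.integers(10, 71))
        leaderless = rng.random() < 0.2
        utr5 = 0 if leaderless else int(rng.integers(15, 40))
        utr3 = int(rng.integers(15, 40))
        orf_ints = None
        if cfg.n_translated_sorfs >= 2:
            if i == 0:
                orf_ints, _, _ = b._random_orf(aa)
                dup_ints = orf_ints
            elif i == cfg.n_translated_sorfs - 1 and dup_ints is not None:
                orf_ints = dup_ints  # identical gene copy (paralog case)
        b.plant_coding(f"sorf_{i:03d}", aa if orf_ints is None
                       else len(orf_ints) // 3 - 1, utr5, utr3, "sORF",
                       orf_ints=orf_ints)

    # untranslated sRNAs, each embedding an ORF-shaped decoy
    for i in range(cfg.n_untranslated_srnas):
        aa = int(rng.integers(10, 41))
        orf_len = 3 * (aa + 1)
        pad5 = int(rng.integers(15, 40))
        pad3 = int(rng.integers(15, 40))
        t_len = pad5 + orf_len + pad3
        rep, t_start = b._place(t_len)
        strand = "+" if rng.random() < 0.5 else "-"
        ints, _, _ = b._random_orf(aa)
        orf_start = t_start + (pad5 if strand == "+" else pad3)
        b._write(rep, orf_start, ints, strand)
        abundance = float(np.exp(rng.uniform(*np.log(cfg.abundance_range))))
        b.add_transcript_feature(
            f"srna_{i:03d}", rep, strand, t_start, t_start + t_len,
            t_start, t_start + t_len, "sRNA", 0.0, abundance, False, "",
        )
        b.add_transcript_feature(
            f"decoy_{i:03d}", rep, strand, orf_start, orf_start + orf_len,
            t_start, t_start + t_len, "decoy_sORF", 0.0, abundance, False,
            _ints_to_protein(ints), host_id=f"srna_{i:03d}",
        )

    # housekeeping RNAs (untranslated, typically highly abundant)
    for i in range(cfg.n_hkrnas):
        t_len = int(rng.integers(100, 300))
        rep, t_start = b._place(t_len)
        strand = "+" if rng.random() < 0.5 else "-"
        abundance = float(np.exp(rng.uniform(np.log(2.0), np.log(8.0))))
        b.add_transcript_feature(
            f"hkrna_{i:03d}", rep, strand, t_start, t_start + t_len,
            t_start, t_start + t_len, "hkRNA", 0.0, abundance, False, "",
        )

    # uORFs inside long 5'-UTRs of translated CDS
    hosts = [r for r in b.rows
             if r["feature_class"] == "CDS"
             and _utr5_length(r) >= 90]
    for i in range(min(cfg.n_uorfs, len(hosts))):
        host = hosts[i]
        aa = int(rng.integers(6, 16))
        orf_len = 3 * (aa + 1)
        ints, _, _ = b._random_orf(aa)
        if host["strand"] == "+":
            orf_start = host["transcript_start"] + 10
        else:
            orf_start = host["transcript_end"] - 10 - orf_len
        b._write(host["replicon_id"], orf_start, ints, host["strand"])
        te = float(rng.uniform(*cfg.te_range))
        b.add_transcript_feature(
            f"uorf_{i:03d}", host["replicon_id"], host["strand"], orf_start,
            orf_start + orf_len, host["transcript_start"],
            host["transcript_end"], "uORF", te, host["abundance"], True,
            _ints_to_protein(ints), host_id=host["feature_id"],
        )

    # antisense sORFs opposite the 3'-UTR of selected CDS transcripts
    for i, host in enumerate(asense_hosts[: cfg.n_antisense_sorfs]):
        aa = int(rng.integers(10, 31))
        orf_len = 3 * (aa + 1)
        pad = 8
        if host["strand"] == "+":
            utr3_start, utr3_end = host["end"], host["transcript_end"]
            strand = "-"
        else:
            utr3_start, utr3_end = host["transcript_start"], host["start"]
            strand = "+"
        orf_start = utr3_start + pad
        if orf_start + orf_len + pad > utr3_end:
            continue
        ints, _, _ = b._random_orf(aa)
        b._write(host["replicon_id"], orf_start, ints, strand)
        te = float(rng.uniform(*cfg.te_range))
        abundance = float(np.exp(rng.uniform(*np.log(cfg.abundance_range))))
        t_start, t_end = orf_start - 5, orf_start + orf_len + 5
        b.add_transcript_feature(
            f"asorf_{i:03d}", host["replicon_id"], strand, orf_start,
            orf_start + orf_len, t_start, t_end, "antisense_sORF", te,
            abundance, True, _ints_to_protein(ints), host_id=host["feature_id"],
        )

    # background transcripts: unannotated, untranslated RNA mass (the real
    # data's rRNA remnants and unannotated transcription).  Their total
    # RNA-seq mass is chosen so that the ribosome-footprint library and the
    # RNA-seq library have equal mapped-read totals in expectation, which
    # makes the planted TE identifiable from the RPKM ratio.
    interim = pd.DataFrame(b.rows, columns=TRUTH_COLUMNS)
    w_rna = float(_transcript_positions(interim)["weight"].sum())
    orfs = interim[interim["translated"]]
    w_ribo = float((orfs["abundance"] * orfs["te"]
                    * _orf_overlap_span(orfs)).sum())
    excess = w_ribo - w_rna
    if excess > 0:
        n_bg = 12
        bg_len = 1000
        bg_abundance = excess / (n_bg * (bg_len - _MEAN_FRAGMENT + 1))
        for i in range(n_bg):
            rep, t_start = b._place(bg_len)
            strand = "+" if rng.random() < 0.5 else "-"
            b.add_transcript_feature(
                f"background_{i:03d}", rep, strand, t_start, t_start + bg_len,
                t_start, t_start + bg_len, "background", 0.0, bg_abundance,
                False, "",
            )

    truth = pd.DataFrame(b.rows, columns=TRUTH_COLUMNS)
    replicons = [Replicon(id=name, sequence=_ints_to_seq(seq))
                 for name, seq in b.sequences.items()]
    truth_annotation = _truth_annotation(truth)
    _verify_planted(truth, replicons)
    return replicons, truth_annotation, truth


def _utr5_length(row) -> int:
    if row["strand"] == "+":
        return row["start"] - row["transcript_start"]
    return row["transcript_end"] - row["end"]


_TRUTH_TO_ANNOT = {
    "CDS": "CDS", "sORF": "sORF", "uORF": "sORF", "antisense_sORF": "sORF",
    "sRNA": "sRNA", "hkRNA": "hkRNA",
}


def _truth_annotation(truth: pd.DataFrame) -> AnnotationSet:
    features = []
    for row in truth.itertuples():
        fclass = _TRUTH_TO_ANNOT.get(row.feature_class)
        if fclass is None:  # decoys are deliberately unannotated
            continue
        features.append(FeatureRecord(
            feature_id=row.feature_id, replicon_id=row.replicon_id,
            strand=row.strand, start=row.start, end=row.end,
            feature_class=fclass, source="truth",
            attributes={"truth_class": row.feature_class},
        ))
        # annotated UTRs of CDS transcripts (residual UTR checks need them)
        if row.feature_class == "CDS":
            left = (row.transcript_start, row.start)
            right = (row.end, row.transcript_end)
            five, three = (left, right) if row.strand == "+" else (right, left)
            for (s, e), cls, tag in ((five, "five_prime_UTR", "5p"),
                                     (three, "three_prime_UTR", "3p")):
                if e > s:
                    features.append(FeatureRecord(
                        feature_id=f"{row.feature_id}_{tag}utr",
                        replicon_id=row.replicon_id, strand=row.strand,
                        start=s, end=e, feature_class=cls, source="truth",
                    ))
    return AnnotationSet(source_name="truth", rank=1, features=features)


def _verify_planted(truth: pd.DataFrame, replicons) -> None:
    """Planted coding features must translate to their recorded protein."""
    by_id = {r.id: r for r in replicons}
    coding = truth[truth["protein"] != ""]
    for row in coding.itertuples():
        feat = FeatureRecord(
            feature_id=row.feature_id, replicon_id=row.replicon_id,
            strand=row.strand, start=row.start, end=row.end,
            feature_class="other",
        )
        seq = feature_sequence(feat, by_id[row.replicon_id])
        if translate_cds(seq) != row.protein:
            raise AssertionError(
                f"planted feature {row.feature_id} does not translate cleanly"
            )


# ---------------------------------------------------------------------------
# read simulation

_MEAN_FRAGMENT = 30  # nominal fragment/footprint length for expectations
_TRANSCRIBED_CLASSES = ("CDS", "sORF", "sRNA", "hkRNA", "antisense_sORF",
                        "background")


def _transcript_positions(truth: pd.DataFrame) -> pd.DataFrame:
    """Unique transcripts with their abundance-weighted number of valid
    fragment start positions (the sampling weight of the RNA library)."""
    t = truth[truth["feature_class"].isin(_TRANSCRIBED_CLASSES)]
    t = t.drop_duplicates(subset=["replicon_id", "strand",
                                  "transcript_start", "transcript_end"]).copy()
    n_pos = np.maximum(
        (t["transcript_end"] - t["transcript_start"]) - _MEAN_FRAGMENT + 1, 1)
    t["weight"] = t["abundance"] * n_pos
    return t


def _orf_overlap_span(orfs: pd.DataFrame) -> np.ndarray:
    """Expected number of RNA fragment start positions whose fragment
    overlaps the ORF by >= 1 nt (under uniform transcript tiling).

    Matching the RIBO expectation to ``TE x`` this quantity makes the
    Ribo/RNA RPKM ratio an unbiased estimate of the planted TE under the
    permissive >=1 nt overlap counting rule.
    """
    lo = np.maximum(orfs["transcript_start"],
                    orfs["start"] - _MEAN_FRAGMENT + 1)
    hi = np.minimum(orfs["end"] - 1,
                    orfs["transcript_end"] - _MEAN_FRAGMENT)
    return np.maximum((hi - lo + 1).to_numpy(), 1)


def simulate_reads(truth: pd.DataFrame, config: SimConfig,
                   replicon_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Simulate aligned Ribo-seq and RNA-seq reads for all replicates.

    RNA-seq fragments tile whole transcripts uniformly; ribosome
    footprints are emitted only from translated ORFs, restricted to
    ``[start-16, stop+16]``, with initiation footprints whose 5' ends pile
    up at start-16 and termination footprints whose 3' ends pile up at
    stop+16.  Expected RIBO read numbers are ``TE x`` the feature's RNA
    expectation, so the empirical Ribo/RNA RPKM ratio recovers the planted
    TE.  Counts are Poisson.  Returns a DataFrame with columns
    ``replicon_id, strand, start, end, library, sample_id``.
    """
    rng = np.random.default_rng([config.seed, 202])
    lengths = np.arange(27, 34)
    weights = np.asarray(config.footprint_length_distribution, dtype=float)
    ext = config.initiation_pileup_extent
    p_init = np.array([config.initiation_prob.get(int(l), 0.18) for l in lengths])
    p_term = config.termination_prob

    t_unique = _transcript_positions(truth)  # operon genes share a transcript
    t_weight = t_unique["weight"].to_numpy()
    w_rna = float(t_weight.sum())

    orfs = truth[truth["translated"]]
    o_span = _orf_overlap_span(orfs)
    w_ribo = float((orfs["abundance"].to_numpy() * orfs["te"].to_numpy()
                    * o_span).sum())
    # per-position sampling density is shared between libraries so the
    # Ribo/RNA RPKM ratio recovers the planted TE (see _orf_overlap_span);
    # the denominator uses whichever library carries more mass
    w_common = max(w_rna, w_ribo)
    frames = []
    for rep_i in range(1, config.n_replicates + 1):
        # RNA-seq: uniform tiling of transcripts
        n_rna = rng.poisson(config.library_size * t_weight / w_common)
        frames.append(_emit_rna(t_unique, n_rna, rng, f"rna_{rep_i}"))
        # Ribo-seq: footprints from translated ORFs
        o_exp = config.library_size * orfs["abundance"].to_numpy() * \
            orfs["te"].to_numpy() * o_span / w_common
        n_ribo = rng.poisson(o_exp)
        frames.append(_emit_ribo(orfs, n_ribo, rng, f"ribo_{rep_i}",
                                 lengths, weights, p_init, p_term, ext))
        if config.ribo_noise_rate > 0 and replicon_lengths:
            frames.append(_emit_noise(replicon_lengths, config, rng,
                                      f"ribo_{rep_i}"))
    reads = pd.concat(frames, ignore_index=True)
    return reads[READ_COLUMNS]


def _emit_rna(transcripts: pd.DataFrame, counts, rng, sample_id) -> pd.DataFrame:
    rows = {c: [] for c in READ_COLUMNS}
    for (row, n) in zip(transcripts.itertuples(), counts):
        if n == 0:
            continue
        t_s, t_e = int(row.transcript_start), int(row.transcript_end)
        frag = rng.integers(26, 35, size=n)
        frag = np.minimum(frag, t_e - t_s)
        starts = t_s + (rng.random(n) * (t_e - t_s - frag + 1)).astype(np.int64)
        rows["replicon_id"].append(np.full(n, row.replicon_id, dtype=object))
        rows["strand"].append(np.full(n, row.strand, dtype=object))
        rows["start"].append(starts)
        rows["end"].append(starts + frag)
        rows["library"].append(np.full(n, "RNA", dtype=object))
        rows["sample_id"].append(np.full(n, sample_id, dtype=object))
    return _concat_rows(rows)


def _emit_ribo(orfs: pd.DataFrame, counts, rng, sample_id, lengths, weights,
               p_init, p_term, ext) -> pd.DataFrame:
    rows = {c: [] for c in READ_COLUMNS}
    for (row, n) in zip(orfs.itertuples(), counts):
        if n == 0:
            continue
        o_s, o_e = int(row.start), int(row.end)
        li = rng.choice(len(lengths), size=n, p=weights)
        L = lengths[li]
        u = rng.random(n)
        is_init = u < p_init[li]
        is_term = (~is_init) & (u < p_init[li] + p_term)
        lo, hi = o_s - ext, o_e + ext  # protected span
        if row.strand == "+":
            starts = lo + (rng.random(n) * (hi - lo - L + 1)).astype(np.int64)
            starts[is_init] = o_s - ext  # 5' end pinned at start-16
            starts[is_term] = o_e + ext - L[is_term]  # 3' end at stop+16
        else:
            starts = lo + (rng.random(n) * (hi - lo - L + 1)).astype(np.int64)
            # biological 5' end at (end-1)+16 -> forward start = end+16-L
            starts[is_init] = o_e + ext - L[is_init]
            starts[is_term] = o_s - ext
        rows["replicon_id"].append(np.full(n, row.replicon_id, dtype=object))
        rows["strand"].append(np.full(n, row.strand, dtype=object))
        rows["start"].append(starts)
        rows["end"].append(starts + L)
        rows["library"].append(np.full(n, "RIBO", dtype=object))
        rows["sample_id"].append(np.full(n, sample_id, dtype=object))
    return _concat_rows(rows)


def _emit_noise(replicon_lengths: dict, config: SimConfig, rng,
                sample_id) -> pd.DataFrame:
    rows = {c: [] for c in READ_COLUMNS}
    for rep, length in replicon_lengths.items():
        n = rng.poisson(config.ribo_noise_rate * length)
        if n == 0:
            continue
        L = rng.choice(np.arange(27, 34), size=n,
                       p=config.footprint_length_distribution)
        starts = (rng.random(n) * (length - 34)).astype(np.int64)
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        rows["replicon_id"].append(np.full(n, rep, dtype=object))
        rows["strand"].append(strands.astype(object))
        rows["start"].append(starts)
        rows["end"].append(starts + L)
        rows["library"].append(np.full(n, "RIBO", dtype=object))
        rows["sample_id"].append(np.full(n, sample_id, dtype=object))
    return _concat_rows(rows)


def _concat_rows(rows: dict) -> pd.DataFrame:
    if not rows["start"]:
        return pd.DataFrame(columns=READ_COLUMNS)
    return pd.DataFrame({c: np.concatenate(rows[c]) for c in READ_COLUMNS})


# ---------------------------------------------------------------------------
# candidate tables and PSM tables


def make_candidate_table(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Emulated ORF-predictor output for standalone sORF candidates.

    Planted translated sORFs receive high DeepRibo-like scores; decoy ORFs
    inside untranslated sRNAs receive scores centred near the calling
    threshold, so that the expression filters -- not the score alone --
    must reject them.  Columns mirror a predictor TSV: candidate id,
    coordinates, score, and a REPARATION-called flag.
    """
    rng = np.random.default_rng([config.seed, 303])
    rows = []
    pool = truth[truth["feature_class"].isin(["sORF", "decoy_sORF"])]
    for row in pool.itertuples():
        translated = bool(row.translated)
        score = float(rng.normal(2.0, 0.6)) if translated else \
            float(rng.normal(-0.5, 0.8))
        rows.append(dict(
            candidate_id=f"cand_{row.feature_id}", replicon_id=row.replicon_id,
            strand=row.strand, start=row.start, end=row.end,
            deepribo_score=round(score, 4),
            reparation_called=bool(rng.random() < (0.4 if translated else 0.05)),
            source="novel", truth_id=row.feature_id,
            truth_translated=translated,
        ))
    return pd.DataFrame(rows)


def simulate_psms(truth: pd.DataFrame, protease: str,
                  config: SimConfig) -> pd.DataFrame:
    """Simulate a filtered PSM table for one protease approach.

    Peptides are sampled from the in-silico digest of each expressed
    (translated) protein: tryptic or LysC peptides with up to two missed
    cleavages, or arbitrary substrings for the no-protease approach.  PSM
    counts are 1 + Poisson distributed and spread over the configured MS
    replicates.  Columns: peptide, replicate, psm_count, condition.
    """
    from .peptide_evidence import digest

    codes = {"trypsin": 1, "lysC": 2, "none": 3}
    if protease not in codes:
        raise ValueError(f"unknown protease {protease!r}")
    rng = np.random.default_rng([config.seed, 404, codes[protease]])
    lo, hi = config.nonspecific_peptide_bounds
    rows = []
    proteins = truth[truth["translated"] & (truth["protein"] != "")]
    for row in proteins.itertuples():
        if protease == "none":
            peptides = sorted(digest(row.protein, "none",
                                     length_bounds=(lo, hi)))
        else:
            peptides = sorted(p for p in digest(row.protein, protease,
                                                max_missed=2)
                              if 7 <= len(p) <= 40)
        if not peptides:
            continue
        k = min(config.peptides_per_protein, len(peptides))
        chosen = rng.choice(len(peptides), size=k, replace=False)
        for pi in sorted(chosen):
            total = 1 + rng.poisson(config.mean_extra_psms)
            reps = rng.integers(1, config.n_ms_replicates + 1, size=total)
            for r in range(1, config.n_ms_replicates + 1):
                c = int((reps == r).sum())
                if c:
                    rows.append(dict(peptide=peptides[pi],
                                     replicate=f"ms_rep{r}", psm_count=c,
                                     condition="minimal_medium"))
    return pd.DataFrame(rows, columns=["peptide", "replicate", "psm_count",
                                       "condition"])


# ---------------------------------------------------------------------------
# multi-source annotation emulation


def split_annotation_sources(truth: pd.DataFrame, replicons,
                             config: SimConfig) -> list[AnnotationSet]:
    """Derive two imperfect annotation releases from the truth annotation.

    The rank-1 source carries all CDS but misses ~40 % of sORFs (the
    classic under-annotation of short ORFs); the rank-2 source includes
    all coding features but adopts a shorter in-frame start for some of
    them when one exists, creating stop-codon-anchored clusters with two
    proteoforms for the database-integration machinery.
    """
    rng = np.random.default_rng([config.seed, 505])
    by_id = {r.id: r for r in replicons}
    coding = truth[truth["feature_class"].isin(["CDS", "sORF"])]
    src1, src2 = [], []
    for row in coding.itertuples():
        fclass = "CDS" if row.feature_class == "CDS" else "sORF"
        rec = FeatureRecord(
            feature_id=f"GB_{row.feature_id}", replicon_id=row.replicon_id,
            strand=row.strand, start=row.start, end=row.end,
            feature_class=fclass, source="genbank_sim",
        )
        keep = fclass == "CDS" or rng.random() > 0.4
        if keep:
            src1.append(rec)
        start, end = row.start, row.end
        if rng.random() < 0.3:
            alt = _shorter_start(row, by_id[row.replicon_id])
            if alt is not None:
                start, end = alt
        try:
            src2.append(FeatureRecord(
                feature_id=f"RS_{row.feature_id}", replicon_id=row.replicon_id,
                strand=row.strand, start=start, end=end,
                feature_class="CDS" if (end - start) // 3 - 1 > 70 else "sORF",
                source="refseq_sim",
            ))
        except Exception:
            pass
    return [
        AnnotationSet("genbank_sim", rank=1, features=src1),
        AnnotationSet("refseq_sim", rank=2, features=src2),
    ]


def _shorter_start(row, replicon):
    """Find a downstream in-frame alternative start; None if absent."""
    feat = FeatureRecord(feature_id="tmp", replicon_id=row.replicon_id,
                         strand=row.strand, start=row.start, end=row.end,
                         feature_class="other")
    seq = feature_sequence(feat, replicon)
    for off in range(3, len(seq) - 6, 3):
        if seq[off: off + 3] in _START_CODONS:
            if (len(seq) - off) // 3 - 1 < 5:
                return None
            if row.strand == "+":
                return row.start + off, row.end
            return row.start, row.end - off
    return None


# ---------------------------------------------------------------------------
# plain-text I/O


def write_reads_tsv(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def read_reads_tsv(path) -> pd.DataFrame:
    reads = pd.read_csv(path, sep="\t", dtype={"replicon_id": str,
                                               "strand": str,
                                               "library": str,
                                               "sample_id": str})
    return reads[READ_COLUMNS]
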