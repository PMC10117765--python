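"""Integrated proteogenomic search databases (iPtgxDB-style).

Multiple annotation sources (reference releases, ab initio predictions,
and either in-silico six-frame ORFs or an experimentally informed
Ribo-seq candidate set) are hierarchically consolidated into annotation
clusters: genomic loci sharing a stop codon, whose start-site variants
are the cluster's proteoforms.  From each cluster a minimally redundant
set of protease-specific protein entries is generated -- the most
upstream proteoform in full, every shorter proteoform only as the
N-terminal stretch that can yield proteoform-specific peptides at the
configured missed-cleavage depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome_io import (
    AnnotationSet,
    FeatureRecord,
    feature_sequence,
    translate_cds,
)
from .peptide_evidence import PROTEASES, cleavage_sites

logger = logging.getLogger(__name__)

__all__ = [
    "Proteoform",
    "AnnotationCluster",
    "ProteinEntry",
    "predict_insilico_orfs",
    "integrate_annotations",
    "generate_entries",
    "generate_all_entries",
    "write_iptgxdb",
    "cluster_summary",
]

_STOPS = ("TAA", "TAG", "TGA")
_CATEGORY_ORDER = {"annotated": 0, "ab_initio": 1, "in_silico": 2, "riboseq": 2}


@dataclass
class Proteoform:
    """One start-site variant within an annotation cluster."""

    start: int  # genomic coordinate of the biological first nt
    interval: tuple[int, int]  # 0-based half-open genomic interval
    protein_sequence: str
    sources: set = field(default_factory=set)  # (source_name, feature_id)
    rank: int = 10**6
    category: str = "in_silico"


@dataclass
class AnnotationCluster:
    """Stop-codon-anchored group of proteoforms.

    ``proteoforms`` are ordered most upstream first, so the first one is
    the longest.  ``category`` is that of the best-ranked contributing
    source; the composite identifier lists every source-qualified feature
    id exactly once.
    """

    replicon_id: str
    strand: str
    stop_coordinate: int  # genomic position of the last base of the stop
    proteoforms: list = field(default_factory=list)

    @property
    def category(self) -> str:
        best = min(self.proteoforms, key=lambda p: p.rank)
        return best.category

    @property
    def cluster_id(self) -> str:
        tags = []
        for p in self.proteoforms:
            for src, fid in sorted(p.sources):
                tags.append(f"{src}:{fid}@{p.start}")
        return (f"{self.replicon_id}|{self.strand}|{self.stop_coordinate}|"
                + ";".join(tags))

    @property
    def short_id(self) -> str:
        return f"{self.replicon_id}_{self.strand}_{self.stop_coordinate}"


@dataclass
class ProteinEntry:
    entry_id: str
    cluster_id: str
    proteoform_start: int
    sequence: str  # full sequence or N-terminal minimal stretch
    protease: str
    category: str


# ---------------------------------------------------------------------------
# six-frame in-silico ORF prediction


def _frame_orfs(seq: str, min_aa: int, start_codons, max_alt_starts):
    """Yield (start, end) local half-open intervals (stop included) for all
    ORFs in the three forward frames of ``seq``."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for frame in range(3):
        n_codons = (len(seq) - frame) // 3
        if n_codons < 2:
            continue
        codons = arr[frame: frame + 3 * n_codons].reshape(-1, 3)
        text = codons.tobytes().decode()
        trip = [text[i: i + 3] for i in range(0, len(text), 3)]
        is_stop = np.array([t in _STOPS for t in trip])
        is_start = np.array([t in start_codons for t in trip])
        prev_stop = -1
        for stop_idx in np.flatnonzero(is_stop):
            starts = np.flatnonzero(is_start[prev_stop + 1: stop_idx])
            emitted = 0
            for s in starts:
                start_idx = prev_stop + 1 + int(s)
                aa = stop_idx - start_idx
                if aa < min_aa:
                    break  # later starts are even shorter
                yield (frame + 3 * start_idx, frame + 3 * (stop_idx + 1))
                emitted += 1
                if emitted >= max_alt_starts:
                    break
            prev_stop = int(stop_idx)


def predict_insilico_orfs(
    replicons,
    min_aa: int = 10,
    start_codons: tuple[str, ...] = ("ATG", "GTG", "TTG"),
    max_alt_starts: int = 5,
    source_name: str = "insilico",
    rank: int = 100,
) -> AnnotationSet:
    """Modified six-frame translation with alternative start sites.

    For every stop-to-stop segment in all six frames, up to
    ``max_alt_starts`` start codons (most upstream first) with at least
    ``min_aa`` residues are emitted as ORFs (stop codon included in the
    interval).
    """
    from Bio.Seq import Seq

    features = []
    counter = 0
    for replicon in replicons:
        L = replicon.length
        for strand in "+-":
            seq = (replicon.sequence if strand == "+"
                   else str(Seq(replicon.sequence).reverse_complement()))
            for lo, hi in _frame_orfs(seq, min_aa, start_codons, max_alt_starts):
                if strand == "+":
                    g_lo, g_hi = lo, hi
                else:
                    g_lo, g_hi = L - hi, L - lo
                counter += 1
                features.append(FeatureRecord(
                    feature_id=f"{source_name}_{counter:07d}",
                    replicon_id=replicon.id, strand=strand,
                    start=g_lo, end=g_hi, feature_class="CDS"
                    if (g_hi - g_lo) // 3 - 1 > 70 else "sORF",
                    source=source_name,
                ))
    return AnnotationSet(source_name=source_name, rank=rank,
                         features=features, category="in_silico")


# ---------------------------------------------------------------------------
# hierarchical integration


def _biological_start(feature: FeatureRecord) -> int:
    return feature.start if feature.strand == "+" else feature.end - 1


def _stop_coordinate(feature: FeatureRecord) -> int:
    return feature.end - 1 if feature.strand == "+" else feature.start


def integrate_annotations(
    sources: list[AnnotationSet],
    extra: AnnotationSet | None,
    replicons,
) -> list[AnnotationCluster]:
    """Hierarchically integrate annotation sources into clusters.

    ``sources`` must be ordered by rank (1 = highest authority); the
    optional ``extra`` set is the lowest tier (in-silico ORFs for a
    standard database, a Ribo-seq candidate set for a custom one).
    Features failing stop-codon validation against the genome (e.g.
    pseudogenes/frameshifts) are rejected and logged.  Lower-ranked
    sources never override a higher-ranked start site; they only add
    proteoforms or source tags.
    """
    by_id = {r.id: r for r in replicons}
    ordered = sorted(sources, key=lambda s: s.rank)
    if extra is not None:
        ordered = ordered + [extra]
    clusters: dict[tuple, AnnotationCluster] = {}
    rejected = 0
    for annotation in ordered:
        for feature in annotation:
            if feature.feature_class not in ("CDS", "sORF"):
                continue
            replicon = by_id[feature.replicon_id]
            try:
                nt = feature_sequence(feature, replicon)
            except Exception:
                rejected += 1
                continue
            if len(nt) % 3 != 0 or nt[-3:] not in _STOPS:
                logger.warning(
                    "rejecting %s:%s without a valid stop codon",
                    annotation.source_name, feature.feature_id,
                )
                rejected += 1
                continue
            key = (feature.replicon_id, feature.strand,
                   _stop_coordinate(feature))
            cluster = clusters.setdefault(
                key, AnnotationCluster(replicon_id=key[0], strand=key[1],
                                       stop_coordinate=key[2]))
            start = _biological_start(feature)
            match = next((p for p in cluster.proteoforms if p.start == start),
                         None)
            if match is None:
                match = Proteoform(
                    start=start, interval=(feature.start, feature.end),
                    protein_sequence=translate_cds(nt),
                )
                cluster.proteoforms.append(match)
            match.sources.add((annotation.source_name, feature.feature_id))
            if annotation.rank < match.rank:
                match.rank = annotation.rank
                match.category = annotation.category
    if rejected:
        logger.info("rejected %d coding features during integration", rejected)
    out = []
    for cluster in clusters.values():
        upstream_first = cluster.strand == "+"
        cluster.proteoforms.sort(
            key=lambda p: p.start, reverse=not upstream_first)
        out.append(cluster)
    out.sort(key=lambda c: (c.replicon_id, c.stop_coordinate, c.strand))
    return out


# ---------------------------------------------------------------------------
# minimally redundant protein entries


def generate_entries(
    cluster: AnnotationCluster,
    protease: str,
    max_missed_cleavages: int = 2,
) -> list[ProteinEntry]:
    """Protein entries for one cluster under one protease dialect.

    The most upstream proteoform is emitted in full.  Each shorter
    proteoform is truncated after cleavage site number
    ``1 + max_missed_cleavages`` downstream of its start (or kept in full
    if fewer sites exist): any proteoform-specific peptide -- one covering
    its N-terminal residue -- with at most that many missed cleavages is
    then contained in the entry, while everything further downstream is
    already covered by the full parent entry.  Without protease
    cleavage, truncation is impossible and every proteoform is emitted in
    full.
    """
    if protease not in PROTEASES:
        raise ValueError(f"unknown protease {protease!r}")
    entries = []
    for i, proteoform in enumerate(cluster.proteoforms):
        seq = proteoform.protein_sequence
        if i > 0 and protease != "none":
            sites = cleavage_sites(seq, protease)
            needed = 1 + max_missed_cleavages
            if len(sites) >= needed:
                seq = seq[: sites[needed - 1] + 1]
        entries.append(ProteinEntry(
            entry_id=f"{cluster.short_id}_p{i:02d}",
            cluster_id=cluster.cluster_id,
            proteoform_start=proteoform.start,
            sequence=seq,
            protease=protease,
            category=cluster.category,
        ))
    return entries


def generate_all_entries(clusters, protease: str,
                         max_missed_cleavages: int = 2) -> list[ProteinEntry]:
    out = []
    for cluster in clusters:
        out.extend(generate_entries(cluster, protease, max_missed_cleavages))
    return out


# ---------------------------------------------------------------------------
# output


def write_iptgxdb(
    clusters,
    protease: str,
    fasta_path,
    gff_path,
    max_missed_cleavages: int = 2,
    contaminants_fasta=None,
) -> int:
    """Write the protein FASTA and companion GFF for one protease.

    Ordering is deterministic (replicon, stop, start).  Optional
    user-supplied contaminant sequences are appended verbatim.  Returns
    the number of entries written (excluding contaminants).
    """
    n = 0
    with open(fasta_path, "w") as fasta, open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for cluster in clusters:
            entries = generate_entries(cluster, protease, max_missed_cleavages)
            for entry, proteoform in zip(entries, cluster.proteoforms):
                sources = ",".join(f"{s}:{f}" for s, f in
                                   sorted(proteoform.sources))
                fasta.write(
                    f">{entry.entry_id} cluster={cluster.short_id} "
                    f"start={proteoform.start} category={cluster.category} "
                    f"sources={sources}\n{entry.sequence}\n"
                )
                lo, hi = proteoform.interval
                gff.write("\t".join([
                    cluster.replicon_id, "iptgxdb", "CDS", str(lo + 1),
                    str(hi), ".", cluster.strand, "0",
                    f"ID={entry.entry_id};cluster={cluster.short_id};"
                    f"category={cluster.category};sources={sources}",
                ]) + "\n")
                n += 1
        if contaminants_fasta is not None:
            from Bio import SeqIO

            for record in SeqIO.parse(str(contaminants_fasta), "fasta"):
                fasta.write(f">CONT_{record.id}\n{record.seq}\n")
    return n


def cluster_summary(clusters) -> "pd.DataFrame":
    import pandas as pd

    rows = [
        dict(
            cluster=c.short_id,
            replicon_id=c.replicon_id,
            strand=c.strand,
            stop_coordinate=c.stop_coordinate,
            n_proteoforms=len(c.proteoforms),
            category=c.category,
            composite_id=c.cluster_id,
        )
        for c in clusters
    ]
    return pd.DataFrame(rows)
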