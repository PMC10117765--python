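"""Genome sequences and multi-source annotations.

Defines the coordinate conventions used throughout the package:
internal coordinates are 0-based, half-open ``[start, end)``; GFF3 files
(1-based, inclusive) are converted at the I/O boundary.  CDS and sORF
intervals include the stop codon; ``aa_length`` excludes it, so a 153 nt
CDS encodes a 50 aa protein.  An sORF is a coding feature of at most
70 amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SORF_MAX_AA",
    "Replicon",
    "FeatureRecord",
    "AnnotationSet",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "feature_sequence",
    "translate_cds",
]

#: coding features at or below this many amino acids are classed as sORFs
SORF_MAX_AA = 70

_IUPAC_NT = set("ACGTUNRYSWKMBDHV")

FEATURE_CLASSES = (
    "CDS",
    "sORF",
    "five_prime_UTR",
    "three_prime_UTR",
    "sRNA",
    "hkRNA",
    "other",
)


class ValidationError(ValueError):
    """Raised when an input file or record violates a format contract."""


@dataclass
class Replicon:
    """A chromosome or plasmid sequence."""

    id: str
    sequence: str
    circular: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class FeatureRecord:
    """A stranded genomic interval with a feature class and source tag.

    Coordinates are 0-based half-open on the forward strand regardless of
    the feature's own strand.
    """

    feature_id: str
    replicon_id: str
    strand: str
    start: int
    end: int
    feature_class: str = "other"
    source: str = ""
    aa_length: int | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"unknown strand {self.strand!r} for {self.feature_id}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"bad interval [{self.start}, {self.end}) for {self.feature_id}"
            )
        if self.feature_class in ("CDS", "sORF"):
            if (self.end - self.start) % 3 != 0:
                raise ValidationError(
                    f"coding feature {self.feature_id} length not divisible by 3"
                )
            expected = (self.end - self.start) // 3 - 1
            if self.aa_length is None:
                self.aa_length = expected
            elif self.aa_length != expected:
                raise ValidationError(
                    f"{self.feature_id}: aa_length {self.aa_length} != {expected}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    def is_sorf(self) -> bool:
        return self.aa_length is not None and self.aa_length <= SORF_MAX_AA


@dataclass
class AnnotationSet:
    """A collection of features from one annotation source.

    ``rank`` orders sources by authority (1 = highest); the hierarchical
    database builder never lets a lower-ranked source override a
    higher-ranked start site.
    """

    source_name: str
    rank: int
    features: list[FeatureRecord] = field(default_factory=list)
    category: str = "annotated"

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate feature ids in {self.source_name}")

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[Replicon]:
    """Read a genome FASTA into Replicon records.

    Sequences are uppercased and U is converted to T.  Duplicate record
    ids, empty files and non-IUPAC characters raise ValidationError.
    """
    replicons: list[Replicon] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValidationError(f"duplicate FASTA record id {record.id!r}")
        seen.add(record.id)
        seq = str(record.seq).upper().replace("U", "T")
        bad = set(seq) - _IUPAC_NT
        if bad:
            raise ValidationError(
                f"non-IUPAC characters {sorted(bad)} in record {record.id!r}"
            )
        replicons.append(Replicon(id=record.id, sequence=seq))
    if not replicons:
        raise ValidationError(f"no FASTA records found in {path}")
    return replicons


def write_fasta(replicons, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in replicons
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3

#: default mapping from GFF3 feature type to internal feature class; ncRNA
#: lines may refine this via an attribute (see ``class_attribute``)
DEFAULT_TYPE_MAP = {
    "CDS": "CDS",
    "five_prime_UTR": "five_prime_UTR",
    "three_prime_UTR": "three_prime_UTR",
    "ncRNA": "sRNA",
    "sRNA": "sRNA",
    "tRNA": "hkRNA",
    "rRNA": "hkRNA",
    "tmRNA": "hkRNA",
}

_INTERNAL_TO_GFF_TYPE = {
    "CDS": "CDS",
    "sORF": "CDS",
    "five_prime_UTR": "five_prime_UTR",
    "three_prime_UTR": "three_prime_UTR",
    "sRNA": "ncRNA",
    "hkRNA": "ncRNA",
    "other": "region",
}


def _parse_attributes(text: str) -> dict:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, value = part.split("=", 1)
            attrs[key] = value
    return attrs


def _format_attributes(attrs: dict) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def read_gff(
    path,
    source_name: str,
    rank: int,
    replicon_lengths: dict[str, int] | None = None,
    type_map: dict[str, str] | None = None,
    class_attribute: str = "rna_class",
    category: str = "annotated",
) -> AnnotationSet:
    """Read a GFF3 file into an AnnotationSet.

    GFF 1-based inclusive coordinates become internal 0-based half-open
    ones.  The feature class is mapped from the GFF type column via
    ``type_map``; non-coding RNAs may carry a ``class_attribute`` key
    (dialect-configurable) that refines sRNA vs hkRNA.  CDS features of
    at most 70 aa are classed as sORFs.
    """
    type_map = dict(DEFAULT_TYPE_MAP if type_map is None else type_map)
    features: list[FeatureRecord] = []
    counter = 0
    with open(path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValidationError(f"malformed GFF line: {line!r}")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            if ftype in ("gene", "region", "exon", "mRNA"):
                continue
            if strand not in ("+", "-"):
                raise ValidationError(f"unknown strand symbol {strand!r} in {path}")
            start = int(start_s) - 1
            end = int(end_s)
            if start < 0 or end <= start:
                raise ValidationError(f"bad coordinates {start_s}..{end_s} in {path}")
            if replicon_lengths is not None:
                length = replicon_lengths.get(seqid)
                if length is None:
                    raise ValidationError(f"unknown replicon {seqid!r} in {path}")
                if end > length:
                    raise ValidationError(
                        f"feature end {end} beyond replicon {seqid} length {length}"
                    )
            attrs = _parse_attributes(attr_s)
            counter += 1
            fid = attrs.get("ID", f"{source_name}_{counter:06d}")
            fclass = type_map.get(ftype, "other")
            if fclass == "sRNA" and attrs.get(class_attribute) == "hkRNA":
                fclass = "hkRNA"
            if fclass == "CDS" and (end - start) % 3 == 0:
                if (end - start) // 3 - 1 <= SORF_MAX_AA:
                    fclass = "sORF"
            features.append(
                FeatureRecord(
                    feature_id=fid,
                    replicon_id=seqid,
                    strand=strand,
                    start=start,
                    end=end,
                    feature_class=fclass,
                    source=source_name,
                    attributes=attrs,
                )
            )
    return AnnotationSet(
        source_name=source_name, rank=rank, features=features, category=category
    )


def write_gff(annotation: AnnotationSet, path) -> None:
    """Write an AnnotationSet as GFF3, converting back to 1-based inclusive
    coordinates.  Attribute keys are preserved verbatim."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for f in annotation.features:
            attrs = dict(f.attributes)
            attrs.setdefault("ID", f.feature_id)
            gff_type = _INTERNAL_TO_GFF_TYPE.get(f.feature_class, "region")
            if f.feature_class in ("sRNA", "hkRNA"):
                attrs.setdefault("rna_class", f.feature_class)
            handle.write(
                "\t".join(
                    [
                        f.replicon_id,
                        annotation.source_name,
                        gff_type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if gff_type == "CDS" else ".",
                        _format_attributes(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# sequence extraction


def feature_sequence(feature: FeatureRecord, replicon: Replicon) -> str:
    """Extract a feature's nucleotide sequence in reading orientation.

    Minus-strand features return the reverse complement of the forward
    slice.  Features wrapping the origin of a circular replicon are not
    supported.
    """
    if feature.replicon_id != replicon.id:
        raise ValueError(
            f"feature {feature.feature_id} is on {feature.replicon_id}, not {replicon.id}"
        )
    if feature.end > replicon.length:
        raise ValidationError(
            f"feature {feature.feature_id} exceeds replicon length "
            f"(origin-wrapping features are not supported)"
        )
    segment = replicon.sequence[feature.start : feature.end]
    if feature.strand == "-":
        return str(Seq(segment).reverse_complement())
    return segment


def translate_cds(nt_sequence: str, table: int = 11) -> str:
    """Translate a CDS (stop codon included) to its protein, bacterial code.

    The initiator codon is reported as M regardless of whether it is ATG,
    GTG or TTG, as in protein databases.
    """
    if len(nt_sequence) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    protein = str(Seq(nt_sequence).translate(table=table))
    if protein.endswith("*"):
        protein = protein[:-1]
    if protein:
        protein = "M" + protein[1:]
    return protein
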