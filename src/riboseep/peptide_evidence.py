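"""In-silico digestion, peptide ambiguity classes and PSM-tier acceptance.

Peptides identified by MS are mapped back onto the proteoform database
and classified by what they imply: class 1a (one protein entry), 2a (a
proper subset of one cluster's proteoforms, e.g. an N-terminal
extension), 2b (all proteoforms of one cluster -- gene-level evidence),
3a (a unique sequence encoded by several identical gene copies), or
ambiguous.  Protein acceptance is tiered by annotation category and
protein mass: small annotated proteins need 1 unique peptide with 2
PSMs, ab initio predictions 3 PSMs, in-silico/Ribo-seq predictions 4
PSMs (or 3 spread over all three replicates); proteins of >= 15 kDa
always need two unique peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

PROTEASES = ("trypsin", "lysC", "none")

__all__ = [
    "PROTEASES",
    "PsmRecord",
    "AcceptanceDecision",
    "cleavage_sites",
    "digest",
    "classify_peptide",
    "classify_peptides",
    "accept_protein",
    "protein_mass",
]


@dataclass
class PsmRecord:
    """One identified peptide with replicate provenance."""

    peptide_sequence: str
    replicate_id: str
    psm_count: int
    sample_condition: str = ""

    def __post_init__(self) -> None:
        if len(self.peptide_sequence) < 5:
            raise ValueError("peptides shorter than 5 aa are not accepted")
        if self.psm_count < 1:
            raise ValueError("psm_count must be >= 1")


@dataclass
class AcceptanceDecision:
    cluster_id: str
    category: str
    mass_kda: float
    unique_peptides: int
    total_psms: int
    replicates_observed: set = field(default_factory=set)
    accepted: bool = False
    rule_applied: str = ""


# ---------------------------------------------------------------------------
# digestion


def cleavage_sites(sequence: str, protease: str) -> list[int]:
    """Residue indices after which the protease can cleave.

    Trypsin cleaves after K or R except before P; LysC after every
    lysine.  A cleavable residue at the C-terminus is included (it counts
    as a site even though cleavage there is a no-op).
    """
    if protease == "trypsin":
        return [
            i for i, aa in enumerate(sequence)
            if aa in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P")
        ]
    if protease == "lysC":
        return [i for i, aa in enumerate(sequence) if aa == "K"]
    if protease == "none":
        return []
    raise ValueError(f"unknown protease {protease!r}")


def digest(
    protein: str,
    protease: str,
    max_missed: int = 0,
    length_bounds: tuple[int, int] = (1, 10**9),
) -> set[str]:
    """In-silico digest of one protein.

    For trypsin/LysC, returns all peptides with at most ``max_missed``
    internal cleavage sites; for the no-protease case, all substrings
    within ``length_bounds``.
    """
    if protease not in PROTEASES:
        raise ValueError(f"unknown protease {protease!r}")
    lo, hi = length_bounds
    if protease == "none":
        n = len(protein)
        return {
            protein[i: i + L]
            for L in range(max(lo, 1), min(hi, n) + 1)
            for i in range(n - L + 1)
        }
    cuts = [i + 1 for i in cleavage_sites(protein, protease)
            if i + 1 < len(protein)]
    bounds = [0, *cuts, len(protein)]
    fragments = [protein[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    peptides = set()
    for i in range(len(fragments)):
        for j in range(i, min(i + max_missed + 1, len(fragments))):
            pep = "".join(fragments[i: j + 1])
            if lo <= len(pep) <= hi:
                peptides.add(pep)
    return peptides


# ---------------------------------------------------------------------------
# peptide-to-database classification


def classify_peptide(peptide: str, clusters) -> str:
    """Ambiguity class of one peptide against a cluster database.

    Matching is full-sequence substring containment against every
    proteoform.  Returns one of ``1a, 2a, 2b, 3a, ambiguous`` or
    ``unmatched`` when the peptide occurs nowhere in the database.
    """
    hits = []  # (cluster, [matched proteoforms])
    for cluster in clusters:
        matched = [p for p in cluster.proteoforms
                   if peptide in p.protein_sequence]
        if matched:
            hits.append((cluster, matched))
    if not hits:
        return "unmatched"
    if len(hits) == 1:
        cluster, matched = hits[0]
        if len(cluster.proteoforms) == 1:
            return "1a"
        if len(matched) < len(cluster.proteoforms):
            return "2a"
        return "2b"
    sequences = {p.protein_sequence for _, matched in hits for p in matched}
    if len(sequences) == 1:
        return "3a"
    return "ambiguous"


def classify_peptides(peptides, clusters) -> dict:
    """Classify many peptides; returns ``{peptide: class}``."""
    return {p: classify_peptide(p, clusters) for p in set(peptides)}


# ---------------------------------------------------------------------------
# tiered acceptance


_UNIQUE_CLASSES = ("1a", "2a", "3a")


def accept_protein(
    cluster,
    psms: pd.DataFrame,
    classes: dict,
    mass_kda: float | None = None,
    include_2a: bool = True,
    n_replicates_required: int = 3,
) -> AcceptanceDecision:
    """Tiered PSM-based acceptance for one annotation cluster.

    ``psms`` needs columns peptide, replicate, psm_count; only rows whose
    peptide occurs in the cluster contribute.  Peptides of class
    1a/2a/3a count as unique evidence (2a participation is
    configurable); 2b peptides add gene-level PSMs but are not unique.
    The mass defaults to that of the best-ranked proteoform; exactly
    15 kDa falls in the two-unique-peptide regime.
    """
    unique_classes = set(_UNIQUE_CLASSES if include_2a else ("1a", "3a"))
    evidence_classes = unique_classes | {"2b"}
    if mass_kda is None:
        best = min(cluster.proteoforms, key=lambda p: p.rank)
        mass_kda = protein_mass(best.protein_sequence)
    in_cluster = {
        pep for pep in psms["peptide"].unique()
        if any(pep in p.protein_sequence for p in cluster.proteoforms)
    }
    usable = {pep for pep in in_cluster
              if classes.get(pep) in evidence_classes}
    unique_peptides = sum(1 for pep in usable
                          if classes.get(pep) in unique_classes)
    rows = psms[psms["peptide"].isin(usable)]
    total_psms = int(rows["psm_count"].sum())
    replicates = set(rows["replicate"].unique())

    category = cluster.category if hasattr(cluster, "category") else "annotated"
    decision = AcceptanceDecision(
        cluster_id=getattr(cluster, "short_id", str(cluster)),
        category=category,
        mass_kda=float(mass_kda),
        unique_peptides=unique_peptides,
        total_psms=total_psms,
        replicates_observed=replicates,
    )
    if mass_kda >= 15.0:
        decision.accepted = unique_peptides >= 2
        decision.rule_applied = ">=15kDa: two unique peptides"
        return decision
    if unique_peptides < 1:
        decision.rule_applied = "<15kDa: no unique peptide"
        return decision
    if category == "annotated":
        decision.accepted = total_psms >= 2
        decision.rule_applied = "annotated <15kDa: 1 unique peptide, 2 PSMs"
    elif category == "ab_initio":
        decision.accepted = total_psms >= 3
        decision.rule_applied = "ab initio <15kDa: 1 unique peptide, 3 PSMs"
    else:  # in_silico or riboseq predictions
        all_reps = len(replicates) >= n_replicates_required
        decision.accepted = total_psms >= 4 or (total_psms >= 3 and all_reps)
        decision.rule_applied = (
            "in silico <15kDa: 4 PSMs, or 3 PSMs across all replicates"
        )
    return decision


# ---------------------------------------------------------------------------
# mass


def protein_mass(sequence: str) -> float:
    """Average (isotope-weighted) protein mass in kDa, including one
    water; the empty chain returns the mass of water alone."""
    from pyteomics import mass as _mass
    from pyteomics.auxiliary import PyteomicsError

    if sequence == "":
        return float(_mass.calculate_mass(formula="H2O", average=True)) / 1000.0

    try:
        return float(_mass.calculate_mass(sequence=sequence, average=True)) / 1000.0
    except PyteomicsError as exc:
        raise ValueError(f"cannot compute mass: {exc}") from exc
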