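"""Metagene diagnostics around annotated start codons.

Aggregates single-nucleotide ribosome density in a window centred on the
first nucleotide of the start codon (profile coordinate 0).  With
RNase-I footprints, 5'-end mapping shows an initiation pile-up at -16 and
3'-end mapping a mirror peak downstream; per-length stratification scores
which footprint lengths carry the strongest start-codon signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, build_coverage

__all__ = [
    "MetageneProfile",
    "metagene_profile",
    "length_stratified_enrichment",
]


@dataclass
class MetageneProfile:
    mapping_end: str  # five_prime or three_prime
    positions: np.ndarray  # window offsets; 0 = first nt of start codon
    matrix: np.ndarray  # genes x positions, per-gene sum-normalized
    mean_profile: np.ndarray
    n_genes: int
    n_dropped: int

    def peak_offset(self) -> int:
        """Window offset with maximal mean density."""
        return int(self.positions[int(np.argmax(self.mean_profile))])


def _start_position(feature) -> int:
    """Genomic coordinate of the biological first nt of the start codon."""
    return feature.start if feature.strand == "+" else feature.end - 1


def metagene_profile(
    track: CoverageTrack,
    starts,
    window: tuple[int, int] = (-30, 30),
    min_window_sum: float = 0.0,
) -> MetageneProfile:
    """Average start-codon-anchored density over many genes.

    ``track`` must be a single-nucleotide track (five_prime or
    three_prime mode).  Each gene's window row is oriented so negative
    offsets are upstream of the start codon regardless of strand,
    normalized to sum 1, then averaged with equal gene weight; rows with
    zero signal and genes whose window leaves the replicon are dropped
    and counted.
    """
    lo, hi = window
    if not (lo <= 0 <= hi):
        raise ValueError("window must contain offset 0 (the start codon)")
    if track.mapping_mode not in ("five_prime", "three_prime"):
        raise ValueError("metagene requires a single-nucleotide track")
    starts = list(starts)
    if not starts:
        raise ValueError("empty gene set")
    width = hi - lo + 1
    rows, dropped = [], 0
    for feature in starts:
        arr = track.arrays.get((feature.replicon_id, feature.strand))
        if arr is None:
            dropped += 1
            continue
        pos0 = _start_position(feature)
        if feature.strand == "+":
            a, bnd = pos0 + lo, pos0 + hi + 1
            if a < 0 or bnd > len(arr):
                dropped += 1
                continue
            row = arr[a:bnd]
        else:
            a, bnd = pos0 - hi, pos0 - lo + 1
            if a < 0 or bnd > len(arr):
                dropped += 1
                continue
            row = arr[a:bnd][::-1]
        total = row.sum()
        if total <= min_window_sum or total == 0:
            dropped += 1
            continue
        rows.append(row / total)
    if not rows:
        raise ValueError("no gene contributed signal inside the window")
    matrix = np.vstack(rows)
    return MetageneProfile(
        mapping_end=track.mapping_mode,
        positions=np.arange(lo, hi + 1),
        matrix=matrix,
        mean_profile=matrix.mean(axis=0),
        n_genes=len(rows),
        n_dropped=dropped,
    )


def length_stratified_enrichment(
    reads: pd.DataFrame,
    starts,
    replicon_lengths: dict[str, int],
    lengths: range = range(27, 34),
    initiation_window: tuple[int, int] = (-16, 0),
) -> pd.Series:
    """Start-codon enrichment score per footprint length.

    For each read length, a 5'-end track is built and the score is the
    mean per-gene density in the initiation window divided by the mean
    density over the ORF body.  Lengths with no reads are absent from the
    result.  The score is a declared proxy for "ribosome density
    strongest at the start codon".
    """
    read_len = reads["end"] - reads["start"]
    scores = {}
    for L in lengths:
        sub = reads[read_len == L]
        if len(sub) == 0:
            continue
        track = build_coverage(sub, replicon_lengths, "five_prime")
        init_total, init_n = 0.0, 0
        body_total, body_n = 0.0, 0
        for feature in starts:
            arr = track.arrays.get((feature.replicon_id, feature.strand))
            if arr is None:
                continue
            pos0 = _start_position(feature)
            lo, hi = initiation_window
            if feature.strand == "+":
                init = arr[max(pos0 + lo, 0): pos0 + hi + 1]
                body = arr[feature.start: feature.end]
            else:
                init = arr[pos0 - hi: pos0 - lo + 1]
                body = arr[feature.start: feature.end]
            init_total += float(init.sum())
            init_n += len(init)
            body_total += float(body.sum())
            body_n += len(body)
        if body_total == 0 or body_n == 0 or init_n == 0:
            continue
        scores[L] = (init_total / init_n) / (body_total / body_n)
    return pd.Series(scores, dtype=float)


def profile_table(profile: MetageneProfile) -> pd.DataFrame:
    """TSV-ready view of a metagene profile."""
    return pd.DataFrame(
        {
            "position": profile.positions,
            "mean_density": profile.mean_profile,
            "n_genes": profile.n_genes,
        }
    )
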