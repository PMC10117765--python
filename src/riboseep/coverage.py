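"""Strand-aware coverage tracks and mil/min normalization.

Reads can be assigned to positions in four modes: ``global`` (every
covered nucleotide), ``centered`` (full read minus ``k`` nt trimmed from
both ends), or single-nucleotide ``five_prime`` / ``three_prime`` (the
biological read end, strand-aware).  Raw integer tracks can be rescaled
per million mapped reads (``mil``) or to the smallest library among a set
of samples (``min``); both are scalar per-sample factors, so ratios of
positions within a sample are preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MAPPING_MODES = ("global", "centered", "five_prime", "three_prime")

__all__ = [
    "CoverageTrack",
    "build_coverage",
    "normalize_mil",
    "normalize_min",
    "reads_from_sam",
    "write_bedgraph",
]


@dataclass
class CoverageTrack:
    """Per-replicon, per-strand position-indexed read density."""

    sample_id: str
    library: str
    mapping_mode: str
    arrays: dict = field(default_factory=dict)  # (replicon_id, strand) -> array
    total_mapped_reads: int = 0
    normalization: str = "raw"

    def get(self, replicon_id: str, strand: str) -> np.ndarray:
        return self.arrays[(replicon_id, strand)]

    def total_signal(self) -> float:
        return float(sum(a.sum() for a in self.arrays.values()))


def build_coverage(
    reads: pd.DataFrame,
    replicon_lengths: dict[str, int],
    mode: str,
    sample_id: str | None = None,
    library: str | None = None,
    center_trim: int = 5,
) -> CoverageTrack:
    """Build one raw coverage track from an aligned-read table.

    ``reads`` needs columns replicon_id, strand, start, end (0-based
    half-open); rows are optionally pre-filtered to one sample/library via
    ``sample_id``/``library``.  In ``centered`` mode ``center_trim`` nt are
    trimmed from both read ends; reads shorter than ``2*center_trim + 1``
    contribute their midpoint.
    """
    if mode not in MAPPING_MODES:
        raise ValueError(f"unknown mapping mode {mode!r}")
    sel = reads
    if sample_id is not None:
        sel = sel[sel["sample_id"] == sample_id]
    if library is not None:
        sel = sel[sel["library"] == library]
    if len(sel) and (
        sel["start"].min() < 0
        or any(
            sel.loc[sel["replicon_id"] == rep, "end"].max() > length
            for rep, length in replicon_lengths.items()
            if (sel["replicon_id"] == rep).any()
        )
    ):
        raise ValueError("read interval outside replicon bounds")
    unknown = set(sel["replicon_id"]) - set(replicon_lengths)
    if unknown:
        raise ValueError(f"reads on unknown replicons: {sorted(unknown)}")

    arrays = {
        (rep, strand): np.zeros(length, dtype=float)
        for rep, length in replicon_lengths.items()
        for strand in "+-"
    }
    for (rep, strand), grp in sel.groupby(["replicon_id", "strand"], sort=False):
        length = replicon_lengths[rep]
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        arr = arrays[(rep, strand)]
        if mode == "five_prime":
            pos = starts if strand == "+" else ends - 1
            np.add.at(arr, pos, 1.0)
        elif mode == "three_prime":
            pos = ends - 1 if strand == "+" else starts
            np.add.at(arr, pos, 1.0)
        else:
            if mode == "centered":
                lengths = ends - starts
                short = lengths < 2 * center_trim + 1
                mid = (starts + ends) // 2
                t_starts = np.where(short, mid, starts + center_trim)
                t_ends = np.where(short, mid + 1, ends - center_trim)
            else:
                t_starts, t_ends = starts, ends
            diff = np.zeros(length + 1, dtype=float)
            np.add.at(diff, t_starts, 1.0)
            np.add.at(diff, t_ends, -1.0)
            arr += np.cumsum(diff[:-1])
    return CoverageTrack(
        sample_id=sample_id or "all",
        library=library or "all",
        mapping_mode=mode,
        arrays=arrays,
        total_mapped_reads=int(len(sel)),
        normalization="raw",
    )


def normalize_mil(track: CoverageTrack) -> CoverageTrack:
    """Scale a raw track per million mapped reads of its own sample."""
    if track.normalization != "raw":
        raise ValueError("mil normalization expects a raw track")
    if track.total_mapped_reads == 0:
        raise ValueError("cannot normalize a track with zero mapped reads")
    factor = 1e6 / track.total_mapped_reads
    arrays = {k: v * factor for k, v in track.arrays.items()}
    return replace(track, arrays=arrays, normalization="mil")


def normalize_min(tracks: list[CoverageTrack]) -> list[CoverageTrack]:
    """Scale each raw track by min(total mapped reads) / its own total.

    The smallest library is returned unchanged in value; all others are
    scaled down to its depth, which is what genome-browser comparison of
    samples at a common scale requires.
    """
    if not tracks:
        raise ValueError("no tracks to normalize")
    totals = [t.total_mapped_reads for t in tracks]
    if any(t == 0 for t in totals):
        raise ValueError("cannot min-normalize with a zero-read sample")
    if any(t.normalization != "raw" for t in tracks):
        raise ValueError("min normalization expects raw tracks")
    min_total = min(totals)
    out = []
    for t in tracks:
        factor = min_total / t.total_mapped_reads
        arrays = {k: v * factor for k, v in t.arrays.items()}
        out.append(replace(t, arrays=arrays, normalization="min"))
    return out


def reads_from_sam(path, library: str, sample_id: str) -> pd.DataFrame:
    """Import aligned reads from SAM/BAM via pysam.

    Unmapped, secondary and supplementary alignments are dropped (the
    count of dropped records is attached as ``DataFrame.attrs['dropped']``);
    multi-mapped reads are assumed removed upstream.
    """
    import pysam

    rows = {c: [] for c in ("replicon_id", "strand", "start", "end")}
    dropped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for aln in handle.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                dropped += 1
                continue
            rows["replicon_id"].append(aln.reference_name)
            rows["strand"].append("-" if aln.is_reverse else "+")
            rows["start"].append(aln.reference_start)
            rows["end"].append(aln.reference_end)
    reads = pd.DataFrame(rows)
    reads["library"] = library
    reads["sample_id"] = sample_id
    reads.attrs["dropped"] = dropped
    return reads


def write_bedgraph(track: CoverageTrack, out_dir, prefix: str | None = None) -> list:
    """Write one bedGraph per strand (0-based half-open intervals) plus a
    JSON sidecar with totals, mode and normalization state."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or f"{track.sample_id}_{track.library}_{track.mapping_mode}"
    written = []
    for strand, tag in (("+", "fwd"), ("-", "rev")):
        path = out_dir / f"{prefix}_{tag}.bedgraph"
        with open(path, "w") as handle:
            for (rep, s), arr in sorted(track.arrays.items()):
                if s != strand:
                    continue
                # run-length encode constant stretches
                change = np.flatnonzero(np.diff(arr)) + 1
                bounds = np.concatenate(([0], change, [len(arr)]))
                for lo, hi in zip(bounds[:-1], bounds[1:]):
                    value = arr[lo]
                    if value != 0:
                        handle.write(f"{rep}\t{lo}\t{hi}\t{value:g}\n")
        written.append(path)
    sidecar = out_dir / f"{prefix}.json"
    with open(sidecar, "w") as handle:
        json.dump(
            {
                "sample_id": track.sample_id,
                "library": track.library,
                "mapping_mode": track.mapping_mode,
                "normalization": track.normalization,
                "total_mapped_reads": track.total_mapped_reads,
            },
            handle,
            indent=2,
        )
    written.append(sidecar)
    return written
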