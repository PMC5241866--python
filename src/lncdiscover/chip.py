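"""Strand-oriented ChIP read profiles and peak handling.

A uniquely-aligned ChIP read is reduced to (chromosome, 5' end, strand).
The binding-intensity profile counts, at every 25-bp grid position p, the
reads whose 5' end lies within ``flank`` bp of p and whose orientation
points toward p: forward reads at or left of p, reverse reads at or right
of p. Around a genuine binding event the forward and reverse read clusters
face each other, producing a plateau of doubly-counted grid positions
between them — the signal the profile statistic is built to expose.

Boundary conventions (all inclusive, symmetric and oracle-tested): a read
exactly at p counts for either strand, and |pos5 - p| == flank counts.
The grid is anchored at coordinate 0 (p = 0, resolution, 2*resolution, ...)
with the last grid point below the chromosome length.

Peak calling proper is an upstream responsibility (external peak files are
first-class input); :func:`naive_peak_call` is a deliberately simple
Poisson-background fallback so a synthetic pipeline can run end to end, and
its peaks are labelled ``naive``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import GenomeLayout, GenomicInterval, ValidationError


class ChipParseError(ValueError):
    """A BED line could not be parsed."""


@dataclass(frozen=True)
class ChipRead:
    """A uniquely-aligned read: chromosome, 5'-end position, strand."""

    chrom: str
    pos5: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"read strand must be + or -, got {self.strand!r}")
        if self.pos5 < 0:
            raise ValidationError(f"negative read position {self.pos5}")


@dataclass
class IntensityProfile:
    """Oriented read counts on a fixed grid along one chromosome.

    ``values[k]`` is the count at grid position ``k * resolution``.
    """

    chrom: str
    resolution: int
    flank: int
    values: np.ndarray
    chrom_length: int

    @property
    def grid_positions(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.resolution


@dataclass(frozen=True)
class Peak:
    """A binding-site interval with a score; source is external or naive."""

    interval: GenomicInterval
    score: float = 0.0
    source: str = "external"

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValidationError(f"negative peak score {self.score}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_chip_bed(path: str | Path) -> list[ChipRead]:
    """Read aligned reads from BED6; pos5 = start on +, end-1 on -."""
    reads: list[ChipRead] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise ChipParseError(f"{path}: line {i}: BED6 with strand required")
        strand = f[5]
        if strand not in ("+", "-"):
            raise ChipParseError(f"{path}: line {i}: missing strand (got {strand!r})")
        start, end = int(f[1]), int(f[2])
        pos5 = start if strand == "+" else end - 1
        reads.append(ChipRead(f[0], pos5, strand))
    return reads


def write_chip_bed(
    reads: Iterable[ChipRead], path: str | Path, read_length: int = 36
) -> None:
    """Write reads as BED6 so that read_chip_bed recovers the same pos5."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            if r.strand == "+":
                start, end = r.pos5, r.pos5 + read_length
            else:
                end = r.pos5 + 1
                start = max(0, end - read_length)
            fh.write(f"{r.chrom}\t{start}\t{end}\tr{i}\t0\t{r.strand}\n")


def read_peaks(path: str | Path) -> list[Peak]:
    """Read peak intervals from BED (>=3 columns; score from column 5)."""
    peaks: list[Peak] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise ChipParseError(f"{path}: line {i}: need >=3 BED columns")
        start, end = int(f[1]), int(f[2])
        if start >= end:
            raise ValidationError(f"{path}: line {i}: start {start} >= end {end}")
        score = float(f[4]) if len(f) >= 5 else 0.0
        peaks.append(Peak(GenomicInterval(f[0], start, end), score, "external"))
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED5 (name carries the source label)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{p.source}_{i}\t{p.score:.6g}\n"
            )


# ---------------------------------------------------------------------------
# profile
# ---------------------------------------------------------------------------


def binding_profile(
    reads: Sequence[ChipRead],
    layout: GenomeLayout,
    resolution: int = 25,
    flank: int = 100,
    dedup: bool = False,
) -> dict[str, IntensityProfile]:
    """Per-chromosome oriented binding-intensity profile.

    At grid position p the count is #{reads: |pos5 - p| <= flank and
    (strand + with pos5 <= p or strand - with pos5 >= p)}. Duplicate
    (chrom, pos5, strand) triples are kept unless ``dedup`` is set;
    unique-alignment filtering is an upstream responsibility.
    """
    if dedup:
        reads = list(dict.fromkeys(reads))
    by_chrom: dict[str, list[ChipRead]] = {}
    for r in reads:
        if r.chrom not in layout:
            raise ValidationError(f"read on unknown chromosome {r.chrom}")
        if r.pos5 >= layout[r.chrom]:
            raise ValidationError(
                f"read at {r.chrom}:{r.pos5} beyond chromosome end"
            )
        by_chrom.setdefault(r.chrom, []).append(r)

    profiles: dict[str, IntensityProfile] = {}
    for chrom in sorted(layout.chroms):
        length = layout[chrom]
        nbins = (length - 1) // resolution + 1
        values = np.zeros(nbins, dtype=np.int64)
        chrom_reads = by_chrom.get(chrom, [])
        if chrom_reads:
            pos = np.array([r.pos5 for r in chrom_reads], dtype=np.int64)
            fwd = np.array([r.strand == "+" for r in chrom_reads])
            # forward reads cover grid points in [pos5, pos5+flank],
            # reverse reads cover [pos5-flank, pos5]; bounds inclusive.
            lo = np.where(fwd, -(-pos // resolution), -(-(pos - flank) // resolution))
            hi = np.where(fwd, (pos + flank) // resolution, pos // resolution)
            lo = np.clip(lo, 0, nbins)
            hi = np.clip(hi, -1, nbins - 1)
            for off in range(flank // resolution + 1):
                idx = lo + off
                m = idx <= hi
                np.add.at(values, idx[m], 1)
        profiles[chrom] = IntensityProfile(chrom, resolution, flank, values, length)
    return profiles


def write_bedgraph(
    profiles: Mapping[str, IntensityProfile] | IntensityProfile,
    path: str | Path,
    merge: bool = False,
    track_header: bool = False,
) -> None:
    """Write profiles as bedGraph; zero bins omitted, sorted by position.

    With ``merge``, adjacent grid intervals carrying the same count are
    collapsed into one line.
    """
    if isinstance(profiles, IntensityProfile):
        profiles = {profiles.chrom: profiles}
    with open(path, "w") as fh:
        if track_header:
            fh.write("track type=bedGraph\n")
        for chrom in sorted(profiles):
            prof = profiles[chrom]
            res = prof.resolution
            run_start = None
            run_val = 0
            prev_end = None
            for k, v in enumerate(prof.values):
                start = k * res
                end = min(start + res, prof.chrom_length)
                if v == 0:
                    continue
                if (
                    merge
                    and run_start is not None
                    and v == run_val
                    and start == prev_end
                ):
                    prev_end = end
                    continue
                if run_start is not None:
                    fh.write(f"{chrom}\t{run_start}\t{prev_end}\t{run_val}\n")
                run_start, prev_end, run_val = start, end, int(v)
                if not merge:
                    fh.write(f"{chrom}\t{run_start}\t{prev_end}\t{run_val}\n")
                    run_start = None
            if merge and run_start is not None:
                fh.write(f"{chrom}\t{run_start}\t{prev_end}\t{run_val}\n")


# ---------------------------------------------------------------------------
# peak calling and overlap
# ---------------------------------------------------------------------------


def naive_peak_call(
    profile: IntensityProfile,
    p_cutoff: float = 0.05,
    min_run_bins: int = 2,
    correction: str = "bonferroni",
) -> list[Peak]:
    """Poisson-background fallback caller (labelled ``naive``).

    The background rate lambda is the mean grid count over the chromosome.
    A bin with count c is significant when the upper Poisson tail
    P(X >= c; lambda) falls below the per-bin threshold — by default the
    genome-wide (Bonferroni) threshold ``p_cutoff / n_bins``, so that a
    uniform background does not generate calls; ``correction="none"`` tests
    each bin at ``p_cutoff`` directly. Runs of at least ``min_run_bins``
    consecutive significant bins merge into one peak scored by the maximum
    bin count.
    """
    values = profile.values
    n = len(values)
    if n == 0:
        raise ValidationError("empty profile")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    lam = float(values.mean())
    alpha = p_cutoff / n if correction == "bonferroni" else p_cutoff
    sig = stats.poisson.sf(values - 1, lam) < alpha

    peaks: list[Peak] = []
    res = profile.resolution
    i = 0
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1]:
            j += 1
        if j - i + 1 >= min_run_bins:
            interval = GenomicInterval(
                profile.chrom, i * res, min((j + 1) * res, profile.chrom_length)
            )
            peaks.append(Peak(interval, float(values[i : j + 1].max()), "naive"))
        i = j + 1
    return peaks


def peaks_overlapping(peaks: Iterable[Peak], window: GenomicInterval) -> list[Peak]:
    """Peaks overlapping the window by >=1 bp (half-open semantics)."""
    return [p for p in peaks if p.interval.overlaps(window)]
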