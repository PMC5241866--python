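"""Integration of annotation, expression, and binding evidence.

Combines the non-coding transcript set, the expression gate, the
differential-expression calls and the promoter-window peak assignments into
per-transcript candidate calls and a diffable report: a transcript is a
candidate when it is expressed, differentially expressed, has at least one
peak in its promoter window, and (when a tissue panel was supplied) is
tissue-restricted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import math

from intervaltree import IntervalTree

from .annotation import (
    GenomeLayout,
    TranscriptModel,
    promoter_window,
)
from .chip import Peak
from .expression import DECall


@dataclass
class CandidateCall:
    """Per-transcript record of every screening axis plus the final flag."""

    transcript_id: str
    expressed: bool
    de_direction: str  # up, down, none
    log2_fc: float  # nan when no DE call was made for this transcript
    tf_bound: bool
    n_peaks_in_window: int
    tissue_restricted: bool | None
    candidate: bool


def classify_tf_regulated(
    transcripts: Sequence[TranscriptModel],
    peaks: Sequence[Peak],
    layout: GenomeLayout,
    upstream: int = 5000,
    downstream: int = 500,
    tss_mode: str = "strand_aware",
    by_gene: bool = False,
) -> dict[str, tuple[bool, int]]:
    """Map transcript_id -> (tf_bound, n_peaks_in_window).

    A transcript is TF-regulated when at least one peak overlaps its
    promoter window (upstream..downstream of the TSS, strand aware). With
    ``by_gene``, transcripts sharing a gene symbol pool their windows: each
    member reports the number of distinct peaks overlapping the union of
    the gene's windows.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, p in enumerate(peaks):
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, idx
        )

    def window_hits(t: TranscriptModel) -> set[int]:
        w = promoter_window(t, layout, upstream, downstream, tss_mode)
        tree = trees.get(w.chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(w.start, w.end)}

    if not by_gene:
        out: dict[str, tuple[bool, int]] = {}
        for t in transcripts:
            hits = window_hits(t)
            out[t.transcript_id] = (len(hits) >= 1, len(hits))
        return out

    groups: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        key = t.gene if t.gene is not None else t.transcript_id
        groups.setdefault(key, []).append(t)
    out = {}
    for members in groups.values():
        hits: set[int] = set()
        for t in members:
            hits |= window_hits(t)
        for t in members:
            out[t.transcript_id] = (len(hits) >= 1, len(hits))
    return out


@dataclass
class IntersectionSummary:
    """DE set x TF-bound set overlap."""

    n_de: int
    n_de_and_bound: int
    ids: list[str]


def intersect_de_with_bound(
    de_calls: Sequence[DECall], bound: Mapping[str, tuple[bool, int]]
) -> IntersectionSummary:
    """Count differentially expressed transcripts that are also TF-bound.

    DE transcripts missing from the bound mapping trigger a warning and are
    treated as unbound, so partial inputs still run.
    """
    de_ids = [c.transcript_id for c in de_calls if c.direction != "none"]
    missing = [tid for tid in de_ids if tid not in bound]
    if missing:
        warnings.warn(
            f"{len(missing)} DE transcript(s) absent from bound mapping; "
            "treated as unbound",
            stacklevel=2,
        )
    hit = sorted(tid for tid in de_ids if bound.get(tid, (False, 0))[0])
    return IntersectionSummary(len(de_ids), len(hit), hit)


def _sort_key(call: CandidateCall) -> tuple[float, str]:
    mag = abs(call.log2_fc)
    if math.isnan(mag):
        mag = -1.0  # rows without a DE call sort last
    return (-mag, call.transcript_id)


def candidate_report(
    transcripts: Sequence[TranscriptModel],
    gate_ids: Sequence[str],
    de_calls: Sequence[DECall],
    bound: Mapping[str, tuple[bool, int]],
    restriction: Mapping[str, bool] | None = None,
    layout: GenomeLayout | None = None,
    upstream: int = 5000,
    downstream: int = 500,
    tss_mode: str = "strand_aware",
    path: str | Path | None = None,
) -> list[CandidateCall]:
    """Assemble candidate calls, optionally writing the report TSV.

    Rows are sorted by |log2 fold change| descending with +/-inf first and
    ties broken by transcript id, making reports byte-diffable.
    """
    gate = set(gate_ids)
    de_map = {c.transcript_id: c for c in de_calls}
    calls: list[CandidateCall] = []
    for t in transcripts:
        tid = t.transcript_id
        expressed = tid in gate
        de = de_map.get(tid)
        direction = de.direction if de is not None else "none"
        lfc = de.log2_fc if de is not None else float("nan")
        tf_bound, n_peaks = bound.get(tid, (False, 0))
        restricted = None if restriction is None else bool(restriction.get(tid, False))
        candidate = (
            expressed
            and direction != "none"
            and tf_bound
            and (restricted is None or restricted)
        )
        calls.append(
            CandidateCall(tid, expressed, direction, lfc, tf_bound, n_peaks,
                          restricted, candidate)
        )
    calls.sort(key=_sort_key)
    if path is not None:
        if layout is None:
            raise ValueError("layout is required to write the report")
        write_report(calls, transcripts, layout, path, upstream, downstream, tss_mode)
    return calls


_REPORT_COLUMNS = [
    "transcript_id", "chrom", "strand", "tss", "window_start", "window_end",
    "expressed", "log2_fc", "de_direction", "n_peaks_in_window", "tf_bound",
    "tissue_restricted", "candidate",
]


def _fmt_bool(v: bool | None) -> str:
    return "NA" if v is None else ("true" if v else "false")


def _fmt_float(v: float) -> str:
    if math.isnan(v):
        return "NA"
    return f"{v:.6g}"


def write_report(
    calls: Sequence[CandidateCall],
    transcripts: Sequence[TranscriptModel],
    layout: GenomeLayout,
    path: str | Path,
    upstream: int = 5000,
    downstream: int = 500,
    tss_mode: str = "strand_aware",
) -> None:
    """Write the candidate report TSV (columns fixed, floats %.6g)."""
    tx = {t.transcript_id: t for t in transcripts}
    with open(path, "w") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for c in calls:
            t = tx[c.transcript_id]
            w = promoter_window(t, layout, upstream, downstream, tss_mode)
            fh.write(
                "\t".join(
                    [
                        c.transcript_id,
                        t.chrom,
                        t.strand,
                        str(t.tss if tss_mode == "strand_aware" else t.tx_start),
                        str(w.start),
                        str(w.end),
                        _fmt_bool(c.expressed),
                        _fmt_float(c.log2_fc),
                        c.de_direction,
                        str(c.n_peaks_in_window),
                        _fmt_bool(c.tf_bound),
                        _fmt_bool(c.tissue_restricted),
                        _fmt_bool(c.candidate),
                    ]
                )
                + "\n"
            )


def read_report(path: str | Path) -> list[CandidateCall]:
    """Read back a report TSV written by :func:`write_report`."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    idx = {name: i for i, name in enumerate(header)}
    calls = []
    for line in lines[1:]:
        f = line.split("\t")
        restricted_raw = f[idx["tissue_restricted"]]
        calls.append(
            CandidateCall(
                transcript_id=f[idx["transcript_id"]],
                expressed=f[idx["expressed"]] == "true",
                de_direction=f[idx["de_direction"]],
                log2_fc=float("nan") if f[idx["log2_fc"]] == "NA" else float(f[idx["log2_fc"]]),
                tf_bound=f[idx["tf_bound"]] == "true",
                n_peaks_in_window=int(f[idx["n_peaks_in_window"]]),
                tissue_restricted=None if restricted_raw == "NA" else restricted_raw == "true",
                candidate=f[idx["candidate"]] == "true",
            )
        )
    return calls


def write_summary(summary: Mapping, path: str | Path) -> None:
    """Write the run-summary JSON deterministically (sorted keys)."""
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
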