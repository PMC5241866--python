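"""Transcript annotation: models, promoter windows, and BED12/refFlat I/O.

All coordinates are 0-based half-open (the BED convention). refFlat files
already store txStart/txEnd and exon lists 0-based half-open, so both
dialects land on the same internal representation.

Coding status is derived purely from the RefSeq accession prefix: a
transcript is non-coding iff its accession starts with ``NR_``. No ORF
scanning is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence


class AnnotationParseError(ValueError):
    """A line of an annotation file could not be parsed."""


class ValidationError(ValueError):
    """A record violates a structural invariant."""


class EmptyWindowError(ValidationError):
    """A promoter window lies entirely outside its chromosome."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 bp overlap under half-open semantics."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome name -> length in bp."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValidationError(f"chromosome {chrom} has length {length}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column chrom.sizes file (name, length)."""
        lengths: dict[str, int] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise AnnotationParseError(f"{path}: line {i}: expected 2 columns")
            try:
                lengths[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}: line {i}: bad length {fields[1]!r}"
                ) from exc
        return cls(lengths)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self.lengths.items():
                fh.write(f"{chrom}\t{length}\n")


@dataclass(frozen=True)
class TranscriptModel:
    """One annotated transcript with exon structure.

    ``coding`` is False exactly for NR_-prefixed accessions. ``gene`` holds
    the gene symbol when the source dialect provides one (refFlat).
    """

    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    coding: bool
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.transcript_id}: strand must be + or -, got {self.strand!r}"
            )
        if not 0 <= self.tx_start < self.tx_end:
            raise ValidationError(
                f"{self.transcript_id}: invalid span {self.tx_start}-{self.tx_end}"
            )
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValidationError(
                    f"{self.transcript_id}: empty exon ({start},{end})"
                )
            if start < self.tx_start or end > self.tx_end:
                raise ValidationError(
                    f"{self.transcript_id}: exon ({start},{end}) outside "
                    f"transcript span {self.tx_start}-{self.tx_end}"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons unsorted or overlapping"
                )
            prev_end = end

    @property
    def tss(self) -> int:
        """Strand-aware start site: tx_start on +, tx_end on -."""
        return self.tx_start if self.strand == "+" else self.tx_end


def exonic_length(t: TranscriptModel) -> int:
    """Summed exon length in bp (the 'kilobase of transcript' in RPKM)."""
    return sum(end - start for start, end in t.exons)


def exonic_length_map(transcripts: Iterable[TranscriptModel]) -> dict[str, int]:
    """transcript_id -> exonic length, for building expression matrices."""
    return {t.transcript_id: exonic_length(t) for t in transcripts}


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(_SKIP_PREFIXES):
            continue
        yield i, line.rstrip("\n")


def _int_list(field: str) -> list[int]:
    return [int(x) for x in field.rstrip(",").split(",")]


def _parse_bed12(line: str) -> TranscriptModel:
    f = line.split("\t")
    if len(f) < 12:
        raise AnnotationParseError(f"expected 12 BED columns, got {len(f)}")
    chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
    block_count = int(f[9])
    sizes = _int_list(f[10])
    starts = _int_list(f[11])
    if len(sizes) != block_count or len(starts) != block_count:
        raise AnnotationParseError(
            f"blockCount {block_count} does not match block lists"
        )
    exons = tuple((start + s, start + s + sz) for s, sz in zip(starts, sizes))
    return TranscriptModel(
        transcript_id=name,
        chrom=chrom,
        strand=strand,
        tx_start=start,
        tx_end=end,
        exons=exons,
        coding=not name.startswith("NR_"),
    )


def _parse_refflat(line: str) -> TranscriptModel:
    f = line.split("\t")
    if len(f) < 11:
        raise AnnotationParseError(f"expected 11 refFlat columns, got {len(f)}")
    gene, name, chrom, strand = f[0], f[1], f[2], f[3]
    tx_start, tx_end = int(f[4]), int(f[5])
    exon_count = int(f[8])
    starts = _int_list(f[9])
    ends = _int_list(f[10])
    if len(starts) != exon_count or len(ends) != exon_count:
        raise AnnotationParseError(f"exonCount {exon_count} does not match lists")
    return TranscriptModel(
        transcript_id=name,
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        exons=tuple(zip(starts, ends)),
        coding=not name.startswith("NR_"),
        gene=gene,
    )


_DIALECTS = {"bed12": _parse_bed12, "refflat": _parse_refflat}


def read_annotation(path: str | Path, dialect: str = "bed12") -> list[TranscriptModel]:
    """Parse a transcript annotation file.

    Parameters
    ----------
    path:
        BED12 or refFlat-style tab-delimited file.
    dialect:
        ``"bed12"`` or ``"refflat"``.
    """
    try:
        parse = _DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}") from None
    out: list[TranscriptModel] = []
    for lineno, line in _data_lines(path):
        try:
            out.append(parse(line))
        except (AnnotationParseError, ValidationError, ValueError) as exc:
            kind = AnnotationParseError if not isinstance(exc, ValidationError) else ValidationError
            raise kind(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_annotation(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as BED12. read_annotation round-trips bit-exactly."""
    with open(path, "w") as fh:
        for t in transcripts:
            sizes = ",".join(str(e - s) for s, e in t.exons)
            starts = ",".join(str(s - t.tx_start) for s, _e in t.exons)
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(t.tx_start),
                        str(t.tx_end),
                        t.transcript_id,
                        "0",
                        t.strand,
                        str(t.tx_start),
                        str(t.tx_start),
                        "0",
                        str(len(t.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def filter_noncoding(transcripts: Sequence[TranscriptModel]) -> list[TranscriptModel]:
    """Keep only non-coding (NR_) transcripts, order preserved."""
    return [t for t in transcripts if not t.coding]


# ---------------------------------------------------------------------------
# promoter windows
# ---------------------------------------------------------------------------


def promoter_window(
    t: TranscriptModel,
    layout: GenomeLayout,
    upstream: int = 5000,
    downstream: int = 500,
    tss_mode: str = "strand_aware",
) -> GenomicInterval:
    """Strand-aware promoter window around the transcription start site.

    On the + strand the window is [tx_start - upstream, tx_start + downstream);
    on the - strand, [tx_end - downstream, tx_end + upstream). The window is
    clipped to the chromosome; a window clipped to zero length raises
    :class:`EmptyWindowError`.

    ``tss_mode="tx_start"`` anchors at the annotation txStart regardless of
    strand (the alternative reading of "relative to its start site").
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be non-negative")
    if upstream == 0 and downstream == 0:
        raise ValueError("upstream and downstream cannot both be zero")
    if t.chrom not in layout:
        raise ValidationError(f"{t.transcript_id}: chromosome {t.chrom} not in layout")
    if tss_mode == "tx_start":
        lo, hi = t.tx_start - upstream, t.tx_start + downstream
    elif tss_mode == "strand_aware":
        if t.strand == "+":
            lo, hi = t.tx_start - upstream, t.tx_start + downstream
        else:
            lo, hi = t.tx_end - downstream, t.tx_end + upstream
    else:
        raise ValueError(f"unknown tss_mode {tss_mode!r}")
    chrom_len = layout[t.chrom]
    lo, hi = max(lo, 0), min(hi, chrom_len)
    if lo >= hi:
        raise EmptyWindowError(
            f"{t.transcript_id}: promoter window empty after clipping"
        )
    return GenomicInterval(t.chrom, lo, hi)


def write_windows_bed6(
    transcripts: Iterable[TranscriptModel],
    layout: GenomeLayout,
    path: str | Path,
    upstream: int = 5000,
    downstream: int = 500,
    tss_mode: str = "strand_aware",
) -> None:
    """Write promoter windows as BED6 (name=transcript_id, score=0)."""
    with open(path, "w") as fh:
        for t in transcripts:
            w = promoter_window(t, layout, upstream, downstream, tss_mode)
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{t.transcript_id}\t0\t{t.strand}\n"
            )
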