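"""Synthetic genomes, expression time courses, ChIP reads and tissue panels
with planted, machine-readable ground truth.

Every generator is a pure function of its parameters and seed. The planted
signals mirror the structure the discovery pipeline is built to detect:

* a minority of non-coding transcripts differentially expressed at a known
  fold between the first and second half of the time course;
* ChIP read pileups with a forward cluster upstream and a reverse cluster
  downstream of a planted summit inside the promoter window of designated
  TF-bound transcripts, over a uniform strand-random background;
* a tissue panel in which designated transcripts are expressed in the
  target tissue only.

Signals are planted on non-coding transcripts, since the discovery screen
operates on those; bound hosts are preferentially drawn from the planted-DE
set (``enriched_frac``) to emulate TF-driven regulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GenomeLayout, TranscriptModel, exonic_length, promoter_window
from .chip import ChipRead
from .expression import ExpressionMatrix
from .integration import CandidateCall


class SimulationError(ValueError):
    """Infeasible simulation parameters."""


# margin kept free of transcripts at each chromosome end, so promoter
# windows are never truncated; minimum intergenic gap large enough that a
# promoter window can never reach a neighbouring transcript's planted site.
_EDGE_MARGIN = 6000
_MIN_INTERGENIC = 6200

_TISSUES = [
    "muscle", "heart", "liver", "brain", "lung", "kidney", "spleen", "intestine",
]


@dataclass
class SimTruth:
    """Planted ground truth plus an echo of all simulation parameters."""

    seed: int
    de: dict[str, dict] = field(default_factory=dict)  # id -> {direction, fold}
    bound: dict[str, int] = field(default_factory=dict)  # id -> summit
    restricted: list[str] | None = None
    params: dict = field(default_factory=dict)

    def candidate_ids(self) -> set[str]:
        """Transcripts planted on every simulated axis."""
        ids = set(self.de) & set(self.bound)
        if self.restricted is not None:
            ids &= set(self.restricted)
        return ids

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "de": self.de,
            "bound": self.bound,
            "restricted": self.restricted,
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            seed=payload["seed"],
            de=payload["de"],
            bound=payload["bound"],
            restricted=payload["restricted"],
            params=payload.get("params", {}),
        )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def simulate_genome(
    n_chroms: int = 2,
    chrom_len: int = 1_000_000,
    n_transcripts: int = 200,
    frac_noncoding: float = 0.5,
    exons_per_tx: tuple[int, int] = (1, 4),
    seed: int = 0,
) -> tuple[list[TranscriptModel], GenomeLayout, SimTruth]:
    """Random non-overlapping transcripts on random strands.

    Transcript accessions are NR_%06d / NM_%06d according to a Bernoulli
    coding flag at ``frac_noncoding``. Transcripts keep a 6-kb margin from
    chromosome ends and a minimum intergenic gap so promoter windows are
    never truncated and never reach a neighbour's planted site.
    """
    if min(n_chroms, chrom_len, n_transcripts) <= 0:
        raise SimulationError("n_chroms, chrom_len, n_transcripts must be positive")
    rng = np.random.default_rng(seed)
    per_chrom = [
        n_transcripts // n_chroms + (1 if c < n_transcripts % n_chroms else 0)
        for c in range(n_chroms)
    ]
    transcripts: list[TranscriptModel] = []
    layout = GenomeLayout({f"chr{c + 1}": chrom_len for c in range(n_chroms)})
    counter = 0
    for c, k in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        if k == 0:
            continue
        lens = rng.integers(500, 2501, size=k)
        needed = 2 * _EDGE_MARGIN + int(lens.sum()) + (k - 1) * _MIN_INTERGENIC
        if needed > chrom_len:
            raise SimulationError(
                f"{k} transcripts do not fit on {chrom} (need {needed} bp, "
                f"have {chrom_len}); increase chrom_len or reduce n_transcripts"
            )
        w = rng.random(k + 1)
        extra = np.floor(w / w.sum() * (chrom_len - needed)).astype(int)
        pos = _EDGE_MARGIN
        for i in range(k):
            pos += int(extra[i])
            start, end = pos, pos + int(lens[i])
            strand = "+" if rng.random() < 0.5 else "-"
            coding = rng.random() >= frac_noncoding
            exons = _random_exons(rng, start, end, exons_per_tx)
            prefix = "NM" if coding else "NR"
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{prefix}_{counter:06d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    exons=exons,
                    coding=coding,
                )
            )
            counter += 1
            pos = end + _MIN_INTERGENIC
    truth = SimTruth(
        seed=seed,
        params={
            "n_chroms": n_chroms,
            "chrom_len": chrom_len,
            "n_transcripts": n_transcripts,
            "frac_noncoding": frac_noncoding,
            "exons_per_tx": list(exons_per_tx),
        },
    )
    return transcripts, layout, truth


def _random_exons(
    rng: np.random.Generator, start: int, end: int, exons_per_tx: tuple[int, int]
) -> tuple[tuple[int, int], ...]:
    n_ex = int(rng.integers(exons_per_tx[0], exons_per_tx[1] + 1))
    span = end - start
    if n_ex <= 1 or span < 20 * (2 * n_ex - 1):
        return ((start, end),)
    # alternate exon/intron segments, first and last are exons
    w = rng.random(2 * n_ex - 1) + 0.2
    seg = np.floor(w / w.sum() * span).astype(int)
    seg = np.maximum(seg, 1)
    seg[-1] = span - int(seg[:-1].sum())
    if seg[-1] < 1:
        return ((start, end),)
    bounds = start + np.concatenate([[0], np.cumsum(seg)])
    return tuple(
        (int(bounds[i]), int(bounds[i + 1])) for i in range(0, 2 * n_ex - 1, 2)
    )


# ---------------------------------------------------------------------------
# expression time course
# ---------------------------------------------------------------------------

_TIMEPOINT_NAMES = ["h0", "h60", "d5", "d7"]


def simulate_expression(
    transcripts: Sequence[TranscriptModel],
    n_timepoints: int = 4,
    depth: int = 1_000_000,
    nb_dispersion: float = 0.1,
    de_frac: float = 0.15,
    fold: float = 4.0,
    seed: int = 0,
    baseline_sigma: float = 1.0,
    min_de_mean: float = 100.0,
) -> tuple[ExpressionMatrix, dict[str, dict]]:
    """Negative-binomial counts over a differentiation-style time course.

    Baseline means are log-normal, normalized to ``depth`` expected reads
    per sample. Planted-DE transcripts (non-coding hosts, split evenly
    between up and down) have the second half of the time points multiplied
    by ``fold`` (up) or 1/``fold`` (down); their baselines are floored at
    ``min_de_mean`` expected counts so planted signal is detectable above
    the expression gate. Library sizes are the realized column sums.
    """
    if n_timepoints < 2:
        raise SimulationError("need at least 2 time points")
    rng = np.random.default_rng(seed)
    ids = [t.transcript_id for t in transcripts]
    noncoding = [t.transcript_id for t in transcripts if not t.coding]
    n_de = round(de_frac * len(transcripts))
    if n_de > len(noncoding):
        raise SimulationError(
            f"cannot plant {n_de} DE transcripts among {len(noncoding)} non-coding"
        )
    de_hosts = [str(x) for x in rng.choice(noncoding, size=n_de, replace=False)]
    n_up = (n_de + 1) // 2
    de_truth = {
        tid: {"direction": "up" if i < n_up else "down", "fold": float(fold)}
        for i, tid in enumerate(de_hosts)
    }

    w = rng.lognormal(0.0, baseline_sigma, size=len(ids))
    base = depth * w / w.sum()
    pos = {tid: i for i, tid in enumerate(ids)}
    for tid in de_hosts:
        base[pos[tid]] = max(base[pos[tid]], min_de_mean)

    means = np.tile(base[:, None], (1, n_timepoints)).astype(float)
    half = n_timepoints // 2
    for tid, rec in de_truth.items():
        i = pos[tid]
        factor = rec["fold"] if rec["direction"] == "up" else 1.0 / rec["fold"]
        means[i, n_timepoints - half :] *= factor

    if nb_dispersion < 1e-8:
        counts = rng.poisson(means)
    else:
        n_param = 1.0 / nb_dispersion
        p_param = n_param / (n_param + means)
        counts = rng.negative_binomial(n_param, p_param)
    counts = counts.astype(np.int64)

    if n_timepoints == 4:
        samples = list(_TIMEPOINT_NAMES)
    else:
        samples = [f"tp{i}" for i in range(n_timepoints)]
    lengths = np.array([exonic_length(t) for t in transcripts], dtype=float)
    libs = np.maximum(counts.sum(axis=0), 1).astype(float)
    matrix = ExpressionMatrix(ids, samples, counts, libs, lengths)
    return matrix, de_truth


# ---------------------------------------------------------------------------
# ChIP reads
# ---------------------------------------------------------------------------


def simulate_chip(
    transcripts: Sequence[TranscriptModel],
    layout: GenomeLayout,
    bound_frac: float = 0.1,
    reads_per_site: int = 60,
    shift: int = 75,
    pos_sd: float = 15.0,
    background_per_kb: float = 1.0,
    seed: int = 0,
    enriched_ids: Sequence[str] | None = None,
    enriched_frac: float = 0.5,
    upstream: int = 5000,
    downstream: int = 500,
) -> tuple[list[ChipRead], dict[str, int]]:
    """ChIP reads with strand-shifted clusters planted at promoter summits.

    Each planted site gets ``reads_per_site/2`` forward reads at
    Normal(summit - shift, pos_sd) and as many reverse reads at
    Normal(summit + shift, pos_sd), over a uniform strand-random background
    of ``background_per_kb`` reads per kb per chromosome. Bound hosts are
    non-coding transcripts; when ``enriched_ids`` is given, a fraction
    ``enriched_frac`` of hosts is drawn from it (TF-driven regulation).
    """
    rng = np.random.default_rng(seed)
    eligible = [t for t in transcripts if not t.coding]
    n_bound = round(bound_frac * len(transcripts))
    if n_bound > len(eligible):
        raise SimulationError(
            f"cannot plant {n_bound} bound sites among {len(eligible)} non-coding"
        )
    by_id = {t.transcript_id: t for t in eligible}
    hosts: list[str] = []
    if enriched_ids:
        pool = [tid for tid in enriched_ids if tid in by_id]
        n_enr = min(round(enriched_frac * n_bound), len(pool))
        if n_enr > 0:
            hosts.extend(str(x) for x in rng.choice(pool, size=n_enr, replace=False))
    rest_pool = [t.transcript_id for t in eligible if t.transcript_id not in hosts]
    n_rest = n_bound - len(hosts)
    if n_rest > 0:
        hosts.extend(str(x) for x in rng.choice(rest_pool, size=n_rest, replace=False))

    clearance = shift + 4.0 * pos_sd
    reads: list[ChipRead] = []
    bound_truth: dict[str, int] = {}
    for tid in hosts:
        t = by_id[tid]
        # summit offset along the direction of transcription, mostly just
        # upstream of the TSS (negative = upstream)
        off = int(rng.integers(-700, 301))
        summit = t.tss + off if t.strand == "+" else t.tss - off
        window = promoter_window(t, layout, upstream, downstream)
        if not (window.start <= summit - clearance and summit + clearance <= window.end):
            raise SimulationError(
                f"{tid}: planted summit {summit} +/- {clearance:.0f} does not fit "
                f"window {window.start}-{window.end}"
            )
        bound_truth[tid] = summit
        n_fwd = reads_per_site // 2
        n_rev = reads_per_site - n_fwd
        length = layout[t.chrom]
        fwd = np.clip(
            np.rint(rng.normal(summit - shift, pos_sd, size=n_fwd)), 0, length - 1
        ).astype(int)
        rev = np.clip(
            np.rint(rng.normal(summit + shift, pos_sd, size=n_rev)), 0, length - 1
        ).astype(int)
        reads.extend(ChipRead(t.chrom, int(p), "+") for p in fwd)
        reads.extend(ChipRead(t.chrom, int(p), "-") for p in rev)

    for chrom in sorted(layout.chroms):
        length = layout[chrom]
        n_bg = round(background_per_kb * length / 1000)
        pos = rng.integers(0, length, size=n_bg)
        strands = rng.random(n_bg) < 0.5
        reads.extend(
            ChipRead(chrom, int(p), "+" if s else "-") for p, s in zip(pos, strands)
        )
    return reads, bound_truth


# ---------------------------------------------------------------------------
# tissue panel
# ---------------------------------------------------------------------------


def simulate_tissue_matrix(
    transcripts: Sequence[TranscriptModel],
    n_tissues: int = 8,
    restricted_frac: float = 0.05,
    on_level: float = 10.0,
    off_level: float = 0.1,
    noise_sigma: float = 0.25,
    seed: int = 0,
    enriched_ids: Sequence[str] | None = None,
    enriched_frac: float = 0.5,
) -> tuple[pd.DataFrame, list[str]]:
    """Tissue x transcript RPKM panel with planted restricted transcripts.

    Restricted hosts (non-coding) sit at ``on_level`` in the first (target)
    tissue and ``off_level`` elsewhere; all other transcripts have one
    uniform level across tissues. Multiplicative log-normal noise with
    ``noise_sigma`` (0 = noiseless) is applied cell-wise. As in
    :func:`simulate_chip`, ``enriched_ids`` biases host selection so the
    restricted set overlaps other planted axes the way a tissue-specific,
    TF-driven transcript population would.
    """
    if n_tissues < 2:
        raise SimulationError("need at least 2 tissues")
    rng = np.random.default_rng(seed)
    tissues = (_TISSUES + [f"tissue{i}" for i in range(len(_TISSUES), n_tissues)])[
        :n_tissues
    ]
    ids = [t.transcript_id for t in transcripts]
    noncoding = [t.transcript_id for t in transcripts if not t.coding]
    n_res = round(restricted_frac * len(transcripts))
    if n_res > len(noncoding):
        raise SimulationError("not enough non-coding transcripts to restrict")
    hosts: list[str] = []
    nc_set = set(noncoding)
    if enriched_ids:
        pool = [tid for tid in enriched_ids if tid in nc_set]
        n_enr = min(round(enriched_frac * n_res), len(pool))
        if n_enr > 0:
            hosts.extend(str(x) for x in rng.choice(pool, size=n_enr, replace=False))
    rest_pool = [tid for tid in noncoding if tid not in hosts]
    if n_res > len(hosts):
        hosts.extend(
            str(x)
            for x in rng.choice(rest_pool, size=n_res - len(hosts), replace=False)
        )
    restricted = sorted(hosts)
    res_set = set(restricted)
    base = rng.lognormal(1.0, 1.0, size=len(ids))
    vals = np.empty((len(ids), n_tissues))
    for i, tid in enumerate(ids):
        if tid in res_set:
            vals[i] = off_level
            vals[i, 0] = on_level
        else:
            vals[i] = base[i]
    if noise_sigma > 0:
        vals = vals * rng.lognormal(0.0, noise_sigma, size=vals.shape)
    table = pd.DataFrame(
        vals, index=pd.Index(ids, name="transcript_id"), columns=tissues
    )
    return table, restricted


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------


@dataclass
class RecoveryMetrics:
    precision: float
    recall: float
    f1: float
    n_called: int
    n_truth: int
    n_hit: int


def evaluate_recovery(
    calls: Sequence[CandidateCall], truth: SimTruth
) -> RecoveryMetrics:
    """Precision/recall/F1 of final candidates against the planted truth.

    Truth is the planted de AND bound set, further intersected with the
    restricted set when a tissue panel was simulated. With no calls there
    are no false positives, so precision is vacuously 1 (in particular 1
    when both sets are empty); recall is 1 when the truth set is empty.
    """
    called = {c.transcript_id for c in calls if c.candidate}
    true_set = truth.candidate_ids()
    tp = len(called & true_set)
    precision = tp / len(called) if called else 1.0
    recall = tp / len(true_set) if true_set else 1.0
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return RecoveryMetrics(precision, recall, f1, len(called), len(true_set), tp)


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic stream of n sub-seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]
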