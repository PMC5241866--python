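"""Expression quantification and screening.

RPKM quantification from raw counts, the summed-RPKM expression gate,
fold-change differential-expression calls (with an exact two-sided binomial
test as the optional significance stand-in), preprocessing plus
average-linkage hierarchical clustering of time-course profiles, and a
tissue-restriction filter.

Conventions that matter downstream:

* RPKM = counts * 1e9 / (exonic length in bp * library size).
* The expression gate is a *strict* inequality: a transcript whose RPKM
  summed over samples equals the threshold exactly is dropped.
* log2 fold change uses no pseudocount; zero versus positive expression
  yields +/-inf and counts as exceeding any fold threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ExpressionError(ValueError):
    """Invalid expression-matrix input or arguments."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Transcripts x samples raw counts with library sizes and lengths."""

    transcript_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (T, S) non-negative integers
    library_sizes: np.ndarray  # (S,) total mapped reads per sample
    lengths: np.ndarray  # (T,) exonic length in bp

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.counts.shape != (len(self.transcript_ids), len(self.sample_ids)):
            raise ExpressionError("counts shape does not match id lists")
        if (self.counts < 0).any():
            raise ExpressionError("counts must be non-negative")
        if self.library_sizes.shape != (len(self.sample_ids),) or (
            self.library_sizes <= 0
        ).any():
            raise ExpressionError("library sizes must be positive, one per sample")
        if self.lengths.shape != (len(self.transcript_ids),) or (
            self.lengths <= 0
        ).any():
            raise ExpressionError("lengths must be positive, one per transcript")

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        lengths: Mapping[str, int],
        library_sizes: Mapping[str, float] | None = None,
    ) -> "ExpressionMatrix":
        """Build from a counts table (index=transcript, columns=samples).

        Library sizes default to column sums of the full table.
        """
        ids = list(counts.index)
        samples = list(counts.columns)
        mat = counts.to_numpy()
        if library_sizes is None:
            libs = mat.sum(axis=0).astype(float)
        else:
            libs = np.array([library_sizes[s] for s in samples], dtype=float)
        lens = np.array([lengths[i] for i in ids], dtype=float)
        return cls(ids, samples, mat, libs, lens)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        lengths: Mapping[str, int],
        library_sizes: Mapping[str, float] | None = None,
    ) -> "ExpressionMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_counts(counts, lengths, library_sizes)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.counts, index=pd.Index(self.transcript_ids, name="transcript_id"),
            columns=self.sample_ids,
        )
        df.to_csv(path, sep="\t")

    def subset(self, ids: Sequence[str]) -> "ExpressionMatrix":
        """Row subset, keeping the original library sizes."""
        index = {tid: i for i, tid in enumerate(self.transcript_ids)}
        rows = [index[i] for i in ids]
        return ExpressionMatrix(
            list(ids),
            self.sample_ids,
            self.counts[rows],
            self.library_sizes,
            self.lengths[rows],
        )


@dataclass
class DECall:
    """Differential-expression call for one transcript (condition A vs B)."""

    transcript_id: str
    mean_a: float
    mean_b: float
    log2_fc: float  # log2(mean_a / mean_b); +/-inf allowed
    direction: str  # up, down, none
    p_value: float | None = None


@dataclass
class ClusterTree:
    """Agglomerative clustering result.

    ``merges`` lists (node_i, node_j, height) in merge order using the usual
    cluster numbering: leaves are 0..n-1 and the t-th merge creates node n+t.
    ``leaf_order`` is the dendrogram leaf permutation (left-before-right),
    given as row labels.
    """

    merges: list[tuple[int, int, float]]
    leaf_order: list

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_i\tnode_j\theight\n")
            for i, j, h in self.merges:
                fh.write(f"{i}\t{j}\t{h:.6g}\n")
            fh.write("# leaf_order\t" + "\t".join(str(x) for x in self.leaf_order) + "\n")


# ---------------------------------------------------------------------------
# quantification and gating
# ---------------------------------------------------------------------------


def rpkm(m: ExpressionMatrix) -> pd.DataFrame:
    """Reads per kilobase of exonic transcript per million mapped reads."""
    vals = m.counts * 1e9 / (m.lengths[:, None] * m.library_sizes[None, :])
    return pd.DataFrame(
        vals, index=pd.Index(m.transcript_ids, name="transcript_id"),
        columns=m.sample_ids,
    )


def expressed_gate(rpkm_table: pd.DataFrame, min_summed: float = 1.0) -> list[str]:
    """Transcripts whose RPKM summed over samples strictly exceeds the cut."""
    sums = rpkm_table.sum(axis=1)
    return list(rpkm_table.index[sums > min_summed])


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def _binom_two_sided(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p: total mass of outcomes no more likely
    than the observed one (the 'minlike' convention)."""
    if n == 0:
        return 1.0
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    return float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-10)].sum()))


def de_call(
    m: ExpressionMatrix,
    cond_a: Sequence[str],
    cond_b: Sequence[str],
    fold_threshold: float = 2.0,
    test: str = "none",
) -> list[DECall]:
    """Fold-change differential expression between two sample sets.

    ``mean_a``/``mean_b`` are mean RPKM over each condition. log2 fold change
    conventions: both means zero -> 0 (direction none); exactly one zero ->
    +/-inf, which exceeds any threshold. With ``test="binomial"`` an exact
    two-sided binomial p-value is attached: pooled count k_a out of k_a+k_b
    against expected proportion N_a/(N_a+N_b) of summed library sizes.
    This significance stand-in is labelled in output metadata downstream; it
    is not the original study's DEGSeq statistic.
    """
    cond_a, cond_b = list(cond_a), list(cond_b)
    if not cond_a or not cond_b:
        raise ExpressionError("condition sample sets must be non-empty")
    if set(cond_a) & set(cond_b):
        raise ExpressionError("condition sample sets must be disjoint")
    for s in [*cond_a, *cond_b]:
        if s not in m.sample_ids:
            raise ExpressionError(f"unknown sample {s!r}")
    if test not in ("none", "binomial"):
        raise ExpressionError(f"unknown test {test!r}")

    table = rpkm(m)
    mean_a = table[cond_a].mean(axis=1).to_numpy()
    mean_b = table[cond_b].mean(axis=1).to_numpy()
    col = {s: i for i, s in enumerate(m.sample_ids)}
    ia = [col[s] for s in cond_a]
    ib = [col[s] for s in cond_b]
    if test == "binomial":
        n_a = float(m.library_sizes[ia].sum())
        n_b = float(m.library_sizes[ib].sum())
        p0 = n_a / (n_a + n_b)
        k_a_all = m.counts[:, ia].sum(axis=1)
        k_b_all = m.counts[:, ib].sum(axis=1)

    log_thresh = np.log2(fold_threshold)
    out: list[DECall] = []
    for i, tid in enumerate(m.transcript_ids):
        a, b = float(mean_a[i]), float(mean_b[i])
        if a == 0.0 and b == 0.0:
            lfc = 0.0
        elif b == 0.0:
            lfc = np.inf
        elif a == 0.0:
            lfc = -np.inf
        else:
            # difference of logs, so swapping conditions negates exactly
            lfc = float(np.log2(a) - np.log2(b))
        if lfc == 0.0 or abs(lfc) < log_thresh:
            direction = "none"
        else:
            direction = "up" if lfc > 0 else "down"
        p = None
        if test == "binomial":
            k_a, k_b = int(k_a_all[i]), int(k_b_all[i])
            p = _binom_two_sided(k_a, k_a + k_b, p0)
        out.append(DECall(tid, a, b, lfc, direction, p))
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def preprocess_for_clustering(
    rpkm_table: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(rpkm + pseudocount), mean-centre rows, scale rows to unit L2 norm.

    Rows with zero variance after the log transform carry no profile shape;
    they are dropped with a warning naming the transcripts.
    """
    if rpkm_table.empty:
        raise ExpressionError("empty table")
    logged = np.log2(rpkm_table.to_numpy(dtype=float) + pseudocount)
    centered = logged - logged.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    keep = norms > 0
    if not keep.all():
        dropped = list(rpkm_table.index[~keep])
        warnings.warn(
            f"dropping {len(dropped)} constant row(s) before clustering: "
            + ",".join(map(str, dropped)),
            stacklevel=2,
        )
    out = centered[keep] / norms[keep, None]
    return pd.DataFrame(out, index=rpkm_table.index[keep], columns=rpkm_table.columns)


def hcluster(
    table: pd.DataFrame | np.ndarray,
    distance: str = "pearson",
    linkage: str = "average",
) -> ClusterTree:
    """Agglomerative clustering with d = 1 - Pearson r and average linkage.

    Deterministic tie-breaking: among minimum-distance pairs the lowest
    (i, j) node-index pair merges first. Leaf order comes from a recursive
    left-before-right traversal of the merge tree.
    """
    if distance != "pearson" or linkage != "average":
        raise ExpressionError("only pearson distance with average linkage is supported")
    if isinstance(table, pd.DataFrame):
        labels = list(table.index)
        x = table.to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
        labels = list(range(x.shape[0]))
    n, ncol = x.shape
    if n < 2:
        raise ExpressionError("need at least 2 rows to cluster")
    if ncol < 2:
        raise ExpressionError("need at least 2 columns to cluster")
    if (x.std(axis=1) == 0).any():
        raise ExpressionError("zero-variance rows; run preprocess_for_clustering first")

    dmat = 1.0 - np.corrcoef(x)
    # snap rounding residue to zero so identical profiles merge at height 0
    dmat[np.abs(dmat) < 1e-12] = 0.0
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dmat[i, j])
    size = {i: 1 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((i, j, h))
        children[next_id] = (i, j)
        others = [k for k in size if k not in (i, j)]
        for k in others:
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dnew = (size[i] * dik + size[j] * djk) / (size[i] + size[j])
            dist[(min(k, next_id), max(k, next_id))] = dnew
        del dist[(i, j)]
        size[next_id] = size.pop(i) + size.pop(j)
        next_id += 1

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        left, right = children[node]
        return leaves(left) + leaves(right)

    leaf_order = [labels[i] for i in leaves(next_id - 1)]
    return ClusterTree(merges, leaf_order)


# ---------------------------------------------------------------------------
# tissue restriction
# ---------------------------------------------------------------------------


def tissue_restriction(
    tissue_rpkm: pd.DataFrame,
    target_tissue: str,
    min_on: float = 1.0,
    min_fold_over_others: float = 5.0,
) -> pd.Series:
    """Boolean per transcript: expressed in the target tissue and at least
    ``min_fold_over_others`` times the maximum of every other tissue.

    A zero maximum elsewhere passes whenever the target clears ``min_on``.
    This is a computable surrogate for a tissue-panel (Northern-blot style)
    specificity screen.
    """
    if tissue_rpkm.shape[1] < 2:
        raise ExpressionError("need at least 2 tissues")
    if target_tissue not in tissue_rpkm.columns:
        raise ExpressionError(f"unknown tissue {target_tissue!r}")
    target = tissue_rpkm[target_tissue]
    others = tissue_rpkm.drop(columns=[target_tissue]).max(axis=1)
    return (target >= min_on) & (target >= min_fold_over_others * others)
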