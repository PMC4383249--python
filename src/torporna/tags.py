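"""Digital tag-count processing: TPM, filters, quantile normalization,
mean-scaled patterns, and divisive (DIANA) clustering.

The counting unit is a 3'-anchored cDNA tag (one tag ~ one transcript
3' region); a library is one sequenced sample.  The stages implemented
here mirror a digital gene-expression workflow:

* tags-per-million conversion,
* an expression floor (>= min_tpm in at least n-1 samples of some group),
* a technical-replicate concordance filter (cross-platform fold limit),
* full-quantile normalization across libraries,
* per-group mean patterns scaled to a grand mean of one,
* DIANA divisive clustering on 1 - Pearson dissimilarity with a
  longest-branch tree cut.

Differential-expression testing (negative-binomial GLM with FDR
correction) is consumed as a precomputed per-tag q-value column, not
reimplemented; see :func:`qvalue_filter`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "TagCountMatrix",
    "DEFAULT_GROUP_ORDER",
    "counts_to_tpm",
    "expression_filter",
    "replicate_concordance_filter",
    "qvalue_filter",
    "full_quantile_normalize",
    "mean_scale_patterns",
    "DianaNode",
    "DianaTree",
    "diana_cluster",
    "cut_tree_longest_branch",
]

#: physiological group order used for pattern vectors
DEFAULT_GROUP_ORDER = ("SpW", "SpC", "SA", "IBA", "Ent", "ET", "LT", "EAr")


@dataclass
class TagCountMatrix:
    """Integer tag counts with per-sample metadata.

    ``counts``: tags x samples.  ``meta``: indexed by sample id with
    columns ``group``, ``platform`` and nullable ``replicate_partner``
    (partnerships must be symmetric).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise ConfigurationError("counts must be non-negative")
        if not np.allclose(c.values, np.round(c.values)):
            raise ConfigurationError("counts must be integers")
        missing = set(c.columns) - set(self.meta.index)
        if missing:
            raise ConfigurationError(f"samples without metadata: {sorted(missing)}")
        if "group" not in self.meta.columns:
            raise ConfigurationError("metadata needs a 'group' column")
        for s, p in self.replicate_pairs():
            back = self.meta.loc[p, "replicate_partner"]
            if back != s:
                raise ConfigurationError(
                    f"replicate partnership {s} -> {p} is not symmetric"
                )

    def groups(self) -> pd.Series:
        return self.meta.loc[self.counts.columns, "group"]

    def replicate_pairs(self) -> list[tuple[str, str]]:
        """Unordered replicate pairs, each reported once as (a, b)."""
        if "replicate_partner" not in self.meta.columns:
            return []
        pairs = []
        for s, p in self.meta["replicate_partner"].dropna().items():
            if s < p:
                pairs.append((s, p))
        return pairs

    @classmethod
    def from_tsv(cls, counts_path, meta_path) -> "TagCountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(counts, meta)

    def to_tsv(self, counts_path, meta_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="tag_id")
        self.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def counts_to_tpm(counts) -> pd.DataFrame:
    """Tags-per-million per library: 1e6 * count / column total.

    All-zero columns cannot be scaled; they are dropped with a warning.
    """
    df = counts.counts if isinstance(counts, TagCountMatrix) else counts
    totals = df.sum(axis=0)
    dead = totals[totals == 0].index
    if len(dead):
        warnings.warn(f"dropping all-zero libraries: {list(dead)}", stacklevel=2)
        df = df.drop(columns=dead)
        totals = totals.drop(dead)
    return df.astype(float) * 1e6 / totals


def expression_filter(
    tpm: pd.DataFrame, groups: pd.Series, min_tpm: float = 2.0
) -> pd.Index:
    """Tags expressed at >= ``min_tpm`` in at least n-1 samples of some group.

    ``groups`` maps sample id -> group label; every group must have at
    least two samples for the n-1 rule to be defined.
    """
    groups = groups.loc[tpm.columns]
    keep = pd.Series(False, index=tpm.index)
    for g, cols in groups.groupby(groups).groups.items():
        n = len(cols)
        if n < 2:
            raise ConfigurationError(
                f"group {g!r} has a single sample; the n-1 rule is undefined"
            )
        hits = (tpm[list(cols)] >= min_tpm).sum(axis=1)
        keep |= hits >= (n - 1)
    return tpm.index[keep]


def replicate_concordance_filter(
    values: pd.DataFrame,
    pairs: list[tuple[str, str]] | TagCountMatrix,
    fold_limit: float = 3.0,
) -> pd.Index:
    """Drop tags whose means across the two technical-replicate sets
    differ by ``fold_limit`` or more.

    The first members of all pairs form one set, the partners the
    other.  The boundary is inclusive (a ratio of exactly 3 removes the
    tag); a zero mean on one side only counts as an infinite ratio and
    removes the tag; zero on both sides is concordant.  With no pairs
    defined the filter is a no-op (with a warning).
    """
    if isinstance(pairs, TagCountMatrix):
        pairs = pairs.replicate_pairs()
    if not pairs:
        warnings.warn("no technical-replicate pairs; filter is a no-op", stacklevel=2)
        return values.index
    a = values[[p[0] for p in pairs]].mean(axis=1)
    b = values[[p[1] for p in pairs]].mean(axis=1)
    both_zero = (a == 0) & (b == 0)
    one_zero = ((a == 0) | (b == 0)) & ~both_zero
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.maximum(a / b, b / a)
    discordant = one_zero | (~both_zero & (ratio >= fold_limit))
    return values.index[~discordant]


def qvalue_filter(qvalues: pd.Series, alpha: float = 0.05) -> pd.Index:
    """Retain tags whose precomputed platform-test q-value is >= alpha.

    The cross-platform differential test itself (negative-binomial GLM
    with FDR correction) is upstream machinery; this consumes its
    output.  Tags with q < alpha are platform-biased and removed.
    """
    return qvalues.index[~(qvalues < alpha)]


def full_quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Full-quantile normalization across columns.

    Each column's sorted values are replaced by the across-column mean
    of sorted values at the same rank, then returned to the original
    row order, so every column ends with an identical sorted-value
    multiset.  Ties share the mean of the quantile values at their tied
    ranks (mid-rank interpolation), the standard convention.
    """
    if matrix.shape[1] < 2:
        raise ConfigurationError("quantile normalization needs >= 2 columns")
    x = matrix.to_numpy(dtype=float)
    ref = np.sort(x, axis=0).mean(axis=1)  # mean order statistics
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        r = pd.Series(x[:, j]).rank(method="average").to_numpy() - 1.0
        lo = np.floor(r).astype(int)
        hi = np.ceil(r).astype(int)
        out[:, j] = ref[lo] + (ref[hi] - ref[lo]) * (r - lo)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def mean_scale_patterns(
    matrix: pd.DataFrame,
    groups: pd.Series,
    group_order: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-tag group means divided by the tag's mean of group means.

    The result is a tags x groups matrix whose rows average to one;
    tags with a zero grand mean carry no pattern and are dropped with a
    warning.
    """
    groups = groups.loc[matrix.columns]
    gm = matrix.T.groupby(groups).mean().T
    if group_order is not None:
        missing = set(group_order) - set(gm.columns)
        if missing:
            raise ConfigurationError(f"groups absent from data: {sorted(missing)}")
        gm = gm[list(group_order)]
    grand = gm.mean(axis=1)
    dead = grand[grand == 0].index
    if len(dead):
        warnings.warn(
            f"dropping {len(dead)} tag(s) with zero grand mean", stacklevel=2
        )
        gm = gm.drop(index=dead)
        grand = grand.drop(dead)
    return gm.div(grand, axis=0)


# ---------------------------------------------------------------------------
# DIANA divisive clustering
# ---------------------------------------------------------------------------


@dataclass
class DianaNode:
    """Node of the divisive tree; ``height`` is the diameter (max pairwise
    dissimilarity) of its member set at the time it was split."""

    members: list[int]
    height: float
    left: "DianaNode | None" = None
    right: "DianaNode | None" = None

    @property
    def is_terminal(self) -> bool:
        return self.left is None


@dataclass
class DianaTree:
    root: DianaNode
    labels: list[str]
    dissimilarity: np.ndarray = field(repr=False)

    def split_heights(self) -> list[float]:
        """All positive split heights, descending."""
        out: list[float] = []

        def walk(node: DianaNode) -> None:
            if not node.is_terminal:
                out.append(node.height)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return sorted(out, reverse=True)


def _split_once(D: np.ndarray, members: list[int]) -> tuple[list[int], list[int]]:
    """One divisive step: seed a splinter group with the object of
    maximal average dissimilarity, then migrate objects whose average
    dissimilarity to the splinter group is lower than to the remainder.
    """
    idx = np.asarray(members)
    sub = D[np.ix_(idx, idx)]
    m = len(members)
    avg = sub.sum(axis=1) / (m - 1)
    splinter = [int(np.argmax(avg))]
    rest = [i for i in range(m) if i != splinter[0]]
    while len(rest) > 1:
        rest_arr = np.asarray(rest)
        d_rest = sub[np.ix_(rest_arr, rest_arr)].sum(axis=1) / (len(rest) - 1)
        d_spl = sub[np.ix_(rest_arr, np.asarray(splinter))].mean(axis=1)
        diff = d_rest - d_spl
        b = int(np.argmax(diff))
        if diff[b] <= 0:
            break
        splinter.append(rest[b])
        rest.pop(b)
    return [members[i] for i in splinter], [members[i] for i in rest]


def diana_cluster(patterns: pd.DataFrame) -> DianaTree:
    """Divisive analysis of tag expression patterns.

    Dissimilarity is 1 - Pearson correlation between pattern vectors.
    Starting from one all-inclusive cluster, the procedure repeatedly
    splits every cluster of positive diameter via the splinter-group
    step until all leaves are single tags.  Constant patterns have no
    defined correlation and are excluded with a warning.
    """
    if len(patterns) < 2:
        raise ConfigurationError("clustering needs at least two tags")
    x = patterns.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("patterns must be finite")
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"excluding {int(flat.sum())} constant-pattern tag(s): "
            "correlation undefined",
            stacklevel=2,
        )
        patterns = patterns.loc[~flat]
        x = x[~flat]
    if len(x) < 2:
        raise ConfigurationError("fewer than two tags with defined correlations")
    D = 1.0 - np.corrcoef(x)
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)  # guard tiny negative rounding

    def build(members: list[int]) -> DianaNode:
        if len(members) == 1:
            return DianaNode(members, 0.0)
        idx = np.asarray(members)
        diam = float(D[np.ix_(idx, idx)].max())
        if diam <= 0.0:
            return DianaNode(members, 0.0)  # identical patterns: no split
        left, right = _split_once(D, members)
        return DianaNode(members, diam, build(left), build(right))

    root = build(list(range(len(x))))
    return DianaTree(root, list(patterns.index), D)


def cut_tree_longest_branch(tree: DianaTree) -> pd.Series:
    """Cut the divisive tree in its longest-branch region.

    The cut height is placed in the widest gap between consecutive
    distinct split heights; every maximal subtree whose split height
    falls below the cut becomes one cluster.  With fewer than two
    distinct split heights there is no gap to cut in and a single
    cluster is returned.  Ties in gap width go to the higher gap.
    """
    heights = sorted({round(h, 12) for h in tree.split_heights()}, reverse=True)
    if len(heights) < 2:
        assign = pd.Series(0, index=tree.labels, name="cluster")
        return assign
    gaps = [heights[i] - heights[i + 1] for i in range(len(heights) - 1)]
    i = int(np.argmax(gaps))  # argmax takes the first (highest) tie
    cut = (heights[i] + heights[i + 1]) / 2.0

    clusters: list[list[int]] = []

    def collect(node: DianaNode) -> None:
        if node.is_terminal or node.height <= cut:
            clusters.append(node.members)
        else:
            collect(node.left)
            collect(node.right)

    collect(tree.root)
    assign = pd.Series(0, index=tree.labels, name="cluster")
    for ci, members in enumerate(clusters):
        for m in members:
            assign.iloc[m] = ci
    return assign
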