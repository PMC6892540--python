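"""Posterior tree-set post-processing: burn-in, MCC, HPD, node ages, LTT.

Conventions:

* burn-in/combining retains the *last* ``retain_per_run`` samples of each
  run (after discarding ``floor(burnin_frac * n)`` leading samples), which
  makes the retained count deterministic even when the burn-in fraction is
  not an integer number of samples;
* the maximum clade credibility (MCC) tree is the posterior *sample*
  maximizing the sum of log clade frequencies over its non-trivial clades,
  reported with its own node heights (target heights) rather than
  annotated averages, which can produce negative branches;
* HPD intervals use the shortest contiguous window of the sorted samples
  containing ``ceil(mass * N)`` points;
* lineage-through-time curves list branching events from the root toward
  the present; after the k-th oldest branching there are k+1 lineages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trees import Node, TimeTree, TreeSet, clade_tips, mrca, node_ages

__all__ = [
    "CladeTable",
    "LTTCurve",
    "NodeAgeSummary",
    "SummaryError",
    "apply_burnin_combine",
    "clade_frequencies",
    "mcc_tree",
    "hpd_interval",
    "node_age_summary",
    "ltt",
]


class SummaryError(ValueError):
    pass


def apply_burnin_combine(
    runs: list[TreeSet], burnin_frac: float, retain_per_run: int
) -> TreeSet:
    """Discard burn-in from each run, retain the last ``retain_per_run``
    samples, and concatenate in run order."""
    if not (0 <= burnin_frac < 1):
        raise SummaryError("burn-in fraction must be in [0, 1)")
    trees = []
    prov = []
    for r, run in enumerate(runs):
        n = len(run)
        discard = math.floor(burnin_frac * n)
        kept = n - discard
        if kept < retain_per_run:
            raise SummaryError(
                f"run {r}: only {kept} samples remain after {discard} burn-in, "
                f"need {retain_per_run}"
            )
        start = n - retain_per_run
        trees.extend(run.trees[start:])
        prov.extend((f"run{r}", i) for i in range(start, n))
    return TreeSet(trees, prov)


@dataclass
class CladeTable:
    """Posterior frequency of every clade (size >= 2) seen in a tree set."""

    frequencies: dict[frozenset[str], float]
    n_samples: int

    def __getitem__(self, clade) -> float:
        return self.frequencies.get(frozenset(clade), 0.0)


def _tree_clades(tree: TimeTree) -> set[frozenset[str]]:
    """Tip-label sets of all internal nodes with >= 2 descendant tips."""
    clades: set[frozenset[str]] = set()
    labels: dict[Node, frozenset[str]] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            labels[node] = frozenset([node.label])
        else:
            labels[node] = frozenset().union(*(labels[c] for c in node.children))
            if len(labels[node]) >= 2:
                clades.add(labels[node])
    return clades


def clade_frequencies(ts: TreeSet) -> CladeTable:
    """Fraction of samples containing each clade (root clade is always 1)."""
    if len(ts) == 0:
        raise SummaryError("empty tree set")
    counts: dict[frozenset[str], int] = {}
    for tree in ts:
        for clade in _tree_clades(tree):
            counts[clade] = counts.get(clade, 0) + 1
    n = len(ts)
    return CladeTable({c: k / n for c, k in counts.items()}, n)


def mcc_tree(ts: TreeSet) -> tuple[TimeTree, dict[frozenset[str], float]]:
    """Maximum clade credibility sample and its per-clade posterior support.

    The score of a sample is the sum of log posterior frequencies over its
    non-trivial clades (tips and the all-tips clade excluded); ties are
    broken by the lowest sample index. The winning sample's own node heights
    are kept.
    """
    if len(ts) == 0:
        raise SummaryError("empty tree set")
    table = clade_frequencies(ts)
    universe = ts.tip_labels
    best_i, best_score = 0, -math.inf
    for i, tree in enumerate(ts):
        score = 0.0
        for clade in _tree_clades(tree):
            if clade == universe:
                continue
            score += math.log(table[clade])
        if score > best_score + 1e-12:
            best_i, best_score = i, score
    winner = ts[best_i].copy()
    support = {c: table[c] for c in _tree_clades(winner)}
    return winner, support


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous window of the sorted samples holding
    ``ceil(mass * N)`` points."""
    values = np.sort(np.asarray(list(samples), dtype=float))
    n = len(values)
    if n == 0:
        raise SummaryError("no samples")
    if not (0 < mass <= 1):
        raise SummaryError("mass must be in (0, 1]")
    k = math.ceil(mass * n)
    if k >= n:
        return float(values[0]), float(values[-1])
    widths = values[k - 1 :] - values[: n - k + 1]
    i = int(np.argmin(widths))
    return float(values[i]), float(values[i + k - 1])


@dataclass
class NodeAgeSummary:
    mean: float | None
    median: float | None
    hpd95: tuple[float, float] | None
    percentile95: tuple[float, float] | None
    recovery: float
    n_recovered: int

    @property
    def recovered(self) -> bool:
        return self.n_recovered > 0


def node_age_summary(ts: TreeSet, clade, mass: float = 0.95) -> NodeAgeSummary:
    """Age summaries for one clade, restricted to samples that contain it.

    A clade never recovered yields an explicit not-recovered result rather
    than an error (its dates are simply missing). Both HPD and symmetric
    percentile intervals are reported.
    """
    clade = frozenset(clade)
    if not clade <= ts.tip_labels:
        raise SummaryError("clade tips not all in the tree set's tip universe")
    ages = []
    for tree in ts:
        if clade in _tree_clades(tree) or (len(clade) == len(ts.tip_labels)):
            node = mrca(tree, clade)
            if clade_tips(node) == clade:
                ages.append(node_ages(tree)[node])
    n = len(ages)
    if n == 0:
        return NodeAgeSummary(None, None, None, None, 0.0, 0)
    arr = np.asarray(ages)
    alpha = (1 - mass) / 2
    return NodeAgeSummary(
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        hpd95=hpd_interval(arr, mass),
        percentile95=(
            float(np.quantile(arr, alpha)),
            float(np.quantile(arr, 1 - alpha)),
        ),
        recovery=n / len(ts),
        n_recovered=n,
    )


@dataclass
class LTTCurve:
    """Branching times (Ma before present, decreasing) and lineage counts."""

    times: list[float]
    counts: list[int]

    def lineages_at(self, age: float) -> int:
        """Number of lineages alive at a given age (time before present)."""
        return 1 + sum(1 for t in self.times if t > age)


def ltt(tree: TimeTree) -> LTTCurve:
    """Lineage-through-time curve of an ultrametric tree.

    Events are internal-node ages sorted descending; the count after the
    k-th oldest branching is k+1, ending at the tip count.
    """
    ages = node_ages(tree)
    internal = sorted(
        (age for node, age in ages.items() if not node.is_leaf), reverse=True
    )
    counts = list(range(2, 2 + len(internal)))
    return LTTCurve(internal, counts)
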