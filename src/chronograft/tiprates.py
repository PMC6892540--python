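"""Tip-level speciation rates (tip DR) and cross-study comparisons.

Tip DR for tip i is the reciprocal of the equal-splits measure:

    ES_i = sum_{j=1..N_i} l_j * (1/2)^(j-1),      TipDR_i = 1 / ES_i

where the sum runs over the N_i edges on the path from tip i to the root,
j = 1 is the pendant edge and l_j the length of edge j. Each rootward edge
is discounted by half because it is shared with a growing number of other
species; sister tips therefore have identical values, and species subtended
by long unshared branches (evolutionarily distinct species) get low rates.
The formula assumes a fully bifurcating tree, and it should be computed on
trees containing every extant (or recently extinct) species — fossil tips
must be pruned first.

Across a credible set of trees, per-species rates are summarized by the
harmonic mean with an empirical 95% CI (2.5/97.5 percentiles across
samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trees import TimeTree, TreeSet

__all__ = [
    "TipRateTable",
    "TipRateError",
    "equal_splits",
    "tip_dr",
    "tree_tip_dr",
    "tip_dr_table",
    "clade_rate_stats",
    "compare_studies",
]


class TipRateError(ValueError):
    pass


def _check_binary_path(tree: TimeTree, tip_label: str) -> list:
    tip = tree.find_tip(tip_label)
    path = []
    node = tip
    while node.parent is not None:
        path.append(node)
        node = node.parent
    for ancestor in (n.parent for n in path):
        if len(ancestor.children) != 2:
            raise TipRateError(
                "tip DR assumes a fully bifurcating tree; resolve the "
                f"polytomy (or unary node) above tip {tip_label!r} first"
            )
    return path


def equal_splits(tree: TimeTree, tip_label: str) -> float:
    """Equal-splits measure of one tip (same units as branch lengths)."""
    path = _check_binary_path(tree, tip_label)
    es = 0.0
    for j, node in enumerate(path):  # j=0 is the pendant edge
        es += node.length * 0.5**j
    return es


def tip_dr(tree: TimeTree, tip_label: str) -> float:
    """Tip-level speciation rate: reciprocal of equal splits."""
    es = equal_splits(tree, tip_label)
    if es <= 0:
        raise TipRateError(f"zero equal-splits value at tip {tip_label!r}")
    return 1.0 / es


def tree_tip_dr(tree: TimeTree) -> dict[str, float]:
    """Tip DR for every tip in one preorder pass.

    Uses the recursion A(child) = l(child) + A(parent)/2 with A(root) = 0,
    so that A(tip) equals the equal-splits sum.
    """
    for node in tree.root.preorder():
        if not node.is_leaf and len(node.children) != 2:
            raise TipRateError("tip DR assumes a fully bifurcating tree")
    acc: dict = {tree.root: 0.0}
    out: dict[str, float] = {}
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        acc[node] = node.length + acc[node.parent] / 2.0
        if node.is_leaf:
            if acc[node] <= 0:
                raise TipRateError(f"zero equal-splits value at tip {node.label!r}")
            out[node.label] = 1.0 / acc[node]
    return out


@dataclass
class TipRateTable:
    """Species x sample matrix of tip DR values with per-species summaries."""

    species: list[str]
    values: np.ndarray  # shape (n_species, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.species):
            raise TipRateError("species list and value matrix disagree")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def harmonic_means(self) -> pd.Series:
        hm = self.values.shape[1] / (1.0 / self.values).sum(axis=1)
        return pd.Series(hm, index=self.species, name="harmonic_mean")

    def summary(self) -> pd.DataFrame:
        """Per-species harmonic mean and empirical 95% CI across samples."""
        lo = np.quantile(self.values, 0.025, axis=1)
        hi = np.quantile(self.values, 0.975, axis=1)
        return pd.DataFrame(
            {
                "species": self.species,
                "harmonic_mean": self.harmonic_means().values,
                "ci_lo": lo,
                "ci_hi": hi,
                "n_samples": self.n_samples,
            }
        )

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)


def tip_dr_table(ts: TreeSet) -> TipRateTable:
    """Tip DR across every sample of a credible tree set."""
    if len(ts) == 0:
        raise TipRateError("empty tree set")
    species = sorted(ts.tip_labels)
    values = np.empty((len(species), len(ts)))
    index = {sp: i for i, sp in enumerate(species)}
    for s, tree in enumerate(ts):
        rates = tree_tip_dr(tree)
        for sp, r in rates.items():
            values[index[sp], s] = r
    return TipRateTable(species, values)


@dataclass
class CladeRateStats:
    median: float
    ci: tuple[float, float]
    skew: float
    mannwhitney_u: float
    p_value: float
    n_clade: int
    n_background: int


def clade_rate_stats(table: TipRateTable, clade) -> CladeRateStats:
    """Clade-versus-background rate comparison on per-species harmonic means.

    The background is every species outside the clade; the test is a
    two-sided Mann-Whitney U. Skewness is the adjusted Fisher-Pearson
    sample estimator.
    """
    clade = set(clade)
    hm = table.harmonic_means()
    in_clade = hm[hm.index.isin(clade)]
    background = hm[~hm.index.isin(clade)]
    if len(in_clade) == 0:
        raise TipRateError("clade has no species in the rate table")
    if len(background) == 0:
        raise TipRateError("clade equals the whole table: empty background")
    u, p = stats.mannwhitneyu(in_clade, background, alternative="two-sided")
    return CladeRateStats(
        median=float(in_clade.median()),
        ci=(float(in_clade.quantile(0.025)), float(in_clade.quantile(0.975))),
        skew=float(stats.skew(in_clade, bias=False)),
        mannwhitney_u=float(u),
        p_value=float(p),
        n_clade=len(in_clade),
        n_background=len(background),
    )


def compare_studies(
    a: TipRateTable, b: TipRateTable, top_fraction: float = 0.01
) -> tuple[float, float]:
    """Spearman correlation and top-percentile overlap between two studies.

    Species are matched by exact binomial. The overlap is the fraction of
    study-a's top ``top_fraction`` species (by harmonic-mean rate) that also
    fall in study-b's top set.
    """
    shared = sorted(set(a.species) & set(b.species))
    if len(shared) < 3:
        raise TipRateError(f"only {len(shared)} shared species; need >= 3")
    hm_a = a.harmonic_means()[shared]
    hm_b = b.harmonic_means()[shared]
    r, _ = stats.spearmanr(hm_a, hm_b)
    k = max(1, int(round(top_fraction * len(shared))))
    top_a = set(hm_a.nlargest(k).index)
    top_b = set(hm_b.nlargest(k).index)
    overlap = len(top_a & top_b) / len(top_a)
    return float(r), float(overlap)
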