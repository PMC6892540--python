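"""Synthetic study systems: birth-death trees, pseudo-posteriors, taxonomies,
occurrence tables, and gapped alignments.

Every pipeline stage can be exercised without downloads because this module
generates all of its inputs from a known ground truth:

* ultrametric birth-death trees conditioned on a fixed number of surviving
  tips (the same branching process the patch-clade branch-length prior
  assumes);
* a decomposition of a true tree into a backbone (pruned to patch
  representatives) and relative-time patch trees with out-groups — the
  exact inverse of the rescale-and-graft assembly, so with zero noise the
  round trip must reproduce the true tree;
* pseudo-posterior tree sets made by multiplicative lognormal age jitter.
  Each set draws a run-level anchor displacement plus independent
  per-sample displacements, so the truth is statistically exchangeable with
  the samples and interval coverage can be checked at its nominal level.
  This emulates posterior spread only — not MCMC autocorrelation or
  topological uncertainty;
* taxonomies built by cutting the true tree at genus/family/order age
  thresholds, with seeded DNA-sampling gaps arranged so that all four
  sampling types occur;
* genus-level fossil occurrence tables from Poisson sampling along
  branches; and
* structurally gapped multi-gene alignments (gap patterns only; no
  substitution model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constraints import ConstraintSet
from .graft import GraftPlan, PatchDefinition
from .paleo import OccurrenceTable
from .supermatrix import GeneAlignment
from .taxonomy import MasterTaxonomy
from .trees import (
    Node,
    TimeTree,
    TreeSet,
    clade_tips,
    mrca,
    node_ages,
    prune_to,
    scale_branch_lengths,
)

__all__ = [
    "SyntheticScenario",
    "SimulationError",
    "simulate_bd_tree",
    "choose_patches",
    "decompose_scenario",
    "TruthRecord",
    "RankThresholds",
    "attach_outgroup",
    "jittered_tree_set",
    "impute_missing_species",
    "simulate_taxonomy_and_sampling",
    "simulate_occurrences",
    "simulate_gene_alignments",
]


class SimulationError(ValueError):
    pass


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic end-to-end exercise.

    Defaults are desk-scale: a 64-species clade with mammal-like rates
    (birth 0.25/Ma, death 0.1/Ma), four patch clades, roughly 30% of
    species missing DNA, credible sets of 100 samples, and 5% lognormal age
    jitter emulating posterior spread.
    """

    seed: int = 0
    birth: float = 0.25
    death: float = 0.1
    n_tips: int = 64
    n_patches: int = 4
    min_patch_size: int = 4
    missing_fraction: float = 0.3
    posterior_size: int = 100
    age_jitter: float = 0.05

    def __post_init__(self) -> None:
        if not (self.birth > self.death >= 0):
            raise SimulationError("need birth > death >= 0")
        if not (0 <= self.missing_fraction < 1):
            raise SimulationError("missing fraction must be in [0, 1)")
        if self.posterior_size < 1:
            raise SimulationError("posterior size must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# birth-death simulation
# ---------------------------------------------------------------------------


def simulate_bd_tree(
    birth: float,
    death: float,
    n_tips: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_attempts: int = 1000,
) -> TimeTree:
    """Ultrametric birth-death tree with exactly ``n_tips`` surviving tips.

    Forward simulation from a crown of two lineages; when the extant count
    first reaches ``n_tips`` the process runs for one further exponential
    holding time and stops, then extinct lineages are pruned and the tree is
    re-rooted at the MRCA of the survivors. Attempts where the clade dies
    out are discarded (conditioning on survival). For a pure-birth process
    the expected crown age is sum_{k=2..n} 1/(k * birth).
    """
    if not (birth > death >= 0):
        raise SimulationError("need birth > death >= 0")
    if n_tips < 2:
        raise SimulationError("need at least two tips")
    if rng is None:
        rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        tree = _bd_attempt(birth, death, n_tips, rng)
        if tree is not None:
            return tree
    raise SimulationError(
        f"no surviving clade of {n_tips} tips in {max_attempts} attempts"
    )


def _bd_attempt(
    birth: float, death: float, n_tips: int, rng: np.random.Generator
) -> TimeTree | None:
    root = Node()
    active: list[tuple[Node, float]] = [(root.add_child(Node()), 0.0),
                                        (root.add_child(Node()), 0.0)]
    t = 0.0
    total_rate = birth + death
    max_events = 200 * n_tips + 1000
    uid = 0
    for _ in range(max_events):
        k = len(active)
        if k == 0:
            return None
        if k == n_tips:
            t += rng.exponential(1.0 / (k * total_rate))
            break
        t += rng.exponential(1.0 / (k * total_rate))
        idx = rng.integers(k)
        node, start = active.pop(idx)
        node.length = t - start
        if rng.random() < birth / total_rate:
            active.append((node.add_child(Node()), t))
            active.append((node.add_child(Node()), t))
        else:
            node.label = f"dead{uid}"
            uid += 1
    else:
        return None
    alive = []
    for node, start in active:
        node.length = t - start
        node.label = f"alive{len(alive)}"
        alive.append(node.label)
    tree = TimeTree(root, units="absolute-Ma")
    tree = prune_to(tree, alive)
    # re-root at the MRCA of survivors (collapse any unary root chain)
    new_root = tree.root
    while len(new_root.children) == 1:
        new_root = new_root.children[0]
    new_root.parent = None
    new_root.length = 0.0
    tree = TimeTree(new_root, units="absolute-Ma")
    # deterministic tip labels in preorder
    for i, tip in enumerate(tree.tips()):
        tip.label = f"t{i + 1:04d}"
    return tree


# ---------------------------------------------------------------------------
# decomposition into backbone + patches (inverse of the graft)
# ---------------------------------------------------------------------------


def choose_patches(
    tree: TimeTree, n_patches: int, min_size: int = 4, max_size: int | None = None
) -> dict[str, frozenset[str]]:
    """Pick disjoint clades of the true tree to act as patch in-groups.

    Deterministic greedy preorder scan; clades are disjoint, sized within
    [min_size, max_size], and never exhaust the whole tip set (at least one
    tip stays outside all patches so the backbone retains structure).
    """
    if max_size is None:
        max_size = max(min_size, tree.n_tips // 2)
    candidates = [
        clade_tips(n)
        for n in tree.root.preorder()
        if n is not tree.root and not n.is_leaf
    ]
    # smallest clades first maximizes how many disjoint patches fit
    candidates.sort(key=lambda tips: (len(tips), sorted(tips)))
    chosen: list[frozenset[str]] = []
    taken: set[str] = set()
    for tips in candidates:
        if len(chosen) == n_patches:
            break
        if tips & taken:
            continue
        if not (min_size <= len(tips) <= max_size):
            continue
        if len(taken | tips) >= tree.n_tips:  # keep >= 1 free tip
            continue
        chosen.append(tips)
        taken |= tips
    if len(chosen) < n_patches:
        raise SimulationError(
            f"could only delimit {len(chosen)} of {n_patches} patches; "
            "use a larger tree or smaller min_size"
        )
    return {f"patch{i + 1}": tips for i, tips in enumerate(chosen)}


@dataclass
class TruthRecord:
    """Ground truth retained after decomposing a simulated tree."""

    tree: TimeTree
    crown_ages: dict[str, float]
    stem_ages: dict[str, float]
    representatives: dict[str, str]


def decompose_scenario(
    true_tree: TimeTree,
    scenario: SyntheticScenario,
    patches: dict[str, frozenset[str]] | None = None,
) -> tuple[TreeSet, dict[str, tuple[PatchDefinition, TreeSet]], GraftPlan, TruthRecord]:
    """Split a true tree into backbone and relative-time patch posteriors.

    With ``scenario.age_jitter == 0`` and posterior size 1 the graft of the
    returned plan reproduces the true tree exactly — the pipeline's master
    round-trip oracle. With jitter, pseudo-posterior sets of size
    ``scenario.posterior_size`` are produced for the backbone and each patch.
    """
    rng = scenario.rng()
    if patches is None:
        patches = choose_patches(
            true_tree, scenario.n_patches, scenario.min_patch_size
        )
    for name, tips in patches.items():
        if tips != clade_tips(mrca(true_tree, tips)):
            raise SimulationError(f"{name}: in-group is not a clade of the true tree")
    all_patch_tips: set[str] = set()
    for name, tips in patches.items():
        if all_patch_tips & tips:
            raise SimulationError("patch in-groups overlap")
        all_patch_tips |= tips

    ages = node_ages(true_tree)
    reps = {name: min(tips) for name, tips in patches.items()}
    rep_of_tip = {}
    for name, tips in patches.items():
        for t in tips:
            rep_of_tip[t] = reps[name]
    free_tips = set(true_tree.tip_labels) - all_patch_tips
    backbone_labels = set(reps.values()) | free_tips
    backbone_true = prune_to(true_tree, backbone_labels)

    defs: dict[str, PatchDefinition] = {}
    patch_true: dict[str, TimeTree] = {}
    crown_ages: dict[str, float] = {}
    stem_ages: dict[str, float] = {}
    for name, tips in patches.items():
        crown = mrca(true_tree, tips)
        parent = crown.parent
        stem_age = ages[parent]
        crown_age = ages[crown]
        # anchor: a backbone tip descending from the other side of the stem node
        sisters = [c for c in parent.children if c is not crown]
        sister_tip = min(
            lab for s in sisters for lab in clade_tips(s)
        )
        anchor = rep_of_tip.get(sister_tip, sister_tip)
        # patch tree: out-group pendant to the stem node + the crown subtree
        root = Node()
        og = root.add_child(Node(anchor, stem_age))
        crown_copy = crown.copy()
        crown_copy.length = stem_age - crown_age
        root.add_child(crown_copy)
        ptree = TimeTree(root, units="absolute-Ma")
        ptree = scale_branch_lengths(ptree, 1.0 / stem_age, units="relative")
        patch_true[name] = ptree
        crown_ages[name] = crown_age
        stem_ages[name] = stem_age
        defs[name] = PatchDefinition(
            name=name,
            representative=reps[name],
            outgroup=anchor,
            ingroup=tips,
        )

    m = scenario.posterior_size
    sigma = scenario.age_jitter
    backbone_ts = jittered_tree_set(backbone_true, m, sigma, rng)
    patch_sets = {
        name: (defs[name], jittered_tree_set(patch_true[name], m, sigma, rng,
                                             normalize_root=True))
        for name in patches
    }
    plan = GraftPlan(backbone_ts, patch_sets)
    truth = TruthRecord(true_tree, crown_ages, stem_ages, reps)
    return backbone_ts, patch_sets, plan, truth


def jittered_tree_set(
    tree: TimeTree,
    m: int,
    sigma: float,
    rng: np.random.Generator,
    normalize_root: bool = False,
) -> TreeSet:
    """Pseudo-posterior of ``m`` samples by multiplicative lognormal age jitter.

    Node ages are re-expressed as parent-relative ratios in (0, 1); each
    ratio r is perturbed as r ** exp(sigma * e), which stays in (0, 1) for
    any displacement e and therefore preserves the parent-older-than-child
    ordering without truncation. The root age is perturbed multiplicatively.
    One run-level anchor displacement is drawn per node, then each sample
    adds an independent displacement of the same scale, so the generating
    tree sits in the sample distribution like one more draw and interval
    coverage of true ages is close to nominal. ``normalize_root`` rescales
    each sample to unit root depth (relative-time patch convention).
    """
    ages = node_ages(tree)
    internal = [n for n in tree.root.preorder() if not n.is_leaf]
    idx = {n: i for i, n in enumerate(internal)}
    true_age = np.array([ages[n] for n in internal])
    n_nodes = len(internal)

    anchor = rng.normal(0.0, 1.0, size=n_nodes) if sigma > 0 else np.zeros(n_nodes)
    samples = []
    for _ in range(m):
        z = rng.normal(0.0, 1.0, size=n_nodes) if sigma > 0 else np.zeros(n_nodes)
        mult = np.exp(sigma * (anchor + z))
        new_age = np.empty(n_nodes)
        for i, node in enumerate(internal):
            if node.parent is None:
                new_age[i] = true_age[i] * mult[i]
            else:
                p = idx[node.parent]
                ratio = true_age[i] / true_age[p] if true_age[p] > 0 else 0.0
                new_age[i] = new_age[p] * ratio ** mult[i]
        clone = tree.copy()
        clone_internal = [n for n in clone.root.preorder() if not n.is_leaf]
        age_of = {node: new_age[i] for i, node in enumerate(clone_internal)}
        for node in clone.root.preorder():
            if node is clone.root:
                node.length = 0.0
                continue
            parent_age = age_of[node.parent]
            node.length = parent_age - (0.0 if node.is_leaf else age_of[node])
        out = TimeTree(clone.root, units=tree.units)
        if normalize_root:
            root_age = new_age[idx[tree.root]]
            out = scale_branch_lengths(out, 1.0 / root_age, units="relative")
        samples.append(out)
    return TreeSet(samples)


def attach_outgroup(tree: TimeTree, label: str, stem_frac: float = 0.25) -> TimeTree:
    """Add a distant out-group tip above the root (new root age =
    (1 + stem_frac) * crown age), as patch-clade guide trees have."""
    if stem_frac <= 0:
        raise SimulationError("stem fraction must be positive")
    crown_age = max(node_ages(tree).values())
    root = Node()
    root.add_child(Node(label, crown_age * (1 + stem_frac)))
    old = tree.root.copy()
    old.length = crown_age * stem_frac
    root.add_child(old)
    return TimeTree(root, units=tree.units)


# ---------------------------------------------------------------------------
# taxonomic imputation of DNA-missing species (desk-scale engine stand-in)
# ---------------------------------------------------------------------------


def impute_missing_species(
    ts: TreeSet,
    cs: ConstraintSet,
    missing: list[str],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TreeSet:
    """Attach each missing species inside its placement clade, per sample.

    The placement clade is the smallest partial-constraint in-set covering
    the species. Within that clade's subtree the attachment edge is chosen
    with probability proportional to edge length and the attachment height
    uniformly along the edge; the new pendant extends to the present, so
    samples stay ultrametric. Length-proportional attachment approximates
    the constant-rate birth-death expectation within the clade; it is a
    stand-in for the inference engine's constrained estimation, not a claim
    about its exact posterior.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    placement = {sp: cs.placement_clade(sp) for sp in missing}
    out = []
    for tree in ts:
        work = tree.copy()
        for sp in missing:
            clade = {t for t in placement[sp] if t in set(work.tip_labels)}
            if not clade:
                raise SimulationError(f"{sp}: placement clade empty in sample")
            _attach_in_clade(work, sp, clade, rng)
        out.append(TimeTree(work.root, units=work.units))
    return TreeSet(out, list(ts.provenance))


def _attach_in_clade(
    tree: TimeTree, new_label: str, clade: set[str], rng: np.random.Generator
) -> None:
    ages = node_ages(tree)
    if len(clade) == 1:
        top = tree.find_tip(next(iter(clade)))
        edges = [top]
    else:
        top = mrca(tree, clade)
        edges = [n for n in top.preorder() if n is not top]
    lengths = np.array([e.length for e in edges])
    if lengths.sum() <= 0:
        raise SimulationError("placement clade has zero total edge length")
    edge = edges[rng.choice(len(edges), p=lengths / lengths.sum())]
    child_age = ages[edge] if not edge.is_leaf else 0.0
    h = child_age + rng.random() * edge.length
    parent = edge.parent
    joint = Node(length=(child_age + edge.length) - h)
    i = parent.children.index(edge)
    parent.children[i] = joint
    joint.parent = parent
    edge.length = h - child_age
    joint.add_child(edge)
    joint.add_child(Node(new_label, h))


# ---------------------------------------------------------------------------
# taxonomy + sampling gaps
# ---------------------------------------------------------------------------


@dataclass
class RankThresholds:
    """Age cutoffs (in tree units) used to delimit nested ranks."""

    genus: float
    family: float
    order: float

    def __post_init__(self) -> None:
        if not (0 < self.genus < self.family < self.order):
            raise SimulationError("need 0 < genus < family < order thresholds")


def _rank_groups(tree: TimeTree, cutoff: float) -> list[list[str]]:
    """Maximal clades whose crown age is below the cutoff (tips grouped)."""
    ages = node_ages(tree)
    groups: list[list[str]] = []

    def walk(node) -> None:
        if node.is_leaf:
            groups.append([node.label])
            return
        if ages[node] < cutoff and node.parent is not None:
            groups.append(sorted(clade_tips(node)))
            return
        for c in node.children:
            walk(c)

    walk(tree.root)
    return groups


def simulate_taxonomy_and_sampling(
    true_tree: TimeTree,
    thresholds: RankThresholds,
    missing_fraction: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TimeTree, MasterTaxonomy, set[str]]:
    """Rank the tips of a tree and mark a DNA-sampling gap.

    Tips are grouped into genera/families/orders by age thresholds and
    relabeled ``G<i>_s<j>`` so the binomial encodes its genus. The
    unsampled set is seeded to include (budget permitting) one whole genus
    in an otherwise sampled family and one whole family in an otherwise
    sampled order, so sampling types 2, 3 and 4 all occur; the remainder of
    the budget removes random species that retain a sampled congener.
    Returns the relabeled tree, the master taxonomy, and the sampled set.
    """
    if not (0 <= missing_fraction < 1):
        raise SimulationError("missing fraction must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    tree = true_tree.copy()
    genera = _rank_groups(tree, thresholds.genus)
    families = _rank_groups(tree, thresholds.family)
    orders = _rank_groups(tree, thresholds.order)

    genus_of: dict[str, str] = {}
    for i, group in enumerate(genera):
        for sp in group:
            genus_of[sp] = f"G{i + 1:03d}"
    family_of = {
        sp: f"F{i + 1:02d}" for i, group in enumerate(families) for sp in group
    }
    order_of = {sp: f"O{i + 1}" for i, group in enumerate(orders) for sp in group}

    # relabel tips so the binomial carries the genus
    counter: dict[str, int] = {}
    rename: dict[str, str] = {}
    for tip in tree.tips():
        g = genus_of[tip.label]
        counter[g] = counter.get(g, 0) + 1
        rename[tip.label] = f"{g}_s{counter[g]:02d}"
        tip.label = rename[tip.label]

    records = []
    for old, new in rename.items():
        records.append(
            {
                "species": new,
                "genus": genus_of[old],
                "family": family_of[old],
                "order": order_of[old],
                "status": "extant",
                "provenance": "base",
            }
        )
    master = MasterTaxonomy.from_records(records)

    species = [r["species"] for r in records]
    n_missing = int(round(missing_fraction * len(species)))
    unsampled: set[str] = set()
    tab = master.table

    def members(col: str, name: str) -> list[str]:
        return tab.loc[tab[col] == name, "species"].tolist()

    # one whole family inside a multi-family order -> type 4
    if n_missing > 0:
        for fam in sorted(tab["family"].unique()):
            fam_sp = members("family", fam)
            order = tab.loc[tab["family"] == fam, "order"].iloc[0]
            if (
                len(members("order", order)) > len(fam_sp)
                and 0 < len(fam_sp) <= max(1, n_missing // 3)
            ):
                unsampled |= set(fam_sp)
                break
    # one whole genus inside a multi-genus family -> type 3
    for gen in sorted(tab["genus"].unique()):
        gen_sp = members("genus", gen)
        if set(gen_sp) & unsampled:
            continue
        fam = tab.loc[tab["genus"] == gen, "family"].iloc[0]
        fam_sp = set(members("family", fam))
        if len(fam_sp - set(gen_sp) - unsampled) > 0 and len(
            unsampled | set(gen_sp)
        ) <= n_missing:
            unsampled |= set(gen_sp)
            break
    # random type-2 removals: keep >= 1 sampled congener
    candidates = [
        sp
        for sp in species
        if sp not in unsampled
        and len(set(members("genus", genus_of_new(sp))) - unsampled) >= 2
    ]
    rng.shuffle(candidates)
    for sp in candidates:
        if len(unsampled) >= n_missing:
            break
        g = genus_of_new(sp)
        if len(set(members("genus", g)) - unsampled - {sp}) >= 1:
            unsampled.add(sp)

    sampled = set(species) - unsampled
    return tree, master, sampled


def genus_of_new(binomial: str) -> str:
    return binomial.split("_")[0]


# ---------------------------------------------------------------------------
# fossil occurrences
# ---------------------------------------------------------------------------


def simulate_occurrences(
    tree: TimeTree,
    master: MasterTaxonomy,
    preservation_rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    include_stem: bool = True,
) -> OccurrenceTable:
    """Poisson-sample fossil occurrences along branches of a ranked tree.

    Each occurrence is assigned the genus of its edge's first descendant
    tip and the order of that tip (the clade column). Occurrences on an
    order's stem edge are strictly older than that order's crown age by
    construction; ``include_stem=False`` restricts sampling to edges inside
    order crowns. Ages get a +/-2% stratigraphic window (clipped at 0).
    """
    if preservation_rate <= 0:
        raise SimulationError("preservation rate must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    tab = master.table
    genus_lookup = dict(zip(tab["species"], tab["genus"]))
    order_lookup = dict(zip(tab["species"], tab["order"]))
    ages = node_ages(tree)

    crown_node: dict[str, object] = {}
    crown_members: dict[str, set] = {}
    for order in sorted(tab["order"].unique()):
        tips = set(tab.loc[tab["order"] == order, "species"])
        node = mrca(tree, tips) if len(tips) > 1 else tree.find_tip(min(tips))
        crown_node[order] = node
        crown_members[order] = set(node.preorder())

    rows = []
    for node in tree.root.preorder():
        if node is tree.root or node.length <= 0:
            continue
        first_tip = min(n.label for n in node.leaves()) if not node.is_leaf else node.label
        order = order_lookup[first_tip]
        # the crown node's own edge is the order's stem edge
        in_crown = node in crown_members[order] and node is not crown_node[order]
        if not include_stem and not in_crown:
            continue
        n_occ = rng.poisson(preservation_rate * node.length)
        child_age = ages[node] if not node.is_leaf else 0.0
        for _ in range(n_occ):
            age = child_age + rng.random() * node.length
            rows.append(
                {
                    "genus": genus_lookup[first_tip],
                    "clade": order,
                    "min_ma": max(0.0, age * 0.98),
                    "max_ma": age * 1.02 if age > 0 else 0.0,
                    "ichnotaxon": False,
                    "uncertain_genus": False,
                }
            )
    return OccurrenceTable(
        pd.DataFrame(
            rows,
            columns=["genus", "clade", "min_ma", "max_ma", "ichnotaxon", "uncertain_genus"],
        ).astype(
            {
                "min_ma": float,
                "max_ma": float,
                "ichnotaxon": bool,
                "uncertain_genus": bool,
            }
        )
    )


# ---------------------------------------------------------------------------
# gapped alignments (structural fixtures, no substitution model)
# ---------------------------------------------------------------------------


def simulate_gene_alignments(
    taxa: list[str],
    genes: list[tuple[str, int]],
    coverage: float = 0.7,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[GeneAlignment]:
    """Random-composition alignments with taxon-level presence gaps.

    Each gene samples ``coverage`` of the taxa; present sequences are
    uniform random A/C/G/T with occasional leading/trailing gap runs. These
    fixtures exercise concatenation and matrix statistics; they carry no
    phylogenetic signal by design.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    out = []
    for name, length in genes:
        n_present = max(2, int(round(coverage * len(taxa))))
        present = sorted(rng.choice(len(taxa), size=n_present, replace=False))
        seqs = {}
        for i in present:
            seq = "".join(rng.choice(alphabet, size=length))
            lead = int(rng.integers(0, max(1, length // 10)))
            trail = int(rng.integers(0, max(1, length // 10)))
            seq = "-" * lead + seq[lead : length - trail] + "-" * trail
            seqs[taxa[i]] = seq
        out.append(GeneAlignment(name, seqs))
    return out
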