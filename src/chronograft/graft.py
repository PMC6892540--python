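"""Rescale-and-graft assembly of full timetrees from backbone and patches.

A small fossil-calibrated backbone carries the absolute timescale; each
patch clade is a species-level subtree estimated separately in *relative*
clock units (root depth normalized to 1) with one out-group tip. The two
share exactly one node — the out-group/in-group split — which is how a
patch is placed in absolute time. For every posterior sample index i, the
procedure is:

a. in backbone sample i, find the MRCA of the patch's backbone
   representative tip and its out-group counterpart, and record that node's
   age ("root time", Ma);
b. in patch sample i, divide the in-group crown age by the patch root age
   to get the relative scale of the stem edge, then multiply root time by
   it to obtain the absolute in-group crown age;
c. rescale all patch branch lengths by (absolute crown age / patch crown
   height) after pruning the out-group and any placeholder taxa;
d. shorten the representative's pendant edge by the absolute crown age; and
e. bind the rescaled patch there, replacing the representative tip.

Patches estimated with a distant out-group are instead rescaled to a crown
divergence read directly off the backbone (``rescale_mode="crown"``). Root
times are always measured on the *unmodified* backbone sample, so grafting
order cannot perturb ages, and topological variation across backbone
samples is honored automatically because the anchor node is re-located per
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .trees import (
    TimeTree,
    TreeSet,
    TreeValidationError,
    bind_at_edge,
    is_ultrametric,
    mrca,
    node_ages,
    prune_to,
    renormalize_tip_depths,
    scale_branch_lengths,
)

__all__ = [
    "PatchDefinition",
    "GraftPlan",
    "GraftError",
    "PatchScale",
    "patch_relative_scale",
    "graft_one",
    "graft_sets",
]


class GraftError(ValueError):
    pass


@dataclass
class PatchDefinition:
    """How one patch clade attaches to the backbone.

    ``representative`` is the backbone tip standing in for the whole patch;
    ``outgroup`` is the out-group tip label inside the patch trees;
    ``outgroup_backbone`` is the backbone tip anchoring the out-group side
    of the split (defaults to ``outgroup`` itself, which is the usual case
    of the out-group species also being a backbone representative).
    ``crown_anchor`` (a pair of backbone tip labels) is required in crown
    mode and names the backbone node whose age is the patch's crown age.
    """

    name: str
    representative: str
    outgroup: str
    ingroup: frozenset[str]
    rescale_mode: str = "stem"  # stem | crown
    placeholders: frozenset[str] = frozenset()
    outgroup_backbone: str | None = None
    crown_anchor: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.ingroup = frozenset(self.ingroup)
        self.placeholders = frozenset(self.placeholders)
        if self.rescale_mode not in ("stem", "crown"):
            raise GraftError(f"unknown rescale mode {self.rescale_mode!r}")
        if self.rescale_mode == "crown" and self.crown_anchor is None:
            raise GraftError(f"{self.name}: crown mode needs a crown_anchor pair")
        if self.outgroup in self.ingroup:
            raise GraftError(f"{self.name}: out-group inside the in-group")
        if self.placeholders & self.ingroup:
            raise GraftError(f"{self.name}: placeholder taxa inside the in-group")

    @property
    def backbone_anchor(self) -> str:
        return self.outgroup_backbone or self.outgroup


@dataclass
class PatchScale:
    root_rel_age: float
    crown_rel_age: float
    ratio: float
    degenerate: bool = False  # single-species in-group: graft is a relabel


def patch_relative_scale(
    patch: TimeTree, definition: PatchDefinition, rel_tol: float = 1e-6
) -> PatchScale:
    """Relative root and in-group crown ages of an ultrametric patch sample.

    ratio = crown/root is the relative scale of the stem edge; a singleton
    in-group has no crown and is flagged degenerate with ratio 0.
    """
    if not is_ultrametric(patch, rel_tol):
        raise GraftError(
            f"{definition.name}: patch sample is not ultrametric within {rel_tol:g}"
        )
    present_ingroup = definition.ingroup & set(patch.tip_labels)
    if not present_ingroup:
        raise GraftError(f"{definition.name}: no in-group tips in patch sample")
    ages = node_ages(patch, rel_tol)
    root_node = mrca(patch, present_ingroup | {definition.outgroup})
    root_age = ages[root_node]
    if len(present_ingroup) == 1:
        return PatchScale(root_age, 0.0, 0.0, degenerate=True)
    crown_age = ages[mrca(patch, present_ingroup)]
    ratio = crown_age / root_age
    if not (0 < ratio <= 1 + rel_tol):
        raise GraftError(
            f"{definition.name}: crown/root ratio {ratio:g} outside (0, 1]"
        )
    return PatchScale(root_age, crown_age, min(ratio, 1.0))


def _prepare_patch(
    patch: TimeTree, definition: PatchDefinition
) -> tuple[TimeTree | None, PatchScale]:
    """Prune placeholders/out-group and report the patch's relative scale."""
    work = patch
    drop = definition.placeholders & set(work.tip_labels)
    if drop:
        work = prune_to(work, set(work.tip_labels) - drop)
    scale = patch_relative_scale(work, definition)
    if scale.degenerate:
        return None, scale
    ingroup_tree = prune_to(work, definition.ingroup & set(work.tip_labels))
    # collapse the stem: the grafted subtree must be rooted at the in-group crown
    root = ingroup_tree.root
    while len(root.children) == 1:
        root = root.children[0]
    root.parent = None
    root.length = 0.0
    return TimeTree(root, units=ingroup_tree.units), scale


def graft_one(
    backbone: TimeTree,
    plan: dict[str, tuple[PatchDefinition, TimeTree]],
    sample_index: int | None = None,
    rel_tol: float = 1e-6,
) -> TimeTree:
    """Graft every patch onto one backbone sample, returning the full tree.

    All anchor ages are measured on the original backbone before any
    binding, so backbone node ages are conserved exactly and the grafting
    order is immaterial.
    """
    ages = node_ages(backbone, rel_tol)
    backbone_tips = set(backbone.tip_labels)

    attach: list[tuple[PatchDefinition, TimeTree | None, float]] = []
    for name, (definition, patch) in plan.items():
        if definition.representative not in backbone_tips:
            raise GraftError(
                f"{name}: representative {definition.representative!r} not a backbone tip"
            )
        ingroup_tree, scale = _prepare_patch(patch, definition)
        if definition.rescale_mode == "crown":
            a, b = definition.crown_anchor
            for lab in (a, b):
                if lab not in backbone_tips:
                    raise GraftError(f"{name}: crown anchor {lab!r} not in backbone")
            abs_crown = ages[mrca(backbone, {a, b})]
        else:
            anchor = definition.backbone_anchor
            if anchor not in backbone_tips:
                raise GraftError(f"{name}: out-group counterpart {anchor!r} not in backbone")
            root_time = ages[mrca(backbone, {definition.representative, anchor})]
            abs_crown = root_time * scale.ratio
        # validate against the representative's pendant edge span
        rep = backbone.find_tip(definition.representative)
        parent_age = ages[rep.parent]
        if abs_crown > parent_age * (1 + rel_tol):
            where = "" if sample_index is None else f" (sample {sample_index})"
            raise GraftError(
                f"{name}{where}: absolute crown age {abs_crown:g} exceeds the "
                f"representative's pendant edge span {parent_age:g} — negative branch"
            )
        attach.append((definition, ingroup_tree, abs_crown))

    out = backbone
    for definition, ingroup_tree, abs_crown in attach:
        if ingroup_tree is None:  # degenerate: relabel the representative
            sole = next(iter(definition.ingroup))
            out = out.copy()
            out.find_tip(definition.representative).label = sole
            continue
        crown_height = node_ages(ingroup_tree)[
            mrca(ingroup_tree, set(ingroup_tree.tip_labels))
        ]
        rescaled = scale_branch_lengths(
            ingroup_tree, abs_crown / crown_height, units=out.units
        )
        out = bind_at_edge(out, rescaled, definition.representative, abs_crown)

    out = renormalize_tip_depths(out)
    out.units = backbone.units
    return out


@dataclass
class GraftPlan:
    """Index-paired backbone and patch posterior sets.

    Sample i of every patch set is combined with backbone sample i; all
    sets must therefore hold the same number of samples, and patch
    in-groups must be pairwise disjoint.
    """

    backbone: TreeSet
    patches: dict[str, tuple[PatchDefinition, TreeSet]]

    def __post_init__(self) -> None:
        n = len(self.backbone)
        for name, (definition, ts) in self.patches.items():
            if len(ts) != n:
                raise GraftError(
                    f"sample count mismatch: backbone has {n}, patch {name!r} has {len(ts)}"
                )
        defs = list(self.patches.values())
        for i in range(len(defs)):
            for j in range(i + 1, len(defs)):
                overlap = defs[i][0].ingroup & defs[j][0].ingroup
                if overlap:
                    raise GraftError(
                        f"patch in-groups overlap: {sorted(overlap)[:5]}"
                    )


def graft_sets(plan: GraftPlan, rel_tol: float = 1e-6) -> TreeSet:
    """Assemble the full credible set: one grafted tree per sample index."""
    full = []
    for i, backbone in enumerate(plan.backbone):
        sample_plan = {
            name: (definition, ts[i])
            for name, (definition, ts) in plan.patches.items()
        }
        full.append(graft_one(backbone, sample_plan, sample_index=i, rel_tol=rel_tol))
    return TreeSet(full, list(plan.backbone.provenance))
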