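"""Hierarchical topology constraints for placing DNA-missing species.

For each patch clade the inference engine receives (i) hard constraints
enforcing every internal node of the guide tree (the globally estimated ML
topology restricted to the patch), and (ii) one partial constraint per
DNA-missing species confining it to the least inclusive guide-tree clade
containing the sampled members of its constraint target (genus, family or
order), without fixing its position inside that clade. When a genus is
paraphyletic in the guide tree, the least inclusive clade naturally widens
to accommodate it. Wholly unsampled genera are placed via an explicit
missing-clade assignment to a family-level (or configured) clade.

The serialized dialect is the MrBayes 3.2 constraint language:
``constraint <name> [hard|partial|negative] = <in-taxa> [: <out-taxa>];``
followed by ``prset topologypr = constraints(<names>);``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .taxonomy import MasterTaxonomy, TaxonTyping
from .trees import TimeTree, mrca, clade_tips

__all__ = [
    "Constraint",
    "ConstraintSet",
    "PatchInputBundle",
    "ConstraintError",
    "least_inclusive_clade",
    "build_constraints",
    "emit_constraint_block",
]


class ConstraintError(ValueError):
    pass


@dataclass(frozen=True)
class Constraint:
    name: str
    kind: str  # hard | partial | negative
    in_taxa: frozenset[str]
    out_taxa: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("hard", "partial", "negative"):
            raise ConstraintError(f"unknown constraint kind {self.kind!r}")
        if self.in_taxa & self.out_taxa:
            raise ConstraintError(f"{self.name}: in/out sets overlap")


@dataclass
class ConstraintSet:
    constraints: list[Constraint]

    def __post_init__(self) -> None:
        names = [c.name for c in self.constraints]
        if len(set(names)) != len(names):
            raise ConstraintError("constraint names must be unique")

    def __len__(self) -> int:
        return len(self.constraints)

    def __iter__(self):
        return iter(self.constraints)

    def partials(self) -> list[Constraint]:
        return [c for c in self.constraints if c.kind == "partial"]

    def placement_clade(self, species: str) -> frozenset[str]:
        """Smallest partial in-set containing the species (minus itself)."""
        candidates = [
            c.in_taxa for c in self.partials() if species in c.in_taxa
        ]
        if not candidates:
            raise KeyError(f"no partial constraint covers {species!r}")
        smallest = min(candidates, key=len)
        return smallest - {species}


@dataclass
class PatchInputBundle:
    """All inputs needed to constrain one patch clade's inference run.

    ``missing_clade_assignments`` maps an unsampled genus to the rank name
    (usually a family) whose sampled guide-tree members define the placement
    clade for all species of that genus.
    """

    patch_name: str
    guide: TimeTree
    dna_sampled: set[str]
    typing: TaxonTyping
    outgroup: str
    missing_clade_assignments: dict[str, str] = field(default_factory=dict)
    taxonomy: MasterTaxonomy | None = None  # needed for family/order targets

    def __post_init__(self) -> None:
        guide_tips = set(self.guide.tip_labels)
        if not self.dna_sampled <= guide_tips:
            extra = self.dna_sampled - guide_tips
            raise ConstraintError(f"sampled taxa absent from guide: {sorted(extra)[:5]}")
        if self.outgroup in self.dna_sampled:
            raise ConstraintError("out-group representative cannot be in the in-group")


def least_inclusive_clade(guide: TimeTree, taxa) -> frozenset[str]:
    """Descendant tip set of the MRCA of ``taxa`` in the guide tree.

    Always a superset of ``taxa``; wider than the input when the group is
    paraphyletic in the guide topology.
    """
    taxa = set(taxa)
    if not taxa:
        raise ConstraintError("least_inclusive_clade needs at least one taxon")
    return clade_tips(mrca(guide, taxa))


def build_constraints(bundle: PatchInputBundle) -> ConstraintSet:
    """Construct the full hard + partial constraint system for one patch.

    Hard constraints: one per internal node of the guide tree (including
    poorly supported ones — the guide topology is enforced in full, root
    excluded as trivial). Partial constraints: one per missing species, with
    in-set = least-inclusive-clade tips of its target plus the species
    itself, and out-set = the remaining in-group taxa. The patch out-group
    representative is excluded from all out-sets (its position is already
    fixed by the in-group hard constraint).
    """
    guide_tips = set(bundle.guide.tip_labels)
    ingroup_guide = sorted(guide_tips - {bundle.outgroup})

    constraints: list[Constraint] = []
    seen_clades: set[frozenset[str]] = set()
    i = 0
    for node in bundle.guide.root.preorder():
        if node.is_leaf or node is bundle.guide.root:
            continue
        tips = clade_tips(node) - {bundle.outgroup}
        if len(tips) < 2 or tips in seen_clades or tips == set(ingroup_guide):
            continue
        seen_clades.add(tips)
        constraints.append(Constraint(f"h_{bundle.patch_name}_{i:04d}", "hard", tips))
        i += 1

    typing = bundle.typing.table
    missing_rows = typing.loc[typing["type"] > 1]
    unplaceable: list[str] = []
    full_species: set[str] = set(ingroup_guide)

    partial_idx: dict[str, int] = {}
    for _, row in missing_rows.iterrows():
        sp = row["species"]
        full_species.add(sp)
        target = row["target"]
        assigned = bundle.missing_clade_assignments.get(_genus_of(sp))
        if assigned is not None:
            rank_taxa = _sampled_members(bundle, "family", assigned)
            target = assigned
        else:
            rank_taxa = _sampled_members(bundle, row["rank"], target)
        if not rank_taxa:
            unplaceable.append(sp)
            continue
        clade = least_inclusive_clade(bundle.guide, rank_taxa) - {bundle.outgroup}
        in_set = frozenset(clade | {sp})
        n = partial_idx.get(target, 0)
        partial_idx[target] = n + 1
        constraints.append(
            Constraint(f"c_{_slug(target)}_{n:03d}", "partial", in_set)
        )

    if unplaceable:
        raise ConstraintError(
            f"species with no resolvable constraint target in the guide tree: "
            f"{sorted(unplaceable)}"
        )

    # out-sets must span the *full* in-group species set (sampled + missing),
    # so rebuild them now that every missing species is known
    final: list[Constraint] = []
    for c in constraints:
        if c.kind == "partial":
            final.append(
                Constraint(
                    c.name, "partial", c.in_taxa, frozenset(full_species) - c.in_taxa
                )
            )
        else:
            final.append(c)
    return ConstraintSet(final)


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name)


def _sampled_members(bundle: PatchInputBundle, rank: str, target: str) -> set[str]:
    """Sampled guide-tree taxa belonging to the target rank name.

    Genus membership is read from the binomial itself; family and order
    membership require the bundle's taxonomy table.
    """
    if not target:
        return set()
    if rank == "genus":
        return {t for t in bundle.dna_sampled if _genus_of(t) == target}
    if bundle.taxonomy is None:
        raise ConstraintError(
            f"a taxonomy table is required to resolve {rank}-level target {target!r}"
        )
    tab = bundle.taxonomy.table
    col = "family" if rank == "family" else "order"
    members = set(tab.loc[tab[col] == target, "species"])
    return members & bundle.dna_sampled


def _genus_of(binomial: str) -> str:
    return binomial.replace("_", " ").split()[0]


def emit_constraint_block(cs: ConstraintSet) -> str:
    """Serialize a constraint system to a MrBayes 3.2 command block.

    Deterministic: taxa are emitted in sorted order and repeated calls are
    byte-identical. An empty set yields a block with no topology prior.
    """
    lines = ["#NEXUS", "begin mrbayes;"]
    for c in cs:
        in_taxa = " ".join(sorted(t.replace(" ", "_") for t in c.in_taxa))
        if c.kind == "partial":
            out_taxa = " ".join(sorted(t.replace(" ", "_") for t in c.out_taxa))
            lines.append(f"  constraint {c.name} partial = {in_taxa} : {out_taxa};")
        else:
            lines.append(f"  constraint {c.name} {c.kind} = {in_taxa};")
    if len(cs):
        names = ",".join(c.name for c in cs)
        lines.append(f"  prset topologypr = constraints({names});")
    lines.append("end;")
    return "\n".join(lines) + "\n"
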