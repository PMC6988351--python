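"""Lineage-specific gene-family expansion detection on species-labeled trees.

An expansion is a maximal monophyletic clade whose leaves all belong to
one species (or one merged species group) and whose size reaches a
threshold — by default five or more gene copies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import dendropy

from .io import SpeciesTree, TreeNode, parse_newick, serialize_newick


@dataclass
class SpeciesMap:
    """Leaf-name -> species mapping plus an optional species -> group
    coarsening used when closely related species are pooled."""

    leaf_to_species: dict[str, str]
    equivalence: dict[str, str] = field(default_factory=dict)

    def group_of_leaf(self, leaf_name: str) -> str:
        if leaf_name not in self.leaf_to_species:
            raise KeyError(f"leaf {leaf_name!r} has no species assignment")
        sp = self.leaf_to_species[leaf_name]
        return self.equivalence.get(sp, sp)

    def species(self) -> set[str]:
        return set(self.leaf_to_species.values())


@dataclass
class ExpansionCall:
    """One called lineage-specific expansion."""

    clade_root: TreeNode
    species_group: str
    size: int
    leaves: list[str]

    def __post_init__(self) -> None:
        if self.size != len(self.leaves):
            raise ValueError("size must equal the number of leaves")


def apply_species_equivalence(
    species_map: SpeciesMap, merges: list[tuple[str, str]]
) -> SpeciesMap:
    """Merge species into shared groups for monospecificity checks.

    ``merges`` is a list of (species, group) pairs. Merging every species
    into one group makes expansion calling vacuous, which warns.
    """
    known = species_map.species()
    for sp, _ in merges:
        if sp not in known:
            raise KeyError(f"merge references unknown species {sp!r}")
    equivalence = dict(species_map.equivalence)
    equivalence.update(merges)
    merged = replace(species_map, equivalence=equivalence)
    groups = {merged.group_of_leaf(leaf) for leaf in merged.leaf_to_species}
    if len(groups) == 1 and len(known) > 1:
        warnings.warn(
            "species merge collapses all species into one group; "
            "every clade is now monospecific",
            stacklevel=2,
        )
    return merged


def find_maximal_monospecific_clades(
    tree: SpeciesTree, species_map: SpeciesMap
) -> list[tuple[TreeNode, str, int]]:
    """Find every maximal clade whose leaves share one species group.

    Returns (node, species_group, leaf count) triples. The returned
    clades partition the leaf set: a monospecific clade is reported only
    if its parent's clade is not monospecific (or it is the root), and
    mixed-species leaves fall through to singleton clades.
    """
    results: list[tuple[TreeNode, str, int]] = []

    def walk(node: TreeNode) -> Optional[str]:
        """Return the node's species group if monospecific, else None,
        reporting maximal monospecific children of mixed nodes."""
        if node.is_leaf:
            return species_map.group_of_leaf(node.name or "")
        child_groups = [walk(c) for c in node.children]
        groups = set(child_groups)
        if len(groups) == 1 and None not in groups:
            return child_groups[0]
        for child, grp in zip(node.children, child_groups):
            if grp is not None:
                results.append((child, grp, len(child.leaves())))
        return None

    top = walk(tree.root)
    if top is not None:
        results.append((tree.root, top, len(tree.root.leaves())))
    results.sort(key=lambda r: (-r[2], r[1], min(l.name or "" for l in r[0].leaves())))
    return results


def call_expansions(
    clades: list[tuple[TreeNode, str, int]], min_size: int = 5
) -> list[ExpansionCall]:
    """Retain clades of at least ``min_size`` gene copies as expansions."""
    if min_size < 2:
        raise ValueError("an expansion requires min_size >= 2")
    calls = [
        ExpansionCall(
            clade_root=node,
            species_group=group,
            size=size,
            leaves=[leaf.name or "" for leaf in node.leaves()],
        )
        for node, group, size in clades
        if size >= min_size
    ]
    calls.sort(key=lambda c: (-c.size, c.species_group))
    return calls


def root_tree(
    tree: SpeciesTree, on_leaf: Optional[str] = None
) -> SpeciesTree:
    """Root an unrooted tree (a basal polytomy) before expansion analysis.

    With ``on_leaf`` the tree is rooted on the edge above that leaf
    (reproducing outgroup rooting); otherwise midpoint rooting is applied,
    which needs branch lengths — if they are absent the basal trifurcation
    is kept as the root and a warning is emitted.
    """
    dt = dendropy.Tree.get(
        data=serialize_newick(tree), schema="newick", preserve_underscores=True
    )
    if on_leaf is not None:
        node = dt.find_node_with_taxon_label(on_leaf)
        if node is None:
            raise KeyError(f"leaf {on_leaf!r} not in tree")
        dt.reroot_at_edge(node.edge, update_bipartitions=False)
    else:
        if any(e.length is None for e in dt.preorder_edge_iter()
               if e.head_node is not dt.seed_node):
            warnings.warn(
                "no branch lengths; keeping the basal multifurcation as root",
                stacklevel=2,
            )
            return tree
        dt.reroot_at_midpoint(update_bipartitions=False)
    newick = dt.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
    rooted = parse_newick(newick)
    rooted.leaf_species = dict(tree.leaf_species)
    return rooted
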