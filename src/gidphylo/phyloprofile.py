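"""Distance trees, monophyly, presence/absence profiles and Dollo parsimony.

Protein distances (p-distance, Poisson, or the Kimura protein correction
d = −ln(1 − p − 0.2 p²)) feed a neighbor-joining tree (Saitou–Nei
Q-criterion) with deterministic tie-breaking by taxon label; bootstrap
support resamples alignment columns and counts bipartitions. Presence/
absence of each complex component across species is summarised on a rooted
taxonomy and ancestral states are reconstructed under Dollo parsimony:
exactly one gain (at the MRCA of the present species) and a minimal set of
loss edges below it.

Trees are dendropy objects throughout; Newick round-trips through
dendropy's reader/writer.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def protein_distance(msa, correction: str = "p_distance") -> tuple[list[str], np.ndarray]:
    """Pairwise distance matrix from a MultipleAlignment.

    Distances are computed over pairwise non-gap columns. ``correction`` is
    ``p_distance``, ``poisson`` (−ln(1−p)) or ``kimura_protein``
    (−ln(1 − p − 0.2 p²)).
    """
    if msa.n_rows < 3:
        raise ValueError("need at least 3 rows for a distance matrix")
    if correction not in ("p_distance", "poisson", "kimura_protein"):
        raise ValueError(f"unknown correction {correction!r}")
    ids = list(msa.ids)
    n = len(ids)
    rows = [msa.rows[i] for i in ids]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = 0
            diffs = 0
            for a, b in zip(rows[i], rows[j]):
                if a == "-" or b == "-":
                    continue
                comparable += 1
                if a != b:
                    diffs += 1
            if comparable == 0:
                raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
            p = diffs / comparable
            if correction == "p_distance":
                d = p
            elif correction == "poisson":
                d = -math.log(max(1.0 - p, 1e-10))
            else:
                arg = 1.0 - p - 0.2 * p * p
                d = -math.log(max(arg, 1e-10))
            dist[i, j] = dist[j, i] = d
    return ids, dist


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(labels: list[str], dist: np.ndarray) -> dendropy.Tree:
    """Unrooted neighbor-joining tree from a symmetric distance matrix.

    Ties in the Q-criterion break on taxon label order; negative branch
    lengths are clamped to zero with the deficit moved to the sister edge.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] != dist.shape[1] or len(labels) != dist.shape[0]:
        raise ValueError("labels and matrix sizes disagree")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix is not symmetric")
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")

    nodes = [_Node(label) for label in labels]
    sort_keys = list(labels)  # lexicographic tie-break key per active node
    d = dist.copy()
    active = list(range(len(labels)))

    while len(active) > 3:
        n = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ii, jj in itertools.combinations(sorted(active, key=lambda k: sort_keys[k]), 2):
            q = (n - 2) * d[ii, jj] - r[ii] - r[jj]
            if best is None or q < best[0] - 1e-12:
                best = (q, ii, jj)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        new_index = len(nodes)
        nodes.append(new)
        sort_keys.append(min(sort_keys[i], sort_keys[j]))
        grown = np.zeros((new_index + 1, new_index + 1))
        grown[:new_index, :new_index] = d
        d = grown
        for k in active:
            if k in (i, j):
                continue
            d[new_index, k] = d[k, new_index] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        active = [k for k in active if k not in (i, j)] + [new_index]

    a, b, c = sorted(active, key=lambda k: sort_keys[k])
    la = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = _Node(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    newick = root.newick() + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _resampled_rows(msa, column_indices) -> "object":
    from .msa import MultipleAlignment

    rows = {
        rec_id: "".join(msa.rows[rec_id][c] for c in column_indices)
        for rec_id in msa.ids
    }
    return MultipleAlignment(list(msa.ids), rows)


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of leaf labels (smaller side
    canonicalised by including the lexicographically smallest leaf's side)."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        splits.add(min(side, other, key=lambda s: sorted(s)[0]))
    return splits


def bootstrap_support(
    msa, n_replicates: int = 100, seed: int = 0,
    correction: str = "p_distance",
) -> dendropy.Tree:
    """NJ tree with bootstrap percentages on internal edges.

    Alignment columns are resampled with replacement per replicate;
    support for each internal bipartition of the full-data tree is the
    percentage of replicate trees containing it. Reproducible under a
    fixed seed.
    """
    if msa.n_rows < 4:
        raise ValueError("bootstrap needs at least 4 rows")
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate")
    rng = np.random.default_rng(seed)
    ids, dist = protein_distance(msa, correction)
    tree = nj_tree(ids, dist)
    counts: dict[frozenset, int] = {}
    n_cols = msa.n_columns
    for _ in range(n_replicates):
        columns = rng.integers(0, n_cols, size=n_cols)
        try:
            rep_ids, rep_dist = protein_distance(_resampled_rows(msa, columns), correction)
        except ValueError:
            continue
        for split in _bipartitions(nj_tree(rep_ids, rep_dist)):
            counts[split] = counts.get(split, 0) + 1
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = min(side, other, key=lambda s: sorted(s)[0])
        node.label = str(round(100.0 * counts.get(key, 0) / n_replicates))
    return tree


# ---------------------------------------------------------------------------
# Monophyly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonophylyResult:
    monophyletic: bool
    intruders: tuple[str, ...]


def monophyly_test(tree: dendropy.Tree, label_map: dict[str, str]) -> dict[str, MonophylyResult]:
    """Per-label monophyly on an unrooted tree, via bipartitions.

    ``label_map`` maps every leaf to a group label. A group is
    monophyletic iff some edge bipartition separates exactly its leaves;
    otherwise the intruders within the smallest containing side are
    listed.
    """
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in label_map]
    if missing:
        raise ValueError(f"unlabelled leaves: {missing}")
    all_leaves = frozenset(leaves)
    sides: list[frozenset] = [all_leaves]
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        sides.append(side)
        sides.append(all_leaves - side)
    results: dict[str, MonophylyResult] = {}
    for label in sorted(set(label_map.values())):
        group = frozenset(l for l in leaves if label_map[l] == label)
        if len(group) <= 1:
            results[label] = MonophylyResult(True, ())
            continue
        containing = [s for s in sides if group <= s]
        smallest = min(containing, key=len)
        intruders = tuple(sorted(smallest - group))
        results[label] = MonophylyResult(len(intruders) == 0, intruders)
    return results


def root_at_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Root an unrooted tree on the edge above the named leaf."""
    node = next(
        (l for l in tree.leaf_node_iter() if l.taxon.label == outgroup_label), None
    )
    if node is None:
        raise KeyError(f"no leaf {outgroup_label!r}")
    tree.to_outgroup_position(node, update_bipartitions=False)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Taxonomy and presence/absence
# ---------------------------------------------------------------------------

def read_taxonomy(source) -> dendropy.Tree:
    """Read a rooted species taxonomy from Newick or a parent-child TSV.

    TSV rows are ``child<TAB>parent``; the root is the parent that never
    appears as a child.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = open(source).read() if "\n" not in str(source) and not str(source).lstrip().startswith("(") else str(source)
    text = text.strip()
    if text.startswith("("):
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
        tree.is_rooted = True
        return tree
    parent_of: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        child, parent = line.split("\t")[:2]
        parent_of[child] = parent
    children: dict[str, list[str]] = {}
    for child, parent in parent_of.items():
        children.setdefault(parent, []).append(child)
    roots = [p for p in children if p not in parent_of]
    if len(roots) != 1:
        raise ValueError(f"taxonomy must have exactly one root, found {roots}")

    def newick(name: str) -> str:
        kids = sorted(children.get(name, []))
        if not kids:
            return name
        return "(" + ",".join(newick(k) for k in kids) + ")" + name

    tree = dendropy.Tree.get(data=newick(roots[0]) + ";", schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def presence_matrix(calls, taxonomy: dendropy.Tree, components=None) -> pd.DataFrame:
    """Species × component boolean matrix from orthology calls.

    A component is present in a species when at least one call there has
    verdict ``orthologue`` (paralogue counts do not change presence).
    Species in the taxonomy but with no calls get all-false rows; call
    species missing from the taxonomy raise.
    """
    from .domain_annotation import COMPONENTS

    taxa = [l.taxon.label for l in taxonomy.leaf_node_iter()]
    components = list(components) if components is not None else list(COMPONENTS)
    matrix = pd.DataFrame(False, index=sorted(taxa), columns=components)
    for call in calls:
        if call.species not in matrix.index:
            raise ValueError(f"species {call.species!r} missing from taxonomy")
        if call.verdict == "orthologue" and call.component in matrix.columns:
            matrix.loc[call.species, call.component] = True
    return matrix


def annotated_taxonomy_report(matrix: pd.DataFrame, taxonomy: dendropy.Tree) -> str:
    """Text report marking encoded components per species with asterisks."""
    lines = ["species\t" + "\t".join(matrix.columns)]
    for leaf in taxonomy.leaf_node_iter():
        species = leaf.taxon.label
        marks = "\t".join("*" if matrix.loc[species, c] else "." for c in matrix.columns)
        lines.append(f"{species}\t{marks}")
    return "\n".join(lines) + "\n"


def supergroup_summary(matrix: pd.DataFrame, supergroups: dict[str, str]) -> pd.DataFrame:
    """Per-supergroup count of species encoding each component."""
    frame = matrix.copy()
    frame["supergroup"] = [supergroups[s] for s in frame.index]
    return frame.groupby("supergroup").sum()


# ---------------------------------------------------------------------------
# Dollo parsimony
# ---------------------------------------------------------------------------

@dataclass
class AncestralStates:
    """Single-gain (Dollo) reconstruction of one component's history."""

    component: str
    gain_clade: frozenset | None          # leaf labels under the gain node
    loss_clades: tuple[frozenset, ...]    # leaf sets of maximal lost subtrees
    states: dict[frozenset, bool] = field(default_factory=dict)  # per node (by leaf set)

    @property
    def n_losses(self) -> int:
        return len(self.loss_clades)

    @property
    def present_anywhere(self) -> bool:
        return self.gain_clade is not None


def dollo_reconstruct(
    taxonomy: dendropy.Tree, presence: dict[str, bool], component: str = ""
) -> AncestralStates:
    """Dollo parsimony: one gain at the MRCA of present species, minimal losses.

    Every node on a path from the gain node to a present leaf is scored
    present; each maximal subtree below the gain without any present leaf
    contributes exactly one loss edge. With no present species the
    component is absent everywhere and has no gain node.
    """
    leaves = [l.taxon.label for l in taxonomy.leaf_node_iter()]
    unknown = [s for s in presence if s not in leaves]
    if unknown:
        raise ValueError(f"species not in taxonomy: {unknown}")
    present_leaves = {s for s in leaves if presence.get(s, False)}
    states: dict[frozenset, bool] = {}
    if not present_leaves:
        for node in taxonomy.preorder_node_iter():
            states[frozenset(l.taxon.label for l in node.leaf_iter())] = False
        return AncestralStates(component, None, (), states)

    taxonomy = taxonomy.clone(depth=1)
    mrca_taxa = [t for t in taxonomy.taxon_namespace if t.label in present_leaves]
    gain = taxonomy.mrca(taxa=mrca_taxa)
    gain_clade = frozenset(l.taxon.label for l in gain.leaf_iter())

    loss_clades: list[frozenset] = []

    def walk(node, inside_gain: bool, lost: bool):
        leafset = frozenset(l.taxon.label for l in node.leaf_iter())
        if node is gain:
            inside_gain = True
        if inside_gain and not lost and not (leafset & present_leaves):
            lost = True
            loss_clades.append(leafset)
        states[leafset] = inside_gain and not lost
        for child in node.child_nodes():
            walk(child, inside_gain, lost)

    walk(taxonomy.seed_node, False, False)
    return AncestralStates(component, gain_clade, tuple(loss_clades), states)


def dollo_report(reconstructions: list[AncestralStates]) -> str:
    lines = ["component\tgain_clade_size\tn_losses\tlost_clades"]
    for rec in reconstructions:
        gain = len(rec.gain_clade) if rec.gain_clade else 0
        lost = ";".join(",".join(sorted(c)) for c in rec.loss_clades) or "-"
        lines.append(f"{rec.component}\t{gain}\t{rec.n_losses}\t{lost}")
    return "\n".join(lines) + "\n"
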