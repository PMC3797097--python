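"""Synthetic gene-family benchmark generator with complete truth tables.

Emulates the statistical structure of a curated multi-supergroup protein
dataset: a rooted, ultrametric-ish species tree whose labelled supergroups
are clades; per-component gene families evolving along it by birth–death
duplication/loss; domain-structured sequences (ordered blocks such as a
35-aa LisH and a 50-aa CTLH joined by fast-evolving linkers) with planted
invariant positions; and lineage-restricted components (a muskelin-like
family present in a single supergroup). Domain blocks evolve without
indels so that every truth coordinate is exact; linkers have fixed length
for the same reason (a documented simplification).

Sequence evolution is a Poisson substitution process: a site with rate
multiplier m on a branch of length t (expected substitutions/site at
m = 1) receives Poisson(m·t) replacement events drawn from a fixed
BLOSUM62-derived exchangeability table. Conserved columns carry m = 0 and
never change. All randomness flows from one integer seed through numbered
`numpy` generator streams, so each stage is independently reproducible.

The Rmnd5-like and MAEA-like families carry planted variant-RING motifs
(S/T substitutions at site S1 for Rmnd5; mixed S and G substitutions for
MAEA) with a conserved proline immediately after slot 7, and the
Rmnd5/MAEA and TWA1/RanBPM family roots are derived pairwise from shared
ancestral LisH+CTLH sequences so the true deep pairing is known.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .domain_annotation import ARCHITECTURE_TEMPLATES, DomainAnnotation
from .seqio_align import AMINO_ACIDS, ProteinRecord, ScoringScheme, write_fasta

DOMAIN_LENGTHS = {
    "LisH": 35, "CTLH": 50, "CRA": 100, "RING": 50, "SPRY": 120,
    "kelch": 47, "WD40": 40, "armadillo": 42, "discoidin": 150, "other": 80,
}
LINKER_LENGTH = 10
LINKER_RATE = 3.0

# Variant-RING motifs planted into the RING block (0-based offsets within
# the block; canonical minimal spacers) plus a conserved proline at slot7+1.
_RING_SLOT_OFFSETS = (0, 3, 13, 15, 18, 21, 26, 29)
_RING_PLANTS = {
    "Rmnd5": "CSCHSSCC",   # S/T-substituted S1, intact S2 -> one zinc
    "MAEA": "CSCHGGGC",    # mixed S and G substitutions -> no zinc
}

DEFAULT_SUPERGROUPS = ("Opisthokonta", "Amoebozoa", "Archaeplastida", "Excavata")


@dataclass
class SimulationConfig:
    """Study conditions for one benchmark realisation. ``seed`` is mandatory."""

    seed: int
    n_species: int = 8
    supergroups: tuple[str, ...] = DEFAULT_SUPERGROUPS
    tree_height: float = 0.25          # expected substitutions/site, root to tip
    components: tuple[str, ...] = tuple(ARCHITECTURE_TEMPLATES)
    duplication_rate: dict = field(default_factory=dict)   # per component, events/unit length
    loss_rate: dict = field(default_factory=dict)
    restricted_components: dict = field(
        default_factory=lambda: {"muskelin": "Opisthokonta"}
    )
    conserved_fraction: float = 0.2    # invariant columns per domain block
    pair_divergence: float = 0.3       # LisH+CTLH divergence between paired family roots
    family_divergence: float = 0.8     # divergence between unpaired family ancestors
    withhold_lish_fraction: float = 0.0
    withhold_ctlh_fraction: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        for rates in (self.duplication_rate, self.loss_rate):
            if any(v < 0 for v in rates.values()):
                raise ValueError("rates must be non-negative")
        if not (0 <= self.conserved_fraction < 1):
            raise ValueError("conserved_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["supergroups"] = list(self.supergroups)
        out["components"] = list(self.components)
        return out


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

@dataclass
class SpeciesNode:
    name: str | None
    children: list = field(default_factory=list)   # (SpeciesNode, branch_length)
    supergroup: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["SpeciesNode"]:
        if self.is_leaf:
            return [self]
        return [l for child, _ in self.children for l in child.leaves()]

    def newick(self, with_root_semicolon: bool = True) -> str:
        def render(node):
            if node.is_leaf:
                return node.name
            inner = ",".join(f"{render(c)}:{bl:.6g}" for c, bl in node.children)
            label = node.name or ""
            return f"({inner}){label}"

        text = render(self)
        return text + ";" if with_root_semicolon else text


def _join_ultrametric(subtrees: list[tuple[SpeciesNode, float]],
                      heights: list[float], rng) -> tuple[SpeciesNode, float]:
    """Random pairwise joins at the given ascending node heights."""
    items = list(subtrees)  # (node, node_height)
    for h in heights:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        (na, ha), (nb, hb) = items[i], items[j]
        parent = SpeciesNode(None, [(na, h - ha), (nb, h - hb)])
        items = [x for k, x in enumerate(items) if k not in (i, j)]
        items.append((parent, h))
    assert len(items) == 1
    return items[0]


def simulate_species_tree(config: SimulationConfig) -> SpeciesNode:
    """Rooted ultrametric-ish species tree whose supergroups are clades.

    Species are split as evenly as possible across the configured
    supergroups; within-supergroup joins happen in the lower part of the
    tree and supergroup stems join above, so each supergroup is a clade.
    The root sits at ``tree_height`` expected substitutions/site.
    """
    rng = np.random.default_rng([config.seed, 0])
    height = config.tree_height
    groups = list(config.supergroups)[: config.n_species]
    counts = [config.n_species // len(groups)] * len(groups)
    for i in range(config.n_species % len(groups)):
        counts[i] += 1
    group_roots: list[tuple[SpeciesNode, float]] = []
    species_index = 1
    for group, count in zip(groups, counts):
        leaves = []
        for _ in range(count):
            leaf = SpeciesNode(f"{group[:3]}_sp{species_index}", supergroup=group)
            leaves.append((leaf, 0.0))
            species_index += 1
        if count == 1:
            group_roots.append(leaves[0])
            continue
        inner = np.sort(rng.uniform(0.1 * height, 0.45 * height, size=count - 1))
        group_roots.append(_join_ultrametric(leaves, list(inner), rng))
    if len(group_roots) == 1:
        return group_roots[0][0]
    outer = np.sort(rng.uniform(0.55 * height, height, size=len(group_roots) - 1))
    outer[-1] = height
    root, _ = _join_ultrametric(group_roots, list(outer), rng)
    return root


def species_supergroups(tree: SpeciesNode) -> dict[str, str]:
    return {leaf.name: leaf.supergroup for leaf in tree.leaves()}


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _exchange_table() -> np.ndarray:
    """Fixed 20×20 replacement distribution: P(b | a) ∝ exp(B62[a,b]/3), b ≠ a."""
    matrix = ScoringScheme().matrix
    table = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i != j:
                table[i, j] = math.exp(matrix[a][b] / 3.0)
        table[i] /= table[i].sum()
    return table


_EXCHANGE = _exchange_table()
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def evolve_sequence(sequence: str, branch_length: float,
                    rate_multipliers: np.ndarray, rng) -> tuple[str, int]:
    """Apply the Poisson substitution process along one branch.

    Returns the evolved sequence and the number of substitution events
    (events at rate ``multiplier × branch_length`` per site).
    """
    events = rng.poisson(rate_multipliers * branch_length)
    residues = list(sequence)
    total = 0
    for site in np.nonzero(events)[0]:
        for _ in range(events[site]):
            current = _AA_INDEX[residues[site]]
            residues[site] = AMINO_ACIDS[rng.choice(20, p=_EXCHANGE[current])]
            total += 1
    return "".join(residues), total


# ---------------------------------------------------------------------------
# Family layout
# ---------------------------------------------------------------------------

@dataclass
class FamilyLayout:
    component: str
    length: int
    domains: list[tuple[str, int, int]]              # (type, start, end) 1-based
    rate_multipliers: np.ndarray
    conserved_positions: list[tuple[int, str]]       # (1-based position, residue)
    ring_slot_positions: tuple[int, ...] | None = None


def _build_layout(component: str, rng, conserved_fraction: float) -> FamilyLayout:
    template = ARCHITECTURE_TEMPLATES[component]
    domains: list[tuple[str, int, int]] = []
    pos = LINKER_LENGTH
    pieces_mult: list[np.ndarray] = [np.full(LINKER_LENGTH, LINKER_RATE)]
    conserved: list[tuple[int, str]] = []
    ring_slots: tuple[int, ...] | None = None
    for dom in template:
        length = DOMAIN_LENGTHS[dom]
        start, end = pos + 1, pos + length
        domains.append((dom, start, end))
        mult = np.ones(length)
        n_cons = int(round(conserved_fraction * length))
        cons_idx = rng.choice(length, size=n_cons, replace=False) if n_cons else []
        for idx in cons_idx:
            mult[idx] = 0.0
        if dom == "RING" and component in _RING_PLANTS:
            offset = 5
            plant = _RING_PLANTS[component]
            slots = tuple(start + offset + o for o in _RING_SLOT_OFFSETS)
            for absolute, residue in zip(slots, plant):
                mult[absolute - start] = 0.0
                conserved.append((absolute, residue))
            proline_at = slots[6] + 1
            mult[proline_at - start] = 0.0
            conserved.append((proline_at, "P"))
            ring_slots = slots
        pieces_mult.append(mult)
        pieces_mult.append(np.full(LINKER_LENGTH, LINKER_RATE))
        pos = end + LINKER_LENGTH
        for idx in cons_idx:
            # conserved residue is fixed when the root sequence is drawn
            conserved.append((start + int(idx), ""))
    length = pos
    return FamilyLayout(component, length, domains,
                        np.concatenate(pieces_mult), conserved, ring_slots)


def _random_sequence(length: int, rng) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.choice(20, size=length))


def _root_sequence(layout: FamilyLayout, rng,
                   lish_ctlh_seed_regions: dict[str, str] | None = None) -> str:
    seq = list(_random_sequence(layout.length, rng))
    if lish_ctlh_seed_regions:
        for dom, start, end in layout.domains:
            if dom in lish_ctlh_seed_regions:
                region = lish_ctlh_seed_regions[dom]
                seq[start - 1 : end] = list(region[: end - start + 1])
    plants: list[tuple[int, str]] = []
    for position, residue in layout.conserved_positions:
        if residue:
            seq[position - 1] = residue
        plants.append((position, seq[position - 1]))
    layout.conserved_positions = plants
    return "".join(seq)


# ---------------------------------------------------------------------------
# Gene family evolution
# ---------------------------------------------------------------------------

@dataclass
class GeneTreeNode:
    label: str | None
    children: list = field(default_factory=list)
    is_duplication: bool = False

    def newick(self) -> str:
        def render(node):
            if not node.children:
                return node.label
            inner = ",".join(render(c) for c in node.children)
            return f"({inner})"

        return render(self) + ";"

    def leaf_labels(self) -> list[str]:
        if not self.children:
            return [self.label]
        return [l for c in self.children for l in c.leaf_labels()]


@dataclass
class FamilyResult:
    component: str
    layout: FamilyLayout
    records: list[ProteinRecord]
    gene_tree: GeneTreeNode | None
    n_duplications: int
    n_losses: int
    presence: dict[str, bool]          # per species


def evolve_gene_family(
    species_tree: SpeciesNode,
    component: str,
    config: SimulationConfig,
    rng,
    root_sequence: str | None = None,
    layout: FamilyLayout | None = None,
) -> FamilyResult:
    """Evolve one component family along the species tree.

    Duplication/loss events are Poisson in branch length; a component
    restricted to one supergroup produces no genes outside it (scored as a
    lineage loss). The true gene tree over emitted genes is returned.
    """
    lam = config.duplication_rate.get(component, 0.0)
    mu = config.loss_rate.get(component, 0.0)
    allowed = config.restricted_components.get(component)
    layout = layout or _build_layout(component, rng, config.conserved_fraction)
    root_seq = root_sequence or _root_sequence(layout, rng)
    counters = {"dup": 0, "loss": 0, "gene": 0}
    records: list[ProteinRecord] = []
    presence = {leaf.name: False for leaf in species_tree.leaves()}
    lineage_of = {leaf.name: [leaf.supergroup, leaf.name]
                  for leaf in species_tree.leaves()}

    def walk(node: SpeciesNode, seq: str) -> GeneTreeNode | None:
        if node.is_leaf:
            if allowed is not None and node.supergroup != allowed:
                counters["loss"] += 1
                return None
            counters["gene"] += 1
            gene_id = f"{node.name}_{component}_g{counters['gene']}"
            records.append(ProteinRecord(
                gene_id, seq, species=node.name,
                lineage=tuple(lineage_of[node.name]),
            ))
            presence[node.name] = True
            return GeneTreeNode(gene_id)
        children: list[GeneTreeNode] = []
        for child, brlen in node.children:
            copies = 1 + (rng.poisson(lam * brlen) if lam > 0 else 0)
            counters["dup"] += copies - 1
            for _ in range(copies):
                if mu > 0 and rng.poisson(mu * brlen) > 0:
                    counters["loss"] += 1
                    continue
                evolved, _ = evolve_sequence(seq, brlen, layout.rate_multipliers, rng)
                sub = walk(child, evolved)
                if sub is not None:
                    children.append(sub)
        if not children:
            return None
        if len(children) == 1:
            return children[0]
        return GeneTreeNode(None, children)

    gene_tree = walk(species_tree, root_seq)
    return FamilyResult(component, layout, records, gene_tree,
                        counters["dup"], counters["loss"], presence)


# ---------------------------------------------------------------------------
# Benchmark emission
# ---------------------------------------------------------------------------

@dataclass
class Benchmark:
    config: SimulationConfig
    species_tree: SpeciesNode
    supergroups: dict[str, str]
    families: dict[str, FamilyResult]

    @property
    def all_records(self) -> list[ProteinRecord]:
        return [r for fam in self.families.values() for r in fam.records]

    def proteomes(self) -> dict[str, list[ProteinRecord]]:
        out: dict[str, list[ProteinRecord]] = {
            leaf.name: [] for leaf in self.species_tree.leaves()
        }
        for record in self.all_records:
            out[record.species].append(record)
        return out

    def true_annotations(self) -> dict[str, list[DomainAnnotation]]:
        annotations: dict[str, list[DomainAnnotation]] = {}
        for fam in self.families.values():
            for record in fam.records:
                annotations[record.id] = [
                    DomainAnnotation(record.id, dom, start, end)
                    for dom, start, end in fam.layout.domains
                ]
        return annotations

    def truth_orthology(self) -> dict[str, tuple[str, str]]:
        """gene id → (component, species)."""
        return {
            r.id: (fam.component, r.species)
            for fam in self.families.values() for r in fam.records
        }


def generate_benchmark(config: SimulationConfig) -> Benchmark:
    """Run the full generator: species tree plus one family per component.

    The Rmnd5/MAEA and TWA1/RanBPM family roots share pairwise LisH+CTLH
    ancestors separated by ``pair_divergence`` within a pair and
    ``family_divergence`` between unrelated families, making the deep
    pairing recoverable from trees of those regions.
    """
    tree = simulate_species_tree(config)
    pair_rng = np.random.default_rng([config.seed, 1])
    # shared LisH+CTLH ancestors for the two deep pairs
    base = {
        "LisH": _random_sequence(DOMAIN_LENGTHS["LisH"], pair_rng),
        "CTLH": _random_sequence(DOMAIN_LENGTHS["CTLH"], pair_rng),
    }

    def diverged(regions: dict[str, str], amount: float) -> dict[str, str]:
        out = {}
        for dom, seq in regions.items():
            evolved, _ = evolve_sequence(
                seq, amount, np.ones(len(seq)), pair_rng
            )
            out[dom] = evolved
        return out

    pair_ancestors = {
        "TWA1_RanBPM": diverged(base, config.family_divergence / 2.0),
        "Rmnd5_MAEA": diverged(base, config.family_divergence / 2.0),
    }
    seeds = {
        "TWA1": diverged(pair_ancestors["TWA1_RanBPM"], config.pair_divergence / 2.0),
        "RanBPM": diverged(pair_ancestors["TWA1_RanBPM"], config.pair_divergence / 2.0),
        "Rmnd5": diverged(pair_ancestors["Rmnd5_MAEA"], config.pair_divergence / 2.0),
        "MAEA": diverged(pair_ancestors["Rmnd5_MAEA"], config.pair_divergence / 2.0),
    }
    families: dict[str, FamilyResult] = {}
    for index, component in enumerate(config.components):
        rng = np.random.default_rng([config.seed, 10 + index])
        layout = _build_layout(component, rng, config.conserved_fraction)
        root = _root_sequence(layout, rng, seeds.get(component))
        families[component] = evolve_gene_family(
            tree, component, config, rng, root_sequence=root, layout=layout
        )
    return Benchmark(config, tree, species_supergroups(tree), families)


def emit_benchmark(config: SimulationConfig, outdir, overwrite: bool = False) -> Benchmark:
    """Write the benchmark file set and its manifest to ``outdir``.

    Layout: ``proteomes/<species>.fasta``, ``domains.tsv`` (annotations
    with the configured withheld fraction of LisH/CTLH rows),
    ``taxonomy.nwk``, ``supergroups.tsv``, ``truth/*`` tables and per-
    component gene trees, and ``manifest.json`` recording seed and config.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {outdir} is not empty")
    bench = generate_benchmark(config)
    (outdir / "proteomes").mkdir(parents=True, exist_ok=True)
    (outdir / "truth" / "gene_trees").mkdir(parents=True, exist_ok=True)

    files: list[str] = []
    for species, records in sorted(bench.proteomes().items()):
        path = outdir / "proteomes" / f"{species}.fasta"
        write_fasta(sorted(records, key=lambda r: r.id), path)
        files.append(str(path.relative_to(outdir)))

    withhold_rng = np.random.default_rng([config.seed, 100])
    with open(outdir / "domains.tsv", "w") as fh:
        for fam in bench.families.values():
            for record in sorted(fam.records, key=lambda r: r.id):
                for dom, start, end in fam.layout.domains:
                    if dom == "LisH" and withhold_rng.random() < config.withhold_lish_fraction:
                        continue
                    if dom == "CTLH" and withhold_rng.random() < config.withhold_ctlh_fraction:
                        continue
                    fh.write(f"{record.id}\t{dom}\t{start}\t{end}\t1e-10\n")
    files.append("domains.tsv")

    with open(outdir / "taxonomy.nwk", "w") as fh:
        fh.write(bench.species_tree.newick() + "\n")
    with open(outdir / "supergroups.tsv", "w") as fh:
        for species, group in sorted(bench.supergroups.items()):
            fh.write(f"{species}\t{group}\n")
    files += ["taxonomy.nwk", "supergroups.tsv"]

    with open(outdir / "truth" / "orthology.tsv", "w") as fh:
        fh.write("gene\tcomponent\tspecies\n")
        for gene, (component, species) in sorted(bench.truth_orthology().items()):
            fh.write(f"{gene}\t{component}\t{species}\n")
    with open(outdir / "truth" / "presence.tsv", "w") as fh:
        components = list(config.components)
        fh.write("species\t" + "\t".join(components) + "\n")
        for species in sorted(bench.supergroups):
            row = "\t".join(
                str(int(bench.families[c].presence[species])) for c in components
            )
            fh.write(f"{species}\t{row}\n")
    with open(outdir / "truth" / "domains.tsv", "w") as fh:
        fh.write("gene\tdomain\tstart\tend\n")
        for fam in bench.families.values():
            for record in sorted(fam.records, key=lambda r: r.id):
                for dom, start, end in fam.layout.domains:
                    fh.write(f"{record.id}\t{dom}\t{start}\t{end}\n")
    with open(outdir / "truth" / "conserved.tsv", "w") as fh:
        fh.write("component\tposition\tresidue\n")
        for fam in bench.families.values():
            for position, residue in sorted(fam.layout.conserved_positions):
                fh.write(f"{fam.component}\t{position}\t{residue}\n")
    for component, fam in bench.families.items():
        if fam.gene_tree is not None:
            path = outdir / "truth" / "gene_trees" / f"{component}.nwk"
            with open(path, "w") as fh:
                fh.write(fam.gene_tree.newick() + "\n")
    files += ["truth/orthology.tsv", "truth/presence.tsv", "truth/domains.tsv",
              "truth/conserved.tsv"]

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "files": files,
        "n_genes": len(bench.all_records),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return bench
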