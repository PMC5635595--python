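"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is deterministic under a fixed seed, uses independent
sub-streams keyed by purpose and replicate (adding families never
perturbs earlier ones), and returns a ground-truth registry sufficient
to score downstream recovery without re-simulation.

What is emulated: a birth-death chronogram; gene families evolved down
it under explicit duplication / transfer / loss rates (transfers regraft
onto a uniformly chosen coexisting branch, matching the reconciler's
model class); ±w gene neighborhoods whose candidate-homolog-group (CHG)
content decays with event-specific retention probabilities (defaults
0.40 speciation / 0.11 duplication / 0.21 transfer) and may carry
planted clade-specific accessory families; intron/exon structures with
clade-specific junction gains; and block-structured all-vs-all hit
tables with configurable between-family noise.
"""

from __future__ import annotations

import math
import random
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .gene_structure import GeneModel
from .io_formats import Alignment, AnnotationTable, HitTable
from .trees import DatedSpeciesTree, GeneTree, TreeNode


def substream(seed: int, *key) -> int:
    """Derive a child seed from a base seed and a hashable key (stable
    across runs and platforms; stays below 2**31)."""
    text = "|".join(str(k) for k in key).encode()
    return (int(seed) * 2654435761 + zlib.crc32(text)) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PlantedAssociation:
    """A CHG inserted into neighborhoods preferentially inside one clade."""

    clade_leaves: frozenset
    chg: str
    p_in: float = 0.95
    p_out: float = 0.05


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline inputs.

    Rates are per lineage per unit time on a chronogram normalized to
    root age 1.  The default duplication/transfer/loss rates yield on
    the order of 2 duplications, 0.5 transfers and 3 losses per family
    on a 30-taxon tree; retention defaults are the event-specific
    neighborhood retention probabilities the analysis estimates.
    """

    seed: int = 0
    n_taxa: int = 30
    birth: float = 1.0
    death: float = 0.2
    dup_rate: float = 0.20
    transfer_rate: float = 0.055
    loss_rate: float = 0.30
    root_copies: int = 1
    n_families: int = 50
    chg_pool: int = 400
    window: int = 20
    retention: dict = field(
        default_factory=lambda: {"S": 0.40, "D": 0.11, "T": 0.21}
    )
    planted: list = field(default_factory=list)
    # gene structure
    protein_core: int = 120
    insert_col_prob: float = 0.15
    insert_owner_frac: float = 0.2
    n_ancestral_junctions: int = 4
    junction_gain: float = 0.01   # per core position per branch
    junction_loss: float = 0.05   # per junction per branch
    # hit table
    hit_noise_density: float = 0.02
    hit_dropout: float = 0.0


# ---------------------------------------------------------------------------
# Chronogram
# ---------------------------------------------------------------------------

def simulate_chronogram(
    n_taxa: int = 30,
    birth: float = 1.0,
    death: float = 0.0,
    seed: int = 0,
    max_retries: int = 100,
) -> DatedSpeciesTree:
    """Birth-death tree conditioned on the extant taxon count.

    Forward Gillespie simulation from a single lineage until ``n_taxa``
    lineages are simultaneously extant (resampling on total extinction,
    bounded retries), followed by a final memoryless stretch to the
    present; extinct side-branches are pruned and ages normalized so
    the root sits at age 1.  Leaves are named ``T1..Tn``.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    for attempt in range(max_retries):
        rng = random.Random(substream(seed, "chrono", attempt))
        tree = _grow_birth_death(rng, n_taxa, birth, death)
        if tree is not None:
            return tree
    raise RuntimeError(
        f"birth-death simulation went extinct {max_retries} times; "
        "lower the death rate"
    )


def _grow_birth_death(
    rng: random.Random, n_taxa: int, birth: float, death: float
) -> Optional[DatedSpeciesTree]:
    # Times run forward from 0; converted to ages afterwards.
    root = TreeNode()
    start = {id(root): 0.0}
    alive = [root]
    t = 0.0
    while len(alive) != n_taxa:
        if not alive:
            return None
        rate = len(alive) * (birth + death)
        t += rng.expovariate(rate)
        node = alive[rng.randrange(len(alive))]
        if rng.random() < birth / (birth + death):
            c1, c2 = TreeNode(), TreeNode()
            node.add_child(c1)
            node.add_child(c2)
            start[id(c1)] = start[id(c2)] = t
            alive.remove(node)
            alive.extend([node.children[0], node.children[1]])
            # node's split time
            start[("split", id(node))] = t
        else:
            alive.remove(node)
            start[("death", id(node))] = t
    # stretch to the present so the last split is not at age 0
    t += rng.expovariate(max(len(alive), 1) * (birth + death))
    present = t

    def prune(node: TreeNode) -> Optional[TreeNode]:
        if not node.children:
            if node in alive:
                leaf = TreeNode()
                leaf.age = 0.0
                start[("age", id(leaf))] = 0.0
                return leaf
            return None
        kept = [prune(c) for c in node.children]
        kept = [k for k in kept if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        new = TreeNode()
        new.age = present - start[("split", id(node))]
        for k in kept:
            new.add_child(k)
        return new

    new_root = prune(root)
    if new_root is None or new_root.is_leaf:
        return None
    # assign names, lengths, normalize root age to 1
    scale = new_root.age
    if scale <= 0:
        return None
    counter = [0]
    for node in new_root.postorder():
        node.age /= scale
    for node in new_root.preorder():
        for c in node.children:
            c.length = node.age - c.age
        if node.is_leaf:
            counter[0] += 1
            node.name = f"T{counter[0]}"
    tree = DatedSpeciesTree(new_root)
    if len(tree.leaves) != n_taxa:
        return None
    return tree


# ---------------------------------------------------------------------------
# Gene families under duplication / transfer / loss
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTruth:
    """Ground-truth event history of one simulated gene family."""

    #: every event: dict(type, age, branch, donor, recipient)
    all_events: list = field(default_factory=list)
    #: gene-tree internal-node label -> "S" | "D" | "T" (visible events:
    #: both descendant copies survived)
    node_events: dict = field(default_factory=dict)
    #: internal-node label -> label of the derived child (new copy) for D/T
    derived_child: dict = field(default_factory=dict)
    #: donor/recipient species-branch info per visible transfer node
    transfer_edges: dict = field(default_factory=dict)
    n_resampled: int = 0

    def visible_count(self, etype: str) -> int:
        return sum(1 for e in self.node_events.values() if e == etype)


def simulate_dtl_family(
    tree: DatedSpeciesTree,
    dup_rate: float,
    transfer_rate: float,
    loss_rate: float,
    seed: int = 0,
    min_genes: int = 2,
    max_retries: int = 1000,
) -> tuple[GeneTree, SimulatedTruth]:
    """Evolve one gene family down the chronogram.

    Duplication copies a lineage in place, transfer regrafts a copy onto
    a uniformly chosen coexisting branch (donor excluded), loss
    terminates the lineage; speciations follow the species tree.  The
    returned gene tree contains only surviving lineages (pass-through
    nodes suppressed); the truth registry records every event plus the
    visible event labels of the surviving internal nodes.
    """
    n_resampled = 0
    for attempt in range(max_retries):
        rng = random.Random(substream(seed, "family", attempt))
        result = _evolve_family(tree, rng, dup_rate, transfer_rate, loss_rate)
        if result is not None:
            gene, truth = result
            if len(gene.leaves) >= min_genes:
                truth.n_resampled = n_resampled
                return gene, truth
        n_resampled += 1
    raise RuntimeError("could not simulate a surviving family; rates too lossy")


def _evolve_family(tree, rng, d, t, l):
    edges = [n for n in tree.nodes if n.parent is not None]
    meta: dict[int, tuple] = {}       # id(gene TreeNode) -> (etype, derived child id, extra)
    events: list[dict] = []
    counters: dict[str, int] = {}

    def alive_at(age: float) -> list:
        return [e for e in edges if e.age <= age < e.parent.age]

    def make_leaf(species: TreeNode) -> TreeNode:
        counters[species.name] = counters.get(species.name, 0) + 1
        leaf = TreeNode(f"{species.name}_{counters[species.name]}")
        leaf.age = 0.0
        return leaf

    def join(etype, age, a, b, derived, extra=None) -> Optional[TreeNode]:
        """Combine two child lineages; suppress the node unless both survive."""
        if a is None and b is None:
            return None
        if a is None or b is None:
            return a if b is None else b
        node = TreeNode()
        node.age = age
        node.add_child(a)
        node.add_child(b)
        meta[id(node)] = (etype, id(derived) if derived is not None else None, extra)
        return node

    total = d + t + l

    def evolve(edge: TreeNode, age: float) -> Optional[TreeNode]:
        while True:
            step = rng.expovariate(total) if total > 0 else math.inf
            nxt = age - step
            if nxt <= edge.age:
                if edge.is_leaf:
                    return make_leaf(edge)
                events.append(
                    {"type": "S", "age": edge.age, "branch": edge.label}
                )
                c1 = evolve(edge.children[0], edge.age)
                c2 = evolve(edge.children[1], edge.age)
                return join("S", edge.age, c1, c2, None)
            r = rng.random() * total
            if r < d:
                events.append({"type": "D", "age": nxt, "branch": edge.label})
                c1 = evolve(edge, nxt)
                c2 = evolve(edge, nxt)
                return join("D", nxt, c1, c2, c2)
            if r < d + t:
                recipients = [e for e in alive_at(nxt) if e is not edge]
                if recipients:
                    rec = recipients[rng.randrange(len(recipients))]
                    events.append(
                        {
                            "type": "T", "age": nxt, "branch": edge.label,
                            "donor": edge.label, "recipient": rec.label,
                        }
                    )
                    c1 = evolve(edge, nxt)
                    c2 = evolve(rec, nxt)
                    return join("T", nxt, c1, c2, c2, (edge.label, rec.label))
                continue
            events.append({"type": "L", "age": nxt, "branch": edge.label})
            return None

    root = tree.root
    events.append({"type": "S", "age": root.age, "branch": root.label})
    c1 = evolve(root.children[0], root.age)
    c2 = evolve(root.children[1], root.age)
    gene_root = join("S", root.age, c1, c2, None)
    if gene_root is None or gene_root.is_leaf:
        return None
    for node in gene_root.preorder():
        for c in node.children:
            c.length = node.age - c.age
    gene = GeneTree(gene_root)
    truth = SimulatedTruth(all_events=events)
    id_to_label = {id(n): n.label for n in gene.nodes}
    for node in gene.nodes:
        if node.is_leaf:
            continue
        etype, derived_id, extra = meta[id(node)]
        truth.node_events[node.label] = etype
        if derived_id is not None:
            truth.derived_child[node.label] = id_to_label[derived_id]
        if etype == "T" and extra is not None:
            truth.transfer_edges[node.label] = extra
    return gene, truth


# ---------------------------------------------------------------------------
# Neighborhoods and CHG content
# ---------------------------------------------------------------------------

@dataclass
class NeighborhoodSim:
    """Simulated genomic context for every extant gene of one family set."""

    annotation: AnnotationTable
    membership: dict                  # neighbor gene id -> CHG id
    chg_sets: dict                    # focal gene id -> set of CHG ids
    planted: list                     # PlantedAssociation registry


def _evolve_chg_sets(
    gene: GeneTree,
    truth: SimulatedTruth,
    retention: dict,
    pool: list[str],
    window: int,
    rng: random.Random,
) -> dict[str, set[str]]:
    """Evolve the 2w-CHG context down the gene tree.

    At each internal node the *derived* copy (new duplicate / regrafted
    transfer copy; a random side for speciations) retains each parental
    CHG with the event-specific probability and refills to 2w from the
    pool (without replacement within the window); the other child keeps
    the parental context.  This one-sided scheme makes the expected
    shared fraction across a single event equal the planted probability.
    """
    size = 2 * window
    if len(pool) < size:
        raise ValueError("CHG pool smaller than the neighborhood window")
    sets: dict[int, list[str]] = {}
    sets[gene.root.index] = rng.sample(sorted(pool), size)
    for node in gene.root.preorder():
        if node.is_leaf:
            continue
        event = truth.node_events.get(node.label, "S")
        p = retention[event]
        derived_label = truth.derived_child.get(node.label)
        if derived_label is None:
            derived_label = node.children[rng.randrange(2)].label
        parent_set = sets[node.index]
        for child in node.children:
            if child.label == derived_label and p < 1.0:
                kept = [c for c in parent_set if rng.random() < p]
                # refill with novel context: dropped CHGs are not redrawn,
                # so the expected shared fraction across one event equals p
                available = sorted(set(pool) - set(parent_set))
                kept += rng.sample(available, size - len(kept))
                sets[child.index] = kept
            else:
                sets[child.index] = list(parent_set)
    return {leaf.name: set(sets[leaf.index]) for leaf in gene.leaves}


def simulate_neighborhoods(
    gene: GeneTree,
    truth: SimulatedTruth,
    cfg: SimConfig,
    seed: Optional[int] = None,
) -> NeighborhoodSim:
    """Simulated annotation + CHG membership for one family's extant genes."""
    rng = random.Random(substream(cfg.seed if seed is None else seed, "nbhd"))
    pool = [f"ch{i + 1}" for i in range(cfg.chg_pool)]
    chg_sets = _evolve_chg_sets(
        gene, truth, cfg.retention, pool, cfg.window, rng
    )
    size = 2 * cfg.window
    planted_ids = {pa.chg for pa in cfg.planted}
    for pa in cfg.planted:
        for leaf in gene.leaves:
            p = pa.p_in if leaf.name in pa.clade_leaves else pa.p_out
            s = chg_sets[leaf.name]
            if rng.random() < p:
                if pa.chg not in s:
                    # keep the context within the 2w window: the planted
                    # CHG displaces a random background member
                    if len(s) >= size:
                        background = sorted(s - planted_ids)
                        s.discard(background[rng.randrange(len(background))])
                    s.add(pa.chg)
            else:
                s.discard(pa.chg)
    records = []
    membership = {}
    for leaf in sorted(gene.leaves, key=lambda n: n.name):
        focal = leaf.name
        scaffold = f"scf_{focal}"
        chgs = sorted(chg_sets[focal])
        half = len(chgs) // 2
        order = chgs[:half] + [None] + chgs[half:]
        for pos, chg in enumerate(order):
            start = 1000 * (pos + 1)
            if chg is None:
                records.append((focal, scaffold, start, start + 500, "+"))
            else:
                nid = f"{focal}|{chg}"
                membership[nid] = chg
                records.append((nid, scaffold, start, start + 500, "+"))
    return NeighborhoodSim(
        annotation=AnnotationTable.from_records(records),
        membership=membership,
        chg_sets=chg_sets,
        planted=list(cfg.planted),
    )


# ---------------------------------------------------------------------------
# Retention study generators
# ---------------------------------------------------------------------------

@dataclass
class RetentionStudy:
    """Gene pairs straddling single events, for retention estimation."""

    families: list                    # (GeneTree, event type) pairs
    chg_sets: dict                    # gene id -> set of CHG ids


def simulate_retention_pairs(
    cfg: SimConfig,
    n_per_class: int = 40,
    seed: Optional[int] = None,
) -> RetentionStudy:
    """Two-member families, each straddling exactly one labeled event.

    The shared-neighborhood statistic across a node convolves retention
    over every branch between the two leaves, so event-specific
    probabilities are identifiable only from single-event pairs; this
    generator provides them (one cherry per family, one event per
    cherry, one-sided retention with refill).
    """
    rng = random.Random(substream(cfg.seed if seed is None else seed, "retpairs"))
    pool = [f"ch{i + 1}" for i in range(cfg.chg_pool)]
    size = 2 * cfg.window
    families = []
    chg_sets: dict[str, set[str]] = {}
    i = 0
    for event in ("S", "D", "T"):
        p = cfg.retention[event]
        for _ in range(n_per_class):
            i += 1
            a, b = f"fam{i}_a", f"fam{i}_b"
            root = TreeNode()
            root.add_child(TreeNode(a, 1.0))
            root.add_child(TreeNode(b, 1.0))
            tree = GeneTree(root, species_map={a: a, b: b})
            parent_set = rng.sample(pool, size)
            kept = [c for c in parent_set if rng.random() < p]
            available = sorted(set(pool) - set(parent_set))
            kept += rng.sample(available, size - len(kept))
            chg_sets[a] = set(parent_set)
            chg_sets[b] = set(kept)
            families.append((tree, event))
    return RetentionStudy(families=families, chg_sets=chg_sets)


def simulate_retention_decay(
    cfg: SimConfig,
    depth: int = 12,
    r0: float = 0.9,
    step: float = 0.06,
    seed: Optional[int] = None,
) -> tuple[GeneTree, dict[str, set[str]]]:
    """A caterpillar family whose context retention decays with node depth.

    The node at depth k shares a fraction of roughly ``max(r0 - step*k,
    0.05)`` of its context across its children, planting a negative
    correlation between retention and topological depth.
    """
    rng = random.Random(substream(cfg.seed if seed is None else seed, "retdecay"))
    pool = [f"ch{i + 1}" for i in range(cfg.chg_pool)]
    size = 2 * cfg.window

    def subsample(s: Sequence[str], p: float) -> set[str]:
        kept = [c for c in s if rng.random() < p]
        available = sorted(set(pool) - set(s))
        kept += rng.sample(available, size - len(kept))
        return set(kept)

    chg_sets: dict[str, set[str]] = {}
    root = TreeNode()
    node = root
    current = rng.sample(pool, size)
    for k in range(depth):
        p = max(r0 - step * k, 0.05)
        leaf = TreeNode(f"cat{k}_x", 1.0)
        chg_sets[leaf.name] = subsample(current, p)
        node.add_child(leaf)
        if k == depth - 1:
            last = TreeNode(f"cat{k}_y", 1.0)
            chg_sets[last.name] = subsample(current, p)
            node.add_child(last)
        else:
            inner = TreeNode()
            inner.length = 1.0
            node.add_child(inner)
            current = sorted(subsample(current, p))
            node = inner
    smap = {name: name for name in chg_sets}
    return GeneTree(root, species_map=smap), chg_sets


# ---------------------------------------------------------------------------
# Gene structures (exons / junctions / alignment)
# ---------------------------------------------------------------------------

@dataclass
class GeneStructureSim:
    """Gene models + alignment with known junction ground truth."""

    models: dict                      # gene id -> GeneModel
    alignment: Alignment
    #: gene id -> set of (core position, phase) junctions
    junctions: dict
    #: (clade leaf frozenset, core position, phase) planted gains
    planted: list
    #: core position -> alignment column
    core_columns: list


def simulate_gene_structures(
    gene: GeneTree,
    cfg: SimConfig,
    seed: Optional[int] = None,
    planted_clades: Optional[list] = None,
    intron_length: int = 60,
) -> GeneStructureSim:
    """Evolve intron/exon junctions along the gene tree and emit gene
    models plus a gapped protein alignment with known row-column maps.

    The alignment has a fully occupied core (one column per core
    position, where all junctions live) interleaved with low-occupancy
    insert columns owned by random row subsets; consensus columns at the
    default 70% threshold are exactly the core.  Plus- and minus-strand
    gene models alternate so strand handling is exercised.
    """
    rng = random.Random(substream(cfg.seed if seed is None else seed, "genestruct"))
    leaves = [l.name for l in gene.leaves]
    core = cfg.protein_core

    # ancestral junctions and their evolution along the tree
    anc = set()
    while len(anc) < cfg.n_ancestral_junctions:
        anc.add((rng.randrange(1, core - 1), rng.randrange(3)))
    junctions: dict[int, set] = {gene.root.index: set(anc)}
    for node in gene.root.preorder():
        if node.is_leaf:
            continue
        for child in node.children:
            j = {x for x in junctions[node.index] if rng.random() >= cfg.junction_loss}
            for pos in range(1, core - 1):
                if rng.random() < cfg.junction_gain:
                    j.add((pos, rng.randrange(3)))
            junctions[child.index] = j
    leaf_junctions = {l.name: set(junctions[l.index]) for l in gene.leaves}

    planted = []
    for clade in planted_clades or []:
        pos = rng.randrange(1, core - 1)
        phase = rng.randrange(3)
        planted.append((frozenset(clade), pos, phase))
        for name in leaves:
            if name in clade:
                leaf_junctions[name] = {
                    (p, ph) for p, ph in leaf_junctions[name] if p != pos
                }
                leaf_junctions[name].add((pos, phase))
            else:
                leaf_junctions[name] = {
                    (p, ph) for p, ph in leaf_junctions[name] if p != pos
                }

    # alignment: core columns (all rows) + insert columns (few rows)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    columns = []                      # (kind, owners)
    core_columns = []
    for pos in range(core):
        if rng.random() < cfg.insert_col_prob:
            owners = {
                l for l in leaves if rng.random() < cfg.insert_owner_frac
            }
            columns.append(("insert", owners))
        core_columns.append(len(columns))
        columns.append(("core", None))
    rows = {}
    for name in leaves:
        chars = []
        for kind, owners in columns:
            if kind == "core" or name in owners:
                chars.append(alphabet[rng.randrange(len(alphabet))])
            else:
                chars.append("-")
        rows[name] = "".join(chars)
    alignment = Alignment(leaves, [rows[n] for n in leaves])

    # gene models: junction core positions -> leaf residue indices -> exons
    models = {}
    for idx, name in enumerate(leaves):
        row = rows[name]
        residue_of_col = {}
        r = 0
        for j, ch in enumerate(row):
            if ch != "-":
                residue_of_col[j] = r
                r += 1
        protein_len = r
        offsets = sorted(
            3 * residue_of_col[core_columns[pos]] + phase
            for pos, phase in leaf_junctions[name]
        )
        strand = "+" if idx % 2 == 0 else "-"
        exon_lengths = []
        prev = 0
        for off in offsets + [3 * protein_len]:
            exon_lengths.append(off - prev)
            prev = off
        exons = []
        cursor = 100
        for ln in exon_lengths:
            exons.append((cursor, cursor + ln))
            cursor += ln + intron_length
        if strand == "-":
            span = cursor
            exons = [(span - e, span - s) for s, e in reversed(exons)]
        models[name] = GeneModel(gene_id=name, strand=strand, exons=exons)
    return GeneStructureSim(
        models=models,
        alignment=alignment,
        junctions=leaf_junctions,
        planted=planted,
        core_columns=core_columns,
    )


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

def simulate_hit_table(
    families: dict[str, list[str]],
    seed: int = 0,
    noise_density: float = 0.02,
    dropout: float = 0.0,
) -> HitTable:
    """Block-structured all-vs-all similarity table.

    Within-family hits are reciprocal with E ~ log-uniform
    [1e-180, 1e-30] and coverage ~ U(0.6, 1.0); between-family noise
    hits (density per ordered pair) have E ~ log-uniform [1e-8, 1e-2].
    ``dropout`` removes individual directed hits, exercising the
    bidirectional filter.
    """
    if len(families) < 2:
        raise ValueError("need at least 2 families")
    rng = random.Random(substream(seed, "hits"))
    genes = [g for fam in sorted(families) for g in families[fam]]
    fam_of = {g: fam for fam, members in families.items() for g in members}
    lengths = {g: rng.randint(300, 500) for g in genes}
    rows = []

    def add_hit(q, s, evalue, cov):
        maxlen = max(lengths[q], lengths[s])
        aln = max(1, int(round(cov * maxlen)))
        rows.append(
            (
                q, s, round(rng.uniform(30, 95), 1), aln, 0, 0,
                1, aln, 1, aln, evalue, round(aln * 1.9, 1),
                lengths[q], lengths[s],
            )
        )

    for i, q in enumerate(genes):
        for s in genes[i + 1:]:
            if fam_of[q] == fam_of[s]:
                cov = rng.uniform(0.6, 1.0)
                for a, b in ((q, s), (s, q)):
                    if rng.random() >= dropout:
                        add_hit(a, b, 10 ** rng.uniform(-180, -30), cov)
            else:
                for a, b in ((q, s), (s, q)):
                    if rng.random() < noise_density:
                        add_hit(a, b, 10 ** rng.uniform(-8, -2), rng.uniform(0.3, 0.9))
    df = pd.DataFrame(
        rows,
        columns=[
            "query", "subject", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore",
            "qlen", "slen",
        ],
    )
    df["coverage"] = df["length"] / df[["qlen", "slen"]].max(axis=1)
    df["coverage"] = df["coverage"].clip(upper=1.0)
    return HitTable(df)
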