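"""End-to-end orchestration: simulate or load inputs, then run the
clustering, reconciliation, synteny and gene-structure stages and write
the report bundle (plain TSV/JSON, byte-reproducible under a fixed seed).

Stages degrade gracefully: inputs that are unavailable cause the
dependent stages to be skipped with a notice in the manifest, never a
failure.  In simulate mode the generator's ground truth doubles as the
clustering stage's validation reference.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .clustering import build_similarity_graph, define_chgs, inflation_sweep, mcl_cluster
from .io_formats import (
    read_annotation,
    read_hits,
    read_tree,
    write_tree,
)
from .reconciliation import (
    CostScheme,
    SlicedTree,
    call_transfers,
    event_support,
    events_table,
    sample_optima,
    summarize_events_on_species,
    transfer_report,
)
from .synteny import (
    association_table,
    clade_chg_scan,
    extract_neighborhoods,
    neighborhood_retention,
    retention_by_event,
    retention_table,
)
from .gene_structure import (
    cds_junctions,
    junction_clade_features,
    junction_column_counts,
    junctions_to_columns,
)
from .synthetic_data import (
    PlantedAssociation,
    SimConfig,
    simulate_chronogram,
    simulate_dtl_family,
    simulate_gene_structures,
    simulate_hit_table,
    simulate_neighborhoods,
    substream,
)
from .trees import GeneTree, TreeNode

log = logging.getLogger("synterec.pipeline")


@dataclass
class PipelineConfig:
    """Either a SimConfig (simulate mode) or real-input paths, plus the
    analysis parameters shared by both modes."""

    sim: Optional[SimConfig] = None
    species_tree_path: Optional[str] = None
    gene_tree_paths: list = field(default_factory=list)
    annotation_path: Optional[str] = None
    hits_path: Optional[str] = None
    out_dir: str = "synterec_out"
    seed: int = 0
    # reconciliation
    dup_cost: float = 4.0
    transfer_costs: tuple = (5, 10, 15, 20)
    loss_costs: tuple = (1, 2, 3)
    n_samples: int = 100
    report_transfer_cost: float = 10.0
    report_loss_cost: float = 1.0
    # clustering / scan
    inflation: float = 1.4
    min_chg: int = 10
    min_clade: int = 5
    alpha: float = 1e-4
    window: int = 20
    retention_mode: str = "min"
    occupancy: float = 0.7
    # simulate-mode extras
    n_cluster_chgs: int = 12
    max_chg_members: int = 15
    auto_plant: bool = True

    def __post_init__(self) -> None:
        real = self.species_tree_path or self.gene_tree_paths
        if self.sim is not None and real:
            raise ValueError(
                "config must carry either a SimConfig or real-input paths, not both"
            )


def _namespace_family(gene: GeneTree, prefix: str) -> GeneTree:
    """Copy a family's gene tree with leaf names prefixed, so several
    families can share one report namespace without id collisions."""

    def copy(node: TreeNode) -> TreeNode:
        new = TreeNode(
            f"{prefix}|{node.name}" if node.is_leaf else None, node.length
        )
        for c in node.children:
            new.add_child(copy(c))
        return new

    smap = {
        f"{prefix}|{leaf}": sp for leaf, sp in gene.species_map.items()
    }
    return GeneTree(copy(gene.root), species_map=smap)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages the available inputs permit; returns the manifest.

    Reports written to ``cfg.out_dir``: events.tsv, transfers.tsv,
    branch_summary.tsv, associations.tsv, retention.tsv,
    junction_counts.tsv, species_tree.nwk (simulate mode) and
    manifest.json.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "mode": "simulate" if cfg.sim is not None else "files",
        "parameters": {
            "dup_cost": cfg.dup_cost,
            "transfer_costs": list(cfg.transfer_costs),
            "loss_costs": list(cfg.loss_costs),
            "n_samples": cfg.n_samples,
            "inflation": cfg.inflation,
            "min_chg": cfg.min_chg,
            "min_clade": cfg.min_clade,
            "alpha": cfg.alpha,
            "window": cfg.window,
            "retention_mode": cfg.retention_mode,
            "occupancy": cfg.occupancy,
        },
        "stages": {},
        "skipped": [],
    }

    t0 = time.time()
    if cfg.sim is not None:
        _run_simulate(cfg, out, manifest)
    else:
        _run_files(cfg, out, manifest)
    manifest["wall_seconds"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return manifest


def _stage(manifest, name):
    log.info("stage %s", name)
    start = time.time()

    def done(**info):
        manifest["stages"][name] = {
            "seconds": round(time.time() - start, 2),
            **info,
        }

    return done


def _write_tsv(df, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _run_simulate(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    sim = cfg.sim
    seed = substream(cfg.seed, "pipeline", sim.seed)

    done = _stage(manifest, "simulate")
    species = simulate_chronogram(
        sim.n_taxa, sim.birth, sim.death, seed=substream(seed, "species")
    )
    write_tree(species, str(out / "species_tree.nwk"))
    sliced = SlicedTree(species)
    families = []
    for i in range(sim.n_families):
        g, truth = simulate_dtl_family(
            species,
            sim.dup_rate,
            sim.transfer_rate,
            sim.loss_rate,
            seed=substream(seed, "family", i),
        )
        families.append((f"fam{i}", _namespace_family(g, f"fam{i}"), truth))
    done(n_taxa=sim.n_taxa, n_families=len(families))

    # ---- reconciliation ---------------------------------------------------
    done = _stage(manifest, "reconciliation")
    costs = CostScheme(
        dup=cfg.dup_cost,
        transfer=cfg.report_transfer_cost,
        loss=cfg.report_loss_cost,
    )
    all_events = []
    recs_by_family = []
    modal_events: dict[str, dict[str, str]] = {}
    grids = []
    for fam_id, g, truth in families:
        recs = sample_optima(
            g, sliced, costs, n=cfg.n_samples, seed=substream(seed, "recs", fam_id)
        )
        recs_by_family.append(recs)
        ev = events_table(recs[:1], sample_ids=[fam_id])
        all_events.append(ev)
        tally: dict[str, dict[str, int]] = {}
        for rec in recs:
            for label, e in rec.events.items():
                tally.setdefault(label, {}).setdefault(e.event, 0)
                tally[label][e.event] += 1
        modal_events[fam_id] = {
            label: min(c.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            for label, c in tally.items()
        }
        grid = event_support(
            g,
            sliced,
            dup=cfg.dup_cost,
            thetas=cfg.transfer_costs,
            losses=cfg.loss_costs,
            n=cfg.n_samples,
            seed=substream(seed, "grid", fam_id),
            tree_id=fam_id,
        )
        grids.append(grid)
    import pandas as pd

    _write_tsv(pd.concat(all_events, ignore_index=True), out / "events.tsv")
    calls = call_transfers(
        grids, report_loss=cfg.report_loss_cost
    )
    _write_tsv(transfer_report(calls), out / "transfers.tsv")
    summary = summarize_events_on_species(recs_by_family, sliced)
    _write_tsv(summary, out / "branch_summary.tsv")
    done(n_transfer_calls=len(calls))

    # ---- neighborhoods + planted association ------------------------------
    done = _stage(manifest, "neighborhoods")
    plant_cfg = sim
    if cfg.auto_plant and not sim.planted:
        for fam_id, g, truth in families:
            # prefer a clade well under half the family so the 2x2 contrast
            # has power under Bonferroni
            node = next(
                (
                    n
                    for n in g.nodes
                    if not n.is_leaf
                    and cfg.min_clade * 2
                    <= len(n.leaves())
                    <= max(cfg.min_clade * 2, (2 * len(g.leaves)) // 5)
                ),
                None,
            )
            if node is not None:
                clade = frozenset(l.name for l in node.leaves())
                plant_cfg = SimConfig(**{**sim.__dict__})
                plant_cfg.planted = [
                    PlantedAssociation(clade, "chP1", 0.95, 0.05)
                ]
                manifest["planted_association"] = {
                    "family": fam_id,
                    "clade": node.label,
                    "n_leaves": len(clade),
                }
                break
    neighborhoods = {}
    memberships: dict[str, str] = {}
    chg_sets_all: dict[str, set] = {}
    for fam_id, g, truth in families:
        nsim = simulate_neighborhoods(
            g, truth, plant_cfg, seed=substream(seed, "nbhd", fam_id)
        )
        nbs = extract_neighborhoods(
            nsim.annotation, sorted(nsim.chg_sets), w=cfg.window
        )
        for nb in nbs:
            nb.with_membership(nsim.membership)
        neighborhoods[fam_id] = nbs
        memberships.update(nsim.membership)
        chg_sets_all.update(nsim.chg_sets)
    done(n_genes=len(chg_sets_all))

    # ---- clustering validation on a hit-table subset ----------------------
    done = _stage(manifest, "clustering")
    member_genes: dict[str, list] = {}
    for gene_id, chg in sorted(memberships.items()):
        member_genes.setdefault(chg, []).append(gene_id)
    big = sorted(
        (chg for chg, m in member_genes.items() if len(m) >= cfg.min_chg),
        key=lambda c: (-len(member_genes[c]), c),
    )[: cfg.n_cluster_chgs]
    if len(big) >= 2:
        fams_for_hits = {
            chg: member_genes[chg][: cfg.max_chg_members] for chg in big
        }
        hits = simulate_hit_table(
            fams_for_hits, seed=substream(seed, "hits"),
            noise_density=sim.hit_noise_density, dropout=sim.hit_dropout,
        )
        graph = build_similarity_graph(hits)
        clustering = mcl_cluster(graph, inflation=cfg.inflation)
        chgs = define_chgs(clustering, min_size=min(cfg.min_chg, cfg.max_chg_members))
        truth_parts = {frozenset(m) for m in fams_for_hits.values()}
        recovered = {frozenset(c.members) for c in chgs}
        sweep = inflation_sweep(graph)
        done(
            n_chgs=len(chgs),
            exact_recovery=truth_parts == recovered,
            silhouette_by_inflation={
                str(k): round(float(v), 4) for k, v in sweep.items()
            },
        )
    else:
        manifest["skipped"].append("clustering: fewer than 2 CHGs of min size")
        done(skipped=True)

    # ---- association scan -------------------------------------------------
    done = _stage(manifest, "association_scan")
    results = []
    for fam_id, g, truth in families:
        nbs = neighborhoods[fam_id]
        chg_universe = sorted(
            {c for nb in nbs for c in nb.chg_presence if c.startswith("chP")}
        )
        if not chg_universe or len(g.leaves) < cfg.min_clade:
            continue
        res = clade_chg_scan(
            g, nbs, chg_universe, min_clade=cfg.min_clade, alpha=cfg.alpha
        )
        df = association_table(res)
        df.insert(0, "family", fam_id)
        results.append(df)
    if results:
        scan_df = pd.concat(results, ignore_index=True)
        _write_tsv(scan_df, out / "associations.tsv")
        done(
            n_tests=len(scan_df),
            n_reported=int(scan_df["reported"].sum()),
        )
    else:
        manifest["skipped"].append("association_scan: no planted CHGs present")
        done(skipped=True)

    # ---- retention by event -----------------------------------------------
    done = _stage(manifest, "retention")
    records = []
    for fam_id, g, truth in families:
        recs = neighborhood_retention(
            g, chg_sets_all, mode=cfg.retention_mode
        )
        for r in recs:
            r.event = modal_events[fam_id].get(r.node)
            r.node = f"{fam_id}|{r.node}"
        records.extend(recs)
    ret_summary = retention_by_event(records)
    _write_tsv(retention_table(records), out / "retention.tsv")
    done(
        means={k: round(float(v), 4) for k, v in ret_summary.means.items()},
        ranksum_p={
            f"{a}v{b}": float(v) for (a, b), v in ret_summary.ranksum_p.items()
        },
        depth_rho=None
        if ret_summary.depth_rho != ret_summary.depth_rho
        else round(float(ret_summary.depth_rho), 4),
    )

    # ---- gene structure ---------------------------------------------------
    done = _stage(manifest, "gene_structure")
    fam_id, g, truth = families[0]
    clade_node = next(
        (
            n
            for n in g.nodes
            if not n.is_leaf
            and cfg.min_clade * 2
            <= len(n.leaves())
            <= max(cfg.min_clade * 2, (2 * len(g.leaves)) // 5)
        ),
        None,
    ) or next(
        (
            n
            for n in g.nodes
            if not n.is_leaf
            and cfg.min_clade <= len(n.leaves()) <= len(g.leaves) // 2
        ),
        None,
    )
    planted_clades = (
        [{l.name for l in clade_node.leaves()}] if clade_node is not None else []
    )
    gs = simulate_gene_structures(
        g, sim, seed=substream(seed, "struct"), planted_clades=planted_clades
    )
    maps = [
        junctions_to_columns(
            cds_junctions(gs.models[l.name]), l.name, gs.alignment, cfg.occupancy
        )
        for l in g.leaves
    ]
    counts = junction_column_counts(maps, gs.alignment, cfg.occupancy)
    counts.rename_axis("consensus_column").reset_index().to_csv(
        out / "junction_counts.tsv", sep="\t", index=False
    )
    features = junction_clade_features(maps, g)
    from .synteny import Neighborhood

    positions = sorted({p for f in features.values() for p in f})
    if positions and len(g.leaves) >= cfg.min_clade:
        nbs = [
            Neighborhood(
                l.name,
                [],
                {f"j{p}" for p, v in features[l.name].items() if v},
            )
            for l in g.leaves
        ]
        res = clade_chg_scan(
            g, nbs, [f"j{p}" for p in positions],
            min_clade=cfg.min_clade, alpha=cfg.alpha,
        )
        df = association_table(res)
        df.insert(0, "family", fam_id)
        _write_tsv(df, out / "junction_associations.tsv")
        done(n_positions=len(positions), n_reported=int(df["reported"].sum()))
    else:
        manifest["skipped"].append("gene_structure scan: no junction features")
        done(skipped=True)


def _run_files(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    import pandas as pd

    if cfg.species_tree_path is None:
        raise ValueError("file mode needs a species tree path")
    species = read_tree(cfg.species_tree_path, kind="species")
    sliced = SlicedTree(species)
    genes = []
    for i, path in enumerate(cfg.gene_tree_paths):
        genes.append((f"tree{i}", read_tree(path, kind="gene", species_tree=species)))
    if not genes:
        raise ValueError("file mode needs at least one gene tree")

    done = _stage(manifest, "reconciliation")
    costs = CostScheme(
        dup=cfg.dup_cost,
        transfer=cfg.report_transfer_cost,
        loss=cfg.report_loss_cost,
    )
    grids = []
    all_events = []
    recs_by_tree = []
    for tree_id, g in genes:
        recs = sample_optima(
            g, sliced, costs, n=cfg.n_samples,
            seed=substream(cfg.seed, "recs", tree_id),
        )
        recs_by_tree.append(recs)
        all_events.append(events_table(recs[:1], sample_ids=[tree_id]))
        grids.append(
            event_support(
                g, sliced, dup=cfg.dup_cost, thetas=cfg.transfer_costs,
                losses=cfg.loss_costs, n=cfg.n_samples,
                seed=substream(cfg.seed, "grid", tree_id), tree_id=tree_id,
            )
        )
    _write_tsv(pd.concat(all_events, ignore_index=True), out / "events.tsv")
    calls = call_transfers(grids, report_loss=cfg.report_loss_cost)
    _write_tsv(transfer_report(calls), out / "transfers.tsv")
    _write_tsv(
        summarize_events_on_species(recs_by_tree, sliced),
        out / "branch_summary.tsv",
    )
    done(n_transfer_calls=len(calls))

    if cfg.hits_path and cfg.annotation_path:
        done = _stage(manifest, "clustering_scan")
        hits = read_hits(cfg.hits_path)
        graph = build_similarity_graph(hits)
        clustering = mcl_cluster(graph, inflation=cfg.inflation)
        chgs = define_chgs(clustering, min_size=cfg.min_chg)
        membership = {g_: c.id for c in chgs for g_ in c.members}
        ann = read_annotation(cfg.annotation_path)
        tree_id, g = genes[0]
        focal = [l.name for l in g.leaves]
        nbs = extract_neighborhoods(ann, focal, w=cfg.window)
        for nb in nbs:
            nb.with_membership(membership)
        res = clade_chg_scan(
            g, nbs, [c.id for c in chgs],
            min_clade=cfg.min_clade, alpha=cfg.alpha,
        )
        _write_tsv(association_table(res), out / "associations.tsv")
        chg_sets = {nb.focal: nb.chg_presence for nb in nbs}
        records = neighborhood_retention(g, chg_sets, mode=cfg.retention_mode)
        _write_tsv(retention_table(records), out / "retention.tsv")
        done(n_chgs=len(chgs))
    else:
        manifest["skipped"].append(
            "clustering/synteny: hit table or annotation not supplied"
        )
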