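"""One-shot orchestration of the full analysis.

``run_all`` executes align -> differential (3 pairs) -> F-ratio/LDA ->
AGNES -> remodeling -> PPI overlay -> subnetwork enrichment on either
simulated or on-disk inputs, writes every stage's table and returns a
machine-readable summary.  The summary of a composed run equals the outputs
of the individual stages on the same config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import align as al
from . import differential as diff
from . import discriminant as disc
from . import network as net
from . import remodeling as rem
from .io import (
    StudyDesign,
    read_design,
    read_ppi_edges,
    read_protein_list,
    write_design,
    write_network_export,
    write_ppi_edges,
    write_protein_list,
)
from .simulate import GeneratorConfig, generate_ppi_fixture, generate_study

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Thresholds, paths and the seed that fully determine one analysis."""

    out_dir: str = "spcpipe_out"
    seed: int = 0
    simulate: bool = True
    protein_list_dir: str | None = None
    design_path: str | None = None
    ppi_edges_path: str | None = None
    memberships_path: str | None = None
    dave_min: float = diff.DAVE_MIN
    dci_min: float = diff.DCI_MIN
    f_min: float = disc.F_MIN
    p_max: float = disc.P_MAX
    pri_range: tuple[float, float] = rem.PRI_RANGE
    pai_range: tuple[float, float] = rem.PAI_RANGE
    dci_exclusion: float = rem.DCI_EXCLUSION
    perturbation_null: float = rem.PERTURBATION_NULL
    score_min: float = net.SCORE_MIN
    metric: str = "dave"
    group_genes: bool = True
    generator: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (0 <= self.dave_min <= 2):
            raise ValueError("dave_min must lie in [0, 2]")
        if self.f_min < 0 or not (0 < self.p_max <= 1):
            raise ValueError("invalid descriptor thresholds")
        if not (0 <= self.score_min <= 1):
            raise ValueError("score_min must lie in [0, 1]")


def _load_inputs(config: PipelineConfig, out: Path):
    if config.simulate:
        gen = GeneratorConfig(seed=config.seed, **config.generator)
        run_tables, design, truth = generate_study(gen)
        sim_dir = out / "simulated"
        sim_dir.mkdir(parents=True, exist_ok=True)
        write_design(design, sim_dir / "design.tsv")
        for rt in run_tables:
            write_protein_list(rt, sim_dir / f"{rt.run_id}.tsv")
        truth.proteins.to_csv(sim_dir / "truth.tsv", sep="\t")
        return run_tables, design, truth
    if not (config.protein_list_dir and config.design_path):
        raise FileNotFoundError(
            "protein_list_dir and design_path are required when simulate=False"
        )
    design = read_design(config.design_path)
    list_dir = Path(config.protein_list_dir)
    run_tables = []
    for run_id in design.run_ids:
        path = list_dir / f"{run_id}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"protein list for run {run_id} not found: {path}")
        run_tables.append(read_protein_list(path, run_id=run_id))
    return run_tables, design, None


def run_all(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the summary dict written to
    ``summary.json`` in the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    run_tables, design, truth = _load_inputs(config, out)
    matrix = al.align_runs(run_tables, design)
    if config.group_genes:
        matrix = al.group_by_gene(matrix)
    matrix.spc.rename_axis("accession").to_csv(out / "spc_runs.tsv", sep="\t")
    matrix.spc_star_condition.rename_axis("accession").to_csv(
        out / "spc_star_condition.tsv", sep="\t"
    )

    venn = al.venn_partition(matrix)
    venn_rows = [
        {"region": "+".join(sorted(key)), "size": len(members)}
        for key, members in venn.regions.items()
    ]
    pd.DataFrame(venn_rows).to_csv(out / "venn_regions.tsv", sep="\t", index=False)

    conditions = matrix.conditions
    pairs = [
        (conditions[0], conditions[1]),
        (conditions[1], conditions[2]),
        (conditions[0], conditions[2]),
    ]
    diff_tables: dict[str, pd.DataFrame] = {}
    dep_set: set[str] = set()
    for cond_a, cond_b in pairs:
        table = diff.differential_table(
            matrix, cond_a, cond_b, dave_min=config.dave_min, dci_min=config.dci_min
        )
        name = f"{cond_a}_vs_{cond_b}"
        diff_tables[name] = table
        table.to_csv(out / f"differential_{name}.tsv", sep="\t")
        dep_set |= set(table.index[table["call"] != "unchanged"])

    descriptors, f_stats = disc.f_ratio_select(
        matrix, f_min=config.f_min, p_max=config.p_max
    )
    f_stats.to_csv(out / "descriptors.tsv", sep="\t")
    lda_result = disc.lda_fit(matrix, descriptors) if descriptors else None
    tree = disc.agnes_cluster(matrix, descriptors or None)
    (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
    tree.merge_table().to_csv(out / "merge_table.tsv", sep="\t", index=False)

    remodel = rem.remodeling_table(
        matrix,
        metric=config.metric,
        pri_range=config.pri_range,
        pai_range=config.pai_range,
        perturbation_null=config.perturbation_null,
        dci_exclusion=config.dci_exclusion,
    )
    remodel.to_csv(out / "remodeling.tsv", sep="\t")

    if config.ppi_edges_path:
        edges = read_ppi_edges(config.ppi_edges_path, score_min=config.score_min)
        memberships = (
            pd.read_csv(config.memberships_path, sep="\t")
            if config.memberships_path
            else None
        )
    else:
        node_pool = sorted(set(descriptors) | dep_set)
        edges, memberships, _ = generate_ppi_fixture(
            n_nodes=max(len(node_pool), 25), seed=config.seed
        )
        # relabel fixture nodes onto the analysis proteins
        rename = dict(zip(sorted(set(edges["protein_a"]) | set(edges["protein_b"])), node_pool))
        edges = edges.assign(
            protein_a=edges["protein_a"].map(rename),
            protein_b=edges["protein_b"].map(rename),
        ).dropna()
        memberships = memberships.assign(node=memberships["node"].map(rename)).dropna()
        write_ppi_edges(edges, out / "ppi_edges.tsv")
        memberships.to_csv(out / "memberships.tsv", sep="\t", index=False)

    node_set = set(descriptors) | dep_set
    graph = net.build_graph(edges, node_set=node_set, score_min=config.score_min)
    remodel_candidates = set(remodel.index[remodel["remodel_class"] != "none"])
    enrichment = pd.DataFrame()
    if graph.number_of_nodes():
        net.overlay_differential(
            graph,
            diff_tables,
            remodeling=remodel,
            spc_star=matrix.spc_star_condition,
        )
        write_network_export(graph, out)
        if memberships is not None:
            enrichment = net.subnetwork_enrichment(
                graph, memberships, remodel_candidates & set(graph.nodes)
            )
            enrichment.to_csv(out / "enrichment.tsv", sep="\t")

    classes = remodel["remodel_class"]
    summary = {
        "seed": config.seed,
        "n_proteins": int(len(matrix.proteins)),
        "n_runs": len(design),
        "venn_union": venn.union_size,
        "venn_marginals": {c: venn.marginal(c) for c in conditions},
        "n_dep": len(dep_set),
        "dep_counts": {
            name: {"n_up": t.attrs["n_up"], "n_down": t.attrs["n_down"]}
            for name, t in diff_tables.items()
        },
        "n_descriptors": len(descriptors),
        "lda_training_accuracy": (
            lda_result.training_accuracy if lda_result else None
        ),
        "agglomerative_coefficient": tree.agglomerative_coefficient,
        "n_recovered": int((classes == "recovered").sum()),
        "n_activated": int((classes == "activated").sum()),
        "n_inhibited": int((classes == "inhibited").sum()),
        "n_remodel_significant": int(
            remodel.loc[classes != "none", "significant"].sum()
        )
        if "significant" in remodel
        else 0,
        "network_nodes": graph.number_of_nodes(),
        "network_edges": graph.number_of_edges(),
        "n_enriched_subnetworks": int(enrichment["enriched"].sum())
        if len(enrichment)
        else 0,
        "config": {
            key: value
            for key, value in asdict(config).items()
            if key != "generator"
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
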