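"""Readers and writers for every external representation the pipeline touches.

All delimited files are tab-separated UTF-8 with a mandatory header row.
Column names are matched case-insensitively against configurable aliases, so
exports from different search engines can be ingested without editing files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

from ._errors import FormatError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "RunTable",
    "StudyDesign",
    "read_protein_list",
    "write_protein_list",
    "read_design",
    "write_design",
    "read_ppi_edges",
    "write_ppi_edges",
    "write_network_export",
    "read_sif",
    "read_node_attributes",
]

#: default aliases, matched case-insensitively, for protein-list columns
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "accession": ("accession", "acc", "protein", "protein_id"),
    "score": ("score", "protein_score"),
    "spc": ("spc", "spectral_count", "spectral_counts", "count", "num_spectra"),
    "description": ("description", "protein_description", "name"),
    "gene_symbol": ("gene_symbol", "gene", "symbol"),
    "mw": ("mw", "molecular_weight", "mass"),
    "pi": ("pi", "isoelectric_point"),
}

_MANDATORY = ("accession", "score", "spc")
_OPTIONAL = ("description", "gene_symbol", "mw", "pi")


@dataclass
class RunTable:
    """One LC-MS/MS run's identified-protein list.

    ``table`` is indexed by accession (unique within the run) and carries at
    least ``score`` (search-engine score) and ``spc`` (MS/MS spectral count),
    plus optional ``description``, ``gene_symbol``, ``mw`` (Da) and ``pi``.
    """

    run_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            raise ValidationError(
                f"run {self.run_id}: accessions must be unique within a run"
            )
        if (self.table["spc"] < 0).any():
            raise ValidationError(f"run {self.run_id}: spc must be >= 0")
        if (self.table["score"] < 0).any():
            raise ValidationError(f"run {self.run_id}: score must be >= 0")

    @property
    def accessions(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class StudyDesign:
    """Maps runs to (condition, animal, technical replicate).

    ``conditions`` is ordered with the reference (baseline) condition first;
    the three-condition remodeling analysis interprets the order as
    (baseline, perturbed, treated).
    """

    conditions: tuple[str, ...]
    run_map: dict[str, tuple[str, str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        if not self.conditions:
            raise ValidationError("design must declare at least one condition")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValidationError("duplicate condition labels in design")
        for run_id, (cond, _animal, _rep) in self.run_map.items():
            if cond not in self.conditions:
                raise ValidationError(
                    f"run {run_id} mapped to unknown condition {cond!r}"
                )
        for cond in self.conditions:
            if not self.animals(cond):
                raise ValidationError(f"condition {cond!r} has no runs")

    @property
    def run_ids(self) -> tuple[str, ...]:
        return tuple(self.run_map)

    def animals(self, condition: str) -> tuple[str, ...]:
        seen: list[str] = []
        for cond, animal, _ in self.run_map.values():
            if cond == condition and animal not in seen:
                seen.append(animal)
        return tuple(seen)

    def runs_of(self, condition: str, animal: str | None = None) -> tuple[str, ...]:
        return tuple(
            run_id
            for run_id, (cond, anim, _) in self.run_map.items()
            if cond == condition and (animal is None or anim == animal)
        )

    def __len__(self) -> int:
        return len(self.run_map)


def _resolve_columns(
    columns: Iterable[str], aliases: Mapping[str, tuple[str, ...]]
) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved: dict[str, str] = {}
    for canonical, names in aliases.items():
        for name in names:
            if name.lower() in lower:
                resolved[canonical] = lower[name.lower()]
                break
    return resolved


def read_protein_list(
    path: str | Path,
    run_id: str | None = None,
    column_aliases: Mapping[str, tuple[str, ...]] | None = None,
    sep: str = "\t",
) -> RunTable:
    """Read one run's protein list from delimited text.

    Duplicate accessions are merged by summing ``spc`` and keeping the
    maximum ``score`` (spectral counts are additive evidence); a warning is
    logged so the merge can be audited.
    """
    path = Path(path)
    aliases = dict(DEFAULT_ALIASES)
    if column_aliases:
        for key, extra in column_aliases.items():
            aliases[key] = tuple(extra) + aliases.get(key, ())
    raw = pd.read_csv(path, sep=sep)
    resolved = _resolve_columns(raw.columns, aliases)
    missing = [c for c in _MANDATORY if c not in resolved]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s) {', '.join(missing)} "
            f"(known aliases: {', '.join(a for m in missing for a in aliases[m])})"
        )
    frame = pd.DataFrame(index=raw.index)
    frame["accession"] = raw[resolved["accession"]].astype(str)
    frame["score"] = pd.to_numeric(raw[resolved["score"]], errors="raise")
    frame["spc"] = pd.to_numeric(raw[resolved["spc"]], errors="raise")
    for col in _OPTIONAL:
        if col in resolved:
            frame[col] = raw[resolved[col]]
    if (frame["spc"] < 0).any():
        bad = frame.index[frame["spc"] < 0][0]
        raise ValidationError(f"{path}: negative spc at data row {bad + 1}")
    dup = frame["accession"].duplicated()
    if dup.any():
        log.warning(
            "%s: %d duplicate accession rows merged (spc summed, max score kept)",
            path,
            int(dup.sum()),
        )
        agg: dict[str, object] = {"score": "max", "spc": "sum"}
        for col in _OPTIONAL:
            if col in frame:
                agg[col] = "first"
        frame = frame.groupby("accession", sort=False).agg(agg).reset_index()
    frame = frame.set_index("accession")
    return RunTable(run_id or path.stem, frame)


def write_protein_list(run: RunTable, path: str | Path) -> None:
    run.table.rename_axis("accession").to_csv(path, sep="\t")


def read_design(path: str | Path) -> StudyDesign:
    """Read a study design from YAML (explicit condition order) or TSV.

    TSV columns: run_id, condition, animal, tech_rep; condition order is the
    order of first appearance.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(path.read_text())
        conditions = tuple(data["conditions"])
        run_map: dict[str, tuple[str, str, int]] = {}
        for run_id, entry in data["runs"].items():
            if run_id in run_map:
                raise ValidationError(f"{path}: duplicate run id {run_id!r}")
            run_map[str(run_id)] = (
                str(entry["condition"]),
                str(entry["animal"]),
                int(entry.get("tech_rep", 1)),
            )
        return StudyDesign(conditions, run_map)
    table = pd.read_csv(path, sep="\t")
    required = {"run_id", "condition", "animal", "tech_rep"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing design column(s) {sorted(missing)}")
    if table["run_id"].duplicated().any():
        dup_id = table.loc[table["run_id"].duplicated(), "run_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate run id {dup_id!r}")
    conditions = tuple(dict.fromkeys(table["condition"].astype(str)))
    run_map = {
        str(r.run_id): (str(r.condition), str(r.animal), int(r.tech_rep))
        for r in table.itertuples()
    }
    return StudyDesign(conditions, run_map)


def write_design(design: StudyDesign, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = {
            "conditions": list(design.conditions),
            "runs": {
                run_id: {"condition": c, "animal": a, "tech_rep": r}
                for run_id, (c, a, r) in design.run_map.items()
            },
        }
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return
    rows = [
        {"run_id": run_id, "condition": c, "animal": a, "tech_rep": r}
        for run_id, (c, a, r) in design.run_map.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ppi_edges(
    path: str | Path,
    score_min: float = 0.15,
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a STRING-export-like scored edge list.

    Keeps rows with combined_score strictly greater than ``score_min``,
    removes self-interactions and duplicate unordered pairs (keeping the
    maximum score).  Integer 0-1000 score dialects are detected (max > 1)
    and divided by 1000 with a logged notice.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep)
    if raw.shape[1] < 3:
        raise FormatError(f"{path}: expected two id columns and a score column")
    cols = list(raw.columns)
    resolved = _resolve_columns(cols, {"combined_score": ("combined_score", "score")})
    score_col = resolved.get("combined_score", cols[2])
    id_cols = [c for c in cols if c != score_col][:2]
    edges = pd.DataFrame(
        {
            "protein_a": raw[id_cols[0]].astype(str),
            "protein_b": raw[id_cols[1]].astype(str),
            "combined_score": pd.to_numeric(raw[score_col], errors="raise"),
        }
    )
    bad = ~edges["combined_score"].between(0, 1000)
    if bad.any():
        row = int(edges.index[bad][0])
        raise ValidationError(
            f"{path}: combined_score out of range at data row {row + 1}"
        )
    if edges["combined_score"].max() > 1:
        log.info("%s: 0-1000 score dialect detected; dividing by 1000", path)
        edges["combined_score"] /= 1000.0
    if not edges["combined_score"].between(0, 1).all():
        raise ValidationError(f"{path}: combined_score outside [0, 1]")
    return dedupe_edges(edges, score_min=score_min)


def dedupe_edges(edges: pd.DataFrame, score_min: float = 0.0) -> pd.DataFrame:
    """Drop self-loops and duplicate unordered pairs (max score kept), then
    filter to combined_score > score_min."""
    edges = edges[edges["protein_a"] != edges["protein_b"]].copy()
    key = edges[["protein_a", "protein_b"]].apply(
        lambda r: tuple(sorted((r.protein_a, r.protein_b))), axis=1
    )
    if len(edges):
        edges["_key"] = key
        edges = (
            edges.sort_values("combined_score", ascending=False)
            .drop_duplicates("_key")
            .drop(columns="_key")
        )
        edges[["protein_a", "protein_b"]] = pd.DataFrame(
            [sorted(t) for t in zip(edges["protein_a"], edges["protein_b"])],
            index=edges.index,
        )
    edges = edges[edges["combined_score"] > score_min]
    return edges.sort_values(["protein_a", "protein_b"]).reset_index(drop=True)


def write_ppi_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_network_export(
    graph: nx.Graph,
    out_dir: str | Path,
    overlays: Mapping[str, Mapping[str, object]] | None = None,
    interaction: str = "pp",
) -> tuple[Path, Path]:
    """Write a Cytoscape-compatible SIF file plus a node-attribute TSV.

    ``overlays`` maps node -> {attribute: value}; overlay rows for nodes
    absent from the graph are skipped with a warning.  Node attributes
    already stored on the graph are exported as well.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sif_path = out_dir / "network.sif"
    attr_path = out_dir / "node_attributes.tsv"

    nodes = sorted(graph.nodes)
    with sif_path.open("w") as fh:
        written = set()
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{interaction}\t{b}\n")
            written.update((a, b))
        for node in nodes:
            if node not in written:
                fh.write(f"{node}\n")

    records: dict[str, dict[str, object]] = {n: dict(graph.nodes[n]) for n in nodes}
    if overlays:
        for node, attrs in overlays.items():
            if node not in records:
                log.warning("overlay node %s absent from graph; row skipped", node)
                continue
            records[node].update(attrs)
    attr_frame = (
        pd.DataFrame.from_dict(records, orient="index")
        .reindex(nodes)
        .rename_axis("node")
    )
    attr_frame.sort_index().to_csv(attr_path, sep="\t")
    return sif_path, attr_path


def read_sif(path: str | Path) -> nx.Graph:
    graph: nx.Graph = nx.Graph()
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) == 1 and parts[0]:
            graph.add_node(parts[0])
        elif len(parts) >= 3:
            source, _interaction, *targets = parts
            for target in targets:
                graph.add_edge(source, target)
    return graph


def read_node_attributes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="node")
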