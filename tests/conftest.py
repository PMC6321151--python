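"""Shared fixtures: hand-built micro-studies and the default synthetic study."""

from __future__ import annotations

import pandas as pd
import pytest

from spcpipe import (
    GeneratorConfig,
    RunTable,
    StudyDesign,
    align_runs,
    generate_study,
    group_by_gene,
)


def make_run(run_id: str, counts: dict[str, int], scores: dict[str, float] | None = None,
             genes: dict[str, str] | None = None) -> RunTable:
    scores = scores or {acc: 10.0 * spc for acc, spc in counts.items()}
    table = pd.DataFrame(
        {
            "score": [scores[a] for a in counts],
            "spc": list(counts.values()),
        },
        index=pd.Index(list(counts), name="accession"),
    )
    if genes:
        table["gene_symbol"] = [genes.get(a) for a in counts]
    return RunTable(run_id, table)


@pytest.fixture
def tiny_design() -> StudyDesign:
    """1 animal x 2 technical replicates per condition, 3 conditions."""
    run_map = {}
    for cond in ("native", "preEVLP", "postEVLP"):
        for rep in (1, 2):
            run_map[f"{cond}_A1_r{rep}"] = (cond, f"{cond}-A1", rep)
    return StudyDesign(("native", "preEVLP", "postEVLP"), run_map)


@pytest.fixture
def tiny_matrix(tiny_design):
    """Hand-built counts: P1 varies across conditions, P2 constant,
    P3 absent from postEVLP."""
    counts = {
        "native_A1_r1": {"P1": 4, "P2": 5, "P3": 2},
        "native_A1_r2": {"P1": 6, "P2": 5, "P3": 4},
        "preEVLP_A1_r1": {"P1": 20, "P2": 5, "P3": 3},
        "preEVLP_A1_r2": {"P1": 20, "P2": 5, "P3": 3},
        "postEVLP_A1_r1": {"P1": 5, "P2": 5},
        "postEVLP_A1_r2": {"P1": 5, "P2": 5},
    }
    runs = [make_run(run_id, c) for run_id, c in counts.items()]
    return align_runs(runs, tiny_design)


#: study conditions: 2000 proteins, 3 conditions x 5 animals x 2 technical
#: replicates, 2x effects, biological log-sd 0.3, one contaminated animal.
DEFAULT_SEED = 0


@pytest.fixture(scope="session")
def default_study():
    config = GeneratorConfig(seed=DEFAULT_SEED)
    run_tables, design, truth = generate_study(config)
    return config, run_tables, design, truth


@pytest.fixture(scope="session")
def default_matrix(default_study):
    _config, run_tables, design, _truth = default_study
    return group_by_gene(align_runs(run_tables, design))


@pytest.fixture(scope="session")
def small_study():
    """A 300-protein study for faster stage-level tests."""
    config = GeneratorConfig(seed=11, n_proteins=300)
    run_tables, design, truth = generate_study(config)
    matrix = group_by_gene(align_runs(run_tables, design))
    return config, matrix, truth
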