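"""Synthetic spectral-count study generator.

Generates complete three-condition (baseline / perturbed / treated) studies
with the statistical structure the analysis assumes: per-protein Poisson
counts whose rates carry planted stable, recovered, activated, inhibited and
condition-specific patterns, log-normal between-animal biological
variability, an optional plasma-contaminated outlier animal, plus Venn and
PPI fixtures with known ground truth.  All randomness flows through one
:class:`numpy.random.Generator` (PCG64) seeded from the config, so output is
fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .io import RunTable, StudyDesign

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_study",
    "generate_venn_fixture",
    "generate_ppi_fixture",
]

#: planted-class fractions over {stable, recovered, activated, inhibited,
#: condition_specific}; any remainder is stable
DEFAULT_CLASS_FRACTIONS = {
    "stable": 0.70,
    "recovered": 0.10,
    "activated": 0.05,
    "inhibited": 0.05,
    "condition_specific": 0.10,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-level parameters of the synthetic generator.

    Defaults emulate the three-condition, five-animal, duplicate-run design:
    2000 proteins, 2x planted effects, log-normal biological variability
    (sigma 0.3 on the log scale, one effect per protein and animal) and a
    base-abundance law SpC rate ~ LogNormal(ln-mean 1.6, ln-sd 1.0).
    ``outlier`` plants a plasma-contaminated animal: ``n_contaminants``
    proteins inflated ``inflation``-fold in every run of one animal.
    """

    seed: int
    n_proteins: int = 2000
    conditions: tuple[str, ...] = ("native", "preEVLP", "postEVLP")
    animals_per_condition: int = 5
    tech_reps: int = 2
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    effect_fold: float = 2.0
    biological_cv: float = 0.3
    abundance_ln_mean: float = 1.6
    abundance_ln_sd: float = 1.0
    overdispersion: float = 0.0  # negative-binomial when > 0 (1/size)
    outlier_condition: str | None = "postEVLP"
    outlier_animal_index: int = 4
    n_contaminants: int = 20
    contaminant_inflation: float = 10.0

    def __post_init__(self) -> None:
        fractions = dict(self.class_fractions)
        unknown = set(fractions) - set(DEFAULT_CLASS_FRACTIONS)
        if unknown:
            raise ValidationError(f"unknown protein classes {sorted(unknown)}")
        if any(v < 0 for v in fractions.values()):
            raise ValidationError("class fractions must be non-negative")
        total_planted = sum(v for k, v in fractions.items() if k != "stable")
        if total_planted > 1 + 1e-9:
            raise ValidationError("class fractions must sum to at most 1")
        if self.n_proteins < 1 or self.animals_per_condition < 1 or self.tech_reps < 1:
            raise ValidationError("study dimensions must be positive")
        if self.effect_fold <= 0 or self.abundance_ln_sd < 0:
            raise ValidationError("rates must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated study.

    ``proteins``: per-protein class label, per-condition true rate and
    contaminant flag.  ``outlier_animal``: (condition, animal) of the planted
    plasma-contaminated animal, or None.
    """

    proteins: pd.DataFrame
    outlier_animal: tuple[str, str] | None

    def accessions_of(self, label: str) -> list[str]:
        return list(self.proteins.index[self.proteins["class"] == label])

    @property
    def contaminants(self) -> list[str]:
        return list(self.proteins.index[self.proteins["contaminant"]])


def _class_labels(config: GeneratorConfig) -> np.ndarray:
    fractions = {**DEFAULT_CLASS_FRACTIONS, **dict(config.class_fractions)}
    n = config.n_proteins
    counts = {
        label: int(round(fractions[label] * n))
        for label in ("recovered", "activated", "inhibited", "condition_specific")
    }
    n_planted = sum(counts.values())
    if n_planted > n:
        raise ValidationError("class fractions exceed the protein count")
    labels = (
        ["stable"] * (n - n_planted)
        + ["recovered"] * counts["recovered"]
        + ["activated"] * counts["activated"]
        + ["inhibited"] * counts["inhibited"]
        + ["condition_specific"] * counts["condition_specific"]
    )
    return np.asarray(labels, dtype=object)


def generate_study(
    config: GeneratorConfig,
) -> tuple[list[RunTable], StudyDesign, SyntheticTruth]:
    """Generate run tables, a design and the ground truth for one study.

    Counts are Poisson(lambda_jc * effect_ja) with effect_ja log-normal(0,
    biological_cv) drawn once per protein and animal; recovered proteins have
    lambda_pre = effect_fold * lambda_native with lambda_post back at
    baseline, activated/inhibited scale lambda_post up/down, and
    condition-specific proteins are absent outside one condition.
    Contaminant proteins (plasma-like, drawn from the upper half of the
    abundance law) are inflated only in the outlier animal's runs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    labels = _class_labels(config)
    lam = rng.lognormal(config.abundance_ln_mean, config.abundance_ln_sd, n)

    conditions = tuple(config.conditions)
    if len(conditions) != 3:
        raise ValidationError("the generator emulates exactly 3 conditions")
    rates = np.tile(lam[:, None], (1, 3)).astype(float)
    rates[labels == "recovered", 1] *= config.effect_fold
    rates[labels == "activated", 2] *= config.effect_fold
    rates[labels == "inhibited", 2] /= config.effect_fold
    cs_rows = np.where(labels == "condition_specific")[0]
    cs_condition = rng.integers(0, 3, size=cs_rows.size)
    for row, keep in zip(cs_rows, cs_condition):
        mask = np.ones(3, dtype=bool)
        mask[keep] = False
        rates[row, mask] = 0.0

    accessions = np.array([f"P{i:05d}" for i in range(n)], dtype=object)
    genes = np.array([f"GENE{i:05d}" for i in range(n)], dtype=object)
    descriptions = np.array([f"synthetic protein {i}" for i in range(n)], dtype=object)
    mw = rng.lognormal(10.8, 0.45, n)  # ~ 20-150 kDa
    pi = rng.uniform(4.0, 11.0, n)

    # plasma-like contaminants: abundant stable proteins
    contaminant = np.zeros(n, dtype=bool)
    outlier: tuple[str, str] | None = None
    if config.outlier_condition is not None:
        eligible = np.where((labels == "stable") & (lam > np.median(lam)))[0]
        chosen = rng.choice(
            eligible, size=min(config.n_contaminants, eligible.size), replace=False
        )
        contaminant[chosen] = True

    design_rows: dict[str, tuple[str, str, int]] = {}
    run_tables: list[RunTable] = []
    for c_idx, cond in enumerate(conditions):
        for a_idx in range(config.animals_per_condition):
            animal = f"{cond}-A{a_idx + 1}"
            is_outlier = (
                config.outlier_condition == cond
                and a_idx == config.outlier_animal_index
            )
            if is_outlier:
                outlier = (cond, animal)
            effects = rng.lognormal(0.0, config.biological_cv, n)
            lam_animal = rates[:, c_idx] * effects
            if is_outlier:
                lam_animal = lam_animal.copy()
                lam_animal[contaminant] *= config.contaminant_inflation
            for rep in range(1, config.tech_reps + 1):
                run_id = f"{cond}_A{a_idx + 1}_r{rep}"
                if config.overdispersion > 0:
                    size = 1.0 / config.overdispersion
                    gamma = rng.gamma(size, 1.0 / size, n)
                    counts = rng.poisson(lam_animal * gamma)
                else:
                    counts = rng.poisson(lam_animal)
                detected = counts > 0
                scores = np.zeros(n)
                scores[detected] = 10.0 * counts[detected] * rng.lognormal(
                    0.0, 0.2, int(detected.sum())
                )
                table = pd.DataFrame(
                    {
                        "score": scores[detected],
                        "spc": counts[detected].astype(int),
                        "description": descriptions[detected],
                        "gene_symbol": genes[detected],
                        "mw": mw[detected],
                        "pi": pi[detected],
                    },
                    index=pd.Index(accessions[detected], name="accession"),
                )
                run_tables.append(RunTable(run_id, table))
                design_rows[run_id] = (cond, animal, rep)

    design = StudyDesign(conditions, design_rows)
    truth_frame = pd.DataFrame(
        {
            "class": labels,
            "gene_symbol": genes,
            **{
                f"lambda_{cond}": rates[:, i] for i, cond in enumerate(conditions)
            },
            "contaminant": contaminant,
        },
        index=pd.Index(accessions, name="accession"),
    )
    truth = SyntheticTruth(truth_frame, outlier)
    _check_truth(truth, conditions)
    return run_tables, design, truth


def _check_truth(truth: SyntheticTruth, conditions: Sequence[str]) -> None:
    """Post-generation consistency check of the planted patterns."""
    t = truth.proteins
    b, p, s = (t[f"lambda_{c}"] for c in conditions)
    rec = t["class"] == "recovered"
    act = t["class"] == "activated"
    inh = t["class"] == "inhibited"
    assert (b[rec] == s[rec]).all() and (p[rec] != b[rec]).all()
    assert (b[act] == p[act]).all() and (s[act] != b[act]).all()
    assert (b[inh] == p[inh]).all() and (s[inh] != b[inh]).all()


def generate_venn_fixture(
    region_sizes: Sequence[int], labels: Sequence[str] = ("A", "B", "C")
) -> dict[str, set]:
    """Three sets realizing exactly the requested 7 disjoint Venn regions.

    ``region_sizes`` order: (triple, AB-only, BC-only, AC-only, A-only,
    B-only, C-only).
    """
    if len(region_sizes) != 7 or any(s < 0 for s in region_sizes):
        raise ValidationError("need 7 non-negative region sizes")
    a_label, b_label, c_label = labels
    membership = [
        (a_label, b_label, c_label),
        (a_label, b_label),
        (b_label, c_label),
        (a_label, c_label),
        (a_label,),
        (b_label,),
        (c_label,),
    ]
    sets: dict[str, set] = {lab: set() for lab in labels}
    counter = 0
    for size, owners in zip(region_sizes, membership):
        for _ in range(size):
            acc = f"V{counter:06d}"
            counter += 1
            for owner in owners:
                sets[owner].add(acc)
    return sets


def generate_ppi_fixture(
    n_nodes: int,
    n_subnetworks: int = 25,
    n_groups: int = 5,
    enriched_subnetworks: Sequence[str] | None = None,
    seed: int = 0,
    intra_p: float = 0.35,
    inter_p: float = 0.01,
    candidate_fraction: float = 0.15,
    enrichment_fold: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame, set]:
    """Random scored PPI fixture with planted subnetwork enrichment.

    Nodes are partitioned into ``n_subnetworks`` subnetworks (denser inside
    than between) which are grouped into ``n_groups`` main groups.  The
    planted candidate set over-represents ``enriched_subnetworks`` by
    ``enrichment_fold``.  Returns (edge frame, membership frame, candidates).
    """
    if n_nodes < n_subnetworks:
        raise ValidationError("need at least one node per subnetwork")
    rng = np.random.default_rng(seed)
    nodes = [f"N{i:04d}" for i in range(n_nodes)]
    sub_of = np.arange(n_nodes) % n_subnetworks
    sub_names = [f"sub{j:02d}" for j in range(n_subnetworks)]
    group_names = [f"group{g}" for g in range(n_groups)]
    group_of_sub = {
        sub_names[j]: group_names[j % n_groups] for j in range(n_subnetworks)
    }
    enriched = set(enriched_subnetworks or [])
    unknown = enriched - set(sub_names)
    if unknown:
        raise ValidationError(f"unknown subnetworks {sorted(unknown)}")

    rows = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            p = intra_p if sub_of[i] == sub_of[j] else inter_p
            if rng.random() < p:
                rows.append(
                    {
                        "protein_a": nodes[i],
                        "protein_b": nodes[j],
                        "combined_score": float(np.round(rng.uniform(0.0, 1.0), 3)),
                    }
                )
    edges = pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"])

    weights = np.ones(n_nodes)
    for i in range(n_nodes):
        if sub_names[sub_of[i]] in enriched:
            weights[i] = enrichment_fold
    weights /= weights.sum()
    n_candidates = max(1, int(round(candidate_fraction * n_nodes)))
    candidates = set(
        rng.choice(nodes, size=n_candidates, replace=False, p=weights)
    )
    memberships = pd.DataFrame(
        {
            "node": nodes,
            "subnetwork": [sub_names[s] for s in sub_of],
            "main_group": [group_of_sub[sub_names[s]] for s in sub_of],
        }
    )
    return edges, memberships, candidates
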