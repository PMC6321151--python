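"""Alignment of run-level protein lists into a study-wide matrix.

The alignment takes the union of accessions over all runs, treats a protein
absent from a run as zero spectral counts, and averages hierarchically:
technical replicates -> per-animal mean -> per-condition mean (SpC* and
Score*).  Identification frequency, Venn partitioning of three conditions,
technical/biological repeatability, scattered-protein (outlier) detection,
equal-total normalization and the 2D virtual MW/pI map all operate on this
matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from ._errors import (
    InsufficientDataError,
    UnsupportedDesignError,
    ValidationError,
)
from .io import RunTable, StudyDesign
from .stats import origin_regression

log = logging.getLogger(__name__)

__all__ = [
    "AlignedMatrix",
    "VennPartition",
    "RepeatabilityResult",
    "align_runs",
    "group_by_gene",
    "venn_partition",
    "venn_from_sets",
    "repeatability",
    "scattered_proteins",
    "normalize_total",
    "overlap_stats",
    "virtual_map",
    "compute_pi_mw",
]


@dataclass
class AlignedMatrix:
    """Proteins x runs spectral counts with hierarchical averages.

    ``spc``/``score``: proteins x runs.  ``spc_star_animal``: proteins x
    (condition, animal) MultiIndex columns, mean over technical replicates.
    ``spc_star_condition``/``score_star_condition``: proteins x conditions,
    mean over animals.  ``id_frequency``: fraction of a condition's runs in
    which the protein was detected (spc > 0).  ``meta`` carries description,
    gene_symbol, mw and pi where available.
    """

    spc: pd.DataFrame
    score: pd.DataFrame
    design: StudyDesign
    spc_star_animal: pd.DataFrame
    spc_star_condition: pd.DataFrame
    score_star_condition: pd.DataFrame
    id_frequency: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def proteins(self) -> pd.Index:
        return self.spc.index

    @property
    def conditions(self) -> tuple[str, ...]:
        return self.design.conditions

    def condition_accessions(self, condition: str, min_runs: int = 1) -> set[str]:
        """Accessions detected in at least ``min_runs`` runs of a condition."""
        runs = list(self.design.runs_of(condition))
        detected = (self.spc[runs] > 0).sum(axis=1) >= min_runs
        return set(self.spc.index[detected])


def _recompute_averages(
    spc: pd.DataFrame, score: pd.DataFrame, design: StudyDesign
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    animal_cols: dict[tuple[str, str], pd.Series] = {}
    cond_spc: dict[str, pd.Series] = {}
    cond_score: dict[str, pd.Series] = {}
    id_freq: dict[str, pd.Series] = {}
    for cond in design.conditions:
        per_animal = []
        for animal in design.animals(cond):
            runs = list(design.runs_of(cond, animal))
            mean = spc[runs].mean(axis=1)
            animal_cols[(cond, animal)] = mean
            per_animal.append(mean)
        cond_runs = list(design.runs_of(cond))
        cond_spc[cond] = pd.concat(per_animal, axis=1).mean(axis=1)
        cond_score[cond] = pd.concat(
            [score[list(design.runs_of(cond, a))].mean(axis=1) for a in design.animals(cond)],
            axis=1,
        ).mean(axis=1)
        id_freq[cond] = (spc[cond_runs] > 0).mean(axis=1)
    spc_star_animal = pd.DataFrame(animal_cols)
    spc_star_animal.columns = pd.MultiIndex.from_tuples(
        spc_star_animal.columns, names=["condition", "animal"]
    )
    return (
        spc_star_animal,
        pd.DataFrame(cond_spc)[list(design.conditions)],
        pd.DataFrame(cond_score)[list(design.conditions)],
        pd.DataFrame(id_freq)[list(design.conditions)],
    )


def align_runs(run_tables: Sequence[RunTable], design: StudyDesign) -> AlignedMatrix:
    """Align per-run protein lists on the union of accessions.

    Every run in the design must have a table; extra tables not in the design
    are rejected.  Row order is the sorted union of accessions, so alignment
    is invariant to the order in which runs are supplied.
    """
    by_id = {rt.run_id: rt for rt in run_tables}
    if len(by_id) != len(run_tables):
        raise ValidationError("duplicate run_id among run tables")
    missing = [r for r in design.run_ids if r not in by_id]
    if missing:
        raise ValidationError(f"design runs without tables: {', '.join(missing)}")
    unknown = [r for r in by_id if r not in design.run_ids]
    if unknown:
        raise ValidationError(f"run tables not in design: {', '.join(unknown)}")

    accessions = sorted(set().union(*(set(rt.accessions) for rt in run_tables)))
    run_ids = list(design.run_ids)
    spc = pd.DataFrame(0.0, index=accessions, columns=run_ids)
    score = pd.DataFrame(0.0, index=accessions, columns=run_ids)
    for run_id in run_ids:
        table = by_id[run_id].table
        spc.loc[table.index, run_id] = table["spc"].astype(float)
        score.loc[table.index, run_id] = table["score"].astype(float)

    meta_cols: dict[str, pd.Series] = {}
    for col in ("description", "gene_symbol", "mw", "pi"):
        pieces = [
            rt.table[col].dropna() for rt in run_tables if col in rt.table.columns
        ]
        if pieces:
            merged = pd.concat(pieces)
            meta_cols[col] = merged[~merged.index.duplicated()]
    meta = pd.DataFrame(meta_cols).reindex(accessions)

    spc_a, spc_c, score_c, freq = _recompute_averages(spc, score, design)
    return AlignedMatrix(spc, score, design, spc_a, spc_c, score_c, freq, meta)


def group_by_gene(matrix: AlignedMatrix) -> AlignedMatrix:
    """Collapse rows sharing a gene symbol by summing spectral counts.

    The grouped row keeps the maximum per-run score of its members and is
    labelled by the first accession of the group; rows lacking a symbol pass
    through unchanged.  Averages are recomputed after grouping.
    """
    if matrix.meta.empty or "gene_symbol" not in matrix.meta.columns:
        return matrix
    symbols = matrix.meta["gene_symbol"]
    has_symbol = symbols.notna()
    group_key = symbols.where(has_symbol, other=pd.Series(matrix.proteins, index=matrix.proteins))

    spc = matrix.spc.groupby(group_key, sort=False).sum()
    score = matrix.score.groupby(group_key, sort=False).max()
    first_acc = (
        pd.Series(matrix.proteins, index=matrix.proteins)
        .groupby(group_key, sort=False)
        .first()
    )
    meta = matrix.meta.groupby(group_key, sort=False).first()
    meta["accession_first"] = first_acc
    new_index = first_acc.values
    spc.index = score.index = meta.index = new_index
    spc = spc.sort_index()
    score = score.sort_index()
    meta = meta.sort_index()
    spc_a, spc_c, score_c, freq = _recompute_averages(spc, score, matrix.design)
    return AlignedMatrix(
        spc, score, matrix.design, spc_a, spc_c, score_c, freq, meta
    )


@dataclass(frozen=True)
class VennPartition:
    """The 7 disjoint regions of three condition sets.

    Region keys are frozensets of condition labels, e.g. the triple region is
    keyed by all three labels and an exclusive region by a single label.
    """

    conditions: tuple[str, str, str]
    regions: Mapping[frozenset, frozenset]

    def sizes(self) -> dict[frozenset, int]:
        return {key: len(members) for key, members in self.regions.items()}

    @property
    def union_size(self) -> int:
        return sum(len(m) for m in self.regions.values())

    def marginal(self, condition: str) -> int:
        return sum(
            len(members) for key, members in self.regions.items() if condition in key
        )


def venn_from_sets(sets: Mapping[str, set]) -> VennPartition:
    if len(sets) != 3:
        raise UnsupportedDesignError("Venn partition requires exactly 3 conditions")
    labels = tuple(sets)
    universe = set().union(*sets.values())
    regions: dict[frozenset, set] = {}
    for item in universe:
        key = frozenset(lab for lab in labels if item in sets[lab])
        regions.setdefault(key, set()).add(item)
    all_keys = [
        frozenset(combo)
        for combo in (
            labels,
            labels[:2],
            labels[1:],
            (labels[0], labels[2]),
            (labels[0],),
            (labels[1],),
            (labels[2],),
        )
    ]
    full = {key: frozenset(regions.get(key, set())) for key in all_keys}
    return VennPartition(labels, full)  # type: ignore[arg-type]


def venn_partition(
    matrix: AlignedMatrix, design: StudyDesign | None = None, min_runs: int = 1
) -> VennPartition:
    """Exact 7-region Venn partition of the three conditions' protein sets.

    A protein is present in a condition iff detected (spc > 0) in at least
    ``min_runs`` of that condition's runs.
    """
    design = design or matrix.design
    if len(design.conditions) != 3:
        raise UnsupportedDesignError(
            f"Venn partition requires exactly 3 conditions, got {len(design.conditions)}"
        )
    sets = {
        cond: matrix.condition_accessions(cond, min_runs=min_runs)
        for cond in design.conditions
    }
    return venn_from_sets(sets)


@dataclass(frozen=True)
class RepeatabilityResult:
    r_squared: float
    slope: float
    n_points: int
    scattered: tuple[str, ...] = ()
    degenerate: bool = False


def repeatability(x: pd.Series, y: pd.Series) -> RepeatabilityResult:
    """Repeatability of two aligned SpC vectors.

    Slope from the least-squares fit through the origin; R^2 as the squared
    Pearson correlation.  Vectors are aligned on the union of accessions with
    absent proteins counted as zero.
    """
    union = x.index.union(y.index)
    xv = x.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    yv = y.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    slope, r2 = origin_regression(xv, yv)
    degenerate = bool(np.isnan(r2))
    if degenerate:
        log.warning("repeatability: zero-variance vector, r_squared undefined")
    return RepeatabilityResult(r2, slope, len(union), degenerate=degenerate)


def scattered_proteins(
    sample_spc: pd.Series,
    peer_spc_star: pd.Series,
    threshold_sd: float = 3.0,
    max_iter: int = 20,
) -> list[str]:
    """Proteins of one sample that scatter off the peer-group trend.

    Fits sample = slope * peer through the origin and flags proteins whose
    standardized residual exceeds ``threshold_sd``.  The residual scale is
    re-estimated iteratively after removing flagged proteins (otherwise the
    outliers inflate their own yardstick), until the flagged set stabilizes.
    """
    common = sample_spc.index.intersection(peer_spc_star.index)
    if len(common) < 10:
        raise InsufficientDataError(
            f"only {len(common)} common proteins; need at least 10"
        )
    s = sample_spc.reindex(common).to_numpy(dtype=float)
    p = peer_spc_star.reindex(common).to_numpy(dtype=float)
    keep = np.ones(len(common), dtype=bool)
    flagged = np.zeros(len(common), dtype=bool)
    for _ in range(max_iter):
        slope, _ = origin_regression(p[keep], s[keep])
        residuals = s - slope * p
        sd = residuals[keep].std(ddof=1)
        if sd == 0 or not np.isfinite(threshold_sd):
            new_flagged = np.zeros_like(flagged)
        else:
            new_flagged = np.abs(residuals) > threshold_sd * sd
        if (new_flagged == flagged).all():
            break
        flagged = new_flagged
        keep = ~flagged
        if keep.sum() < 10:  # refuse to trim away the bulk of the data
            keep = ~np.zeros_like(flagged)
            break
    return sorted(common[flagged])


def normalize_total(
    a: pd.Series | pd.DataFrame, b: pd.Series | pd.DataFrame
) -> tuple[pd.Series | pd.DataFrame, pd.Series | pd.DataFrame]:
    """Scale two SpC* datasets so both totals equal their common mean total.

    Preserves within-dataset ratios (and therefore rank order).
    """
    total_a = float(np.asarray(a).sum())
    total_b = float(np.asarray(b).sum())
    if total_a == 0 or total_b == 0:
        raise ValidationError("cannot normalize a dataset with zero total SpC*")
    target = (total_a + total_b) / 2
    return a * (target / total_a), b * (target / total_b)


def overlap_stats(reference: set, query: set) -> dict[str, float]:
    """Overlap of a query protein set against a reference set.

    Returns counts plus the confirmation percentage (share of the query also
    seen in the reference).
    """
    shared = reference & query
    return {
        "n_reference": len(reference),
        "n_query": len(query),
        "n_shared": len(shared),
        "n_union": len(reference | query),
        "confirmation_pct": 100.0 * len(shared) / len(query) if query else float("nan"),
    }


def virtual_map(
    matrix: AlignedMatrix,
    condition: str | None = None,
    confidence_rule: Callable[[float], str] | None = None,
    score_cut: float = 100.0,
) -> pd.DataFrame:
    """2D virtual map: one (MW, pI) point per protein with a confidence code.

    The default rule bins Score* at ``score_cut`` into 'high'/'low'.
    Proteins lacking both mw and pi are skipped with a warning.
    """
    if confidence_rule is None:
        confidence_rule = lambda s: "high" if s >= score_cut else "low"  # noqa: E731
    if condition is None:
        scores = matrix.score_star_condition.mean(axis=1)
    else:
        scores = matrix.score_star_condition[condition]
    rows = []
    skipped = 0
    meta = matrix.meta
    for acc in matrix.proteins:
        mw = meta.at[acc, "mw"] if "mw" in meta.columns else np.nan
        pi = meta.at[acc, "pi"] if "pi" in meta.columns else np.nan
        if pd.isna(mw) or pd.isna(pi):
            skipped += 1
            continue
        rows.append(
            {
                "accession": acc,
                "mw": float(mw),
                "pi": float(pi),
                "confidence_code": confidence_rule(float(scores[acc])),
            }
        )
    if skipped:
        warnings.warn(f"virtual_map: skipped {skipped} proteins lacking MW/pI")
    return pd.DataFrame(rows, columns=["accession", "mw", "pi", "confidence_code"])


_AA = set("ACDEFGHIKLMNPQRSTVWY")


def compute_pi_mw(sequence: str) -> tuple[float, float]:
    """Theoretical isoelectric point and average molecular weight (Da).

    pI is solved by bisection on the net-charge curve with the Bjellqvist pKa
    set; MW is the sum of average residue masses plus one water.
    """
    seq = sequence.upper()
    for pos, residue in enumerate(seq):
        if residue not in _AA:
            raise ValidationError(
                f"invalid residue {residue!r} at position {pos + 1}"
            )
    if not seq:
        raise ValidationError("empty sequence")
    analysis = ProteinAnalysis(seq)
    return float(analysis.isoelectric_point()), float(analysis.molecular_weight())
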