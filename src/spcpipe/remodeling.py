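"""Proteome remodeling (PRi) and activation (PAi) indices.

For a three-condition study ordered (baseline b, perturbed p, treated t),
three pairwise differential modules are computed per protein from the
condition-level SpC* values:

    perturbation module  M(b-p) = metric(b, p)
    treatment module     M(p-t) = metric(p, t)
    baseline module      M(t-b) = metric(t, b)

with metric either DAve (default) or ln fold change.  Then

    PRi = M(b-p) / M(p-t)     ~ -1 when the treated level returns to baseline
    PAi = M(t-b) / M(p-t)     ~ -1 when an unperturbed protein responds to
                                   the treatment only

A protein is classified recovered when PRi falls in the acceptance window
(default [-2, -0.5]); activated/inhibited when PAi falls in its window, the
perturbation module is null (|DAve| below 0.2), and the treatment module is
negative/positive respectively (activated = abundance rises after treatment).
Proteins whose module DCIs are all below the exclusion threshold (default
|5|) are noise-level and excluded before classification.  Candidates are
validated by one-way ANOVA across conditions plus Tukey's HSD on the
animal-level SpC*.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import UnsupportedDesignError, ValidationError
from .align import AlignedMatrix
from .differential import dave as _dave, dci as _dci
from .stats import TukeyResult, anova_oneway, tukey_hsd

__all__ = [
    "compute_modules",
    "pri",
    "pai",
    "classify_remodeling",
    "validate_anova_tukey",
    "remodeling_table",
    "PRI_RANGE",
    "PAI_RANGE",
    "DCI_EXCLUSION",
    "PERTURBATION_NULL",
]

PRI_RANGE = (-2.0, -0.5)
PAI_RANGE = (-2.0, -0.5)
DCI_EXCLUSION = 5.0
PERTURBATION_NULL = 0.2
LNFC_PSEUDOCOUNT = 0.5


def _lnfc(x: np.ndarray, y: np.ndarray, pseudocount: float) -> np.ndarray:
    # pseudocount replaces zeros only, so nonzero ratios are untouched
    xs = np.where(x > 0, x, pseudocount)
    ys = np.where(y > 0, y, pseudocount)
    return np.log(xs / ys)


def compute_modules(
    matrix: AlignedMatrix,
    metric: str = "dave",
    pseudocount: float = LNFC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Perturbation / treatment / baseline modules for every protein.

    Requires exactly three conditions ordered (baseline, perturbed, treated).
    Returns columns m_perturbation, m_treatment, m_baseline and the matching
    DCIs (always DAve-scaled counts, used by the exclusion filter).
    """
    if len(matrix.conditions) != 3:
        raise UnsupportedDesignError(
            "remodeling analysis requires exactly 3 ordered conditions"
        )
    b_label, p_label, t_label = matrix.conditions
    b = matrix.spc_star_condition[b_label].to_numpy(dtype=float)
    p = matrix.spc_star_condition[p_label].to_numpy(dtype=float)
    t = matrix.spc_star_condition[t_label].to_numpy(dtype=float)
    if metric == "dave":
        m_pert, m_treat, m_base = _dave(b, p), _dave(p, t), _dave(t, b)
    elif metric in {"lnfc", "ln_fold_change"}:
        m_pert = _lnfc(b, p, pseudocount)
        m_treat = _lnfc(p, t, pseudocount)
        m_base = _lnfc(t, b, pseudocount)
    else:
        raise ValidationError(f"unknown module metric {metric!r}")
    table = pd.DataFrame(
        {
            "m_perturbation": m_pert,
            "m_treatment": m_treat,
            "m_baseline": m_base,
            "dave_perturbation": _dave(b, p),
            "dci_perturbation": _dci(b, p),
            "dci_treatment": _dci(p, t),
            "dci_baseline": _dci(t, b),
        },
        index=matrix.proteins,
    ).rename_axis("accession")
    table.attrs["metric"] = metric
    table.attrs["conditions"] = matrix.conditions
    return table


def pri(m_perturbation: float, m_treatment: float) -> float:
    """Proteome remodeling index M(b-p)/M(p-t); NaN when the treatment
    module is zero (undefined)."""
    if m_treatment == 0:
        return math.nan
    return m_perturbation / m_treatment


def pai(m_baseline: float, m_treatment: float) -> float:
    """Proteome activated index M(t-b)/M(p-t); NaN when the treatment
    module is zero (undefined)."""
    if m_treatment == 0:
        return math.nan
    return m_baseline / m_treatment


def classify_remodeling(
    modules: pd.DataFrame,
    pri_range: tuple[float, float] = PRI_RANGE,
    pai_range: tuple[float, float] = PAI_RANGE,
    perturbation_null: float = PERTURBATION_NULL,
    dci_exclusion: float = DCI_EXCLUSION,
    dci_rule: str = "all",
) -> pd.DataFrame:
    """Assign recovered / activated / inhibited / none per protein.

    ``dci_rule='all'`` excludes a protein only when every module's |DCI| is
    below ``dci_exclusion`` (the permissive reading of "multiple DCI < |5|");
    'any' excludes when any module fails.
    """
    dcis = modules[["dci_perturbation", "dci_treatment", "dci_baseline"]].abs()
    if dci_rule == "all":
        excluded = (dcis < dci_exclusion).all(axis=1)
    elif dci_rule == "any":
        excluded = (dcis < dci_exclusion).any(axis=1)
    else:
        raise ValidationError(f"unknown dci_rule {dci_rule!r}")

    m_pert = modules["m_perturbation"].to_numpy(dtype=float)
    m_treat = modules["m_treatment"].to_numpy(dtype=float)
    m_base = modules["m_baseline"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pri_vals = np.where(m_treat != 0, m_pert / np.where(m_treat != 0, m_treat, 1), np.nan)
        pai_vals = np.where(m_treat != 0, m_base / np.where(m_treat != 0, m_treat, 1), np.nan)

    in_pri = (pri_vals >= pri_range[0]) & (pri_vals <= pri_range[1])
    in_pai = (pai_vals >= pai_range[0]) & (pai_vals <= pai_range[1])
    # perturbation-null gate uses the DAve scale regardless of module metric
    pert_null = np.abs(modules["dave_perturbation"].to_numpy(dtype=float)) < perturbation_null

    eligible = ~excluded.to_numpy()
    recovered = eligible & np.nan_to_num(in_pri)
    activation = eligible & ~recovered & np.nan_to_num(in_pai) & pert_null
    activated = activation & (m_treat < 0)
    inhibited = activation & (m_treat > 0)

    remodel_class = np.full(len(modules), "none", dtype=object)
    remodel_class[recovered] = "recovered"
    remodel_class[activated] = "activated"
    remodel_class[inhibited] = "inhibited"

    out = modules.copy()
    out["pri"] = pri_vals
    out["pai"] = pai_vals
    out["dci_excluded"] = excluded
    out["remodel_class"] = remodel_class
    return out


def validate_anova_tukey(
    matrix: AlignedMatrix,
    candidates: Sequence[str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, TukeyResult]]:
    """One-way ANOVA across the three conditions per candidate, plus Tukey
    HSD pairwise comparisons on animal-level SpC*.

    Degenerate (zero-variance) candidates are reported with p = 1 and
    flagged.  Returns (summary frame, per-candidate Tukey results).
    """
    groups_by_cond = {
        cond: [(cond, a) for a in matrix.design.animals(cond)]
        for cond in matrix.conditions
    }
    rows = []
    tukeys: dict[str, TukeyResult] = {}
    for acc in candidates:
        if acc not in matrix.proteins:
            raise ValidationError(f"candidate {acc!r} not in matrix")
        groups = [
            matrix.spc_star_animal.loc[acc, cols].to_numpy(dtype=float)
            for cols in groups_by_cond.values()
        ]
        degenerate = all(np.ptp(g) == 0 for g in groups) and len(
            {g[0] for g in groups}
        ) == 1
        if degenerate:
            rows.append(
                {"accession": acc, "anova_F": 0.0, "anova_p": 1.0, "degenerate": True}
            )
            continue
        f, p = anova_oneway(groups)
        rows.append(
            {"accession": acc, "anova_F": f, "anova_p": p, "degenerate": False}
        )
        tukeys[acc] = tukey_hsd(groups, alpha=alpha)
    summary = pd.DataFrame(
        rows, columns=["accession", "anova_F", "anova_p", "degenerate"]
    ).set_index("accession")
    summary["significant"] = summary["anova_p"] <= alpha
    return summary, tukeys


def remodeling_table(
    matrix: AlignedMatrix,
    metric: str = "dave",
    validate: bool = True,
    alpha: float = 0.05,
    **classify_kwargs,
) -> pd.DataFrame:
    """Full remodeling analysis: modules -> indices -> class -> validation."""
    modules = compute_modules(matrix, metric=metric)
    classified = classify_remodeling(modules, **classify_kwargs)
    if validate:
        candidates = classified.index[classified["remodel_class"] != "none"]
        if len(candidates):
            summary, _ = validate_anova_tukey(matrix, list(candidates), alpha=alpha)
            classified = classified.join(summary[["anova_F", "anova_p", "significant"]])
        else:
            classified["anova_F"] = np.nan
            classified["anova_p"] = np.nan
            classified["significant"] = False
    return classified
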