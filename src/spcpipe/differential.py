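"""Label-free differential analysis with the DAve / DCI indices.

For two averaged spectral counts x and y (condition A vs condition B):

    DAve = 2 (x - y) / (x + y)          bounded in [-2, 2]
    DCI  = (x + y) (x - y) / 2          count-scaled confidence of DAve

A protein is called up in A iff DAve >= dave_min and DCI >= dci_min
(defaults +0.2 / +10); down symmetrically.  When x + y = 0 both indices are 0
and the protein is marked not evaluable, so downstream filters stay total.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .align import AlignedMatrix

__all__ = ["dave", "dci", "differential_table", "DAVE_MIN", "DCI_MIN"]

DAVE_MIN = 0.2
DCI_MIN = 10.0


def _validate(x, y):
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if (xa < 0).any() or (ya < 0).any():
        raise ValidationError("spectral counts must be non-negative")
    return xa, ya


def dave(x, y):
    """Differential average: signed relative ratio in [-2, 2].

    Accepts scalars or arrays; x + y = 0 yields 0 (not evaluable).
    """
    xa, ya = _validate(x, y)
    total = xa + ya
    with np.errstate(invalid="ignore", divide="ignore"):
        result = np.where(total > 0, 2 * (xa - ya) / np.where(total > 0, total, 1.0), 0.0)
    return float(result) if np.isscalar(x) and np.isscalar(y) else result


def dci(x, y):
    """Differential confidence index: (x + y)(x - y) / 2."""
    xa, ya = _validate(x, y)
    result = (xa + ya) * (xa - ya) / 2
    return float(result) if np.isscalar(x) and np.isscalar(y) else result


def differential_table(
    matrix: AlignedMatrix,
    cond_a: str,
    cond_b: str,
    dave_min: float = DAVE_MIN,
    dci_min: float = DCI_MIN,
) -> pd.DataFrame:
    """Per-protein DAve/DCI between two conditions, with threshold calls.

    Returns one row per protein with columns spc_star_a, spc_star_b, dave,
    dci, evaluable, call (up / down / unchanged).  Summary counts are stored
    in ``.attrs`` as n_up and n_down.
    """
    for cond in (cond_a, cond_b):
        if cond not in matrix.conditions:
            raise ValidationError(f"unknown condition label {cond!r}")
    x = matrix.spc_star_condition[cond_a]
    y = matrix.spc_star_condition[cond_b]
    d = dave(x.to_numpy(), y.to_numpy())
    c = dci(x.to_numpy(), y.to_numpy())
    evaluable = (x.to_numpy() + y.to_numpy()) > 0
    call = np.where(
        (d >= dave_min) & (c >= dci_min),
        "up",
        np.where((d <= -dave_min) & (c <= -dci_min), "down", "unchanged"),
    )
    call = np.where(evaluable, call, "unchanged")
    table = pd.DataFrame(
        {
            "spc_star_a": x,
            "spc_star_b": y,
            "dave": d,
            "dci": c,
            "evaluable": evaluable,
            "call": call,
        },
        index=matrix.proteins,
    ).rename_axis("accession")
    table.attrs["pair"] = (cond_a, cond_b)
    table.attrs["n_up"] = int((table["call"] == "up").sum())
    table.attrs["n_down"] = int((table["call"] == "down").sum())
    return table
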