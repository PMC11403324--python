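"""Fixed-effect design construction for the cortisol mixed models.

Terms are colon-separated products of named factors, e.g. ``"time"``,
``"time:stage"`` or ``"time:stage:awakening"``.  Categorical factors expand
to treatment-coded indicator columns (early pregnancy, summer season,
secondary education as references); continuous covariates other than time
since awakening are centered at the grand mean of the modelling table, so
the intercept is the expected log concentration at awakening in early
pregnancy for an average woman.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# factor name -> (kind, source column, levels/label)
_CATEGORICAL = {
    "stage": ("stage", ["early", "mid", "late"],
              {"mid": "Mid pregnancy", "late": "Late pregnancy"}),
    "season": ("season", ["summer", "winter"], {"winter": "Season (winter)"}),
    "education": ("education", ["secondary", "lower tertiary", "upper tertiary"],
                  {"lower tertiary": "Lower tertiary education",
                   "upper tertiary": "Upper tertiary education"}),
}

# continuous covariates centered at the grand mean of the rows being modelled
_CENTERED = {
    "awakening": ("awakening_time", "Time at awakening"),
    "bmi": ("bmi", "Maternal BMI"),
    "age": ("age", "Maternal age"),
}

# binary 0/1 indicators taken as-is
_BINARY = {
    "hypertensive": ("hypertensive", "Maternal hypertensive disorder (yes)"),
    "gdm": ("gdm", "GDM (yes)"),
    "smoking": ("smoking", "Smoking (yes)"),
    "parity": ("parity_primiparous", "Parity (primiparous)"),
    "chromosomal_testing": ("chromosomal_testing", "Chromosomal testing (yes)"),
    "mental_disorder": ("mental_disorder", "Lifetime mental disorder (yes)"),
}


class DesignError(ValueError):
    """Raised when the fixed-effect design cannot be built."""


def _expand_factor(name: str, table: pd.DataFrame) -> list[tuple[str, np.ndarray]]:
    """Return [(label, column vector)] for one factor."""
    n = len(table)
    if name == "time":
        return [("Time", table["time"].to_numpy(float))]
    if name == "time2":
        return [("Time squared", table["time"].to_numpy(float) ** 2)]
    if name in _CATEGORICAL:
        col, levels, labels = _CATEGORICAL[name]
        vals = table[col].astype(str)
        unknown = set(vals.unique()) - set(levels)
        if unknown:
            raise DesignError(f"unknown {name} levels: {sorted(unknown)}")
        out = []
        for lev in levels[1:]:  # first level is the reference
            out.append((labels[lev], (vals == lev).to_numpy(float)))
        return out
    if name in _CENTERED:
        col, label = _CENTERED[name]
        x = table[col].to_numpy(float)
        return [(label, x - x.mean())]
    if name in _BINARY:
        col, label = _BINARY[name]
        return [(label, table[col].to_numpy(float))]
    raise DesignError(f"unknown design factor {name!r}")


def expand_terms(terms: list[str], table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Expand term strings into a design matrix with an intercept column."""
    n = len(table)
    cols = [np.ones(n)]
    names = ["Intercept"]
    for term in terms:
        pieces = [_expand_factor(f.strip(), table) for f in term.split(":")]
        expanded = pieces[0]
        for nxt in pieces[1:]:
            expanded = [(f"{la} × {lb}", va * vb) for la, va in expanded for lb, vb in nxt]
        for label, vec in expanded:
            cols.append(vec)
            names.append(label)
    X = np.column_stack(cols)
    return X, names


def check_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise DesignError naming aliased columns if X is rank deficient."""
    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return
    # identify aliased columns via pivoted QR on the scaled matrix
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    _, R, piv = _qr_pivot(X / scale)
    keep = piv[:r]
    aliased = [names[j] for j in range(X.shape[1]) if j not in keep]
    raise DesignError(f"rank-deficient fixed-effect design; aliased terms: {aliased}")


def _qr_pivot(A):
    from scipy.linalg import qr

    Q, R, piv = qr(A, mode="economic", pivoting=True)
    return Q, R, piv


def build_design(table: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Build and rank-check the fixed-effect design for the given terms."""
    X, names = expand_terms(terms, table)
    check_rank(X, names)
    return X, names
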