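"""Fixed-time binarization of right-censored progression outcomes.

A progression-free-interval record (event indicator, time in days) becomes
a binary label at horizon t: positive if the event occurred strictly
before t; negative if the subject was followed (with or without a later
event) to at least t; excluded if censored strictly before t, because the
event status at t cannot be determined.  Records with missing outcome
fields are excluded with a distinct "missing" status.

Class imbalance is handled by random oversampling (duplication of minority
rows) or SMOTE (synthetic minority points interpolated between minority
nearest neighbours); both are meant to be applied to training folds only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .expression_data import PhenotypeTable

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "EXCLUDED",
    "MISSING",
    "DEFAULT_HORIZON_DAYS",
    "binarize_pfi",
    "label_dataset",
    "horizon_months",
    "random_oversample",
    "smote_oversample",
]

POSITIVE = "positive"
NEGATIVE = "negative"
EXCLUDED = "excluded"
MISSING = "missing"

#: default fixed horizon in days (~7.67 months)
DEFAULT_HORIZON_DAYS = 230.0


def binarize_pfi(pfi_event, pfi_time, t: float = DEFAULT_HORIZON_DAYS,
                 strict: bool = True) -> str:
    """Label one record at horizon ``t`` days.

    ``strict`` reads "before t" as ``time < t`` (the default); with
    ``strict=False`` the boundary ``time == t`` counts as before, for both
    the event and the censoring-exclusion rule.
    """
    if t <= 0:
        raise ValueError("horizon t must be positive")
    if pfi_event is None or pfi_time is None or pd.isna(pfi_event) or pd.isna(pfi_time):
        return MISSING
    if pfi_time < 0:
        raise ValueError("pfi_time must be non-negative")
    if int(pfi_event) not in (0, 1):
        raise ValueError(f"pfi_event must be 0/1, got {pfi_event!r}")
    before = pfi_time < t if strict else pfi_time <= t
    if before:
        return POSITIVE if int(pfi_event) == 1 else EXCLUDED
    return NEGATIVE


def label_dataset(pheno: PhenotypeTable, t: float = DEFAULT_HORIZON_DAYS,
                  strict: bool = True):
    """Label every sample and summarize retention and class balance.

    Returns ``(labels, report)``: ``labels`` is a DataFrame indexed by
    sample with ``status`` and ``cohort`` columns; ``report`` gives, overall
    and per cohort, the retained count and the positive fraction among
    retained samples.
    """
    records = {}
    for sid, row in pheno.data.iterrows():
        records[sid] = binarize_pfi(row["pfi_event"], row["pfi_time"], t, strict=strict)
    labels = pd.DataFrame(
        {"status": pd.Series(records), "cohort": pheno.data["cohort"]}
    )

    def summarize(sub: pd.DataFrame) -> dict:
        retained = sub["status"].isin([POSITIVE, NEGATIVE]).sum()
        pos = (sub["status"] == POSITIVE).sum()
        return {
            "total": int(len(sub)),
            "retained": int(retained),
            "positive": int(pos),
            "positive_fraction": float(pos / retained) if retained else float("nan"),
            "excluded": int((sub["status"] == EXCLUDED).sum()),
            "missing": int((sub["status"] == MISSING).sum()),
        }

    report = {"overall": summarize(labels)}
    for cohort, sub in labels.groupby("cohort"):
        report[str(cohort)] = summarize(sub)
    return labels, report


def horizon_months(t_days: float = DEFAULT_HORIZON_DAYS, days_per_month: float = 30.0) -> float:
    """Express a horizon in months under a 30-day-month convention."""
    return t_days / days_per_month


def _class_split(labels: np.ndarray):
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to resample")
    if len(classes) > 2:
        raise ValueError("resampling supports binary labels only")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    return minority, majority


def random_oversample(features, labels, seed: int):
    """Duplicate minority rows (with replacement) until the classes balance."""
    X = np.asarray(features)
    y = np.asarray(labels)
    minority, majority = _class_split(y)
    n_min = int((y == minority).sum())
    n_maj = int((y == majority).sum())
    if n_min == n_maj:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    idx_min = np.flatnonzero(y == minority)
    extra = rng.choice(idx_min, size=n_maj - n_min, replace=True)
    order = np.concatenate([np.arange(len(y)), extra])
    return X[order], y[order]


def smote_oversample(features, labels, k_neighbors: int = 5, seed: int = 0):
    """Balance classes with synthetic minority over-sampling (SMOTE).

    Each synthetic point is ``x + u * (x_nn - x)`` with ``u ~ U[0, 1]``,
    where ``x`` is a minority point and ``x_nn`` one of its ``k_neighbors``
    nearest minority neighbours.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    minority, majority = _class_split(y)
    X_min = X[y == minority]
    n_min, n_maj = len(X_min), int((y == majority).sum())
    if n_min <= k_neighbors:
        raise ValueError(
            f"minority class has {n_min} samples; needs more than k_neighbors={k_neighbors}"
        )
    if n_min == n_maj:
        return X.copy(), y.copy()
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    _, neigh = nn.kneighbors(X_min)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k_neighbors + 1, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    anchors = X_min[base]
    partners = X_min[neigh[base, pick]]
    synthetic = anchors + u[:, None] * (partners - anchors)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out
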