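"""Error matrices and the three ecosite accuracy modes.

Map accuracy is assessed three ways against field-assessed ecosites:

* **ellipse-based** — plots are projected onto the original overlapping
  ellipse grid using their *field-assessed* (SNR, SMR) coordinates;
* **rectangle-based** — plots are projected onto the simplified rectangle
  grid, again from field-assessed coordinates;
* **model-prediction** — plots are projected onto the rectangle grid from
  *model-predicted* (SNR, SMR) values, i.e. the accuracy of the map itself.

For the ordinal regimes (drainage, SMR, SNR) agreement is summarized in an
error matrix (field classes in rows, predicted classes in columns) with
producer's accuracy per class — exact and within +/-1 class — and overall
accuracy.  Ecosites are categorical, so only exact agreement is reported
for them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .class_systems import OrdinalClassSystem
from .edatopic import EdatopicGrid, classify_point, ellipse_assign

__all__ = [
    "AccuracyError",
    "ErrorMatrix",
    "build_error_matrix",
    "producers_accuracy",
    "overall_accuracy",
    "ecosite_accuracy",
    "ACCURACY_MODES",
]

ACCURACY_MODES = ("ellipse", "rectangle", "model")


class AccuracyError(ValueError):
    pass


@dataclass(frozen=True)
class ErrorMatrix:
    """Field-class x predicted-class count matrix in system class order."""

    labels: tuple[str, ...]
    counts: pd.DataFrame  # rows: field classes, columns: predicted classes

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def build_error_matrix(
    field_labels,
    predicted_labels,
    system: OrdinalClassSystem,
) -> ErrorMatrix:
    """Tally plots into a field x predicted error matrix.

    Half-class labels are resolved to the nearest full class first (ties
    toward the wetter/poorer class) since error-matrix rows and columns
    are full classes only.
    """
    field_labels = list(field_labels)
    predicted_labels = list(predicted_labels)
    if len(field_labels) != len(predicted_labels):
        raise AccuracyError(
            f"length mismatch: {len(field_labels)} field vs "
            f"{len(predicted_labels)} predicted labels"
        )
    labels = system.classes
    mat = pd.DataFrame(0, index=list(labels), columns=list(labels), dtype=int)
    for f, p in zip(field_labels, predicted_labels):
        mat.loc[system.resolve_to_full(f), system.resolve_to_full(p)] += 1
    return ErrorMatrix(labels=labels, counts=mat)


def producers_accuracy(matrix: ErrorMatrix) -> pd.DataFrame:
    """Per-class producer's accuracy: exact % and within +/-1 class %.

    Classes with no field plots (empty rows) are reported as NaN rather
    than 0 so they do not bias summaries.
    """
    counts = matrix.counts.to_numpy()
    n = len(matrix.labels)
    exact = np.full(n, np.nan)
    within1 = np.full(n, np.nan)
    for i in range(n):
        row_total = counts[i].sum()
        if row_total == 0:
            continue
        exact[i] = 100.0 * counts[i, i] / row_total
        lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        within1[i] = 100.0 * counts[i, lo : hi + 1].sum() / row_total
    return pd.DataFrame(
        {"exact_pct": exact, "within1_pct": within1}, index=list(matrix.labels)
    )


def overall_accuracy(matrix: ErrorMatrix) -> tuple[float, float]:
    """Overall exact % and within +/-1 class % over all plots."""
    counts = matrix.counts.to_numpy()
    total = counts.sum()
    if total == 0:
        raise AccuracyError("empty error matrix")
    n = counts.shape[0]
    diag = np.trace(counts)
    band = sum(
        counts[i, max(i - 1, 0) : min(i + 1, n - 1) + 1].sum() for i in range(n)
    )
    return 100.0 * diag / total, 100.0 * band / total


def ecosite_accuracy(
    plots: pd.DataFrame,
    grid: EdatopicGrid,
    mode: str,
) -> tuple[pd.DataFrame, float]:
    """Per-ecosite and overall agreement of reassigned vs field ecosites.

    ``plots`` needs columns ``ecosite_field`` plus the coordinates the
    mode uses: ``snr_field``/``smr_field`` for ellipse and rectangle
    modes, ``snr_pred``/``smr_pred`` for model mode.  Returns a table
    indexed by field ecosite id with columns ``total_plots``,
    ``within_plots`` and ``accuracy_pct``, and the pooled overall
    accuracy in percent.
    """
    if mode not in ACCURACY_MODES:
        raise AccuracyError(f"mode must be one of {ACCURACY_MODES}, got {mode!r}")
    snr_col, smr_col = (
        ("snr_pred", "smr_pred") if mode == "model" else ("snr_field", "smr_field")
    )
    for col in ("ecosite_field", snr_col, smr_col):
        if col not in plots.columns:
            raise AccuracyError(f"plots table missing column {col!r} for mode {mode!r}")
    bad = plots.index[plots[[snr_col, smr_col]].isna().any(axis=1)].tolist()
    if bad:
        raise AccuracyError(
            f"plots missing {mode}-mode coordinates: ids {bad[:10]}"
            + ("..." if len(bad) > 10 else "")
        )
    if mode == "ellipse":
        if not grid.ellipses:
            raise AccuracyError(f"grid {grid.region!r} has no ellipses")
        # ellipse grid carries *original* ids; compare on combined ids when
        # combination rules are available
        relabel = {o: c for o, (c, _) in grid.combination_rules.items()}
        assigned = []
        for x, y in zip(plots[snr_col], plots[smr_col]):
            raw = ellipse_assign(grid.ellipses, float(x), float(y))
            if raw is not None and relabel:
                raw = relabel.get(int(raw), raw)
            assigned.append(raw)
    else:
        assigned = [
            classify_point(grid, float(x), float(y))[0]
            for x, y in zip(plots[snr_col], plots[smr_col])
        ]

    field = plots["ecosite_field"].astype(int).to_numpy()
    rows = []
    for eid in sorted(set(field)):
        sel = field == eid
        total = int(sel.sum())
        within = int(sum(a == eid for a, s in zip(assigned, sel) if s))
        rows.append(
            {
                "ecosite": eid,
                "total_plots": total,
                "within_plots": within,
                "accuracy_pct": 100.0 * within / total,
            }
        )
    table = pd.DataFrame(rows).set_index("ecosite")
    overall = 100.0 * table["within_plots"].sum() / table["total_plots"].sum()
    return table, float(overall)
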