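"""Agreement accounting between two binary OG presence/absence matrices.

Used to compare the screen's own presence calls against an external
annotation source (e.g. an automated metabolic-model reconstruction) over
a shared strain × OG grid.  The comparison subtracts the second matrix
from the first row-wise, so with n strains each per-OG difference sum lies
in [-n, n]; a positive cell means the OG is called present by the first
matrix only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import LabelMismatchError

OG_CLASSES = ("identical", "a_only", "b_only", "mixed")


@dataclass
class ComparisonReport:
    per_og: pd.DataFrame  # columns: diff_sum, og_class; index: og_id
    class_counts: dict[str, int]
    class_percentages: dict[str, float]
    n_strains: int
    n_ogs: int


def binarize(hit_matrix: pd.DataFrame) -> pd.DataFrame:
    """Presence/absence calls: 1 iff hitN > 0."""
    return (hit_matrix > 0).astype(np.int64)


def _check_binary(df: pd.DataFrame, name: str) -> None:
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"matrix {name!r} contains non-binary entries")


def compare_annotations(
    a: pd.DataFrame, b: pd.DataFrame
) -> ComparisonReport:
    """Row-wise subtraction a − b with per-OG agreement classes.

    Both matrices must cover the same strains and OGs (order is reconciled
    by label).  Per OG: ``identical`` when every strain agrees, ``a_only``
    when every disagreement is a presence in ``a`` only, ``b_only`` for the
    mirror case, ``mixed`` when disagreements go both ways.
    """
    strains_a, strains_b = set(a.index), set(b.index)
    ogs_a, ogs_b = set(a.columns), set(b.columns)
    if strains_a != strains_b or ogs_a != ogs_b:
        diff = sorted((strains_a ^ strains_b) | (ogs_a ^ ogs_b))
        raise LabelMismatchError(f"label sets differ; symmetric difference: {diff}")
    _check_binary(a, "a")
    _check_binary(b, "b")
    b = b.loc[a.index, a.columns]

    diff = a.to_numpy(dtype=np.int64) - b.to_numpy(dtype=np.int64)
    classes: list[str] = []
    for j in range(diff.shape[1]):
        col = diff[:, j]
        if np.all(col == 0):
            classes.append("identical")
        elif np.all(col >= 0):
            classes.append("a_only")
        elif np.all(col <= 0):
            classes.append("b_only")
        else:
            classes.append("mixed")
    per_og = pd.DataFrame(
        {"diff_sum": diff.sum(axis=0), "og_class": classes}, index=a.columns
    )
    counts = {c: classes.count(c) for c in OG_CLASSES}
    m = len(classes)
    percentages = {c: 100.0 * counts[c] / m for c in OG_CLASSES}
    return ComparisonReport(per_og, counts, percentages, a.shape[0], m)
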