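"""Criteria quantification, scoring and ranking of species.

Each species row of the hit-count matrix C is turned into a criteria vector
x by the per-category quantification rules, then scored either unweighted,

    score(i) = sum_j c(i, j),

or with optimized criterion weights,

    score(i) = w^T x_i,

and species are ranked by descending score (rank 1 = best FFA-production
potential).  Reported scores are min–max normalized to [0, 1] so the top
strain prints 1.000000.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import OGCatalog
from .errors import DegenerateNormalizationError, MatrixAlignmentError


def quantify_criteria(hit_matrix: pd.DataFrame, catalog: OGCatalog) -> pd.DataFrame:
    """Apply the category quantification rules to a hit-count matrix.

    nOG columns become ``-hitN`` (presence of the OG hurts production);
    pOG columns keep ``hitN`` but an absent pOG (hitN = 0) is penalised
    with ``-1``; rOG columns keep ``hitN``.
    """
    if list(hit_matrix.columns) != catalog.og_ids:
        raise MatrixAlignmentError(
            "hit-matrix columns do not match catalog OG order"
        )
    values = hit_matrix.to_numpy(dtype=float).copy()
    cats = np.array([og.category for og in catalog.ogs])
    neg = cats == "nOG"
    pos = cats == "pOG"
    values[:, neg] *= -1.0
    pos_block = values[:, pos]
    pos_block[pos_block == 0] = -1.0
    values[:, pos] = pos_block
    return pd.DataFrame(values, index=hit_matrix.index, columns=hit_matrix.columns)


def score_unweighted(x: Sequence[float] | pd.Series) -> float:
    """Sum of the criteria values of one species (all weights equal 1)."""
    return float(np.asarray(x, dtype=float).sum())


def score_weighted(x: Sequence[float] | pd.Series, w: Sequence[float] | pd.Series) -> float:
    """Weighted score w^T x of one species."""
    xa = np.asarray(x, dtype=float)
    wa = np.asarray(w, dtype=float)
    if xa.shape != wa.shape:
        raise ValueError(
            f"length mismatch: criteria {xa.shape} vs weights {wa.shape}"
        )
    return float(wa @ xa)


def score_matrix(
    criteria: pd.DataFrame, weights: Sequence[float] | pd.Series | None = None
) -> pd.Series:
    """Score every species row; ``weights=None`` means unit weights."""
    if weights is None:
        return criteria.sum(axis=1)
    wa = np.asarray(weights, dtype=float)
    if wa.shape[0] != criteria.shape[1]:
        raise ValueError("weight length does not match criteria columns")
    return pd.Series(criteria.to_numpy(dtype=float) @ wa, index=criteria.index)


def rank_species(scores: Mapping[str, float] | pd.Series) -> pd.DataFrame:
    """Rank species by descending score; ties broken by ascending id.

    Returns a DataFrame with columns ``rank, species_id, raw_score``,
    ordered by rank (rank 1 = highest score).
    """
    series = pd.Series(dict(scores), dtype=float)
    if series.empty:
        raise ValueError("no scores to rank")
    order = sorted(series.index, key=lambda s: (-series[s], s))
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "species_id": order,
            "raw_score": [series[s] for s in order],
        }
    )


def normalize_scores(scores: Mapping[str, float] | pd.Series) -> pd.Series:
    """Min–max transform: best score -> 1.0, worst -> 0.0.

    Raises :class:`DegenerateNormalizationError` when all scores are equal.
    """
    series = pd.Series(dict(scores), dtype=float)
    if len(series) < 2:
        raise DegenerateNormalizationError("need at least 2 species to normalize")
    lo, hi = series.min(), series.max()
    if hi == lo:
        raise DegenerateNormalizationError("degenerate normalization: all scores equal")
    return (series - lo) / (hi - lo)


def rank_table(
    criteria: pd.DataFrame,
    weights: Sequence[float] | pd.Series | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Full ranking table: rank, species_id, raw_score, normalized_score.

    Normalized scores are the min–max transform of the raw scores (monotone,
    so they induce the same ranking); with ``normalize=False`` the column
    repeats the raw scores.
    """
    scores = score_matrix(criteria, weights)
    table = rank_species(scores)
    if normalize:
        norm = normalize_scores(scores)
        table["normalized_score"] = [norm[s] for s in table["species_id"]]
    else:
        table["normalized_score"] = table["raw_score"]
    return table
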