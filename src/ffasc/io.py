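"""TSV readers/writers for the matrices and tables the CLI exchanges."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Labeled species × OG matrix: first column species_id, header og ids."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="species_id")


def read_weights_tsv(path: str | Path) -> pd.Series:
    """Two-column TSV og_id/weight, in catalog column order."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns[:2]) != ["og_id", "weight"]:
        raise ValueError("weights file must have columns og_id, weight")
    return pd.Series(df["weight"].to_numpy(), index=df["og_id"], name="weight")


def write_weights_tsv(weights: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"og_id": weights.index, "weight": weights.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def write_ranking_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Ranking table with scores printed to 6 decimals."""
    out = table[["rank", "species_id", "raw_score", "normalized_score"]].copy()
    out["raw_score"] = out["raw_score"].map(lambda v: f"{v:.6f}")
    out["normalized_score"] = out["normalized_score"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)
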