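"""SuperTiles: class-balanced aggregation augmentation of feature tables.

A SuperTile is one synthetic data row formed by averaging ``t`` randomly
sampled single-cell rows of the same class. Sampling within one tile is
uniform without replacement (a subset of the class's rows); tiles are
drawn independently, so for sample-time ``s`` > 1 the scheme bootstraps
the class with replacement across tiles. Every class receives the same
number of tiles,

    n_tiles_per_class = floor(n_minority * s / t),

anchored on the minority class, which simultaneously balances the
classes and couples the synthetic dataset size to the original one.
Averaging contracts within-class variance by ~1/t while preserving the
class means and inter-feature correlations, which is what turns heavily
overlapping single-cell class distributions into separable tile-level
ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SuperTileParams", "SuperTileSet", "n_supertiles", "generate_supertiles", "sweep_supertiles"]


@dataclass(frozen=True)
class SuperTileParams:
    """t = rows averaged per tile; s = sample-time (bootstrap factor)."""

    t: int
    s: int
    seed: int = 0
    replace: bool = False  # within-tile sampling with replacement

    def __post_init__(self):
        if self.t < 1 or self.s < 1:
            raise ValueError(f"t and s must be >= 1, got t={self.t}, s={self.s}")


@dataclass
class SuperTileSet:
    """Balanced table of aggregated rows with full provenance.

    ``table`` carries the averaged numeric features plus the class
    label column; ``source_rows`` maps each tile (row position) to the
    positional indices of the original rows it averaged.
    """

    table: pd.DataFrame
    params: SuperTileParams
    label_col: str = "class_id"
    source_rows: list[np.ndarray] = field(default_factory=list)

    @property
    def tiles_per_class(self) -> pd.Series:
        return self.table[self.label_col].value_counts()


def n_supertiles(n_minority: int, s: int, t: int) -> int:
    """Per-class tile count: floor(n_minority * s / t)."""
    if n_minority < 1 or s < 1 or t < 1:
        raise ValueError("n_minority, s and t must all be >= 1")
    return (n_minority * s) // t


def generate_supertiles(
    table: pd.DataFrame,
    params: SuperTileParams,
    label_col: str = "class_id",
    feature_cols: list[str] | None = None,
    keep_sources: bool = True,
) -> SuperTileSet:
    """Build the class-balanced SuperTile set from a feature table.

    Each class contributes ``n_supertiles(n_minority, s, t)`` tiles; a
    tile is the arithmetic mean of ``t`` rows sampled uniformly from
    that class (without replacement within the tile unless
    ``params.replace``). Donor identity is not propagated: tiles average
    across donors; provenance keeps the source row indices instead.
    Deterministic for fixed (table, params).
    """
    if label_col not in table.columns:
        raise ValueError(f"label column {label_col!r} not in table")
    labels = table[label_col]
    counts = labels.value_counts()
    if len(counts) < 1 or (counts < 1).any():
        raise ValueError("every class must be nonempty")
    if feature_cols is None:
        feature_cols = [
            c
            for c in table.columns
            if c not in (label_col, "cell_id", "donor_id")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    t, s = params.t, params.s
    if not params.replace and t > counts.min():
        raise ValueError(
            f"t={t} exceeds the smallest class size {counts.min()} with replace=False"
        )
    n_tiles = n_supertiles(int(counts.min()), s, t)

    rng = np.random.default_rng(params.seed)
    X = table[feature_cols].to_numpy(dtype=float)
    out_rows = []
    out_labels = []
    sources: list[np.ndarray] = []
    for cls in sorted(counts.index):
        idx = np.flatnonzero((labels == cls).to_numpy())
        # one (n_tiles, t) index draw per class
        if params.replace:
            picks = rng.choice(idx, size=(n_tiles, t), replace=True)
        else:
            picks = np.stack([rng.choice(idx, size=t, replace=False) for _ in range(n_tiles)])
        out_rows.append(X[picks].mean(axis=1))
        out_labels.append(np.full(n_tiles, cls))
        if keep_sources:
            sources.extend(picks)
    tiles = pd.DataFrame(np.concatenate(out_rows), columns=feature_cols)
    tiles[label_col] = np.concatenate(out_labels)
    return SuperTileSet(table=tiles, params=params, label_col=label_col, source_rows=sources)


def sweep_supertiles(
    table: pd.DataFrame,
    t_values: list[int],
    s_values: list[int],
    seed: int = 0,
    label_col: str = "class_id",
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Union of SuperTile sets over a (t, s) grid, provenance-tagged.

    Returns one concatenated table with ``t`` and ``s`` columns so
    downstream accuracy-vs-tiles experiments can group per block.
    Per-class counts are equal within each (t, s) block.
    """
    if not t_values or not s_values:
        raise ValueError("t_values and s_values must be nonempty")
    blocks = []
    for ti in t_values:
        for si in s_values:
            # same base seed per block: a singleton grid reproduces a single call
            params = SuperTileParams(t=ti, s=si, seed=seed)
            block = generate_supertiles(
                table, params, label_col=label_col, feature_cols=feature_cols, keep_sources=False
            ).table
            block["t"] = ti
            block["s"] = si
            blocks.append(block)
    return pd.concat(blocks, ignore_index=True)
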