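"""Topology-based target prioritization with the R-statistic.

Each candidate target carries two topology statistics computed on the PPI
network: its average shortest path length ``xi`` and its betweenness
centrality ``xj``.  Targets that are close to everything (small ``xi``)
and that broker many shortest paths (large ``xj``) are topologically
important.  The R-statistic combines the two on a common [0, 1] scale::

    R = w * minmax(xi) + (1 - w) * minmax(1 / xj),      w = 0.5

where ``minmax`` rescales over the cohort of targets being ranked
(smaller R = more important).  Because 1/xj diverges at zero, betweenness
values are clamped below at a small floor before inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ScoreConfig",
    "r_score",
    "rank_targets",
    "load_cki_target_table",
]

REQUIRED_COLUMNS = ("avg_shortest_path", "betweenness")


@dataclass(frozen=True)
class ScoreConfig:
    """Weights and numerical guards for the R-statistic.

    weight_xi
        Weight on the path-length term; the betweenness term gets
        ``1 - weight_xi``.  Default 0.5 (the two terms each count 50%).
    xj_floor
        Betweenness values are clamped below at this floor before the
        1/xj transform, keeping the statistic finite for leaf nodes.
        Default 1e-5.
    """

    weight_xi: float = 0.5
    xj_floor: float = 1e-5

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_xi <= 1.0:
            raise ValueError("weight_xi must lie in [0, 1]")
        if self.xj_floor <= 0:
            raise ValueError("xj_floor must be positive")


def load_cki_target_table() -> pd.DataFrame:
    """Packaged table of the 48 candidate anti-HCC targets of Compound
    Kushen Injection with their published topology statistics
    (``avg_shortest_path``, ``betweenness``) and status
    (validated/predicted)."""
    ref = resources.files("netpharm.data") / "cki_target_topology.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def r_score(records: pd.DataFrame, cfg: ScoreConfig | None = None) -> pd.DataFrame:
    """Compute the R-statistic for a cohort of targets.

    Parameters
    ----------
    records
        DataFrame with columns ``avg_shortest_path`` (xi, positive) and
        ``betweenness`` (xj).  Any other columns pass through.
    cfg
        Weighting and clamping options.

    Returns
    -------
    Copy of ``records`` with an ``r`` column appended.  Min/max
    normalization is taken over exactly the rows supplied, so R values
    are only comparable within one cohort.  If a cohort is degenerate on
    an axis (max = min), that term contributes 0 for every record.
    """
    cfg = cfg or ScoreConfig()
    if len(records) < 2:
        raise ValueError("R-statistic needs a cohort of at least 2 records")
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"missing required column {col!r}")
    xi = records["avg_shortest_path"].to_numpy(dtype=float)
    xj = records["betweenness"].to_numpy(dtype=float)
    if np.any(~np.isfinite(xi)) or np.any(xi <= 0):
        raise ValueError("avg_shortest_path (xi) must be positive and finite")
    inv_xj = 1.0 / np.maximum(xj, cfg.xj_floor)

    def _minmax(v: np.ndarray) -> np.ndarray:
        span = v.max() - v.min()
        if span == 0:
            return np.zeros_like(v)
        return (v - v.min()) / span

    r = cfg.weight_xi * _minmax(xi) + (1.0 - cfg.weight_xi) * _minmax(inv_xj)
    out = records.copy()
    out["r"] = r
    return out


def rank_targets(
    records: pd.DataFrame,
    k: int,
    status: str | None = None,
) -> pd.DataFrame:
    """Return the top-``k`` targets by ascending R.

    Ties are broken by larger betweenness, then by accession (or gene
    name) lexicographically; the sort is stable, so fully tied records
    keep their input order.  ``status`` optionally restricts the ranking
    to ``"validated"`` or ``"predicted"`` targets (the R column must
    already have been computed on the full cohort).
    """
    if "r" not in records.columns:
        raise ValueError("records lack an 'r' column; call r_score first")
    if k < 1:
        raise ValueError("k must be a positive integer")
    df = records
    if status is not None:
        df = df[df["status"] == status]
    if k > len(df):
        warnings.warn(
            f"requested top-{k} of a cohort of {len(df)}; returning all",
            stacklevel=2,
        )
        k = len(df)
    tiebreak = "accession" if "accession" in df.columns else (
        "gene" if "gene" in df.columns else None
    )
    df = df.copy()
    df["_neg_xj"] = -df["betweenness"]
    by = ["r", "_neg_xj"] + ([tiebreak] if tiebreak else [])
    out = df.sort_values(by, kind="stable").drop(columns="_neg_xj")
    return out.head(k)
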