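"""Rank-sum TLR7 ligation score and cross-tissue aggregation.

Each gene in a tissue is ranked in ascending order on four criteria —
total UU count, maximum UU richness, female expression bias (strongest
male bias ranked 1), and expression level (mean female TPM) — and the
TLR7 ligation score is the sum of the four ranks, so a higher score means
stronger evidence for being a TLR7-ligand source.  Per-tissue scores are
normalized by the tissue maximum and averaged across tissues.

Ties receive the average of the spanned ranks, which preserves the total
rank mass: each criterion's ranks always average to (N + 1) / 2.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

RANK_COLUMNS = ("rank_uu", "rank_maxrichness", "rank_sexbias", "rank_expression")


def rank_ascending(values) -> np.ndarray:
    """Ascending ranks (smallest value gets rank 1); ties averaged."""
    arr = np.asarray(values, dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError("cannot rank missing values")
    return rankdata(arr, method="average")


def top_percent(position: int, n: int) -> float:
    """Descending-rank position as a percentage of N, rounded half-up to
    two decimals (position 4 of 15,003 -> 0.03)."""
    if not 1 <= position <= n:
        raise ValueError(f"position {position} outside 1..{n}")
    pct = Decimal(100 * position) / Decimal(n)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def ligation_score(
    profiles: pd.DataFrame,
    expression: pd.Series,
    sexbias: pd.Series,
) -> pd.DataFrame:
    """Per-gene rank-sum ligation score for one tissue.

    Parameters
    ----------
    profiles : gene-indexed table with ``uu_count`` and ``max_window_uu``.
    expression : per-gene expression criterion (mean female TPM).
    sexbias : per-gene log2 female/male fold-change.

    The three inputs must cover the same gene universe.  Output is sorted
    by score descending, with normalized_score = score / max score and
    top_percent from the descending position (ties share the best
    position).
    """
    universe = set(profiles.index)
    for name, other in (("expression", expression), ("sexbias", sexbias)):
        diff = universe.symmetric_difference(other.index)
        if diff:
            raise ValueError(
                f"gene universe mismatch between profiles and {name}: "
                f"{sorted(diff)[:10]}"
            )
    genes = profiles.index
    out = pd.DataFrame(index=genes)
    out["rank_uu"] = rank_ascending(profiles["uu_count"])
    out["rank_maxrichness"] = rank_ascending(profiles["max_window_uu"])
    out["rank_sexbias"] = rank_ascending(sexbias.loc[genes])
    out["rank_expression"] = rank_ascending(expression.loc[genes])
    out["ligation_score"] = out[list(RANK_COLUMNS)].sum(axis=1)
    out["normalized_score"] = out["ligation_score"] / out["ligation_score"].max()
    position = rankdata(-out["ligation_score"], method="min").astype(int)
    n = len(genes)
    out["top_percent"] = [top_percent(int(p), n) for p in position]
    # Stable sort on a pre-sorted index makes tie order deterministic.
    return out.sort_index().sort_values(
        "ligation_score", ascending=False, kind="mergesort"
    )


def normalize_and_average(per_tissue: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Average per-tissue normalized ligation scores per gene.

    A gene absent from some tissues (it failed that tissue's filters) is
    averaged over the tissues where it is present; ``n_tissues`` records
    how many contributed, so tissue-restricted genes are not punished for
    missingness.
    """
    if not per_tissue:
        raise ValueError("no tissue tables supplied")
    frames = []
    for tissue, table in per_tissue.items():
        frames.append(
            pd.DataFrame(
                {"normalized_score": table["normalized_score"], "tissue": tissue}
            )
        )
    stacked = pd.concat(frames)
    grouped = stacked.groupby(level=0)["normalized_score"]
    out = pd.DataFrame(
        {
            "mean_normalized_score": grouped.mean(),
            "n_tissues": grouped.size().astype(int),
        }
    )
    return out.sort_values("mean_normalized_score", ascending=False, kind="mergesort")
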