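"""Single-cell gene-set module scoring and the per-patient IFN screen.

The module score is the classic bin-matched control score: genes are
binned into equal-frequency bins by average expression across cells, each
gene-set gene draws control genes from its own bin, and a cell's score is
the mean expression of the gene set minus the mean of the pooled control
genes.  Subtracting expression-matched controls removes the cell-level
depth/activity component that a raw gene-set mean would carry.

The screen aggregates scores and gene expression per patient (patients
contributing fewer than ``min_cells`` cells are excluded) and correlates
each gene's per-patient mean expression with the per-patient mean score
(Pearson), flagging positively correlated genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def module_score(
    expr: pd.DataFrame,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell module score with expression-bin-matched controls.

    Parameters
    ----------
    expr : genes x cells matrix on a log-normalized scale.
    gene_set : gene symbols of the module (e.g. IFN-stimulated genes).
    n_bins : number of equal-frequency bins on average expression.
    n_ctrl : control genes drawn (with replacement) per gene-set gene.
    seed : seed for the control draw and tie-break shuffle; fixed seed
        gives bit-reproducible scores.
    """
    if not gene_set:
        raise ValueError("gene set is empty")
    gene_set = list(dict.fromkeys(gene_set))
    missing = [g for g in gene_set if g not in expr.index]
    if missing:
        raise ValueError(f"gene set genes absent from matrix: {missing}")

    rng = np.random.default_rng(seed)
    avg = expr.mean(axis=1).to_numpy()
    n_genes = len(expr.index)
    # Equal-frequency bins on average expression; ties broken by a seeded
    # shuffle so bin boundaries are not order-dependent.
    tiebreak = rng.permutation(n_genes)
    order = np.lexsort((tiebreak, avg))
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = (np.arange(n_genes) * n_bins) // n_genes
    bin_index = pd.Series(bin_of, index=expr.index)

    members_by_bin = {
        b: expr.index[bin_index.to_numpy() == b] for b in np.unique(bin_of)
    }
    control_pool: list[str] = []
    for gene in gene_set:
        candidates = members_by_bin[bin_index[gene]]
        control_pool.extend(rng.choice(candidates, size=n_ctrl, replace=True))

    set_mean = expr.loc[gene_set].mean(axis=0)
    ctrl_mean = expr.loc[control_pool].mean(axis=0)
    score = set_mean - ctrl_mean
    score.name = "module_score"
    return score


def patient_screen(
    expr: pd.DataFrame,
    scores: pd.Series,
    cell_meta: pd.DataFrame,
    min_cells: int = 10,
    genes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient aggregation and gene-vs-score correlation screen.

    Parameters
    ----------
    expr : genes x cells matrix (same cells as ``scores``).
    scores : per-cell module score.
    cell_meta : table with a ``patient_id`` column indexed by cell id,
        covering every cell in ``expr``.
    min_cells : patients contributing fewer cells are excluded.
    genes : restrict the screen to these genes (default: all genes).

    Returns
    -------
    per_patient : patient-indexed table with ``mean_score`` and ``n_cells``
        plus one mean-expression column per screened gene.
    screen : gene-indexed table with Pearson ``r``, two-sided ``p``,
        ``direction`` and a ``positive`` flag (r > 0 and p < 0.05).
    """
    cells = expr.columns
    unmapped = cells.difference(cell_meta.index)
    if len(unmapped):
        raise ValueError(f"cells without patient metadata: {list(unmapped)[:5]}")
    patient = cell_meta.loc[cells, "patient_id"]
    sizes = patient.value_counts()
    kept_patients = sizes.index[sizes >= min_cells]
    if len(kept_patients) < 3:
        raise ValueError(
            f"only {len(kept_patients)} patients with >= {min_cells} cells; "
            "correlation needs at least 3"
        )
    keep_cells = cells[patient.isin(kept_patients)]
    patient = patient.loc[keep_cells]

    if genes is None:
        genes = list(expr.index)
    mean_expr = expr.loc[genes, keep_cells].T.groupby(patient).mean()
    mean_score = scores.loc[keep_cells].groupby(patient).mean()
    n_cells = patient.groupby(patient).size()

    per_patient = mean_expr.copy()
    per_patient.insert(0, "mean_score", mean_score)
    per_patient.insert(1, "n_cells", n_cells.astype(int))
    per_patient = per_patient.sort_index()

    rows = []
    y = per_patient["mean_score"].to_numpy()
    for gene in genes:
        x = per_patient[gene].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x, y)
        rows.append(
            {
                "gene_symbol": gene,
                "r": r,
                "p": p,
                "direction": "positive" if r > 0 else ("negative" if r < 0 else "none"),
                "positive": bool(r > 0 and p < 0.05),
            }
        )
    screen = pd.DataFrame(rows).set_index("gene_symbol")
    return per_patient, screen
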