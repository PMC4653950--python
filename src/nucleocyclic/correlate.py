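"""The 48-parameter table per representative TSS and its Spearman matrix.

Parameter roster (48 columns, 1128 pairs): per strain x tissue, expression
(log10 with pseudocount) and TSS-cluster breadth (12); per strain x tissue
x side, nucleosome periodicity Np and consistency Na (24); focal strain
only, each base's upstream count, downstream count and asymmetry (12).
Rows with any missing value are dropped before correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

STRAINS = ("focal", "sister")
TISSUES = ("blastula", "testes", "liver")
SIDES = ("upstream", "downstream")
EXPRESSION_PSEUDOCOUNT = 0.01


def default_parameter_roster(
    strains=STRAINS, tissues=TISSUES, sides=SIDES, bases="ACGT"
) -> list[str]:
    roster = []
    for s in strains:
        for t in tissues:
            roster += [f"{s}_Exp_{t}", f"{s}_Br_{t}"]
    for s in strains:
        for t in tissues:
            for side in sides:
                roster += [f"{s}_Np_{t}_{side}", f"{s}_Na_{t}_{side}"]
    for b in bases:
        roster += [f"focal_{b}_up", f"focal_{b}_down", f"focal_{b}_Sa"]
    return roster


def log_expression(expr: np.ndarray, pseudocount: float = EXPRESSION_PSEUDOCOUNT):
    """log10(expression + pseudocount), the scale entering the table."""
    return np.log10(np.asarray(expr, dtype=float) + pseudocount)


def assemble_parameter_table(
    columns: pd.DataFrame | dict,
    roster: list[str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Validate the column roster and drop rows with missing values.

    Returns (complete table, number of dropped rows).  Raises when roster
    columns are absent (listing them) or the complete table is empty.
    """
    frame = pd.DataFrame(columns)
    if roster is None:
        roster = default_parameter_roster()
    missing_cols = [c for c in roster if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"parameter roster incomplete; absent: {missing_cols}")
    frame = frame[roster].astype(float)
    complete = frame.dropna()
    n_dropped = len(frame) - len(complete)
    if complete.empty:
        raise ValueError("no TSS has complete information for all parameters")
    return complete, n_dropped


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame  # Spearman rank correlation, symmetric, unit diagonal
    p: pd.DataFrame  # two-sided p (t approximation)
    threshold: float  # Bonferroni-corrected significance level
    significant: pd.DataFrame  # p < threshold (off-diagonal mask)
    n_rows: int


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """alpha / n_tests (e.g. 0.05 / 1128 ~ 4.4e-5)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def spearman_matrix(table: pd.DataFrame, alpha: float = 0.05) -> CorrelationMatrix:
    """Pairwise Spearman correlation with Bonferroni mask over all pairs.

    Ties receive average ranks; constant columns yield NaN correlations
    (flagged, not significant).  Needs >= 3 complete rows.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 complete rows")
    cols = list(table.columns)
    k = len(cols)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", sps.ConstantInputWarning)
        r, p = sps.spearmanr(table.to_numpy(), axis=0)
    if k == 2:  # scipy returns scalars for a single pair
        r = np.array([[1.0, r], [r, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    np.fill_diagonal(r, 1.0)
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    n_tests = k * (k - 1) // 2
    thr = bonferroni_threshold(alpha, n_tests)
    sig = (p_df < thr) & ~np.eye(k, dtype=bool)
    return CorrelationMatrix(
        r=r_df, p=p_df, threshold=thr, significant=sig, n_rows=len(table)
    )


def save_heatmap(matrix: CorrelationMatrix, path) -> None:
    """Render the correlation matrix as a heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 9))
    im = ax.imshow(matrix.r.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(matrix.r.columns)))
    ax.set_xticklabels(matrix.r.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(len(matrix.r.index)))
    ax.set_yticklabels(matrix.r.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="Spearman r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
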