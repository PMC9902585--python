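"""Per-sample program activity scores with rank-matched control genes.

A program's activity in a sample is the differential mean expression of the
program genes versus a pool of control genes matched on overall expression
level: all genes are ranked by mean expression, split into 25 contiguous
rank intervals, and from every interval that contains a program gene the
top-ranked non-program genes (up to 100 per interval) enter the control
pool.  Matching the controls' expression rank removes the depth/abundance
component of the difference, so the score isolates the program-specific
signal.

Scores are computed on log2(CPM + 1): differential means on raw CPM would be
dominated by a handful of high expressors.  Control selection is
deterministic given (matrix, program); an optional resampled-control variant
draws the per-bin controls at random instead (seeded), for uncertainty
checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableGeneSet",
    "ActivityScoreVector",
    "cpm_normalize",
    "select_variable_genes",
    "assign_rank_bins",
    "score_activity",
]

CPM_TOTAL = 1e6


def cpm_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale every sample column to a total of one million counts.

    Parameters
    ----------
    matrix
        Genes x samples, non-negative entries.

    Raises
    ------
    ValueError
        On negative entries or an all-zero sample column (named in the
        message).
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression matrix contains negative entries")
    totals = values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [str(matrix.columns[i]) for i in zero]
        raise ValueError(f"all-zero sample column(s): {names}")
    out = pd.DataFrame(
        values * (CPM_TOTAL / totals), index=matrix.index, columns=matrix.columns
    )
    out.attrs["normalization"] = "cpm"
    return out


@dataclass
class VariableGeneSet:
    """Most-variable genes and the mean/CV statistics behind the selection."""

    genes: list[str]
    stats: pd.DataFrame  # columns: mean, cv, cv_residual

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("variable gene set is empty")


def select_variable_genes(
    matrix: pd.DataFrame, top_n: int, n_windows: int = 20
) -> VariableGeneSet:
    """Top genes by coefficient of variation above the mean-CV trend.

    The CV of every expressed gene is compared with the median CV of genes
    of similar mean (``n_windows`` contiguous mean-rank windows); the genes
    with the largest positive residual are returned.  Deterministic: ties
    break by gene symbol.
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    expressed = mean > 0
    if int(expressed.sum()) < top_n:
        raise ValueError(
            f"only {int(expressed.sum())} genes with nonzero mean; "
            f"cannot select top_n={top_n}"
        )
    sd = values.std(axis=1, ddof=1) if values.shape[1] > 1 else np.zeros(len(mean))
    stats = pd.DataFrame(
        {"mean": mean, "cv": np.where(expressed, sd / np.where(expressed, mean, 1), np.nan)},
        index=matrix.index,
    ).loc[expressed]

    # rolling-median trend over mean-rank windows; residual = CV - window median.
    # Each window needs several genes for a stable median, so the window count
    # shrinks on small matrices.
    order = stats.sort_values(["mean", "cv"]).index
    n_windows_eff = max(1, min(n_windows, len(order) // 10))
    windows = np.array_split(np.arange(len(order)), n_windows_eff)
    trend = pd.Series(index=order, dtype=float)
    for w in windows:
        block = order[w]
        trend.loc[block] = stats.loc[block, "cv"].median()
    stats["cv_residual"] = stats["cv"] - trend

    # stable sort on symbol first so equal residuals break lexicographically
    ranked = stats.sort_index().sort_values(
        "cv_residual", ascending=False, kind="mergesort"
    )
    positive = [g for g in ranked.index if stats.loc[g, "cv"] > 0]
    selected = positive[:top_n]
    if len(selected) < top_n:
        # constant genes only as a last resort, in symbol order
        flat = sorted(g for g in ranked.index if stats.loc[g, "cv"] == 0)
        selected += flat[: top_n - len(selected)]
    return VariableGeneSet(genes=selected, stats=stats)


def assign_rank_bins(matrix: pd.DataFrame, n_bins: int = 25) -> pd.Series:
    """Contiguous expression-rank intervals of near-equal size.

    Genes are ranked by mean expression (highest first, ties broken by gene
    symbol) and split into ``n_bins`` contiguous intervals whose sizes
    differ by at most one; earlier bins hold the higher-expressed genes.
    """
    if not 1 <= n_bins <= matrix.shape[0]:
        raise ValueError("n_bins must lie in [1, n_genes]")
    mean = matrix.mean(axis=1)
    order = mean.to_frame("mean").sort_index().sort_values(
        "mean", ascending=False, kind="mergesort"
    ).index
    bins = pd.Series(0, index=matrix.index, name="bin")
    for b, chunk in enumerate(np.array_split(np.arange(len(order)), n_bins)):
        bins.loc[order[chunk]] = b
    return bins


@dataclass
class ActivityScoreVector:
    """Per-sample score for one functional attribute (EMT or mitotic).

    ``control_genes`` records the rank-matched background pool actually
    used; ``bin_assignments`` the expression bin of every gene.
    """

    attribute: str
    scores: pd.Series
    control_genes: list[str]
    program_genes: list[str]
    bin_assignments: pd.Series = field(repr=False)
    seed: int | None = None

    def __post_init__(self) -> None:
        overlap = set(self.control_genes) & set(self.program_genes)
        if overlap:
            raise ValueError(f"control genes overlap the program: {sorted(overlap)}")


def score_activity(
    matrix: pd.DataFrame,
    program: Sequence[str],
    attribute: str = "score",
    n_bins: int = 25,
    n_control_per_bin: int = 100,
    seed: int | None = None,
    resample_controls: bool = False,
) -> ActivityScoreVector:
    """Differential mean expression of program genes vs bin-matched controls.

    For every expression-rank bin that contains at least one program gene,
    up to ``n_control_per_bin`` top-ranked non-program genes from that bin
    join the control pool; the per-sample score is
    mean(log2(CPM+1) of program) - mean(log2(CPM+1) of controls).

    ``matrix`` must be CPM-normalized (see :func:`cpm_normalize`).  With
    ``resample_controls=True`` the per-bin controls are drawn uniformly at
    random (seeded) instead of top-ranked.
    """
    program = list(dict.fromkeys(program))
    present = [g for g in program if g in matrix.index]
    if not present:
        raise ValueError(f"program genes absent from the matrix: {sorted(program)}")

    bins = assign_rank_bins(matrix, n_bins=n_bins)
    mean = matrix.mean(axis=1)
    program_set = set(present)
    rng = np.random.default_rng(seed) if resample_controls else None

    controls: list[str] = []
    for b in sorted(bins.loc[present].unique()):
        members = bins.index[bins == b]
        eligible = [g for g in members if g not in program_set]
        if not eligible:
            continue
        ranked = (
            mean.loc[eligible]
            .to_frame("mean")
            .sort_index()
            .sort_values("mean", ascending=False, kind="mergesort")
            .index.tolist()
        )
        if rng is not None:
            take = min(n_control_per_bin, len(ranked))
            controls += list(rng.choice(ranked, size=take, replace=False))
        else:
            controls += ranked[:n_control_per_bin]

    if not controls:
        # degenerate: program fills all of its bins; fall back to every
        # non-program gene as background
        controls = [g for g in matrix.index if g not in program_set]
        if not controls:
            raise ValueError("no control genes available: program covers the matrix")
        warnings.warn(
            "program genes exhaust their expression bins; falling back to a "
            "matrix-wide control pool",
            stacklevel=2,
        )

    log_expr = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    log_df = pd.DataFrame(log_expr, index=matrix.index, columns=matrix.columns)
    scores = log_df.loc[present].mean(axis=0) - log_df.loc[controls].mean(axis=0)
    scores.name = attribute
    return ActivityScoreVector(
        attribute=attribute,
        scores=scores,
        control_genes=controls,
        program_genes=present,
        bin_assignments=bins,
        seed=seed,
    )
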