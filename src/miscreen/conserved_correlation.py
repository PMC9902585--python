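"""Cross-dataset conserved correlation with a focal gene, plus ORA.

Given several independent expression datasets, the focal gene (e.g. a
receptor of interest) is Spearman-correlated against every other gene
within each dataset; after per-dataset Benjamini-Hochberg correction, a
gene is called *conserved-associated* when its correlation is significant
in at least ``k`` of the datasets (default 2, mirroring a 2-of-8 rule).
The conserved set is then tested for pathway over-representation with the
one-sided hypergeometric tail.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["ConservationResult", "correlate_focal", "ora", "spearman_vs_reference"]


def spearman_vs_reference(
    values: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p of every row of ``values`` vs ``reference``.

    Vectorized: Pearson correlation of midranks with the t-distribution
    p-value (n-2 df), matching ``scipy.stats.spearmanr`` row by row.
    Constant rows get rho = 0 and p = 1.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    if n != np.asarray(reference).size:
        raise ValueError("reference length must match the number of columns")
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    r_rows = sps.rankdata(values, axis=1)
    r_ref = sps.rankdata(reference)
    r_rows -= r_rows.mean(axis=1, keepdims=True)
    r_ref = r_ref - r_ref.mean()
    denom = np.sqrt((r_rows**2).sum(axis=1) * (r_ref**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (r_rows @ r_ref) / denom
    rho = np.where(np.isfinite(rho), rho, 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * sps.t.sf(np.abs(t), n - 2))
    p = np.where(denom > 0, p, 1.0)
    return rho, p


@dataclass
class ConservationResult:
    """Per-dataset correlations and the conserved set under the >=k rule."""

    per_dataset: pd.DataFrame  # long: dataset, gene, rho, p, q, significant
    n_significant: pd.Series  # per gene
    conserved: list[str]
    focal_gene: str
    k: int
    alpha: float
    params: dict = field(default_factory=dict)


def correlate_focal(
    datasets: Sequence[pd.DataFrame] | Mapping[str, pd.DataFrame],
    focal_gene: str,
    alpha: float = 0.05,
    k: int = 2,
    use_adjusted: bool = True,
) -> ConservationResult:
    """Spearman-screen the focal gene against all genes in every dataset.

    Parameters
    ----------
    datasets
        Genes x samples matrices (bulk samples or single cells), as a list
        or a name -> matrix mapping.
    use_adjusted
        Call significance on BH-adjusted q <= alpha (default) or on raw
        p <= alpha.

    The focal gene itself is excluded from the result.  Genes absent from a
    dataset are simply untested there.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(datasets, Mapping):
        named = list(datasets.items())
    else:
        named = [(f"dataset_{i}", d) for i, d in enumerate(datasets)]
    if not named:
        raise ValueError("no datasets given")

    frames = []
    for name, mat in named:
        if focal_gene not in mat.index:
            raise ValueError(f"focal gene {focal_gene!r} missing from {name!r}")
        others = mat.index[mat.index != focal_gene]
        rho, p = spearman_vs_reference(
            mat.loc[others].to_numpy(dtype=float),
            mat.loc[focal_gene].to_numpy(dtype=float),
        )
        q = multipletests(p, method="fdr_bh")[1]
        sig = (q <= alpha) if use_adjusted else (p <= alpha)
        frames.append(
            pd.DataFrame(
                {"dataset": name, "gene": others, "rho": rho, "p": p, "q": q,
                 "significant": sig}
            )
        )
    per_dataset = pd.concat(frames, ignore_index=True)
    n_significant = (
        per_dataset.groupby("gene")["significant"].sum().astype(int)
    )
    conserved = sorted(n_significant.index[n_significant >= k]) if len(named) >= 2 else []
    if len(named) < 2 and n_significant.ge(k).any():
        logger.info("single dataset: conservation criterion needs >=2 datasets")
    logger.info(
        "conserved correlation: %d genes significant in >=%d of %d datasets",
        len(conserved), k, len(named),
    )
    return ConservationResult(
        per_dataset=per_dataset,
        n_significant=n_significant,
        conserved=conserved,
        focal_gene=focal_gene,
        k=k,
        alpha=alpha,
        params={"use_adjusted": use_adjusted, "n_datasets": len(named)},
    )


def ora(
    selected: Sequence[str],
    pathways: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each pathway.

    ``p = P(overlap >= observed)`` drawing |selected| genes from the
    universe without replacement, with BH correction across pathways.
    Pathways are intersected with the universe first; pathways that become
    empty are dropped with a warning.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    selected_set = set(selected)
    if not selected_set:
        raise ValueError("empty selected set")
    stray = selected_set - universe_set
    if stray:
        raise ValueError(f"selected genes outside the universe: {sorted(stray)[:5]}")

    rows = []
    m = len(universe_set)
    n_sel = len(selected_set)
    for name, genes in pathways.items():
        members = set(genes) & universe_set
        if not members:
            warnings.warn(
                f"pathway {name!r} has no genes in the universe; dropped",
                stacklevel=2,
            )
            continue
        overlap = len(members & selected_set)
        p = float(sps.hypergeom.sf(overlap - 1, m, len(members), n_sel))
        rows.append(
            {"pathway": name, "overlap": overlap, "pathway_size": len(members),
             "selected_size": n_sel, "universe_size": m, "p": p}
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values(["p", "pathway"], kind="mergesort").reset_index(
            drop=True
        )
    return table
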