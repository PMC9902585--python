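"""Genome-wide EMT x cell-cycle co-association screen.

Every gene is tested for dependence on the EMT activity score, on the
mitotic activity score, and on both jointly (triple co-information), using
permutation p-values for plugin mutual information.  Benjamini-Hochberg
correction is applied separately within each of the three statistic
families; the genes significant in all three form the co-associated
intersection, which a ligand-receptor annotation then filters down to
signaling receptors.  Directionality comes from the Spearman correlation of
the raw per-sample expression against each score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .infotheory import DiscretizedVariable, discretize, preprocess_for_entropy
from . import infotheory
from .activity_score import ActivityScoreVector
from .conserved_correlation import spearman_vs_reference

logger = logging.getLogger(__name__)

__all__ = ["ReceptorAnnotation", "ScreenResult", "run_screen", "rank_receptors"]


@dataclass(frozen=True)
class ReceptorAnnotation:
    """Set of gene symbols annotated as signaling receptors."""

    genes: frozenset[str]
    source: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("receptor annotation is empty")
        object.__setattr__(
            self, "genes", frozenset(g.upper() for g in self.genes)
        )


@dataclass
class ScreenResult:
    """Outcome of the co-association screen.

    ``table`` has one row per gene: mi/nmi/p/q against the EMT score
    (``*_emt``), the mitotic score (``*_cycle``) and the triple statistic
    (``*_triple``), plus Spearman rho and BH-adjusted p against each score.
    The three significant sets, their intersection and the receptor subset
    are materialized as sorted lists.
    """

    table: pd.DataFrame
    set_emt: list[str]
    set_cycle: list[str]
    set_joint: list[str]
    intersection: list[str]
    receptors_in_intersection: list[str]
    q_threshold: float
    params: dict = field(default_factory=dict)


def _discretize_gene(values: np.ndarray, n_levels: int, name: str) -> DiscretizedVariable:
    if np.any(values > 0):
        values = preprocess_for_entropy(values)
    return discretize(values, n_levels=n_levels, name=name)


def run_screen(
    matrix: pd.DataFrame,
    emt_scores: ActivityScoreVector,
    cycle_scores: ActivityScoreVector,
    receptors: ReceptorAnnotation,
    n_perm: int = 1499,
    q_threshold: float = 0.05,
    n_levels: int = 10,
    seed: int = 0,
) -> ScreenResult:
    """Run the three-way MI screen over every gene of the matrix.

    ``matrix`` may be raw counts or normalized values (genes x samples);
    each gene is preprocessed (zeros -> 1, total-normalized, log2) and
    quantile-binned, the scores are quantile-binned directly (they are
    signed), and pairwise MI plus triple co-information against the two
    score variables are tested by label permutation under one shared seed.
    Spearman correlations are computed on the untransformed values.

    Raises
    ------
    ValueError
        If the score vectors do not cover the matrix samples exactly.
    """
    if not 0 < q_threshold < 1:
        raise ValueError("q_threshold must lie in (0, 1)")
    for name, vec in (("EMT", emt_scores), ("cycle", cycle_scores)):
        missing = matrix.columns.difference(vec.scores.index)
        extra = vec.scores.index.difference(matrix.columns)
        if len(missing) or len(extra):
            raise ValueError(
                f"sample mismatch between matrix and {name} scores: "
                f"missing={list(missing)[:5]} extra={list(extra)[:5]}"
            )

    emt = emt_scores.scores.loc[matrix.columns].to_numpy(dtype=float)
    cyc = cycle_scores.scores.loc[matrix.columns].to_numpy(dtype=float)
    anchor_emt = discretize(emt, n_levels=n_levels, name="emt_score")
    anchor_cyc = discretize(cyc, n_levels=n_levels, name="cycle_score")

    values = matrix.to_numpy(dtype=float)
    genes = list(matrix.index)
    targets = [
        _discretize_gene(values[i], n_levels, genes[i]) for i in range(len(genes))
    ]
    stats = infotheory.permutation_screen(
        targets, anchor_emt, anchor_cyc, n_perm=n_perm, seed=seed
    )

    table = pd.DataFrame(
        {
            "mi_emt": stats["mi_1"],
            "mi_cycle": stats["mi_2"],
            "mi_triple": stats["mi_3"],
            "nmi_emt": stats["nmi_1"],
            "nmi_cycle": stats["nmi_2"],
            "nmi_triple": stats["nmi_3"],
            "p_emt": stats["p_1"],
            "p_cycle": stats["p_2"],
            "p_triple": stats["p_3"],
        },
        index=pd.Index(genes, name="gene"),
    )
    for col in ("emt", "cycle", "triple"):
        table[f"q_{col}"] = multipletests(table[f"p_{col}"], method="fdr_bh")[1]

    rho_emt, p_rho_emt = spearman_vs_reference(values, emt)
    rho_cyc, p_rho_cyc = spearman_vs_reference(values, cyc)
    table["rho_emt"] = rho_emt
    table["rho_cycle"] = rho_cyc
    table["rho_q_emt"] = multipletests(p_rho_emt, method="fdr_bh")[1]
    table["rho_q_cycle"] = multipletests(p_rho_cyc, method="fdr_bh")[1]

    set_emt = sorted(table.index[table["q_emt"] <= q_threshold])
    set_cycle = sorted(table.index[table["q_cycle"] <= q_threshold])
    set_joint = sorted(table.index[table["q_triple"] <= q_threshold])
    intersection = sorted(set(set_emt) & set(set_cycle) & set(set_joint))

    receptor_universe = {g.upper() for g in genes} & receptors.genes
    if not receptor_universe:
        warnings.warn(
            "no receptor-annotation genes present in the matrix", stacklevel=2
        )
    receptors_in_intersection = sorted(
        g for g in intersection if g.upper() in receptors.genes
    )
    logger.info(
        "screen: %d/%d/%d significant (emt/cycle/joint), %d in intersection, "
        "%d receptors",
        len(set_emt), len(set_cycle), len(set_joint),
        len(intersection), len(receptors_in_intersection),
    )
    return ScreenResult(
        table=table,
        set_emt=set_emt,
        set_cycle=set_cycle,
        set_joint=set_joint,
        intersection=intersection,
        receptors_in_intersection=receptors_in_intersection,
        q_threshold=q_threshold,
        params={"n_perm": n_perm, "n_levels": n_levels, "seed": seed},
    )


def rank_receptors(result: ScreenResult) -> pd.DataFrame:
    """Receptors of the intersection ordered by EMT-score association.

    Most negative Spearman rho against the EMT score first (the inversely
    correlated receptors), ties broken by rho against the mitotic score and
    then by symbol.
    """
    sub = result.table.loc[result.receptors_in_intersection].copy()
    sub = sub.sort_index().sort_values(
        ["rho_emt", "rho_cycle"], kind="mergesort"
    )
    return sub[
        ["rho_emt", "rho_cycle", "rho_q_emt", "rho_q_cycle",
         "mi_emt", "mi_cycle", "mi_triple", "q_emt", "q_cycle", "q_triple"]
    ]
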