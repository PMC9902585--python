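"""Discrete Shannon entropy and multivariate mutual information.

All quantities are *plugin* estimates in bits (log base 2): probabilities are
empirical cell frequencies of discretized variables.  Multivariate mutual
information of k variables is assembled by inclusion-exclusion over joint
entropies,

    MI(X_1..X_k) = - sum_{S nonempty} (-1)^{|S|} H(S),

which for k=2 is the familiar I(X;Y) = H(X)+H(Y)-H(X,Y) and for k=3 the
co-information H(X)+H(Y)+H(Z)-H(XY)-H(XZ)-H(YZ)+H(XYZ).  Pairwise MI is
non-negative; co-information is signed (negative = synergy, positive =
redundancy).

Continuous inputs (expression values, activity scores) are discretized into
equal-frequency bins before any entropy is taken.  Expression vectors are
first passed through :func:`preprocess_for_entropy` (zeros -> 1, divide by
the total, log2); the transform is monotone, so quantile bin labels are
unaffected except where the zero->1 replacement merges ties.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DiscretizedVariable",
    "preprocess_for_entropy",
    "discretize",
    "entropy",
    "mutual_information",
    "normalized_mi",
    "permutation_pvalue",
    "permutation_screen",
]


@dataclass(frozen=True)
class DiscretizedVariable:
    """A named per-sample integer coding of one variable.

    ``labels`` lie in ``[0, n_levels)``; ties in the raw values share a
    label, and the coding is monotone in the raw values.  ``provenance``
    records how the coding was produced (binning rule, any transform,
    whether levels collapsed on a constant input).
    """

    name: str
    labels: np.ndarray
    n_levels: int
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if labels.size and (labels.min() < 0 or labels.max() >= self.n_levels):
            raise ValueError("labels must lie in [0, n_levels)")

    def __len__(self) -> int:
        return self.labels.size


def preprocess_for_entropy(values: Sequence[float]) -> np.ndarray:
    """Transform non-negative values for entropy estimation.

    Zeros are replaced by 1, the vector is divided by its (post-replacement)
    total, and the result is log2-transformed.  The map is monotone, so any
    rank-based discretization downstream is unchanged apart from the tie
    between original zeros and ones.

    Raises
    ------
    ValueError
        If any value is negative or all values are zero.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a one-dimensional vector")
    if np.any(arr < 0):
        raise ValueError("values must be non-negative")
    if not np.any(arr > 0):
        raise ValueError("all-zero input: nothing to normalize")
    arr = np.where(arr == 0, 1.0, arr)
    arr = arr / arr.sum()
    return np.log2(arr)


def discretize(
    values: Sequence[float],
    n_levels: int = 10,
    name: str = "",
    method: str = "quantile",
) -> DiscretizedVariable:
    """Discretize a real-valued variable for entropy estimation.

    With ``method='quantile'`` (default), bin edges are the
    ``1/n_levels .. (n_levels-1)/n_levels`` quantiles, so with distinct
    values the bins are balanced.  With ``method='distinct'`` every
    distinct value becomes its own level (``n_levels`` is ignored).  Either
    way the coding is monotone and ties always share a bin.  A constant
    input collapses to a single level; ``provenance['collapsed']`` is set
    when fewer than ``n_levels`` distinct labels survive.
    """
    if method not in ("quantile", "distinct"):
        raise ValueError(f"unknown discretization method {method!r}")
    if method == "quantile" and n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("expected a nonempty one-dimensional vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")

    if method == "distinct":
        uniq, labels = np.unique(arr, return_inverse=True)
        return DiscretizedVariable(
            name, labels.astype(np.int64), int(uniq.size),
            {"rule": "distinct-values"},
        )

    prov: dict = {"rule": "equal-frequency", "requested_levels": n_levels}
    if np.all(arr == arr[0]):
        prov["collapsed"] = True
        return DiscretizedVariable(name, np.zeros(arr.size, dtype=np.int64), 1, prov)

    edges = np.quantile(arr, np.linspace(0, 1, n_levels + 1)[1:-1])
    labels = np.searchsorted(edges, arr, side="left").astype(np.int64)
    # heavy ties can leave duplicate edges; relabel to consecutive codes
    used = np.unique(labels)
    if used.size < n_levels:
        prov["collapsed"] = True
        labels = np.searchsorted(used, labels)
        return DiscretizedVariable(name, labels, int(used.size), prov)
    return DiscretizedVariable(name, labels, n_levels, prov)


def _joint_codes(vars: Sequence[DiscretizedVariable]) -> tuple[np.ndarray, int]:
    """Mixed-radix encoding of the joint cell of each sample."""
    n = len(vars[0])
    for v in vars:
        if len(v) != n:
            raise ValueError(
                f"sample-count mismatch: {v.name!r} has {len(v)}, expected {n}"
            )
    code = np.zeros(n, dtype=np.int64)
    radix = 1
    for v in vars:
        code += v.labels * radix
        radix *= v.n_levels
    return code, radix


def _entropy_from_counts(counts: np.ndarray, n: int) -> float:
    c = counts[counts > 0]
    return float(np.log2(n) - (c * np.log2(c)).sum() / n)


def entropy(*vars: DiscretizedVariable) -> float:
    """Plugin (empirical joint) Shannon entropy in bits, with 0*log 0 = 0."""
    if not vars:
        raise ValueError("at least one variable required")
    code, radix = _joint_codes(vars)
    counts = np.bincount(code, minlength=radix)
    return _entropy_from_counts(counts, code.size)


def mutual_information(*vars: DiscretizedVariable) -> float:
    """Multivariate mutual information by inclusion-exclusion, in bits.

    Two variables give ordinary MI (non-negative up to rounding); three give
    the signed co-information.
    """
    k = len(vars)
    if k not in (2, 3):
        raise ValueError(f"mutual information is defined here for 2 or 3 variables, got {k}")
    _joint_codes(vars)  # validate matching lengths up front
    mi = 0.0
    for r in range(1, k + 1):
        for subset in itertools.combinations(vars, r):
            mi -= (-1) ** r * entropy(*subset)
    return mi


def normalized_mi(mi: float, marginal_entropies: Sequence[float]) -> float:
    """MI divided by the square root of the product of marginal entropies.

    Defined as 0 whenever any marginal entropy is 0 (a constant variable
    carries no information to normalize against).
    """
    h = np.asarray(marginal_entropies, dtype=float)
    if np.any(h <= 0):
        return 0.0
    return float(mi / np.sqrt(np.prod(h)))


def permutation_pvalue(
    target: DiscretizedVariable,
    anchors: Sequence[DiscretizedVariable],
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided permutation p-value for the MI between target and anchors.

    The target's sample labels are permuted ``n_perm`` times and the MI
    recomputed each time; ``p = (1 + #{perm >= observed}) / (1 + n_perm)``.
    With one anchor the statistic is the pairwise MI, tested one-sided.
    With two anchors the statistic is the co-information, which is signed
    (synergy negative, redundancy positive) and whose permutation null is
    *not* centred at zero (the plugin estimate of the conditional dependence
    carries a finite-sample bias); the test is therefore two-sided on the
    deviation from the permutation mean, so both synergy and redundancy
    count as association.

    Returns ``(observed_mi, p_value)``; the observed MI is always the
    signed value.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    anchors = list(anchors)
    if len(anchors) not in (1, 2):
        raise ValueError("need 1 or 2 anchor variables")
    rng = np.random.default_rng(seed)
    n = len(target)
    perm_idx = np.empty((n_perm, n), dtype=np.intp)
    for i in range(n_perm):
        perm_idx[i] = rng.permutation(n)

    if len(anchors) == 1:
        mi_obs, _, _, perm_stats = _pairwise_perm_stats(target, anchors[0], perm_idx)
        p = _one_sided_p(mi_obs, perm_stats)
    else:
        mi_obs, perm_stats = _triple_perm_stats(target, anchors[0], anchors[1], perm_idx)
        p = _centered_two_sided_p(mi_obs, perm_stats)
    return mi_obs, p


def _one_sided_p(obs: float, perm: np.ndarray) -> float:
    return (1.0 + np.count_nonzero(perm >= obs)) / (1.0 + perm.size)


def _centered_two_sided_p(obs: float, perm: np.ndarray) -> float:
    """Two-sided permutation p on the deviation from the null center.

    The center pools the observed value with the permuted ones, keeping the
    test statistic a symmetric function of the exchangeable set and the
    p-value exact under the null.
    """
    center = (perm.sum() + obs) / (perm.size + 1)
    return (1.0 + np.count_nonzero(np.abs(perm - center) >= abs(obs - center))) / (
        1.0 + perm.size
    )


# ---------------------------------------------------------------------------
# vectorized permutation machinery (shared by permutation_pvalue and the
# genome-wide screen, where one target gene is tested against fixed anchors)
# ---------------------------------------------------------------------------


def _batch_joint_entropy(codes: np.ndarray, radix: int, n: int) -> np.ndarray:
    """Joint entropy of each row of an integer code matrix (P, n)."""
    p = codes.shape[0]
    flat = (np.arange(p, dtype=np.int64)[:, None] * radix + codes).ravel()
    counts = np.bincount(flat, minlength=p * radix).reshape(p, radix)
    with np.errstate(divide="ignore", invalid="ignore"):
        clogc = np.where(counts > 0, counts * np.log2(np.where(counts > 0, counts, 1)), 0.0)
    return np.log2(n) - clogc.sum(axis=1) / n


def _pairwise_perm_stats(
    target: DiscretizedVariable, anchor: DiscretizedVariable, perm_idx: np.ndarray
) -> tuple[float, float, float, np.ndarray]:
    """Observed MI, H(target), H(anchor) and the permuted-MI vector."""
    n = len(target)
    h_t = entropy(target)
    h_a = entropy(anchor)
    radix = target.n_levels * anchor.n_levels
    obs_code = target.labels * anchor.n_levels + anchor.labels
    h_joint_obs = _entropy_from_counts(np.bincount(obs_code, minlength=radix), n)
    perm_codes = target.labels[perm_idx] * anchor.n_levels + anchor.labels[None, :]
    h_joint_perm = _batch_joint_entropy(perm_codes, radix, n)
    mi_obs = h_t + h_a - h_joint_obs
    return mi_obs, h_t, h_a, h_t + h_a - h_joint_perm


def _triple_perm_stats(
    target: DiscretizedVariable,
    a1: DiscretizedVariable,
    a2: DiscretizedVariable,
    perm_idx: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Observed co-information and its permuted values (target permuted)."""
    n = len(target)
    h_t, h_1, h_2 = entropy(target), entropy(a1), entropy(a2)
    h_12 = entropy(a1, a2)
    base = h_t + h_1 + h_2 - h_12

    lt, l1, l2 = target.n_levels, a1.n_levels, a2.n_levels
    tp = target.labels[perm_idx]

    def joint2(anchor_labels: np.ndarray, la: int) -> tuple[float, np.ndarray]:
        radix = lt * la
        obs = _entropy_from_counts(
            np.bincount(target.labels * la + anchor_labels, minlength=radix), n
        )
        perm = _batch_joint_entropy(tp * la + anchor_labels[None, :], radix, n)
        return obs, perm

    h_t1_obs, h_t1_perm = joint2(a1.labels, l1)
    h_t2_obs, h_t2_perm = joint2(a2.labels, l2)
    radix3 = lt * l1 * l2
    code12 = a1.labels * l2 + a2.labels
    h_t12_obs = _entropy_from_counts(
        np.bincount(target.labels * (l1 * l2) + code12, minlength=radix3), n
    )
    h_t12_perm = _batch_joint_entropy(tp * (l1 * l2) + code12[None, :], radix3, n)

    co_obs = base - h_t1_obs - h_t2_obs + h_t12_obs
    co_perm = base - h_t1_perm - h_t2_perm + h_t12_perm
    return co_obs, co_perm


def permutation_screen(
    targets: Sequence[DiscretizedVariable],
    anchor1: DiscretizedVariable,
    anchor2: DiscretizedVariable,
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Pairwise and triple MI with permutation p-values for many targets.

    Every target (typically one gene) is tested against the two fixed anchor
    variables (the two activity scores): MI(target; anchor1),
    MI(target; anchor2) and the triple co-information, each with a one-sided
    permutation p-value obtained by permuting the target's sample labels.
    One common set of seeded permutations is shared across targets, so a
    whole matrix screens reproducibly under a single seed.

    Returns arrays ``mi_1, mi_2, mi_3, nmi_1, nmi_2, nmi_3, p_1, p_2, p_3``
    aligned with ``targets``.  Pairwise tests are one-sided on MI; the
    triple test is two-sided on the co-information's deviation from its
    permutation mean (the signed statistic's null is bias-shifted).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    n = len(anchor1)
    perm_idx = np.empty((n_perm, n), dtype=np.intp)
    for i in range(n_perm):
        perm_idx[i] = rng.permutation(n)

    h_a1, h_a2 = entropy(anchor1), entropy(anchor2)
    g = len(targets)
    out = {k: np.empty(g) for k in
           ("mi_1", "mi_2", "mi_3", "nmi_1", "nmi_2", "nmi_3", "p_1", "p_2", "p_3")}
    for i, t in enumerate(targets):
        mi1, h_t, _, perm1 = _pairwise_perm_stats(t, anchor1, perm_idx)
        mi2, _, _, perm2 = _pairwise_perm_stats(t, anchor2, perm_idx)
        mi3, perm3 = _triple_perm_stats(t, anchor1, anchor2, perm_idx)
        out["mi_1"][i], out["mi_2"][i], out["mi_3"][i] = mi1, mi2, mi3
        out["nmi_1"][i] = normalized_mi(mi1, [h_t, h_a1])
        out["nmi_2"][i] = normalized_mi(mi2, [h_t, h_a2])
        out["nmi_3"][i] = normalized_mi(mi3, [h_t, h_a1, h_a2])
        out["p_1"][i] = _one_sided_p(mi1, perm1)
        out["p_2"][i] = _one_sided_p(mi2, perm2)
        out["p_3"][i] = _centered_two_sided_p(mi3, perm3)
    return out
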