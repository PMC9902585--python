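"""Validation experiments: oracle checks, calibration and power studies.

Each function runs one self-contained experiment on synthetic data and
returns plain numbers.  They are the package's evidence that the statistics
are computed correctly (independent-oracle equivalence, closed forms), that
the permutation significance is calibrated (null type-I error, p-value
uniformity), and that the screen recovers planted structure at realistic
effect sizes (receptor detection, conserved-module sensitivity).  The test
suite asserts on these numbers; ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import itertools
import json
import math
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .activity_score import cpm_normalize, score_activity
from .coassoc_screen import ReceptorAnnotation, run_screen
from .conserved_correlation import correlate_focal, ora
from .infotheory import (
    DiscretizedVariable,
    discretize,
    entropy,
    mutual_information,
    normalized_mi,
    permutation_screen,
    preprocess_for_entropy,
)
from .io_cli import PipelineConfig, run_pipeline, write_gmt, write_matrix
from .synthetic_data import ReceptorEffect, SimulationConfig, simulate_bulk, simulate_multidataset

__all__ = [
    "mi_oracle_check",
    "closed_form_checkpoints",
    "null_calibration",
    "screen_power",
    "score_shift_recovery",
    "conserved_recovery",
    "ora_check",
    "pipeline_determinism",
]


# ---------------------------------------------------------------------------
# 1-2: estimator correctness
# ---------------------------------------------------------------------------


def _direct_plugin_mi(labels: list[np.ndarray]) -> float:
    """MI straight from the empirical joint table, bypassing joint-entropy
    inclusion-exclusion: I(X;Y) for two variables, I(X;Y) - I(X;Y|Z) for
    three.  Serves as the independent oracle."""
    n = len(labels[0])
    counts: dict[tuple, int] = {}
    for cell in zip(*labels):
        counts[cell] = counts.get(cell, 0) + 1
    probs = {c: k / n for c, k in counts.items()}

    def marginal(axes):
        out: dict[tuple, float] = {}
        for cell, p in probs.items():
            key = tuple(cell[a] for a in axes)
            out[key] = out.get(key, 0.0) + p
        return out

    if len(labels) == 2:
        px, py = marginal([0]), marginal([1])
        return sum(
            p * math.log2(p / (px[(c[0],)] * py[(c[1],)]))
            for c, p in probs.items()
        )
    pz = marginal([2])
    pxz, pyz = marginal([0, 2]), marginal([1, 2])
    i_xy_z = sum(
        p * math.log2(p * pz[(c[2],)] / (pxz[(c[0], c[2])] * pyz[(c[1], c[2])]))
        for c, p in probs.items()
    )
    return _direct_plugin_mi(labels[:2]) - i_xy_z


def _dv(labels: np.ndarray, n_levels: int) -> DiscretizedVariable:
    return DiscretizedVariable("v", labels, n_levels)


def mi_oracle_check(seed: int = 0, n_tables: int = 500) -> dict[str, float]:
    """Inclusion-exclusion MI vs the direct plugin oracle over random joint
    tables (2-3 variables, 2-4 levels) plus degenerate and uniform cases."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    min_pairwise = np.inf
    n_checked = 0

    def check(labels, levels):
        nonlocal max_err, min_pairwise, n_checked
        vars_ = [_dv(l, L) for l, L in zip(labels, levels)]
        mi = mutual_information(*vars_)
        oracle = _direct_plugin_mi([v.labels for v in vars_])
        max_err = max(max_err, abs(mi - oracle))
        if len(labels) == 2:
            min_pairwise = min(min_pairwise, mi)
        n_checked += 1

    for _ in range(n_tables):
        k = int(rng.integers(2, 4))
        levels = [int(rng.integers(2, 5)) for _ in range(k)]
        n = int(rng.integers(8, 41))
        labels = [rng.integers(0, L, n) for L in levels]
        check(labels, levels)

    # degenerate and structured cases: constants, identical, uniform, XOR
    n = 64
    u4 = np.tile(np.arange(4), n // 4)
    const = np.zeros(n, dtype=int)
    b = np.tile([0, 1], n // 2)
    b2 = np.repeat([0, 1], n // 2)
    for labels, levels in [
        ([const, const], [1, 1]),
        ([u4, u4], [4, 4]),
        ([b, b2], [2, 2]),
        ([b, b, b], [2, 2, 2]),
        ([b, b2, b ^ b2], [2, 2, 2]),
        ([u4, const, b], [4, 1, 2]),
    ]:
        check(labels, levels)

    return {
        "max_abs_error_bits": float(max_err),
        "min_pairwise_mi_bits": float(min_pairwise),
        "n_tables": n_checked,
    }


def closed_form_checkpoints() -> dict[str, float]:
    """Exactly solvable cases of the entropy / MI / NMI estimators."""
    u4 = _dv(np.tile(np.arange(4), 25), 4)
    b = _dv(np.tile([0, 1], 50), 2)
    b2 = _dv(np.repeat([0, 1], 50), 2)
    rows = np.array(list(itertools.product([0, 1], repeat=2)))
    x, y = rows[:, 0], rows[:, 1]
    xor = [_dv(x, 2), _dv(y, 2), _dv(x ^ y, 2)]
    mi_identical = mutual_information(b, b)
    return {
        "uniform4_entropy_bits": entropy(u4),
        "identical_binary_mi_bits": mi_identical,
        "identical_binary_nmi": normalized_mi(mi_identical, [entropy(b)] * 2),
        "independent_binary_mi_bits": mutual_information(b, b2),
        "xor_coinformation_bits": mutual_information(*xor),
    }


# ---------------------------------------------------------------------------
# 3: permutation-null calibration
# ---------------------------------------------------------------------------


def null_calibration(
    seed: int = 0,
    n_test_genes: int = 200,
    n_perm: int = 499,
    n_samples: int = 300,
    n_levels: int = 10,
) -> dict[str, float]:
    """Type-I error and p-value uniformity on a fully null dataset.

    Activity scores are computed from designated pseudo-program genes of a
    structureless count matrix; the tested genes are disjoint from the
    program and from the control pool (a control gene is a summand of the
    score, so its dependence on the score is real).  Reports the type-I
    error at alpha=0.05 pooled over the three statistic families and the
    smallest per-family Kolmogorov-Smirnov uniformity p-value.
    """
    cfg = SimulationConfig(
        n_genes=4000, n_samples=n_samples, n_program_genes_emt=0,
        n_program_genes_cycle=0, seed=seed,
    )
    ds = simulate_bulk(cfg)
    cpm = cpm_normalize(ds.matrix)
    genes = list(cpm.index)
    prog_e, prog_c = genes[:50], genes[50:100]
    emt = score_activity(cpm, prog_e, "EMT")
    cyc = score_activity(cpm, prog_c, "mitotic")
    used = set(prog_e) | set(prog_c) | set(emt.control_genes) | set(cyc.control_genes)
    test_genes = [g for g in genes if g not in used][:n_test_genes]

    targets = [
        discretize(preprocess_for_entropy(cpm.loc[g].to_numpy()), n_levels, g)
        for g in test_genes
    ]
    a1 = discretize(emt.scores.to_numpy(), n_levels, "emt")
    a2 = discretize(cyc.scores.to_numpy(), n_levels, "cycle")
    res = permutation_screen(targets, a1, a2, n_perm=n_perm, seed=seed + 1)

    pooled = np.concatenate([res["p_1"], res["p_2"], res["p_3"]])
    ks = [float(sps.kstest(res[f], "uniform").pvalue) for f in ("p_1", "p_2", "p_3")]
    return {
        "type1_error_alpha05": float(np.mean(pooled <= 0.05)),
        "ks_uniformity_min_pvalue": float(min(ks)),
        "n_pvalues": int(pooled.size),
    }


# ---------------------------------------------------------------------------
# 4: screen power and FDR
# ---------------------------------------------------------------------------


def screen_power(
    seed: int = 0,
    n_replicates: int = 20,
    n_null_genes: int = 500,
    n_receptors: int = 10,
    rho_target: float = 0.5,
    n_samples: int = 300,
    n_perm: int = 1499,
    q_threshold: float = 0.05,
) -> dict[str, float]:
    """Detection rate of planted dual-program receptors and realized FDR.

    Each replicate simulates a dataset with ``n_receptors`` receptors whose
    means follow a saturating link of both latent activities (alternating
    sign, |rho| = ``rho_target`` vs each latent) among ``n_null_genes``
    independent genes, scores both programs, runs the full screen, and
    counts a receptor detected when it sits in the receptor-filtered
    intersection with both Spearman signs matching the planted direction.
    The realized false-discovery proportion counts null genes in the
    intersection.
    """
    detections = []
    fdps = []
    for rep in range(n_replicates):
        effects = tuple(
            ReceptorEffect("both", +1 if i % 2 else -1, rho_target)
            for i in range(n_receptors)
        )
        cfg = SimulationConfig(
            n_genes=60 + n_receptors + n_null_genes,
            n_samples=n_samples,
            n_program_genes_emt=30,
            n_program_genes_cycle=30,
            receptor_effects=effects,
            seed=seed + 1000 * rep,
        )
        ds = simulate_bulk(cfg)
        truth = ds.truth
        cpm = cpm_normalize(ds.matrix)
        emt = score_activity(cpm, list(truth.index[truth.label == "program_emt"]), "EMT")
        cyc = score_activity(cpm, list(truth.index[truth.label == "program_cycle"]), "mitotic")
        receptors = ReceptorAnnotation(frozenset(truth.index[truth.label == "receptor"]))
        res = run_screen(
            cpm, emt, cyc, receptors, n_perm=n_perm,
            q_threshold=q_threshold, seed=seed + rep,
        )
        detected = 0
        for g in truth.index[truth.label == "receptor"]:
            d = truth.loc[g, "direction"]
            if (
                g in res.receptors_in_intersection
                and np.sign(res.table.loc[g, "rho_emt"]) == d
                and np.sign(res.table.loc[g, "rho_cycle"]) == d
            ):
                detected += 1
        detections.append(detected / n_receptors)
        nulls = set(truth.index[truth.label == "null"])
        false = len([g for g in res.intersection if g in nulls])
        fdps.append(false / max(len(res.intersection), 1))
    return {
        "detection_rate": float(np.mean(detections)),
        "intersection_fdr": float(np.mean(fdps)),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# 5: activity-score recovery
# ---------------------------------------------------------------------------


def score_shift_recovery(
    seed: int = 0, delta: float = 1.0, n_genes: int = 500, n_samples: int = 200
) -> dict[str, float]:
    """Recovery of a planted uniform shift and null-program centring.

    A structureless count matrix is CPM-normalized; the program genes are
    shifted by +delta on the log2(CPM+1) scale in half of the samples.  The
    difference between group-mean scores estimates delta.  Separately, 200
    random bin-matched programs on the unshifted matrix give an ensemble
    whose per-sample mean should sit within 3 standard errors of zero.
    """
    rng = np.random.default_rng(seed)
    counts = rng.negative_binomial(5, 0.05, size=(n_genes, n_samples))
    mat = pd.DataFrame(
        counts.astype(float),
        index=[f"G{i:04d}" for i in range(n_genes)],
        columns=[f"S{j:04d}" for j in range(n_samples)],
    )
    cpm = cpm_normalize(mat)
    program = list(mat.index[:40])
    shifted = cpm.copy()
    group_b = mat.columns[n_samples // 2:]
    shifted.loc[program, group_b] = (
        2.0 ** (np.log2(shifted.loc[program, group_b] + 1.0) + delta) - 1.0
    )
    vec = score_activity(shifted, program)
    diff = float(
        vec.scores[group_b].mean() - vec.scores[mat.columns[: n_samples // 2]].mean()
    )

    ens = []
    genes = list(cpm.index)
    for _ in range(200):
        prog = list(rng.choice(genes, size=50, replace=False))
        ens.append(score_activity(cpm, prog).scores)
    ens = pd.concat(ens, axis=1)
    z = ens.mean(axis=1) / (ens.std(axis=1, ddof=1) / np.sqrt(ens.shape[1]))
    return {
        "recovered_shift": diff,
        "relative_error": abs(diff - delta) / delta,
        "null_fraction_within_3se": float((z.abs() <= 3).mean()),
        "n_random_programs": 200,
    }


# ---------------------------------------------------------------------------
# 6: conserved-correlation recovery
# ---------------------------------------------------------------------------


def conserved_recovery(
    seed: int = 0,
    n_runs: int = 50,
    n_datasets: int = 4,
    datasets_with_signal: int = 3,
    rho_target: float = 0.5,
    n_samples: int = 150,
    module_size: int = 20,
    n_genes: int = 150,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Sensitivity and specificity of the >=k-of-N conservation rule, plus
    monotonicity of the conserved set in k."""
    sens, fps, mono = [], [], []
    module = [f"G{i:05d}" for i in range(module_size)]
    focal = f"G{module_size:05d}"
    for run in range(n_runs):
        cfg = SimulationConfig(
            n_genes=n_genes, n_samples=n_samples, n_program_genes_emt=0,
            n_program_genes_cycle=0, seed=seed + 101 * run,
        )
        dss = simulate_multidataset(
            cfg, n_datasets, focal, module, datasets_with_signal,
            rho_target=rho_target,
        )
        mats = [d.matrix for d in dss]
        res = correlate_focal(mats, focal, alpha=alpha, k=2)
        hit = len(set(module) & set(res.conserved))
        sens.append(hit / module_size)
        nulls = set(cfg.gene_names()) - set(module) - {focal}
        fps.append(len(set(res.conserved) & nulls) / len(nulls))
        k3 = set(correlate_focal(mats, focal, alpha=alpha, k=3).conserved)
        mono.append(k3 <= set(res.conserved))
    return {
        "sensitivity": float(np.mean(sens)),
        "null_false_positive_rate": float(np.mean(fps)),
        "k_monotonicity_holds": float(np.mean(mono)),
        "n_runs": n_runs,
    }


# ---------------------------------------------------------------------------
# 7: ORA correctness
# ---------------------------------------------------------------------------


def ora_check(max_universe: int = 12) -> dict[str, float]:
    """Hypergeometric tail vs exhaustive enumeration on small universes,
    plus the closed-form full-overlap case p = 1/C(20,5)."""
    universe20 = [f"U{i}" for i in range(20)]
    worked = ora(universe20[:5], {"pw": universe20[:5]}, universe20)
    worked_p = float(worked.loc[0, "p"])
    worked_expected = 1.0 / math.comb(20, 5)

    max_rel_err = 0.0
    for m in (8, max_universe):
        universe = [f"U{i}" for i in range(m)]
        for k_path in (2, 4):
            for k_sel in (3, 5):
                for shift in (0, 1, 2):
                    pathway = universe[:k_path]
                    selected = universe[shift : shift + k_sel]
                    table = ora(selected, {"pw": pathway}, universe)
                    observed = len(set(selected) & set(pathway))
                    hits = total = 0
                    for combo in itertools.combinations(universe, k_sel):
                        total += 1
                        if len(set(combo) & set(pathway)) >= observed:
                            hits += 1
                    enum_p = hits / total
                    rel = abs(float(table.loc[0, "p"]) - enum_p) / enum_p
                    max_rel_err = max(max_rel_err, rel)
    return {
        "worked_example_p": worked_p,
        "worked_example_rel_error": abs(worked_p - worked_expected) / worked_expected,
        "enumeration_max_rel_error": max_rel_err,
    }


# ---------------------------------------------------------------------------
# 8: pipeline determinism
# ---------------------------------------------------------------------------


def pipeline_determinism(seed: int = 0, workdir: str | Path | None = None) -> dict[str, float]:
    """Run the small bundled synthetic configuration twice; 1.0 when every
    output checksum matches between the runs."""
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    root = Path(ctx.name) if ctx else Path(workdir)
    try:
        effects = (ReceptorEffect("both", -1, 0.5), ReceptorEffect("both", 1, 0.5))
        cfg = SimulationConfig(
            n_genes=200, n_samples=100, n_program_genes_emt=20,
            n_program_genes_cycle=20, receptor_effects=effects, seed=seed,
        )
        ds = simulate_bulk(cfg)
        write_matrix(ds.matrix, root / "counts.tsv.gz")
        truth = ds.truth
        write_gmt(
            {
                "EMT": list(truth.index[truth.label == "program_emt"]),
                "CYCLE": list(truth.index[truth.label == "program_cycle"]),
            },
            root / "programs.gmt",
        )
        (root / "receptors.tsv").write_text(
            "receptor\n" + "\n".join(truth.index[truth.label == "receptor"]) + "\n"
        )
        manifests = []
        for run in ("a", "b"):
            cfg_run = PipelineConfig(
                matrix=str(root / "counts.tsv.gz"),
                programs_gmt=str(root / "programs.gmt"),
                emt_program="EMT", cycle_program="CYCLE",
                receptors=str(root / "receptors.tsv"),
                out_dir=str(root / f"out_{run}"),
                n_perm=199, seed=seed,
            )
            out = run_pipeline(cfg_run)
            manifests.append(
                json.loads((out / "manifest.json").read_text())["outputs"]
            )
        return {
            "identical_checksums": float(manifests[0] == manifests[1]),
            "n_outputs": len(manifests[0]),
        }
    finally:
        if ctx:
            ctx.cleanup()
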