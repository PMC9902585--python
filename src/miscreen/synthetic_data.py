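"""Synthetic RNA-seq count data with planted EMT / cell-cycle structure.

The generator emulates the inputs the co-association screen expects:

* two latent per-sample program activities (an EMT-like and a mitotic-like
  activity), lognormally distributed and optionally correlated — tumour
  transcriptomes couple proliferation and mesenchymal programs, and the
  screen's premise is that some receptors track both;
* program gene sets whose negative-binomial means increase with the matching
  latent activity;
* receptor genes whose means follow a *monotone nonlinear* (saturating) link
  of one or both latents, with a configurable sign and a target Spearman
  correlation |rho| against the driving latent, calibrated by bisection;
* null genes independent of both latents;
* library-size variation across samples.

Counts are negative binomial (gamma-Poisson) with a common dispersion, so
the discretization downstream sees realistic ties and zeros.  Everything is
reproducible from a single seed; multi-dataset simulations derive one seed
per dataset from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "ReceptorEffect",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_bulk",
    "simulate_multidataset",
]

_CAL_N = 2000  # samples per calibration draw
_CAL_DRAWS = 2
_B_MAX = 8.0


@dataclass(frozen=True)
class ReceptorEffect:
    """Planted dependence of one receptor gene on the latent activities.

    ``target`` names the driving latent(s), ``direction`` the sign of the
    monotone link, and ``rho_target`` the desired magnitude of the realized
    Spearman correlation between the receptor's counts and the driving
    latent (the EMT latent when ``target == 'both'``).
    """

    target: Literal["emt", "cycle", "both"]
    direction: int
    rho_target: float

    def __post_init__(self) -> None:
        if self.target not in ("emt", "cycle", "both"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if not 0.0 <= self.rho_target <= 1.0:
            raise ValueError("rho_target must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 1000
    n_samples: int = 300
    n_program_genes_emt: int = 30
    n_program_genes_cycle: int = 30
    receptor_effects: tuple[ReceptorEffect, ...] = ()
    latent_sigma: float = 0.4
    latent_correlation: float = 0.35
    library_size_mean: float = 2e5
    library_size_sigma: float = 0.3
    dispersion: float = 0.3
    seed: int = 0

    @property
    def n_receptors(self) -> int:
        return len(self.receptor_effects)

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples) <= 0:
            raise ValueError("n_genes and n_samples must be positive")
        if self.n_program_genes_emt < 0 or self.n_program_genes_cycle < 0:
            raise ValueError("program gene counts must be non-negative")
        n_special = (
            self.n_program_genes_emt + self.n_program_genes_cycle + self.n_receptors
        )
        if n_special > self.n_genes:
            raise ValueError(
                "program genes plus receptors exceed n_genes "
                f"({n_special} > {self.n_genes})"
            )
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not -1.0 < self.latent_correlation < 1.0:
            raise ValueError("latent_correlation must lie in (-1, 1)")
        for eff in self.receptor_effects:
            if eff.rho_target >= 1.0 and self.dispersion > 0:
                raise ValueError(
                    "impossible calibration: rho_target=1 cannot be realized "
                    "with dispersion > 0 (counting noise bounds the attainable "
                    "Spearman correlation); lower rho_target"
                )

    def gene_names(self) -> list[str]:
        names = [f"EMT{i:03d}" for i in range(self.n_program_genes_emt)]
        names += [f"CYC{i:03d}" for i in range(self.n_program_genes_cycle)]
        names += [f"RC{i:03d}" for i in range(self.n_receptors)]
        names += [f"G{i:05d}" for i in range(self.n_genes - len(names))]
        return names


@dataclass
class SyntheticDataset:
    """One simulated expression matrix plus ground truth.

    ``matrix`` holds raw counts (genes x samples); ``truth`` has one row per
    gene with its label (``program_emt``, ``program_cycle``, ``receptor`` or
    ``null``) and, for receptors, the planted target, direction and
    rho_target.
    """

    matrix: pd.DataFrame
    latent_emt: pd.Series
    latent_cycle: pd.Series
    truth: pd.DataFrame
    config: SimulationConfig = field(repr=False)

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.config.n_genes, self.config.n_samples):
            raise ValueError("matrix dimensions do not match the configuration")
        if not self.truth.index.isin(self.matrix.index).all():
            raise ValueError("truth refers to genes absent from the matrix")


def _saturating(x: np.ndarray, ref: float) -> np.ndarray:
    """Monotone increasing, concave link: x / (x + ref)."""
    return x / (x + ref)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-Poisson counts with mean mu and variance mu + phi*mu^2."""
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def _latents(
    rng: np.random.Generator, n: int, sigma: float, corr: float
) -> tuple[np.ndarray, np.ndarray]:
    z1 = rng.standard_normal(n)
    z2 = corr * z1 + np.sqrt(1.0 - corr**2) * rng.standard_normal(n)
    return np.exp(sigma * z1), np.exp(sigma * z2)


def _receptor_driver(
    latent_emt: np.ndarray, latent_cycle: np.ndarray, target: str
) -> np.ndarray:
    ge = _saturating(latent_emt, float(np.median(latent_emt)))
    gc = _saturating(latent_cycle, float(np.median(latent_cycle)))
    if target == "emt":
        u = ge
    elif target == "cycle":
        u = gc
    else:
        u = 0.5 * (ge + gc)
    return _standardize(u)


def _calibrate_link(
    mean_count: float,
    effect: ReceptorEffect,
    config: SimulationConfig,
    cal_key: tuple[int, ...],
) -> float:
    """Bisect the link strength b so the realized |Spearman rho| between the
    receptor's counts and its driving latent hits ``rho_target``.

    The calibration uses its own large, seeded draws so the returned b is a
    deterministic function of (config, effect, gene mean) and independent of
    the main simulation draw.
    """
    if effect.rho_target == 0.0:
        return 0.0
    rng = np.random.default_rng(cal_key)
    draws = []
    for _ in range(_CAL_DRAWS):
        le, lc = _latents(rng, _CAL_N, config.latent_sigma, config.latent_correlation)
        u = _receptor_driver(le, lc, effect.target)
        ref = le if effect.target in ("emt", "both") else lc
        # library-size variation contributes real count noise: include it
        lib_rel = np.exp(
            config.library_size_sigma * rng.standard_normal(_CAL_N)
            - 0.5 * config.library_size_sigma**2
        )
        draws.append((u, ref, lib_rel, int(rng.integers(0, 2**31))))

    def realized(b: float) -> float:
        rhos = []
        for u, ref, lib_rel, noise_seed in draws:
            mu = mean_count * lib_rel * np.exp(effect.direction * b * u)
            counts = _nb_draw(np.random.default_rng(noise_seed), mu, config.dispersion)
            rhos.append(abs(spearmanr(counts, ref).statistic))
        return float(np.mean(rhos))

    rho_max = realized(_B_MAX)
    if rho_max + 0.05 < effect.rho_target:
        raise ValueError(
            f"impossible calibration: rho_target={effect.rho_target} for "
            f"target={effect.target!r} is unattainable at dispersion="
            f"{config.dispersion} and mean count {mean_count:.1f} "
            f"(maximum attainable |rho| ~ {rho_max:.2f})"
        )
    lo, hi = 0.0, _B_MAX
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        if realized(mid) < effect.rho_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_bulk(config: SimulationConfig) -> SyntheticDataset:
    """Draw one negative-binomial count matrix with the planted structure.

    Program-gene means increase with the matching latent activity (a power
    link with gene-specific exponent); receptor means follow
    ``exp(direction * b * g(latent))`` with g saturating and b calibrated so
    the realized Spearman correlation against the driving latent is
    ``rho_target`` (within about +/-0.1 at n_samples >= 300); null genes are
    independent of both latents.  Identical seeds give identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    n_g, n_s = config.n_genes, config.n_samples
    genes = config.gene_names()
    samples = [f"S{i:04d}" for i in range(n_s)]

    latent_emt, latent_cycle = _latents(
        rng, n_s, config.latent_sigma, config.latent_correlation
    )
    lib = config.library_size_mean * np.exp(
        config.library_size_sigma * rng.standard_normal(n_s)
        - 0.5 * config.library_size_sigma**2
    )

    # relative abundances: lognormal, normalized so mean count tracks library size
    abundance = np.exp(rng.normal(0.0, 1.0, n_g))
    abundance /= abundance.sum()

    n_emt, n_cyc = config.n_program_genes_emt, config.n_program_genes_cycle
    n_rec = config.n_receptors
    factors = np.ones((n_g, n_s))

    # program genes: mean proportional to (latent / mean latent)^gamma
    gammas_emt = rng.uniform(0.8, 1.6, n_emt)
    gammas_cyc = rng.uniform(0.8, 1.6, n_cyc)
    factors[:n_emt] = (latent_emt / latent_emt.mean()) ** gammas_emt[:, None]
    factors[n_emt : n_emt + n_cyc] = (
        latent_cycle / latent_cycle.mean()
    ) ** gammas_cyc[:, None]

    # receptors: saturating link, strength calibrated to rho_target
    link_strengths = []
    for j, eff in enumerate(config.receptor_effects):
        row = n_emt + n_cyc + j
        mean_count = abundance[row] * config.library_size_mean
        b = _calibrate_link(mean_count, eff, config, (config.seed, 7919, j))
        link_strengths.append(b)
        u = _receptor_driver(latent_emt, latent_cycle, eff.target)
        factors[row] = np.exp(eff.direction * b * u)

    mu = abundance[:, None] * factors * lib[None, :]
    counts = _nb_draw(rng, mu, config.dispersion)

    matrix = pd.DataFrame(counts, index=genes, columns=samples)
    labels = (
        ["program_emt"] * n_emt
        + ["program_cycle"] * n_cyc
        + ["receptor"] * n_rec
        + ["null"] * (n_g - n_emt - n_cyc - n_rec)
    )
    truth = pd.DataFrame({"label": labels}, index=pd.Index(genes, name="gene"))
    truth["target"] = ""
    truth["direction"] = 0
    truth["rho_target"] = np.nan
    truth["link_strength"] = np.nan
    for j, eff in enumerate(config.receptor_effects):
        g = genes[n_emt + n_cyc + j]
        truth.loc[g, ["target", "direction", "rho_target", "link_strength"]] = [
            eff.target,
            eff.direction,
            eff.rho_target,
            link_strengths[j],
        ]

    return SyntheticDataset(
        matrix=matrix,
        latent_emt=pd.Series(latent_emt, index=samples, name="latent_emt"),
        latent_cycle=pd.Series(latent_cycle, index=samples, name="latent_cycle"),
        truth=truth,
        config=config,
    )


def simulate_multidataset(
    config: SimulationConfig,
    n_datasets: int,
    focal_gene: str,
    conserved_module: Sequence[str],
    datasets_with_signal: int,
    rho_target: float = 0.5,
) -> list[SyntheticDataset]:
    """Independent datasets sharing a planted focal-gene-correlated module.

    In the first ``datasets_with_signal`` datasets the module genes'
    negative-binomial means follow a monotone link of the focal gene's own
    latent driver, calibrated so their realized Spearman correlation with
    the focal gene's counts is about ``rho_target``; in the remaining
    datasets (and for all non-module genes) expression is independent of the
    focal gene.  Dataset d uses seed ``config.seed + d``.
    """
    if not 0 <= datasets_with_signal <= n_datasets:
        raise ValueError("datasets_with_signal must lie in [0, n_datasets]")
    module = list(dict.fromkeys(conserved_module))
    if not module:
        raise ValueError("conserved_module must not be empty")
    universe = set(config.gene_names())
    missing = [g for g in [focal_gene, *module] if g not in universe]
    if missing:
        raise ValueError(f"genes absent from the simulated universe: {missing}")
    if focal_gene in module:
        raise ValueError("focal_gene cannot be part of conserved_module")

    out = []
    for d in range(n_datasets):
        ds_config = replace(config, seed=config.seed + d)
        ds = simulate_bulk(ds_config)
        rng = np.random.default_rng((ds_config.seed, 104729))
        n_s = config.n_samples

        # focal gene driven by its own lognormal latent
        z_f = np.exp(config.latent_sigma * rng.standard_normal(n_s))
        u_f = _standardize(_saturating(z_f, float(np.median(z_f))))
        idx = {g: i for i, g in enumerate(ds.matrix.index)}
        abundance_focal = max(
            float(ds.matrix.iloc[idx[focal_gene]].mean()), 1.0
        )
        mu_f = abundance_focal * np.exp(1.0 * u_f)
        focal_counts = _nb_draw(rng, mu_f, config.dispersion)
        ds.matrix.iloc[idx[focal_gene]] = focal_counts

        if d < datasets_with_signal:
            for g in module:
                mean_count = max(float(ds.matrix.iloc[idx[g]].mean()), 1.0)
                b = _calibrate_module_link(
                    mean_count, abundance_focal, rho_target, config,
                    (config.seed, 224737, d, idx[g]),
                )
                mu_g = mean_count * np.exp(b * u_f)
                ds.matrix.iloc[idx[g]] = _nb_draw(rng, mu_g, config.dispersion)
        out.append(ds)
    return out


def _calibrate_module_link(
    mean_count: float,
    focal_mean: float,
    rho_target: float,
    config: SimulationConfig,
    cal_key: tuple[int, ...],
) -> float:
    """Bisect b so Spearman(module counts, focal counts) hits rho_target."""
    if rho_target == 0.0:
        return 0.0
    if rho_target >= 1.0:
        raise ValueError(
            "impossible calibration: rho_target=1 cannot be realized with "
            "dispersion > 0; lower rho_target"
        )
    rng = np.random.default_rng(cal_key)
    z_f = np.exp(config.latent_sigma * rng.standard_normal(_CAL_N))
    u_f = _standardize(_saturating(z_f, float(np.median(z_f))))
    focal_counts = _nb_draw(rng, focal_mean * np.exp(1.0 * u_f), config.dispersion)
    noise_state = rng.integers(0, 2**31)

    def realized(b: float) -> float:
        sub = np.random.default_rng(noise_state)
        counts = _nb_draw(sub, mean_count * np.exp(b * u_f), config.dispersion)
        return abs(spearmanr(counts, focal_counts).statistic)

    rho_max = realized(_B_MAX)
    if rho_max + 0.05 < rho_target:
        raise ValueError(
            f"impossible calibration: rho_target={rho_target} unattainable "
            f"for a module gene with mean count {mean_count:.1f} at "
            f"dispersion={config.dispersion} (max |rho| ~ {rho_max:.2f})"
        )
    lo, hi = 0.0, _B_MAX
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        if realized(mid) < rho_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
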