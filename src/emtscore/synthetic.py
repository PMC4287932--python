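"""Synthetic expression cohorts with a planted EMT axis.

The generator emulates a normalized log2-scale cohort in which every
sample occupies a position ``phi`` in [-1, +1] on an epithelial-to-
mesenchymal continuum and a known block of genes responds linearly to it:

    x_gs = mu_g + beta_g * phi_s + eps_gs

with ``beta_g = +b`` for mesenchymal-block genes, ``-b`` for epithelial-
block genes and 0 for background genes; baselines ``mu_g ~ Normal(7, 1)``
(a log2-microarray-like scale) and noise ``eps ~ Normal(0, sigma^2)``.
Everything is reproducible from an integer seed. The multi-disease variant
plants the same consensus blocks in every cohort plus disease-private
signature genes, exercising the "present in all diseases" membership rule
of the generic combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import EMTSignature, ExpressionMatrix, GeneSet, matrix_from_arrays

DEFAULT_B = 2.0
DEFAULT_SIGMA = 0.5
BASELINE_MEAN = 7.0
BASELINE_SD = 1.0


@dataclass(frozen=True, eq=False)
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    phi: pd.Series            # per-sample planted EMT position in [-1, +1]
    roles: pd.Series          # per-gene: epi_block / mes_block / background
    b: float
    sigma: float
    seed: int

    @property
    def epi_genes(self) -> tuple[str, ...]:
        return tuple(self.roles.index[self.roles == "epi_block"])

    @property
    def mes_genes(self) -> tuple[str, ...]:
        return tuple(self.roles.index[self.roles == "mes_block"])

    @property
    def background_genes(self) -> tuple[str, ...]:
        return tuple(self.roles.index[self.roles == "background"])

    def signature(self) -> EMTSignature:
        """The planted Epi/Mes blocks as a scoring signature."""
        return EMTSignature(epi_genes=self.epi_genes, mes_genes=self.mes_genes,
                            source=f"planted(seed={self.seed})")

    def gene_sets(self) -> list[GeneSet]:
        """The planted blocks as published-style gene sets."""
        return [GeneSet("planted_epi", self.epi_genes),
                GeneSet("planted_mes", self.mes_genes)]


def _draw_phi(n: int, phi_dist: Literal["uniform", "two_cluster"],
              rng: np.random.Generator) -> np.ndarray:
    if phi_dist == "uniform":
        return rng.uniform(-1.0, 1.0, size=n)
    if phi_dist == "two_cluster":
        # distinct Epi/Mes groups at +-0.8 for SAM/ROC-style two-group designs
        sign = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        return np.clip(sign * 0.8 + rng.normal(0.0, 0.1, size=n), -1.0, 1.0)
    raise ValueError(f"unknown phi_dist {phi_dist!r}")


def generate_cohort(n_samples: int = 200, n_background: int = 500,
                    n_epi: int = 50, n_mes: int = 50,
                    b: float = DEFAULT_B, sigma: float = DEFAULT_SIGMA,
                    phi_dist: Literal["uniform", "two_cluster"] = "uniform",
                    seed: int = 0,
                    phi: Sequence[float] | None = None,
                    gene_prefix: str = "",
                    sample_prefix: str = "S",
                    ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate one cohort with planted Epi/Mes blocks.

    ``phi`` overrides the sampled positions with explicit values (useful for
    deterministic extreme-sample constructions); its length must equal
    ``n_samples``.
    """
    if min(n_samples, n_background, n_epi, n_mes) < 1:
        raise ValueError("all counts must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if b <= 0:
        raise ValueError("effect size b must be > 0")
    rng = np.random.default_rng(seed)
    if phi is None:
        phi_arr = _draw_phi(n_samples, phi_dist, rng)
    else:
        phi_arr = np.asarray(phi, dtype=float)
        if phi_arr.shape != (n_samples,):
            raise ValueError("explicit phi must have length n_samples")
        if ((phi_arr < -1) | (phi_arr > 1)).any():
            raise ValueError("phi values outside [-1, +1]")

    width = len(str(max(n_epi, n_mes, n_background)))
    genes = (
        [f"{gene_prefix}EPI{i + 1:0{width}d}" for i in range(n_epi)]
        + [f"{gene_prefix}MES{i + 1:0{width}d}" for i in range(n_mes)]
        + [f"{gene_prefix}BG{i + 1:0{width}d}" for i in range(n_background)]
    )
    roles = pd.Series(["epi_block"] * n_epi + ["mes_block"] * n_mes
                      + ["background"] * n_background, index=genes, name="role")
    beta = np.concatenate([np.full(n_epi, -b), np.full(n_mes, b),
                           np.zeros(n_background)])
    n_genes = len(genes)
    mu = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_genes)
    eps = rng.normal(0.0, sigma, size=(n_genes, n_samples)) if sigma > 0 \
        else np.zeros((n_genes, n_samples))
    x = mu[:, None] + beta[:, None] * phi_arr[None, :] + eps

    samples = [f"{sample_prefix}{i + 1:04d}" for i in range(n_samples)]
    matrix = matrix_from_arrays(genes, samples, x)
    truth = SyntheticTruth(
        phi=pd.Series(phi_arr, index=samples, name="phi"),
        roles=roles, b=b, sigma=sigma, seed=seed,
    )
    return matrix, truth


@dataclass(frozen=True, eq=False)
class MultiDiseaseTruth:
    """Ground truth shared across a multi-disease simulation."""

    shared_epi: tuple[str, ...]
    shared_mes: tuple[str, ...]
    private_genes: dict[str, tuple[str, ...]]  # disease -> its private signature genes


def generate_multidisease(D: int = 6, shared_epi: int = 10, shared_mes: int = 10,
                          private_per_disease: int = 60,
                          n_samples: int = 120, n_background: int = 300,
                          b: float = DEFAULT_B, sigma: float = DEFAULT_SIGMA,
                          phi_dist: Literal["uniform", "two_cluster"] = "two_cluster",
                          seed: int = 0,
                          ) -> tuple[list[tuple[ExpressionMatrix, SyntheticTruth]],
                                     MultiDiseaseTruth]:
    """Generate D cohorts sharing consensus blocks plus private signature genes.

    Each disease's matrix plants the shared Epi/Mes blocks under common gene
    names and ``private_per_disease`` additional responsive genes (half Epi,
    half Mes) under disease-specific names, over a disease-specific
    background. Consensus genes are a small minority of the pooled signature
    population, as required for the z-threshold selection to be meaningful.
    """
    if D < 2:
        raise ValueError("need D >= 2 diseases")
    if min(shared_epi, shared_mes, n_samples, n_background) < 1:
        raise ValueError("all counts must be >= 1")
    if private_per_disease < 2 or private_per_disease % 2:
        raise ValueError("private_per_disease must be a positive even number")
    p_half = private_per_disease // 2
    sh_epi = tuple(f"SHEPI{i + 1:03d}" for i in range(shared_epi))
    sh_mes = tuple(f"SHMES{i + 1:03d}" for i in range(shared_mes))
    cohorts: list[tuple[ExpressionMatrix, SyntheticTruth]] = []
    private: dict[str, tuple[str, ...]] = {}
    for d in range(D):
        disease = f"disease{d + 1}"
        dseed = seed * 1000 + d  # distinct, reproducible per-disease streams
        matrix, truth = generate_cohort(
            n_samples=n_samples, n_background=n_background,
            n_epi=shared_epi + p_half, n_mes=shared_mes + p_half,
            b=b, sigma=sigma, phi_dist=phi_dist, seed=dseed,
            gene_prefix=f"D{d + 1}", sample_prefix=f"D{d + 1}S",
        )
        # rename: first shared_epi/shared_mes block genes carry consensus names
        ren: dict[str, str] = {}
        epi_list, mes_list = truth.epi_genes, truth.mes_genes
        for i, g in enumerate(epi_list[:shared_epi]):
            ren[g] = sh_epi[i]
        for i, g in enumerate(mes_list[:shared_mes]):
            ren[g] = sh_mes[i]
        data = matrix.data.rename(index=ren).sort_index()
        roles = truth.roles.rename(index=ren)
        roles = roles.loc[data.index]
        matrix = ExpressionMatrix(data)
        truth = SyntheticTruth(phi=truth.phi, roles=roles, b=b, sigma=sigma,
                               seed=dseed)
        priv = tuple(g for g in (*epi_list[shared_epi:], *mes_list[shared_mes:]))
        private[disease] = priv
        cohorts.append((matrix, truth))
    return cohorts, MultiDiseaseTruth(shared_epi=sh_epi, shared_mes=sh_mes,
                                      private_genes=private)
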