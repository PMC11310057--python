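"""Synthetic region-level summary statistics with known ground truth.

Emulates the two-sample design the pipeline assumes: a cis region of m
SNPs with AR-1 linkage disequilibrium, a handful of causal eQTLs for
gene expression, a known (possibly zero) causal effect theta of
expression on a binary outcome on the log-odds scale, optional per-SNP
directional pleiotropy, and independent exposure and outcome samples.

The generative model works on marginal summary statistics directly:
joint causal effects b map to marginal effects via the signed LD matrix
(beta_marg = R·b), each SNP's standard error is the standard
1/sqrt(2·p(1−p)·N) approximation, and the observed betas are one
multivariate-normal draw whose correlation follows the LD matrix —
drawn independently for the exposure and the outcome (non-overlapping
samples).  Binary-outcome effects are simulated directly on the
log-odds scale; the outcome SE carries the case-control variance factor
phi(1-phi), i.e. 1/sqrt(2·p(1-p)·N·phi(1-phi)), which is the large-N
logistic-regression approximation.  No liability-scale conversion is
attempted; this is a simplification adequate for method testing.

All randomness flows from one seed via named substreams so stages can
be re-run in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from mrtriage.instruments import LDMatrix
from mrtriage.sumstats import COLUMNS, GeneRegion


def _stream_key(s: str | int) -> int:
    # process-independent, unlike builtin hash()
    return zlib.crc32(str(s).encode()) & 0x7FFFFFFF


def _rng(seed: int, *stream: str | int) -> np.random.Generator:
    """Named substream of the master seed (stable across processes)."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=tuple(_stream_key(s) for s in stream))
    )


@dataclass
class RegionTruth:
    """Ground-truth parameters of one simulated region.

    Defaults describe a typical cis-eQTL region feeding a well-powered
    two-sample analysis: 10 common SNPs in moderate AR-1 LD (rho 0.5),
    two causal eQTLs of effect 0.25 (per-allele SD units of expression,
    marginal z near 30 at N = 31,684 — the eQTL-consortium scale), no
    causal effect on the outcome and no pleiotropy unless requested, and
    a case-control outcome on the scale of a large T2D meta-GWAS
    (N = 898,130 with case fraction 0.0825; ``case_fraction=None``
    treats the outcome as a unit-variance quantitative trait).
    """

    m_snps: int = 10
    ld_rho: float = 0.5
    causal_exp_indices: tuple[int, ...] = (2, 7)
    causal_exp_effects: tuple[float, ...] = (0.25, 0.25)
    theta: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_exp: int = 31_684
    n_out: int = 898_130
    case_fraction: float | None = 0.0825
    shared_causal: bool = True
    chrom: str = "1"
    start_pos: int = 1_000_000
    spacing_bp: int = 5_000
    eaf_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.causal_exp_indices) != len(self.causal_exp_effects):
            raise ValueError("causal indices and effects must align")
        if any(not 0 <= i < self.m_snps for i in self.causal_exp_indices):
            raise ValueError("causal index out of range")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")

    @property
    def positions(self) -> np.ndarray:
        return self.start_pos + self.spacing_bp * np.arange(self.m_snps)

    def eafs(self) -> np.ndarray:
        lo, hi = self.eaf_range
        return _rng(self.seed, "eaf").uniform(lo, hi, self.m_snps)

    def gene(self, gene_id: str = "SIMGENE") -> GeneRegion:
        """Gene body spanning the simulated SNPs."""
        pos = self.positions
        return GeneRegion(gene_id, gene_id, self.chrom, int(pos[0]), int(pos[-1]))

    def to_dict(self) -> dict:
        return asdict(self)


def _trait_var(case_fraction: float | None) -> float:
    """Per-observation variance factor of the phenotype: phi(1-phi) for
    a binary trait with case fraction phi, 1 for a unit-variance
    quantitative trait.  Enters the log-odds SE as
    1/sqrt(2p(1-p)·N·phi(1-phi))."""
    if case_fraction is None:
        return 1.0
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must be in (0, 1) or None")
    return case_fraction * (1.0 - case_fraction)


def simulate_ld(m: int, rho: float, seed: int = 0) -> LDMatrix:
    """AR-1 LD over SNP order: r_jk = rho^|j−k| (positive-definite for
    0 ≤ rho < 1)."""
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    idx = np.arange(m)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    return LDMatrix([f"rs{seed}_{j}" for j in range(m)], r)


def _marginal_draw(
    rng: np.random.Generator,
    beta_marg: np.ndarray,
    se: np.ndarray,
    chol: np.ndarray,
) -> np.ndarray:
    z = rng.standard_normal(beta_marg.size)
    return beta_marg + se * (chol @ z)


def _sumstats_frame(
    truth: RegionTruth,
    ld: LDMatrix,
    eafs: np.ndarray,
    beta_hat: np.ndarray,
    se: np.ndarray,
    n: int,
) -> pd.DataFrame:
    from scipy import stats

    z = beta_hat / se
    df = pd.DataFrame(
        {
            "snp": ld.snp_ids,
            "chr": truth.chrom,
            "pos": truth.positions,
            "ea": "A",
            "oa": "G",
            "eaf": eafs,
            "beta": beta_hat,
            "se": se,
            "p": np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-320, 1.0),
            "n": n,
        }
    )
    return df.loc[:, COLUMNS]


def region_ld(truth: RegionTruth) -> LDMatrix:
    """The region's LD matrix, SNPs labelled by locus (chrom + position)
    so that draws for different cohorts over the same region share ids."""
    base = simulate_ld(truth.m_snps, truth.ld_rho, truth.seed)
    ids = [f"rs{truth.chrom}_{p}" for p in truth.positions]
    return LDMatrix(ids, base.r)


def simulate_region_pair(
    truth: RegionTruth,
) -> tuple[pd.DataFrame, pd.DataFrame, LDMatrix]:
    """Draw one exposure/outcome summary-statistics pair for a region.

    Returns the exposure (eQTL) table, the outcome (log-odds GWAS)
    table, and the LD matrix, all in the canonical dialect.  The
    outcome's true marginal effects are theta times the exposure's true
    marginals plus the LD-propagated pleiotropy marginals.
    """
    ld = region_ld(truth)
    eafs = truth.eafs()
    chol = np.linalg.cholesky(ld.r)

    b_joint = np.zeros(truth.m_snps)
    for i, eff in zip(truth.causal_exp_indices, truth.causal_exp_effects):
        b_joint[i] = eff
    bx_marg = ld.r @ b_joint

    pleio_joint = np.zeros(truth.m_snps)
    if truth.pleiotropy_mean != 0.0 or truth.pleiotropy_sd != 0.0:
        pleio_joint = _rng(truth.seed, "pleiotropy").normal(
            truth.pleiotropy_mean, truth.pleiotropy_sd, truth.m_snps
        )
    by_marg = truth.theta * bx_marg + ld.r @ pleio_joint

    se_exp = 1.0 / np.sqrt(2.0 * eafs * (1.0 - eafs) * truth.n_exp)
    se_out = 1.0 / np.sqrt(
        2.0 * eafs * (1.0 - eafs) * truth.n_out * _trait_var(truth.case_fraction)
    )

    bx_hat = _marginal_draw(_rng(truth.seed, "noise_exp"), bx_marg, se_exp, chol)
    by_hat = _marginal_draw(_rng(truth.seed, "noise_out"), by_marg, se_out, chol)

    exposure = _sumstats_frame(truth, ld, eafs, bx_hat, se_exp, truth.n_exp)
    outcome = _sumstats_frame(truth, ld, eafs, by_hat, se_out, truth.n_out)
    return exposure, outcome, ld


def simulate_coloc_scenario(
    shared: bool,
    strength: float = 12.0,
    base: RegionTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, LDMatrix]:
    """Two traits over one region, sharing a causal variant or not.

    ``strength`` is the target marginal z-score of the causal SNP in
    each trait.  With ``shared`` the same SNP drives both traits; else
    two causal SNPs with pairwise r² < 0.01 are used.  Returns region
    tables for the two traits plus the LD matrix.
    """
    truth = base or RegionTruth(m_snps=100, ld_rho=0.5, spacing_bp=20_000)
    m = truth.m_snps
    ld = region_ld(truth)
    eafs = truth.eafs()
    chol = np.linalg.cholesky(ld.r)

    idx1 = m // 4
    if shared:
        idx2 = idx1
    else:
        idx2 = 3 * m // 4
        if ld.r[idx1, idx2] ** 2 >= 0.01:
            raise ValueError("distinct causal SNPs are in LD; widen the region")

    def trait(idx: int, n: int, stream: str) -> pd.DataFrame:
        se = 1.0 / np.sqrt(2.0 * eafs * (1.0 - eafs) * n)
        b_joint = np.zeros(m)
        b_joint[idx] = strength * se[idx]
        b_marg = ld.r @ b_joint
        b_hat = _marginal_draw(_rng(truth.seed, stream), b_marg, se, chol)
        return _sumstats_frame(truth, ld, eafs, b_hat, se, n)

    trait1 = trait(idx1, truth.n_exp, "coloc_t1")
    trait2 = trait(idx2, truth.n_out, "coloc_t2")
    return trait1, trait2, ld


def simulate_null_ensemble(
    n_genes: int, template: RegionTruth | None = None, seed: int = 0
) -> list[RegionTruth]:
    """A panel of independent regions with no causal effect on the
    outcome (theta = 0); per-gene seeds derive from the master seed by a
    fixed offset so the panel is reproducible."""
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    template = template or RegionTruth()
    panel = []
    for g in range(n_genes):
        t = RegionTruth(**{**template.to_dict(), "theta": 0.0, "seed": seed + g})
        panel.append(t)
    return panel


def simulate_gene_panel(
    n_genes: int,
    template: RegionTruth | None = None,
    theta: float | Sequence[float] = 0.0,
    seed: int = 0,
    gene_prefix: str = "G",
) -> list[tuple[GeneRegion, RegionTruth]]:
    """Independent regions laid out on one chromosome, each with its own
    causal effect (scalar theta applies to all genes)."""
    template = template or RegionTruth()
    thetas = (
        np.full(n_genes, float(theta))
        if np.isscalar(theta)
        else np.asarray(theta, dtype=float)
    )
    if thetas.size != n_genes:
        raise ValueError("theta vector must match n_genes")
    span = template.m_snps * template.spacing_bp
    out = []
    for g in range(n_genes):
        t = RegionTruth(
            **{
                **template.to_dict(),
                "theta": float(thetas[g]),
                "seed": seed + g,
                # regions spaced far apart: independent loci
                "start_pos": template.start_pos + g * (span + 10_000_000),
            }
        )
        gene = t.gene(f"{gene_prefix}{g:04d}")
        out.append((gene, t))
    return out
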