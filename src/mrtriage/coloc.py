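"""Bayesian colocalization with Wakefield approximate Bayes factors.

For a region shared by two traits (here a gene's eQTL and a disease
GWAS, ±1 Mb around the gene), enumerate the five hypotheses under the
single-causal-variant-per-trait assumption:

* H0 — no causal variant for either trait;
* H1/H2 — a causal variant for trait 1 / trait 2 only;
* H3 — distinct causal variants;
* H4 — one shared causal variant.

Each SNP's evidence is the approximate Bayes factor computed from its
beta and SE with a normal effect-size prior; hypothesis masses are
accumulated entirely in log space.  Posterior PP.H4 > 0.80 is the
conventional colocalization call.  Default per-SNP priors are 1e-4 for
each single trait and 1e-5 for a shared variant.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from mrtriage.sumstats import GeneRegion

#: conventional effect-size prior SDs
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_BINARY = 0.20

HYPOTHESES = ("pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4")


class ColocError(ValueError):
    """The region cannot support the enumeration (e.g. too few SNPs)."""


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP causal priors: trait 1 only, trait 2 only, shared."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")

    def check_region(self, m: int) -> None:
        if m * (self.p1 + self.p2 + self.p12) >= 1:
            warnings.warn(
                f"priors sum to >=1 over the {m}-SNP region; posteriors "
                "remain defined but the prior model is degenerate",
                stacklevel=3,
            )


def extract_region(
    assocs: pd.DataFrame, gene: GeneRegion, flank: int = 1_000_000
) -> pd.DataFrame:
    """SNPs on the gene's chromosome within the closed interval
    [start − flank, end + flank]."""
    keep = (
        (assocs["chr"].astype(str) == str(gene.chrom))
        & (assocs["pos"] >= gene.start - flank)
        & (assocs["pos"] <= gene.end + flank)
    )
    return assocs.loc[keep].reset_index(drop=True)


def log_abf(beta, se, prior_sd: float = PRIOR_SD_QUANTITATIVE):
    """Log approximate Bayes factor for one association.

    With V = se², W = prior_sd² and z = beta/se, the shrinkage factor is
    r = W/(V+W) and log ABF = 0.5·[log(1−r) + r·z²].
    """
    se = np.asarray(se, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    v = se**2
    w = float(prior_sd) ** 2
    r = w / (v + w)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z**2)


def _log_h3_mass(l1: np.ndarray, l2: np.ndarray) -> float:
    """log Σ_{j≠k} exp(L1_j + L2_k), i.e. log(Σe^L1·Σe^L2 − Σe^(L1j+L2j)).

    The fast route subtracts in log space; when a single SNP dominates
    both traits the two terms cancel to machine precision, so the mass
    is then re-accumulated by direct pairwise summation over the j ≠ k
    grid, which involves no subtraction.
    """
    a = logsumexp(l1) + logsumexp(l2)
    b = logsumexp(l1 + l2)
    if a - b > 1e-10:
        return float(a + np.log1p(-np.exp(b - a)))
    grid = l1[:, None] + l2[None, :]
    np.fill_diagonal(grid, -np.inf)
    out = float(logsumexp(grid))
    if not np.isfinite(out):
        raise FloatingPointError(
            f"irrecoverable cancellation in H3 mass: log terms {a} vs {b}"
        )
    return out


@dataclass
class ColocResults:
    """Posterior probabilities of the five colocalization hypotheses."""

    n_snps: int
    pp: dict[str, float]
    priors: ColocPriors
    log_abf1: np.ndarray
    log_abf2: np.ndarray
    h4_cut: float = 0.80

    @property
    def colocalized(self) -> bool:
        return self.pp["pp_h4"] > self.h4_cut

    def to_dict(self) -> dict:
        out = {"n_snps": self.n_snps, **self.pp}
        out["colocalized"] = self.colocalized
        return out

    def summary(self) -> str:
        lines = [f"Colocalization over {self.n_snps} SNPs "
                 f"(priors p1={self.priors.p1:g}, p2={self.priors.p2:g}, "
                 f"p12={self.priors.p12:g})"]
        for h in HYPOTHESES:
            lines.append(f"  {h.upper().replace('_', '.')}: {self.pp[h]:.4f}")
        lines.append(
            f"  colocalized (PP.H4 > {self.h4_cut}): {self.colocalized}"
        )
        return "\n".join(lines)


class ColocModel:
    """Colocalization model for one region and two traits.

    Parameters
    ----------
    trait1, trait2
        Region summary statistics in the canonical dialect, already
        harmonized to common effect alleles; SNPs are inner-joined on
        ``snp`` and SNPs missing from either side are dropped (counted
        in ``n_dropped``).
    prior_sd1, prior_sd2
        Effect-size prior SDs (0.15 suits a quantitative trait such as
        expression; 0.20 a binary log-odds trait).
    """

    def __init__(
        self,
        trait1: pd.DataFrame,
        trait2: pd.DataFrame,
        prior_sd1: float = PRIOR_SD_QUANTITATIVE,
        prior_sd2: float = PRIOR_SD_BINARY,
    ):
        merged = trait1.merge(trait2, on="snp", suffixes=("_1", "_2"))
        if len(merged) < 2:
            raise ColocError(
                f"only {len(merged)} shared SNP(s) in the region; need >= 2"
            )
        self.snp_ids = list(merged["snp"])
        self.n_dropped = len(trait1) + len(trait2) - 2 * len(merged)
        self.l1 = np.asarray(
            log_abf(merged["beta_1"], merged["se_1"], prior_sd1)
        )
        self.l2 = np.asarray(
            log_abf(merged["beta_2"], merged["se_2"], prior_sd2)
        )

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def fit(
        self, priors: ColocPriors | None = None, h4_cut: float = 0.80
    ) -> ColocResults:
        """Enumerate hypothesis masses in log space and normalize.

        H1 ∝ p1·Σexp(L1j); H2 ∝ p2·Σexp(L2j); H4 ∝ p12·Σexp(L1j+L2j);
        H3 ∝ p1·p2·(Σexp(L1)·Σexp(L2) − Σexp(L1j+L2j)), computed by a
        stable log-space subtraction; H0 ∝ 1.
        """
        priors = priors or ColocPriors()
        priors.check_region(self.n_snps)
        l1, l2 = self.l1, self.l2
        s1 = logsumexp(l1)
        s2 = logsumexp(l2)
        s12 = logsumexp(l1 + l2)
        log_h = np.array(
            [
                0.0,
                np.log(priors.p1) + s1,
                np.log(priors.p2) + s2,
                np.log(priors.p1) + np.log(priors.p2)
                + _log_h3_mass(l1, l2),
                np.log(priors.p12) + s12,
            ]
        )
        pp = np.exp(log_h - logsumexp(log_h))
        return ColocResults(
            self.n_snps,
            dict(zip(HYPOTHESES, pp.tolist())),
            priors,
            l1,
            l2,
            h4_cut,
        )


def coloc_abf(
    trait1: pd.DataFrame,
    trait2: pd.DataFrame,
    priors: ColocPriors | None = None,
    prior_sd1: float = PRIOR_SD_QUANTITATIVE,
    prior_sd2: float = PRIOR_SD_BINARY,
    h4_cut: float = 0.80,
) -> ColocResults:
    """One-call convenience wrapper: build the model and fit it."""
    return ColocModel(trait1, trait2, prior_sd1, prior_sd2).fit(priors, h4_cut)
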