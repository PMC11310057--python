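"""Per-gene instrument construction for cis-MR.

Builds the instrument set for one gene from harmonized exposure/outcome
summary statistics: cis-window restriction, genome-wide significance and
MAF filters, greedy LD clumping, instrument-strength statistics (R² and
F), and Steiger directionality.  The stage order and thresholds follow
the standard drug-target MR quality-control recipe: common variants
(MAF > 0.01) at p < 5e-8 within ±100 kb of the gene body, clumped at
r² ≤ 0.1 within 10,000 kb, per-SNP F ≥ 10, and target-level Steiger
filtering (Σ R²_exposure must exceed Σ R²_outcome).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from mrtriage.sumstats import GeneRegion, HarmonizeResult, harmonize


class ClumpError(KeyError):
    """A SNP required for clumping is absent from the LD matrix."""


@dataclass
class LDMatrix:
    """Signed pairwise LD correlations over an ordered SNP list."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} != ({m}, {m})")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValueError("LD correlation outside [-1, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two SNPs."""
        try:
            return float(self.r[self._index[a], self._index[b]] ** 2)
        except KeyError as err:
            raise ClumpError(f"SNP {err.args[0]} absent from LD matrix") from None

    def subset(self, snps: Sequence[str]) -> "LDMatrix":
        idx = [self._index[s] for s in snps]
        return LDMatrix(list(snps), self.r[np.ix_(idx, idx)])

    @classmethod
    def read_tsv(cls, path) -> "LDMatrix":
        """Read a square TSV whose header and first column are SNP ids."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.r, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t"
        )


@dataclass
class InstrumentSet:
    """Clumped, strength-filtered instruments for one gene.

    ``variants`` is a harmonized-pair table extended with per-SNP
    ``r2_exp``, ``f_stat`` and ``r2_out`` columns.  ``stage_counts``
    records how many SNPs each QC stage removed.  An empty set carries
    the reason the gene yielded no valid instruments.
    """

    gene: GeneRegion
    variants: pd.DataFrame
    config: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    steiger: dict = field(default_factory=dict)
    reason: str | None = None

    @property
    def is_empty(self) -> bool:
        return len(self.variants) == 0

    @property
    def n_snp(self) -> int:
        return len(self.variants)


def cis_window_filter(
    assocs: pd.DataFrame, gene: GeneRegion, flank: int = 100_000
) -> pd.DataFrame:
    """Keep SNPs on the gene's chromosome with position in the closed
    interval [start - flank, end + flank]."""
    keep = (
        (assocs["chr"].astype(str) == str(gene.chrom))
        & (assocs["pos"] >= gene.start - flank)
        & (assocs["pos"] <= gene.end + flank)
    )
    return assocs.loc[keep].reset_index(drop=True)


def significance_maf_filter(
    assocs: pd.DataFrame, p_max: float = 5e-8, maf_min: float = 0.01
) -> pd.DataFrame:
    """Keep SNPs with p < p_max and minor-allele frequency > maf_min
    (both strict)."""
    maf = np.minimum(assocs["eaf"], 1.0 - assocs["eaf"])
    return assocs.loc[(assocs["p"] < p_max) & (maf > maf_min)].reset_index(
        drop=True
    )


def ld_clump(
    assocs: pd.DataFrame,
    ld: LDMatrix,
    r2_max: float = 0.1,
    window: int = 10_000_000,
) -> pd.DataFrame:
    """Greedy LD clumping: keep index SNPs in ascending p-value order.

    SNPs are sorted by p-value (ties broken by position, then snp id);
    the best remaining SNP is kept and every remaining SNP within
    ``window`` bp having r² > r2_max with it is discarded.  Returns the
    kept index SNPs in selection order.

    Raises
    ------
    ClumpError
        If any input SNP is missing from the LD matrix.
    """
    if assocs.empty:
        return assocs.copy()
    for snp in assocs["snp"]:
        if snp not in ld._index:
            raise ClumpError(f"SNP {snp} absent from LD matrix")
    ranked = assocs.sort_values(
        ["p", "pos", "snp"], kind="mergesort"
    ).reset_index(drop=True)
    kept_rows = []
    remaining = list(ranked.itertuples(index=False))
    while remaining:
        best = remaining.pop(0)
        kept_rows.append(best)
        remaining = [
            s
            for s in remaining
            if abs(s.pos - best.pos) > window or ld.r2(s.snp, best.snp) <= r2_max
        ]
    return pd.DataFrame(kept_rows, columns=ranked.columns)


def variance_explained(eaf, beta):
    """Variance in the trait explained by one SNP: R² = 2·EAF·(1−EAF)·β²."""
    eaf = np.asarray(eaf, dtype=float)
    beta = np.asarray(beta, dtype=float)
    return 2.0 * eaf * (1.0 - eaf) * beta**2


def f_statistic(r2, n):
    """Instrument strength F = R²·(N−2)/(1−R²); F < 10 flags a weak
    instrument."""
    r2 = np.asarray(r2, dtype=float)
    n = np.asarray(n, dtype=float)
    return r2 * (n - 2.0) / (1.0 - r2)


def steiger_filter(variants: pd.DataFrame) -> dict:
    """Target-level directionality check.

    The gene passes iff its instruments jointly explain more variance in
    the exposure than in the outcome: Σ r2_exp > Σ r2_out (strict).  The
    outcome R² uses the same 2p(1−p)β² formula on the log-odds betas,
    a scale-consistent approximation for a binary outcome.
    """
    total_exp = float(variants["r2_exp"].sum())
    total_out = float(variants["r2_out"].sum())
    return {
        "pass": total_exp > total_out,
        "r2_exp_total": total_exp,
        "r2_out_total": total_out,
    }


def build_instruments(
    gene: GeneRegion,
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: LDMatrix,
    flank: int = 100_000,
    p_max: float = 5e-8,
    maf_min: float = 0.01,
    clump_r2: float = 0.1,
    clump_window: int = 10_000_000,
    f_min: float = 10.0,
    palindrome_eaf_band: float = 0.08,
    per_snp_steiger: bool = False,
) -> InstrumentSet:
    """Run the full instrument QC cascade for one gene.

    Stage order: cis window -> significance/MAF -> harmonization ->
    LD clumping -> strength (drop F < f_min) -> Steiger.  A gene whose
    cascade ends empty (or that fails Steiger at target level) returns
    an empty InstrumentSet carrying the reason, never an exception, so a
    multi-gene pipeline can skip it.
    """
    config = {
        "flank_bp": flank,
        "p_max": p_max,
        "maf_min": maf_min,
        "clump_r2": clump_r2,
        "clump_window_bp": clump_window,
        "f_min": f_min,
        "palindrome_eaf_band": palindrome_eaf_band,
        "per_snp_steiger": per_snp_steiger,
    }
    counts: dict[str, int] = {"input": len(exposure)}

    def empty(reason: str) -> InstrumentSet:
        return InstrumentSet(
            gene, pd.DataFrame(), config, counts, reason="no valid instruments: " + reason
        )

    stage = cis_window_filter(exposure, gene, flank)
    counts["removed_cis_window"] = counts["input"] - len(stage)
    stage = significance_maf_filter(stage, p_max, maf_min)
    counts["removed_significance_maf"] = (
        counts["input"] - counts["removed_cis_window"] - len(stage)
    )
    if stage.empty:
        return empty("no genome-wide-significant common cis SNP")

    pairs, _audit = harmonize(stage, outcome, palindrome_eaf_band)
    counts["removed_harmonization"] = len(stage) - len(pairs)
    if pairs.empty:
        return empty("no SNP survived harmonization")

    ranked = pairs.rename(columns={"p_exp": "p"})
    clumped = ld_clump(ranked, ld, clump_r2, clump_window)
    counts["removed_clumping"] = len(pairs) - len(clumped)
    clumped = clumped.rename(columns={"p": "p_exp"})

    clumped = clumped.assign(
        r2_exp=variance_explained(clumped["eaf_exp"], clumped["beta_exp"]),
        r2_out=variance_explained(clumped["eaf_out"], clumped["beta_out"]),
    )
    clumped = clumped.assign(
        f_stat=f_statistic(clumped["r2_exp"], clumped["n_exp"])
    )
    strong = clumped.loc[clumped["f_stat"] >= f_min].reset_index(drop=True)
    counts["removed_weak_f"] = len(clumped) - len(strong)
    if strong.empty:
        return empty("all instruments weak (F below threshold)")

    if per_snp_steiger:
        keep = strong["r2_exp"] > strong["r2_out"]
        counts["removed_steiger_snp"] = int((~keep).sum())
        strong = strong.loc[keep].reset_index(drop=True)
        if strong.empty:
            return empty("all SNPs failed per-SNP Steiger")

    steiger = steiger_filter(strong)
    counts["kept"] = len(strong)
    if not steiger["pass"]:
        out = empty("failed Steiger directionality")
        out.steiger = steiger
        return out
    return InstrumentSet(gene, strong, config, counts, steiger=steiger)
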