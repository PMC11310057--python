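"""Discovery -> sensitivity -> replication -> colocalization orchestration.

Runs the per-gene triage over a panel of candidate drug-target genes:

1. **Discovery** — build instruments for every gene, estimate the
   primary causal effect (Wald ratio for a single instrument, otherwise
   IVW with multiplicative random effects), gate at the Bonferroni
   threshold ``family_alpha / m`` where m counts genes with at least one
   valid instrument, and apply the sensitivity verdict (direction
   concordance across estimators, heterogeneity with possible
   weighted-median rescue, Egger-intercept pleiotropy, Steiger).
2. **Replication** — repeat the identical protocol against a second
   outcome for the genes that survived, at ``family_alpha`` divided by
   the number of carried hits; a hit validates only when significant
   with the same effect direction as in discovery.
3. **Colocalization** — annotate (never gate) each carried gene with
   the posterior probability that the gene's expression signal and the
   outcome share one causal variant in the ±1 Mb region.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd

from mrtriage import diagnostics
from mrtriage.coloc import ColocError, ColocPriors, coloc_abf, extract_region
from mrtriage.estimators import EstimationError, MRModel, MRResults
from mrtriage.instruments import InstrumentSet, LDMatrix, build_instruments
from mrtriage.sumstats import GeneRegion

STATUS_VALIDATED = "significant_validated"
STATUS_DISCOVERY_ONLY = "significant_discovery_only"
STATUS_EXCLUDED = "excluded_sensitivity"
STATUS_NOT_SIG = "not_significant"
STATUS_NO_INSTRUMENTS = "no_instruments"


class BonferroniThreshold(NamedTuple):
    """Per-test threshold: exact value and the value rounded for display."""

    exact: float
    rounded: float


def bonferroni_threshold(
    family_alpha: float, m: int, sig_digits: int = 2
) -> BonferroniThreshold:
    """Family-wise threshold family_alpha / m.

    Reported both exact and rounded to ``sig_digits`` significant
    figures (e.g. 0.05/499 -> 1.00e-4; 0.05/31 -> 0.0016).  Gating
    always uses the exact value.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must be in (0, 1)")
    exact = family_alpha / m
    rounded = float(f"%.{sig_digits - 1}e" % exact)
    return BonferroniThreshold(exact, rounded)


@dataclass
class PipelineConfig:
    """All thresholds of the triage; serialized verbatim into the manifest."""

    p_max: float = 5e-8
    maf_min: float = 0.01
    flank_bp: int = 100_000
    clump_r2: float = 0.1
    clump_window_bp: int = 10_000_000
    f_min: float = 10.0
    palindrome_eaf_band: float = 0.08
    family_alpha: float = 0.05
    coloc_flank_bp: int = 1_000_000
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    pp_h4_cut: float = 0.80
    n_boot: int = 5000
    seed: int = 0

    def priors(self) -> ColocPriors:
        return ColocPriors(self.coloc_p1, self.coloc_p2, self.coloc_p12)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GeneData:
    """One gene's inputs: region, exposure/outcome tables, LD matrix."""

    gene: GeneRegion
    exposure: pd.DataFrame
    outcome: pd.DataFrame
    ld: LDMatrix


@dataclass
class GeneAnalysis:
    """Per-gene artefacts of one phase."""

    gene: GeneRegion
    instruments: InstrumentSet
    results: MRResults | None = None
    significant: bool = False
    verdict: diagnostics.SensitivityVerdict | None = None
    error: str | None = None

    @property
    def has_instruments(self) -> bool:
        return self.results is not None


def _gene_seed(seed: int, gene_id: str) -> int:
    return (seed * 7919 + zlib.crc32(gene_id.encode())) % (2**31 - 1)


def _analyze_gene(g: GeneData, config: PipelineConfig) -> GeneAnalysis:
    iset = build_instruments(
        g.gene,
        g.exposure,
        g.outcome,
        g.ld,
        flank=config.flank_bp,
        p_max=config.p_max,
        maf_min=config.maf_min,
        clump_r2=config.clump_r2,
        clump_window=config.clump_window_bp,
        f_min=config.f_min,
        palindrome_eaf_band=config.palindrome_eaf_band,
    )
    if iset.is_empty:
        return GeneAnalysis(g.gene, iset)
    model = MRModel.from_instruments(iset)
    try:
        results = model.fit_all(
            seed=_gene_seed(config.seed, g.gene.gene_id), n_boot=config.n_boot
        )
    except EstimationError as err:
        return GeneAnalysis(g.gene, iset, error=str(err))
    return GeneAnalysis(g.gene, iset, results)


def _apply_sensitivity(
    analysis: GeneAnalysis, alpha_sig: float
) -> diagnostics.SensitivityVerdict:
    results = analysis.results
    model = results.model
    het = (
        diagnostics.cochran_q(model, "ivw") if model.n_snp >= 2 else None
    )
    pleio = (
        diagnostics.egger_intercept_test(model) if model.n_snp >= 3 else None
    )
    wm = results.estimates.get("weighted_median")
    return diagnostics.sensitivity_verdict(
        list(results.estimates.values()),
        het,
        pleio,
        steiger_pass=bool(analysis.instruments.steiger.get("pass", True)),
        alpha_sig=alpha_sig,
        weighted_median=wm,
    )


def _phase_row(a: GeneAnalysis, threshold: float | None) -> dict:
    row = {
        "gene": a.gene.gene_id,
        "symbol": a.gene.symbol,
        "nsnp": a.instruments.n_snp,
        "method": None,
        "beta": np.nan,
        "se": np.nan,
        "p": np.nan,
        "or": np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "threshold": threshold,
        "significant": False,
    }
    if a.results is not None:
        row.update(a.results.primary.to_dict())
        row["gene"] = a.gene.gene_id
        row["significant"] = a.significant
    if a.verdict is not None:
        v = a.verdict
        row.update(
            direction_concordant=v.direction_concordant,
            heterogeneity_flag=v.heterogeneity_flag,
            heterogeneity_rescued=v.heterogeneity_rescued,
            pleiotropy_flag=v.pleiotropy_flag,
            steiger_pass=v.steiger_pass,
            sensitivity_pass=v.passes,
        )
    return row


class PhaseResult(NamedTuple):
    table: pd.DataFrame
    analyses: dict[str, GeneAnalysis]
    threshold: BonferroniThreshold | None
    m_tested: int


def run_discovery(
    gene_data: list[GeneData], config: PipelineConfig
) -> PhaseResult:
    """Discovery phase over the full candidate panel.

    The Bonferroni denominator m counts only genes that yielded at least
    one valid instrument; genes without instruments are reported with
    status ``no_instruments`` and excluded from m.  The sensitivity
    verdict is evaluated for the significant genes at the same
    per-phase threshold (used by the weighted-median rescue rule).
    """
    analyses = {g.gene.gene_id: _analyze_gene(g, config) for g in gene_data}
    tested = [a for a in analyses.values() if a.has_instruments]
    thr = (
        bonferroni_threshold(config.family_alpha, len(tested))
        if tested
        else None
    )
    for a in tested:
        a.significant = a.results.primary.pvalue < thr.exact
        if a.significant:
            a.verdict = _apply_sensitivity(a, thr.exact)
    table = pd.DataFrame(
        [_phase_row(a, thr.exact if thr else None) for a in analyses.values()]
    )
    return PhaseResult(table, analyses, thr, len(tested))


def run_replication(
    hits: list[str],
    gene_data: list[GeneData],
    discovery: PhaseResult,
    config: PipelineConfig,
) -> PhaseResult:
    """Replication of the carried hits against a second outcome, with
    the identical estimation protocol.

    The threshold is family_alpha divided by the number of carried
    hits; a gene validates only when significant and its primary-effect
    sign matches the discovery sign.
    """
    by_id = {g.gene.gene_id: g for g in gene_data}
    missing = [h for h in hits if h not in by_id]
    if missing:
        raise KeyError(f"replication data missing for hits: {missing}")
    analyses = {h: _analyze_gene(by_id[h], config) for h in hits}
    thr = bonferroni_threshold(config.family_alpha, len(hits)) if hits else None
    rows = []
    for h, a in analyses.items():
        sig = a.has_instruments and a.results.primary.pvalue < thr.exact
        direction_ok = False
        if a.has_instruments:
            disc = discovery.analyses[h]
            if disc.has_instruments:
                direction_ok = (
                    np.sign(a.results.primary.beta)
                    == np.sign(disc.results.primary.beta)
                ) and a.results.primary.beta != 0
            a.significant = sig and direction_ok
            if a.significant:
                a.verdict = _apply_sensitivity(a, thr.exact)
        row = _phase_row(a, thr.exact if thr else None)
        row["direction_consistent_with_discovery"] = direction_ok
        rows.append(row)
    table = pd.DataFrame(rows)
    return PhaseResult(table, analyses, thr, len(hits))


def run_coloc(
    hits: list[str],
    gene_data: list[GeneData],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Colocalize each carried gene's exposure signal with the outcome
    over the ±1 Mb region; one row per gene."""
    by_id = {g.gene.gene_id: g for g in gene_data}
    rows = []
    for h in hits:
        g = by_id[h]
        t1 = extract_region(g.exposure, g.gene, config.coloc_flank_bp)
        t2 = extract_region(g.outcome, g.gene, config.coloc_flank_bp)
        row = {"gene": h}
        try:
            res = coloc_abf(
                t1, t2, priors=config.priors(), h4_cut=config.pp_h4_cut
            )
            row.update(res.to_dict())
        except ColocError as err:
            row.update(n_snps=0, colocalized=False, error=str(err))
        rows.append(row)
    return pd.DataFrame(rows)


def classify_target(
    gene_id: str,
    discovery: PhaseResult,
    replication: PhaseResult | None,
    coloc_table: pd.DataFrame | None,
) -> dict:
    """Final status ladder for one gene.

    ``significant_validated`` requires instruments, discovery
    significance, a passing sensitivity verdict, and a significant,
    direction-consistent replication.  Colocalization only annotates.
    """
    a = discovery.analyses[gene_id]
    if not a.has_instruments:
        status = STATUS_NO_INSTRUMENTS
    elif not a.significant:
        status = STATUS_NOT_SIG
    elif a.verdict is not None and not a.verdict.passes:
        status = STATUS_EXCLUDED
    else:
        status = STATUS_DISCOVERY_ONLY
        if replication is not None and gene_id in replication.analyses:
            r = replication.analyses[gene_id]
            if r.has_instruments and r.significant:
                status = STATUS_VALIDATED
    out = {"gene": gene_id, "status": status}
    if coloc_table is not None and gene_id in set(coloc_table["gene"]):
        rec = coloc_table.loc[coloc_table["gene"] == gene_id].iloc[0]
        out["pp_h4"] = rec.get("pp_h4", np.nan)
        out["colocalized"] = bool(rec.get("colocalized", False))
    return out


@dataclass
class PipelineResult:
    """All phase tables plus the run manifest."""

    discovery: PhaseResult
    replication: PhaseResult | None
    coloc: pd.DataFrame | None
    verdicts: pd.DataFrame
    manifest: dict

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.discovery.table.to_csv(
            outdir / "discovery.tsv", sep="\t", index=False
        )
        if self.replication is not None:
            self.replication.table.to_csv(
                outdir / "replication.tsv", sep="\t", index=False
            )
        if self.coloc is not None:
            self.coloc.to_csv(outdir / "coloc.tsv", sep="\t", index=False)
        self.verdicts.to_csv(outdir / "verdicts.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def run_pipeline(
    discovery_data: list[GeneData],
    replication_data: list[GeneData] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """End-to-end triage: discovery, sensitivity, replication over a
    second outcome (when provided), colocalization annotation, and the
    final per-gene verdict table."""
    from mrtriage import __version__

    config = config or PipelineConfig()
    disc = run_discovery(discovery_data, config)
    hits = [
        gid
        for gid, a in disc.analyses.items()
        if a.significant and a.verdict is not None and a.verdict.passes
    ]
    rep = None
    if replication_data is not None and hits:
        rep_ids = {g.gene.gene_id for g in replication_data}
        carried = [h for h in hits if h in rep_ids]
        rep = run_replication(carried, replication_data, disc, config)
    coloc_sources = replication_data if replication_data is not None else discovery_data
    coloc_table = (
        run_coloc(
            [h for h in hits if h in {g.gene.gene_id for g in coloc_sources}],
            coloc_sources,
            config,
        )
        if hits
        else None
    )
    verdicts = pd.DataFrame(
        [
            classify_target(gid, disc, rep, coloc_table)
            for gid in disc.analyses
        ]
    )
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "n_genes": len(discovery_data),
        "m_discovery": disc.m_tested,
        "discovery_threshold": disc.threshold._asdict() if disc.threshold else None,
        "hits_carried": hits,
        "replication_threshold": (
            rep.threshold._asdict() if rep and rep.threshold else None
        ),
        "stage_counts": {
            gid: a.instruments.stage_counts for gid, a in disc.analyses.items()
        },
        "status_counts": verdicts["status"].value_counts().to_dict(),
    }
    return PipelineResult(disc, rep, coloc_table, verdicts, manifest)
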