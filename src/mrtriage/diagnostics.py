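"""Heterogeneity, pleiotropy and direction-concordance diagnostics.

These checks feed the triage verdict applied to each significant gene:

* Cochran's Q (against the IVW fit or the Egger fit) quantifies
  instrument heterogeneity, flagged at p < 0.05;
* the MR-Egger intercept tests directional pleiotropy, flagged at
  p < 0.05;
* direction concordance requires every estimator's causal estimate to
  share one sign;
* a heterogeneity flag can be rescued when the weighted-median estimate
  stays significant at the phase's multiple-testing threshold —
  heterogeneous but rescued genes survive, heterogeneous unrescued ones
  are excluded ("unaccountable heterogeneity").
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from mrtriage.estimators import MREstimate, MRModel


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q heterogeneity test."""

    method: str  # "ivw" or "egger"
    q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class PleiotropyResult:
    """MR-Egger intercept test for directional pleiotropy."""

    intercept: float
    se: float
    pvalue: float


@dataclass(frozen=True)
class SensitivityVerdict:
    """Aggregate sensitivity triage for one gene."""

    direction_concordant: bool
    heterogeneity_flag: bool
    heterogeneity_rescued: bool
    pleiotropy_flag: bool
    steiger_pass: bool

    def __post_init__(self) -> None:
        if self.heterogeneity_rescued and not self.heterogeneity_flag:
            raise ValueError("rescue implies a heterogeneity flag")

    @property
    def passes(self) -> bool:
        return (
            self.direction_concordant
            and (not self.heterogeneity_flag or self.heterogeneity_rescued)
            and not self.pleiotropy_flag
            and self.steiger_pass
        )


def cochran_q(model: MRModel, reference: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q: weighted squared deviations of per-SNP estimates
    from the reference fit (first-order ratio weights for IVW,
    regression weights for Egger); p from chi-square with k − 1 or
    k − 2 degrees of freedom."""
    k = model.n_snp
    if reference == "ivw":
        if k < 2:
            raise ValueError("IVW Q needs at least 2 instruments")
        _, _, q = model._ivw_core()
        df = k - 1
    elif reference == "egger":
        est = model.egger()  # raises below 3 instruments
        q, df = est.extra["q"], est.extra["df"]
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return HeterogeneityResult(reference, q, df, float(stats.chi2.sf(q, df)))


def egger_intercept_test(model: MRModel) -> PleiotropyResult:
    """Intercept, SE and two-sided t p-value from the MR-Egger fit."""
    e = model.egger().extra
    return PleiotropyResult(e["intercept"], e["intercept_se"], e["intercept_p"])


def direction_concordance(estimates: list[MREstimate]) -> bool:
    """True iff every estimate's beta shares one strict sign.

    A zero beta counts as discordant; a single estimate is vacuously
    concordant.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    if len(estimates) == 1:
        return True
    signs = {1 if e.beta > 0 else (-1 if e.beta < 0 else 0) for e in estimates}
    return len(signs) == 1 and 0 not in signs


def sensitivity_verdict(
    estimates: list[MREstimate],
    heterogeneity: HeterogeneityResult | None,
    pleiotropy: PleiotropyResult | None,
    steiger_pass: bool,
    alpha_sig: float,
    weighted_median: MREstimate | None = None,
    alpha_flag: float = 0.05,
) -> SensitivityVerdict:
    """Combine the diagnostics into the per-gene triage verdict.

    The gene passes iff the estimator directions agree, any apparent
    heterogeneity (Q p < ``alpha_flag``) is rescued by a weighted-median
    estimate significant at the phase threshold ``alpha_sig``, the Egger
    intercept shows no pleiotropy, and Steiger directionality holds.
    Single-instrument genes have no Q or intercept to flag.
    """
    het_flag = heterogeneity is not None and heterogeneity.pvalue < alpha_flag
    rescued = (
        het_flag
        and weighted_median is not None
        and weighted_median.pvalue < alpha_sig
    )
    pleio_flag = pleiotropy is not None and pleiotropy.pvalue < alpha_flag
    return SensitivityVerdict(
        direction_concordant=direction_concordance(estimates),
        heterogeneity_flag=het_flag,
        heterogeneity_rescued=rescued,
        pleiotropy_flag=pleio_flag,
        steiger_pass=steiger_pass,
    )
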