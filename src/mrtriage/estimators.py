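"""Two-sample MR causal-effect estimators.

The central object is :class:`MRModel`, built from harmonized per-SNP
summary statistics (exposure and outcome betas with standard errors).
``fit(method=...)`` returns an :class:`MREstimate` results object for
one estimator; ``fit_all()`` returns an :class:`MRResults` collection
with a ``summary()`` table in the forest-plot shape (beta, SE, p, OR and
its 95% CI).

Five estimators are provided:

* ``wald_ratio`` — single-SNP ratio with a delta-method SE;
* ``ivw_fe`` / ``ivw_mre`` — inverse-variance-weighted regression
  through the origin, fixed or multiplicative-random-effects SE (the
  MRE factor sqrt(Q/(k−1)) is floored at 1, it never deflates);
* ``egger`` — weighted regression with a free intercept; the intercept
  estimates directional pleiotropy;
* ``weighted_median`` — inverse-variance-weighted median of per-SNP
  ratios, SE by seeded parametric bootstrap;
* ``max_likelihood`` — profile likelihood of a bivariate normal
  measurement model with the per-SNP true exposure effects profiled out
  in closed form.

All p-values are two-sided; IVW/Wald/ML use the normal reference, Egger
uses t with k−2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from mrtriage.instruments import InstrumentSet

Z_95 = 1.959964  # two-sided 95% normal quantile

METHODS = (
    "wald_ratio",
    "ivw_fe",
    "ivw_mre",
    "egger",
    "weighted_median",
    "max_likelihood",
)


class EstimationError(RuntimeError):
    """Raised when an estimator's preconditions fail or it cannot converge."""


@dataclass
class MREstimate:
    """One method's causal-effect estimate on the log-odds scale."""

    gene_id: str
    method: str
    n_snp: int
    beta: float
    se: float
    pvalue: float
    extra: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z_95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z_95 * self.se))

    def to_dict(self) -> dict:
        return {
            "gene": self.gene_id,
            "method": self.method,
            "nsnp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "p": self.pvalue,
            "or": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def _norm_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _wald_arrays(bx, sx, by, sy, second_order: bool):
    theta = by / bx
    if second_order:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / np.abs(bx)
    return theta, se


class MRModel:
    """Two-sample MR model for one gene's instrument set.

    Parameters
    ----------
    beta_exp, se_exp
        Per-SNP effects of each instrument on the exposure (gene
        expression) and their standard errors.
    beta_out, se_out
        Corresponding effects on the outcome (log-odds for a binary
        trait), harmonized to the same effect allele.
    snp_ids, gene_id
        Optional labels carried into results.
    """

    def __init__(
        self,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        snp_ids: Iterable[str] | None = None,
        gene_id: str = "",
    ):
        self.bx = np.asarray(beta_exp, dtype=float)
        self.sx = np.asarray(se_exp, dtype=float)
        self.by = np.asarray(beta_out, dtype=float)
        self.sy = np.asarray(se_out, dtype=float)
        if not (self.bx.shape == self.sx.shape == self.by.shape == self.sy.shape):
            raise ValueError("beta/se arrays must share one shape")
        if self.bx.ndim != 1 or self.bx.size == 0:
            raise ValueError("need a non-empty 1-D instrument set")
        if np.any(self.sx <= 0) or np.any(self.sy <= 0):
            raise ValueError("standard errors must be positive")
        self.snp_ids = (
            list(snp_ids) if snp_ids is not None
            else [f"snp{i}" for i in range(self.bx.size)]
        )
        self.gene_id = gene_id

    @classmethod
    def from_instruments(cls, s: InstrumentSet) -> "MRModel":
        """Build the model from an :class:`InstrumentSet`."""
        if s.is_empty:
            raise EstimationError(f"gene {s.gene.gene_id}: {s.reason}")
        v = s.variants
        return cls(
            v["beta_exp"], v["se_exp"], v["beta_out"], v["se_out"],
            snp_ids=list(v["snp"]), gene_id=s.gene.gene_id,
        )

    @property
    def n_snp(self) -> int:
        return int(self.bx.size)

    # ------------------------------------------------------------------
    # individual estimators
    # ------------------------------------------------------------------
    def wald_ratio(self, second_order: bool = False) -> MREstimate:
        """Single-SNP ratio estimate beta_out / beta_exp.

        The default SE is the first-order delta method se_out/|beta_exp|;
        ``second_order`` adds the exposure-noise term.
        """
        if self.n_snp != 1:
            raise EstimationError("wald_ratio is defined for exactly one SNP")
        if self.bx[0] == 0:
            raise EstimationError("undefined ratio: beta_exp is zero")
        theta, se = _wald_arrays(
            self.bx[0], self.sx[0], self.by[0], self.sy[0], second_order
        )
        return MREstimate(
            self.gene_id, "wald_ratio", 1, float(theta), float(se),
            _norm_p(theta / se),
        )

    def _ivw_core(self):
        w = 1.0 / self.sy**2
        denom = float(np.sum(w * self.bx**2))
        if denom == 0:
            raise EstimationError("degenerate design: all beta_exp are zero")
        theta = float(np.sum(w * self.bx * self.by) / denom)
        se_fe = denom**-0.5
        q = float(np.sum(w * (self.by - theta * self.bx) ** 2))
        return theta, se_fe, q

    def ivw(self, model: str = "multiplicative_random") -> MREstimate:
        """Inverse-variance-weighted estimate (regression through the
        origin with weights 1/se_out²).

        ``model="fixed"`` reports the fixed-effect SE; the default
        multiplicative random-effects model inflates it by
        max(1, sqrt(Q/(k−1))) where Q is Cochran's Q.  A single SNP
        delegates to the Wald ratio.
        """
        if model not in ("fixed", "multiplicative_random"):
            raise ValueError(f"unknown IVW model {model!r}")
        if self.n_snp == 1:
            est = self.wald_ratio()
            est.method = "ivw_fe" if model == "fixed" else "ivw_mre"
            return est
        theta, se_fe, q = self._ivw_core()
        if model == "fixed":
            se, method = se_fe, "ivw_fe"
        else:
            se = se_fe * max(1.0, np.sqrt(q / (self.n_snp - 1)))
            method = "ivw_mre"
        return MREstimate(
            self.gene_id, method, self.n_snp, theta, float(se),
            _norm_p(theta / se), extra={"q": q},
        )

    def egger(self) -> MREstimate:
        """MR-Egger: weighted regression of outcome on exposure effects
        with a free intercept.

        Each SNP is oriented so beta_exp ≥ 0 (negating both betas where
        needed), weights are 1/se_out², and both SEs are inflated by
        max(1, sqrt(Q'/(k−2))).  The slope estimate is returned; the
        intercept (the directional-pleiotropy estimate) with its SE and
        t-test p-value rides along in ``extra``.
        """
        k = self.n_snp
        if k < 3:
            raise EstimationError("MR-Egger needs at least 3 instruments")
        sign = np.where(self.bx < 0, -1.0, 1.0)
        bx, by = self.bx * sign, self.by * sign
        w = 1.0 / self.sy**2
        X = np.column_stack([np.ones(k), bx])
        fit = sm.WLS(by, X, weights=w).fit()
        coef = fit.params
        # fit.scale is Q'/(k-2); re-floor the inflation at 1 so the SE
        # never deflates below the fixed-weight value
        q = float(fit.scale * (k - 2))
        infl = max(1.0, np.sqrt(q / (k - 2)))
        se = np.sqrt(np.diag(fit.normalized_cov_params)) * infl
        df = k - 2
        p_slope = float(min(1.0, 2.0 * stats.t.sf(abs(coef[1] / se[1]), df)))
        p_int = float(min(1.0, 2.0 * stats.t.sf(abs(coef[0] / se[0]), df)))
        return MREstimate(
            self.gene_id, "egger", k, float(coef[1]), float(se[1]), p_slope,
            extra={
                "intercept": float(coef[0]),
                "intercept_se": float(se[0]),
                "intercept_p": p_int,
                "q": q,
                "df": df,
            },
        )

    def weighted_median(
        self, n_boot: int = 5000, seed: int | np.random.Generator = 0
    ) -> MREstimate:
        """Inverse-variance-weighted median of the per-SNP ratios.

        Ratios are sorted; weights (inverse first-order ratio variances)
        are normalized and cumulated with the half-weight convention,
        and the estimate is the linear interpolation of the ratio at
        cumulative weight 0.5.  The SE is the standard deviation of the
        estimate over ``n_boot`` parametric-bootstrap resamples in which
        each beta pair is redrawn from its sampling normal.
        """
        if self.n_snp < 3:
            raise EstimationError("weighted median needs at least 3 instruments")
        theta = _weighted_median(self.by / self.bx, (self.bx / self.sy) ** 2)
        rng = (
            seed if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        bx_b = rng.normal(self.bx, self.sx, size=(n_boot, self.n_snp))
        by_b = rng.normal(self.by, self.sy, size=(n_boot, self.n_snp))
        boots = np.empty(n_boot)
        for i in range(n_boot):
            boots[i] = _weighted_median(
                by_b[i] / bx_b[i], (bx_b[i] / self.sy) ** 2
            )
        se = float(np.std(boots, ddof=1))
        return MREstimate(
            self.gene_id, "weighted_median", self.n_snp, float(theta), se,
            _norm_p(theta / se) if se > 0 else (1.0 if theta == 0 else 0.0),
        )

    def _profile_loglik(self, theta: float) -> float:
        # closed-form profile over the per-SNP true exposure effects
        num = self.bx / self.sx**2 + theta * self.by / self.sy**2
        den = 1.0 / self.sx**2 + theta**2 / self.sy**2
        xi = num / den
        return float(
            -0.5 * np.sum(
                (self.bx - xi) ** 2 / self.sx**2
                + (self.by - theta * xi) ** 2 / self.sy**2
            )
        )

    def max_likelihood(self) -> MREstimate:
        """Profile-likelihood estimate of the causal effect.

        Model: the observed (beta_exp_j, beta_out_j) are independent
        normals around (xi_j, theta·xi_j) with known SEs; each xi_j is
        profiled out in closed form and theta maximized by bounded 1-D
        optimization bracketing the IVW estimate.  The SE comes from the
        numerical curvature of the profile log-likelihood.
        """
        if self.n_snp == 1:
            est = self.wald_ratio()
            est.method = "max_likelihood"
            return est
        ivw = self.ivw(model="fixed")
        center, scale = ivw.beta, max(ivw.se, 1e-8)
        half = 10.0 * scale
        nll = lambda t: -self._profile_loglik(t)
        for _ in range(60):
            lo, hi = center - half, center + half
            if nll(lo) > nll(center) and nll(hi) > nll(center):
                break
            half *= 2.0
        else:
            raise EstimationError(
                f"profile likelihood not bracketed: center={center}, "
                f"half-width={half}, nll(center)={nll(center)}"
            )
        res = optimize.minimize_scalar(
            nll, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        if not res.success:
            raise EstimationError(
                f"profile optimization failed in [{lo}, {hi}]: {res.message}"
            )
        theta = float(res.x)
        h = max(1e-6, 1e-4 * scale)
        curv = (nll(theta + h) - 2.0 * nll(theta) + nll(theta - h)) / h**2
        if curv <= 0:
            raise EstimationError(
                f"non-positive curvature {curv} at theta={theta}"
            )
        se = float(curv**-0.5)
        return MREstimate(
            self.gene_id, "max_likelihood", self.n_snp, theta, se,
            _norm_p(theta / se),
        )

    # ------------------------------------------------------------------
    def fit(self, method: str = "ivw_mre", **kwargs) -> MREstimate:
        """Fit one estimator by name (see :data:`METHODS`)."""
        if method == "wald_ratio":
            return self.wald_ratio(**kwargs)
        if method == "ivw_fe":
            return self.ivw(model="fixed")
        if method == "ivw_mre":
            return self.ivw(model="multiplicative_random")
        if method == "egger":
            return self.egger()
        if method == "weighted_median":
            return self.weighted_median(**kwargs)
        if method == "max_likelihood":
            return self.max_likelihood()
        raise ValueError(f"unknown method {method!r}")

    def fit_all(self, seed: int = 0, n_boot: int = 5000) -> "MRResults":
        """Fit the primary estimator plus every secondary one the
        instrument count permits.

        The primary estimate is the Wald ratio for a single instrument,
        else IVW with multiplicative random effects; Egger and the
        weighted median require k ≥ 3.
        """
        estimates: dict[str, MREstimate] = {}
        if self.n_snp == 1:
            primary = self.wald_ratio()
            estimates["wald_ratio"] = primary
        else:
            primary = self.ivw(model="multiplicative_random")
            estimates["ivw_mre"] = primary
            estimates["ivw_fe"] = self.ivw(model="fixed")
            estimates["max_likelihood"] = self.max_likelihood()
            if self.n_snp >= 3:
                estimates["egger"] = self.egger()
                estimates["weighted_median"] = self.weighted_median(
                    n_boot=n_boot, seed=seed
                )
        return MRResults(self, estimates, primary_method=primary.method)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, r))


class MRResults:
    """Collection of fitted estimates for one gene."""

    def __init__(
        self,
        model: MRModel,
        estimates: dict[str, MREstimate],
        primary_method: str,
    ):
        self.model = model
        self.estimates = estimates
        self.primary_method = primary_method

    @property
    def primary(self) -> MREstimate:
        return self.estimates[self.primary_method]

    def __getitem__(self, method: str) -> MREstimate:
        return self.estimates[method]

    def __contains__(self, method: str) -> bool:
        return method in self.estimates

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-method table (gene, method, nsnp, beta, se,
        p, OR, CI bounds)."""
        return pd.DataFrame([e.to_dict() for e in self.estimates.values()])

    def summary(self) -> str:
        """Human-readable forest-style summary."""
        df = self.to_frame()
        lines = [
            f"MR estimates for gene {self.model.gene_id or '(unnamed)'} "
            f"({self.model.n_snp} instrument(s); primary: {self.primary_method})",
            df.to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
            ),
        ]
        egger = self.estimates.get("egger")
        if egger is not None:
            lines.append(
                "Egger intercept: {intercept:.4g} (SE {intercept_se:.4g}, "
                "p {intercept_p:.3g})".format(**egger.extra)
            )
        return "\n".join(lines)

    def plot_forest(self, ax=None):
        """Forest plot of the per-method odds ratios with 95% CIs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 0.6 * len(self.estimates) + 1))
        ests = list(self.estimates.values())
        y = np.arange(len(ests))[::-1]
        for yi, e in zip(y, ests):
            ax.plot([e.ci_low, e.ci_high], [yi, yi], color="0.3")
            ax.plot(e.or_, yi, "s", color="C0")
        ax.axvline(1.0, color="0.7", linestyle="--", linewidth=1)
        ax.set_yticks(y)
        ax.set_yticklabels([e.method for e in ests])
        ax.set_xlabel("odds ratio (95% CI)")
        ax.set_title(self.model.gene_id or "MR estimates")
        return ax
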