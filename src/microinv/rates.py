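"""Microinversion rate models.

The observation for locus *i* is a count :math:`c_i` of inversions
accumulated over an exposure :math:`E_i = L_i \\cdot T_i` (sequence
length in Mb times treelength in MY).  Under genome-wide rate
homogeneity the counts are Poisson,

.. math:: c_i \\sim \\mathrm{Poisson}(\\lambda E_i),

with closed-form MLE :math:`\\hat\\lambda = \\sum c_i / \\sum E_i`.
Among-locus rate variation (hotspots) is modelled by a gamma-distributed
rate multiplier with mean 1 and shape *k*, giving the NB2 negative
binomial marginal with mean :math:`\\lambda E_i` and variance
:math:`\\lambda E_i + (\\lambda E_i)^2/k`.  The two are nested
(Poisson is the :math:`k \\to \\infty` boundary), so homogeneity is
tested with a likelihood-ratio statistic referred to
:math:`\\chi^2_1`.

Rates are expressed throughout in inversions Mb\\ :sup:`-1` MY\\ :sup:`-1`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .io import LocusRecord, ValidationError

logger = logging.getLogger(__name__)

_LOGK_MAX = 25.0  # beyond this the NB is numerically Poisson


class FitError(RuntimeError):
    """Maximum-likelihood optimisation failed to converge."""


class DegenerateModelError(ValueError):
    """The NB model is not identifiable (e.g. all counts zero)."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding as used in the report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# exposures and plug-in rates
# ---------------------------------------------------------------------------

@dataclass
class ExposureRecord:
    """Count and exposure (Mb·MY) for one locus."""

    locus_id: str
    exposure: float
    count: int

    def __post_init__(self) -> None:
        if self.exposure <= 0:
            raise ValidationError(f"{self.locus_id}: exposure must be > 0")
        if self.count < 0:
            raise ValidationError(f"{self.locus_id}: count must be >= 0")


def exposure(record: LocusRecord) -> ExposureRecord:
    """E = length(Mb) x treelength(MY); length converted from bp."""
    if record.mean_noncoding_length <= 0 or record.treelength <= 0:
        raise ValidationError(f"{record.locus_id}: non-positive inputs")
    return ExposureRecord(
        locus_id=record.locus_id,
        exposure=record.mean_noncoding_length / 1e6 * record.treelength,
        count=record.inversion_count)


def per_locus_rate(record: LocusRecord) -> float:
    """Plug-in rate c/E for one locus, full precision."""
    e = exposure(record)
    return e.count / e.exposure


def pooled_rate(records: Sequence[ExposureRecord | LocusRecord]) -> float:
    """Pooled rate sum(c)/sum(E); identical to the Poisson MLE."""
    recs = _as_exposures(records)
    tot_e = sum(r.exposure for r in recs)
    if tot_e <= 0:
        raise ValidationError("total exposure must be > 0")
    return sum(r.count for r in recs) / tot_e


def _as_exposures(records: Iterable) -> list[ExposureRecord]:
    out = []
    for r in records:
        out.append(r if isinstance(r, ExposureRecord) else exposure(r))
    if not out:
        raise ValidationError("need at least one record")
    return out


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class InversionRateModel:
    """ML rate model for per-locus inversion counts with exposures.

    Parameters
    ----------
    counts : array-like of int
        Observed inversion counts per locus.
    exposures : array-like of float
        Exposure E_i = length(Mb) x treelength(MY) per locus, > 0.
    locus_ids : sequence of str, optional

    Examples
    --------
    >>> model = InversionRateModel([19, 5], [12.1568, 7.32])
    >>> res = model.fit(dist="poisson")
    >>> round(res.lambda_hat, 3)
    1.232
    """

    def __init__(self, counts, exposures, locus_ids=None):
        self.counts = np.asarray(counts, dtype=float)
        self.exposures = np.asarray(exposures, dtype=float)
        if self.counts.shape != self.exposures.shape or self.counts.ndim != 1:
            raise ValidationError("counts and exposures must be equal-length 1-D")
        if self.counts.size == 0:
            raise ValidationError("need at least one locus")
        if np.any(self.exposures <= 0):
            raise ValidationError("exposures must be > 0")
        if np.any(self.counts < 0) or np.any(self.counts != np.round(self.counts)):
            raise ValidationError("counts must be non-negative integers")
        self.locus_ids = (list(locus_ids) if locus_ids is not None
                          else [f"locus{i}" for i in range(self.counts.size)])

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_records(cls, records: Sequence[LocusRecord | ExposureRecord],
                     exclude: Sequence[str] = ()) -> "InversionRateModel":
        recs = [r for r in _as_exposures(records) if r.locus_id not in set(exclude)]
        if not recs:
            raise ValidationError("no loci left after exclusion")
        return cls([r.count for r in recs], [r.exposure for r in recs],
                   [r.locus_id for r in recs])

    @classmethod
    def from_table(cls, df: pd.DataFrame, exclude: Sequence[str] = ()
                   ) -> "InversionRateModel":
        records = [LocusRecord(str(r["locus"]),
                               float(r["mean_noncoding_length_bp"]),
                               float(r["treelength_my"]),
                               int(r["inversion_count"]))
                   for _, r in df.iterrows()]
        return cls.from_records(records, exclude=exclude)

    # -- likelihoods ------------------------------------------------------
    def loglike_poisson(self, lam: float) -> float:
        mu = lam * self.exposures
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(self.counts > 0,
                             self.counts * np.log(np.where(mu > 0, mu, 1.0)),
                             0.0)
        if np.any((mu == 0) & (self.counts > 0)):
            return -np.inf
        return float(np.sum(terms - mu - gammaln(self.counts + 1)))

    def loglike_negbin(self, lam: float, k: float) -> float:
        """Gamma-mixed Poisson (NB2): mean lam*E, variance mean + mean^2/k."""
        mu = lam * self.exposures
        if lam <= 0 or k <= 0:
            return -np.inf
        return float(np.sum(
            gammaln(self.counts + k) - gammaln(k) - gammaln(self.counts + 1)
            + k * np.log(k / (k + mu))
            + self.counts * np.log(mu / (k + mu))))

    # -- fitting ----------------------------------------------------------
    def fit(self, dist: str = "poisson", tol: float = 1e-8
            ) -> "InversionRateResults":
        """Fit by maximum likelihood.

        Poisson is closed form.  The NB2 likelihood is maximised over
        (log lambda, log k) by Nelder-Mead with multi-start on
        k in {0.1, 1, 10}; the surface can be flat near the Poisson
        boundary (large k).
        """
        if dist == "poisson":
            lam = pooled_rate([ExposureRecord(l, e, int(c)) for l, e, c in
                               zip(self.locus_ids, self.exposures, self.counts)])
            return InversionRateResults(self, "poisson", lam, None,
                                        self.loglike_poisson(lam))
        if dist != "negbin":
            raise ValueError(f"unknown dist {dist!r}")
        if self.counts.size < 2:
            raise ValidationError("negbin fit needs >=2 loci")
        if np.all(self.counts == 0):
            raise DegenerateModelError(
                "all counts zero: dispersion not identifiable, "
                "report the Poisson fit only")
        lam0 = max(self.counts.sum() / self.exposures.sum(), 1e-8)

        def nll(p):
            loglam, logk = p
            if logk > _LOGK_MAX:
                logk = _LOGK_MAX
            return -self.loglike_negbin(np.exp(loglam), np.exp(logk))

        best = None
        for k0 in (0.1, 1.0, 10.0):
            res = optimize.minimize(
                nll, x0=[np.log(lam0), np.log(k0)], method="Nelder-Mead",
                options=dict(xatol=1e-10, fatol=tol, maxiter=20000,
                             maxfev=20000))
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise FitError(f"negbin fit failed: {best}")
        lam = float(np.exp(best.x[0]))
        k = float(np.exp(min(best.x[1], _LOGK_MAX)))
        llf = float(-best.fun)
        # nesting guard: NB at its MLE can never sit below the Poisson MLE
        ll_pois = self.loglike_poisson(
            self.counts.sum() / self.exposures.sum())
        if llf < ll_pois:
            lam = self.counts.sum() / self.exposures.sum()
            k = float(np.exp(_LOGK_MAX))
            llf = self.loglike_negbin(lam, k)
        return InversionRateResults(self, "negbin", lam, k, llf)

    def lrt_overdispersion(self) -> "LrtResult":
        """LRT of Poisson (homogeneous rates) vs NB2 (hotspots), chi2(1)."""
        pois = self.fit("poisson")
        nb = self.fit("negbin")
        stat = max(2.0 * (nb.llf - pois.llf), 0.0)
        return LrtResult(stat=stat, df=1, p=float(stats.chi2.sf(stat, 1)),
                         poisson=pois, negbin=nb)


@dataclass
class LrtResult:
    """Likelihood-ratio test output: 2*dlnL against chi2(1)."""

    stat: float
    df: int
    p: float
    poisson: "InversionRateResults | None" = None
    negbin: "InversionRateResults | None" = None


class InversionRateResults:
    """Fitted rate model: estimates, uncertainty, and a summary table."""

    def __init__(self, model: InversionRateModel, dist: str,
                 lambda_hat: float, dispersion: float | None, llf: float):
        self.model = model
        self.dist = dist
        self.lambda_hat = float(lambda_hat)
        self.dispersion = None if dispersion is None else float(dispersion)
        self.llf = float(llf)

    @property
    def nobs(self) -> int:
        return self.model.counts.size

    @property
    def df_model(self) -> int:
        return 1 if self.dist == "poisson" else 2

    @property
    def bse_lambda(self) -> float:
        """Asymptotic s.e. of lambda (observed information)."""
        if self.dist == "poisson":
            return float(np.sqrt(self.lambda_hat / self.model.exposures.sum()))
        # numerical second derivative in log lambda space
        h = 1e-4
        ll = np.log(self.lambda_hat)
        f = lambda x: self.model.loglike_negbin(np.exp(x), self.dispersion)
        d2 = (f(ll + h) - 2 * f(ll) + f(ll - h)) / h ** 2
        if d2 >= 0:
            return float("nan")
        return float(self.lambda_hat / np.sqrt(-d2))

    def conf_int_lambda(self, level: float = 0.95) -> tuple[float, float]:
        """Exact (Garwood) CI for the pooled rate under the Poisson model."""
        return poisson_exact_ci(int(self.model.counts.sum()),
                                float(self.model.exposures.sum()), level)

    def summary(self) -> str:
        lines = [
            "Microinversion rate model",
            "=" * 46,
            f"model:            {'Poisson' if self.dist == 'poisson' else 'negative binomial (NB2)'}",
            f"loci:             {self.nobs}",
            f"total count:      {int(self.model.counts.sum())}",
            f"total exposure:   {self.model.exposures.sum():.4f} Mb*MY",
            f"lambda_hat:       {self.lambda_hat:.4f} inversions/Mb/MY"
            f"  (s.e. {self.bse_lambda:.4f})",
        ]
        if self.dist == "negbin":
            lines.append(f"dispersion k:     {self.dispersion:.4g}")
        else:
            lo, hi = self.conf_int_lambda()
            lines.append(f"exact 95% CI:     ({lo:.4f}, {hi:.4f})")
        lines.append(f"log-likelihood:   {self.llf:.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<InversionRateResults {self.dist} lambda={self.lambda_hat:.4g} "
                f"llf={self.llf:.4g}>")


# ---------------------------------------------------------------------------
# functional wrappers over the model class
# ---------------------------------------------------------------------------

def fit_poisson(records: Sequence) -> InversionRateResults:
    return InversionRateModel.from_records(records).fit("poisson")


def fit_negbin(records: Sequence) -> InversionRateResults:
    return InversionRateModel.from_records(records).fit("negbin")


def lrt_overdispersion(records: Sequence) -> LrtResult:
    return InversionRateModel.from_records(records).lrt_overdispersion()


def poisson_exact_ci(count: int, exposure_mb_my: float, level: float = 0.95
                     ) -> tuple[float, float]:
    """Garwood exact Poisson CI for a rate, in events per unit exposure.

    lower = chi2.ppf(a/2, 2c)/2/E (0 when c = 0),
    upper = chi2.ppf(1-a/2, 2c+2)/2/E.
    """
    if exposure_mb_my <= 0:
        raise ValidationError("exposure must be > 0")
    if count < 0:
        raise ValidationError("count must be >= 0")
    alpha = 1.0 - level
    lower = 0.0 if count == 0 else float(
        stats.chi2.ppf(alpha / 2, 2 * count) / 2 / exposure_mb_my)
    upper = float(stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2
                  / exposure_mb_my)
    return lower, upper


def rates_report(records: Sequence[LocusRecord],
                 exclude: Sequence[str] = ()) -> pd.DataFrame:
    """Per-locus rate table plus pooled row (2-dp presentation column)."""
    rows = []
    kept = [r for r in records if r.locus_id not in set(exclude)]
    for r in kept:
        e = exposure(r)
        lam = per_locus_rate(r)
        rows.append([r.locus_id, r.mean_noncoding_length, r.treelength,
                     r.inversion_count, e.exposure, lam, round_half_up(lam)])
    pooled = pooled_rate(kept)
    rows.append(["POOLED", sum(r.mean_noncoding_length for r in kept), np.nan,
                 sum(r.inversion_count for r in kept),
                 sum(exposure(r).exposure for r in kept),
                 pooled, round_half_up(pooled)])
    return pd.DataFrame(rows, columns=[
        "locus", "mean_noncoding_length_bp", "treelength_my",
        "inversion_count", "exposure_mb_my", "rate", "rate_2dp"])
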