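"""Per-class mutation-rate estimation and dose-dependence screening.

Rates come from *identity-link* (additive) Poisson regression with a
non-negative intercept: count_i ~ Poisson(b + r * dose_i), b >= 0, r >= 0.
The intercept b is the dose-independent background burden per sample and r
the induced rate per Gray; rates are reported per 80 Gy, the study's highest
dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .io_formats import SampleMeta
from .spectra import MutationSpectrum, class_totals

__all__ = [
    "RateEstimate",
    "DoseScreenResult",
    "fit_rate",
    "screen_dose_response",
    "SCREEN_CLASSES",
]

SCREEN_CLASSES = ("substitutions", "indels", "SVs")


@dataclass(frozen=True)
class RateEstimate:
    genotype: str
    class_label: str
    background: float
    rate_per_gy: float
    se_rate: float
    degenerate: bool = False

    @property
    def per80(self) -> float:
        return 80.0 * self.rate_per_gy

    @property
    def se_per80(self) -> float:
        return 80.0 * self.se_rate

    @property
    def ci95(self) -> tuple[float, float]:
        lo = max(0.0, self.per80 - 1.96 * self.se_per80)
        return (lo, self.per80 + 1.96 * self.se_per80)


def _nll(params: np.ndarray, doses: np.ndarray, counts: np.ndarray) -> float:
    mu = params[0] + params[1] * doses
    if np.any(mu < 0):
        return np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(mu) - mu, -mu)
    if np.any((counts > 0) & (mu <= 0)):
        return np.inf
    return -float(ll.sum())


def _nll_grad(params: np.ndarray, doses: np.ndarray, counts: np.ndarray) -> np.ndarray:
    mu = np.maximum(params[0] + params[1] * doses, 1e-12)
    resid = 1.0 - counts / mu
    return np.array([resid.sum(), (resid * doses).sum()])


def fit_rate(
    counts: Iterable[tuple[float, float]],
    genotype: str = "",
    class_label: str = "",
) -> RateEstimate:
    """Maximum-likelihood (b, r) for count ~ Poisson(b + r*dose), b, r >= 0.

    Standard error of r from the observed Fisher information at the MLE;
    boundary solutions (b=0 or r=0) get one-sided standard errors from the
    profile information of the free parameter.
    """
    pairs = list(counts)
    doses = np.array([d for d, _ in pairs], float)
    y = np.array([c for _, c in pairs], float)
    if len(np.unique(doses)) < 2:
        raise ValueError("fit_rate requires at least 2 distinct dose levels")
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    if not y.any():
        return RateEstimate(genotype, class_label, 0.0, 0.0, 0.0, degenerate=True)

    # multi-start bounded optimization; the likelihood is concave in (b, r)
    # over the feasible region so one interior start usually suffices
    b0 = max(y[doses == doses.min()].mean(), 0.01) if (doses == 0).any() else max(y.mean() / 2, 0.01)
    r0 = max((y.mean() - b0) / max(doses.mean(), 1e-9), 1e-4)
    best = None
    for start in ((b0, r0), (0.01, max(y.max() / max(doses.max(), 1), 1e-4)), (y.mean(), 1e-6)):
        res = optimize.minimize(
            _nll, np.array(start), args=(doses, y), method="L-BFGS-B",
            jac=_nll_grad, bounds=[(0.0, None), (0.0, None)],
        )
        if best is None or res.fun < best.fun:
            best = res
    b, r = float(best.x[0]), float(best.x[1])

    mu = b + r * doses
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(mu > 0, y / np.maximum(mu, 1e-300) ** 2, 0.0)
    info = np.array([[w.sum(), (w * doses).sum()], [(w * doses).sum(), (w * doses**2).sum()]])
    se_r = _se_rate(info, b, r)
    return RateEstimate(genotype, class_label, b, r, se_r, degenerate=False)


def _se_rate(info: np.ndarray, b: float, r: float, boundary_tol: float = 1e-9) -> float:
    at_boundary = b <= boundary_tol or r <= boundary_tol
    if not at_boundary:
        try:
            cov = np.linalg.inv(info)
            if cov[1, 1] > 0:
                return float(np.sqrt(cov[1, 1]))
        except np.linalg.LinAlgError:
            pass
    # one-sided / profile SE: curvature in r alone
    return float(1.0 / np.sqrt(info[1, 1])) if info[1, 1] > 0 else 0.0


@dataclass(frozen=True)
class DoseScreenResult:
    """Pearson dose-dependence screen over the three reporting classes."""

    genotype: str
    pearson_r: dict[str, float]
    p_value: dict[str, float]
    passes: bool
    alpha: float = 0.05


def screen_dose_response(
    spectra: Sequence[MutationSpectrum],
    metas: Sequence[SampleMeta],
    alpha: float = 0.05,
    min_significant_classes: int = 2,
) -> dict[str, DoseScreenResult]:
    """Per genotype: Pearson r and two-sided p between class totals and dose.

    A genotype passes when at least ``min_significant_classes`` reporting
    classes show a significant positive correlation (r > 0, p < alpha).
    Zero-variance classes yield r = NaN and are treated as non-significant.
    """
    by_id = {s.sample_id: s for s in spectra}
    genotypes: dict[str, list[SampleMeta]] = {}
    for m in metas:
        genotypes.setdefault(m.genotype, []).append(m)
    results = {}
    for genotype, ms in genotypes.items():
        ms = [m for m in ms if m.sample_id in by_id]
        doses = np.array([m.dose_gy for m in ms])
        if len(ms) < 3 or len(np.unique(doses)) < 2:
            raise ValueError(
                f"genotype {genotype!r} needs >= 3 samples spanning >= 2 doses"
            )
        totals = {cls: np.array([class_totals(by_id[m.sample_id])[cls] for m in ms], float)
                  for cls in SCREEN_CLASSES}
        rs, ps = {}, {}
        n_sig = 0
        for cls, t in totals.items():
            if np.ptp(t) == 0:
                rs[cls], ps[cls] = float("nan"), float("nan")
                continue
            r, p = stats.pearsonr(t, doses)
            rs[cls], ps[cls] = float(r), float(p)
            if r > 0 and p < alpha:
                n_sig += 1
        results[genotype] = DoseScreenResult(
            genotype=genotype, pearson_r=rs, p_value=ps,
            passes=n_sig >= min_significant_classes, alpha=alpha,
        )
    return results
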