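"""Analytic and Monte-Carlo power for discrete-trait case-control allelic tests.

The model is the multiplicative (per-allele) odds model used by classic
discrete-trait genetic power calculators: a disease with population prevalence
``K``, a risk allele at population frequency ``p`` in Hardy-Weinberg
proportions, and a per-allele odds ratio ``R``.  The baseline odds are solved
so the population prevalence matches ``K``; case and control allele
frequencies then follow by Bayes inversion of the penetrance model, and the
1-df allelic (2N-allele) chi-square test has a noncentral chi-square
distribution whose noncentrality is computed at the design sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PowerSpec",
    "case_control_allele_freqs",
    "cc_allelic_power",
    "min_cases_for_power",
    "mc_power_check",
]


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a discrete-trait allelic power calculation.

    Attributes
    ----------
    prevalence : population frequency of the trait, in (0, 1).
    risk_allele_freq : population risk allele frequency, in (0, 1).
    allelic_or : per-allele (multiplicative) odds ratio, > 0.
    n_cases, n_controls : numbers of case and control individuals.
    alpha : two-sided type-I error rate of the 1-df allelic test.
    """

    prevalence: float
    risk_allele_freq: float
    allelic_or: float
    n_cases: int
    n_controls: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("prevalence", "risk_allele_freq", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.allelic_or <= 0:
            raise ValueError("allelic_or must be positive")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")


def _penetrances(prevalence: float, raf: float, allelic_or: float) -> np.ndarray:
    """Genotype penetrances (g = 0, 1, 2 risk alleles) under the odds model.

    Solves for baseline odds b such that
    sum_g HWE(g) * b*R^g / (1 + b*R^g) = prevalence.
    """
    p = raf
    gfreq = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    r_pow = allelic_or ** np.arange(3)

    def mean_penetrance(log_b: float) -> float:
        odds = np.exp(log_b) * r_pow
        return float(gfreq @ (odds / (1 + odds))) - prevalence

    log_b = optimize.brentq(mean_penetrance, -60.0, 60.0, xtol=1e-14)
    odds = np.exp(log_b) * r_pow
    pen = odds / (1 + odds)
    if np.any(pen <= 0) or np.any(pen >= 1):
        raise ValueError("parameters imply penetrance outside (0, 1)")
    return pen


def case_control_allele_freqs(
    prevalence: float, raf: float, allelic_or: float
) -> tuple[float, float]:
    """Risk-allele frequency in cases and in (unaffected) controls.

    Bayes inversion: P(g | case) ∝ HWE(g)·f_g and
    P(g | control) ∝ HWE(g)·(1 − f_g); the allele frequency is then
    P(g=1)/2 + P(g=2).
    """
    p = raf
    gfreq = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    pen = _penetrances(prevalence, raf, allelic_or)
    case_g = gfreq * pen
    case_g /= case_g.sum()
    ctrl_g = gfreq * (1 - pen)
    ctrl_g /= ctrl_g.sum()
    half = np.array([0.0, 0.5, 1.0])
    return float(case_g @ half), float(ctrl_g @ half)


def cc_allelic_power(spec: PowerSpec) -> float:
    """Analytic power of the 1-df allelic case-control chi-square test.

    The test compares risk-allele counts between 2·n_cases case alleles and
    2·n_controls control alleles.  Power is P(noncentral chi2(1, ncp) exceeds
    the rejection threshold), with the noncentrality evaluated at the model's
    case/control allele frequencies.  The pooled (null) variance enters the
    rejection threshold — that is the variance the chi-square statistic
    actually uses — while the unpooled variance under the alternative scales
    the noncentral distribution; ignoring the distinction biases power
    noticeably at these unbalanced designs.
    """
    p_case, p_ctrl = case_control_allele_freqs(
        spec.prevalence, spec.risk_allele_freq, spec.allelic_or
    )
    n1 = 2 * spec.n_cases
    n2 = 2 * spec.n_controls
    pbar = (n1 * p_case + n2 * p_ctrl) / (n1 + n2)
    var_null = pbar * (1 - pbar) * (1 / n1 + 1 / n2)
    var_alt = p_case * (1 - p_case) / n1 + p_ctrl * (1 - p_ctrl) / n2
    ncp = (p_case - p_ctrl) ** 2 / var_alt
    crit = stats.chi2.ppf(1 - spec.alpha, df=1) * var_null / var_alt
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))


def min_cases_for_power(
    spec: PowerSpec,
    target_power: float,
    n_cases_cap: int = 100_000,
) -> int:
    """Smallest case count reaching ``target_power``, other parameters fixed.

    ``spec.n_cases`` is ignored; found by bracketing doubling plus bisection
    (power is monotone non-decreasing in the case count).
    """
    if not spec.alpha < target_power < 1.0:
        raise ValueError("target_power must lie in (alpha, 1)")

    def power_at(n: int) -> float:
        return cc_allelic_power(
            PowerSpec(
                prevalence=spec.prevalence,
                risk_allele_freq=spec.risk_allele_freq,
                allelic_or=spec.allelic_or,
                n_cases=n,
                n_controls=spec.n_controls,
                alpha=spec.alpha,
            )
        )

    hi = 1
    while power_at(hi) < target_power:
        hi *= 2
        if hi > n_cases_cap:
            raise ValueError(f"target power unreachable with <= {n_cases_cap} cases")
    lo = hi // 2 if hi > 1 else 0  # power_at(lo) < target (or lo == 0)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def mc_power_check(
    spec: PowerSpec, n_reps: int = 20_000, seed: int = 0
) -> tuple[float, float]:
    """Empirical power of the allelic test by Monte Carlo.

    Simulates risk-allele counts in cases and controls from the model's
    case/control allele frequencies and applies the 1-df two-proportion
    chi-square.  Returns (rejection fraction, binomial standard error).
    """
    if n_reps < 1000:
        raise ValueError("n_reps must be >= 1000")
    rng = np.random.default_rng(seed)
    p_case, p_ctrl = case_control_allele_freqs(
        spec.prevalence, spec.risk_allele_freq, spec.allelic_or
    )
    n1 = 2 * spec.n_cases
    n2 = 2 * spec.n_controls
    x1 = rng.binomial(n1, p_case, size=n_reps)
    x2 = rng.binomial(n2, p_ctrl, size=n_reps)
    p1 = x1 / n1
    p2 = x2 / n2
    pbar = (x1 + x2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (p1 - p2) ** 2 / (pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    chi2 = np.nan_to_num(chi2)  # pbar in {0,1} -> no evidence -> 0
    crit = stats.chi2.ppf(1 - spec.alpha, df=1)
    power = float(np.mean(chi2 > crit))
    se = float(np.sqrt(power * (1 - power) / n_reps))
    return power, se
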