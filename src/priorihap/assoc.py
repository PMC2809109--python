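"""Per-SNP logistic association with covariates and set-restricted multiple testing.

Each marker is tested with a maximum-likelihood logistic regression of
case/control status on additive minor-allele dosage plus covariates (a sex
indicator by default), reporting the Wald two-sided p-value, the per-copy
odds ratio, and adjusted p-values whose multiple-testing denominator is the
size of the *submitted* (prioritized) marker set — the point of restricting a
genome-wide scan to a candidate set is precisely that this denominator
shrinks.  On detected separation or non-convergence the marker is refit with
Firth's penalized likelihood (Jeffreys-prior penalty), which always yields
finite estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .genio import GenotypeMatrix

__all__ = [
    "AssocResult",
    "ConvergenceRecord",
    "logistic_snp_assoc",
    "adjust_pvalues",
    "genomic_control_lambda",
    "top_k_by_p",
    "convergence_loci",
    "qq_table",
    "firth_logistic",
]

# median of the 1-df chi-square distribution
_CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class AssocResult:
    marker_id: str
    beta: float
    se: float
    odds_ratio: float
    p_raw: float
    n_used: int
    fit_flag: str = "wald"  # "wald" | "firth" | "degenerate"
    p_adjusted: dict[str, float] = field(default_factory=dict)


@dataclass
class ConvergenceRecord:
    locus_id: str
    strategies_hit: set[str]
    top_marker_per_strategy: dict[str, str]
    min_p: float


def firth_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Firth penalized-likelihood logistic fit; returns (beta, se).

    Maximizes l(b) + 0.5·log|I(b)| by Newton steps with step-halving; the
    score correction uses the hat-matrix diagonal.
    """
    n, p = X.shape
    beta = np.zeros(p)

    def penalized_ll(b: np.ndarray) -> float:
        eta = X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        info = (X * w[:, None]).T @ X
        sign, logdet = np.linalg.slogdet(info)
        ll = float(y @ eta - np.logaddexp(0, eta).sum())
        return ll + 0.5 * logdet

    ll_old = penalized_ll(beta)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        info = (X * w[:, None]).T @ X
        info_inv = np.linalg.pinv(info)
        # hat diagonal of the weighted design
        Xw = X * np.sqrt(w)[:, None]
        h = np.einsum("ij,jk,ik->i", Xw, info_inv, Xw)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        # step-halving on the penalized likelihood
        for _ in range(30):
            cand = beta + step
            ll_new = penalized_ll(cand)
            if np.isfinite(ll_new) and ll_new >= ll_old - 1e-12:
                break
            step *= 0.5
        else:  # pragma: no cover
            break
        beta = cand
        if abs(ll_new - ll_old) < tol:
            ll_old = ll_new
            break
        ll_old = ll_new
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    info = (X * w[:, None]).T @ X
    se = np.sqrt(np.diag(np.linalg.pinv(info)))
    return beta, se


def _degenerate(marker_id: str, n_used: int) -> AssocResult:
    return AssocResult(marker_id, 0.0, np.inf, 1.0, 1.0, n_used, "degenerate")


def logistic_snp_assoc(
    G: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    marker_subset: list[str] | None = None,
    use_sex_covariate: bool = True,
) -> list[AssocResult]:
    """Additive logistic association for each marker in the subset.

    ``covariates`` (indexed like the phenotype table rows or by individual id)
    are added to the model; by default a 0/1 sex indicator (male = 1) is built
    from the phenotype table, and individuals of unknown sex are dropped while
    the sex covariate is active.  Individuals missing at a marker are dropped
    for that marker only.
    """
    ph = phenotypes.set_index("individual_id").loc[G.individual_ids]
    status = ph["status"].to_numpy()
    valid_pheno = status != "missing"
    y_all = (status == "case").astype(float)

    cov_cols: list[np.ndarray] = []
    if use_sex_covariate:
        sex = ph["sex"].to_numpy()
        valid_pheno &= sex != "unknown"
        cov_cols.append((sex == "male").astype(float))
    if covariates is not None:
        cov = covariates.reindex(G.individual_ids) if not isinstance(covariates.index, pd.RangeIndex) else covariates
        for c in cov.columns:
            col = cov[c].to_numpy(dtype=float)
            valid_pheno &= ~np.isnan(col)
            cov_cols.append(col)

    ids = marker_subset if marker_subset is not None else G.marker_ids
    col_of = {m: j for j, m in enumerate(G.marker_ids)}
    results: list[AssocResult] = []
    for mid in ids:
        j = col_of[mid]
        dose = G.dosage[:, j]
        use = valid_pheno & ~np.isnan(dose)
        n_used = int(use.sum())
        y = y_all[use]
        if n_used == 0 or y.min() == y.max():
            results.append(_degenerate(mid, n_used))
            continue
        x = dose[use]
        if x.min() == x.max():
            results.append(_degenerate(mid, n_used))
            continue
        # constant covariate columns are absorbed by the intercept; drop them
        active_covs = [c[use] for c in cov_cols if c[use].min() != c[use].max()]
        X = np.column_stack([np.ones(n_used), x] + active_covs)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"collinear covariates at marker {mid}")
        beta = se = None
        flag = "wald"
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100, warn_convergence=False)
            if fit.mle_retvals.get("converged", False) and np.all(
                np.isfinite(fit.bse)
            ) and abs(fit.params[1]) < 15 and fit.bse[1] < 50:
                beta, se = float(fit.params[1]), float(fit.bse[1])
        except (PerfectSeparationError, np.linalg.LinAlgError):
            pass
        if beta is None:
            b, s = firth_logistic(X, y)
            beta, se = float(b[1]), float(s[1])
            flag = "firth"
        z = beta / se if se > 0 else 0.0
        p = float(2 * stats.norm.sf(abs(z)))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        results.append(
            AssocResult(mid, beta, se, float(np.exp(beta)), p, n_used, flag)
        )
    return results


def adjust_pvalues(
    p_raw: list[float] | np.ndarray, method: str, m: int | None = None
) -> np.ndarray:
    """Adjust p-values; ``m`` overrides the test count (Bonferroni only).

    ``bonferroni``: min(1, m·p) with m the size of the submitted prioritized
    set (defaults to len(p_raw)); ``holm`` and ``bh`` follow the standard
    step-down/step-up procedures.  Input order is preserved.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if method == "bonferroni":
        mm = m if m is not None else p.size
        return np.minimum(1.0, mm * p)
    if method == "holm":
        return multipletests(p, method="holm")[1]
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method: {method}")


def genomic_control_lambda(
    chi2: np.ndarray | None = None, p_raw: np.ndarray | None = None
) -> float:
    """Genomic-control inflation factor: median 1-df chi-square / 0.4549."""
    if chi2 is None:
        if p_raw is None:
            raise ValueError("provide chi2 or p_raw")
        chi2 = stats.chi2.isf(np.asarray(p_raw, dtype=float), df=1)
    chi2 = np.asarray(chi2, dtype=float)
    if chi2.size < 10:
        raise ValueError("need at least 10 tests for genomic control")
    return float(np.median(chi2) / _CHI2_1DF_MEDIAN)


def top_k_by_p(results: list[AssocResult], k: int) -> list[AssocResult]:
    """The k smallest raw p-values; ties broken by (p, marker_id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return sorted(results, key=lambda r: (r.p_raw, r.marker_id))[:k]


def convergence_loci(
    top_lists: dict[str, list[AssocResult]],
    marker_to_locus: dict[str, str],
    min_strategies: int = 2,
) -> list[ConvergenceRecord]:
    """Loci hit by the top lists of at least ``min_strategies`` strategies.

    Markers without a locus assignment form singleton loci named after the
    marker.  Sorted by descending number of strategies, then ascending min p.
    """
    per_locus: dict[str, ConvergenceRecord] = {}
    for strategy, results in top_lists.items():
        best_seen: dict[str, AssocResult] = {}
        for r in results:
            locus = marker_to_locus.get(r.marker_id, r.marker_id)
            if locus not in best_seen or r.p_raw < best_seen[locus].p_raw:
                best_seen[locus] = r
        for locus, r in best_seen.items():
            rec = per_locus.setdefault(
                locus, ConvergenceRecord(locus, set(), {}, np.inf)
            )
            rec.strategies_hit.add(strategy)
            rec.top_marker_per_strategy[strategy] = r.marker_id
            rec.min_p = min(rec.min_p, r.p_raw)
    hits = [r for r in per_locus.values() if len(r.strategies_hit) >= min_strategies]
    return sorted(hits, key=lambda r: (-len(r.strategies_hit), r.min_p))


def qq_table(p_raw: list[float] | np.ndarray) -> pd.DataFrame:
    """Expected vs observed −log10 p for a QQ plot, smallest p first."""
    p = np.sort(np.asarray(p_raw, dtype=float))
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    return pd.DataFrame({"expected_neglog10p": expected, "observed_neglog10p": observed})
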