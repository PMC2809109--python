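"""EM haplotype-frequency estimation and case-control haplotype association.

Unphased genotypes over a short marker window are compatible with many
ordered haplotype pairs; the EM algorithm treats the pair as the latent
variable.  The E-step gives each individual posterior weights over its
compatible ordered pairs proportional to f_h·f_k (enumerating both orders of
a heterozygous assignment, and summing over both alleles at missing sites);
the M-step sets each haplotype frequency to its expected count over 2·n
chromosomes.  The observed-data log-likelihood is non-decreasing every
iteration and is asserted so.

Association then splits the expected haplotype counts by case/control status
(EM is run on the pooled sample) and tests each haplotype against all others
in a fractional 2x2 table with a 1-df Pearson chi-square; odds ratios use the
cross-product with a Haldane-Anscombe 0.5 correction when any cell is below
0.5, and 95% CIs come from the log-OR standard error.  Rare haplotypes
(pooled frequency below a threshold, default 1%) are merged into a single
pooled class.  A window scan runs this over every contiguous marker window of
widths in a requested range that intersects an anchor region, reporting the
window minimizing the best haplotype p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix

__all__ = [
    "EMState",
    "EMResult",
    "HaplotypeWindowResult",
    "WindowScan",
    "em_haplotype_freqs",
    "haplotype_assoc",
    "window_scan",
]

MAX_WINDOW = 12

_PAIR_OPTIONS = {
    0: (np.array([0]), np.array([0])),
    1: (np.array([0, 1]), np.array([1, 0])),
    2: (np.array([1]), np.array([1])),
    -1: (np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1])),
}


@dataclass
class EMState:
    frequencies: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool


@dataclass
class EMResult:
    """EM output for one window.

    ``haplotype_codes[k]`` is the integer bit-code of haplotype k (bit = 1
    for the minor allele, marker order from MSB to LSB);
    ``expected_counts`` is an (n_used x H) matrix of per-individual expected
    haplotype counts (rows sum to 2), the posterior summary downstream
    association needs.
    """

    state: EMState
    window_marker_ids: list[str]
    haplotype_codes: np.ndarray
    haplotype_strings: list[str]
    used_individual_ids: list[str]
    expected_counts: np.ndarray


@dataclass
class HaplotypeWindowResult:
    window_marker_ids: list[str]
    n_case_used: int
    n_control_used: int
    table: pd.DataFrame  # one row per tested haplotype class

    @property
    def min_p(self) -> float:
        return float(self.table["p"].min()) if len(self.table) else 1.0

    @property
    def best(self) -> pd.Series:
        return self.table.loc[self.table["p"].idxmin()]


@dataclass
class WindowScan:
    results: list[HaplotypeWindowResult]
    best_index: int | None = None

    @property
    def best(self) -> HaplotypeWindowResult | None:
        return self.results[self.best_index] if self.best_index is not None else None


def _enumerate_pairs(pattern: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """All ordered haplotype-pair codes compatible with a dosage pattern.

    Pattern entries: 0/1/2 minor-allele dosage, -1 missing.
    """
    h1 = np.zeros(1, dtype=np.int64)
    h2 = np.zeros(1, dtype=np.int64)
    for d in pattern:
        b1, b2 = _PAIR_OPTIONS[d]
        h1 = (h1[:, None] * 2 + b1[None, :]).ravel()
        h2 = (h2[:, None] * 2 + b2[None, :]).ravel()
    return h1, h2


def _code_to_string(code: int, width: int, minor: list[str], major: list[str]) -> str:
    bits = [(code >> (width - 1 - s)) & 1 for s in range(width)]
    return "".join(minor[s] if b else major[s] for s, b in enumerate(bits))


def _run_em(
    f0: np.ndarray,
    pair_h1: np.ndarray,
    pair_h2: np.ndarray,
    pattern_of_pair: np.ndarray,
    pattern_counts: np.ndarray,
    n_used: int,
    tol: float,
    max_iter: int,
) -> EMState:
    H = len(f0)
    n_patterns = len(pattern_counts)
    f = f0.copy()
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P = f[pair_h1] * f[pair_h2]
        s = np.bincount(pattern_of_pair, weights=P, minlength=n_patterns)
        if np.any(s <= 0):
            # a pattern got zero mass (possible only from a degenerate start)
            bad = s <= 0
            P = P + np.where(bad[pattern_of_pair], 1e-300, 0.0)
            s = np.bincount(pattern_of_pair, weights=P, minlength=n_patterns)
        ll = float(pattern_counts @ np.log(s))
        if ll < ll_old - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        w = P / s[pattern_of_pair] * pattern_counts[pattern_of_pair]
        counts = np.bincount(pair_h1, weights=w, minlength=H) + np.bincount(
            pair_h2, weights=w, minlength=H
        )
        f = counts / (2.0 * n_used)
        if ll - ll_old < tol and np.isfinite(ll_old):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return EMState(f, ll_old, it, converged)


def em_haplotype_freqs(
    G: GenotypeMatrix,
    window_marker_ids: list[str],
    markers: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 1000,
    max_missing_frac: float = 0.5,
) -> EMResult:
    """Maximum-likelihood haplotype frequencies for a marker window.

    Individuals missing at more than ``max_missing_frac`` of the window's
    markers are excluded.  Two EM starts are run — product of marginal allele
    frequencies, and uniform over the compatible haplotype universe — and the
    better final likelihood is kept (the product start on a tie).
    """
    w = len(window_marker_ids)
    if not 1 <= w <= MAX_WINDOW:
        raise ValueError(f"window width must be 1..{MAX_WINDOW}")
    col_of = {m: j for j, m in enumerate(G.marker_ids)}
    cols = [col_of[m] for m in window_marker_ids]
    dose = G.dosage[:, cols]

    mtab = markers.set_index("marker_id").loc[window_marker_ids]
    minor = mtab["minor_allele"].tolist()
    a1 = mtab["allele1"].tolist()
    a2 = mtab["allele2"].tolist()
    major = [x2 if mi == x1 else x1 for x1, x2, mi in zip(a1, a2, minor)]

    miss = np.isnan(dose)
    used = miss.sum(axis=1) <= max_missing_frac * w
    if not used.any():
        raise ValueError("no usable individuals in window")
    dose_u = dose[used]
    n_used = int(used.sum())
    used_ids = [i for i, u in zip(G.individual_ids, used) if u]

    enc = np.where(np.isnan(dose_u), -1, dose_u).astype(np.int64)
    patterns, inverse, counts = np.unique(
        enc, axis=0, return_inverse=True, return_counts=True
    )

    # enumerate compatible ordered pairs per unique pattern
    h1_list, h2_list, pat_idx = [], [], []
    for pi, pat in enumerate(patterns):
        h1, h2 = _enumerate_pairs(tuple(pat))
        h1_list.append(h1)
        h2_list.append(h2)
        pat_idx.append(np.full(len(h1), pi))
    pair_h1 = np.concatenate(h1_list)
    pair_h2 = np.concatenate(h2_list)
    pattern_of_pair = np.concatenate(pat_idx)

    universe = np.unique(np.concatenate([pair_h1, pair_h2]))
    code_idx = {c: k for k, c in enumerate(universe)}
    ph1 = np.array([code_idx[c] for c in pair_h1])
    ph2 = np.array([code_idx[c] for c in pair_h2])
    H = len(universe)

    # start 1: product of marginal minor-allele frequencies
    with np.errstate(invalid="ignore"):
        p_site = np.nanmean(dose_u, axis=0) / 2.0
    p_site = np.nan_to_num(p_site, nan=0.5)
    bits = ((universe[:, None] >> np.arange(w - 1, -1, -1)[None, :]) & 1).astype(float)
    f_prod = np.prod(np.where(bits == 1, p_site[None, :], 1 - p_site[None, :]), axis=1)
    f_prod = f_prod / f_prod.sum() if f_prod.sum() > 0 else np.full(H, 1.0 / H)
    # start 2: uniform over the compatible universe
    f_unif = np.full(H, 1.0 / H)

    states = [
        _run_em(f0, ph1, ph2, pattern_of_pair, counts.astype(float), n_used, tol, max_iter)
        for f0 in (f_prod, f_unif)
    ]
    state = states[0] if states[0].log_likelihood >= states[1].log_likelihood else states[1]

    # posterior expected haplotype counts per pattern, expanded to individuals
    f = state.frequencies
    P = f[ph1] * f[ph2]
    s = np.bincount(pattern_of_pair, weights=P, minlength=len(counts))
    s = np.where(s > 0, s, 1.0)
    wnorm = P / s[pattern_of_pair]
    pat_counts = np.zeros((len(counts), H))
    np.add.at(pat_counts, (pattern_of_pair, ph1), wnorm)
    np.add.at(pat_counts, (pattern_of_pair, ph2), wnorm)
    expected = pat_counts[inverse]

    strings = [_code_to_string(int(c), w, minor, major) for c in universe]
    return EMResult(
        state=state,
        window_marker_ids=list(window_marker_ids),
        haplotype_codes=universe,
        haplotype_strings=strings,
        used_individual_ids=used_ids,
        expected_counts=expected,
    )


def _two_by_two(a: float, b: float, c: float, d: float) -> tuple[float, float, float, float, float]:
    """(chi2, p, OR, ci_low, ci_high) for a fractional 2x2 table."""
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) <= 0:
        return 0.0, 1.0, 1.0, 0.0, np.inf
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    if min(a, b, c, d) < 0.5:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log((a * d) / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(chi2), p, float(np.exp(log_or)), float(np.exp(log_or - 1.959964 * se)), float(
        np.exp(log_or + 1.959964 * se)
    )


def haplotype_assoc(
    em: EMResult,
    phenotypes: pd.DataFrame,
    pool_threshold: float = 0.01,
) -> HaplotypeWindowResult:
    """Case-control association of each haplotype class in a window.

    Haplotypes with pooled (overall) frequency below ``pool_threshold`` are
    merged into one pooled class (flagged).  Classes absent from both groups
    are not tested.  Alongside the cross-product odds ratio the per-group
    haplotype odds f/(1-f) are reported (``case_odds``/``control_odds``).
    """
    ph = phenotypes.set_index("individual_id").loc[em.used_individual_ids]
    is_case = (ph["status"] == "case").to_numpy()
    is_ctrl = (ph["status"] == "control").to_numpy()
    case_counts = em.expected_counts[is_case].sum(axis=0)
    ctrl_counts = em.expected_counts[is_ctrl].sum(axis=0)
    n_case = int(is_case.sum())
    n_ctrl = int(is_ctrl.sum())
    total = case_counts + ctrl_counts
    freq_all = total / total.sum() if total.sum() > 0 else total

    rare = freq_all < pool_threshold
    classes: list[tuple[str, float, float, bool]] = []
    for k, hap in enumerate(em.haplotype_strings):
        if not rare[k]:
            classes.append((hap, float(case_counts[k]), float(ctrl_counts[k]), False))
    if rare.any():
        classes.append(
            ("pooled_rare", float(case_counts[rare].sum()), float(ctrl_counts[rare].sum()), True)
        )

    rows = []
    tot_case = 2.0 * n_case
    tot_ctrl = 2.0 * n_ctrl
    denom = tot_case + tot_ctrl
    for hap, a, c, pooled in classes:
        if a + c <= 1e-6:
            continue  # absent in both groups (or numerically extinct in EM)
        b = tot_case - a
        d = tot_ctrl - c
        chi2, p, orat, lo, hi = _two_by_two(a, b, c, d)
        fa = a / tot_case if tot_case else 0.0
        fu = c / tot_ctrl if tot_ctrl else 0.0
        rows.append(
            {
                "haplotype": hap,
                "freq_case": fa,
                "freq_control": fu,
                "freq_all": (a + c) / denom if denom else 0.0,
                "case_count": a,
                "control_count": c,
                "chi2": chi2,
                "p": p,
                "odds_ratio": orat,
                "ci_low": lo,
                "ci_high": hi,
                "case_odds": fa / (1 - fa) if fa < 1 else np.inf,
                "control_odds": fu / (1 - fu) if fu < 1 else np.inf,
                "pooled_flag": pooled,
            }
        )
    table = pd.DataFrame(rows)
    return HaplotypeWindowResult(
        window_marker_ids=list(em.window_marker_ids),
        n_case_used=n_case,
        n_control_used=n_ctrl,
        table=table,
    )


def window_scan(
    G: GenotypeMatrix,
    markers: pd.DataFrame,
    phenotypes: pd.DataFrame,
    anchor_marker_ids: list[str],
    min_width: int = 2,
    max_width: int = 9,
    pool_threshold: float = 0.01,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> WindowScan:
    """EM + association over all contiguous windows intersecting the anchor.

    Windows are contiguous in marker order (the order of ``G.marker_ids``)
    with widths in [min_width, max_width]; each must share at least one
    marker with the anchor set.  The scan's best window minimizes the
    per-window minimum haplotype p-value.
    """
    if min_width > max_width:
        return WindowScan(results=[])
    idx_of = {m: j for j, m in enumerate(G.marker_ids)}
    anchor_idx = sorted(idx_of[m] for m in anchor_marker_ids)
    if len(anchor_idx) < min_width:
        raise ValueError("anchor interval contains fewer markers than min_width")
    anchor_set = set(anchor_idx)
    M = G.n_markers

    results: list[HaplotypeWindowResult] = []
    for width in range(min_width, min(max_width, M) + 1):
        for start in range(0, M - width + 1):
            win = range(start, start + width)
            if anchor_set.isdisjoint(win):
                continue
            ids = [G.marker_ids[j] for j in win]
            em = em_haplotype_freqs(G, ids, markers, tol=tol, max_iter=max_iter)
            results.append(haplotype_assoc(em, phenotypes, pool_threshold))
    best = None
    if results:
        best = int(np.argmin([r.min_p for r in results]))
    return WindowScan(results=results, best_index=best)
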