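"""EM-independent oracles used by the haplotype and acceptance tests.

The grid-search oracle maximizes the observed-data haplotype log-likelihood
directly over a simplex lattice (multi-resolution refinement), sharing no
code with the EM implementation: pair enumeration and the likelihood are
re-derived here from first principles.
"""

from itertools import product

import numpy as np

# per-site (h1_bit, h2_bit) options for a dosage value; -1 = missing
_SITE_OPTIONS = {
    0: [(0, 0)],
    1: [(0, 1), (1, 0)],
    2: [(1, 1)],
    -1: [(0, 0), (0, 1), (1, 0), (1, 1)],
}


def enumerate_pairs_oracle(pattern):
    """All ordered haplotype-code pairs compatible with a dosage pattern."""
    pairs = [(0, 0)]
    for d in pattern:
        pairs = [
            (a * 2 + x, b * 2 + y)
            for (a, b) in pairs
            for (x, y) in _SITE_OPTIONS[int(d)]
        ]
    return pairs


def haplotype_loglik(freq_of_code, pattern_pairs, counts):
    """Observed-data log-likelihood at the given frequency assignment.

    ``freq_of_code`` maps haplotype code -> frequency; codes not present get
    frequency 0.
    """
    ll = 0.0
    for pairs, c in zip(pattern_pairs, counts):
        s = sum(freq_of_code.get(a, 0.0) * freq_of_code.get(b, 0.0) for a, b in pairs)
        ll += c * np.log(max(s, 1e-300))
    return ll


def grid_search_freqs(
    universe, pattern_pairs, counts, points_per_dim=None, rounds=None, zoom=3.0
):
    """Dense multi-resolution lattice search for the ML haplotype frequencies.

    The first H-1 frequencies are free lattice coordinates inside a box that
    shrinks by ``zoom`` each round around the incumbent; the last frequency is
    1 minus their sum (points leaving the simplex are skipped).  The
    likelihood is evaluated over the whole lattice in one vectorized pass per
    round.  Final per-coordinate resolution is
    (1 / (points_per_dim-1)) * zoom**-(rounds-1).
    """
    universe = [int(c) for c in universe]
    H = len(universe)
    if H == 1:
        return np.array([1.0])
    if points_per_dim is None:
        points_per_dim = 13 if H <= 5 else 5
    if rounds is None:
        rounds = 7 if H <= 5 else 12

    code_idx = {c: k for k, c in enumerate(universe)}
    ph1 = np.array([code_idx[a] for pairs in pattern_pairs for a, _ in pairs])
    ph2 = np.array([code_idx[b] for pairs in pattern_pairs for _, b in pairs])
    pair_slices = []
    start = 0
    for pairs in pattern_pairs:
        pair_slices.append((start, start + len(pairs)))
        start += len(pairs)
    counts = np.asarray(counts, dtype=float)

    def batch_ll(F):
        P = F[:, ph1] * F[:, ph2]
        ll = np.zeros(F.shape[0])
        for (s0, s1), c in zip(pair_slices, counts):
            ll += c * np.log(np.maximum(P[:, s0:s1].sum(axis=1), 1e-300))
        return ll

    lo = np.zeros(H - 1)
    hi = np.ones(H - 1)
    best = np.full(H, 1.0 / H)
    for _ in range(rounds):
        axes = [np.linspace(lo[k], hi[k], points_per_dim) for k in range(H - 1)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, H - 1)
        ssum = grid.sum(axis=1)
        grid = grid[ssum <= 1.0 + 1e-12]
        F = np.column_stack([grid, 1.0 - grid.sum(axis=1)])
        # keep the incumbent in every round's candidate set
        F = np.vstack([F, best])
        ll = batch_ll(F)
        best = F[int(np.argmax(ll))]
        span = (hi - lo) / zoom
        center = best[: H - 1]
        lo = np.clip(center - span / 2, 0.0, 1.0)
        hi = np.clip(center + span / 2, 0.0, 1.0)
    return best


def oracle_freqs_for_window(dosage_window):
    """Run the grid oracle on a dosage matrix (NaN = missing).

    Returns (universe_codes, frequencies) with the universe defined exactly as
    the set of codes appearing in any compatible pair, matching the EM's
    convention so the two frequency vectors are comparable.
    """
    enc = np.where(np.isnan(dosage_window), -1, dosage_window).astype(int)
    patterns, counts = np.unique(enc, axis=0, return_counts=True)
    pattern_pairs = [enumerate_pairs_oracle(tuple(p)) for p in patterns]
    universe = sorted({c for pairs in pattern_pairs for ab in pairs for c in ab})
    freqs = grid_search_freqs(universe, pattern_pairs, counts.astype(float))
    return np.array(universe), freqs
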