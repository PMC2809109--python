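"""SNP-set prioritization: rank-product differential expression, gene-region
flanking and merging, marker-to-region intersection, and multi-source
set-overlap accounting.

The workflow this supports: external sources (literature/network tools,
functional SNP catalogues, expression analyses) each yield a gene list or a
region list; regions are flanked by a buffer (default 5 kb) to capture
nearby regulatory elements, merged, and intersected with the genotyping
array's markers to give one named :class:`PrioritySet` per source.  Sets
from multiple sources are then compared with pairwise and triple overlap
counts, and drive set-restricted multiple testing downstream.

All interval arithmetic here is 0-based half-open; marker positions (1-based,
MAP convention) are converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ExpressionMatrix

__all__ = [
    "PrioritySet",
    "RPResult",
    "rank_product_de",
    "flank_and_merge",
    "map_markers_to_set",
    "overlap_table",
    "triple_overlap",
]


@dataclass
class PrioritySet:
    """A named set of marker ids with a provenance label."""

    label: str
    marker_ids: set[str]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.marker_ids)


@dataclass
class RPResult:
    gene_id: str
    rank_product: float
    p_perm: float
    pfp: float
    direction: str  # "up" | "down"


def _pairings(
    n_case: int,
    n_ctrl: int,
    max_pairings: int,
    rng: np.random.Generator,
    scheme: str = "disjoint",
) -> list[tuple[int, int]]:
    """Case-by-control sample pairings defining the K comparisons.

    ``disjoint`` (default): min(n_case, n_ctrl) random pairs with every
    sample used at most once, so the comparisons are mutually independent
    under the null — the condition the iid-rank permutation null requires
    for calibrated p-values.  ``all``: every case x control pairing (a
    seeded subset of ``max_pairings`` when there are more); comparisons then
    share samples and the permutation p-values are anticonservative.
    """
    if scheme == "disjoint":
        k = min(n_case, n_ctrl, max_pairings)
        ci = rng.permutation(n_case)[:k]
        ui = rng.permutation(n_ctrl)[:k]
        return list(zip(ci.tolist(), ui.tolist()))
    if scheme == "all":
        all_pairs = [(i, j) for i in range(n_case) for j in range(n_ctrl)]
        if len(all_pairs) <= max_pairings:
            return all_pairs
        idx = rng.choice(len(all_pairs), size=max_pairings, replace=False)
        return [all_pairs[i] for i in sorted(idx)]
    raise ValueError(f"unknown pairing scheme: {scheme}")


def rank_product_de(
    expr: ExpressionMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
    max_pairings: int = 64,
    pairing: str = "disjoint",
) -> list[RPResult]:
    """Rank-product differential expression with a permutation p-value.

    For each of the K case-by-control sample pairings the genes are ranked by
    between-group fold change (log scale difference); rank 1 is the most
    changed in the given direction.  The rank product is the geometric mean of
    a gene's K ranks.  The permutation null draws, ``n_perm`` times, K
    independent uniform ranks — every rank configuration of a single gene is
    equally likely under the null — and
    ``p_perm = (1 + #{null RP <= observed}) / (n_perm + 1)``.
    The proportion of false positives (pfp) is ``p_perm * n_genes / rank`` of
    the gene when sorted by RP (mean rank on ties).

    Results are returned for both directions for every gene.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    levels = sorted(expr.groups.unique())
    g1 = expr.values.loc[:, (expr.groups == levels[0]).to_numpy()].to_numpy()
    g2 = expr.values.loc[:, (expr.groups == levels[1]).to_numpy()].to_numpy()
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    n_genes = g1.shape[0]
    rng = np.random.default_rng(seed)
    pairs = _pairings(g2.shape[1], g1.shape[1], max_pairings, rng, scheme=pairing)
    K = len(pairs)

    # fold change of group2 relative to group1 per pairing (genes x K)
    fc = np.stack([g2[:, i] - g1[:, j] for i, j in pairs], axis=1)

    out: list[RPResult] = []
    null_log_rp = (
        np.log(rng.integers(1, n_genes + 1, size=(n_perm, K))).mean(axis=1)
    )
    null_sorted = np.sort(null_log_rp)
    gene_ids = list(expr.values.index)
    for direction, signed in (("up", -fc), ("down", fc)):
        # rank 1 = most changed in this direction (smallest signed value)
        ranks = np.argsort(np.argsort(signed, axis=0), axis=0) + 1.0
        log_rp = np.log(ranks).mean(axis=1)
        n_le = np.searchsorted(null_sorted, log_rp + 1e-12, side="right")
        p_perm = (1.0 + n_le) / (n_perm + 1.0)
        order_rank = pd.Series(log_rp).rank(method="average").to_numpy()
        pfp = p_perm * n_genes / order_rank
        rp = np.exp(log_rp)
        for g in range(n_genes):
            out.append(
                RPResult(gene_ids[g], float(rp[g]), float(min(p_perm[g], 1.0)),
                         float(pfp[g]), direction)
            )
    return out


def flank_and_merge(
    regions: pd.DataFrame, flank_bp: int = 5_000
) -> pd.DataFrame:
    """Expand each region by ``flank_bp`` on both sides, clip at 0, and merge.

    ``regions`` needs chromosome/start_bp/end_bp columns (0-based half-open).
    Overlapping or book-ended intervals on the same chromosome are merged;
    output is sorted by (chromosome, start).
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    if regions.empty:
        return pd.DataFrame(columns=["chromosome", "start_bp", "end_bp"])
    df = regions.copy()
    df["start_bp"] = (df["start_bp"] - flank_bp).clip(lower=0)
    df["end_bp"] = df["end_bp"] + flank_bp
    df = df.sort_values(["chromosome", "start_bp", "end_bp"])
    merged: list[list] = []
    for chrom, start, end in df[["chromosome", "start_bp", "end_bp"]].itertuples(index=False):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    return pd.DataFrame(merged, columns=["chromosome", "start_bp", "end_bp"])


def map_markers_to_set(
    intervals: pd.DataFrame, markers: pd.DataFrame, label: str, provenance: str = ""
) -> PrioritySet:
    """Markers whose (0-based) position falls inside a half-open interval.

    Marker positions are 1-based (MAP convention); position - 1 is tested for
    interval membership.  A marker at an interval's end coordinate is outside.
    """
    ids: set[str] = set()
    if len(intervals):
        by_chrom = {c: g for c, g in intervals.groupby("chromosome")}
        for mid, chrom, pos in markers[["marker_id", "chromosome", "position_bp"]].itertuples(index=False):
            g = by_chrom.get(chrom)
            if g is None:
                continue
            p0 = pos - 1
            starts = g["start_bp"].to_numpy()
            ends = g["end_bp"].to_numpy()
            if ((starts <= p0) & (p0 < ends)).any():
                ids.add(mid)
    return PrioritySet(label=label, marker_ids=ids, provenance=provenance)


def overlap_table(sets: list[PrioritySet]) -> pd.DataFrame:
    """Symmetric pairwise-intersection count matrix; diagonal is set size."""
    if not sets:
        raise ValueError("need at least one set")
    labels = [s.label for s in sets]
    mat = np.zeros((len(sets), len(sets)), dtype=int)
    for i, a in enumerate(sets):
        for j, b in enumerate(sets):
            mat[i, j] = len(a.marker_ids & b.marker_ids)
    return pd.DataFrame(mat, index=labels, columns=labels)


def triple_overlap(a: PrioritySet, b: PrioritySet, c: PrioritySet) -> int:
    """Size of the three-way intersection of the sets."""
    return len(a.marker_ids & b.marker_ids & c.marker_ids)
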