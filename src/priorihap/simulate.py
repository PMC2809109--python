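"""Synthetic case-control cohorts with LD-block structure and a planted risk haplotype.

The generative model: the genome is a set of statistically independent LD
blocks; each block carries a small pool of founder haplotypes with fixed
population frequencies, and every individual draws two founder haplotypes per
block independently (Hardy-Weinberg within block, full LD within block, no
inter-block LD).  Disease risk follows a logistic model on the number of
copies of one designated founder haplotype in one designated block, plus a
sex effect; the intercept is calibrated by root-finding so the population
prevalence matches the target.  Cases and controls are then ascertained by
rejection sampling, with controls drawn either as population controls (the
default: a random population sample, so roughly a prevalence-sized fraction
may carry the trait) or screened to be unaffected.

Defaults mirror a rare congenital-trait study design: 68 cases, 830 controls,
1% prevalence, a planted per-copy odds ratio of 4, ~80% male, and 2% missing
genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .genio import GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "BlockPool",
    "ExpressionMatrix",
    "build_block_pool",
    "calibrate_intercept",
    "simulate_cohort",
    "inject_missingness",
    "simulate_expression",
]

_LETTERS = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator."""

    n_cases: int = 68
    n_controls: int = 830
    prevalence: float = 0.01
    n_blocks: int = 3
    markers_per_block: int = 9
    founder_haplotypes_per_block: int = 4
    founder_freqs: list[list[float]] | None = None  # per block; None -> Dirichlet(1)
    founder_haplotypes: list[list[str]] | None = None  # explicit strings; None -> random
    risk_block_index: int = 0
    risk_haplotype_index: int = 0
    risk_or: float = 4.0
    sex_effect_or: float = 1.0
    male_freq: float = 0.8
    missing_rate: float = 0.02
    screened_controls: bool = False
    max_rejection_draws: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.risk_or <= 0 or self.sex_effect_or <= 0:
            raise ValueError("odds ratios must be positive")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.founder_freqs is not None:
            for b, fr in enumerate(self.founder_freqs):
                if abs(sum(fr) - 1.0) > 1e-12:
                    raise ValueError(f"founder_freqs for block {b} do not sum to 1")
                if len(fr) != self.founder_haplotypes_per_block:
                    raise ValueError(f"founder_freqs length mismatch in block {b}")
        if not 0 <= self.risk_block_index < self.n_blocks:
            raise ValueError("risk_block_index out of range")
        if not 0 <= self.risk_haplotype_index < self.founder_haplotypes_per_block:
            raise ValueError("risk_haplotype_index out of range")


@dataclass
class SimTruth:
    """Ground truth recorded for parameter-recovery tests."""

    risk_haplotype_string: str
    risk_block_marker_ids: list[str]
    realized_or: float
    calibrated_intercept: float
    realized_prevalence: float
    seed: int


@dataclass
class BlockPool:
    """Founder haplotypes for all blocks.

    ``haplotypes[b]`` is the list of allele-letter strings of block ``b``;
    ``freqs[b]`` their population frequencies; ``site_alleles[b]`` the two
    allele letters segregating at each site of the block.
    """

    haplotypes: list[list[str]]
    freqs: list[np.ndarray]
    site_alleles: list[list[tuple[str, str]]]


@dataclass
class ExpressionMatrix:
    """Log-intensity expression values with a two-level group factor."""

    values: pd.DataFrame  # genes x samples
    groups: pd.Series  # per sample, two levels
    de_genes: list[str] = field(default_factory=list)  # truth labels

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression values must not contain missing entries")
        if (self.groups.value_counts() < 2).any() or self.groups.nunique() != 2:
            raise ValueError("need two groups with >= 2 samples each")


def _random_block_haplotypes(
    n_hap: int, n_sites: int, rng: np.random.Generator, max_tries: int = 1000
) -> tuple[list[str], list[tuple[str, str]]]:
    """Distinct founder haplotypes over biallelic sites, every site polymorphic."""
    for _ in range(max_tries):
        site_alleles = []
        for _ in range(n_sites):
            pair = rng.choice(4, size=2, replace=False)
            site_alleles.append((str(_LETTERS[pair[0]]), str(_LETTERS[pair[1]])))
        picks = rng.integers(0, 2, size=(n_hap, n_sites))
        if n_hap > 1 and not (picks.min(axis=0) != picks.max(axis=0)).all():
            continue  # a monomorphic site
        haps = ["".join(site_alleles[s][picks[h, s]] for s in range(n_sites)) for h in range(n_hap)]
        if len(set(haps)) == n_hap:
            return haps, site_alleles
    raise RuntimeError("could not draw distinct polymorphic founder haplotypes")


def _site_alleles_from_strings(haps: list[str]) -> list[tuple[str, str]]:
    n_sites = len(haps[0])
    out = []
    for s in range(n_sites):
        letters = sorted({h[s] for h in haps})
        if len(letters) > 2:
            raise ValueError(f"site {s} has more than two alleles")
        if len(letters) == 1:
            letters = [letters[0], letters[0]]
        out.append((letters[0], letters[1]))
    return out


def build_block_pool(config: SimConfig) -> BlockPool:
    """Draw (or validate) the founder haplotype pool for every block."""
    rng = np.random.default_rng(config.seed)
    haplotypes: list[list[str]] = []
    freqs: list[np.ndarray] = []
    site_alleles: list[list[tuple[str, str]]] = []
    for b in range(config.n_blocks):
        if config.founder_haplotypes is not None:
            haps = list(config.founder_haplotypes[b])
            if len(haps) != config.founder_haplotypes_per_block:
                raise ValueError(f"block {b}: wrong number of founder haplotypes")
            if len(set(haps)) != len(haps):
                raise ValueError(f"block {b}: duplicate founder haplotype strings")
            if any(len(h) != config.markers_per_block for h in haps):
                raise ValueError(f"block {b}: haplotype length != markers_per_block")
            sa = _site_alleles_from_strings(haps)
        else:
            haps, sa = _random_block_haplotypes(
                config.founder_haplotypes_per_block, config.markers_per_block, rng
            )
        if config.founder_freqs is not None:
            fr = np.asarray(config.founder_freqs[b], dtype=float)
        else:
            fr = rng.dirichlet(np.ones(config.founder_haplotypes_per_block))
        if abs(fr.sum() - 1.0) > 1e-12:
            raise ValueError(f"block {b}: frequencies do not sum to 1")
        haplotypes.append(haps)
        freqs.append(fr)
        site_alleles.append(sa)
    return BlockPool(haplotypes, freqs, site_alleles)


def calibrate_intercept(
    pool: BlockPool,
    risk_block_index: int,
    risk_haplotype_index: int,
    risk_or: float,
    sex_effect_or: float,
    prevalence: float,
    male_freq: float = 0.8,
) -> float:
    """Log-odds intercept making the population prevalence match the target.

    Solves E[expit(b0 + log(OR)·copies + log(OR_sex)·male)] = prevalence over
    the exact Hardy-Weinberg copy distribution of the risk haplotype and the
    Bernoulli sex distribution; monotone in b0, solved by Brent's method.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    f = float(pool.freqs[risk_block_index][risk_haplotype_index])
    copy_probs = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
    sex_probs = np.array([1 - male_freq, male_freq])
    lo, ls = np.log(risk_or), np.log(sex_effect_or)

    def mean_risk(b0: float) -> float:
        total = 0.0
        for c in range(3):
            for s in range(2):
                total += copy_probs[c] * sex_probs[s] * special.expit(b0 + lo * c + ls * s)
        return total - prevalence

    try:
        return float(optimize.brentq(mean_risk, -700.0, 700.0, xtol=1e-12))
    except ValueError as exc:  # pragma: no cover - pathological parameters
        raise ValueError("no intercept root in bracket for these parameters") from exc


def _population_prevalence(
    pool: BlockPool, cfg: SimConfig, intercept: float
) -> float:
    f = float(pool.freqs[cfg.risk_block_index][cfg.risk_haplotype_index])
    copy_probs = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
    sex_probs = np.array([1 - cfg.male_freq, cfg.male_freq])
    lo, ls = np.log(cfg.risk_or), np.log(cfg.sex_effect_or)
    c = np.arange(3)[:, None]
    s = np.arange(2)[None, :]
    p = special.expit(intercept + lo * c + ls * s)
    return float((copy_probs[:, None] * sex_probs[None, :] * p).sum())


def _disease_prob(
    intercept: float, copies: np.ndarray, male: np.ndarray, risk_or: float, sex_or: float
) -> np.ndarray:
    return special.expit(intercept + np.log(risk_or) * copies + np.log(sex_or) * male)


def _sample_group(
    rng: np.random.Generator,
    pool: BlockPool,
    cfg: SimConfig,
    intercept: float,
    n_wanted: int,
    want_affected: bool | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rejection-sample individuals; returns (risk diplotype idx pairs, male, affected).

    ``want_affected`` None accepts everyone (population controls).
    """
    rb = cfg.risk_block_index
    rh = cfg.risk_haplotype_index
    freqs = pool.freqs[rb]
    pairs = np.empty((0, 2), dtype=np.int64)
    male = np.empty(0, dtype=np.int64)
    affected = np.empty(0, dtype=bool)
    max_draws = cfg.max_rejection_draws
    drawn = 0
    while len(pairs) < n_wanted:
        batch = max(1024, n_wanted)
        drawn += batch
        if drawn > max_draws:
            raise RuntimeError(
                f"rejection sampling exceeded {max_draws} draws; prevalence "
                f"{cfg.prevalence} too extreme for the requested sample size"
            )
        hp = rng.choice(len(freqs), size=(batch, 2), p=freqs)
        ml = (rng.random(batch) < cfg.male_freq).astype(np.int64)
        copies = (hp == rh).sum(axis=1)
        dis = rng.random(batch) < _disease_prob(
            intercept, copies, ml, cfg.risk_or, cfg.sex_effect_or
        )
        if want_affected is None:
            keep = np.ones(batch, dtype=bool)
        else:
            keep = dis == want_affected
        pairs = np.vstack([pairs, hp[keep]])
        male = np.concatenate([male, ml[keep]])
        affected = np.concatenate([affected, dis[keep]])
    return pairs[:n_wanted], male[:n_wanted], affected[:n_wanted]


def _marker_ids(cfg: SimConfig) -> list[list[str]]:
    return [
        [f"b{b:03d}m{s:02d}" for s in range(cfg.markers_per_block)]
        for b in range(cfg.n_blocks)
    ]


def _block_dosage(
    pool: BlockPool, b: int, hap_idx: np.ndarray, minor_letter: list[str]
) -> np.ndarray:
    """Dosage (minor-allele counts) for block b from hap index pairs (n x 2)."""
    hap_mat = np.array([list(h) for h in pool.haplotypes[b]])  # n_hap x n_sites
    minor = np.array(minor_letter)
    is_minor = (hap_mat == minor[None, :]).astype(np.int64)  # n_hap x n_sites
    return is_minor[hap_idx[:, 0]] + is_minor[hap_idx[:, 1]]


def simulate_cohort(
    config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate an ascertained case-control cohort.

    Returns (GenotypeMatrix, PhenotypeTable, MarkerTable, SimTruth).  Cases
    are affected individuals; controls are population controls by default
    (``config.screened_controls`` switches to unaffected-only controls).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)
    pool = build_block_pool(cfg)
    intercept = calibrate_intercept(
        pool,
        cfg.risk_block_index,
        cfg.risk_haplotype_index,
        cfg.risk_or,
        cfg.sex_effect_or,
        cfg.prevalence,
        cfg.male_freq,
    )

    case_pairs, case_male, _ = _sample_group(rng, pool, cfg, intercept, cfg.n_cases, True)
    ctrl_pairs, ctrl_male, _ = _sample_group(
        rng, pool, cfg, intercept, cfg.n_controls,
        False if cfg.screened_controls else None,
    )

    n = cfg.n_cases + cfg.n_controls
    male = np.concatenate([case_male, ctrl_male])
    status = ["case"] * cfg.n_cases + ["control"] * cfg.n_controls
    ind_ids = [f"case{i:04d}" for i in range(cfg.n_cases)] + [
        f"ctrl{i:04d}" for i in range(cfg.n_controls)
    ]

    ids_per_block = _marker_ids(cfg)
    # population minor allele per site from founder frequencies
    minor_letters: list[list[str]] = []
    rows = []
    for b in range(cfg.n_blocks):
        hap_mat = np.array([list(h) for h in pool.haplotypes[b]])
        block_minor = []
        for s in range(cfg.markers_per_block):
            a1, a2 = pool.site_alleles[b][s]
            freq_a1 = float(pool.freqs[b][hap_mat[:, s] == a1].sum())
            if freq_a1 < 0.5:
                minor = a1
            elif freq_a1 > 0.5:
                minor = a2
            else:
                minor = min(a1, a2)
            if a1 == a2:  # monomorphic site (explicit pools only)
                minor = "0"
            block_minor.append(minor)
            rows.append(
                {
                    "marker_id": ids_per_block[b][s],
                    "chromosome": "1",
                    "position_bp": 1 + b * 100_000 + s * 1_000,
                    "allele1": min(a1, a2),
                    "allele2": max(a1, a2) if a1 != a2 else "0",
                    "minor_allele": minor,
                }
            )
        minor_letters.append(block_minor)
    marker_table = pd.DataFrame(rows)

    dosage_blocks = []
    for b in range(cfg.n_blocks):
        if b == cfg.risk_block_index:
            hap_idx = np.vstack([case_pairs, ctrl_pairs])
        else:
            hap_idx = rng.choice(len(pool.freqs[b]), size=(n, 2), p=pool.freqs[b])
        dosage_blocks.append(_block_dosage(pool, b, hap_idx, minor_letters[b]))
    dosage = np.concatenate(dosage_blocks, axis=1).astype(float)

    G = GenotypeMatrix(ind_ids, marker_table["marker_id"].tolist(), dosage)
    if cfg.missing_rate > 0:
        G = inject_missingness(G, cfg.missing_rate, seed=cfg.seed + 2)
    # recode to the observed (sample) minor allele, matching the convention
    # of the PED/MAP reader so that write -> read is an exact round trip
    _recode_to_sample_minor(G, marker_table)

    phenos = pd.DataFrame(
        {
            "family_id": ind_ids,
            "individual_id": ind_ids,
            "sex": np.where(male == 1, "male", "female"),
            "status": status,
        }
    )
    truth = SimTruth(
        risk_haplotype_string=pool.haplotypes[cfg.risk_block_index][cfg.risk_haplotype_index],
        risk_block_marker_ids=ids_per_block[cfg.risk_block_index],
        realized_or=cfg.risk_or,
        calibrated_intercept=intercept,
        realized_prevalence=_population_prevalence(pool, cfg, intercept),
        seed=cfg.seed,
    )
    return G, phenos, marker_table, truth


def _recode_to_sample_minor(G: GenotypeMatrix, marker_table: pd.DataFrame) -> None:
    """Flip dosage coding so it counts the *observed* minor allele.

    Ties at frequency 0.5 pick the lexicographically smaller letter; markers
    monomorphic in the sample end up with dosage 0 and minor allele '0'.
    Mutates ``G.dosage`` and the allele columns of ``marker_table`` in place.
    """
    for j in range(G.n_markers):
        col = G.dosage[:, j]
        obs = col[~np.isnan(col)]
        cur_minor = marker_table.at[j, "minor_allele"]
        a1, a2 = marker_table.at[j, "allele1"], marker_table.at[j, "allele2"]
        other = a2 if cur_minor == a1 else a1
        if obs.size == 0:
            marker_table.loc[j, ["allele1", "allele2", "minor_allele"]] = ["0", "0", "0"]
            continue
        f = obs.mean() / 2.0
        flip = f > 0.5 or (f == 0.5 and other < cur_minor)
        if flip:
            G.dosage[:, j] = 2.0 - G.dosage[:, j]
            cur_minor, other = other, cur_minor
            f = 1.0 - f
        if f == 0.0:  # monomorphic in the sample
            marker_table.loc[j, ["allele1", "allele2", "minor_allele"]] = [other, "0", "0"]
        else:
            lo, hi = sorted([cur_minor, other])
            marker_table.loc[j, ["allele1", "allele2", "minor_allele"]] = [lo, hi, cur_minor]


def inject_missingness(G: GenotypeMatrix, missing_rate: float, seed: int) -> GenotypeMatrix:
    """Set each genotype to missing independently with the given probability."""
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    dosage = G.dosage.copy()
    mask = rng.random(dosage.shape) < missing_rate
    dosage[mask] = np.nan
    return GenotypeMatrix(list(G.individual_ids), list(G.marker_ids), dosage)


def simulate_expression(
    n_genes: int,
    n_per_group: int,
    n_de: int,
    effect_size: float,
    noise_sd: float,
    seed: int,
) -> ExpressionMatrix:
    """Gaussian log-intensity matrix with the first ``n_de`` genes shifted up in group 2."""
    if n_de > n_genes:
        raise ValueError("n_de must be <= n_genes")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    genes = [f"gene{g:04d}" for g in range(n_genes)]
    samples = [f"g1_s{i}" for i in range(n_per_group)] + [
        f"g2_s{i}" for i in range(n_per_group)
    ]
    base = rng.normal(8.0, 1.0, size=n_genes)
    vals = base[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, 2 * n_per_group))
    vals[:n_de, n_per_group:] += effect_size
    groups = pd.Series(
        ["group1"] * n_per_group + ["group2"] * n_per_group, index=samples, name="group"
    )
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=genes, columns=samples),
        groups=groups,
        de_genes=genes[:n_de],
    )
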