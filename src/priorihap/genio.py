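"""Genotype, marker, phenotype and region file I/O plus quality control.

The on-disk dialect is the classic whitespace-separated PED/MAP pair: each
PED row is ``family individual paternal maternal sex status`` followed by two
allele letters per marker ("0 0" encoding a missing genotype); the MAP file
gives ``chromosome marker_id genetic_distance position`` per marker.  In
memory genotypes are held as minor-allele dosages (0/1/2, NaN for missing),
the coding used by every downstream association routine.

Coordinates follow the MAP convention (1-based positions); interval logic in
:mod:`priorihap.prioritize` converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QCThresholds",
    "QCReport",
    "read_ped_map",
    "write_ped_map",
    "read_bed",
    "apply_qc",
]

_VALID_ALLELES = frozenset("ACGT0")

MARKER_COLUMNS = ["marker_id", "chromosome", "position_bp", "allele1", "allele2", "minor_allele"]
PHENO_COLUMNS = ["family_id", "individual_id", "sex", "status"]

_SEX_CODE = {"1": "male", "2": "female"}
_SEX_CODE_INV = {"male": "1", "female": "2", "unknown": "0"}
_STATUS_CODE = {"2": "case", "1": "control"}
_STATUS_CODE_INV = {"case": "2", "control": "1", "missing": "0"}


@dataclass
class GenotypeMatrix:
    """N individuals x M markers of minor-allele dosages.

    ``dosage`` is a float array with values in {0, 1, 2} and NaN for missing.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError("dosage shape does not match id lists")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage values must be 0, 1, 2 or NaN")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def genotyping_rate(self) -> float:
        """Fraction of non-missing cells."""
        if self.dosage.size == 0:
            return 1.0
        return 1.0 - float(np.isnan(self.dosage).mean())


def _recode_alleles(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, str, str, str]:
    """Allele-pair columns -> minor-allele dosage.

    Minor allele is the less frequent observed allele over all individuals,
    ties at 0.5 broken lexicographically.  Returns (dosage, allele1, allele2,
    minor_allele) with allele1/allele2 sorted lexicographically ('0' stands in
    for an unobserved second allele at monomorphic markers).
    """
    observed = np.concatenate([a, b])
    observed = observed[observed != "0"]
    letters, counts = np.unique(observed, return_counts=True)
    if len(letters) > 2:
        raise ValueError(f"more than two alleles observed: {letters.tolist()}")
    n = len(a)
    dosage = np.full(n, np.nan)
    missing = (a == "0") | (b == "0")
    if len(letters) == 0:
        return dosage, "0", "0", "0"
    if len(letters) == 1:
        dosage[~missing] = 0.0
        return dosage, str(letters[0]), "0", "0"
    # two observed alleles: lexicographic tie-break on equal counts
    order = np.lexsort((letters, counts))  # ascending count, then letter
    minor = str(letters[order[0]])
    dosage[~missing] = (a[~missing] == minor).astype(float) + (b[~missing] == minor).astype(float)
    a1, a2 = sorted(str(x) for x in letters)
    return dosage, a1, a2, minor


def read_ped_map(ped_path: str, map_path: str) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Read a PED/MAP pair into (GenotypeMatrix, MarkerTable, PhenotypeTable)."""
    markers = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "marker_id", "genetic_distance", "position_bp"],
        dtype={"chromosome": str, "marker_id": str},
    )
    if markers["marker_id"].duplicated().any():
        raise ValueError("duplicate marker ids in MAP file")
    m = len(markers)

    fam, ind, sexes, statuses = [], [], [], []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise ValueError(
                    f"PED line {lineno}: expected {6 + 2 * m} fields, got {len(tok)}"
                )
            alleles = np.array(tok[6:], dtype="U1")
            bad = set(alleles) - _VALID_ALLELES
            if bad:
                raise ValueError(f"PED line {lineno}: invalid allele symbol(s) {sorted(bad)}")
            fam.append(tok[0])
            ind.append(tok[1])
            sexes.append(_SEX_CODE.get(tok[4], "unknown"))
            statuses.append(_STATUS_CODE.get(tok[5], "missing"))
            allele_rows.append(alleles)

    if len(set(ind)) != len(ind):
        raise ValueError("duplicate individual ids in PED file")
    allele_mat = np.array(allele_rows, dtype="U1").reshape(len(ind), m, 2) if ind else np.empty((0, m, 2), "U1")

    dosage = np.full((len(ind), m), np.nan)
    a1s, a2s, minors = [], [], []
    for j in range(m):
        dosage[:, j], a1, a2, minor = _recode_alleles(allele_mat[:, j, 0], allele_mat[:, j, 1])
        a1s.append(a1)
        a2s.append(a2)
        minors.append(minor)

    marker_table = pd.DataFrame(
        {
            "marker_id": markers["marker_id"],
            "chromosome": markers["chromosome"],
            "position_bp": markers["position_bp"].astype(int),
            "allele1": a1s,
            "allele2": a2s,
            "minor_allele": minors,
        }
    )
    phenos = pd.DataFrame(
        {"family_id": fam, "individual_id": ind, "sex": sexes, "status": statuses}
    )
    G = GenotypeMatrix(ind, marker_table["marker_id"].tolist(), dosage)
    return G, marker_table, phenos


def write_ped_map(
    G: GenotypeMatrix,
    markers: pd.DataFrame,
    phenos: pd.DataFrame,
    out_prefix: str,
) -> tuple[str, str]:
    """Write a PED/MAP pair; returns the (ped, map) paths."""
    if list(markers["marker_id"]) != G.marker_ids:
        raise ValueError("marker table does not match genotype matrix")
    ph = phenos.set_index("individual_id")
    missing_ids = [i for i in G.individual_ids if i not in ph.index]
    if missing_ids:
        raise ValueError(f"phenotype rows missing for individuals: {missing_ids[:5]}")

    minor = markers["minor_allele"].to_numpy(dtype="U1")
    a1 = markers["allele1"].to_numpy(dtype="U1")
    a2 = markers["allele2"].to_numpy(dtype="U1")
    major = np.where(a1 == minor, a2, a1)
    # monomorphic markers: the single observed allele is in allele1
    mono = minor == "0"
    major[mono] = a1[mono]

    ped_path = f"{out_prefix}.ped"
    map_path = f"{out_prefix}.map"
    with open(ped_path, "w") as fh:
        for i, ind_id in enumerate(G.individual_ids):
            row = ph.loc[ind_id]
            fields = [
                str(row["family_id"]),
                ind_id,
                "0",
                "0",
                _SEX_CODE_INV[row["sex"]],
                _STATUS_CODE_INV[row["status"]],
            ]
            d = G.dosage[i]
            for j in range(G.n_markers):
                if np.isnan(d[j]):
                    fields += ["0", "0"]
                elif d[j] == 2:
                    fields += [minor[j], minor[j]]
                elif d[j] == 1:
                    fields += [minor[j], major[j]]
                else:
                    fields += [major[j], major[j]]
            fh.write(" ".join(fields) + "\n")
    with open(map_path, "w") as fh:
        for _, row in markers.iterrows():
            fh.write(
                f"{row['chromosome']} {row['marker_id']} 0 {int(row['position_bp'])}\n"
            )
    return ped_path, map_path


def read_bed(path: str) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into chrom/start/end/name columns."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chromosome", "start_bp", "end_bp", "name"],
        dtype={"chromosome": str, "name": str},
    )
    if (df["start_bp"] >= df["end_bp"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    return df


@dataclass(frozen=True)
class QCThresholds:
    """Quality-control thresholds.

    ``mind``: minimum per-individual call rate (individuals below are removed).
    ``geno``: maximum per-marker missing fraction; the default 1.0 removes only
    completely missing markers.  ``maf``: exclusive minor-allele-frequency
    floor; the default 0 removes monomorphic markers only.
    """

    mind: float = 0.80
    geno: float = 1.0
    maf: float = 0.0
    haploid_chromosomes: tuple[str, ...] = ("X", "Y")
    maf_controls_only: bool = False

    def __post_init__(self) -> None:
        for name in ("mind", "geno", "maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    n_markers_removed_missingness: int = 0
    n_markers_removed_maf: int = 0
    n_individuals_removed: int = 0
    n_het_haploid_set_missing: int = 0
    overall_genotyping_rate: float = 1.0


def apply_qc(
    G: GenotypeMatrix,
    markers: pd.DataFrame,
    phenos: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, QCReport]:
    """Apply the standard QC cascade, in order.

    1. Heterozygous haploid genotypes (males on haploid-flagged chromosomes
       with dosage 1) are set to missing.
    2. Individuals with call rate below ``mind`` are removed.
    3. Markers with missing fraction >= ``geno`` are removed.
    4. Markers with MAF <= ``maf`` (computed on the remaining individuals) are
       removed; with the defaults this prunes monomorphic markers only.
    """
    thr = thresholds or QCThresholds()
    report = QCReport()

    dosage = G.dosage.copy()
    ph = phenos.set_index("individual_id").loc[G.individual_ids].reset_index()

    # step 1: heterozygous haploid -> missing
    haploid_cols = markers["chromosome"].isin(thr.haploid_chromosomes).to_numpy()
    if haploid_cols.any():
        male_rows = (ph["sex"] == "male").to_numpy()
        het = dosage == 1.0
        hh = np.outer(male_rows, haploid_cols) & het
        report.n_het_haploid_set_missing = int(hh.sum())
        dosage[hh] = np.nan

    # step 2: individual call rate
    n_markers = dosage.shape[1]
    if n_markers > 0:
        call_rate = 1.0 - np.isnan(dosage).mean(axis=1)
    else:
        call_rate = np.ones(dosage.shape[0])
    keep_ind = call_rate >= thr.mind
    report.n_individuals_removed = int((~keep_ind).sum())
    dosage = dosage[keep_ind]
    kept_ids = [i for i, k in zip(G.individual_ids, keep_ind) if k]
    ph = ph[keep_ind.tolist()].reset_index(drop=True)

    # step 3: marker missingness
    n_ind = dosage.shape[0]
    if n_ind > 0:
        miss_frac = np.isnan(dosage).mean(axis=0)
    else:
        miss_frac = np.ones(dosage.shape[1])
    keep_geno = miss_frac < thr.geno
    # geno == 1.0 means "remove markers with missing fraction >= 1.0"
    report.n_markers_removed_missingness = int((~keep_geno).sum())

    # step 4: MAF on remaining individuals
    if thr.maf_controls_only:
        maf_rows = (ph["status"] == "control").to_numpy()
    else:
        maf_rows = np.ones(n_ind, dtype=bool)
    sub = dosage[maf_rows] if n_ind else dosage
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(sub, axis=0) / 2.0 if sub.shape[0] else np.zeros(dosage.shape[1])
    freq = np.nan_to_num(freq)
    maf = np.minimum(freq, 1.0 - freq)
    keep_maf = maf > thr.maf
    report.n_markers_removed_maf = int((keep_geno & ~keep_maf).sum())

    keep_marker = keep_geno & keep_maf
    dosage = dosage[:, keep_marker]
    markers_out = markers.loc[keep_marker.tolist()].reset_index(drop=True)

    G_out = GenotypeMatrix(kept_ids, markers_out["marker_id"].tolist(), dosage)
    report.overall_genotyping_rate = G_out.genotyping_rate()
    return G_out, markers_out, ph[PHENO_COLUMNS], report
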