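"""Case-control genotype loading and quality control.

Genotypes arrive as PLINK PED/MAP text and are held as an A1-allele
dosage matrix (0/1/2, -1 for missing).  QC applies, in order: per-person
missingness, per-SNP missingness, minor-allele frequency (cases plus
controls of the analysis stratum) and a Hardy-Weinberg exact test in
controls only.  Default thresholds: persons with >10% missing calls and
SNPs with >5% missing calls, MAF < 1%, or control-HWE p < 1e-3 are
excluded.  The order mirrors the conventional GWAS toolchain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .snp_select import SnpRecord, write_map

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str  # "female" | "male"
    phenotype: str  # "case" | "control"

    def __post_init__(self) -> None:
        if self.sex not in {"female", "male"}:
            raise ValueError(f"{self.id}: sex must be female/male, got {self.sex!r}")
        if self.phenotype not in {"case", "control"}:
            raise ValueError(f"{self.id}: phenotype must be case/control")


@dataclass
class GenotypeDataset:
    """Individuals x SNPs with A1-dosage calls.

    ``calls[i, j]`` counts copies of SNP j's designated A1 allele carried
    by individual i (-1 = missing).  A1 is initially the lexicographically
    smaller observed allele; the minor allele is re-designated per stratum
    at analysis time.
    """

    individuals: list[Individual]
    snps: list[SnpRecord]
    calls: np.ndarray  # int8, shape (n_individuals, n_snps)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs"
            )
        self._ind_index = {ind.id: i for i, ind in enumerate(self.individuals)}
        self._snp_index = {s.rsid: j for j, s in enumerate(self.snps)}
        if len(self._ind_index) != len(self.individuals):
            raise ValueError("duplicate individual ids")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def ind_idx(self, id_: str) -> int:
        try:
            return self._ind_index[id_]
        except KeyError:
            raise KeyError(f"unknown individual id {id_!r}") from None

    def snp_idx(self, rsid: str) -> int:
        try:
            return self._snp_index[rsid]
        except KeyError:
            raise KeyError(f"unknown rsid {rsid!r}") from None

    def stratum_mask(self, sex: str | None = None, phenotype: str | None = None) -> np.ndarray:
        mask = np.ones(self.n_individuals, dtype=bool)
        if sex is not None:
            mask &= np.array([ind.sex == sex for ind in self.individuals])
        if phenotype is not None:
            mask &= np.array([ind.phenotype == phenotype for ind in self.individuals])
        return mask

    def subset(
        self, ind_mask: np.ndarray | None = None, snp_mask: np.ndarray | None = None
    ) -> "GenotypeDataset":
        ind_mask = np.ones(self.n_individuals, bool) if ind_mask is None else ind_mask
        snp_mask = np.ones(self.n_snps, bool) if snp_mask is None else snp_mask
        return GenotypeDataset(
            [ind for ind, keep in zip(self.individuals, ind_mask) if keep],
            [s for s, keep in zip(self.snps, snp_mask) if keep],
            self.calls[np.ix_(ind_mask, snp_mask)],
        )

    def restrict_to(self, rsids: Iterable[str]) -> "GenotypeDataset":
        wanted = set(rsids)
        return self.subset(snp_mask=np.array([s.rsid in wanted for s in self.snps]))


@dataclass(frozen=True)
class QcThresholds:
    max_snp_missing: float = 0.05
    min_maf: float = 0.01
    min_hwe_p_controls: float = 0.001
    max_person_missing: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "max_snp_missing",
            "min_maf",
            "min_hwe_p_controls",
            "max_person_missing",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class QcReport:
    excluded_individuals: list[tuple[str, str, float]] = field(default_factory=list)
    excluded_snps: list[tuple[str, str, float]] = field(default_factory=list)
    n_individuals_before: int = 0
    n_individuals_after: int = 0
    n_snps_before: int = 0
    n_snps_after: int = 0

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tid\treason\tvalue\n")
            for id_, reason, value in self.excluded_individuals:
                fh.write(f"individual\t{id_}\t{reason}\t{value:.6g}\n")
            for rsid, reason, value in self.excluded_snps:
                fh.write(f"snp\t{rsid}\t{reason}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# PED/MAP I/O

_SEX_FROM_PED = {"1": "male", "2": "female"}
_PHE_FROM_PED = {"1": "control", "2": "case"}


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Load PLINK text PED/MAP into a dosage dataset.

    PED columns: FID IID PAT MAT SEX PHE then two allele columns per SNP
    (0 = missing allele).  A half-missing genotype is treated as missing
    with a warning.  A1 is the lexicographically smaller observed allele.
    """
    from .snp_select import read_map

    snps = read_map(map_path)
    n_snps = len(snps)
    individuals: list[Individual] = []
    allele_rows: list[list[str]] = []
    ped_path = Path(ped_path)
    with open(ped_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.split()
            if len(fields) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} columns for "
                    f"{n_snps} MAP SNPs, got {len(fields)}"
                )
            _fid, iid, _pat, _mat, sex, phe = fields[:6]
            if sex not in _SEX_FROM_PED:
                raise ValueError(f"{ped_path}:{lineno}: bad sex code {sex!r}")
            if phe not in _PHE_FROM_PED:
                raise ValueError(f"{ped_path}:{lineno}: bad phenotype code {phe!r}")
            individuals.append(Individual(iid, _SEX_FROM_PED[sex], _PHE_FROM_PED[phe]))
            allele_rows.append(fields[6:])

    alleles = np.array(allele_rows, dtype="U1").reshape(len(individuals), n_snps, 2)
    calls = np.full((len(individuals), n_snps), MISSING, dtype=np.int8)
    snps_with_alleles: list[SnpRecord] = []
    half_missing = (alleles == "0").sum(axis=2) == 1
    if half_missing.any():
        logger.warning(
            "%d half-missing genotypes treated as missing", int(half_missing.sum())
        )
    for j, snp in enumerate(snps):
        col = alleles[:, j, :]
        ok = ~(col == "0").any(axis=1)
        observed = sorted(set(col[ok].ravel()))
        if len(observed) > 2:
            raise ValueError(f"SNP {snp.rsid}: more than two alleles {observed}")
        if not observed:
            snps_with_alleles.append(replace(snp, alleles=None))
            continue
        a1 = observed[0]
        a2 = observed[1] if len(observed) > 1 else observed[0]
        calls[ok, j] = (col[ok] == a1).sum(axis=1)
        snps_with_alleles.append(replace(snp, alleles=(a1, a2)))
    return GenotypeDataset(individuals, snps_with_alleles, calls)


def write_ped_map(ds: GenotypeDataset, ped_path: str | Path, map_path: str | Path) -> None:
    """Inverse of :func:`read_ped_map` (A1 dosage back to allele pairs)."""
    write_map(ds.snps, map_path)
    sex_code = {"male": "1", "female": "2"}
    phe_code = {"control": "1", "case": "2"}
    geno_strings = []
    for snp in ds.snps:
        a1, a2 = snp.alleles if snp.alleles else ("A", "A")
        geno_strings.append({2: f"{a1} {a1}", 1: f"{a1} {a2}", 0: f"{a2} {a2}", MISSING: "0 0"})
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(ds.individuals):
            geno = " ".join(
                geno_strings[j][int(ds.calls[i, j])] for j in range(ds.n_snps)
            )
            fh.write(
                f"{ind.id} {ind.id} 0 0 {sex_code[ind.sex]} {phe_code[ind.phenotype]} {geno}\n"
            )


# ---------------------------------------------------------------------------
# Rates and the HWE exact test


def person_missing_rate(ds: GenotypeDataset, id_: str) -> float:
    i = ds.ind_idx(id_)
    if ds.n_snps == 0:
        return 0.0
    return float((ds.calls[i] == MISSING).sum()) / ds.n_snps


def snp_missing_rate(
    ds: GenotypeDataset, rsid: str, stratum: np.ndarray | None = None
) -> float:
    j = ds.snp_idx(rsid)
    col = ds.calls[:, j] if stratum is None else ds.calls[stratum, j]
    if col.size == 0:
        raise ValueError("empty stratum")
    return float((col == MISSING).sum()) / col.size


def snp_maf(ds: GenotypeDataset, rsid: str, stratum: np.ndarray | None = None) -> float:
    """Minor-allele frequency over non-missing alleles in the stratum."""
    j = ds.snp_idx(rsid)
    col = ds.calls[:, j] if stratum is None else ds.calls[stratum, j]
    obs = col[col != MISSING]
    if obs.size == 0:
        raise ValueError(f"{rsid}: all calls missing in stratum; MAF undefined")
    f_a1 = float(obs.sum()) / (2 * obs.size)
    return min(f_a1, 1.0 - f_a1)


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test (conditional enumeration).

    Conditional on the observed allele totals, heterozygote counts with
    the same parity as the rare-allele total are enumerated via the
    standard probability recurrence; the p-value sums the probabilities of
    all configurations no more probable than the observed one.
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        raise ValueError("no genotypes")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0  # monomorphic: single attainable configuration

    # Unnormalised probabilities over attainable het counts (same parity as
    # n_rare), built from the mode outward with the standard ratio
    #   P(het+2)/P(het) = 4*hom_r*hom_c / ((het+2)*(het+1)).
    probs = {}
    mid = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if mid % 2 != n_rare % 2:
        mid += 1 if mid < n_rare else -1
    probs[mid] = 1.0
    het = mid
    while het >= 2:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[het - 2] = probs[het] * het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
    het = mid
    while het + 2 <= n_rare:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / ((het + 2) * (het + 1))
        het += 2
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def hwe_p_from_dosages(col: np.ndarray) -> float:
    obs = col[col != MISSING]
    if obs.size == 0:
        return 1.0
    return hwe_exact_test(
        int((obs == 1).sum()), int((obs == 2).sum()), int((obs == 0).sum())
    )


# ---------------------------------------------------------------------------
# QC driver


def apply_qc(
    ds: GenotypeDataset,
    thresholds: QcThresholds = QcThresholds(),
    stratum: np.ndarray | None = None,
) -> tuple[GenotypeDataset, QcReport]:
    """Apply the four QC filters within an analysis stratum.

    Order: (1) drop individuals with missing rate > ``max_person_missing``;
    (2) on the survivors, drop SNPs failing missingness, then MAF (cases
    plus controls), then the HWE exact test computed in controls only.
    ``stratum`` restricts the dataset (e.g. one sex) before any filtering;
    QC is self-contained per analysis.
    """
    if stratum is not None:
        ds = ds.subset(ind_mask=stratum)
    report = QcReport(
        n_individuals_before=ds.n_individuals, n_snps_before=ds.n_snps
    )
    miss_per_person = (ds.calls == MISSING).mean(axis=1) if ds.n_snps else np.zeros(ds.n_individuals)
    keep_ind = miss_per_person <= thresholds.max_person_missing
    for ind, keep, rate in zip(ds.individuals, keep_ind, miss_per_person):
        if not keep:
            report.excluded_individuals.append((ind.id, "person_missing", float(rate)))
    ds = ds.subset(ind_mask=keep_ind)
    if ds.n_individuals == 0:
        raise ValueError("no individuals left after person-missingness filter")

    controls = ds.stratum_mask(phenotype="control")
    keep_snp = np.ones(ds.n_snps, dtype=bool)
    for j, snp in enumerate(ds.snps):
        col = ds.calls[:, j]
        miss = float((col == MISSING).mean())
        if miss > thresholds.max_snp_missing:
            report.excluded_snps.append((snp.rsid, "snp_missing", miss))
            keep_snp[j] = False
            continue
        obs = col[col != MISSING]
        if obs.size == 0:
            report.excluded_snps.append((snp.rsid, "maf", float("nan")))
            keep_snp[j] = False
            continue
        f_a1 = float(obs.sum()) / (2 * obs.size)
        maf = min(f_a1, 1 - f_a1)
        if maf < thresholds.min_maf:
            report.excluded_snps.append((snp.rsid, "maf", maf))
            keep_snp[j] = False
            continue
        if controls.any():
            p_hwe = hwe_p_from_dosages(col[controls])
            if p_hwe < thresholds.min_hwe_p_controls:
                report.excluded_snps.append((snp.rsid, "hwe_controls", p_hwe))
                keep_snp[j] = False
    ds = ds.subset(snp_mask=keep_snp)
    report.n_individuals_after = ds.n_individuals
    report.n_snps_after = ds.n_snps
    return ds, report
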