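"""Sex- and disease-stratified allelic case-control association.

For each SNP in each stratum (disease x sex) a 2x2 table of minor/major
allele counts in cases versus controls is tested with the two-tailed
Fisher exact test (probability-mass convention).  Effect size is the
allelic odds ratio for the minor allele with a Woolf (log-normal) 95%
confidence interval.  Multiple testing is handled by a single study-wide
Bonferroni factor: diseases x sexes x panel size, where the panel size is
the maximum post-QC panel across strata (one shared factor even when
per-stratum panels differ slightly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genotype_qc import MISSING, GenotypeDataset, QcReport, QcThresholds, apply_qc

DISEASES = ("bipolar", "depression")
SEXES = ("female", "male")


@dataclass(frozen=True)
class Stratum:
    disease: str
    sex: str


@dataclass(frozen=True)
class AlleleTable:
    """Minor/major allele counts: (a, b) in cases, (c, d) in controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def maf_cases(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def maf_controls(self) -> float:
        return self.c / (self.c + self.d)


@dataclass
class AssocResult:
    rsid: str
    stratum: Stratum
    table: AlleleTable
    maf_cases: float
    maf_controls: float
    p: float
    p_corrected: float
    or_: float
    l95: float
    u95: float
    minor_allele: str | None = None
    major_allele: str | None = None

    @property
    def p_corrected_display(self) -> str:
        return format_corrected_p(self.p_corrected)


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up with a pre-quantisation absorbing float noise."""
    d = Decimal(repr(float(x)))
    d = d.quantize(Decimal(1).scaleb(-(ndigits + 6)), rounding=ROUND_HALF_UP)
    return float(d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def format_corrected_p(p_corrected: float, ndigits: int = 3) -> str:
    """Display rule: corrected p above 1 prints as ``>1``; values that
    would round to all zeros fall back to 3 significant figures."""
    if p_corrected > 1.0:
        return ">1"
    if p_corrected < 10 ** -ndigits / 2:
        return f"{p_corrected:.3g}"
    return f"{round_half_up(p_corrected, ndigits):.{ndigits}f}"


def allele_table(
    ds: GenotypeDataset,
    rsid: str,
    case_mask: np.ndarray,
    control_mask: np.ndarray,
) -> tuple[AlleleTable, tuple[str, str] | None]:
    """2x2 minor/major allele counts from non-missing genotypes.

    The minor allele is designated by pooled (cases + controls) frequency
    below 0.5; an exact tie is broken toward the lexicographically smaller
    allele.  Returns the table and, when allele labels are known, the
    (minor, major) pair.
    """
    j = ds.snp_idx(rsid)
    cases = ds.calls[case_mask, j]
    controls = ds.calls[control_mask, j]
    cases = cases[cases != MISSING]
    controls = controls[controls != MISSING]
    if cases.size == 0 or controls.size == 0:
        raise ValueError(f"{rsid}: no non-missing genotypes in cases or controls")
    a1_cases = int(cases.sum())
    a1_controls = int(controls.sum())
    tot_cases = 2 * cases.size
    tot_controls = 2 * controls.size
    pooled_f_a1 = (a1_cases + a1_controls) / (tot_cases + tot_controls)
    labels = ds.snps[j].alleles
    # A1 is the lexicographically smaller allele, so on an exact 0.5 tie
    # keeping A1 as "minor" realises the smaller-allele tie-break.
    if pooled_f_a1 <= 0.5:
        table = AlleleTable(a1_cases, tot_cases - a1_cases, a1_controls, tot_controls - a1_controls)
        pair = labels
    else:
        table = AlleleTable(tot_cases - a1_cases, a1_cases, tot_controls - a1_controls, a1_controls)
        pair = (labels[1], labels[0]) if labels else None
    return table, pair


def fisher_exact_two_sided(t: AlleleTable) -> float:
    """Two-tailed Fisher exact p (probability-mass convention).

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities no larger than that of the observed table.
    """
    if (t.a + t.b) == 0 or (t.c + t.d) == 0 or (t.a + t.c) == 0 or (t.b + t.d) == 0:
        raise ValueError("all margins must be positive")
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return float(min(1.0, p))


def odds_ratio_ci(
    t: AlleleTable, confidence: float = 0.95, continuity: bool = False
) -> tuple[float, float, float]:
    """Allelic odds ratio (ad/bc) with Woolf log-normal confidence interval.

    A zero cell makes the estimate degenerate; with ``continuity`` the
    Haldane-Anscombe +0.5 correction is applied to every cell instead of
    raising.
    """
    cells = [t.a, t.b, t.c, t.d]
    if min(cells) == 0:
        if not continuity:
            raise ValueError("zero cell; enable continuity for Haldane-Anscombe +0.5")
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + confidence / 2)
    lo, hi = math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)
    return or_, lo, hi


def bonferroni_correct(p: float, multiplier: int) -> float:
    """Bonferroni correction: raw p times the number of tests."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0,1], got {p}")
    if multiplier < 1 or multiplier != int(multiplier):
        raise ValueError(f"multiplier must be a positive integer, got {multiplier}")
    return p * multiplier


def compute_multiplier(n_diseases: int, n_sexes: int, panel_size: int) -> int:
    """Study-wide Bonferroni factor: diseases x sexes x panel size."""
    if min(n_diseases, n_sexes, panel_size) < 1:
        raise ValueError("all factors must be >= 1")
    return n_diseases * n_sexes * panel_size


def run_stratified(
    datasets: Mapping[str, GenotypeDataset],
    candidate_rsids: Sequence[str] | None = None,
    strata: Sequence[Stratum] | None = None,
    thresholds: QcThresholds = QcThresholds(),
    multiplier: int | str = "auto",
) -> tuple[list[AssocResult], dict[Stratum, QcReport], int]:
    """QC and test every candidate SNP in every disease x sex stratum.

    ``datasets`` maps disease label to its genotype dataset.  QC runs
    independently per stratum on the candidate-restricted panel; with
    ``multiplier='auto'`` the Bonferroni factor is diseases x sexes x the
    maximum post-QC panel size across strata.  Returns the per-SNP results
    (sorted by stratum then raw p), the per-stratum QC reports and the
    multiplier used.
    """
    if strata is None:
        strata = [Stratum(d, s) for d in datasets for s in SEXES]
    qc_data: dict[Stratum, GenotypeDataset] = {}
    qc_reports: dict[Stratum, QcReport] = {}
    for st in strata:
        ds = datasets[st.disease]
        if candidate_rsids is not None:
            ds = ds.restrict_to(candidate_rsids)
        clean, report = apply_qc(ds, thresholds, stratum=ds.stratum_mask(sex=st.sex))
        qc_data[st] = clean
        qc_reports[st] = report

    if multiplier == "auto":
        panel = max((d.n_snps for d in qc_data.values()), default=0)
        mult = compute_multiplier(len({st.disease for st in strata}),
                                  len({st.sex for st in strata}), max(panel, 1))
    else:
        mult = int(multiplier)

    results: list[AssocResult] = []
    for st in strata:
        ds = qc_data[st]
        case_mask = ds.stratum_mask(phenotype="case")
        control_mask = ds.stratum_mask(phenotype="control")
        for snp in ds.snps:
            table, pair = allele_table(ds, snp.rsid, case_mask, control_mask)
            p = fisher_exact_two_sided(table)
            # Post-QC (MAF floor) zero cells are rare; fall back to the
            # continuity-corrected estimate rather than dropping the row.
            or_, lo, hi = odds_ratio_ci(table, continuity=min(table.a, table.b, table.c, table.d) == 0)
            results.append(
                AssocResult(
                    rsid=snp.rsid,
                    stratum=st,
                    table=table,
                    maf_cases=table.maf_cases,
                    maf_controls=table.maf_controls,
                    p=p,
                    p_corrected=bonferroni_correct(p, mult),
                    or_=or_,
                    l95=lo,
                    u95=hi,
                    minor_allele=pair[0] if pair else None,
                    major_allele=pair[1] if pair else None,
                )
            )
    results.sort(key=lambda r: (r.stratum.disease, r.stratum.sex, r.p, r.rsid))
    return results, qc_reports, mult


def write_results_tsv(results: Sequence[AssocResult], path: str | Path) -> None:
    """Display table mirroring the study's reporting conventions."""
    with open(path, "w") as fh:
        fh.write(
            "disease\tsex\trsid\talleles\tmaf_cases\tmaf_controls\tp\t"
            "p_corrected\tOR\tL95\tU95\n"
        )
        for r in results:
            alleles = (
                f"{r.minor_allele}<{r.major_allele}"
                if r.minor_allele and r.major_allele
                else "."
            )
            fh.write(
                f"{r.stratum.disease}\t{r.stratum.sex}\t{r.rsid}\t{alleles}\t"
                f"{r.maf_cases:.4f}\t{r.maf_controls:.4f}\t{r.p:.4g}\t"
                f"{r.p_corrected_display}\t{round_half_up(r.or_, 3):.3f}\t"
                f"{round_half_up(r.l95, 3):.3f}\t{round_half_up(r.u95, 3):.3f}\n"
            )


def write_results_full(results: Sequence[AssocResult], path: str | Path) -> None:
    """Machine-readable full-precision results."""
    with open(path, "w") as fh:
        fh.write(
            "disease\tsex\trsid\ta\tb\tc\td\tmaf_cases\tmaf_controls\tp\t"
            "p_corrected\tOR\tL95\tU95\n"
        )
        for r in results:
            t = r.table
            fh.write(
                f"{r.stratum.disease}\t{r.stratum.sex}\t{r.rsid}\t{t.a}\t{t.b}\t"
                f"{t.c}\t{t.d}\t{r.maf_cases!r}\t{r.maf_controls!r}\t{r.p!r}\t"
                f"{r.p_corrected!r}\t{r.or_!r}\t{r.l95!r}\t{r.u95!r}\n"
            )
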