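"""PED/MAP I/O, missingness/MAF rates, HWE exact test and QC filtering."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from erevar.genotype_qc import (
    MISSING,
    GenotypeDataset,
    Individual,
    QcThresholds,
    apply_qc,
    hwe_exact_test,
    person_missing_rate,
    read_ped_map,
    snp_maf,
    snp_missing_rate,
    write_ped_map,
)
from erevar.snp_select import SnpRecord


def _dataset(calls, sexes=None, phenos=None, alleles=("A", "G")):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    individuals = [
        Individual(
            f"i{i}",
            (sexes or ["female"] * n)[i],
            (phenos or ["case"] * n)[i],
        )
        for i in range(n)
    ]
    snps = [SnpRecord(f"rs{j}", "chr1", 100 + j, alleles) for j in range(m)]
    return GenotypeDataset(individuals, snps, calls)


# ---------------------------------------------------------------------------
# PED/MAP I/O


def test_read_ped_map_dosages(tmp_path):
    (tmp_path / "d.map").write_text("1\trs1\t0\t100\n")
    (tmp_path / "d.ped").write_text(
        "f1 p1 0 0 2 2 A A\nf2 p2 0 0 1 1 A G\n"
    )
    ds = read_ped_map(tmp_path / "d.ped", tmp_path / "d.map")
    assert [ind.sex for ind in ds.individuals] == ["female", "male"]
    assert [ind.phenotype for ind in ds.individuals] == ["case", "control"]
    assert ds.snps[0].alleles == ("A", "G")
    assert ds.calls.tolist() == [[2], [1]]  # A1 = lexicographically smaller (A)


def test_read_ped_map_missing_and_half_missing(tmp_path, caplog):
    (tmp_path / "d.map").write_text("1\trs1\t0\t100\n")
    (tmp_path / "d.ped").write_text("f1 p1 0 0 2 2 0 0\nf2 p2 0 0 2 1 A 0\nf3 p3 0 0 2 1 A G\n")
    with caplog.at_level("WARNING"):
        ds = read_ped_map(tmp_path / "d.ped", tmp_path / "d.map")
    assert ds.calls[:, 0].tolist() == [MISSING, MISSING, 1]
    assert "half-missing" in caplog.text


def test_read_ped_map_column_mismatch(tmp_path):
    (tmp_path / "d.map").write_text("1\trs1\t0\t100\n1\trs2\t0\t200\n")
    (tmp_path / "d.ped").write_text("f1 p1 0 0 2 2 A A\n")
    with pytest.raises(ValueError, match="columns"):
        read_ped_map(tmp_path / "d.ped", tmp_path / "d.map")


def test_ped_map_round_trip(tmp_path, rng):
    calls = rng.integers(-1, 3, size=(10, 5))
    calls[0, :] = 1  # both alleles observed at every SNP
    ds = _dataset(calls, sexes=list(rng.choice(["female", "male"], 10)), phenos=list(rng.choice(["case", "control"], 10)))
    write_ped_map(ds, tmp_path / "a.ped", tmp_path / "a.map")
    back = read_ped_map(tmp_path / "a.ped", tmp_path / "a.map")
    write_ped_map(back, tmp_path / "b.ped", tmp_path / "b.map")
    assert (tmp_path / "a.ped").read_text() == (tmp_path / "b.ped").read_text()
    assert (tmp_path / "a.map").read_text() == (tmp_path / "b.map").read_text()
    assert np.array_equal(ds.calls, back.calls)


# ---------------------------------------------------------------------------
# Rates


def test_person_missing_rate():
    ds = _dataset([[0, 1, 2, 0, 1], [MISSING, 1, 2, 0, 1]])
    assert person_missing_rate(ds, "i0") == 0.0
    assert person_missing_rate(ds, "i1") == 0.2
    with pytest.raises(KeyError):
        person_missing_rate(ds, "nobody")


@pytest.mark.parametrize(
    "dosages, maf",
    [([0, 1, 2], 0.5), ([0, 0, 0, 1], 0.125), ([2, 2, 2], 0.0)],
)
def test_snp_maf_examples(dosages, maf):
    ds = _dataset([[d] for d in dosages])
    assert snp_maf(ds, "rs0") == pytest.approx(maf)


def test_snp_maf_all_missing_errors():
    ds = _dataset([[MISSING], [MISSING]])
    with pytest.raises(ValueError, match="missing"):
        snp_maf(ds, "rs0")


def test_rates_match_direct_count(rng):
    calls = rng.integers(-1, 3, size=(50, 8))
    ds = _dataset(calls)
    for j in range(8):
        col = calls[:, j]
        assert snp_missing_rate(ds, f"rs{j}") == pytest.approx((col == -1).mean())
        obs = col[col != -1]
        if obs.size:
            f = obs.sum() / (2 * obs.size)
            assert snp_maf(ds, f"rs{j}") == pytest.approx(min(f, 1 - f))


# ---------------------------------------------------------------------------
# HWE exact test


def _hwe_oracle(n_het, n_hom1, n_hom2):
    """Independent enumeration from the exact conditional probability
    formula P(het) = n! 2^het n_a! n_b! / (hom1! hom2! het! (2n)!)."""
    n = n_het + n_hom1 + n_hom2
    na = 2 * n_hom1 + n_het  # allele-1 total
    probs = {}
    for het in range(min(na, 2 * n - na) + 1):
        if (na - het) % 2:
            continue
        h1 = (na - het) // 2
        h2 = n - het - h1
        if h1 < 0 or h2 < 0:
            continue
        probs[het] = (
            Fraction(
                comb(n, h1) * comb(n - h1, het) * 2**het,
                comb(2 * n, na),
            )
        )
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    return float(sum(v for v in probs.values() if v / total <= p_obs) / total)


def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(0, 0, 50) == 1.0
    assert hwe_exact_test(0, 50, 0) == 1.0


def test_hwe_small_table_enumeration():
    # 5 diploids, 4 minor alleles: attainable het in {0, 2, 4}
    assert hwe_exact_test(2, 0, 3) == pytest.approx(_hwe_oracle(2, 0, 3), rel=1e-12)


def test_hwe_cohort_scale_table_against_oracle():
    assert hwe_exact_test(57, 21, 22) == pytest.approx(_hwe_oracle(57, 21, 22), rel=1e-12)


def test_hwe_symmetric_under_hom_swap(rng):
    for _ in range(20):
        het, h1, h2 = (int(x) for x in rng.integers(0, 40, 3))
        if het + h1 + h2 == 0:
            continue
        assert hwe_exact_test(het, h1, h2) == pytest.approx(hwe_exact_test(het, h2, h1))


def test_hwe_matches_enumeration_up_to_200_alleles(rng):
    for _ in range(60):
        n = int(rng.integers(1, 100))  # up to 200 alleles
        na = int(rng.integers(0, 2 * n + 1))
        het_max = min(na, 2 * n - na)
        attainable = [h for h in range(het_max + 1) if (na - h) % 2 == 0]
        het = int(rng.choice(attainable))
        h1 = (na - het) // 2
        h2 = n - het - h1
        p = hwe_exact_test(het, h1, h2)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(_hwe_oracle(het, h1, h2), rel=1e-10)


def test_hwe_negative_counts_error():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)


# ---------------------------------------------------------------------------
# QC driver


def _qc_fixture(rng, n=60, m=8):
    """Clean HWE genotypes at MAF 0.3, half cases / half controls."""
    calls = rng.binomial(1, 0.3, size=(n, m)) + rng.binomial(1, 0.3, size=(n, m))
    phenos = ["case"] * (n // 2) + ["control"] * (n - n // 2)
    return _dataset(calls, phenos=phenos)


def test_apply_qc_clean_fixture_excludes_nothing(rng):
    ds = _qc_fixture(rng)
    clean, report = apply_qc(ds)
    assert report.excluded_individuals == [] and report.excluded_snps == []
    assert clean.n_individuals == ds.n_individuals and clean.n_snps == ds.n_snps


def test_apply_qc_planted_missing_snp_excluded(rng):
    ds = _qc_fixture(rng, m=30)  # wide panel keeps per-person rates low
    ds.calls[: ds.n_individuals // 10 + 1, 0] = MISSING  # ~10% missing at SNP 0
    clean, report = apply_qc(ds)
    assert ("rs0", "snp_missing") in {(r, why) for r, why, _ in report.excluded_snps}
    assert "rs0" not in {s.rsid for s in clean.snps}


def test_apply_qc_planted_person_excluded(rng):
    ds = _qc_fixture(rng)
    ds.calls[0, :] = MISSING
    clean, report = apply_qc(ds)
    assert ("i0", "person_missing") in {(i, why) for i, why, _ in report.excluded_individuals}


def test_apply_qc_rare_snp_excluded(rng):
    ds = _qc_fixture(rng)
    ds.calls[:, 1] = 0
    ds.calls[0, 1] = 1  # single copy: MAF 1/120 < 0.01
    _, report = apply_qc(ds)
    assert ("rs1", "maf") in {(r, why) for r, why, _ in report.excluded_snps}


def test_apply_qc_control_hwe_violator_excluded(rng):
    ds = _qc_fixture(rng, n=400)
    controls = ds.stratum_mask(phenotype="control")
    ds.calls[controls, 2] = 1  # all controls heterozygous: gross HWE violation
    assert hwe_exact_test(int(controls.sum()), 0, 0) < 1e-3  # fixture built on the oracle
    _, report = apply_qc(ds)
    assert ("rs2", "hwe_controls") in {(r, why) for r, why, _ in report.excluded_snps}
    # HWE is assessed in controls only: same pattern in cases is no violation
    ds2 = _qc_fixture(rng, n=400)
    ds2.calls[ds2.stratum_mask(phenotype="case"), 2] = 1
    _, report2 = apply_qc(ds2)
    assert "hwe_controls" not in {why for _, why, _ in report2.excluded_snps}


def test_apply_qc_idempotent(rng):
    ds = _qc_fixture(rng)
    ds.calls[0, :] = MISSING
    ds.calls[1:8, 0] = MISSING
    once, _ = apply_qc(ds)
    twice, report2 = apply_qc(once)
    assert report2.excluded_individuals == [] and report2.excluded_snps == []
    assert np.array_equal(once.calls, twice.calls)


def test_apply_qc_monotone_in_thresholds(rng):
    ds = _qc_fixture(rng, n=100, m=20)
    miss = rng.random((100, 20)) < 0.08
    ds.calls[miss] = MISSING
    strict = QcThresholds(max_snp_missing=0.05)
    loose = QcThresholds(max_snp_missing=0.15)
    _, r_strict = apply_qc(ds, strict)
    _, r_loose = apply_qc(ds, loose)
    assert len(r_loose.excluded_snps) <= len(r_strict.excluded_snps)
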