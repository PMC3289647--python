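"""Candidate panel assembly, LD proxies and nearest-gene annotation."""

import logging

import pytest

from erevar.intervals import GenomicInterval, IntervalSet
from erevar.snp_select import (
    CandidateSnp,
    GeneModel,
    LdRecord,
    SnpRecord,
    annotate_nearest_gene,
    assemble_candidates,
    find_proxies,
    read_ld_table,
    read_map,
    snps_in_regions,
)


def _cand(rsid, pos=100, chrom="chr1", provenance="consensus_region"):
    return CandidateSnp(SnpRecord(rsid, chrom, pos), provenance)


# ---------------------------------------------------------------------------
# MAP reading and region membership


def test_read_map(tmp_path):
    p = tmp_path / "a.map"
    p.write_text("1\trs1\t0\t100\n2\trs2\t0\t50\n")
    snps = read_map(p)
    assert [(s.rsid, s.chrom, s.pos_1based) for s in snps] == [("rs1", "1", 100), ("rs2", "2", 50)]


def test_read_map_duplicate_rsid_errors(tmp_path):
    p = tmp_path / "d.map"
    p.write_text("1 rs1 0 100\n1 rs1 0 200\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_map(p)


def test_snps_in_regions_membership():
    regions = IntervalSet([GenomicInterval("chr1", 10, 20)])
    snps = [SnpRecord("rs1", "chr1", 15), SnpRecord("rs2", "chr1", 25), SnpRecord("rs3", "chr2", 15)]
    cands = snps_in_regions(snps, regions, "consensus_region")
    assert [c.snp.rsid for c in cands] == ["rs1"]
    assert cands[0].provenance == "consensus_region"
    assert snps_in_regions(snps, IntervalSet([]), "consensus_region") == []


def test_snps_in_regions_matches_linear_scan(rng):
    ivs = [
        GenomicInterval("chr1", int(s), int(s) + int(l))
        for s, l in zip(rng.integers(0, 5000, 20), rng.integers(1, 300, 20))
    ]
    regions = IntervalSet(ivs)
    snps = [SnpRecord(f"rs{i}", "chr1", int(p)) for i, p in enumerate(rng.integers(1, 5500, 100))]
    got = {c.snp.rsid for c in snps_in_regions(snps, regions, "consensus_region")}
    expected = {
        s.rsid for s in snps if any(iv.start <= s.pos_1based - 1 < iv.end for iv in ivs)
    }
    assert got == expected


# ---------------------------------------------------------------------------
# LD table


def test_read_ld_table_well_formed(tmp_path):
    p = tmp_path / "ld.txt"
    p.write_text("100 200 CEU rs1 rs2 1.0 0.95 5.1\n")
    (rec,) = read_ld_table(p)
    assert (rec.rsid_a, rec.rsid_b, rec.r2) == ("rs1", "rs2", 0.95)


def test_read_ld_table_empty(tmp_path):
    p = tmp_path / "ld.txt"
    p.write_text("")
    assert read_ld_table(p) == []


def test_read_ld_table_malformed_line_named(tmp_path):
    p = tmp_path / "ld.txt"
    lines = ["100 200 CEU rs1 rs2 1.0 0.95 5.1\n"] * 5
    lines[3] = "100 200 CEU rs1 rs2 1.0\n"  # line 4 short
    p.write_text("".join(lines))
    with pytest.raises(ValueError, match=":4"):
        read_ld_table(p)


def test_read_ld_table_r2_range(tmp_path):
    p = tmp_path / "ld.txt"
    p.write_text("100 200 CEU rs1 rs2 1.0 1.5 5.1\n")
    with pytest.raises(ValueError, match="r2"):
        read_ld_table(p)


# ---------------------------------------------------------------------------
# Proxy substitution


def test_genotyped_candidate_passes_through():
    cand = _cand("rs1")
    out = find_proxies([cand], {"rs1"}, [])
    assert out == [cand]


def test_best_r2_proxy_chosen():
    cand = _cand("rs1")
    ld = [
        LdRecord("rs1", "rsA", 0.90, pos_a=100, pos_b=200),
        LdRecord("rs1", "rsB", 0.95, pos_a=100, pos_b=900),
    ]
    (out,) = find_proxies([cand], {"rsA", "rsB"}, ld)
    assert out.snp.rsid == "rsB" and out.proxy_r2 == 0.95
    assert out.provenance == "ld_proxy" and out.proxy_source == "rs1"


def test_proxy_tie_breaks_distance_then_rsid():
    cand = _cand("rs1")
    ld = [
        LdRecord("rs1", "rsFar", 0.95, pos_a=100, pos_b=9000),
        LdRecord("rs1", "rsNear", 0.95, pos_a=100, pos_b=300),
    ]
    (out,) = find_proxies([cand], {"rsFar", "rsNear"}, ld)
    assert out.snp.rsid == "rsNear"
    ld = [
        LdRecord("rs1", "rsB", 0.95, pos_a=100, pos_b=300),
        LdRecord("rs1", "rsA", 0.95, pos_a=100, pos_b=300),
    ]
    (out,) = find_proxies([cand], {"rsA", "rsB"}, ld)
    assert out.snp.rsid == "rsA"


def test_unproxied_candidate_dropped_and_logged(caplog):
    cand = _cand("rs1")
    ld = [LdRecord("rs1", "rsA", 0.5, pos_a=100, pos_b=200)]
    with caplog.at_level(logging.INFO, logger="erevar.snp_select"):
        out = find_proxies([cand], {"rsA"}, ld)
    assert out == []
    assert "rs1" in caplog.text


def test_symmetric_lookup_both_orderings():
    cand = _cand("rs1")
    ld = [LdRecord("rsA", "rs1", 0.93, pos_a=200, pos_b=100)]  # candidate second
    (out,) = find_proxies([cand], {"rsA"}, ld)
    assert out.snp.rsid == "rsA"


def test_find_proxies_matches_exhaustive_search(rng):
    """Random candidates/LD pairs against a brute-force oracle."""
    rsids = [f"rs{i}" for i in range(30)]
    positions = {r: int(p) for r, p in zip(rsids, rng.integers(1, 10_000, 30))}
    genotyped = set(rng.choice(rsids, size=15, replace=False))
    candidates = [
        CandidateSnp(SnpRecord(r, "chr1", positions[r]), "consensus_region")
        for r in rng.choice(rsids, size=20, replace=False)
    ]
    ld = []
    for _ in range(60):
        a, b = rng.choice(rsids, size=2, replace=False)
        ld.append(
            LdRecord(str(a), str(b), float(rng.uniform(0.5, 1.0)), pos_a=positions[a], pos_b=positions[b])
        )
    out = find_proxies(candidates, genotyped, ld, r2_min=0.89)
    out_by_source = {
        c.proxy_source: (c.snp.rsid, c.proxy_r2) for c in out if c.provenance == "ld_proxy"
    }
    passthrough = {c.snp.rsid for c in out if c.provenance != "ld_proxy"}
    for cand in candidates:
        r = cand.snp.rsid
        if r in genotyped:
            assert r in passthrough
            continue
        pool = [
            (q.rsid_b if q.rsid_a == r else q.rsid_a, q.r2, abs(q.pos_a - q.pos_b))
            for q in ld
            if r in (q.rsid_a, q.rsid_b)
        ]
        pool = [(p, r2, d) for p, r2, d in pool if p in genotyped and r2 >= 0.89]
        if not pool:
            assert r not in out_by_source
        else:
            best = min(pool, key=lambda q: (-q[1], q[2], q[0]))
            assert out_by_source[r] == (best[0], best[1])
    # invariants: no proxy below threshold, proxies all genotyped
    for c in out:
        if c.provenance == "ld_proxy":
            assert c.proxy_r2 >= 0.89 and c.snp.rsid in genotyped


# ---------------------------------------------------------------------------
# Panel assembly


def test_assemble_disjoint_groups():
    a = [_cand("rs1", 100), _cand("rs2", 200)]
    b = [_cand("rs3", 300, provenance="ere_halfsite"), _cand("rs4", 400, provenance="ere_halfsite"), _cand("rs5", 500, provenance="ere_halfsite")]
    assert len(assemble_candidates(a, b)) == 5


def test_assemble_dedup_consensus_wins():
    a = [_cand("rs1", 100)]
    b = [_cand("rs1", 100, provenance="ere_halfsite")]
    (out,) = assemble_candidates(a, b)
    assert out.provenance == "consensus_region"
    assert out.secondary_provenance == "ere_halfsite"
    # commutative up to provenance priority
    (out2,) = assemble_candidates(b, a)
    assert out2.provenance == "consensus_region"


def test_assemble_union_size_and_idempotence(rng):
    pool = [f"rs{i}" for i in range(40)]
    a = [_cand(str(r), 10 * i + 1) for i, r in enumerate(rng.choice(pool, 25, replace=False))]
    b = [
        _cand(str(r), 10 * i + 5, provenance="ere_halfsite")
        for i, r in enumerate(rng.choice(pool, 25, replace=False))
    ]
    out = assemble_candidates(a, b)
    assert len(out) == len({c.snp.rsid for c in a} | {c.snp.rsid for c in b})
    assert len(out) <= len(a) + len(b)
    again = assemble_candidates(out, [])
    assert [c.snp.rsid for c in again] == [c.snp.rsid for c in out]
    # sorted by chrom/pos
    keys = [(c.snp.chrom, c.snp.pos_1based) for c in out]
    assert keys == sorted(keys)


# ---------------------------------------------------------------------------
# Nearest-gene annotation


GENES = [
    GeneModel("FWD", "chr1", 1000, 2000, "+"),
    GeneModel("REV", "chr1", 5000, 6000, "-"),
]


def test_annotation_within_gene():
    ann = annotate_nearest_gene(SnpRecord("rs1", "chr1", 1500), GENES)
    assert (ann.gene, ann.relation, ann.distance_bp) == ("FWD", "within", 0)


def test_annotation_downstream_plus_strand():
    # 100 bp past the 3' end of the + strand gene (end-exclusive 2000)
    ann = annotate_nearest_gene(SnpRecord("rs1", "chr1", 2100), GENES)
    assert (ann.gene, ann.relation, ann.distance_bp) == ("FWD", "downstream", 100)


def test_annotation_strand_aware_between_genes():
    # position 0-based 4600: 2601 bp past FWD end, 400 bp before REV start;
    # REV is nearer, and "before a - strand gene's start" is downstream.
    ann = annotate_nearest_gene(SnpRecord("rs1", "chr1", 4601), GENES)
    assert (ann.gene, ann.relation) == ("REV", "downstream")
    assert ann.distance_bp == 400
    # past the - strand gene's end = upstream
    ann = annotate_nearest_gene(SnpRecord("rs1", "chr1", 6050), GENES)
    assert (ann.gene, ann.relation, ann.distance_bp) == ("REV", "upstream", 50)


def test_annotation_no_gene_on_chromosome():
    ann = annotate_nearest_gene(SnpRecord("rs1", "chrX", 100), GENES)
    assert ann.relation == "none"
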