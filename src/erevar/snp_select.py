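"""Candidate SNP panel assembly and LD-proxy substitution.

Two candidate sources are combined: SNPs inside the three-way ChIP
consensus regions, and ERE-half-site-disrupting SNPs supported by any one
ChIP study.  Candidates absent from the genotyped panel are replaced by
the genotyped SNP in highest linkage disequilibrium with them, subject to
an r-squared floor (default 0.89, inclusive).  A light strand-aware
nearest-gene annotation supports reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .intervals import IntervalSet, make_position_index

logger = logging.getLogger(__name__)

#: Inclusive r-squared floor for accepting a genotyped proxy.
DEFAULT_R2_MIN = 0.89


@dataclass(frozen=True)
class SnpRecord:
    rsid: str
    chrom: str
    pos_1based: int
    alleles: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.pos_1based < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1")


@dataclass
class CandidateSnp:
    """A panel member with provenance.

    ``provenance`` is ``consensus_region`` (inside the three-way ChIP
    consensus), ``ere_halfsite`` (half-site-disrupting SNP in any ChIP
    region) or ``ld_proxy`` (genotyped stand-in; ``proxy_source`` and
    ``proxy_r2`` then identify the original candidate and its LD).
    """

    snp: SnpRecord
    provenance: str
    proxy_source: str | None = None
    proxy_r2: float | None = None
    secondary_provenance: str | None = None

    def __post_init__(self) -> None:
        if self.provenance not in {"consensus_region", "ere_halfsite", "ld_proxy"}:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if (self.provenance == "ld_proxy") != (
            self.proxy_source is not None and self.proxy_r2 is not None
        ):
            raise ValueError("ld_proxy requires proxy_source and proxy_r2 (and only then)")


@dataclass(frozen=True)
class LdRecord:
    """One pairwise LD entry; the pair is unordered (a<->b equivalent)."""

    rsid_a: str
    rsid_b: str
    r2: float
    pos_a: int | None = None
    pos_b: int | None = None
    dprime: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 out of [0,1]: {self.r2}")


@dataclass(frozen=True)
class GeneModel:
    name: str
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name}: start >= end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.name}: strand must be + or -")


def read_map(path: str | Path) -> list[SnpRecord]:
    """PLINK MAP: chrom, rsid, genetic distance (ignored), 1-based bp."""
    path = Path(path)
    snps: list[SnpRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 MAP columns")
            chrom, rsid, _cm, bp = fields[:4]
            if rsid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate rsid {rsid}")
            seen.add(rsid)
            try:
                pos = int(bp)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric position {bp!r}") from exc
            snps.append(SnpRecord(rsid, chrom, pos))
    return snps


def write_map(snps: Sequence[SnpRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in snps:
            fh.write(f"{s.chrom}\t{s.rsid}\t0\t{s.pos_1based}\n")


def snps_in_regions(
    snps: Iterable[SnpRecord], regions: IntervalSet, provenance: str
) -> list[CandidateSnp]:
    """Candidates = SNPs whose 1-based position lies inside ``regions``."""
    index = make_position_index(regions)
    return [
        CandidateSnp(snp, provenance)
        for snp in snps
        if index.covers(snp.chrom, snp.pos_1based - 1)
    ]


def read_ld_table(path: str | Path) -> list[LdRecord]:
    """HapMap pairwise-LD text: pos1 pos2 population rsid_a rsid_b dprime r2 lod."""
    path = Path(path)
    records: list[LdRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.split()
            if len(fields) < 8:
                raise ValueError(
                    f"{path}:{lineno}: expected 8 whitespace-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                pos_a, pos_b = int(fields[0]), int(fields[1])
                dprime, r2 = float(fields[5]), float(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"{path}:{lineno}: r2 {r2} outside [0,1]")
            records.append(
                LdRecord(fields[3], fields[4], r2, pos_a=pos_a, pos_b=pos_b, dprime=dprime)
            )
    return records


def write_ld_table(records: Sequence[LdRecord], path: str | Path, population: str = "CEU") -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.pos_a or 0} {r.pos_b or 0} {population} {r.rsid_a} {r.rsid_b} "
                f"{r.dprime if r.dprime is not None else 1.0:.3f} {r.r2:.4f} 0.0\n"
            )


def find_proxies(
    candidates: Sequence[CandidateSnp],
    genotyped: set[str],
    ld: Sequence[LdRecord],
    r2_min: float = DEFAULT_R2_MIN,
) -> list[CandidateSnp]:
    """Substitute genotyped LD proxies for ungenotyped candidates.

    Genotyped candidates pass through unchanged.  For each ungenotyped
    candidate the genotyped partner with maximal r2 >= ``r2_min`` is added
    as an ``ld_proxy`` candidate (ties broken by smaller base-pair
    distance, then lexicographic rsid).  Candidates with no qualifying
    proxy are dropped and logged.  A proxy may stand in for more than one
    source SNP.
    """
    if not 0.0 < r2_min <= 1.0:
        raise ValueError(f"r2_min must be in (0,1], got {r2_min}")
    # neighbours[rsid] = list of (partner, r2, distance)
    neighbours: dict[str, list[tuple[str, float, int]]] = {}
    for rec in ld:
        dist = (
            abs(rec.pos_a - rec.pos_b)
            if rec.pos_a is not None and rec.pos_b is not None
            else 0
        )
        neighbours.setdefault(rec.rsid_a, []).append((rec.rsid_b, rec.r2, dist))
        neighbours.setdefault(rec.rsid_b, []).append((rec.rsid_a, rec.r2, dist))

    out: list[CandidateSnp] = []
    for cand in candidates:
        if cand.snp.rsid in genotyped:
            out.append(cand)
            continue
        qualifying = [
            (partner, r2, dist)
            for partner, r2, dist in neighbours.get(cand.snp.rsid, [])
            if partner in genotyped and r2 >= r2_min
        ]
        if not qualifying:
            logger.info(
                "candidate %s not genotyped and no proxy with r2 >= %.3f; dropped",
                cand.snp.rsid,
                r2_min,
            )
            continue
        best = min(qualifying, key=lambda q: (-q[1], q[2], q[0]))
        out.append(
            CandidateSnp(
                SnpRecord(best[0], cand.snp.chrom, cand.snp.pos_1based),
                "ld_proxy",
                proxy_source=cand.snp.rsid,
                proxy_r2=best[1],
            )
        )
    return out


def assemble_candidates(
    group_a: Sequence[CandidateSnp], group_b: Sequence[CandidateSnp]
) -> list[CandidateSnp]:
    """Union by rsid; consensus-region provenance wins over ere_halfsite.

    When a SNP appears in both groups the consensus-region record is kept
    and the other provenance is recorded secondarily.  Output is
    deduplicated and sorted by (chrom, position, rsid).
    """
    priority = {"consensus_region": 0, "ere_halfsite": 1, "ld_proxy": 2}
    by_rsid: dict[str, CandidateSnp] = {}
    for cand in list(group_a) + list(group_b):
        cur = by_rsid.get(cand.snp.rsid)
        if cur is None:
            by_rsid[cand.snp.rsid] = cand
        elif priority[cand.provenance] < priority[cur.provenance]:
            cand.secondary_provenance = cur.provenance
            by_rsid[cand.snp.rsid] = cand
        elif cand.provenance != cur.provenance:
            cur.secondary_provenance = cand.provenance
    return sorted(
        by_rsid.values(), key=lambda c: (c.snp.chrom, c.snp.pos_1based, c.snp.rsid)
    )


@dataclass(frozen=True)
class GeneAnnotation:
    gene: str | None
    relation: str  # within | upstream | downstream | none
    distance_bp: int


def annotate_nearest_gene(
    snp: SnpRecord, genes: Sequence[GeneModel]
) -> GeneAnnotation:
    """Nearest gene by boundary distance, strand-aware up/downstream.

    Distance is 0 when the SNP lies inside the gene; otherwise base pairs
    from the nearest gene boundary.  For a forward-strand gene, positions
    below its start are upstream and positions beyond its end downstream;
    for a reverse-strand gene the senses swap.
    """
    pos0 = snp.pos_1based - 1
    same_chrom = [g for g in genes if g.chrom == snp.chrom]
    if not same_chrom:
        return GeneAnnotation(None, "none", -1)
    best: tuple[int, str, str] | None = None  # (distance, relation, gene name)
    for g in same_chrom:
        if g.start <= pos0 < g.end:
            return GeneAnnotation(g.name, "within", 0)
        if pos0 < g.start:
            dist = g.start - pos0
            relation = "upstream" if g.strand == "+" else "downstream"
        else:
            dist = pos0 - (g.end - 1)
            relation = "downstream" if g.strand == "+" else "upstream"
        key = (dist, relation, g.name)
        if best is None or key < best:
            best = key
    assert best is not None
    return GeneAnnotation(best[2], best[1], best[0])


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """BED6 gene models: chrom, start, end, name, score (ignored), strand."""
    path = Path(path)
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            fields = raw.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected BED6 (6 columns)")
            genes.append(
                GeneModel(fields[3], fields[0], int(fields[1]), int(fields[2]), fields[5])
            )
    return genes


def write_candidates_tsv(candidates: Sequence[CandidateSnp], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos\tprovenance\tsecondary\tproxy_source\tproxy_r2\n")
        for c in candidates:
            fh.write(
                f"{c.snp.rsid}\t{c.snp.chrom}\t{c.snp.pos_1based}\t{c.provenance}\t"
                f"{c.secondary_provenance or '.'}\t{c.proxy_source or '.'}\t"
                f"{'.' if c.proxy_r2 is None else f'{c.proxy_r2:.4f}'}\n"
            )
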