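"""Synthetic inputs with known ground truth for the whole pipeline.

The generator emits every file the analysis consumes — an IUPAC-masked
genome, three ChIP binding-region BED sets, a SNP map, pairwise LD text,
and case-control PED/MAP per disease — together with a truth record of
what was planted where.  Default cohort sizes reproduce the study
conditions: bipolar disorder 487/490 female and 477/508 male
cases/controls; major depression 1200/1076 female and 527/682 male.

Layout is controlled by a slot grid: features (planted motifs, SNP
positions, ChIP-region anchors) occupy distinct slots 250 bp apart, and
region-bearing slots are spaced >=500 bp so that intervals from
different loci never touch.  Background sequence is scrubbed of
accidental motif copies, so every motif hit and every consensus interval
is planted and recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .ere_scan import IUPAC_CODES, MaskedSequence
from .genotype_qc import GenotypeDataset, Individual, write_ped_map
from .snp_select import LdRecord, SnpRecord, write_ld_table, write_map

_SLOT_SPACING = 250
_CORE_HALF = 100  # consensus core reaches anchor +/- this
_MAX_EXT = 120  # per-set extension beyond the core

_CODE_FOR_PAIR = {frozenset(v): k for k, v in IUPAC_CODES.items() if len(v) == 2}

#: Study-condition cohort sizes: disease -> sex -> (n_cases, n_controls).
DEFAULT_COHORTS: dict[str, dict[str, tuple[int, int]]] = {
    "bipolar": {"female": (487, 490), "male": (477, 508)},
    "depression": {"female": (1200, 1076), "male": (527, 682)},
}


@dataclass
class SimConfig:
    seed: int = 17
    n_chroms: int = 2
    chrom_length: int = 100_000
    n_snps: int = 300
    n_planted_halfsites: int = 60
    fraction_disrupting: float = 0.5
    region_count: int = 40  # per ChIP source
    triple_overlap_fraction: float = 0.4
    n_double_loci: int = 6
    n_ld_noise_pairs: int = 30
    fraction_ungenotyped: float = 0.2
    cohorts: dict[str, dict[str, tuple[int, int]]] = field(
        default_factory=lambda: {
            d: dict(v) for d, v in DEFAULT_COHORTS.items()
        }
    )
    n_causal: int = 1
    planted_or: float = 0.6
    causal_strata: tuple[tuple[str, str], ...] = (("bipolar", "female"),)
    base_maf_range: tuple[float, float] = (0.05, 0.5)
    causal_maf: float = 0.35  # causal SNPs are common variants
    missing_rate_person: float = 0.01
    missing_rate_snp: float = 0.01
    n_high_missing_persons: int = 1
    high_missing_person_rate: float = 0.5
    n_high_missing_snps: int = 1
    high_missing_snp_rate: float = 0.2
    n_hwe_violators: int = 2
    hwe_het_excess: float = 0.35

    def __post_init__(self) -> None:
        for name in ("fraction_disrupting", "triple_overlap_fraction", "fraction_ungenotyped"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.planted_or <= 0:
            raise ValueError("planted_or must be positive")
        if self.chrom_length < 10 * self.n_planted_halfsites * 5:
            raise ValueError("chromosomes too short for the requested motif packing")
        for disease, by_sex in self.cohorts.items():
            for sex, (ncase, nctrl) in by_sex.items():
                if min(ncase, nctrl) < 2:
                    raise ValueError(f"{disease}/{sex}: cohort sizes must be >= 2")


@dataclass
class SimTruth:
    """Ground truth for every planted feature, JSON-serialisable."""

    planted_hits: list[dict] = field(default_factory=list)
    consensus_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    snps: list[dict] = field(default_factory=list)  # universe with flags
    candidate_rsids: list[str] = field(default_factory=list)
    ungenotyped_rsids: list[str] = field(default_factory=list)
    proxy_map: dict[str, tuple[str, float] | None] = field(default_factory=dict)
    causal: dict[str, dict] = field(default_factory=dict)
    hwe_violators: list[str] = field(default_factory=list)
    high_missing_snps: list[str] = field(default_factory=list)
    high_missing_persons: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)

    def snp_records(self, genotyped_only: bool = False) -> list[SnpRecord]:
        return [
            SnpRecord(s["rsid"], s["chrom"], s["pos_1based"], tuple(s["alleles"]))
            for s in self.snps
            if s["genotyped"] or not genotyped_only
        ]


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2**31), stage])


def _scrub_exact_motifs(
    seq: list[str], protected: set[int], rng: np.random.Generator
) -> None:
    """Destroy accidental GGTCA/TGACC copies outside protected spans."""
    bases = "ACGT"
    for _ in range(50):
        dirty = False
        s = "".join(seq)
        for motif in ("GGTCA", "TGACC"):
            start = s.find(motif)
            while start != -1:
                free = [i for i in range(start, start + 5) if i not in protected]
                if free:
                    i = free[len(free) // 2]
                    old = seq[i]
                    seq[i] = bases[int(rng.integers(4))]
                    if seq[i] == old:
                        seq[i] = bases[(bases.index(old) + 1) % 4]
                    dirty = True
                start = s.find(motif, start + 1)
        if not dirty:
            return
    raise RuntimeError("could not scrub accidental motif copies")


def _window_matches_local(window: str, pattern: str) -> bool:
    if len(window) != len(pattern):
        return False
    return all(p == "n" or p in IUPAC_CODES[w] for w, p in zip(window, pattern))


def _has_unplanted_match(seq: list[str], center: int, planted_starts: set[int]) -> bool:
    n = len(seq)
    for start in range(max(0, center - 4), min(n - 5, center) + 1):
        if start in planted_starts:
            continue
        window = "".join(seq[start : start + 5])
        if _window_matches_local(window, "GGTCA") or _window_matches_local(window, "TGACC"):
            return True
    return False


def simulate_genome(cfg: SimConfig) -> tuple[list[MaskedSequence], SimTruth]:
    """Masked genome with planted half-sites, SNP universe and ChIP plan.

    Also decides — so that downstream generators agree with the genome —
    which slots host ChIP loci, which SNPs are candidates, which are
    genotyped, causal, HWE-violating or high-missing.  The truth record
    is completed by :func:`simulate_chip_sets`, :func:`simulate_ld_table`
    and :func:`simulate_genotype_dataset`.
    """
    rng = _rng(cfg, 0)
    truth = SimTruth()
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    seqs: dict[str, list[str]] = {
        c: list(map(str, rng.choice(list("ACGT"), size=cfg.chrom_length)))
        for c in chroms
    }
    for c in chroms:
        _scrub_exact_motifs(seqs[c], set(), rng)

    # Slot grid: even slots may host ChIP loci (>=500 bp apart), odd slots
    # host free (out-of-region) features.
    locus_slots: list[tuple[str, int]] = []
    free_slots: list[tuple[str, int]] = []
    for c in chroms:
        # anchors stay >= 300 from either end: locus reach is +/- 220
        positions = list(range(300, cfg.chrom_length - 300, _SLOT_SPACING))
        for k, pos in enumerate(positions):
            (locus_slots if k % 2 == 0 else free_slots).append((c, pos))
    locus_slots = [locus_slots[i] for i in rng.permutation(len(locus_slots))]
    free_slots = [free_slots[i] for i in rng.permutation(len(free_slots))]

    n_disrupt = round(cfg.n_planted_halfsites * cfg.fraction_disrupting)
    n_exact = cfg.n_planted_halfsites - n_disrupt
    n_triple = round(cfg.region_count * cfg.triple_overlap_fraction)
    n_double = min(cfg.n_double_loci, cfg.region_count - n_triple)

    # Assign locus slots: first triple loci, then double, then singles;
    # every set gets region_count loci: n_triple triple + n_double double
    # (each double shared by 2 of 3 sets, rotating) + singles to fill.
    pair_cycle = [(0, 1), (1, 2), (0, 2)]
    loci: list[dict] = []
    for i in range(n_triple):
        loci.append({"sets": (0, 1, 2)})
    for i in range(n_double):
        loci.append({"sets": pair_cycle[i % 3]})
    singles_needed = {k: cfg.region_count - sum(k in l["sets"] for l in loci) for k in range(3)}
    for k in range(3):
        for _ in range(max(singles_needed[k], 0)):
            loci.append({"sets": (k,)})
    if len(loci) > len(locus_slots):
        raise ValueError("infeasible packing: not enough locus slots")
    for locus, slot in zip(loci, locus_slots):
        locus["chrom"], locus["anchor"] = slot

    triple_loci = [l for l in loci if len(l["sets"]) == 3]
    other_loci = [l for l in loci if len(l["sets"]) < 3]

    # Disrupting motifs: thirds into triple loci, other loci, outside
    # regions (capped by what exists); decoy SNPs likewise.
    n_dis_triple = min(n_disrupt // 3, len(triple_loci))
    n_dis_other = min(n_disrupt // 3, len(other_loci))
    n_dis_free = n_disrupt - n_dis_triple - n_dis_other
    n_decoy = cfg.n_snps - n_disrupt
    n_dec_triple = min(len(triple_loci) - n_dis_triple, max(n_decoy // 8, 1), n_decoy)
    n_dec_other = min(n_decoy // 8, 10, len(other_loci) - n_dis_other)
    n_dec_free = n_decoy - n_dec_triple - n_dec_other
    if n_dec_free < 0 or len(free_slots) < n_dis_free + n_dec_free + n_exact:
        raise ValueError("infeasible packing: not enough free slots")

    def plant_motif(chrom: str, pos: int, disrupting: bool, planted_starts: dict[str, set[int]]):
        seq = seqs[chrom]
        pattern = ("GGTCA", "TGACC")[int(rng.integers(2))]
        masked_offset = None
        code = None
        window = list(pattern)
        if disrupting:
            masked_offset = int(rng.integers(5))
            consensus_base = pattern[masked_offset]
            alt = rng.choice([b for b in "ACGT" if b != consensus_base])
            code = _CODE_FOR_PAIR[frozenset({consensus_base, str(alt)})]
            window[masked_offset] = code
        seq[pos : pos + 5] = window
        planted_starts[chrom].add(pos)
        for _ in range(30):
            if not _has_unplanted_match(seq, pos + 2, planted_starts[chrom]):
                break
            # mutate a flanking base to break the accidental overlap match
            flank = [i for i in range(max(0, pos - 4), min(len(seq), pos + 9)) if not pos <= i < pos + 5]
            i = int(rng.choice(flank))
            seq[i] = "ACGT"[int(rng.integers(4))]
        else:
            raise RuntimeError("could not isolate planted motif")
        truth.planted_hits.append(
            {
                "chrom": chrom,
                "start": pos,
                "end": pos + 5,
                "pattern": pattern,
                "disrupting": disrupting,
                "masked_offset": masked_offset,
            }
        )
        if disrupting:
            alleles = tuple(sorted(IUPAC_CODES[code]))
            return {"chrom": chrom, "pos0": pos + masked_offset, "alleles": alleles, "code": code, "disrupting": True}
        return None

    def plant_decoy(chrom: str, pos: int) -> dict:
        seq = seqs[chrom]
        for _ in range(30):
            pair = frozenset(rng.choice(list("ACGT"), size=2, replace=False).tolist())
            code = _CODE_FOR_PAIR[pair]
            old = seq[pos]
            seq[pos] = code
            if not _has_unplanted_match(seq, pos, planted_starts[chrom]):
                break
            seq[pos] = old
        else:
            raise RuntimeError("could not place decoy mask")
        return {"chrom": chrom, "pos0": pos, "alleles": tuple(sorted(pair)), "code": code, "disrupting": False}

    planted_starts: dict[str, set[int]] = {c: set() for c in chroms}
    universe: list[dict] = []  # snp dicts with placement flags

    def place(slot: tuple[str, int], kind: str, locus: dict | None) -> None:
        chrom, pos = slot
        in_triple = locus is not None and len(locus["sets"]) == 3
        in_any = locus is not None
        if kind in ("disrupt", "exact"):
            rec = plant_motif(chrom, pos, kind == "disrupt", planted_starts)
        else:
            rec = plant_decoy(chrom, pos)
        if rec is not None:
            rec.update(in_consensus=in_triple, in_union=in_any)
            universe.append(rec)
        if locus is not None:
            locus["snp_pos0"] = pos

    li = iter(triple_loci)
    for _ in range(n_dis_triple):
        locus = next(li)
        place((locus["chrom"], locus["anchor"]), "disrupt", locus)
    for _ in range(n_dec_triple):
        locus = next(li)
        place((locus["chrom"], locus["anchor"]), "decoy", locus)
    oi = iter(other_loci)
    for _ in range(n_dis_other):
        locus = next(oi)
        place((locus["chrom"], locus["anchor"]), "disrupt", locus)
    for _ in range(n_dec_other):
        locus = next(oi)
        place((locus["chrom"], locus["anchor"]), "decoy", locus)
    fi = iter(free_slots)
    for _ in range(n_dis_free):
        place(next(fi), "disrupt", None)
    for _ in range(n_exact):
        place(next(fi), "exact", None)
    for _ in range(n_dec_free):
        place(next(fi), "decoy", None)

    # rsids ordered by genomic position.
    universe.sort(key=lambda s: (s["chrom"], s["pos0"]))
    for i, s in enumerate(universe):
        s["rsid"] = f"rs{100000 + i}"
        s["pos_1based"] = s["pos0"] + 1

    # Candidate panel per the selection rules (recorded, later verified by
    # the pipeline): consensus SNPs plus disrupting SNPs in any ChIP region.
    candidates = [s for s in universe if s["in_consensus"] or (s["disrupting"] and s["in_union"])]
    truth.candidate_rsids = [s["rsid"] for s in candidates]

    # Genotyping status: a fraction of candidates is ungenotyped (needing
    # LD proxies); everything else is genotyped.
    n_ungeno = max(2, round(len(candidates) * cfg.fraction_ungenotyped)) if cfg.fraction_ungenotyped > 0 else 0
    n_ungeno = min(n_ungeno, max(len(candidates) - cfg.n_causal - cfg.n_hwe_violators - cfg.n_high_missing_snps - 1, 0))
    ungeno_idx = rng.choice(len(candidates), size=n_ungeno, replace=False) if n_ungeno else []
    ungenotyped = {candidates[int(i)]["rsid"] for i in ungeno_idx}
    for s in universe:
        s["genotyped"] = s["rsid"] not in ungenotyped
    truth.ungenotyped_rsids = sorted(ungenotyped)

    # Planted association signal and QC violators among genotyped candidates.
    geno_cands = [s for s in candidates if s["genotyped"]]
    dis_triple_geno = [s for s in geno_cands if s["disrupting"] and s["in_consensus"]]
    pool = dis_triple_geno + [s for s in geno_cands if s not in dis_triple_geno]
    causal = pool[: cfg.n_causal]
    for s in causal:
        truth.causal[s["rsid"]] = {
            "or": cfg.planted_or,
            "strata": [list(st) for st in cfg.causal_strata],
        }
    rest = [s for s in geno_cands if s["rsid"] not in truth.causal]
    truth.hwe_violators = [s["rsid"] for s in rest[: cfg.n_hwe_violators]]
    rest = rest[cfg.n_hwe_violators :]
    truth.high_missing_snps = [s["rsid"] for s in rest[: cfg.n_high_missing_snps]]

    truth.snps = universe
    # Stash the locus plan for simulate_chip_sets (not serialised per-locus).
    truth._loci = loci  # type: ignore[attr-defined]

    masked = [MaskedSequence(c, "".join(seqs[c])) for c in chroms]
    return masked, truth


def simulate_chip_sets(cfg: SimConfig, truth: SimTruth) -> list[list[tuple[str, int, int]]]:
    """Three interval lists; records the true three-way consensus.

    Each locus contributes one interval to every covering set: the core
    (anchor +/- 100) extended independently per set by up to 120 bp each
    side.  The true consensus of a triple locus is [max starts, min ends],
    computed arithmetically here rather than by the interval sweep.
    """
    rng = _rng(cfg, 1)
    loci = getattr(truth, "_loci")
    sets: list[list[tuple[str, int, int]]] = [[], [], []]
    consensus: list[tuple[str, int, int]] = []
    for locus in loci:
        anchor, chrom = locus["anchor"], locus["chrom"]
        starts, ends = [], []
        for k in locus["sets"]:
            ext_l, ext_r = rng.integers(0, _MAX_EXT + 1, size=2)
            start, end = anchor - _CORE_HALF - int(ext_l), anchor + _CORE_HALF + int(ext_r)
            sets[k].append((chrom, start, end))
            starts.append(start)
            ends.append(end)
        if len(locus["sets"]) == 3:
            consensus.append((chrom, max(starts), min(ends)))
    truth.consensus_intervals = sorted(consensus)
    return [sorted(s) for s in sets]


def simulate_ld_table(cfg: SimConfig, truth: SimTruth) -> list[LdRecord]:
    """Pairwise LD straddling the 0.89 proxy threshold.

    Every ungenotyped candidate gets exactly one genotyped LD partner;
    partners alternate between qualifying (r2 in [0.90, 0.99]) and
    non-qualifying (r2 in [0.30, 0.85]), so at least one candidate is
    proxied and at least one is dropped.  Extra noise pairs between
    genotyped non-candidates straddle the threshold too.
    """
    rng = _rng(cfg, 2)
    by_rsid = {s["rsid"]: s for s in truth.snps}
    geno_noncand = [
        s for s in truth.snps if s["genotyped"] and s["rsid"] not in set(truth.candidate_rsids)
    ]
    records: list[LdRecord] = []
    for i, rsid in enumerate(truth.ungenotyped_rsids):
        cand = by_rsid[rsid]
        partners = [s for s in geno_noncand if s["chrom"] == cand["chrom"]] or geno_noncand
        partner = partners[int(rng.integers(len(partners)))]
        qualifying = i % 2 == 0
        r2 = float(rng.uniform(0.90, 0.99)) if qualifying else float(rng.uniform(0.30, 0.85))
        records.append(
            LdRecord(
                rsid,
                partner["rsid"],
                round(r2, 4),
                pos_a=cand["pos_1based"],
                pos_b=partner["pos_1based"],
                dprime=1.0,
            )
        )
        truth.proxy_map[rsid] = (partner["rsid"], round(r2, 4)) if qualifying else None
    for _ in range(cfg.n_ld_noise_pairs):
        i, j = rng.choice(len(geno_noncand), size=2, replace=False)
        a, b = geno_noncand[int(i)], geno_noncand[int(j)]
        records.append(
            LdRecord(
                a["rsid"],
                b["rsid"],
                round(float(rng.uniform(0.1, 1.0)), 4),
                pos_a=a["pos_1based"],
                pos_b=b["pos_1based"],
                dprime=1.0,
            )
        )
    return records


def make_genotype_only_truth(
    n_snps: int, causal: dict[str, dict] | None = None
) -> SimTruth:
    """Truth with a bare genotyped SNP universe and no genome or regions.

    Supports frequency-level simulation studies (null type-I error,
    planted-OR recovery) that need genotypes but no motif/interval layer.
    ``causal`` maps rsid -> {"or": float, "strata": [[disease, sex], ...]}.
    """
    truth = SimTruth()
    truth.snps = [
        {
            "rsid": f"rs{i}",
            "chrom": "chr1",
            "pos0": 100 * i,
            "pos_1based": 100 * i + 1,
            "alleles": ("A", "G"),
            "code": "R",
            "disrupting": False,
            "in_consensus": False,
            "in_union": False,
            "genotyped": True,
        }
        for i in range(n_snps)
    ]
    truth.causal = dict(causal or {})
    return truth


def _case_freq(p0: float, odds_ratio: float) -> float:
    """Allele frequency in cases given control frequency and allelic OR."""
    return odds_ratio * p0 / (1.0 - p0 + odds_ratio * p0)


def simulate_genotype_dataset(
    cfg: SimConfig, truth: SimTruth, disease: str, stage: int = 3
) -> GenotypeDataset:
    """In-memory case-control genotypes for one disease.

    Controls draw both allele copies independently at the SNP's control
    minor-allele frequency (HWE); cases of a causal SNP's target stratum
    use the OR-shifted frequency.  Designated HWE violators get excess
    heterozygosity in controls only.  Missingness is the union of a
    per-person and a per-SNP Bernoulli mask, with planted high-missing
    persons and SNPs exceeding the QC thresholds.
    """
    # stable per-disease stream: offset by position in sorted disease list
    rng = _rng(cfg, stage + 10 * (sorted(cfg.cohorts).index(disease)))
    snps = [s for s in truth.snps if s["genotyped"]]
    n_snp = len(snps)
    individuals: list[Individual] = []
    for sex in cfg.cohorts[disease]:
        n_case, n_ctrl = cfg.cohorts[disease][sex]
        individuals += [
            Individual(f"{disease[:3]}_{sex[0]}_case_{i}", sex, "case") for i in range(n_case)
        ]
        individuals += [
            Individual(f"{disease[:3]}_{sex[0]}_ctl_{i}", sex, "control") for i in range(n_ctrl)
        ]
    n_ind = len(individuals)
    sex_arr = np.array([ind.sex for ind in individuals])
    case_arr = np.array([ind.phenotype == "case" for ind in individuals])

    p0 = rng.uniform(*cfg.base_maf_range, size=n_snp)
    for j, s in enumerate(snps):
        if s["rsid"] in truth.causal:
            # plant signal on a common variant: separates the effect-model
            # demonstration from power loss at rare frequencies
            p0[j] = cfg.causal_maf
    freq = np.tile(p0, (n_ind, 1))
    for j, s in enumerate(snps):
        info = truth.causal.get(s["rsid"])
        if info:
            for d, sex in info["strata"]:
                if d == disease:
                    rows = case_arr & (sex_arr == sex)
                    freq[rows, j] = _case_freq(p0[j], info["or"])
    calls = rng.binomial(2, freq).astype(np.int8)

    # Excess-heterozygosity HWE violators, controls only.
    violator_cols = [j for j, s in enumerate(snps) if s["rsid"] in set(truth.hwe_violators)]
    ctrl_rows = np.where(~case_arr)[0]
    for j in violator_cols:
        p = p0[j]
        h = min(0.95, 2 * p * (1 - p) + cfg.hwe_het_excess)
        w_hom1 = (1 - h) * p**2 / (p**2 + (1 - p) ** 2)
        u = rng.random(ctrl_rows.size)
        v = rng.random(ctrl_rows.size)
        g = np.where(u < h, 1, np.where(v < w_hom1 / max(1 - h, 1e-12), 2, 0))
        calls[ctrl_rows, j] = g.astype(np.int8)

    rate_person = np.full(n_ind, cfg.missing_rate_person)
    truth.high_missing_persons.setdefault(disease, [])
    for i in range(min(cfg.n_high_missing_persons, n_ind)):
        rate_person[i] = cfg.high_missing_person_rate
        truth.high_missing_persons[disease].append(individuals[i].id)
    rate_snp = np.full(n_snp, cfg.missing_rate_snp)
    for j, s in enumerate(snps):
        if s["rsid"] in set(truth.high_missing_snps):
            rate_snp[j] = cfg.high_missing_snp_rate
    miss = (rng.random((n_ind, n_snp)) < rate_person[:, None]) | (
        rng.random((n_ind, n_snp)) < rate_snp[None, :]
    )
    calls[miss] = -1

    snp_records = [
        SnpRecord(s["rsid"], s["chrom"], s["pos_1based"], tuple(s["alleles"])) for s in snps
    ]
    return GenotypeDataset(individuals, snp_records, calls)


def write_fasta(seqs: Sequence[MaskedSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.name}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def simulate_all(cfg: SimConfig, out_dir: str | Path) -> tuple[dict[str, Path], SimTruth]:
    """Generate and write every pipeline input; returns paths and truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seqs, truth = simulate_genome(cfg)
    chip_sets = simulate_chip_sets(cfg, truth)
    ld = simulate_ld_table(cfg, truth)

    paths: dict[str, Path] = {}
    paths["fasta"] = out / "genome.fa"
    write_fasta(seqs, paths["fasta"])
    for k, name in enumerate(("chip_a", "chip_b", "chip_c")):
        p = out / f"{name}.bed"
        with open(p, "w") as fh:
            for chrom, start, end in chip_sets[k]:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
        paths[name] = p
    paths["map"] = out / "snps.map"
    write_map(truth.snp_records(), paths["map"])
    paths["ld"] = out / "ld.txt"
    write_ld_table(ld, paths["ld"])
    for disease in sorted(cfg.cohorts):
        ds = simulate_genotype_dataset(cfg, truth, disease)
        ped, mp = out / f"{disease}.ped", out / f"{disease}.map"
        write_ped_map(ds, ped, mp)
        paths[f"{disease}_ped"], paths[f"{disease}_map"] = ped, mp
    paths["truth"] = out / "truth.json"
    truth.to_json(paths["truth"])
    return paths, truth
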