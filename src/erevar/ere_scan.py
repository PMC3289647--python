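"""Scan an IUPAC-masked genome for estrogen-response-element half-sites.

Estrogen-receptor dimers bind the palindromic response element
5'-GGTCAnnnTGACC-3'.  In a SNP-masked genome (known variant positions
replaced by IUPAC ambiguity codes, e.g. Y = C or T), a window matches a
half-site core when every non-wildcard consensus base is contained in the
allele set of the corresponding residue — i.e. the binding site exists
under at least one allele.  A matching window carries a potentially
*site-disrupting* SNP when some masked position admits an allele different
from the consensus base there, so the alternate allele breaks the site.

Both half-site cores (GGTCA and its reverse complement TGACC) are scanned
on the forward strand only, which covers both orientations without
double-counting palindromic placements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

# Standard IUPAC nucleotide ambiguity codes.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_allele_set(code: str) -> frozenset[str]:
    """The set of bases an IUPAC code stands for (``Y`` -> ``{C, T}``)."""
    try:
        return IUPAC_CODES[code.upper()]
    except KeyError:
        raise ValueError(f"unknown IUPAC code: {code!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MaskedSequence:
    """A named sequence over the IUPAC alphabet; ambiguous residues mark SNPs."""

    name: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MotifPattern:
    """A consensus pattern over {A,C,G,T,n}; ``n`` is an any-base wildcard."""

    label: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("empty motif consensus")
        bad = set(self.consensus) - set("ACGTn")
        if bad:
            raise ValueError(f"motif {self.label}: invalid symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.consensus)


#: The two ERE half-site cores; TGACC is the reverse complement of GGTCA.
DEFAULT_PATTERNS: tuple[MotifPattern, MotifPattern] = (
    MotifPattern("GGTCA", "GGTCA"),
    MotifPattern("TGACC", "TGACC"),
)

#: Optional full 13-bp palindromic element with a 3-bp any-base spacer.
FULL_SITE_PATTERN = MotifPattern("ERE", "GGTCAnnnTGACC")


@dataclass
class MotifHit:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    pattern_label: str
    masked_positions: list[int] = field(default_factory=list)  # offsets within hit
    disrupting: bool = False


def read_masked_fasta(path: str | Path) -> list[MaskedSequence]:
    """Read a (multi-record, line-wrapped) IUPAC-masked FASTA file.

    Residues are upper-cased; record order is preserved.  Malformed content
    raises ``ValueError`` naming the offending line; a residue outside the
    15-letter IUPAC alphabet raises naming its 1-based position.
    """
    path = Path(path)
    records: list[MaskedSequence] = []
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is not None:
            records.append(MaskedSequence(name, "".join(chunks)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}:{lineno}: sequence before any '>' header")
                chunk = line.upper()
                bad = set(chunk) - set(IUPAC_CODES)
                if bad:
                    offset = sum(len(c) for c in chunks)
                    col = next(i for i, ch in enumerate(chunk) if ch in bad)
                    raise ValueError(
                        f"{path}:{lineno}: invalid residue {chunk[col]!r} at "
                        f"position {offset + col + 1} of record {name!r}"
                    )
                chunks.append(chunk)
    flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def _window_matches(window: str, pattern: MotifPattern) -> list[int] | None:
    """Offsets of ambiguous residues if the window matches, else None."""
    masked: list[int] = []
    for i, pbase in enumerate(pattern.consensus):
        allele_set = IUPAC_CODES.get(window[i])
        if allele_set is None:
            raise ValueError(f"invalid residue {window[i]!r} in sequence")
        if pbase != "n" and pbase not in allele_set:
            return None
        if len(allele_set) > 1:
            masked.append(i)
    return masked


def scan_halfsites(
    seq: MaskedSequence,
    patterns: Sequence[MotifPattern] = DEFAULT_PATTERNS,
    count_n_as_snp: bool = False,
) -> list[MotifHit]:
    """All pattern occurrences in ``seq`` under IUPAC containment matching.

    ``masked_positions`` lists window offsets whose residue is ambiguous.
    By default ``N`` is treated as covering all bases but is NOT recorded
    as a SNP position (assembly gaps are not variants); set
    ``count_n_as_snp`` to include it.  Overlapping hits are all reported;
    output is sorted by start then pattern label.
    """
    if not patterns:
        raise ValueError("patterns must be non-empty")
    hits: list[MotifHit] = []
    s = seq.residues
    for pattern in patterns:
        m = len(pattern)
        for start in range(len(s) - m + 1):
            masked = _window_matches(s[start : start + m], pattern)
            if masked is None:
                continue
            if not count_n_as_snp:
                masked = [i for i in masked if s[start + i] != "N"]
            hits.append(MotifHit(seq.name, start, start + m, pattern.label, masked))
    hits.sort(key=lambda h: (h.start, h.pattern_label))
    return hits


def filter_snp_disrupting(
    hits: Iterable[MotifHit],
    seq: MaskedSequence,
    patterns: Sequence[MotifPattern] = DEFAULT_PATTERNS,
) -> list[MotifHit]:
    """Keep hits where a masked position can break the binding site.

    A hit is disrupting when at least one masked position sits at a
    non-wildcard pattern column and its allele set contains a base other
    than the consensus base there.  SNPs in wildcard (spacer) columns
    cannot disrupt and do not qualify.
    """
    by_label = {p.label: p for p in patterns}
    kept: list[MotifHit] = []
    for hit in hits:
        pattern = by_label[hit.pattern_label]
        disrupting_offsets = [
            off
            for off in hit.masked_positions
            if pattern.consensus[off] != "n"
            and iupac_allele_set(seq.residues[hit.start + off]) - {pattern.consensus[off]}
        ]
        if disrupting_offsets:
            hit.disrupting = True
            kept.append(hit)
    return kept


def write_hits_bed(hits: Iterable[MotifHit], path: str | Path) -> None:
    """BED6-like output: chrom, start, end, pattern label, masked count, '.'"""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.pattern_label}\t"
                f"{len(h.masked_positions)}\t.\n"
            )


def write_hits_offsets_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tpattern\tmasked_offsets\tdisrupting\n")
        for h in hits:
            offs = ",".join(map(str, h.masked_positions)) or "."
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.pattern_label}\t{offs}\t"
                f"{int(h.disrupting)}\n"
            )
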