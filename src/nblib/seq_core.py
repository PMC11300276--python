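"""Sequence primitives shared by every stage of the library-design pipeline.

Provides amino-acid and (possibly degenerate) nucleotide sequence types, the
IMGT-style region scheme used for VHH domains, anchored region annotation,
global pairwise alignment, translation/back-translation, and FASTA/TSV I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Data.CodonTable import unambiguous_dna_by_name
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AA_LETTERS",
    "AminoAcidSequence",
    "AnnotatedNanobody",
    "AnnotationError",
    "IMGT_SCHEME",
    "IUPAC_NT",
    "ImgtScheme",
    "NucleotideSequence",
    "PairwiseAlignment",
    "PREFERRED_CODONS",
    "TranslationResult",
    "annotate_anchor",
    "annotate_regions",
    "back_translate",
    "fmt_pos",
    "global_align",
    "parse_pos",
    "place_loop",
    "read_fasta_aa",
    "read_fasta_nt",
    "translate",
    "write_annotation_tsv",
    "write_fasta",
]

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = set(AA_LETTERS) | {"X", "-"}

#: IUPAC nucleotide degeneracy codes and their expansions.
IUPAC_NT: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_STRICT_NT = set("ACGT")

_standard = unambiguous_dna_by_name["Standard"]
#: codon -> amino acid, with '*' for the three stop codons.
CODON_TABLE: dict[str, str] = dict(_standard.forward_table)
CODON_TABLE.update({c: "*" for c in _standard.stop_codons})

#: One deterministic codon per amino acid (common E. coli usage).
PREFERRED_CODONS: dict[str, str] = {
    "A": "GCG", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}

# An IMGT position: (number, insertion index). (111, 1) renders as "111.1".
ImgtPos = tuple[int, int]


def fmt_pos(pos: ImgtPos) -> str:
    """Render an IMGT position as ``"42"`` or ``"111.1"``."""
    num, ins = pos
    return f"{num}.{ins}" if ins else str(num)


def parse_pos(text: str | int) -> ImgtPos:
    """Parse ``"42"``, ``42`` or ``"111.1"`` into an (int, int) position."""
    if isinstance(text, int):
        return (text, 0)
    s = str(text)
    if "." in s:
        num, ins = s.split(".", 1)
        return (int(num), int(ins))
    return (int(s), 0)


class AnnotationError(ValueError):
    """Raised when a sequence cannot be annotated against the anchor."""


@dataclass(frozen=True)
class AminoAcidSequence:
    """An identified amino-acid sequence over the 20 standard letters + X + gap."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id!r}: empty amino-acid sequence")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise ValueError(f"{self.id!r}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "AminoAcidSequence":
        if "-" not in self.residues:
            return self
        return AminoAcidSequence(self.id, self.residues.replace("-", ""))


@dataclass(frozen=True)
class NucleotideSequence:
    """A nucleotide sequence; IUPAC degeneracy codes allowed only when flagged."""

    id: str
    bases: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"{self.id!r}: empty nucleotide sequence")
        allowed = set(IUPAC_NT) if self.degenerate else _STRICT_NT
        bad = set(self.bases) - allowed
        if bad:
            raise ValueError(f"{self.id!r}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def degenerate_positions(self) -> tuple[int, ...]:
        """0-based indices carrying a degeneracy code."""
        return tuple(i for i, b in enumerate(self.bases) if b not in _STRICT_NT)


@dataclass(frozen=True)
class ImgtScheme:
    """Region spans (1-based, inclusive) plus hallmark and CDR-anchor positions.

    Position 66 belongs to CDR2 in this delineation.
    """

    regions: tuple[tuple[str, int, int], ...] = (
        ("FR1", 1, 26),
        ("CDR1", 27, 38),
        ("FR2", 39, 55),
        ("CDR2", 56, 66),
        ("FR3", 67, 104),
        ("CDR3", 105, 117),
        ("FR4", 118, 128),
    )
    hallmark_positions: frozenset[int] = frozenset({42, 49, 50, 52})
    # conserved CDR anchors: position -> canonical residue
    cdr_anchors: tuple[tuple[int, str], ...] = (
        (27, "G"), (29, "I"), (35, "A"),
        (56, "I"), (63, "G"), (65, "T"),
        (105, "A"), (117, "Y"),
    )

    def __post_init__(self) -> None:
        prev_end = 0
        for name, start, end in self.regions:
            if start != prev_end + 1 or end < start:
                raise ValueError(f"region {name} spans must be contiguous and ordered")
            prev_end = end
        fr2 = self.span("FR2")
        if not all(fr2[0] <= h <= fr2[1] for h in self.hallmark_positions):
            raise ValueError("hallmark positions must lie within FR2")

    def span(self, name: str) -> tuple[int, int]:
        for rname, start, end in self.regions:
            if rname == name:
                return (start, end)
        raise KeyError(name)

    def region_of(self, pos: int) -> str:
        for name, start, end in self.regions:
            if start <= pos <= end:
                return name
        raise ValueError(f"position {pos} outside scheme")

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.regions)

    @property
    def framework_regions(self) -> tuple[str, ...]:
        return tuple(n for n in self.region_names if n.startswith("FR"))

    @property
    def cdr_regions(self) -> tuple[str, ...]:
        return tuple(n for n in self.region_names if n.startswith("CDR"))

    def anchor_map(self) -> dict[int, str]:
        return dict(self.cdr_anchors)


IMGT_SCHEME = ImgtScheme()


def place_loop(start: int, end: int, length: int) -> tuple[ImgtPos, ...]:
    """Assign IMGT positions to a loop of ``length`` residues in span start..end.

    Loops shorter than the span leave gaps symmetrically about the loop apex,
    with the tie residue going to the N-terminal side.  Loops longer than the
    span take insertion codes at the span midpoint (e.g. 111.1).
    """
    if length <= 0:
        raise ValueError("loop length must be positive")
    size = end - start + 1
    if length <= size:
        n_front = math.ceil(length / 2)
        n_back = length - n_front
        front = [(start + i, 0) for i in range(n_front)]
        back = [(end - n_back + 1 + i, 0) for i in range(n_back)]
        return tuple(front + back)
    extra = length - size
    apex = (start + end) // 2
    out: list[ImgtPos] = [(p, 0) for p in range(start, apex + 1)]
    out += [(apex, j) for j in range(1, extra + 1)]
    out += [(p, 0) for p in range(apex + 1, end + 1)]
    return tuple(out)


@dataclass(frozen=True)
class AnnotatedNanobody:
    """A VHH sequence with a per-residue IMGT position map."""

    sequence: AminoAcidSequence
    scheme: ImgtScheme
    position_map: tuple[ImgtPos, ...]

    def __post_init__(self) -> None:
        if len(self.position_map) != len(self.sequence):
            raise ValueError("position map length must equal sequence length")
        if list(self.position_map) != sorted(set(self.position_map)):
            raise ValueError("position map must be strictly increasing and unique")

    def region_of_index(self, idx: int) -> str:
        return self.scheme.region_of(self.position_map[idx][0])

    def region_indices(self, name: str) -> tuple[int, ...]:
        start, end = self.scheme.span(name)
        return tuple(
            i for i, (p, _) in enumerate(self.position_map) if start <= p <= end
        )

    def region_seq(self, name: str) -> str:
        return "".join(self.sequence.residues[i] for i in self.region_indices(name))

    def region_positions(self, name: str) -> tuple[ImgtPos, ...]:
        return tuple(self.position_map[i] for i in self.region_indices(name))

    def regions(self) -> dict[str, str]:
        return {name: self.region_seq(name) for name in self.scheme.region_names}

    def residue_at(self, pos: ImgtPos | int | str) -> str | None:
        if not isinstance(pos, tuple):
            pos = parse_pos(pos)
        try:
            return self.sequence.residues[self.position_map.index(pos)]
        except ValueError:
            return None

    @property
    def cdr3_length(self) -> int:
        return len(self.region_indices("CDR3"))

    def framework_seq(self) -> str:
        return "".join(self.region_seq(n) for n in self.scheme.framework_regions)


@dataclass(frozen=True)
class PairwiseAlignment:
    a_gapped: str
    b_gapped: str
    score: float
    identity: float

    def __len__(self) -> int:
        return len(self.a_gapped)


def _make_aligner(match: float, mismatch: float, gap: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def global_align(
    a: AminoAcidSequence | str,
    b: AminoAcidSequence | str,
    *,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> PairwiseAlignment:
    """Optimal global alignment (linear gap cost); identity over all columns."""
    sa = (a.residues if isinstance(a, AminoAcidSequence) else a).replace("-", "")
    sb = (b.residues if isinstance(b, AminoAcidSequence) else b).replace("-", "")
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(sa, sb)[0]
    a_g, b_g = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a_g, b_g) if x == y and x != "-")
    return PairwiseAlignment(a_g, b_g, float(aln.score), matches / len(a_g))


def identity_fraction(a, b, **kwargs) -> float:
    return global_align(a, b, **kwargs).identity


def annotate_anchor(
    seq: AminoAcidSequence,
    scheme: ImgtScheme,
    region_lengths: Mapping[str, int] | Sequence[int],
) -> AnnotatedNanobody:
    """Annotate a reference of known region lengths by direct sequential assignment.

    Framework residues fill their span from its start; CDR residues follow the
    symmetric loop-placement rule.
    """
    if not isinstance(region_lengths, Mapping):
        region_lengths = dict(zip(scheme.region_names, region_lengths))
    residues = seq.ungapped().residues
    total = sum(region_lengths.get(n, 0) for n in scheme.region_names)
    if total != len(residues):
        raise AnnotationError(
            f"region lengths sum to {total}, sequence has {len(residues)} residues"
        )
    pos_map: list[ImgtPos] = []
    for name, start, end in scheme.regions:
        length = region_lengths.get(name, 0)
        if length == 0:
            continue
        if name.startswith("FR"):
            if length > end - start + 1:
                raise AnnotationError(f"{name} length {length} exceeds span")
            pos_map.extend((start + i, 0) for i in range(length))
        else:
            pos_map.extend(place_loop(start, end, length))
    return AnnotatedNanobody(seq.ungapped(), scheme, tuple(pos_map))


def _column_regions(a_g: str, b_g: str, anchor: AnnotatedNanobody) -> list[str]:
    """Region label for each alignment column (a = query, b = anchor)."""
    n = len(a_g)
    raw: list[str | None] = [None] * n
    bi = 0
    for col in range(n):
        if b_g[col] != "-":
            raw[col] = anchor.region_of_index(bi)
            bi += 1
    # inserted columns (anchor gap): prefer an adjacent CDR, else nearest region
    regions: list[str] = []
    for col in range(n):
        if raw[col] is not None:
            regions.append(raw[col])
            continue
        prev_r = next((raw[c] for c in range(col - 1, -1, -1) if raw[c]), None)
        next_r = next((raw[c] for c in range(col + 1, n) if raw[c]), None)
        if prev_r and prev_r.startswith("CDR"):
            regions.append(prev_r)
        elif next_r and next_r.startswith("CDR"):
            regions.append(next_r)
        else:
            regions.append(prev_r or next_r or "FR1")
    return regions


def annotate_regions(
    seq: AminoAcidSequence,
    scheme: ImgtScheme,
    frame_anchor: Union[AnnotatedNanobody, AminoAcidSequence],
    *,
    anchor_region_lengths: Mapping[str, int] | Sequence[int] | None = None,
    min_framework_identity: float = 0.7,
) -> AnnotatedNanobody:
    """Annotate ``seq`` by anchored alignment to a reference of known numbering.

    Framework segments inherit span-start-relative numbering; CDR loops are
    numbered by the symmetric placement rule.  Fails when the worst framework
    region falls below ``min_framework_identity`` or does not fit its span.
    """
    if isinstance(frame_anchor, AnnotatedNanobody):
        anchor = frame_anchor
    else:
        if anchor_region_lengths is None:
            raise ValueError("plain anchor sequence requires anchor_region_lengths")
        anchor = annotate_anchor(frame_anchor, scheme, anchor_region_lengths)
    query = seq.ungapped()
    aln = global_align(query, anchor.sequence)
    col_regions = _column_regions(aln.a_gapped, aln.b_gapped, anchor)

    # framework identity per region, over all columns assigned to it
    worst_name, worst_id = None, 2.0
    for name in scheme.framework_regions:
        cols = [c for c, r in enumerate(col_regions) if r == name]
        if not cols:
            raise AnnotationError(f"framework region {name} absent from alignment")
        matches = sum(
            1 for c in cols
            if aln.a_gapped[c] == aln.b_gapped[c] and aln.a_gapped[c] != "-"
        )
        ident = matches / len(cols)
        if ident < worst_id:
            worst_name, worst_id = name, ident
    if worst_id < min_framework_identity:
        raise AnnotationError(
            f"framework identity too low: region {worst_name} at {worst_id:.2f} "
            f"(minimum {min_framework_identity:.2f})"
        )

    # collect query residues per region, in order, then number region-wise
    by_region: dict[str, int] = {n: 0 for n in scheme.region_names}
    for col, region in enumerate(col_regions):
        if aln.a_gapped[col] != "-":
            by_region[region] += 1
    pos_map: list[ImgtPos] = []
    for name, start, end in scheme.regions:
        length = by_region[name]
        if length == 0:
            if name.startswith("CDR"):
                raise AnnotationError(f"empty {name} loop")
            continue
        if name.startswith("FR"):
            if length > end - start + 1:
                raise AnnotationError(f"{name} has {length} residues, span is "
                                      f"{end - start + 1}")
            pos_map.extend((start + i, 0) for i in range(length))
        else:
            pos_map.extend(place_loop(start, end, length))
    return AnnotatedNanobody(query, scheme, tuple(pos_map))


@dataclass(frozen=True)
class TranslationResult:
    """Protein string (stops as ``*``), premature-stop codon indices, flags."""

    protein: str
    stop_codon_indices: tuple[int, ...]
    dropped_trailing_bases: int

    @property
    def has_premature_stop(self) -> bool:
        """True when a stop codon occurs before the final codon."""
        return any(i < len(self.protein) - 1 for i in self.stop_codon_indices)

    def aa_sequence(self, seq_id: str = "translation") -> AminoAcidSequence:
        if "*" in self.protein:
            raise ValueError("translation contains stop codons")
        return AminoAcidSequence(seq_id, self.protein)


def translate(nt: NucleotideSequence | str, frame: int = 0) -> TranslationResult:
    """Translate with the standard genetic code; trailing partial codon dropped."""
    bases = nt.bases if isinstance(nt, NucleotideSequence) else nt
    if set(bases) - _STRICT_NT:
        raise ValueError("degenerate bases present; expand before translating")
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    coding = bases[frame:]
    dropped = len(coding) % 3
    if dropped:
        coding = coding[: len(coding) - dropped]
    protein = []
    stops = []
    for i in range(0, len(coding), 3):
        aa = CODON_TABLE[coding[i : i + 3]]
        if aa == "*":
            stops.append(i // 3)
        protein.append(aa)
    return TranslationResult("".join(protein), tuple(stops), dropped)


def back_translate(
    aa: AminoAcidSequence | str,
    codon_table: Mapping[str, str] = PREFERRED_CODONS,
    seq_id: str | None = None,
) -> NucleotideSequence:
    """Deterministic reverse translation with one preferred codon per residue."""
    if isinstance(aa, AminoAcidSequence):
        residues, name = aa.residues, aa.id
    else:
        residues, name = aa, "back_translation"
    if "-" in residues:
        raise ValueError("cannot back-translate gapped sequence")
    if "X" in residues:
        raise ValueError("cannot back-translate unknown residue 'X'")
    bases = "".join(codon_table[r] for r in residues)
    return NucleotideSequence(seq_id or name, bases)


# ---------------------------------------------------------------------------
# I/O

def read_fasta_aa(path: str | Path) -> list[AminoAcidSequence]:
    return [
        AminoAcidSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_fasta_nt(path: str | Path, degenerate: bool = True) -> list[NucleotideSequence]:
    return [
        NucleotideSequence(rec.id, str(rec.seq).upper(), degenerate=degenerate)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(
    seqs: Iterable[AminoAcidSequence | NucleotideSequence], path: str | Path
) -> None:
    records = []
    for s in seqs:
        letters = s.residues if isinstance(s, AminoAcidSequence) else s.bases
        records.append(SeqRecord(Seq(letters), id=s.id, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_annotation_tsv(
    annotated: Iterable[AnnotatedNanobody], path: str | Path
) -> None:
    """Annotation report: id, region, imgt_start, imgt_end, length, sequence."""
    with open(path, "w") as fh:
        fh.write("id\tregion\timgt_start\timgt_end\tlength\tsequence\n")
        for ann in annotated:
            for name in ann.scheme.region_names:
                positions = ann.region_positions(name)
                if not positions:
                    continue
                fh.write(
                    f"{ann.sequence.id}\t{name}\t{fmt_pos(positions[0])}\t"
                    f"{fmt_pos(positions[-1])}\t{len(positions)}\t"
                    f"{ann.region_seq(name)}\n"
                )
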