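"""Primer/fragment planning, in-silico library sampling, synthesis-error
simulation, clone-defect classification, and QC statistics."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .diversity_design import CodonChoice, DiversitySpec
from .seq_core import (
    CODON_TABLE,
    IUPAC_NT,
    AnnotatedNanobody,
    NucleotideSequence,
    back_translate,
    fmt_pos,
    translate,
)

__all__ = [
    "CloneRecord",
    "ErrorModel",
    "LibraryQCReport",
    "PrimerPlan",
    "ReferenceDesign",
    "assemble_in_silico",
    "classify_clone",
    "design_primers",
    "qc_report",
    "qc_report_from_counts",
    "sample_library",
    "simulate_synthesis_errors",
    "titer_from_dilution",
]

SFI_FLANK = "GGCCCAGCCGGCC"  # matches the GGCCNNNNNGGCC recognition pattern
NOTI_FLANK = "GCGGCCGC"
SFI_PATTERN = "GGCCNNNNNGGCC"

CLASSIFICATIONS = (
    "correct",
    "stop_codon",
    "base_missing",
    "base_shifting",
    "large_region_missing",
    "no_insert",
)


def _matches_pattern(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        s in IUPAC_NT[p] for s, p in zip(seq, pattern)
    )


def _count_pattern(seq: str, pattern: str) -> int:
    return sum(
        1
        for i in range(len(seq) - len(pattern) + 1)
        if _matches_pattern(seq[i : i + len(pattern)], pattern)
    )


@dataclass
class PrimerPlan:
    """Named assembly fragments with overlaps and restriction-site flanks.

    ``F1_flank``/``R1_flank`` carry the SfiI/NotI sites; ``F2R2`` carries the
    CDR1+CDR2 degeneracy; one ``F3R3_<len>`` fragment per CDR3 length class.
    """

    fragments: dict[str, NucleotideSequence]
    overlaps: tuple[tuple[str, str, str], ...]  # (left, right, shared sequence)
    flank_sites: dict[str, str]
    min_overlap: int
    cdr3_lengths: tuple[int, ...]

    def fragment_order(self, cdr3_length: int) -> tuple[str, ...]:
        return ("F1_flank", "F2R2", f"F3R3_{cdr3_length}", "R1_flank")


@dataclass(frozen=True)
class ErrorModel:
    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    large_deletion_rate: float = 0.0
    large_deletion_size: tuple[int, int] = (15, 60)
    no_insert_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "substitution_rate",
            "insertion_rate",
            "deletion_rate",
            "large_deletion_rate",
            "no_insert_rate",
        ):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class CloneRecord:
    id: str
    nt_sequence: str
    aa_sequence: str | None
    classification: str
    cdr_signature: str
    cdr3_length: int | None = None

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")


def _cdr_nt(
    codon_plan: Mapping[str, CodonChoice],
    spec: DiversitySpec,
    region: str,
    length: int | None,
) -> str:
    tag = region if length is None else f"{region}[{length}]"
    specs = {
        "CDR1": spec.cdr1_specs,
        "CDR2": spec.cdr2_specs,
    }.get(region, spec.cdr3_specs.get(length or -1, ()))
    return "".join(
        codon_plan[f"{tag}:{fmt_pos(s.imgt_position)}"].codon.iupac_triplet
        for s in specs
    )


def _framework_nt(scaffold: AnnotatedNanobody) -> dict[str, str]:
    return {
        name: back_translate(scaffold.region_seq(name)).bases
        for name in scaffold.scheme.framework_regions
    }


def design_primers(
    scaffold: AnnotatedNanobody,
    spec: DiversitySpec,
    codon_plan: Mapping[str, CodonChoice],
    min_overlap: int = 18,
) -> PrimerPlan:
    """Lay out the overlap-extension fragments encoding the designed library.

    CDR1/CDR2 degeneracy is embedded in the F-2/R-2 fragment, CDR3 degeneracy
    (one variant per length class) in the F-3/R-3 fragments, and the SfiI/NotI
    flanks in the F-1/R-1 fragments.
    """
    fr = _framework_nt(scaffold)
    for name, bases in fr.items():
        if min_overlap > len(bases):
            raise ValueError(
                f"overlap {min_overlap} nt exceeds framework segment {name} "
                f"({len(bases)} nt): junction {name}"
            )
    cdr1 = _cdr_nt(codon_plan, spec, "CDR1", None)
    cdr2 = _cdr_nt(codon_plan, spec, "CDR2", None)

    body = fr["FR1"] + cdr1 + fr["FR2"] + cdr2 + fr["FR3"]
    fragments: dict[str, NucleotideSequence] = {
        "F1_flank": NucleotideSequence(
            "F1_flank", SFI_FLANK + fr["FR1"][:min_overlap]
        ),
        "F2R2": NucleotideSequence("F2R2", body, degenerate=True),
        "R1_flank": NucleotideSequence(
            "R1_flank", fr["FR4"][-min_overlap:] + NOTI_FLANK
        ),
    }
    overlaps: list[tuple[str, str, str]] = [
        ("F1_flank", "F2R2", fr["FR1"][:min_overlap])
    ]
    for length in spec.cdr3_lengths:
        name = f"F3R3_{length}"
        cdr3 = _cdr_nt(codon_plan, spec, "CDR3", length)
        fragments[name] = NucleotideSequence(
            name, fr["FR3"][-min_overlap:] + cdr3 + fr["FR4"], degenerate=True
        )
        overlaps.append(("F2R2", name, fr["FR3"][-min_overlap:]))
        overlaps.append((name, "R1_flank", fr["FR4"][-min_overlap:]))

    # flank sites must each occur exactly once in the assembled product
    for length in spec.cdr3_lengths:
        product = _assemble_bases(fragments, overlaps, length)
        if _count_pattern(product, SFI_PATTERN) != 1:
            raise ValueError("SfiI site must occur exactly once in the product")
        if product.count(NOTI_FLANK) != 1:
            raise ValueError("NotI site must occur exactly once in the product")
    return PrimerPlan(
        fragments, tuple(overlaps), {"SfiI": SFI_FLANK, "NotI": NOTI_FLANK},
        min_overlap, spec.cdr3_lengths,
    )


def _assemble_bases(
    fragments: Mapping[str, NucleotideSequence],
    overlaps: Sequence[tuple[str, str, str]],
    cdr3_length: int,
) -> str:
    order = ("F1_flank", "F2R2", f"F3R3_{cdr3_length}", "R1_flank")
    overlap_map = {(l, r): s for l, r, s in overlaps}
    product = fragments[order[0]].bases
    for left, right in zip(order, order[1:]):
        shared = overlap_map[(left, right)]
        nxt = fragments[right].bases
        if not product.endswith(shared):
            raise ValueError(
                f"overlap mismatch at junction {left}/{right} "
                f"(position {len(product) - len(shared)})"
            )
        if not nxt.startswith(shared):
            raise ValueError(f"overlap mismatch at junction {left}/{right}")
        product += nxt[len(shared):]
    return product


def assemble_in_silico(
    plan: PrimerPlan, cdr3_length: int | None = None
) -> NucleotideSequence:
    """Join fragments through their shared overlaps into the full-length product."""
    if cdr3_length is None:
        if len(plan.cdr3_lengths) != 1:
            raise ValueError("cdr3_length required when plan has several classes")
        cdr3_length = plan.cdr3_lengths[0]
    bases = _assemble_bases(plan.fragments, plan.overlaps, cdr3_length)
    return NucleotideSequence(f"assembly_{cdr3_length}", bases, degenerate=True)


@dataclass
class ReferenceDesign:
    """Degenerate reference (no flanks) per CDR3 length, for classification."""

    scaffold: AnnotatedNanobody
    designs: dict[int, str]  # length -> degenerate nt
    aa_lengths: dict[int, int]
    coverage_floor: float = 0.5
    large_deletion_threshold: int = 15


def reference_design(
    scaffold: AnnotatedNanobody,
    spec: DiversitySpec,
    codon_plan: Mapping[str, CodonChoice],
    coverage_floor: float = 0.5,
    large_deletion_threshold: int = 15,
) -> ReferenceDesign:
    fr = _framework_nt(scaffold)
    designs = {}
    aa_lengths = {}
    for length in spec.cdr3_lengths:
        nt = (
            fr["FR1"]
            + _cdr_nt(codon_plan, spec, "CDR1", None)
            + fr["FR2"]
            + _cdr_nt(codon_plan, spec, "CDR2", None)
            + fr["FR3"]
            + _cdr_nt(codon_plan, spec, "CDR3", length)
            + fr["FR4"]
        )
        designs[length] = nt
        aa_lengths[length] = len(nt) // 3
    return ReferenceDesign(
        scaffold, designs, aa_lengths, coverage_floor, large_deletion_threshold
    )


def sample_library(
    scaffold: AnnotatedNanobody,
    spec: DiversitySpec,
    codon_plan: Mapping[str, CodonChoice],
    n: int,
    seed: int,
) -> list[CloneRecord]:
    """Draw ``n`` clones: CDR3 length from the spec weights, then one concrete
    codon per degenerate position, uniformly over its expansion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    fr = _framework_nt(scaffold)
    lengths = list(spec.cdr3_lengths)
    weights = np.array([spec.length_weights[l] for l in lengths])
    drawn = rng.choice(len(lengths), size=n, p=weights / weights.sum())

    # per length class: ordered codon sets for every degenerate position
    class_layout: dict[int, list[tuple[str, ...]]] = {}
    for length in lengths:
        codons: list[tuple[str, ...]] = []
        for region, cls in (("CDR1", None), ("CDR2", None), ("CDR3", length)):
            tag = region if cls is None else f"{region}[{cls}]"
            specs = (
                spec.cdr1_specs
                if region == "CDR1"
                else spec.cdr2_specs
                if region == "CDR2"
                else spec.cdr3_specs[length]
            )
            for pspec in specs:
                key = f"{tag}:{fmt_pos(pspec.imgt_position)}"
                codons.append(codon_plan[key].codon.codon_set)
        class_layout[length] = codons

    clones: list[CloneRecord] = []
    for class_idx, length in enumerate(lengths):
        member_ids = np.flatnonzero(drawn == class_idx)
        if member_ids.size == 0:
            continue
        codon_sets = class_layout[length]
        picks = [
            rng.integers(0, len(cs), size=member_ids.size) for cs in codon_sets
        ]
        n_cdr12 = 16  # 8 + 8 positions ahead of CDR3
        for row, clone_i in enumerate(member_ids):
            chosen = [codon_sets[j][picks[j][row]] for j in range(len(codon_sets))]
            cdr1_nt = "".join(chosen[:8])
            cdr2_nt = "".join(chosen[8:16])
            cdr3_nt = "".join(chosen[n_cdr12:])
            nt = (
                fr["FR1"] + cdr1_nt + fr["FR2"] + cdr2_nt + fr["FR3"]
                + cdr3_nt + fr["FR4"]
            )
            tr = translate(nt)
            aa = tr.protein
            cdr_aa = "".join(
                CODON_TABLE[c] for c in chosen
            )
            clones.append(
                CloneRecord(
                    id=f"clone_{clone_i:06d}",
                    nt_sequence=nt,
                    aa_sequence=None if "*" in aa else aa,
                    classification="stop_codon" if tr.stop_codon_indices else "correct",
                    cdr_signature=cdr_aa,
                    cdr3_length=length,
                )
            )
    clones.sort(key=lambda c: c.id)
    return clones


def simulate_synthesis_errors(
    clones: Sequence[CloneRecord], model: ErrorModel, seed: int
) -> list[CloneRecord]:
    """Inject per-clone no-insert / large-deletion events, then per-base
    substitution, insertion and deletion errors.  Truth labels follow the same
    priority rule as the classifier."""
    rng = np.random.default_rng(seed)
    out: list[CloneRecord] = []
    bases = "ACGT"
    for clone in clones:
        nt = clone.nt_sequence
        had_stop_at_birth = clone.classification == "stop_codon"
        if rng.random() < model.no_insert_rate:
            out.append(
                CloneRecord(clone.id, "", None, "no_insert", "", clone.cdr3_length)
            )
            continue
        large_cut = 0
        if rng.random() < model.large_deletion_rate:
            lo, hi = model.large_deletion_size
            size = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, max(1, len(nt) - size)))
            nt = nt[:start] + nt[start + size:]
            large_cut = size
        n_sub = n_ins = n_del = 0
        if model.substitution_rate or model.insertion_rate or model.deletion_rate:
            new = []
            for b in nt:
                r = rng.random()
                if r < model.deletion_rate:
                    n_del += 1
                    continue
                if r < model.deletion_rate + model.substitution_rate:
                    choices = [x for x in bases if x != b]
                    b = choices[int(rng.integers(0, 3))]
                    n_sub += 1
                new.append(b)
                if rng.random() < model.insertion_rate:
                    new.append(bases[int(rng.integers(0, 4))])
                    n_ins += 1
            nt = "".join(new)

        net = n_ins - n_del - large_cut
        tr = translate(nt) if nt else None
        if large_cut >= 15:
            label = "large_region_missing"
        elif net % 3 != 0:
            label = "base_shifting"
        elif n_del + large_cut > 0:
            label = "base_missing"
        elif tr is not None and tr.has_premature_stop:
            label = "stop_codon"
        elif had_stop_at_birth:
            label = "stop_codon"
        else:
            label = "correct"
        aa = tr.protein if tr is not None and not tr.stop_codon_indices else None
        out.append(
            CloneRecord(
                clone.id,
                nt,
                aa,
                label,
                clone.cdr_signature if label == "correct" else "",
                clone.cdr3_length,
            )
        )
    return out


_NT_MATRIX_CACHE: dict[tuple[float, float], object] = {}


def _iupac_aligner(match: float = 1.0, gap: float = -1.0) -> PairwiseAligner:
    key = (match, gap)
    matrix = _NT_MATRIX_CACHE.get(key)
    if matrix is None:
        letters = "".join(sorted(IUPAC_NT))
        matrix = substitution_matrices.Array(letters, dims=2)
        for a in letters:
            for b in letters:
                matrix[a, b] = (
                    match if set(IUPAC_NT[a]) & set(IUPAC_NT[b]) else 0.0
                )
        _NT_MATRIX_CACHE[key] = matrix
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    # affine costs keep real deletion runs contiguous in the alignment
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.2
    return aligner


def classify_clone(clone_nt: str, reference: ReferenceDesign) -> str:
    """Classify a sequenced clone against the designed product.

    Priority: no_insert > large_region_missing > base_shifting > base_missing
    > stop_codon > correct.
    """
    if not clone_nt:
        return "no_insert"
    aligner = _iupac_aligner()
    # pick the length class by best alignment score, not raw length proximity:
    # a large deletion can make the wrong class look closer in length
    best = None
    for length, design in reference.designs.items():
        aln = aligner.align(clone_nt, design)[0]
        if best is None or aln.score > best[0]:
            best = (aln.score, length, aln)
    _, length, aln = best
    design = reference.designs[length]
    if len(clone_nt) < reference.coverage_floor * len(design):
        return "no_insert"
    clone_g, design_g = str(aln[0]), str(aln[1])
    covered = sum(1 for c, d in zip(clone_g, design_g) if c != "-" and d != "-")
    if covered < reference.coverage_floor * len(design):
        return "no_insert"
    # deletion runs = gaps in the clone row opposite design bases
    max_run = run = total_del = 0
    for c, d in zip(clone_g, design_g):
        if c == "-" and d != "-":
            run += 1
            total_del += 1
            max_run = max(max_run, run)
        else:
            run = 0
    if max_run >= reference.large_deletion_threshold:
        return "large_region_missing"
    net = len(clone_nt) - len(design)
    if net % 3 != 0:
        return "base_shifting"
    if total_del > 0:
        return "base_missing"
    tr = translate(clone_nt)
    if tr.stop_codon_indices:  # the design encodes no stop codon at all
        return "stop_codon"
    return "correct"


@dataclass
class LibraryQCReport:
    n_picked: int
    n_insert_positive: int
    insertion_rate: float
    n_sequenced: int
    n_correct: int
    correctness_rate: float
    n_redundant: int
    effective_size: float | None = None

    def as_dict(self) -> dict:
        return {
            "n_picked": self.n_picked,
            "n_insert_positive": self.n_insert_positive,
            "insertion_rate": self.insertion_rate,
            "n_sequenced": self.n_sequenced,
            "n_correct": self.n_correct,
            "correctness_rate": self.correctness_rate,
            "n_redundant": self.n_redundant,
            "effective_size": self.effective_size,
        }


def qc_report(
    picked: Sequence[bool],
    sequenced: Sequence[tuple[str, str]],
    effective_size: float | None = None,
) -> LibraryQCReport:
    """Compute insertion/correctness/redundancy statistics.

    ``picked`` holds per-colony insert-assay outcomes; ``sequenced`` holds
    (classification, cdr_signature) pairs.  Redundancy counts correct clones
    sharing an already-seen CDR signature.
    """
    if not picked or not sequenced:
        raise ValueError("picked and sequenced counts must be non-zero")
    n_picked = len(picked)
    n_pos = sum(1 for p in picked if p)
    n_seq = len(sequenced)
    correct_sigs = [sig for cls, sig in sequenced if cls == "correct"]
    n_correct = len(correct_sigs)
    n_redundant = n_correct - len(set(correct_sigs))
    return LibraryQCReport(
        n_picked=n_picked,
        n_insert_positive=n_pos,
        insertion_rate=n_pos / n_picked,
        n_sequenced=n_seq,
        n_correct=n_correct,
        correctness_rate=n_correct / n_seq,
        n_redundant=n_redundant,
        effective_size=effective_size,
    )


def qc_report_from_counts(
    n_picked: int,
    n_insert_negative: int,
    n_sequenced: int,
    n_incorrect: int,
    n_redundant_correct: int = 0,
    effective_size: float | None = None,
) -> LibraryQCReport:
    """Convenience wrapper taking the printed worked-example counts."""
    picked = [True] * (n_picked - n_insert_negative) + [False] * n_insert_negative
    n_correct = n_sequenced - n_incorrect
    sequenced: list[tuple[str, str]] = [
        ("correct", "sig0" if i <= n_redundant_correct else f"sig{i}")
        for i in range(n_correct)
    ]
    sequenced += [("stop_codon", "")] * n_incorrect
    return qc_report(picked, sequenced, effective_size)


def titer_from_dilution(
    colony_counts: Sequence[int],
    dilution_factors: Sequence[float],
    plated_volume: float,
    total_volume: float,
    countable_range: tuple[int, int] = (30, 300),
) -> float:
    """Library size from serial dilution: mean over countable plates of
    count x dilution x (total volume / plated volume)."""
    if len(colony_counts) != len(dilution_factors):
        raise ValueError("counts and dilution factors must align")
    if plated_volume <= 0 or total_volume <= 0:
        raise ValueError("volumes must be positive")
    lo, hi = countable_range
    estimates = [
        count * factor * (total_volume / plated_volume)
        for count, factor in zip(colony_counts, dilution_factors)
        if lo <= count <= hi
    ]
    if not estimates:
        raise ValueError("no countable plate in range "
                         f"[{lo}, {hi}]: counts {list(colony_counts)}")
    return float(np.mean(estimates))
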