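"""Scaffold humanization: hallmark and consensus-framework substitutions toward
a human germline, with a framework-identity humanness score."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .repertoire_analysis import ConsensusProfile
from .seq_core import (
    AminoAcidSequence,
    AnnotatedNanobody,
    ImgtPos,
    fmt_pos,
    global_align,
)

__all__ = [
    "GermlineReference",
    "ScaffoldDesign",
    "SubstitutionRecord",
    "apply_design",
    "humanness_score",
    "propose_consensus_substitutions",
    "propose_hallmark_humanization",
    "write_design_tsv",
]

#: position whose germline-directed leucine substitution is flagged: it raises
#: thermostability but promotes aggregation at high concentration.
CAUTION_POSITION = 50
CAUTION_RESIDUE = "L"


@dataclass(frozen=True)
class GermlineReference:
    """A human germline framework reference (FR1–FR3 must be annotated)."""

    id: str
    sequence: AnnotatedNanobody

    def __post_init__(self) -> None:
        for name in ("FR1", "FR2", "FR3"):
            if not self.sequence.region_indices(name):
                raise ValueError(f"germline reference must cover {name}")


@dataclass(frozen=True)
class SubstitutionRecord:
    imgt_position: ImgtPos
    from_residue: str
    to_residue: str
    source: Literal["hallmark", "consensus"]
    conservation: float | None = None
    caution_flag: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.from_residue == self.to_residue:
            raise ValueError("substitution must change the residue")


@dataclass
class ScaffoldDesign:
    template: AnnotatedNanobody
    substitutions: tuple[SubstitutionRecord, ...]
    scaffold: AnnotatedNanobody
    humanness_before: float | None = None
    humanness_after: float | None = None

    @property
    def scaffold_sequence(self) -> AminoAcidSequence:
        return self.scaffold.sequence

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)


def propose_hallmark_humanization(
    template: AnnotatedNanobody,
    germline: GermlineReference,
    hallmarks: Iterable[int] | None = None,
) -> list[SubstitutionRecord]:
    """Propose germline-directed substitutions at the FR2 hallmark positions.

    Substitutions introducing L at position 50 carry a caution flag.
    """
    positions = sorted(hallmarks) if hallmarks else sorted(
        template.scheme.hallmark_positions
    )
    records = []
    for pos in positions:
        t_res = template.residue_at(pos)
        g_res = germline.sequence.residue_at(pos)
        if t_res is None or g_res is None:
            raise ValueError(f"hallmark position {pos} unresolvable")
        if t_res == g_res:
            continue
        caution = pos == CAUTION_POSITION and g_res == CAUTION_RESIDUE
        records.append(
            SubstitutionRecord(
                (pos, 0),
                t_res,
                g_res,
                source="hallmark",
                caution_flag=caution,
                note=(
                    "L50 raises thermostability but favors aggregation at high "
                    "concentration" if caution else ""
                ),
            )
        )
    return records


def propose_consensus_substitutions(
    template: AnnotatedNanobody,
    consensus: ConsensusProfile,
    germline: GermlineReference,
    k: int,
) -> list[SubstitutionRecord]:
    """Top-``k`` framework positions where the template disagrees with consensus.

    Ranking: conservation descending, then consensus-matches-germline first,
    then ascending IMGT position.
    """
    if len(consensus) == 0:
        raise ValueError("empty consensus profile")
    if k < 0:
        raise ValueError("k must be non-negative")
    scheme = template.scheme
    candidates = []
    for entry in consensus:
        pos_num = entry.position[0]
        if not scheme.region_of(pos_num).startswith("FR"):
            continue
        t_res = template.residue_at(entry.position)
        if t_res is None or t_res == entry.residue:
            continue
        g_res = germline.sequence.residue_at(entry.position)
        germline_agrees = g_res == entry.residue
        candidates.append((entry, t_res, germline_agrees))
    candidates.sort(
        key=lambda c: (-c[0].conservation, not c[2], c[0].position)
    )
    if len(candidates) < k:
        warnings.warn(
            f"only {len(candidates)} consensus candidates available for k={k}"
        )
    return [
        SubstitutionRecord(
            entry.position,
            t_res,
            entry.residue,
            source="consensus",
            conservation=entry.conservation,
            note="matches germline" if agrees else "",
        )
        for entry, t_res, agrees in candidates[:k]
    ]


def humanness_score(
    seq: AnnotatedNanobody,
    germline: GermlineReference,
    regions: Literal["framework", "full"] = "framework",
) -> float:
    """Identity to the germline over the selected regions (global alignment)."""
    if regions == "framework":
        names = [
            n
            for n in seq.scheme.framework_regions
            if germline.sequence.region_indices(n)
        ]
        a = "".join(seq.region_seq(n) for n in names)
        b = "".join(germline.sequence.region_seq(n) for n in names)
    else:
        a = seq.sequence.residues
        b = germline.sequence.sequence.residues
    return global_align(a, b).identity


def apply_design(
    template: AnnotatedNanobody,
    substitutions: Sequence[SubstitutionRecord],
    germline: GermlineReference | None = None,
) -> ScaffoldDesign:
    """Apply framework substitutions to the template and emit the scaffold.

    Verifies that the scaffold differs from the template at exactly
    ``len(substitutions)`` positions.
    """
    seen: set[ImgtPos] = set()
    residues = list(template.sequence.residues)
    for rec in substitutions:
        if rec.imgt_position in seen:
            raise ValueError(
                f"conflicting substitutions at {fmt_pos(rec.imgt_position)}"
            )
        seen.add(rec.imgt_position)
        if not template.scheme.region_of(rec.imgt_position[0]).startswith("FR"):
            raise ValueError(
                f"substitution at CDR position {fmt_pos(rec.imgt_position)} "
                "rejected: framework-only contract"
            )
        try:
            idx = template.position_map.index(rec.imgt_position)
        except ValueError:
            raise ValueError(
                f"position {fmt_pos(rec.imgt_position)} absent from template"
            ) from None
        if residues[idx] != rec.from_residue:
            raise ValueError(
                f"template has {residues[idx]} at {fmt_pos(rec.imgt_position)}, "
                f"record says {rec.from_residue}"
            )
        residues[idx] = rec.to_residue

    scaffold_seq = AminoAcidSequence(
        f"{template.sequence.id}_scaffold", "".join(residues)
    )
    scaffold = AnnotatedNanobody(scaffold_seq, template.scheme, template.position_map)
    n_diff = sum(
        1
        for a, b in zip(template.sequence.residues, scaffold_seq.residues)
        if a != b
    )
    if n_diff != len(substitutions):
        raise AssertionError(
            f"scaffold differs at {n_diff} positions, expected {len(substitutions)}"
        )
    before = after = None
    if germline is not None:
        before = humanness_score(template, germline)
        after = humanness_score(scaffold, germline)
    return ScaffoldDesign(template, tuple(substitutions), scaffold, before, after)


def write_design_tsv(design: ScaffoldDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("imgt_position\tfrom\tto\tsource\tconservation\tcaution\tnote\n")
        for rec in design.substitutions:
            cons = "" if rec.conservation is None else f"{rec.conservation:.4f}"
            fh.write(
                f"{fmt_pos(rec.imgt_position)}\t{rec.from_residue}\t"
                f"{rec.to_residue}\t{rec.source}\t{cons}\t"
                f"{int(rec.caution_flag)}\t{rec.note}\n"
            )
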