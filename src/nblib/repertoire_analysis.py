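"""Repertoire curation and positional statistics.

Greedy identity clustering for redundancy removal, complex-dataset curation
filters, per-position amino-acid frequency profiles, consensus distillation,
and the hallmark-residue vs CDR3-length association.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .seq_core import (
    AA_LETTERS,
    AminoAcidSequence,
    AnnotatedNanobody,
    ImgtPos,
    ImgtScheme,
    fmt_pos,
    global_align,
    parse_pos,
)

__all__ = [
    "ComplexRecord",
    "ConsensusEntry",
    "ConsensusProfile",
    "CurationCriteria",
    "CurationResult",
    "HallmarkAssociation",
    "PositionalProfile",
    "Repertoire",
    "curate_complex_dataset",
    "dedup_cluster",
    "distill_consensus",
    "hallmark_cdr3_association",
    "positional_profile",
    "read_complex_csv",
    "write_complex_csv",
]


@dataclass
class Repertoire:
    members: list[AnnotatedNanobody]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.members:
            scheme = self.members[0].scheme
            if any(m.scheme != scheme for m in self.members):
                raise ValueError("all members must share one scheme")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def scheme(self) -> ImgtScheme:
        if not self.members:
            raise ValueError("empty repertoire")
        return self.members[0].scheme


def dedup_cluster(
    rep: Repertoire, threshold: float
) -> tuple[list[list[AnnotatedNanobody]], Repertoire]:
    """Greedy longest-first identity clustering, CD-HIT style.

    A sequence joins the first existing cluster whose representative shares
    pairwise global-alignment identity strictly above ``threshold``; otherwise
    it founds a new cluster.  Returns the clusters and the representatives.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if not rep.members:
        raise ValueError("empty repertoire")
    ordered = sorted(
        rep.members, key=lambda m: (-len(m.sequence), m.sequence.id)
    )
    clusters: list[list[AnnotatedNanobody]] = []
    for member in ordered:
        for cluster in clusters:
            rep_seq = cluster[0].sequence
            if member.sequence.residues == rep_seq.residues:
                cluster.append(member)
                break
            if global_align(member.sequence, rep_seq).identity > threshold:
                cluster.append(member)
                break
        else:
            clusters.append([member])
    representatives = Repertoire(
        [c[0] for c in clusters], provenance=f"{rep.provenance}|dedup>{threshold}"
    )
    return clusters, representatives


@dataclass(frozen=True)
class CurationCriteria:
    allowed_cdr3_lengths: frozenset[int] = frozenset({8, 11, 14})
    max_resolution: float = 3.0
    identity_threshold: float = 0.9
    distinct_antigens_required: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")
        if any(l <= 0 for l in self.allowed_cdr3_lengths):
            raise ValueError("CDR3 lengths must be positive")


@dataclass(frozen=True)
class ComplexRecord:
    id: str
    nanobody_seq: AminoAcidSequence
    cdr3_length: int
    resolution: float
    antigen_id: str

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


@dataclass
class CurationResult:
    survivors: list[ComplexRecord]
    removed: dict[str, int]
    empty_result: bool = False

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def curate_complex_dataset(
    records: Sequence[ComplexRecord], criteria: CurationCriteria
) -> CurationResult:
    """Apply, in order: CDR3-length, resolution, identity, distinct-antigen filters."""
    kept = list(records)
    removed: dict[str, int] = {}

    n0 = len(kept)
    kept = [r for r in kept if r.cdr3_length in criteria.allowed_cdr3_lengths]
    removed["cdr3_length"] = n0 - len(kept)

    n0 = len(kept)
    kept = [r for r in kept if r.resolution <= criteria.max_resolution]
    removed["resolution"] = n0 - len(kept)

    n0 = len(kept)
    if kept:
        # greedy longest-first reduction on the nanobody sequences
        ordered = sorted(
            kept, key=lambda r: (-len(r.nanobody_seq), r.nanobody_seq.id)
        )
        rep_records: list[ComplexRecord] = []
        for rec in ordered:
            if not any(
                rec.nanobody_seq.residues == kr.nanobody_seq.residues
                or global_align(rec.nanobody_seq, kr.nanobody_seq).identity
                > criteria.identity_threshold
                for kr in rep_records
            ):
                rep_records.append(rec)
        keep_ids = {r.id for r in rep_records}
        kept = [r for r in kept if r.id in keep_ids]
    removed["identity"] = n0 - len(kept)

    n0 = len(kept)
    if criteria.distinct_antigens_required:
        seen: set[str] = set()
        deduped = []
        for rec in kept:
            if rec.antigen_id not in seen:
                seen.add(rec.antigen_id)
                deduped.append(rec)
        kept = deduped
    removed["antigen"] = n0 - len(kept)

    return CurationResult(kept, removed, empty_result=not kept)


@dataclass
class PositionalProfile:
    """Per-IMGT-position empirical amino-acid frequencies over a repertoire."""

    positions: tuple[ImgtPos, ...]
    freq: dict[ImgtPos, dict[str, float]]
    support: dict[ImgtPos, int]

    def defined(self, pos: ImgtPos) -> bool:
        return self.support.get(pos, 0) > 0

    def to_frame(self) -> pd.DataFrame:
        rows = {
            fmt_pos(p): {aa: self.freq[p].get(aa, 0.0) for aa in AA_LETTERS}
            for p in self.positions
            if self.defined(p)
        }
        return pd.DataFrame.from_dict(rows, orient="index")[list(AA_LETTERS)]

    def to_tsv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.insert(0, "support", [self.support[parse_pos(p)] for p in frame.index])
        frame.to_csv(path, sep="\t", index_label="imgt_position")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PositionalProfile":
        frame = pd.read_csv(path, sep="\t", index_col="imgt_position")
        positions = tuple(parse_pos(str(p)) for p in frame.index)
        freq = {}
        support = {}
        for p, (_, row) in zip(positions, frame.iterrows()):
            support[p] = int(row["support"])
            freq[p] = {
                aa: float(row[aa]) for aa in AA_LETTERS if float(row[aa]) > 0
            }
        return cls(positions, freq, support)


def positional_profile(rep: Repertoire) -> PositionalProfile:
    """Empirical residue frequencies per IMGT position; gaps carry no counts."""
    counts: dict[ImgtPos, Counter] = {}
    for member in rep.members:
        for idx, pos in enumerate(member.position_map):
            res = member.sequence.residues[idx]
            if res in ("-", "X"):
                continue
            counts.setdefault(pos, Counter())[res] += 1
    positions = tuple(sorted(counts))
    freq: dict[ImgtPos, dict[str, float]] = {}
    support: dict[ImgtPos, int] = {}
    for pos in positions:
        total = sum(counts[pos].values())
        support[pos] = total
        freq[pos] = {aa: n / total for aa, n in sorted(counts[pos].items())}
    return PositionalProfile(positions, freq, support)


@dataclass(frozen=True)
class ConsensusEntry:
    position: ImgtPos
    residue: str
    conservation: float
    tie: bool = False


@dataclass
class ConsensusProfile:
    entries: dict[ImgtPos, ConsensusEntry]

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)


def distill_consensus(
    profile: PositionalProfile,
    min_conservation: float,
    positions: Iterable[ImgtPos] | None = None,
) -> ConsensusProfile:
    """Keep positions whose modal residue reaches ``min_conservation``.

    Frequency ties are broken alphabetically and flagged; undefined positions
    are skipped.
    """
    wanted = tuple(positions) if positions is not None else profile.positions
    entries: dict[ImgtPos, ConsensusEntry] = {}
    for pos in wanted:
        if not profile.defined(pos):
            continue
        dist = profile.freq[pos]
        best = max(dist.values())
        modal = sorted(aa for aa, f in dist.items() if f == best)
        if best >= min_conservation:
            entries[pos] = ConsensusEntry(pos, modal[0], best, tie=len(modal) > 1)
    return ConsensusProfile(entries)


@dataclass
class HallmarkAssociation:
    """Hallmark residue usage split by CDR3 length (≤ split vs > split)."""

    split_length: int
    tables: dict[str, dict[int, dict[str, float]]]  # partition -> pos -> aa -> freq
    sizes: dict[str, int]
    undefined: tuple[str, ...] = ()

    def logo_matrix(self, partition: str) -> pd.DataFrame:
        """Sequence-logo-ready matrix: rows = hallmark positions, cols = residues."""
        table = self.tables[partition]
        return pd.DataFrame.from_dict(
            {
                str(pos): {aa: table[pos].get(aa, 0.0) for aa in AA_LETTERS}
                for pos in sorted(table)
            },
            orient="index",
        )[list(AA_LETTERS)]


def hallmark_cdr3_association(
    rep: Repertoire, split_length: int = 14
) -> HallmarkAssociation:
    """Partition by CDR3 length and tabulate residue frequencies at hallmarks."""
    if split_length <= 0:
        raise ValueError("split_length must be positive")
    if not rep.members:
        raise ValueError("empty repertoire")
    scheme = rep.scheme
    hallmarks = sorted(scheme.hallmark_positions)
    parts = {
        "short": [m for m in rep.members if m.cdr3_length <= split_length],
        "long": [m for m in rep.members if m.cdr3_length > split_length],
    }
    tables: dict[str, dict[int, dict[str, float]]] = {}
    undefined: list[str] = []
    for name, members in parts.items():
        if not members:
            undefined.append(name)
            tables[name] = {}
            continue
        table: dict[int, dict[str, float]] = {}
        for pos in hallmarks:
            counter: Counter = Counter()
            for m in members:
                res = m.residue_at(pos)
                if res is not None:
                    counter[res] += 1
            total = sum(counter.values())
            table[pos] = (
                {aa: n / total for aa, n in sorted(counter.items())} if total else {}
            )
        tables[name] = table
    return HallmarkAssociation(
        split_length,
        tables,
        {name: len(members) for name, members in parts.items()},
        tuple(undefined),
    )


# ---------------------------------------------------------------------------
# complex-record CSV I/O: header `id,seq,cdr3_len,resolution,antigen`

def read_complex_csv(path: str | Path) -> list[ComplexRecord]:
    frame = pd.read_csv(path)
    records = []
    for _, row in frame.iterrows():
        records.append(
            ComplexRecord(
                id=str(row["id"]),
                nanobody_seq=AminoAcidSequence(str(row["id"]), str(row["seq"])),
                cdr3_length=int(row["cdr3_len"]),
                resolution=float(row["resolution"]),
                antigen_id=str(row["antigen"]),
            )
        )
    return records


def write_complex_csv(records: Iterable[ComplexRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": r.id,
                "seq": r.nanobody_seq.residues,
                "cdr3_len": r.cdr3_length,
                "resolution": r.resolution,
                "antigen": r.antigen_id,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
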