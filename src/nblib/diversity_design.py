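"""CDR randomization strategy and degenerate-codon optimization.

A single IUPAC triplet is chosen per diversified position by exhaustive search
over all 3,375 triplets, minimizing total-variation distance to the target
amino-acid distribution plus soft penalties for stop codons and cysteine.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Literal, Mapping, Sequence

import yaml

from .repertoire_analysis import PositionalProfile
from .seq_core import (
    AA_LETTERS,
    CODON_TABLE,
    IMGT_SCHEME,
    IUPAC_NT,
    ImgtPos,
    ImgtScheme,
    fmt_pos,
    parse_pos,
    place_loop,
)

__all__ = [
    "CodonChoice",
    "DegenerateCodon",
    "DiversitySpec",
    "PositionSpec",
    "SpecSummary",
    "build_diversity_spec",
    "choose_codons",
    "codon_aa_distribution",
    "optimize_degenerate_codon",
    "spec_summary",
    "total_variation",
    "write_codon_plan_tsv",
    "read_codon_plan_tsv",
]

_IUPAC_LETTERS = sorted(IUPAC_NT)  # lexicographic order fixes tie-breaks


@dataclass(frozen=True)
class DegenerateCodon:
    """An IUPAC triplet with its expanded codon set and implied distributions."""

    iupac_triplet: str
    codon_set: tuple[str, ...]
    aa_dist: tuple[tuple[str, float], ...]
    stop_fraction: float
    cys_fraction: float

    @property
    def aa_distribution(self) -> dict[str, float]:
        return dict(self.aa_dist)

    @property
    def n_codons(self) -> int:
        return len(self.codon_set)


@lru_cache(maxsize=None)
def codon_aa_distribution(iupac_triplet: str) -> DegenerateCodon:
    """Expand an IUPAC triplet uniformly and tabulate its amino-acid distribution."""
    triplet = iupac_triplet.upper()
    if len(triplet) != 3 or any(b not in IUPAC_NT for b in triplet):
        raise ValueError(f"invalid IUPAC triplet {iupac_triplet!r}")
    codons = tuple(
        "".join(bases)
        for bases in itertools.product(*(IUPAC_NT[b] for b in triplet))
    )
    n = len(codons)
    counts: dict[str, int] = {}
    for codon in codons:
        aa = CODON_TABLE[codon]
        counts[aa] = counts.get(aa, 0) + 1
    stop = counts.pop("*", 0) / n
    dist = tuple(sorted((aa, c / n) for aa, c in counts.items()))
    return DegenerateCodon(triplet, codons, dist, stop, counts.get("C", 0) / n)


def total_variation(p: Mapping[str, float], q: Mapping[str, float]) -> float:
    """TV distance over the union of outcome supports."""
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


@dataclass(frozen=True)
class CodonChoice:
    position: str  # e.g. "CDR1:28" or "CDR3[11]:107"
    codon: DegenerateCodon
    divergence: float
    penalty_terms: tuple[tuple[str, float], ...]

    @property
    def objective(self) -> float:
        return self.divergence + sum(v for _, v in self.penalty_terms)


@lru_cache(maxsize=1)
def _all_degenerate_codons() -> tuple[DegenerateCodon, ...]:
    return tuple(
        codon_aa_distribution("".join(t))
        for t in itertools.product(_IUPAC_LETTERS, repeat=3)
    )


def optimize_degenerate_codon(
    target: Mapping[str, float],
    stop_penalty: float = 10.0,
    cys_penalty: float = 5.0,
    position: str = "",
) -> CodonChoice:
    """Exhaustive search over all 3,375 IUPAC triplets.

    Objective: TV(target, implied distribution incl. stop mass) +
    stop_penalty * stop_fraction + cys_penalty * cys_fraction.  Ties resolve
    to the lexicographically first triplet.  Infinite penalties exclude any
    triplet with positive mass on the penalized outcome.
    """
    total = sum(target.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"target distribution sums to {total}, expected 1")
    best: CodonChoice | None = None
    for dc in _all_degenerate_codons():
        if stop_penalty == float("inf") and dc.stop_fraction > 0:
            continue
        if cys_penalty == float("inf") and dc.cys_fraction > 0:
            continue
        implied = dict(dc.aa_dist)
        if dc.stop_fraction:
            implied["*"] = dc.stop_fraction
        div = total_variation(target, implied)
        penalties = (
            ("stop", (stop_penalty * dc.stop_fraction) if dc.stop_fraction else 0.0),
            ("cys", (cys_penalty * dc.cys_fraction) if dc.cys_fraction else 0.0),
        )
        choice = CodonChoice(position, dc, div, penalties)
        if best is None or choice.objective < best.objective - 1e-12:
            best = choice
    assert best is not None
    return best


@dataclass(frozen=True)
class PositionSpec:
    """Randomization plan for one IMGT position."""

    imgt_position: ImgtPos
    mode: Literal["fixed", "anchored", "natural"]
    target_dist: tuple[tuple[str, float], ...]
    anchor_residue: str | None = None
    anchor_floor: float | None = None

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.target_dist)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"target_dist sums to {total}")
        dist = dict(self.target_dist)
        if self.mode == "fixed":
            if len(dist) != 1:
                raise ValueError("fixed position must be a point mass")
        if self.mode == "anchored":
            if self.anchor_residue is None or self.anchor_floor is None:
                raise ValueError("anchored position needs residue and floor")
            if dist.get(self.anchor_residue, 0.0) < self.anchor_floor - 1e-9:
                raise ValueError("anchored mass below floor")

    @property
    def target(self) -> dict[str, float]:
        return dict(self.target_dist)


@dataclass
class DiversitySpec:
    """Per-position randomization plans for CDR1/CDR2 (fixed length 8) and the
    CDR3 length classes, plus CDR3 length sampling weights."""

    cdr1_specs: tuple[PositionSpec, ...]
    cdr2_specs: tuple[PositionSpec, ...]
    cdr3_specs: dict[int, tuple[PositionSpec, ...]]
    length_weights: dict[int, float]

    def __post_init__(self) -> None:
        if len(self.cdr1_specs) != 8 or len(self.cdr2_specs) != 8:
            raise ValueError("CDR1 and CDR2 must each have exactly 8 positions")
        for length, specs in self.cdr3_specs.items():
            if len(specs) != length:
                raise ValueError(f"CDR3[{length}] has {len(specs)} specs")
        if set(self.length_weights) != set(self.cdr3_specs):
            raise ValueError("length_weights keys must match cdr3_specs")
        total = sum(self.length_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length_weights sum to {total}")

    @property
    def cdr3_lengths(self) -> tuple[int, ...]:
        return tuple(sorted(self.cdr3_specs))

    def position_groups(self) -> list[tuple[str, int | None, tuple[PositionSpec, ...]]]:
        groups: list[tuple[str, int | None, tuple[PositionSpec, ...]]] = [
            ("CDR1", None, self.cdr1_specs),
            ("CDR2", None, self.cdr2_specs),
        ]
        for length in self.cdr3_lengths:
            groups.append(("CDR3", length, self.cdr3_specs[length]))
        return groups

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def enc(spec: PositionSpec) -> dict:
            d = {
                "imgt_position": fmt_pos(spec.imgt_position),
                "mode": spec.mode,
                "target_dist": {aa: float(f) for aa, f in spec.target_dist},
            }
            if spec.anchor_residue is not None:
                d["anchor_residue"] = spec.anchor_residue
                d["anchor_floor"] = float(spec.anchor_floor)
            return d

        return {
            "cdr1": [enc(s) for s in self.cdr1_specs],
            "cdr2": [enc(s) for s in self.cdr2_specs],
            "cdr3": {int(k): [enc(s) for s in v] for k, v in self.cdr3_specs.items()},
            "length_weights": {int(k): float(v) for k, v in self.length_weights.items()},
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "DiversitySpec":
        def dec(d: Mapping) -> PositionSpec:
            return PositionSpec(
                imgt_position=parse_pos(d["imgt_position"]),
                mode=d["mode"],
                target_dist=tuple(sorted(d["target_dist"].items())),
                anchor_residue=d.get("anchor_residue"),
                anchor_floor=d.get("anchor_floor"),
            )

        return cls(
            cdr1_specs=tuple(dec(d) for d in data["cdr1"]),
            cdr2_specs=tuple(dec(d) for d in data["cdr2"]),
            cdr3_specs={
                int(k): tuple(dec(d) for d in v) for k, v in data["cdr3"].items()
            },
            length_weights={int(k): float(v) for k, v in data["length_weights"].items()},
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DiversitySpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _strip_cys(dist: Mapping[str, float]) -> dict[str, float]:
    """Remove Cys mass and renormalize proportionally."""
    kept = {aa: f for aa, f in dist.items() if aa != "C" and f > 0}
    total = sum(kept.values())
    if total <= 0:
        raise ValueError("distribution has no non-Cys support")
    return {aa: f / total for aa, f in kept.items()}


def cdr_positions(
    scheme: ImgtScheme, region: str, length: int
) -> tuple[ImgtPos, ...]:
    start, end = scheme.span(region)
    return place_loop(start, end, length)


def build_diversity_spec(
    profile: PositionalProfile,
    anchors: Mapping[int, str] | None = None,
    lengths: Sequence[int] = (8, 11, 14),
    anchor_floor: float = 0.5,
    length_weights: Mapping[int, float] | None = None,
    fixed: Mapping[int, str] | None = None,
    scheme: ImgtScheme = IMGT_SCHEME,
) -> DiversitySpec:
    """Assemble the randomization strategy over the CDR positions.

    Anchored positions mix ``anchor_floor`` mass on the anchor residue with the
    Cys-free natural distribution; natural positions take the Cys-free profile
    distribution; fixed positions are point masses.
    """
    anchors = dict(anchors) if anchors is not None else scheme.anchor_map()
    fixed = dict(fixed or {})
    weights = (
        {int(l): float(w) for l, w in length_weights.items()}
        if length_weights
        else {int(l): 1.0 / len(lengths) for l in lengths}
    )

    def spec_for(pos: ImgtPos) -> PositionSpec:
        num = pos[0]
        if num in fixed:
            return PositionSpec(pos, "fixed", ((fixed[num], 1.0),))
        if profile.defined(pos):
            natural = _strip_cys(profile.freq[pos])
        else:
            warnings.warn(
                f"profile lacks position {fmt_pos(pos)}; using uniform non-Cys"
            )
            non_cys = [aa for aa in AA_LETTERS if aa != "C"]
            natural = {aa: 1.0 / len(non_cys) for aa in non_cys}
        if num in anchors:
            anchor = anchors[num]
            if anchor not in natural:
                warnings.warn(
                    f"anchor residue {anchor} absent from profile support at "
                    f"{fmt_pos(pos)}"
                )
            mixed = {aa: (1.0 - anchor_floor) * f for aa, f in natural.items()}
            mixed[anchor] = mixed.get(anchor, 0.0) + anchor_floor
            return PositionSpec(
                pos,
                "anchored",
                tuple(sorted(mixed.items())),
                anchor_residue=anchor,
                anchor_floor=anchor_floor,
            )
        return PositionSpec(pos, "natural", tuple(sorted(natural.items())))

    cdr1 = tuple(spec_for(p) for p in cdr_positions(scheme, "CDR1", 8))
    cdr2 = tuple(spec_for(p) for p in cdr_positions(scheme, "CDR2", 8))
    cdr3 = {
        int(l): tuple(spec_for(p) for p in cdr_positions(scheme, "CDR3", int(l)))
        for l in lengths
    }
    return DiversitySpec(cdr1, cdr2, cdr3, weights)


def choose_codons(
    spec: DiversitySpec,
    stop_penalty: float = 10.0,
    cys_penalty: float = 5.0,
) -> dict[str, CodonChoice]:
    """Optimize one degenerate codon per spec position.

    Keys are ``"CDR1:<pos>"``, ``"CDR2:<pos>"`` and ``"CDR3[<len>]:<pos>"``.
    """
    plan: dict[str, CodonChoice] = {}
    for region, length, specs in spec.position_groups():
        tag = region if length is None else f"{region}[{length}]"
        for pspec in specs:
            key = f"{tag}:{fmt_pos(pspec.imgt_position)}"
            plan[key] = optimize_degenerate_codon(
                pspec.target, stop_penalty, cys_penalty, position=key
            )
    return plan


@dataclass
class SpecSummary:
    expected_stop_clone_fraction: dict[int, float]
    expected_cys_clone_fraction: dict[int, float]
    overall_stop_clone_fraction: float
    overall_cys_clone_fraction: float
    divergence_table: dict[str, float]
    theoretical_size: dict[int, float]


def spec_summary(spec: DiversitySpec, codon_choices: Mapping[str, CodonChoice]) -> SpecSummary:
    """Closed-form library expectations from the chosen codons.

    Per CDR3 length class: expected stop/Cys-bearing clone fraction
    ``1 - prod(1 - f_i)`` and theoretical sequence-space size
    ``prod(|support_i|)``; overall figures weight classes by length weight.
    """
    def keys_for(length: int) -> list[str]:
        keys = [f"CDR1:{fmt_pos(s.imgt_position)}" for s in spec.cdr1_specs]
        keys += [f"CDR2:{fmt_pos(s.imgt_position)}" for s in spec.cdr2_specs]
        keys += [
            f"CDR3[{length}]:{fmt_pos(s.imgt_position)}"
            for s in spec.cdr3_specs[length]
        ]
        return keys

    stop_frac: dict[int, float] = {}
    cys_frac: dict[int, float] = {}
    size: dict[int, float] = {}
    for length in spec.cdr3_lengths:
        p_no_stop = 1.0
        p_no_cys = 1.0
        n_space = 1.0
        for key in keys_for(length):
            dc = codon_choices[key].codon
            p_no_stop *= 1.0 - dc.stop_fraction
            p_no_cys *= 1.0 - dc.cys_fraction
            n_space *= len(dc.aa_dist)
        stop_frac[length] = 1.0 - p_no_stop
        cys_frac[length] = 1.0 - p_no_cys
        size[length] = n_space
    overall_stop = sum(
        spec.length_weights[l] * stop_frac[l] for l in spec.cdr3_lengths
    )
    overall_cys = sum(
        spec.length_weights[l] * cys_frac[l] for l in spec.cdr3_lengths
    )
    divergences = {key: choice.divergence for key, choice in codon_choices.items()}
    return SpecSummary(stop_frac, cys_frac, overall_stop, overall_cys, divergences, size)


def write_codon_plan_tsv(
    codon_choices: Mapping[str, CodonChoice], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("position\ttriplet\tdivergence\tstop_fraction\tcys_fraction\n")
        for key in sorted(codon_choices):
            c = codon_choices[key]
            fh.write(
                f"{key}\t{c.codon.iupac_triplet}\t{c.divergence:.6f}\t"
                f"{c.codon.stop_fraction:.6f}\t{c.codon.cys_fraction:.6f}\n"
            )


def read_codon_plan_tsv(path: str | Path) -> dict[str, CodonChoice]:
    plan: dict[str, CodonChoice] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            key, triplet, div, _, _ = line.rstrip("\n").split("\t")
            dc = codon_aa_distribution(triplet)
            plan[key] = CodonChoice(key, dc, float(div), (("stop", 0.0), ("cys", 0.0)))
    return plan
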