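"""Seeded generators for every input the pipeline consumes: repertoires with
controlled positional conservation, two-state melt curves, 4PL binding series,
and error-bearing clone reads with ground-truth defect labels.

Also hosts the packaged example scaffold/template/germline fixtures used by
tests and the CLI demos.  The fixtures are illustrative VHH-like sequences,
not any published scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assay_analysis import BindingSeries, MeltCurve
from .diversity_design import CodonChoice, DiversitySpec
from .library_build import (
    CloneRecord,
    ErrorModel,
    sample_library,
    simulate_synthesis_errors,
)
from .repertoire_analysis import Repertoire
from .seq_core import (
    AA_LETTERS,
    IMGT_SCHEME,
    AminoAcidSequence,
    AnnotatedNanobody,
    ImgtPos,
    ImgtScheme,
    annotate_anchor,
    place_loop,
)

__all__ = [
    "AssayModel",
    "RepertoireModel",
    "example_germline",
    "example_scaffold",
    "example_template",
    "gen_binding_series",
    "gen_clone_reads",
    "gen_melt_curve",
    "gen_repertoire",
]

# ---------------------------------------------------------------------------
# packaged fixtures

_TEMPLATE_REGIONS = {
    "FR1": "QVQLVESGGGLVQAGGSLRLSCAAS",  # 25 aa
    "CDR1": "GAIFANYA",  # 8 aa -> IMGT 27-30 + 35-38; anchors G27/I29/A35
    "FR2": "WVRYAPGKGLQRELVAA",  # 17 aa; hallmarks Y42 Q49 R50 L52
    "CDR2": "ITSGGSTN",  # 8 aa -> IMGT 56-59 + 63-66; anchors I56/G63/T65
    "FR3": "ADSVKGRFTISRDNAKNTVYLQMNSLKPEDTAVYYCAA",  # 38 aa
    "CDR3": "ARDSTYYSGSYDFY",  # 14 aa, anchors A105/Y117
    "FR4": "WGQGTQVTVSS",  # 11 aa
}

_REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")


def _build_fixture(seq_id: str, regions: Mapping[str, str]) -> AnnotatedNanobody:
    seq = AminoAcidSequence(seq_id, "".join(regions[r] for r in _REGION_ORDER))
    lengths = {r: len(regions[r]) for r in _REGION_ORDER}
    return annotate_anchor(seq, IMGT_SCHEME, lengths)


def example_template() -> AnnotatedNanobody:
    """A llama-like VHH template with camelid hallmarks (Y42, Q49, R50, L52)."""
    return _build_fixture("template", _TEMPLATE_REGIONS)


def example_scaffold() -> AnnotatedNanobody:
    """The humanized example scaffold: template with 5 framework substitutions."""
    regions = dict(_TEMPLATE_REGIONS)
    # hallmark substitutions Q49G, R50L plus three consensus substitutions
    fr2 = list(regions["FR2"])
    fr2[49 - 39] = "G"
    fr2[50 - 39] = "L"
    regions["FR2"] = "".join(fr2)
    fr1 = list(regions["FR1"])
    fr1[4] = "L"   # position 5
    fr1[13] = "P"  # position 14
    regions["FR1"] = "".join(fr1)
    fr3 = list(regions["FR3"])
    fr3[83 - 67] = "R"  # position 83
    regions["FR3"] = "".join(fr3)
    return _build_fixture("scaffold", regions)


def example_germline() -> AnnotatedNanobody:
    """A human-VH3-like germline framework fixture covering FR1-FR3."""
    regions = {
        "FR1": "QVQLLESGGGLVQPGGSLRLSCAAS",  # L5, P14
        "CDR1": "GFTFSSYA",
        "FR2": "WVRYAPGKGLGLELVSS",  # hallmarks Y42 G49 L50 L52
        "CDR2": "ISGSGGST",
        "FR3": "ADSVKGRFTISRDNAKRTVYLQMNSLKPEDTAVYYCAA",  # R83
    }
    seq = AminoAcidSequence(
        "germline_vh3", "".join(regions[r] for r in ("FR1", "CDR1", "FR2", "CDR2", "FR3"))
    )
    lengths = {r: len(regions[r]) for r in regions}
    return annotate_anchor(seq, IMGT_SCHEME, lengths)


# ---------------------------------------------------------------------------
# repertoire generator

@dataclass
class RepertoireModel:
    """Position-wise generative model for a synthetic VHH repertoire.

    Residues default to the scaffold residue; ``position_dists`` overrides
    individual positions, and ``length_conditional_dists`` plants CDR3-length-
    conditional residue usage (e.g. hallmark associations) keyed by partition
    ("short"/"long" relative to ``split_length``).
    """

    scaffold: AnnotatedNanobody
    n_sequences: int
    seed: int
    cdr3_length_weights: Mapping[int, float] = field(
        default_factory=lambda: {8: 1 / 3, 11: 1 / 3, 14: 1 / 3}
    )
    position_dists: Mapping[ImgtPos, Mapping[str, float]] = field(default_factory=dict)
    length_conditional_dists: Mapping[
        str, Mapping[ImgtPos, Mapping[str, float]]
    ] = field(default_factory=dict)
    split_length: int = 14
    cdr_entropy: float = 0.0  # mass spread uniformly over residues at CDR sites

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        total = sum(self.cdr3_length_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("cdr3_length_weights must sum to 1")


def _draw(rng: np.random.Generator, dist: Mapping[str, float]) -> str:
    letters = sorted(dist)
    probs = np.array([dist[l] for l in letters], dtype=float)
    return letters[rng.choice(len(letters), p=probs / probs.sum())]


def gen_repertoire(model: RepertoireModel) -> Repertoire:
    """Draw sequences position-wise; deterministic under the model seed."""
    rng = np.random.default_rng(model.seed)
    scheme = model.scaffold.scheme
    lengths = sorted(model.cdr3_length_weights)
    weights = np.array([model.cdr3_length_weights[l] for l in lengths], dtype=float)
    weights /= weights.sum()

    scaffold_res = {
        pos: model.scaffold.sequence.residues[i]
        for i, pos in enumerate(model.scaffold.position_map)
    }
    cdr3_span = scheme.span("CDR3")
    members = []
    for i in range(model.n_sequences):
        cdr3_len = int(lengths[rng.choice(len(lengths), p=weights)])
        partition = "short" if cdr3_len <= model.split_length else "long"
        cond = model.length_conditional_dists.get(partition, {})
        pos_map: list[ImgtPos] = []
        for pos in model.scaffold.position_map:
            if cdr3_span[0] <= pos[0] <= cdr3_span[1]:
                continue
            pos_map.append(pos)
        cdr3_positions = place_loop(*cdr3_span, cdr3_len)
        # keep the map ordered: everything before CDR3, CDR3, FR4
        fr4_start = scheme.span("FR4")[0]
        head = [p for p in pos_map if p[0] < cdr3_span[0]]
        tail = [p for p in pos_map if p[0] >= fr4_start]
        full_map = head + list(cdr3_positions) + tail

        residues = []
        for pos in full_map:
            dist = cond.get(pos) or model.position_dists.get(pos)
            if dist is None:
                base = scaffold_res.get(pos)
                if base is None:  # CDR3 position absent from scaffold length
                    base = "G"
                if model.cdr_entropy > 0 and scheme.region_of(pos[0]).startswith("CDR"):
                    dist = {
                        aa: model.cdr_entropy / len(AA_LETTERS) for aa in AA_LETTERS
                    }
                    dist[base] = dist.get(base, 0.0) + (1.0 - model.cdr_entropy)
                else:
                    residues.append(base)
                    continue
            residues.append(_draw(rng, dist))
        seq = AminoAcidSequence(f"rep_{i:05d}", "".join(residues))
        members.append(AnnotatedNanobody(seq, scheme, tuple(full_map)))
    return Repertoire(members, provenance=f"synthetic(seed={model.seed})")


# ---------------------------------------------------------------------------
# assay generators

@dataclass
class AssayModel:
    """Ground-truth parameters for synthetic melt and binding data."""

    # melt
    tm: float = 73.7
    transition_slope: float = 1.5
    folded_baseline: tuple[float, float] = (-11000.0, 5.0)
    unfolded_baseline: tuple[float, float] = (-2500.0, 2.0)
    melt_noise_sd: float = 0.0  # absolute signal units
    temp_range: tuple[float, float, float] = (25.0, 95.0, 1.0)
    # binding
    ec50_M: float = 22.16e-9
    hill: float = 1.0
    bottom: float = 0.05
    top: float = 1.8
    binding_noise_sd: float = 0.0  # fraction of top
    n_points: int = 10
    dilution_factor: float = 3.0
    top_concentration_M: float = 1e-6

    def __post_init__(self) -> None:
        if self.melt_noise_sd < 0 or self.binding_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.ec50_M <= 0:
            raise ValueError("EC50 must be positive")


def gen_melt_curve(model: AssayModel, seed: int = 0) -> MeltCurve:
    """Two-state sigmoid with linear baselines plus Gaussian noise."""
    lo, hi, step = model.temp_range
    T = np.arange(lo, hi + step / 2, step)
    f = 1.0 / (1.0 + np.exp((T - model.tm) / model.transition_slope))
    af, bf = model.folded_baseline
    au, bu = model.unfolded_baseline
    y = (af + bf * T) * f + (au + bu * T) * (1.0 - f)
    if model.melt_noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, model.melt_noise_sd, size=len(T))
    return MeltCurve(T, y, metadata={"true_tm": model.tm, "seed": seed})


def gen_binding_series(model: AssayModel, seed: int = 0) -> BindingSeries:
    """Serial-dilution 4PL response with Gaussian noise."""
    conc = model.top_concentration_M / model.dilution_factor ** np.arange(
        model.n_points
    )
    ratio = (model.ec50_M / conc) ** model.hill
    y = model.bottom + (model.top - model.bottom) / (1.0 + ratio)
    if model.binding_noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, model.binding_noise_sd * model.top, size=len(y))
    order = np.argsort(conc)
    return BindingSeries(conc[order], y[order])


def gen_clone_reads(
    scaffold: AnnotatedNanobody,
    spec: DiversitySpec,
    codon_plan: Mapping[str, CodonChoice],
    error_model: ErrorModel,
    n: int,
    seed: int,
) -> list[CloneRecord]:
    """Sample clones and inject synthesis errors; classifications carried on the
    records are the ground-truth labels implied by the injected events."""
    clones = sample_library(scaffold, spec, codon_plan, n, seed)
    return simulate_synthesis_errors(clones, error_model, seed + 1)
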