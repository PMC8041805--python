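"""Synthetic substrates, variant libraries, planted editing levels and reads.

The generator emulates a hairpin substrate with two stems separated by an
internal loop that carries the editing site (optionally as an A:C mismatch).
Editing levels follow a planted logistic function of structural features
(probability of active conformation, structure similarity to WT, mutation
count, A:C-mismatch flag) plus replicate Gaussian noise; reads are drawn
binomially at a configurable coverage.  Everything is deterministic under a
seed, so every pipeline stage is testable without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import annotate as an
from . import fold as fe
from .library import (
    Deletion,
    DesignSpec,
    Insertion,
    Substrate,
    VariantRecord,
    enumerate_designed_variants,
    variant_site_index,
)

__all__ = [
    "SynthSpec",
    "gen_substrate",
    "gen_library",
    "planted_features",
    "plant_editing",
    "gen_reads",
    "write_fastq",
]

_STEM_PAIRS = (("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"))


@dataclass(frozen=True)
class SynthSpec:
    """Layout and statistical parameters of one synthetic experiment."""

    seed: int = 0
    ext5: int = 2
    ext3: int = 2
    stem1: int = 6
    stem2: int = 5
    loop5: int = 1  # 5' width of the internal loop holding the editing site
    loop3: int = 1
    hairpin: int = 4
    ac_mismatch: bool = True
    n_singles: int = 30
    n_doubles: int = 10  # number of disjoint position pairs (4 transversion combos each)
    n_compensatory: int = 0  # number of WT stem pairs rewritten to other canonical pairs
    n_indels: int = 0
    weights: tuple[float, float, float, float] = (2.5, 3.0, -1.0, 1.0)
    # (probability_active_conf, sim_nor_score, num_mutations, A:C flag)
    wt_editing: float = 0.66
    noise_sd: float = 0.02
    replicates: int = 3
    coverage: int = 2000
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.stem1, self.stem2) < 1 or self.hairpin < 3:
            raise ValueError("layout infeasible: stems >= 1 and hairpin >= 3 required")
        if min(self.loop5, self.loop3, self.ext5, self.ext3) < 0:
            raise ValueError("counts must be non-negative")
        if self.loop5 < 1:
            raise ValueError("the 5' internal-loop side must hold the editing site")
        if self.noise_sd < 0 or not 0 <= self.error_rate < 1:
            raise ValueError("invalid noise/error parameters")
        if not 0 < self.wt_editing < 1:
            raise ValueError("wt_editing must be in (0, 1)")


def _layout(spec: SynthSpec) -> tuple[str, int, int]:
    """Designed dot-bracket, editing-site position, mismatch position."""
    db = (
        "." * spec.ext5
        + "(" * spec.stem1
        + "." * spec.loop5
        + "(" * spec.stem2
        + "." * spec.hairpin
        + ")" * spec.stem2
        + "." * spec.loop3
        + ")" * spec.stem1
        + "." * spec.ext3
    )
    site = spec.ext5 + spec.stem1 + 1  # first unpaired position of the loop
    mismatch = spec.ext5 + spec.stem1 + spec.loop5 + 2 * spec.stem2 + spec.hairpin + spec.loop3
    # mismatch = last unpaired position of the 3' loop side (mirrors the site)
    return db, site, mismatch


def gen_substrate(spec: SynthSpec) -> Substrate:
    """Build a substrate whose built-in-model MFE equals the designed layout.

    Stem pair types are drawn from a seeded shuffle and re-drawn (up to a
    bounded number of attempts) until the designed structure is the unique
    deterministic MFE, so downstream stages can rely on the annotation.
    """
    db, site, mismatch = _layout(spec)
    rng = np.random.default_rng(spec.seed)
    pairs_db = fe.dotbracket_pairs(db)
    n = len(db)
    for _attempt in range(64):
        seq = ["A"] * n
        for k, (i, j) in enumerate(sorted(pairs_db)):
            # GC-rich stems with occasional AU keep the design the clear optimum
            b5, b3 = _STEM_PAIRS[rng.integers(0, 2) if rng.random() < 0.8 else rng.integers(0, 4)]
            seq[i], seq[j] = b5, b3
        seq[site - 1] = "A"
        seq[mismatch - 1] = "C" if spec.ac_mismatch else "A"
        # remaining unpaired 3'-loop positions: C avoids spurious AU pairing
        loop3_start = spec.ext5 + spec.stem1 + spec.loop5 + 2 * spec.stem2 + spec.hairpin + 1
        for p in range(loop3_start, loop3_start + spec.loop3):
            if p != mismatch:
                seq[p - 1] = "C"
        sequence = "".join(seq)
        structure, _ = fe.fold_mfe(sequence)
        if structure == db:
            break
    else:
        raise ValueError("layout infeasible: could not realize the designed MFE")

    # Constraint: the 3' strand of the core stem (stem2) must pair upstream.
    stem2_pairs = [
        (i + 1, j + 1)
        for i, j in pairs_db
        if spec.ext5 + spec.stem1 + spec.loop5 < i + 1 <= spec.ext5 + spec.stem1 + spec.loop5 + spec.stem2
    ]
    constraint = ["."] * n
    reference = ["."] * n
    for i, j in stem2_pairs:
        constraint[j - 1] = ">"
        reference[i - 1] = "("
        reference[j - 1] = ")"
    ecs_start = spec.ext5 + spec.stem1 + spec.loop5 + spec.stem2 + spec.hairpin + 1
    return Substrate(
        name=f"synth{spec.seed}",
        wt_sequence=sequence,
        editing_site=site,
        ecs_region=(ecs_start, n - spec.ext3),
        constraint="".join(constraint),
        reference="".join(reference),
        wt_structure=db,
    )


def gen_library(substrate: Substrate, spec: SynthSpec) -> list[VariantRecord]:
    """WT plus a seeded sample of singles, transversion doubles and indels."""
    rng = np.random.default_rng(spec.seed + 1)
    lo = spec.ext5 + 1
    hi = substrate.length - spec.ext3
    design = DesignSpec(region=(lo, hi), singles=True)
    singles = enumerate_designed_variants(substrate, design)
    if spec.n_singles < len(singles):
        keep = rng.choice(len(singles), size=spec.n_singles, replace=False)
        singles = [singles[k] for k in sorted(keep)]

    # Disjoint position pairs (4 transversion combos each): co-mutation
    # grouping stays fine-grained, so position-based splitting is feasible.
    pool = [p for p in range(lo, hi + 1) if p != substrate.editing_site]
    n_pairs = min(-(-spec.n_doubles // 4), len(pool) // 2)
    chosen = rng.choice(len(pool), size=2 * n_pairs, replace=False)
    pair_choices = {
        (pool[min(a, b)], pool[max(a, b)])
        for a, b in zip(chosen[::2], chosen[1::2])
    }
    doubles_design = DesignSpec(
        region=(lo, hi), singles=False, double_pairs=tuple(sorted(pair_choices))
    )
    doubles = enumerate_designed_variants(substrate, doubles_design)[: spec.n_doubles]

    compensatory: list[VariantRecord] = []
    if spec.n_compensatory:
        stem_pairs = [
            (i + 1, j + 1) for i, j in fe.dotbracket_pairs(substrate.wt_structure)
        ][: spec.n_compensatory]
        comp_design = DesignSpec(
            region=(lo, hi), singles=False, compensatory_pairs=tuple(stem_pairs)
        )
        compensatory = [
            v
            for v in enumerate_designed_variants(substrate, comp_design)
            if len(v.mutations) == 2  # both-strand rewrites only; singles covered above
        ]

    # Hairpin-loop indels <= 3 nt; inserted C's keep sequences distinct even
    # inside the loop's A-run.
    indels: list[VariantRecord] = []
    hp_start = spec.ext5 + spec.stem1 + spec.loop5 + spec.stem2 + 1
    for k in range(spec.n_indels):
        if k % 2 == 0:
            mut = Insertion(hp_start + (k // 2) % spec.hairpin, "C" * (1 + k % 3))
        else:
            mut = Deletion(hp_start + (k // 2) % spec.hairpin, 1)
        indels.append(VariantRecord.from_mutations(substrate, (mut,)))

    wt = VariantRecord(id="WT", mutations=(), sequence=substrate.wt_sequence)
    out = [wt] + singles + doubles + compensatory + indels
    seen: set[str] = set()
    unique = []
    for v in out:
        if v.sequence not in seen:
            seen.add(v.sequence)
            unique.append(v)
    return unique


def planted_features(
    variant: VariantRecord,
    substrate: Substrate,
    model: fe.EnergyModel = fe.DEFAULT_MODEL,
    wt_tree: "an.TreeNode | None" = None,
) -> tuple[float, float, float, float]:
    """(probability_active_conf, similarity, num_mutations, A:C flag)."""
    if wt_tree is None:
        wt_structure, _ = fe.fold_mfe(substrate.wt_sequence, model)
        wt_tree = an.to_tree(an.annotate_elements(an.parse_dotbracket(wt_structure)))
    structure, _ = fe.fold_mfe(variant.sequence, model)
    pt = an.parse_dotbracket(structure)
    elements = an.annotate_elements(pt)
    sim = an.similarity_score(wt_tree, an.to_tree(elements))
    if len(variant.sequence) == substrate.length and substrate.constraint:
        res = fe.active_conformation_probability(
            variant.sequence, model, substrate.constraint, substrate.reference
        )
        p_active = res.probability if res.satisfiable else 0.0
    else:
        p_active = 0.0
    site = variant_site_index(substrate, variant.mutations)
    ctx = an.locate_site_context(elements, site, variant.sequence, pt)
    ac = float(
        ctx.site.kind == "internal"
        and ctx.site.dims == (1, 1)
        and ctx.opposing_nt == "C"
    )
    return float(p_active), float(sim), float(variant.num_mutations), ac


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def plant_editing(
    library: Sequence[VariantRecord],
    substrate: Substrate,
    spec: SynthSpec,
    model: fe.EnergyModel = fe.DEFAULT_MODEL,
) -> tuple[list[VariantRecord], dict[str, float]]:
    """Attach replicate editing levels from the planted logistic function.

    The intercept is solved so the WT truth equals ``spec.wt_editing``; the
    function is monotone increasing in probability_active_conf by
    construction (w[0] > 0 in the default weights).  Returns the library with
    editing attached plus the per-variant noiseless truth.
    """
    rng = np.random.default_rng(spec.seed + 2)
    w = np.asarray(spec.weights, dtype=float)
    wt = next((v for v in library if v.is_wt), None)
    if wt is None:
        raise ValueError("library must contain the WT variant")
    wt_structure, _ = fe.fold_mfe(substrate.wt_sequence, model)
    wt_tree = an.to_tree(an.annotate_elements(an.parse_dotbracket(wt_structure)))
    f_wt = np.asarray(planted_features(wt, substrate, model, wt_tree))
    bias = math.log(spec.wt_editing / (1.0 - spec.wt_editing)) - float(w @ f_wt)

    truth: dict[str, float] = {}
    out: list[VariantRecord] = []
    for v in library:
        f = np.asarray(planted_features(v, substrate, model, wt_tree))
        t = _logistic(float(w @ f) + bias)
        truth[v.id] = t
        reps = np.clip(
            t + rng.normal(0.0, spec.noise_sd, size=spec.replicates), 0.0, 1.0
        )
        out.append(v.with_editing(reps))
    return out, truth


def gen_reads(
    variant: VariantRecord,
    substrate: Substrate,
    coverage: int,
    editing: float,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Simulated amplicon reads as (read id, sequence) tuples.

    Binomial(coverage, editing) reads carry G at the editing site, the rest
    A; independent per-base substitution errors occur at ``error_rate``.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    rng = np.random.default_rng(seed)
    site = variant_site_index(substrate, variant.mutations)
    n_edited = int(rng.binomial(coverage, editing))
    reads: list[tuple[str, str]] = []
    others = {b: [c for c in "ACGU" if c != b] for b in "ACGU"}
    for k in range(coverage):
        seq = list(variant.sequence)
        if k < n_edited:
            seq[site - 1] = "G"
        if error_rate > 0.0:
            hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
            for h in hits:
                seq[h] = others[seq[h]][rng.integers(0, 3)]
        reads.append((f"{variant.id}|r{k}", "".join(seq)))
    return reads


def write_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
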