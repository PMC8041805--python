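"""Substrates, variant libraries, read-based editing quantification and
library standardization.

A substrate is a wild-type hairpin-forming sequence with a single editing
site; variants carry substitutions and small indels relative to it.  Editing
levels are quantified from amplicon reads by exact signature matching (the
editing site itself is masked), standardized into library Z-scores, and each
single substitution is classified into one of six sequence-by-structure
categories.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .annotate import PairTable, parse_dotbracket
from .fold import clean_sequence, validate_constraint

__all__ = [
    "Substitution",
    "Insertion",
    "Deletion",
    "Mutation",
    "Substrate",
    "VariantRecord",
    "MutationClass",
    "LibraryStats",
    "DesignSpec",
    "DesignError",
    "DegenerateLibraryError",
    "format_mutations",
    "parse_mutations",
    "apply_mutations",
    "variant_site_index",
    "enumerate_designed_variants",
    "assign_reads_to_variants",
    "zscore_library",
    "library_stats",
    "classify_mutation",
    "save_library",
    "load_library",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CU")
CANONICAL_PAIRS = (("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G"))


class DesignError(ValueError):
    """Library design problem (ambiguous signatures, bad regions...)."""


class DegenerateLibraryError(ValueError):
    """All editing levels identical; the Z-score denominator is zero."""


@dataclass(frozen=True)
class Substitution:
    pos: int  # 1-based, WT coordinates
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class Insertion:
    pos: int  # inserted immediately AFTER this WT position (0 = before start)
    seq: str

    def __str__(self) -> str:
        return f"{self.pos}:ins:{self.seq}"


@dataclass(frozen=True)
class Deletion:
    pos: int  # first deleted WT position
    length: int

    def __str__(self) -> str:
        return f"{self.pos}:del:{self.length}"


Mutation = Union[Substitution, Insertion, Deletion]


def format_mutations(mutations: Sequence[Mutation]) -> str:
    return ";".join(str(m) for m in mutations)


def parse_mutations(text: str) -> tuple[Mutation, ...]:
    """Parse 'pos:ref>alt;pos:ins:SEQ;pos:del:k' (empty string = WT)."""
    text = (text or "").strip()
    if not text or text.upper() == "WT":
        return ()
    out: list[Mutation] = []
    for tok in text.split(";"):
        parts = tok.strip().split(":")
        try:
            pos = int(parts[0])
            if len(parts) == 2 and ">" in parts[1]:
                ref, alt = parts[1].split(">")
                out.append(Substitution(pos, ref.upper(), alt.upper()))
            elif len(parts) == 3 and parts[1] == "ins":
                out.append(Insertion(pos, clean_sequence(parts[2])))
            elif len(parts) == 3 and parts[1] == "del":
                out.append(Deletion(pos, int(parts[2])))
            else:
                raise ValueError
        except ValueError as exc:
            raise ValueError(f"malformed mutation token {tok!r}") from exc
    return tuple(out)


@dataclass(frozen=True)
class Substrate:
    """Wild-type editing substrate with its folding constraint strings."""

    name: str
    wt_sequence: str
    editing_site: int  # 1-based
    ecs_region: Optional[tuple[int, int]] = None
    constraint: Optional[str] = None
    reference: Optional[str] = None
    wt_structure: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "wt_sequence", clean_sequence(self.wt_sequence))
        n = len(self.wt_sequence)
        if not 1 <= self.editing_site <= n:
            raise ValueError(f"editing site {self.editing_site} outside 1..{n}")
        if self.wt_sequence[self.editing_site - 1] != "A":
            raise ValueError("editing site must be an adenosine")
        if self.constraint is not None:
            validate_constraint(self.constraint, n)
        for name, s in (("reference", self.reference), ("wt_structure", self.wt_structure)):
            if s is not None:
                if len(s) != n:
                    raise ValueError(f"{name} length {len(s)} != sequence length {n}")
                parse_dotbracket(s)

    @property
    def length(self) -> int:
        return len(self.wt_sequence)


def apply_mutations(wt_sequence: str, mutations: Sequence[Mutation]) -> str:
    """Apply substitutions and indels (all in WT coordinates) to a sequence."""
    seq = list(wt_sequence)
    n = len(seq)
    positions = set()
    for m in mutations:
        lo = m.pos if not isinstance(m, Insertion) else m.pos
        hi = m.pos + m.length - 1 if isinstance(m, Deletion) else m.pos
        if isinstance(m, Insertion):
            if not 0 <= m.pos <= n:
                raise ValueError(f"insertion anchor {m.pos} outside 0..{n}")
        elif not (1 <= lo and hi <= n):
            raise ValueError(f"mutation {m} outside sequence 1..{n}")
        span = range(lo, hi + 1) if not isinstance(m, Insertion) else (m.pos + 0.5,)
        for p in span:
            if p in positions:
                raise ValueError(f"overlapping mutations at position {p}")
            positions.add(p)
        if isinstance(m, Substitution) and seq[m.pos - 1] != m.ref:
            raise ValueError(
                f"reference mismatch at {m.pos}: sequence has "
                f"{seq[m.pos - 1]}, mutation says {m.ref}"
            )
    # Apply 3' -> 5' so earlier coordinates stay valid.
    for m in sorted(mutations, key=lambda m: -m.pos):
        if isinstance(m, Substitution):
            seq[m.pos - 1] = m.alt
        elif isinstance(m, Deletion):
            del seq[m.pos - 1 : m.pos - 1 + m.length]
        else:
            seq[m.pos : m.pos] = list(m.seq)
    return "".join(seq)


def variant_site_index(substrate: Substrate, mutations: Sequence[Mutation]) -> int:
    """Editing-site position (1-based) in variant coordinates."""
    site = substrate.editing_site
    shift = 0
    for m in mutations:
        if isinstance(m, Substitution) and m.pos == site:
            raise DesignError("mutations at the editing site are not allowed")
        if isinstance(m, Insertion) and m.pos < site:
            shift += len(m.seq)
        if isinstance(m, Deletion):
            if m.pos <= site <= m.pos + m.length - 1:
                raise DesignError("deletion removes the editing site")
            if m.pos + m.length - 1 < site:
                shift -= m.length
    return site + shift


@dataclass(frozen=True)
class VariantRecord:
    id: str
    mutations: tuple[Mutation, ...]
    sequence: str
    editing_levels: tuple[float, ...] = ()
    mean_editing: Optional[float] = None
    zscore: Optional[float] = None

    def __post_init__(self) -> None:
        for lv in self.editing_levels:
            if not (math.isnan(lv) or 0.0 <= lv <= 1.0):
                raise ValueError(f"editing level {lv} outside [0, 1]")

    @property
    def num_mutations(self) -> int:
        return len(self.mutations)

    @property
    def is_wt(self) -> bool:
        return not self.mutations

    @classmethod
    def from_mutations(
        cls,
        substrate: Substrate,
        mutations: Sequence[Mutation],
        id: str | None = None,
        **kw,
    ) -> "VariantRecord":
        variant_site_index(substrate, mutations)  # validates site safety
        seq = apply_mutations(substrate.wt_sequence, mutations)
        vid = id if id is not None else (format_mutations(mutations).replace(";", "+") or "WT")
        return cls(id=vid, mutations=tuple(mutations), sequence=seq, **kw)

    def with_editing(
        self, levels: Sequence[float], zscore: float | None = None
    ) -> "VariantRecord":
        levels = tuple(float(x) for x in levels)
        mean = float(np.nanmean(levels)) if levels else None
        return replace(
            self, editing_levels=levels, mean_editing=mean, zscore=zscore
        )


class MutationClass(Enum):
    """Six sequence-by-structure categories for single substitutions."""

    TRANSITION = "transition"
    TRANSVERSION = "transversion"
    TRANSITION_BREAK = "transition+break"
    TRANSVERSION_BREAK = "transversion+break"
    TRANSITION_SHIFT = "transition+shift"
    TRANSVERSION_SHIFT = "transversion+shift"


def classify_mutation(
    substitution: Substitution,
    wt_structure: Union[str, PairTable],
    variant_structure: Union[str, PairTable],
) -> MutationClass:
    """Classify one substitution by sequence change and structural outcome.

    Base label: transition (purine<->purine or pyrimidine<->pyrimidine) vs
    transversion.  Suffix: none if the pair tables are identical; '+break' if
    the only difference is the loss of the pair at the mutated position;
    '+shift' for every other pair-table change.
    """
    if not isinstance(substitution, Substitution):
        raise TypeError("classification is defined for single substitutions only")
    wt_pt = parse_dotbracket(wt_structure) if isinstance(wt_structure, str) else wt_structure
    var_pt = (
        parse_dotbracket(variant_structure)
        if isinstance(variant_structure, str)
        else variant_structure
    )
    if wt_pt.length != var_pt.length:
        raise ValueError("structures must have equal length for classification")
    transition = (
        substitution.ref in PURINES and substitution.alt in PURINES
    ) or (substitution.ref in PYRIMIDINES and substitution.alt in PYRIMIDINES)

    wt_pairs = set(wt_pt.pairs())
    var_pairs = set(var_pt.pairs())
    if wt_pairs == var_pairs:
        return MutationClass.TRANSITION if transition else MutationClass.TRANSVERSION
    m = substitution.pos
    mate = wt_pt[m]
    own_pair = (min(m, mate), max(m, mate)) if mate else None
    if own_pair is not None and var_pairs == wt_pairs - {own_pair}:
        return MutationClass.TRANSITION_BREAK if transition else MutationClass.TRANSVERSION_BREAK
    return MutationClass.TRANSITION_SHIFT if transition else MutationClass.TRANSVERSION_SHIFT


@dataclass(frozen=True)
class LibraryStats:
    el_wt: float
    s: float  # population SD of editing levels (Z-score denominator)
    n: int


def library_stats(variants: Sequence[VariantRecord], el_wt: float) -> LibraryStats:
    els = np.array([v.mean_editing for v in variants], dtype=float)
    if els.size < 2:
        raise ValueError("need at least 2 variants with editing levels")
    if np.isnan(els).any():
        raise ValueError("all variants must have a mean editing level")
    x = els - el_wt
    s = float(np.sqrt(np.mean((x - x.mean()) ** 2)))
    return LibraryStats(el_wt=float(el_wt), s=s, n=int(els.size))


def zscore_library(
    variants: Sequence[VariantRecord], el_wt: float
) -> list[VariantRecord]:
    """Return variants with library-standardized Z-scores attached.

    Z_i = (EL_i - EL_WT) / S with S the population standard deviation of the
    deviations x_i = EL_i - EL_WT over the whole library.
    """
    stats = library_stats(variants, el_wt)
    if stats.s == 0.0:
        raise DegenerateLibraryError("all editing levels identical (S = 0)")
    return [
        replace(v, zscore=float((v.mean_editing - el_wt) / stats.s))
        for v in variants
    ]


@dataclass(frozen=True)
class DesignSpec:
    """Declarative description of a designed mutagenesis library."""

    region: tuple[int, int]  # 1-based closed interval of mutable positions
    singles: bool = True
    exclude_ag_adjacent: bool = True  # A->G at site +/- 1 indistinguishable from editing
    double_pairs: tuple[tuple[int, int], ...] = ()
    n_random_doubles: int = 0
    doubles_seed: int = 0
    compensatory_pairs: tuple[tuple[int, int], ...] = ()
    indels: tuple[Mutation, ...] = ()


def _transversion_alts(ref: str) -> tuple[str, ...]:
    return tuple(sorted(PYRIMIDINES if ref in PURINES else PURINES))


def enumerate_designed_variants(
    substrate: Substrate, design: DesignSpec
) -> list[VariantRecord]:
    """Expand a design into concrete, deduplicated variant records.

    Singles cover every non-site position in the region (3 substitutions
    each); A->G substitutions adjacent to the editing site are excluded by
    default because editing itself would make them unreadable.  Double
    transversions come from explicit position pairs and/or a seeded random
    sample; compensatory doubles rewrite a stem pair to another canonical
    pair.
    """
    lo, hi = design.region
    n = substrate.length
    if not (1 <= lo <= hi <= n):
        raise DesignError(f"region {design.region} outside sequence 1..{n}")
    site = substrate.editing_site
    wt = substrate.wt_sequence

    def excluded(pos: int, ref: str, alt: str) -> bool:
        if pos == site:
            return True
        return (
            design.exclude_ag_adjacent
            and ref == "A"
            and alt == "G"
            and abs(pos - site) == 1
        )

    candidates: list[tuple[Mutation, ...]] = []
    if design.singles:
        for pos in range(lo, hi + 1):
            if pos == site:
                continue
            ref = wt[pos - 1]
            for alt in "ACGU":
                if alt != ref and not excluded(pos, ref, alt):
                    candidates.append((Substitution(pos, ref, alt),))

    pair_list = list(design.double_pairs)
    if design.n_random_doubles:
        rng = np.random.default_rng(design.doubles_seed)
        pool = [p for p in range(lo, hi + 1) if p != site]
        seen_pairs = set(pair_list)
        while len(pair_list) < len(design.double_pairs) + design.n_random_doubles:
            a, b = sorted(rng.choice(len(pool), size=2, replace=False))
            pair = (pool[a], pool[b])
            if pair not in seen_pairs:
                seen_pairs.add(pair)
                pair_list.append(pair)
    for p1, p2 in pair_list:
        if not (lo <= p1 <= hi and lo <= p2 <= hi) or site in (p1, p2):
            raise DesignError(f"double pair ({p1}, {p2}) invalid for region/site")
        for a1 in _transversion_alts(wt[p1 - 1]):
            for a2 in _transversion_alts(wt[p2 - 1]):
                if not excluded(p1, wt[p1 - 1], a1) and not excluded(p2, wt[p2 - 1], a2):
                    candidates.append(
                        (Substitution(p1, wt[p1 - 1], a1), Substitution(p2, wt[p2 - 1], a2))
                    )

    for i, j in design.compensatory_pairs:
        bi, bj = wt[i - 1], wt[j - 1]
        if (bi, bj) not in CANONICAL_PAIRS:
            raise DesignError(f"compensatory positions ({i}, {j}) do not pair in WT")
        for ci, cj in CANONICAL_PAIRS:
            if (ci, cj) == (bi, bj):
                continue
            muts = tuple(
                Substitution(p, r, c)
                for p, r, c in ((i, bi, ci), (j, bj, cj))
                if r != c and not excluded(p, r, c)
            )
            if muts:
                candidates.append(muts)

    candidates.extend((m,) for m in design.indels)

    variants: list[VariantRecord] = []
    seen_seq = {wt}
    for muts in candidates:
        v = VariantRecord.from_mutations(substrate, muts)
        if v.sequence in seen_seq:
            continue
        seen_seq.add(v.sequence)
        variants.append(v)
    return variants


def _signature_index(
    substrate: Substrate, variants: Sequence[VariantRecord]
) -> dict[str, tuple[str, str]]:
    """Map read sequence -> (variant id, base at site).  Site masked over ACGU."""
    index: dict[str, tuple[str, str]] = {}
    for v in variants:
        site = variant_site_index(substrate, v.mutations)
        for b in "ACGU":
            key = v.sequence[: site - 1] + b + v.sequence[site:]
            prev = index.get(key)
            if prev is not None and prev[0] != v.id:
                raise DesignError(
                    f"ambiguous signatures: variants {prev[0]!r} and {v.id!r} "
                    "are indistinguishable outside the editing site"
                )
            index[key] = (v.id, b)
    return index


def assign_reads_to_variants(
    reads: Iterable,
    substrate: Substrate,
    variants: Sequence[VariantRecord],
    min_reads: int = 100,
) -> pd.DataFrame:
    """Assign reads to variant signatures and quantify editing per variant.

    A read is assigned iff it exactly matches exactly one variant outside the
    editing site; the editing level is G / (A + G) at the site among assigned
    reads.  Returns a frame indexed by variant id with columns n_reads,
    n_edited, editing_level and low_coverage; the number of unassigned reads
    is stored in ``frame.attrs['unassigned']``.
    """
    index = _signature_index(substrate, variants)
    counts: dict[str, dict[str, int]] = {v.id: {"A": 0, "G": 0, "other": 0} for v in variants}
    unassigned = 0
    for read in reads:
        seq = str(getattr(read, "seq", read)).upper().replace("T", "U")
        hit = index.get(seq)
        if hit is None:
            unassigned += 1
            continue
        vid, base = hit
        counts[vid][base if base in ("A", "G") else "other"] += 1
    rows = []
    for v in variants:
        c = counts[v.id]
        total = c["A"] + c["G"] + c["other"]
        denom = c["A"] + c["G"]
        rows.append(
            {
                "id": v.id,
                "n_reads": total,
                "n_edited": c["G"],
                "editing_level": (c["G"] / denom) if denom else math.nan,
                "low_coverage": total < min_reads,
            }
        )
    frame = pd.DataFrame(rows).set_index("id")
    frame.attrs["unassigned"] = unassigned
    return frame


def save_library(variants: Sequence[VariantRecord], path) -> None:
    """Write the documented TSV format (id, mutations, rep*, mean, zscore)."""
    n_rep = max((len(v.editing_levels) for v in variants), default=0)
    rows = []
    for v in variants:
        row = {"id": v.id, "mutations": format_mutations(v.mutations)}
        for k in range(n_rep):
            row[f"rep{k + 1}"] = (
                v.editing_levels[k] if k < len(v.editing_levels) else math.nan
            )
        row["mean_editing"] = v.mean_editing if v.mean_editing is not None else math.nan
        row["zscore"] = v.zscore if v.zscore is not None else math.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_library(path, substrate: Substrate) -> list[VariantRecord]:
    """Read the TSV format back, rebuilding and validating sequences."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"id": str, "mutations": str})
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty library file")
        return []
    if df.empty:
        warnings.warn(f"{path}: empty library file")
        return []
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    variants: list[VariantRecord] = []
    for line_no, (_, row) in enumerate(df.iterrows(), start=2):
        try:
            muts = parse_mutations(row.get("mutations", "") if pd.notna(row.get("mutations")) else "")
            levels = [float(row[c]) for c in rep_cols if pd.notna(row[c])]
            v = VariantRecord.from_mutations(substrate, muts, id=str(row["id"]))
            zs = row.get("zscore")
            v = v.with_editing(levels, zscore=float(zs) if pd.notna(zs) else None)
        except (ValueError, KeyError, DesignError) as exc:
            raise ValueError(f"{path}: line {line_no}: {exc}") from exc
        variants.append(v)
    return variants
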