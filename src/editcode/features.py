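"""Per-mutated-base feature matrix construction.

Each variant contributes one row per mutated base (the WT contributes a
single row with num_mutations = 0).  Features combine ensemble
thermodynamics, the structural context of the editing site (element kinds,
loop dimensions, closing pairs, flanking nucleotides), the same context for
up to two upstream and three downstream elements, and mutation-level
descriptors.  Features fall into nine high-level groups used for grouped
attribution.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import annotate as an
from . import fold as fe
from .library import (
    Deletion,
    Insertion,
    MutationClass,
    Substitution,
    Substrate,
    VariantRecord,
    classify_mutation,
    variant_site_index,
)

__all__ = [
    "NINE_GROUPS",
    "FeatureRegistry",
    "FeatureMatrix",
    "META_COLUMNS",
    "group_for",
    "build_feature_row",
    "build_matrix",
    "apply_split_masks",
]

NINE_GROUPS = (
    "structure",
    "num_mutations",
    "mutation_sequence",
    "mutation_structure",
    "mutation_other",
    "site_sequence",
    "site_structure",
    "upstream",
    "downstream",
)

META_COLUMNS = ("variant_id", "row_position", "target_editing", "label_edited")

# Columns guaranteed to exist in every registry regardless of what the
# library happens to exercise (stable schema for cross-substrate alignment).
_SEEDED_COLUMNS = (
    ["mfe", "ensemble_energy", "mfe_frequency", "ensemble_diversity",
     "all_stem_length", "probability_active_conf", "sim_nor_score",
     "num_mutations", "mut_pos", "mut_dist_to_site", "mut_same_elem_as_site",
     "is_mutated", "site_dim5", "site_dim3"]
    + [f"site_1_1:A:{b}" for b in "ACGU"]
    + [f"site_prev_nt:{b}" for b in "ACGU"]
    + [f"site_next_nt:{b}" for b in "ACGU"]
    + [f"site_opposing_nt:{b}" for b in "ACGU"]
    + [f"site_elem:{k}" for k in an.ELEMENT_KINDS]
    + ["site_5prm_cp_internal:C:G", "site_5prm_cp_internal:G:C",
       "d2_5prm_cp_internal:G:C"]
    + [f"mut_ref:{b}" for b in "ACGU"]
    + [f"mut_alt:{b}" for b in "ACGU"]
    + [f"mut_class:{c.value}" for c in MutationClass]
    + ["mut_type:SNP", "mut_type:indel"]
    + [f"mut_elem:{k}" for k in an.ELEMENT_KINDS]
)

_GROUP_PREFIXES = (
    ("num_mutations", "num_mutations"),
    ("mut_class", "mutation_structure"),
    ("mut_elem", "mutation_structure"),
    ("mut_up_elem", "mutation_structure"),
    ("mut_down_elem", "mutation_structure"),
    ("mut_same_elem_as_site", "mutation_structure"),
    ("mut_type", "mutation_other"),
    ("is_mutated", "mutation_other"),
    ("mut_", "mutation_sequence"),
    ("site_prev_nt", "site_sequence"),
    ("site_next_nt", "site_sequence"),
    ("site_opposing_nt", "site_sequence"),
    ("site_", "site_structure"),
    ("u1_", "upstream"),
    ("u2_", "upstream"),
    ("d1_", "downstream"),
    ("d2_", "downstream"),
    ("d3_", "downstream"),
)


def group_for(name: str) -> str:
    """Assign a feature column to one of the nine high-level groups."""
    for prefix, group in _GROUP_PREFIXES:
        if name.startswith(prefix):
            return group
    return "structure"


def _kind_for(name: str) -> str:
    if ":" in name:
        return "onehot"
    if name in ("mut_same_elem_as_site", "is_mutated"):
        return "bool"
    return "numeric"


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered, versioned list of feature columns with group and kind."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    @classmethod
    def from_columns(cls, observed: Sequence[str]) -> "FeatureRegistry":
        names = list(_SEEDED_COLUMNS)
        known = set(names)
        for c in sorted(observed):
            if c not in known:
                names.append(c)
                known.add(c)
        return cls(tuple(names))

    def __contains__(self, name: str) -> bool:
        if name in self.names:
            return True
        # categorical base names resolve to their one-hot expansions
        return any(n.startswith(name + ":") for n in self.names)

    def __len__(self) -> int:
        return len(self.names)

    def group(self, name: str) -> str:
        return group_for(name)

    def kind(self, name: str) -> str:
        return _kind_for(name)

    @property
    def version(self) -> str:
        h = hashlib.sha1("\n".join(self.names).encode()).hexdigest()[:12]
        return f"registry-{h}"

    def to_json(self, path) -> None:
        payload = {
            "version": self.version,
            "features": [
                {"name": n, "group": self.group(n), "kind": self.kind(n)}
                for n in self.names
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FeatureRegistry":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(tuple(f["name"] for f in payload["features"]))


class _Row:
    """Mutable feature-row accumulator with explicit missingness."""

    def __init__(self) -> None:
        self.values: dict[str, float] = {}
        self.known_prefixes: set[str] = set()
        self.missing_prefixes: set[str] = set()

    def num(self, name: str, value) -> None:
        self.values[name] = math.nan if value is None else float(value)

    def cat(self, prefix: str, value: Optional[str]) -> None:
        if value is None:
            self.missing_prefixes.add(prefix)
        else:
            self.known_prefixes.add(prefix)
            self.values[f"{prefix}:{value}"] = 1.0


def _element_features(row: _Row, slot: str, element: Optional[an.StructureElement], sequence: str) -> None:
    """kind/dims/closing-pair features for one context slot (site/u*/d*)."""
    if element is None:
        row.cat(f"{slot}_elem", None)
        row.num(f"{slot}_dim5", None)
        row.num(f"{slot}_dim3", None)
        row.missing_prefixes.add(f"{slot}_5prm_cp")
        row.missing_prefixes.add(f"{slot}_3prm_cp")
        return
    row.cat(f"{slot}_elem", element.kind)
    dims = element.dims
    row.num(f"{slot}_dim5", dims[0] if dims else 0)
    row.num(f"{slot}_dim3", dims[1] if len(dims) > 1 else 0)
    for side, tag in (("5", "5prm"), ("3", "3prm")):
        nts = element.closing_nts(sequence, side)
        if nts is None:
            row.missing_prefixes.add(f"{slot}_{tag}_cp")
        else:
            row.known_prefixes.add(f"{slot}_{tag}_cp")
            row.values[f"{slot}_{tag}_cp_{element.kind}:{nts}"] = 1.0


def build_feature_row(
    variant: VariantRecord,
    mutated_pos: Optional[int],
    substrate: Substrate,
    fold: Optional[fe.FoldResult],
    active: Optional[fe.ActiveConfResult],
    ctx: Optional[an.SiteContext],
    sim: Optional[float],
    elements: Optional[Sequence[an.StructureElement]] = None,
    wt_pt: Optional[an.PairTable] = None,
    var_pt: Optional[an.PairTable] = None,
) -> dict:
    """One feature row for one mutated base (or the WT row).

    Missing upstream computations yield explicit NaN, never silent zeros.
    """
    row = _Row()
    seq = variant.sequence

    # --- thermodynamic / global structure ---
    if fold is not None:
        row.num("mfe", fold.mfe_energy)
        row.num("ensemble_energy", fold.ensemble_energy)
        row.num("mfe_frequency", fold.mfe_frequency)
        row.num("ensemble_diversity", fold.ensemble_diversity)
    else:
        for name in ("mfe", "ensemble_energy", "mfe_frequency", "ensemble_diversity"):
            row.num(name, None)
    row.num(
        "all_stem_length",
        an.stem_length_summary(elements) if elements is not None else None,
    )
    row.num(
        "probability_active_conf",
        active.probability if active is not None and active.satisfiable else None,
    )
    row.num("sim_nor_score", sim)

    # --- editing-site context ---
    if ctx is not None:
        _element_features(row, "site", ctx.site, seq)
        row.cat("site_prev_nt", ctx.prev_nt)
        row.cat("site_next_nt", ctx.next_nt)
        row.cat("site_opposing_nt", ctx.opposing_nt)
        if ctx.site.kind == "internal" and ctx.site.dims == (1, 1) and ctx.opposing_nt:
            row.known_prefixes.add("site_1_1")
            site_nt = seq[ctx.editing_pos - 1]
            row.values[f"site_1_1:{site_nt}:{ctx.opposing_nt}"] = 1.0
        else:
            row.known_prefixes.add("site_1_1")  # known to be absent -> all zeros
        for slot, el in (("u1", ctx.u1), ("u2", ctx.u2), ("d1", ctx.d1), ("d2", ctx.d2), ("d3", ctx.d3)):
            _element_features(row, slot, el, seq)
    else:
        _element_features(row, "site", None, seq)
        row.cat("site_prev_nt", None)
        row.cat("site_next_nt", None)
        row.cat("site_opposing_nt", None)
        row.missing_prefixes.add("site_1_1")
        for slot in ("u1", "u2", "d1", "d2", "d3"):
            _element_features(row, slot, None, seq)

    # --- mutation descriptors ---
    row.num("num_mutations", variant.num_mutations)
    row.num("is_mutated", 0.0 if variant.is_wt else 1.0)
    if mutated_pos is None:
        row.num("mut_pos", None)
        row.num("mut_dist_to_site", None)
        row.num("mut_same_elem_as_site", None)
        row.cat("mut_ref", None)
        row.cat("mut_alt", None)
        row.cat("mut_type", None)
        row.cat("mut_class", None)
        row.cat("mut_elem", None)
        row.cat("mut_up_elem", None)
        row.cat("mut_down_elem", None)
    else:
        mut = next(m for m in variant.mutations if m.pos == mutated_pos)
        row.num("mut_pos", mutated_pos)
        row.num("mut_dist_to_site", mutated_pos - substrate.editing_site)
        if isinstance(mut, Substitution):
            row.cat("mut_type", "SNP")
            row.cat("mut_ref", mut.ref)
            row.cat("mut_alt", mut.alt)
            if wt_pt is not None and var_pt is not None and wt_pt.length == var_pt.length:
                row.cat("mut_class", classify_mutation(mut, wt_pt, var_pt).value)
            else:
                row.cat("mut_class", None)
        else:
            row.cat("mut_type", "indel")
            row.cat("mut_ref", None)
            row.cat("mut_alt", None)
            row.cat("mut_class", None)
        if elements is not None and ctx is not None:
            vpos = _variant_coord(variant, substrate, mutated_pos)
            if vpos is None:
                for slot in ("mut_elem", "mut_up_elem", "mut_down_elem"):
                    row.cat(slot, None)
                row.num("mut_same_elem_as_site", None)
            else:
                ordered = sorted((e for e in elements if e.spans), key=lambda e: e.start)
                idx = next(
                    (k for k, e in enumerate(ordered) if vpos in e.positions()), None
                )
                if idx is None:
                    for slot in ("mut_elem", "mut_up_elem", "mut_down_elem"):
                        row.cat(slot, None)
                    row.num("mut_same_elem_as_site", None)
                else:
                    row.cat("mut_elem", ordered[idx].kind)
                    row.cat("mut_up_elem", ordered[idx - 1].kind if idx > 0 else None)
                    row.cat(
                        "mut_down_elem",
                        ordered[idx + 1].kind if idx + 1 < len(ordered) else None,
                    )
                    row.num(
                        "mut_same_elem_as_site",
                        1.0 if ordered[idx] is ctx.site else 0.0,
                    )
        else:
            for slot in ("mut_elem", "mut_up_elem", "mut_down_elem"):
                row.cat(slot, None)
            row.num("mut_same_elem_as_site", None)

    return {
        "values": row.values,
        "known_prefixes": row.known_prefixes,
        "missing_prefixes": row.missing_prefixes,
    }


def _variant_coord(
    variant: VariantRecord, substrate: Substrate, wt_pos: int
) -> Optional[int]:
    """Map a WT coordinate into variant coordinates across this variant's indels."""
    shift = 0
    for m in variant.mutations:
        if isinstance(m, Insertion) and m.pos < wt_pos:
            shift += len(m.seq)
        elif isinstance(m, Deletion):
            if m.pos <= wt_pos <= m.pos + m.length - 1:
                return None
            if m.pos + m.length - 1 < wt_pos:
                shift -= m.length
    pos = wt_pos + shift
    return pos if 1 <= pos <= len(variant.sequence) else None


@dataclass
class FeatureMatrix:
    """Feature rows (meta columns + feature columns) with their registry."""

    data: pd.DataFrame
    registry: FeatureRegistry
    dropped: tuple[str, ...] = ()

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS and c != "split"]

    def features_frame(self) -> pd.DataFrame:
        return self.data[self.feature_columns]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def build_matrix(
    library: Sequence[VariantRecord],
    substrate: Substrate,
    model: fe.EnergyModel = fe.DEFAULT_MODEL,
    edited_threshold: float = 0.01,
) -> FeatureMatrix:
    """Fold, annotate and featurize every variant of a library.

    Deterministic: rows are ordered by variant id then mutated position; the
    matrix is a pure function of (library, substrate, energy model).
    """
    wt_fold = fe.fold_result(substrate.wt_sequence, model)
    wt_pt = an.parse_dotbracket(wt_fold.mfe_structure)
    wt_tree = an.to_tree(an.annotate_elements(wt_pt))

    raw_rows: list[tuple[dict, dict]] = []
    for variant in sorted(library, key=lambda v: v.id):
        fold = fe.fold_result(variant.sequence, model)
        var_pt = an.parse_dotbracket(fold.mfe_structure)
        elements = an.annotate_elements(var_pt)
        tree = an.to_tree(elements)
        sim = an.similarity_score(wt_tree, tree)
        active = None
        if substrate.constraint is not None and substrate.reference is not None:
            if len(variant.sequence) == substrate.length:
                active = fe.active_conformation_probability(
                    variant.sequence, model, substrate.constraint, substrate.reference
                )
        site_idx = variant_site_index(substrate, variant.mutations)
        ctx = an.locate_site_context(elements, site_idx, variant.sequence, var_pt)

        target = variant.mean_editing
        label = (
            math.nan
            if target is None or math.isnan(target)
            else float(target > edited_threshold)
        )
        positions = [m.pos for m in variant.mutations] or [None]
        for pos in sorted(positions, key=lambda p: (p is None, p)):
            meta = {
                "variant_id": variant.id,
                "row_position": math.nan if pos is None else pos,
                "target_editing": math.nan if target is None else target,
                "label_edited": label,
            }
            raw = build_feature_row(
                variant, pos, substrate, fold, active, ctx, sim,
                elements=elements, wt_pt=wt_pt, var_pt=var_pt,
            )
            raw_rows.append((meta, raw))

    observed = sorted({name for _, raw in raw_rows for name in raw["values"]})
    registry = FeatureRegistry.from_columns(observed)
    records = []
    for meta, raw in raw_rows:
        rec = dict(meta)
        for name in registry.names:
            if name in raw["values"]:
                rec[name] = raw["values"][name]
            elif ":" in name:
                prefix = _prefix_of(name)
                if prefix in raw["known_prefixes"]:
                    rec[name] = 0.0
                else:
                    rec[name] = math.nan
            else:
                rec[name] = math.nan
        records.append(rec)
    data = pd.DataFrame.from_records(
        records, columns=list(META_COLUMNS) + list(registry.names)
    )
    return FeatureMatrix(data=data, registry=registry)


def _prefix_of(onehot_name: str) -> str:
    """Categorical family of a one-hot column.

    Closing-pair columns embed the element kind ('site_5prm_cp_internal:C:G'
    belongs to family 'site_5prm_cp'); other one-hots use the text before the
    first colon.
    """
    base = onehot_name.split(":", 1)[0]
    for marker in ("_5prm_cp", "_3prm_cp"):
        k = base.find(marker)
        if k >= 0:
            return base[: k + len(marker)]
    return base


def apply_split_masks(matrix: FeatureMatrix, row_splits: Sequence[str]) -> FeatureMatrix:
    """Drop features that are null or non-varying across the training split.

    ``row_splits`` assigns 'train'/'validation'/'test' per row.  The mask is
    computed on training rows only and applied to every split.  Missingness
    counts as a value: a feature that is constant among observed rows but
    missing in others still varies.
    """
    data = matrix.data.copy()
    data["split"] = list(row_splits)
    train = data[data["split"] == "train"]
    if train.empty:
        raise ValueError("training split is empty")
    dropped = []
    for col in matrix.feature_columns:
        vals = train[col]
        distinct = vals.nunique(dropna=True) + (1 if vals.isna().any() else 0)
        if distinct <= 1:
            dropped.append(col)
    data = data.drop(columns=dropped)
    return FeatureMatrix(
        data=data,
        registry=matrix.registry,
        dropped=tuple(dropped),
    )
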