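"""Typed annotation of dot-bracket structures and tree-based similarity.

Structures are segmented into stems, hairpin loops, bulges, internal loops,
multiloops and a single exterior element, each with dimensions and closing
pairs.  The element list converts losslessly to an ordered rooted tree whose
labels carry element kind and dimensions; structure similarity between two
molecules is one minus the (unit-cost) tree-edit distance normalized by the
larger tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .fold import FoldError, dotbracket_pairs

__all__ = [
    "PairTable",
    "StructureElement",
    "SiteContext",
    "TreeNode",
    "parse_dotbracket",
    "annotate_elements",
    "locate_site_context",
    "to_tree",
    "tree_edit_distance",
    "similarity_score",
    "stem_length_summary",
    "elements_to_dotbracket",
    "element_string",
]

ELEMENT_KINDS = ("stem", "hairpin", "bulge", "internal", "multiloop", "exterior")

_KIND_CODE = {
    "stem": "S",
    "hairpin": "H",
    "bulge": "B",
    "internal": "I",
    "multiloop": "M",
    "exterior": "E",
}


class PairTable:
    """1-based partner table; partner 0 means unpaired.  Nested pairs only."""

    def __init__(self, partner: Sequence[int]):
        # partner[0] is a placeholder so that partner[i] is the mate of i.
        self._partner = tuple(partner)
        n = len(self._partner) - 1
        if n < 0 or self._partner[0] != 0:
            raise FoldError("partner table must start with a 0 placeholder")
        for i in range(1, n + 1):
            p = self._partner[i]
            if p:
                if not (1 <= p <= n) or self._partner[p] != i or p == i:
                    raise FoldError(f"partner table is not an involution at {i}")
        pairs = self.pairs()
        for a, b in pairs:
            for c, d in pairs:
                if a < c < b < d:
                    raise FoldError(f"crossing pairs ({a},{b}) and ({c},{d})")

    @classmethod
    def from_dotbracket(cls, structure: str) -> "PairTable":
        n = len(structure)
        partner = [0] * (n + 1)
        for i, j in dotbracket_pairs(structure):
            partner[i + 1] = j + 1
            partner[j + 1] = i + 1
        return cls(partner)

    def to_dotbracket(self) -> str:
        out = []
        for i in range(1, self.length + 1):
            p = self._partner[i]
            out.append("." if p == 0 else ("(" if p > i else ")"))
        return "".join(out)

    @property
    def length(self) -> int:
        return len(self._partner) - 1

    def __getitem__(self, i: int) -> int:
        if not 1 <= i <= self.length:
            raise IndexError(f"position {i} out of range 1..{self.length}")
        return self._partner[i]

    def pairs(self) -> list[tuple[int, int]]:
        """Sorted 1-based (i, j) pairs with i < j."""
        return [
            (i, self._partner[i])
            for i in range(1, self.length + 1)
            if self._partner[i] > i
        ]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PairTable) and self._partner == other._partner

    def __hash__(self) -> int:
        return hash(self._partner)

    def __repr__(self) -> str:
        return f"PairTable({self.to_dotbracket()!r})"


def parse_dotbracket(structure: str) -> PairTable:
    """Parse '(', ')' and '.' into a validated PairTable."""
    return PairTable.from_dotbracket(structure)


@dataclass(frozen=True)
class StructureElement:
    """One typed structural element.

    ``spans`` are 1-based closed intervals of the nucleotides belonging to the
    element (paired positions belong to stems; unpaired ones to loops or the
    exterior).  ``dims`` is (length,) for stems, the unpaired count for
    hairpins, (5' count, 3' count) for internal loops and bulges, and the
    per-gap unpaired counts for multiloops.  ``closing5`` / ``closing3`` are
    the outer and first inner closing pairs where applicable.
    """

    kind: str
    spans: tuple[tuple[int, int], ...]
    dims: tuple[int, ...]
    closing5: Optional[tuple[int, int]] = None
    closing3: Optional[tuple[int, int]] = None
    pairs: tuple[tuple[int, int], ...] = ()

    def positions(self) -> list[int]:
        out: list[int] = []
        for a, b in self.spans:
            out.extend(range(a, b + 1))
        return out

    @property
    def start(self) -> int:
        return min((a for a, _ in self.spans), default=10**9)

    def closing_nts(self, sequence: str, side: str = "5") -> Optional[str]:
        cp = self.closing5 if side == "5" else self.closing3
        if cp is None:
            return None
        i, j = cp
        return f"{sequence[i - 1]}:{sequence[j - 1]}"

    def label(self) -> str:
        return f"{self.kind}:" + ",".join(map(str, self.dims))


def _runs(positions: Iterable[int]) -> tuple[tuple[int, int], ...]:
    """Collapse a sorted iterable of positions into closed intervals."""
    spans: list[tuple[int, int]] = []
    for p in positions:
        if spans and p == spans[-1][1] + 1:
            spans[-1] = (spans[-1][0], p)
        else:
            spans.append((p, p))
    return tuple(spans)


def annotate_elements(pt: PairTable, sequence: str | None = None) -> list[StructureElement]:
    """Segment a pair table into non-overlapping typed elements.

    Every nucleotide lands in exactly one element.  The exterior (all
    top-level unpaired positions) is emitted as a single element whenever the
    top level is not exactly one stem with nothing around it.
    """
    n = pt.length
    elements: list[StructureElement] = []

    # Stems: maximal runs of stacked pairs.
    seen: set[tuple[int, int]] = set()
    for i, j in pt.pairs():
        if (i, j) in seen:
            continue
        if i > 1 and pt[i - 1] == j + 1:
            continue  # interior of a run; handled from its outermost pair
        run = [(i, j)]
        while run[-1][0] + 1 < run[-1][1] - 1 and pt[run[-1][0] + 1] == run[-1][1] - 1:
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        seen.update(run)
        a, b = run[0]
        p, q = run[-1]
        elements.append(
            StructureElement(
                kind="stem",
                spans=((a, p), (q, b)),
                dims=(len(run),),
                closing5=(a, b),
                closing3=(p, q),
                pairs=tuple(run),
            )
        )

    # Loops: one per stem-terminating pair.
    for stem in [e for e in elements if e.kind == "stem"]:
        a, b = stem.closing3  # innermost pair of the stem
        children: list[tuple[int, int]] = []
        unpaired: list[int] = []
        p = a + 1
        while p < b:
            mate = pt[p]
            if mate == 0:
                unpaired.append(p)
                p += 1
            else:
                children.append((p, mate))
                p = mate + 1
        if not children:
            elements.append(
                StructureElement(
                    kind="hairpin",
                    spans=_runs(unpaired),
                    dims=(b - a - 1,),
                    closing5=(a, b),
                )
            )
        elif len(children) == 1:
            (p1, q1) = children[0]
            l5, l3 = p1 - a - 1, b - q1 - 1
            kind = "internal" if (l5 > 0 and l3 > 0) else "bulge"
            elements.append(
                StructureElement(
                    kind=kind,
                    spans=_runs(unpaired),
                    dims=(l5, l3),
                    closing5=(a, b),
                    closing3=(p1, q1),
                )
            )
        else:
            gaps = []
            prev = a
            for p1, q1 in children:
                gaps.append(p1 - prev - 1)
                prev = q1
            gaps.append(b - prev - 1)
            elements.append(
                StructureElement(
                    kind="multiloop",
                    spans=_runs(unpaired),
                    dims=tuple(gaps),
                    closing5=(a, b),
                    closing3=children[0],
                )
            )

    # Exterior: top-level unpaired positions (single element, possibly several
    # spans); emitted also when the top level holds more than one stem so the
    # tree view keeps a single root.
    ext_unpaired: list[int] = []
    top_pairs: list[tuple[int, int]] = []
    p = 1
    while p <= n:
        mate = pt[p]
        if mate == 0:
            ext_unpaired.append(p)
            p += 1
        else:
            top_pairs.append((p, mate))
            p = mate + 1
    if ext_unpaired or len(top_pairs) != 1:
        elements.append(
            StructureElement(
                kind="exterior",
                spans=_runs(ext_unpaired),
                dims=tuple(b - a + 1 for a, b in _runs(ext_unpaired)) or (0,),
            )
        )

    elements.sort(key=lambda e: (e.start, e.kind))
    return elements


def elements_to_dotbracket(elements: Sequence[StructureElement], n: int) -> str:
    """Reconstruct the dot-bracket string from stem pair lists (round-trip)."""
    out = ["."] * n
    for e in elements:
        for i, j in e.pairs:
            out[i - 1] = "("
            out[j - 1] = ")"
    return "".join(out)


def element_string(elements: Sequence[StructureElement], n: int) -> str:
    """Per-position one-letter element code (S/H/B/I/M/E)."""
    out = ["E"] * n
    for e in elements:
        code = _KIND_CODE[e.kind]
        for p in e.positions():
            out[p - 1] = code
    return "".join(out)


@dataclass(frozen=True)
class SiteContext:
    """Structural neighborhood of the editing site."""

    site: StructureElement
    u1: Optional[StructureElement]
    u2: Optional[StructureElement]
    d1: Optional[StructureElement]
    d2: Optional[StructureElement]
    d3: Optional[StructureElement]
    prev_nt: Optional[str]
    next_nt: Optional[str]
    opposing_nt: Optional[str]
    editing_pos: int = 0


def _opposing(
    pt: PairTable, element: StructureElement, pos: int, sequence: str
) -> Optional[str]:
    mate = pt[pos]
    if mate:
        return sequence[mate - 1]
    if element.kind != "internal" or element.closing5 is None:
        return None
    a, b = element.closing5
    p, q = element.closing3
    if a < pos < p:  # 5' strand of the loop; mirror onto the 3' strand
        opp = b - (pos - a)
        return sequence[opp - 1] if q < opp < b else None
    if q < pos < b:
        opp = a + (b - pos)
        return sequence[opp - 1] if a < opp < p else None
    return None


def locate_site_context(
    elements: Sequence[StructureElement],
    editing_pos: int,
    sequence: str,
    pt: PairTable,
) -> SiteContext:
    """Site element plus up to 2 upstream / 3 downstream flanking elements."""
    n = len(sequence)
    if not 1 <= editing_pos <= n:
        raise IndexError(f"editing position {editing_pos} out of range 1..{n}")
    ordered = sorted(
        (e for e in elements if e.spans),
        key=lambda e: e.start,
    )
    idx = next(
        (k for k, e in enumerate(ordered) if editing_pos in e.positions()), None
    )
    if idx is None:
        raise FoldError(f"no element contains position {editing_pos}")
    site = ordered[idx]

    def grab(offset: int) -> Optional[StructureElement]:
        k = idx + offset
        return ordered[k] if 0 <= k < len(ordered) else None

    return SiteContext(
        site=site,
        u1=grab(-1),
        u2=grab(-2),
        d1=grab(1),
        d2=grab(2),
        d3=grab(3),
        prev_nt=sequence[editing_pos - 2] if editing_pos > 1 else None,
        next_nt=sequence[editing_pos] if editing_pos < n else None,
        opposing_nt=_opposing(pt, site, editing_pos, sequence),
        editing_pos=editing_pos,
    )


@dataclass
class TreeNode:
    label: str
    children: list["TreeNode"] = field(default_factory=list)

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)

    def __repr__(self) -> str:  # compact bracket form, useful in test output
        if not self.children:
            return self.label
        return f"{self.label}({','.join(map(repr, self.children))})"


def to_tree(elements: Sequence[StructureElement]) -> TreeNode:
    """Ordered rooted tree over elements; node count equals element count."""
    if not elements:
        raise FoldError("cannot build a tree from an empty element list")
    stems_by_outer = {
        e.closing5: e for e in elements if e.kind == "stem"
    }
    loops_by_outer = {
        e.closing5: e for e in elements if e.kind in ("hairpin", "bulge", "internal", "multiloop")
    }

    def build_stem(outer: tuple[int, int]) -> TreeNode:
        stem = stems_by_outer[outer]
        node = TreeNode(stem.label())
        inner = stem.closing3
        loop = loops_by_outer.get(inner)
        if loop is not None:
            lnode = TreeNode(loop.label())
            node.children.append(lnode)
            if loop.kind in ("bulge", "internal"):
                lnode.children.append(build_stem(loop.closing3))
            elif loop.kind == "multiloop":
                a, b = inner
                # branch pairs in 5'->3' order
                pt_children = []
                p = a + 1
                while p < b:
                    hit = next(
                        (o for o in stems_by_outer if o[0] == p), None
                    )
                    if hit is None:
                        p += 1
                    else:
                        pt_children.append(hit)
                        p = hit[1] + 1
                lnode.children.extend(build_stem(c) for c in pt_children)
        return node

    exterior = next((e for e in elements if e.kind == "exterior"), None)
    all_pairs = [p for e in elements if e.kind == "stem" for p in e.pairs]
    top_stems = sorted(
        o
        for o in stems_by_outer
        if not any(a < o[0] and o[1] < b for a, b in all_pairs)
    )
    if exterior is not None:
        root = TreeNode(exterior.label())
        root.children.extend(build_stem(o) for o in top_stems)
        return root
    if len(top_stems) == 1:
        return build_stem(top_stems[0])
    raise FoldError("element list has no unique root")


def _postorder(root: TreeNode) -> tuple[list[TreeNode], list[int]]:
    """Postorder node list and leftmost-leaf index per node (Zhang-Shasha)."""
    nodes: list[TreeNode] = []
    lml: list[int] = []

    def rec(node: TreeNode) -> int:
        first = None
        for c in node.children:
            idx = rec(c)
            if first is None:
                first = lml[idx]
        nodes.append(node)
        lml.append(first if first is not None else len(nodes) - 1)
        return len(nodes) - 1

    rec(root)
    return nodes, lml


def tree_edit_distance(a: TreeNode, b: TreeNode) -> int:
    """Zhang-Shasha ordered tree-edit distance with unit costs."""
    an, al = _postorder(a)
    bn, bl = _postorder(b)
    na, nb = len(an), len(bn)
    keyroots_a = [i for i in range(na) if not any(al[j] == al[i] for j in range(i + 1, na))]
    keyroots_b = [i for i in range(nb) if not any(bl[j] == bl[i] for j in range(i + 1, nb))]
    td = [[0] * nb for _ in range(na)]

    def rename(x: TreeNode, y: TreeNode) -> int:
        return 0 if x.label == y.label else 1

    for i in keyroots_a:
        for j in keyroots_b:
            m, n = i - al[i] + 2, j - bl[j] + 2
            fd = [[0] * n for _ in range(m)]
            for x in range(1, m):
                fd[x][0] = fd[x - 1][0] + 1
            for y in range(1, n):
                fd[0][y] = fd[0][y - 1] + 1
            for x in range(1, m):
                for y in range(1, n):
                    ax, by = al[i] + x - 1, bl[j] + y - 1
                    if al[ax] == al[i] and bl[by] == bl[j]:
                        fd[x][y] = min(
                            fd[x - 1][y] + 1,
                            fd[x][y - 1] + 1,
                            fd[x - 1][y - 1] + rename(an[ax], bn[by]),
                        )
                        td[ax][by] = fd[x][y]
                    else:
                        px = al[ax] - al[i]
                        py = bl[by] - bl[j]
                        fd[x][y] = min(
                            fd[x - 1][y] + 1,
                            fd[x][y - 1] + 1,
                            fd[px][py] + td[ax][by],
                        )
    return td[na - 1][nb - 1]


def similarity_score(a: TreeNode, b: TreeNode) -> float:
    """1 - tree_edit_distance / max(|a|, |b|), floored at 0; 1 iff identical."""
    d = tree_edit_distance(a, b)
    return max(0.0, 1.0 - d / max(a.size(), b.size()))


def stem_length_summary(elements: Sequence[StructureElement]) -> int:
    """Total number of base pairs across all stems."""
    return sum(e.dims[0] for e in elements if e.kind == "stem")
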