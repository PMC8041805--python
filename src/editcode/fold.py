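"""Secondary-structure prediction for short RNAs under a simplified pair-energy model.

The engine scores a structure as the sum of independent base-pair energies
(GC/AU/GU), with a minimum span between paired positions and support for
hard constraints.  It provides minimum-free-energy folding, a McCaskill-style
partition function with base-pair probabilities (inside-outside, log-space),
ensemble summary metrics, a brute-force enumerator used as a test oracle, and
the constrained-ensemble "probability of active conformation".

An adapter hook allows delegating folding to an external thermodynamic folder
(ViennaRNA) when it is installed; the built-in engine is the default and the
only backend required by the rest of the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "EnergyModel",
    "DEFAULT_MODEL",
    "FoldResult",
    "ActiveConfResult",
    "FoldError",
    "ConstraintUnsatisfiableError",
    "BackendUnavailableError",
    "clean_sequence",
    "validate_constraint",
    "dotbracket_pairs",
    "fold_mfe",
    "partition_function",
    "log_partition_function",
    "ensemble_metrics",
    "fold_result",
    "brute_force_fold",
    "active_conformation_probability",
    "external_fold_adapter",
]

NEG_INF = float("-inf")

_PAIR_TYPE: Mapping[tuple[str, str], str] = {
    ("G", "C"): "GC",
    ("C", "G"): "GC",
    ("A", "U"): "AU",
    ("U", "A"): "AU",
    ("G", "U"): "GU",
    ("U", "G"): "GU",
}

CONSTRAINT_CHARS = frozenset(".><x|")
_BRUTE_FORCE_MAX_LEN = 22


class FoldError(ValueError):
    """Invalid folding input (alphabet, constraint syntax, lengths)."""


class ConstraintUnsatisfiableError(FoldError):
    """No structure satisfies the hard constraints for this sequence."""


class BackendUnavailableError(RuntimeError):
    """The requested external folding backend is not installed."""


def clean_sequence(sequence: str) -> str:
    """Uppercase, map T->U and validate the alphabet."""
    seq = str(sequence).upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise FoldError(f"invalid nucleotides in sequence: {sorted(bad)!r}")
    return seq


def validate_constraint(constraint: str, n: int) -> str:
    if len(constraint) != n:
        raise FoldError(
            f"constraint length {len(constraint)} != sequence length {n}"
        )
    bad = set(constraint) - CONSTRAINT_CHARS
    if bad:
        raise FoldError(f"invalid constraint characters: {sorted(bad)!r}")
    return constraint


@dataclass(frozen=True)
class EnergyModel:
    """Simplified additive pair-energy model.

    ``pair_energies`` maps canonical pair type (GC, AU, GU) to a stabilizing
    (negative) energy in kcal/mol.  ``min_hairpin`` is the minimum number of
    unpaired nucleotides that must separate the two partners of any pair.
    ``kT`` is the thermal energy used in Boltzmann factors; the default of
    0.6 kcal corresponds to 37 degrees C.
    """

    pair_energies: Mapping[str, float] = field(
        default_factory=lambda: {"GC": -3.0, "AU": -2.0, "GU": -1.0}
    )
    min_hairpin: int = 3
    kT: float = 0.6
    allow_lone_pairs: bool = True

    def __post_init__(self) -> None:
        if set(self.pair_energies) != {"GC", "AU", "GU"}:
            raise ValueError("pair_energies must define exactly GC, AU, GU")
        if any(e >= 0 for e in self.pair_energies.values()):
            raise ValueError("all pair energies must be negative")
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if not self.allow_lone_pairs:
            # The additive model has no stack bonus, so prohibiting lone
            # pairs would change the structure space in ways the rest of
            # the engine does not model.
            raise ValueError("the simplified engine only supports allow_lone_pairs=True")

    def pair_energy(self, a: str, b: str) -> float | None:
        """Energy of pairing nucleotide ``a`` (5') with ``b`` (3'), or None."""
        t = _PAIR_TYPE.get((a, b))
        return None if t is None else self.pair_energies[t]


DEFAULT_MODEL = EnergyModel()

# Memoization for the two hot entry points: variants are folded once while
# planting editing levels and again while featurizing.  Keys include the
# model parameters; caches are bounded and cleared wholesale when full.
_CACHE_MAX = 20_000
_mfe_cache: dict = {}
_logz_cache: dict = {}


def _model_key(model: EnergyModel) -> tuple:
    return (
        tuple(sorted(model.pair_energies.items())),
        model.min_hairpin,
        model.kT,
    )


@dataclass(frozen=True)
class FoldResult:
    """MFE structure plus ensemble thermodynamics for one sequence."""

    sequence: str
    mfe_structure: str
    mfe_energy: float
    ensemble_energy: float
    mfe_frequency: float
    ensemble_diversity: float
    bp_prob: np.ndarray  # upper-triangular (i<j) pair probabilities


@dataclass(frozen=True)
class ActiveConfResult:
    """Constrained-ensemble probability of the WT-like (active) conformation."""

    e_wt: float
    z_full: float
    log_z_full: float
    noncanonical_core_count: int
    probability: float
    satisfiable: bool = True


def dotbracket_pairs(structure: str) -> list[tuple[int, int]]:
    """Return 0-based (i, j) pairs from a dot-bracket string.

    Raises FoldError on unbalanced brackets or illegal characters.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise FoldError(f"unbalanced ')' at position {idx + 1}")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise FoldError(f"illegal structure character {ch!r} at position {idx + 1}")
    if stack:
        raise FoldError(f"unbalanced '(' at position {stack[-1] + 1}")
    return sorted(pairs)


def _tables(
    seq: str, model: EnergyModel, constraint: str | None
) -> tuple[np.ndarray, np.ndarray]:
    """Pair-energy matrix (inf = disallowed) and per-position unpaired mask."""
    n = len(seq)
    c = constraint if constraint is not None else "." * n
    E = np.full((n, n), np.inf)
    for i in range(n):
        if c[i] not in ".|<":  # i cannot open a pair (pairs downstream)
            continue
        for j in range(i + model.min_hairpin + 1, n):
            if c[j] not in ".|>":
                continue
            e = model.pair_energy(seq[i], seq[j])
            if e is not None:
                E[i, j] = e
    unpaired_ok = np.array([c[i] in ".x" for i in range(n)], dtype=bool)
    return E, unpaired_ok


def fold_mfe(
    sequence: str,
    model: EnergyModel = DEFAULT_MODEL,
    constraint: str | None = None,
) -> tuple[str, float]:
    """Minimum-free-energy structure and energy.

    Tie-breaking is deterministic: at equal energy the leftmost undecided
    position is paired rather than unpaired, and paired to its 5'-most
    admissible partner.
    """
    seq = clean_sequence(sequence)
    n = len(seq)
    if constraint is not None:
        validate_constraint(constraint, n)
    if n == 0:
        return "", 0.0
    key = (seq, constraint, _model_key(model))
    hit = _mfe_cache.get(key)
    if hit is not None:
        if isinstance(hit, Exception):
            raise hit
        return hit
    if len(_mfe_cache) > _CACHE_MAX:
        _mfe_cache.clear()
    E, unp = _tables(seq, model, constraint)

    # W[i, j] = optimal energy on closed interval [i, j]; empty intervals
    # (i > j) read 0 because those cells are never written.
    W = np.zeros((n + 2, n + 2))
    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            best = W[i + 1, j] if unp[i] else np.inf
            ks = np.nonzero(np.isfinite(E[i, i + 1 : j + 1]))[0] + i + 1
            if ks.size:
                cand = E[i, ks] + W[i + 1, ks - 1] + W[ks + 1, j]
                best = min(best, cand.min())
            W[i, j] = best
    total = W[0, n - 1]
    if not np.isfinite(total):
        exc = ConstraintUnsatisfiableError(
            "no structure satisfies the constraints for this sequence"
        )
        _mfe_cache[key] = exc
        raise exc

    # Traceback, preferring 'pair i' (5'-most partner) over 'leave i unpaired'.
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i > j:
            continue
        target = W[i, j]
        ks = np.nonzero(np.isfinite(E[i, i + 1 : j + 1]))[0] + i + 1
        paired = False
        for k in ks:
            if E[i, k] + W[i + 1, k - 1] + W[k + 1, j] <= target + 1e-12:
                structure[i] = "("
                structure[k] = ")"
                stack.append((k + 1, j))
                stack.append((i + 1, k - 1))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    result = ("".join(structure), float(total))
    _mfe_cache[key] = result
    return result


def _log_inside(
    seq: str, model: EnergyModel, constraint: str | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-space inside matrix LZ plus pair log-Boltzmann weights."""
    n = len(seq)
    E, unp = _tables(seq, model, constraint)
    with np.errstate(invalid="ignore"):
        LB = np.where(np.isfinite(E), -E / model.kT, NEG_INF)
    LZ = np.zeros((n + 2, n + 2))
    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            terms = [LZ[i + 1, j] if unp[i] else NEG_INF]
            ks = np.nonzero(LB[i, i + 1 : j + 1] > NEG_INF)[0] + i + 1
            if ks.size:
                terms.append(
                    np.logaddexp.reduce(
                        LB[i, ks] + LZ[i + 1, ks - 1] + LZ[ks + 1, j]
                    )
                )
            LZ[i, j] = np.logaddexp.reduce(np.array(terms))
    return LZ, LB, unp


def log_partition_function(
    sequence: str,
    model: EnergyModel = DEFAULT_MODEL,
    constraint: str | None = None,
) -> float:
    """log Z, finite for any satisfiable input (log-space accumulation)."""
    seq = clean_sequence(sequence)
    n = len(seq)
    if constraint is not None:
        validate_constraint(constraint, n)
    if n == 0:
        return 0.0
    key = (seq, constraint, _model_key(model))
    hit = _logz_cache.get(key)
    if hit is not None:
        return hit
    if len(_logz_cache) > _CACHE_MAX:
        _logz_cache.clear()
    LZ, _, _ = _log_inside(seq, model, constraint)
    logz = float(LZ[0, n - 1])
    if logz == NEG_INF:
        raise ConstraintUnsatisfiableError(
            "constrained partition function is empty"
        )
    _logz_cache[key] = logz
    return logz


def partition_function(
    sequence: str,
    model: EnergyModel = DEFAULT_MODEL,
    constraint: str | None = None,
) -> tuple[float, float, np.ndarray]:
    """Partition function Z, ensemble free energy -kT ln Z, and pair probabilities.

    The pair-probability matrix is computed with the outside recursion in log
    space, so results stay finite well beyond the point where Z itself
    overflows a double.
    """
    seq = clean_sequence(sequence)
    n = len(seq)
    if constraint is not None:
        validate_constraint(constraint, n)
    if n == 0:
        return 1.0, 0.0, np.zeros((0, 0))
    LZ, LB, unp = _log_inside(seq, model, constraint)
    logz = float(LZ[0, n - 1])
    if logz == NEG_INF:
        raise ConstraintUnsatisfiableError(
            "constrained partition function is empty"
        )

    # Outside pass: LO[i, j] is the log weight of all contexts in which the
    # interval [i, j] appears in a parse; Lp accumulates pair usage.
    LO = np.full((n + 2, n + 2), NEG_INF)
    LO[0, n - 1] = 0.0
    Lp = np.full((n, n), NEG_INF)
    for span in range(n, 0, -1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            lo = LO[i, j]
            if lo == NEG_INF:
                continue
            if unp[i] and j >= i + 1:
                LO[i + 1, j] = np.logaddexp(LO[i + 1, j], lo)
            ks = np.nonzero(LB[i, i + 1 : j + 1] > NEG_INF)[0] + i + 1
            if not ks.size:
                continue
            c = lo + LB[i, ks]
            inner = LZ[i + 1, ks - 1]
            outer = LZ[ks + 1, j]
            np.logaddexp.at(Lp[i], ks, c + inner + outer)
            np.logaddexp.at(LO[i + 1], ks - 1, c + outer)
            m = ks < j
            if m.any():
                np.logaddexp.at(LO[:, j], ks[m] + 1, (c + inner)[m])

    with np.errstate(over="ignore"):
        bp = np.exp(Lp - logz)
    bp[~np.isfinite(bp)] = 0.0
    np.clip(bp, 0.0, 1.0, out=bp)
    z = math.exp(logz) if logz < 700 else math.inf
    return z, -model.kT * logz, bp


def ensemble_metrics(
    mfe_energy: float,
    ensemble_energy: float,
    bp_prob: np.ndarray,
    model: EnergyModel = DEFAULT_MODEL,
) -> tuple[float, float]:
    """MFE frequency exp(-(E_MFE - G)/kT) and ensemble diversity.

    Diversity is the expected symmetric-difference distance between two
    independent draws from the ensemble: 2 * sum_{i<j} p_ij (1 - p_ij).
    """
    freq = math.exp(-(mfe_energy - ensemble_energy) / model.kT)
    diversity = float(2.0 * np.sum(np.triu(bp_prob) * (1.0 - np.triu(bp_prob))))
    return freq, diversity


def fold_result(
    sequence: str,
    model: EnergyModel = DEFAULT_MODEL,
    constraint: str | None = None,
) -> FoldResult:
    """Convenience: MFE + partition function + ensemble metrics in one call."""
    seq = clean_sequence(sequence)
    structure, e_mfe = fold_mfe(seq, model, constraint)
    z, g, bp = partition_function(seq, model, constraint)
    freq, div = ensemble_metrics(e_mfe, g, bp, model)
    return FoldResult(
        sequence=seq,
        mfe_structure=structure,
        mfe_energy=e_mfe,
        ensemble_energy=g,
        mfe_frequency=freq,
        ensemble_diversity=div,
        bp_prob=bp,
    )


def _enumerate(
    i: int, j: int, E: np.ndarray, unp: np.ndarray
) -> Iterator[tuple[tuple[int, int], ...]]:
    if i > j:
        yield ()
        return
    if unp[i]:
        yield from _enumerate(i + 1, j, E, unp)
    for k in range(i + 1, j + 1):
        if not np.isfinite(E[i, k]):
            continue
        for inner in _enumerate(i + 1, k - 1, E, unp):
            for outer in _enumerate(k + 1, j, E, unp):
                yield ((i, k),) + inner + outer


def brute_force_fold(
    sequence: str,
    model: EnergyModel = DEFAULT_MODEL,
    constraint: str | None = None,
) -> list[tuple[str, float]]:
    """Exhaustively enumerate every valid structure with its energy.

    Test oracle for the DP engine; guarded to sequences of length <= 22.
    """
    seq = clean_sequence(sequence)
    n = len(seq)
    if n > _BRUTE_FORCE_MAX_LEN:
        raise FoldError(f"brute-force enumeration limited to n <= {_BRUTE_FORCE_MAX_LEN}")
    if constraint is not None:
        validate_constraint(constraint, n)
    if n == 0:
        return [("", 0.0)]
    E, unp = _tables(seq, model, constraint)
    out: list[tuple[str, float]] = []
    for pairs in _enumerate(0, n - 1, E, unp):
        db = ["."] * n
        energy = 0.0
        for a, b in pairs:
            db[a] = "("
            db[b] = ")"
            energy += E[a, b]
        out.append(("".join(db), energy))
    if not out:
        raise ConstraintUnsatisfiableError(
            "no structure satisfies the constraints for this sequence"
        )
    return out


def active_conformation_probability(
    sequence: str,
    model: EnergyModel,
    constraint: str,
    reference: str,
) -> ActiveConfResult:
    """Boltzmann probability of the constrained WT-like state.

    probability = exp(-E_wt / kT) / Z, divided by the number of reference-core
    pairs that the variant cannot realize canonically (floored at 1).  E_wt is
    the energy of the constrained MFE state; Z is the unconstrained partition
    function.  Variants for which the constraint is unsatisfiable return a
    flagged NaN instead of a number.
    """
    seq = clean_sequence(sequence)
    n = len(seq)
    validate_constraint(constraint, n)
    if len(reference) != n:
        raise FoldError(
            f"reference length {len(reference)} != sequence length {n}"
        )
    ref_pairs = dotbracket_pairs(reference)
    noncanonical = sum(
        1 for i, j in ref_pairs if model.pair_energy(seq[i], seq[j]) is None
    )
    logz = log_partition_function(seq, model, constraint=None)
    try:
        _, e_wt = fold_mfe(seq, model, constraint)
    except ConstraintUnsatisfiableError:
        return ActiveConfResult(
            e_wt=math.nan,
            z_full=math.exp(logz) if logz < 700 else math.inf,
            log_z_full=logz,
            noncanonical_core_count=noncanonical,
            probability=math.nan,
            satisfiable=False,
        )
    log_p = -e_wt / model.kT - logz - math.log(max(1, noncanonical))
    return ActiveConfResult(
        e_wt=e_wt,
        z_full=math.exp(logz) if logz < 700 else math.inf,
        log_z_full=logz,
        noncanonical_core_count=noncanonical,
        probability=math.exp(min(log_p, 0.0)),
        satisfiable=True,
    )


def external_fold_adapter(
    sequence: str,
    constraint: str | None = None,
    backend: str = "builtin",
    model: EnergyModel = DEFAULT_MODEL,
) -> FoldResult:
    """Backend-agnostic folding entry point.

    ``builtin`` uses the simplified engine; ``vienna`` delegates to the
    ViennaRNA Python bindings when installed and raises
    BackendUnavailableError otherwise (never a silent fallback).
    """
    if backend == "builtin":
        return fold_result(sequence, model, constraint)
    if backend == "vienna":
        return _vienna_fold(sequence, constraint)
    raise ValueError(f"unknown backend {backend!r}")


def _vienna_fold(sequence: str, constraint: str | None) -> FoldResult:
    try:
        import RNA  # type: ignore
    except ImportError as exc:  # pragma: no cover - backend optional
        raise BackendUnavailableError(
            "ViennaRNA Python bindings are not installed; "
            "install the 'viennarna' package or use backend='builtin'"
        ) from exc
    # pragma: no cover - exercised only where ViennaRNA is available
    seq = clean_sequence(sequence)
    md = RNA.md()
    md.noLP = 0  # lone pairs allowed, matching the builtin engine
    fc = RNA.fold_compound(seq, md)
    if constraint is not None:
        validate_constraint(constraint, len(seq))
        fc.hc_add_from_db(constraint)
    ss, mfe = fc.mfe()
    fc.exp_params_rescale(mfe)
    _, gibbs = fc.pf()
    n = len(seq)
    bp = np.zeros((n, n))
    raw = fc.bpp()
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            bp[i - 1, j - 1] = raw[i][j]
    kt = fc.exp_params().kT / 1000.0
    freq = math.exp(-(mfe - gibbs) / kt)
    diversity = float(fc.mean_bp_distance())
    return FoldResult(
        sequence=seq,
        mfe_structure=ss,
        mfe_energy=float(mfe),
        ensemble_energy=float(gibbs),
        mfe_frequency=freq,
        ensemble_diversity=diversity,
        bp_prob=bp,
    )
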