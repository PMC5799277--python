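"""RNA secondary structures and the four hairpin descriptors.

A structure is a sequence plus a nested (pseudoknot-free) base-pairing map.
Four descriptor variables summarise it:

1. ``loop_pct``  — percent of nucleotides not involved in self-hybridisation;
2. ``eloop_pct`` — percent of loop nucleotides sitting in hairpin (terminal)
   loops, i.e. loops closed by a single base pair at a stem extremity;
3. ``stem_gc``   — GC percent among paired nucleotides;
4. ``loop_gc``   — GC percent among unpaired nucleotides.

Structures can be imported from dot-bracket text (e.g. Mfold/Vienna output)
or predicted with the built-in deterministic maximum-scoring nested folder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

from .errors import ConfigError, DotBracketError, InputError

ALPHABET = set("ACGUTN")
GC = set("GC")

#: Base-pair scores for the built-in folder: strong GC, weaker AU, weak GU
#: wobble. An extra ``stack_bonus`` rewards each pair stacked directly on
#: another, favouring long helices over isolated pairs.
DEFAULT_PAIR_SCORES: dict[frozenset, int] = {
    frozenset("GC"): 3,
    frozenset("AT"): 2,  # sequences are normalised to the DNA alphabet
    frozenset("GT"): 1,
}


def _normalize(sequence: str) -> str:
    """Uppercase and map U->T; descriptors are T/U-agnostic."""
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise InputError(f"unexpected symbols in sequence: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class SecondaryStructure:
    """A nucleotide sequence with a nested base-pairing map.

    ``pairing`` holds 0-based index pairs ``(i, j)`` with ``i < j``; every
    index occurs in at most one pair and no two pairs cross.
    """

    sequence: str
    pairing: tuple[tuple[int, int], ...]

    def __post_init__(self):
        n = len(self.sequence)
        object.__setattr__(self, "pairing", tuple(sorted(tuple(p) for p in self.pairing)))
        seen: set[int] = set()
        for i, j in self.pairing:
            if not (0 <= i < j < n):
                raise InputError(f"pair ({i}, {j}) out of range for length {n}")
            if i in seen or j in seen:
                raise InputError(f"index used by more than one pair near ({i}, {j})")
            seen.update((i, j))
        stack: list[int] = []
        opens = {i: j for i, j in self.pairing}
        closes = {j: i for i, j in self.pairing}
        for k in range(n):
            if k in opens:
                stack.append(opens[k])
            elif k in closes:
                if not stack or stack[-1] != k:
                    raise InputError(
                        f"pairing is not nested (pseudoknot) at position {k}"
                    )
                stack.pop()

    @property
    def n(self) -> int:
        return len(self.sequence)

    @property
    def paired_indices(self) -> frozenset:
        return frozenset(k for pair in self.pairing for k in pair)

    def to_dot_bracket(self) -> str:
        out = ["."] * self.n
        for i, j in self.pairing:
            out[i], out[j] = "(", ")"
        return "".join(out)

    def validate_min_hairpin(self, min_hairpin: int = 3) -> None:
        """Reject hairpin-closing pairs enclosing fewer than ``min_hairpin``
        unpaired nucleotides."""
        for start, end in hairpin_loops(self):
            if end - start + 1 < min_hairpin:
                raise InputError(
                    f"hairpin loop of {end - start + 1} nt at {start}-{end} "
                    f"is below min_hairpin={min_hairpin}"
                )


def parse_dot_bracket(text: str, *, min_hairpin: int = 3,
                      validate_hairpin: bool = True) -> SecondaryStructure:
    """Parse a two-line record (sequence line, then bracket line).

    A leading ``>`` header line is tolerated. Round-trips losslessly with
    :meth:`SecondaryStructure.to_dot_bracket`.
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise DotBracketError("expected a sequence line and a bracket line")
    seq, db = _normalize(lines[0]), lines[1].split()[0]
    if len(db) != len(seq):
        raise InputError(
            f"sequence length {len(seq)} != structure length {len(db)}"
        )
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(db):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise DotBracketError(
                    f"unbalanced ')' at position {pos}", position=pos
                )
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise DotBracketError(
                f"unexpected character {ch!r} at position {pos}", position=pos
            )
    if stack:
        raise DotBracketError(
            f"unbalanced '(' at position {stack[-1]}", position=stack[-1]
        )
    structure = SecondaryStructure(seq, tuple(pairs))
    if validate_hairpin:
        structure.validate_min_hairpin(min_hairpin)
    return structure


def hairpin_loops(structure: SecondaryStructure) -> list[tuple[int, int]]:
    """Terminal ("closed at stem extremity") loops as 0-based inclusive
    ``(start, end)`` intervals.

    Each is a maximal unpaired run whose flanking positions form one base
    pair with nothing nested between them.
    """
    paired = structure.paired_indices
    loops = []
    for i, j in structure.pairing:
        if j - i > 1 and all(k not in paired for k in range(i + 1, j)):
            loops.append((i + 1, j - 1))
    return sorted(loops)


# --------------------------------------------------------------------------
# Descriptor profile


@dataclass(frozen=True)
class StructureProfile:
    """The four descriptor variables plus length and optional cluster label.

    ``empty_categories`` flags descriptors whose denominator was empty
    (e.g. ``stem_gc`` of a fully unpaired molecule, reported as 0).
    """

    label: str
    n: int
    loop_pct: float
    eloop_pct: float
    stem_gc: float
    loop_gc: float
    cluster: str = "none"
    empty_categories: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        for name in ("loop_pct", "eloop_pct", "stem_gc", "loop_gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise InputError(f"{name}={v} outside [0, 100]")

    def vector(self) -> tuple[float, float, float, float]:
        """Descriptor 4-vector in the fixed order (loop, eloop, stem GC,
        loop GC) used for profile comparisons."""
        return (self.loop_pct, self.eloop_pct, self.stem_gc, self.loop_gc)

    def with_cluster(self, cluster: str) -> "StructureProfile":
        return replace(self, cluster=cluster)


def compute_profile(structure: SecondaryStructure, *, label: str = "",
                    cluster: str = "none",
                    gc_denominator: str = "category") -> StructureProfile:
    """Compute the four descriptors from a structure.

    GC counts treat U as non-GC; N counts toward length and category sizes
    but never toward GC. ``gc_denominator`` selects whether GC percentages
    are relative to the nucleotides of that category (default) or to the
    whole sequence length (``"total"``).
    """
    if gc_denominator not in ("category", "total"):
        raise ConfigError(f"unknown gc_denominator {gc_denominator!r}")
    seq = structure.sequence
    n = structure.n
    if n == 0:
        raise InputError("empty structure")
    paired = structure.paired_indices
    unpaired = [k for k in range(n) if k not in paired]
    eloop_nt = sum(e - s + 1 for s, e in hairpin_loops(structure))
    gc_stem = sum(1 for k in paired if seq[k] in GC)
    gc_loop = sum(1 for k in unpaired if seq[k] in GC)

    empty = set()
    loop_pct = 100.0 * len(unpaired) / n
    # terminal loops need both a denominator (unpaired nt) and stems to
    # close them; either absence is the degenerate case
    if unpaired and paired:
        eloop_pct = 100.0 * eloop_nt / len(unpaired)
    else:
        eloop_pct = 0.0
        empty.add("eloop")
    stem_den = n if gc_denominator == "total" else len(paired)
    loop_den = n if gc_denominator == "total" else len(unpaired)
    if paired:
        stem_gc = 100.0 * gc_stem / stem_den
    else:
        stem_gc = 0.0
        empty.add("stem")
    if unpaired:
        loop_gc = 100.0 * gc_loop / loop_den
    else:
        loop_gc = 0.0
        empty.add("loop")
    return StructureProfile(label, n, loop_pct, eloop_pct, stem_gc, loop_gc,
                            cluster, frozenset(empty))


# --------------------------------------------------------------------------
# Built-in folder: Nussinov-style maximum pair+stack score, deterministic


@dataclass(frozen=True)
class FoldConfig:
    """Scoring for the built-in nested folder."""

    pair_scores: tuple = tuple(sorted(
        (tuple(sorted(k)), v) for k, v in DEFAULT_PAIR_SCORES.items()
    ))
    stack_bonus: int = 1
    min_hairpin: int = 3

    def score_of(self, a: str, b: str) -> int | None:
        return dict(self.pair_scores).get(tuple(sorted((a, b))))


def structure_score(structure: SecondaryStructure,
                    config: FoldConfig = FoldConfig()) -> int:
    """Total pair + stacking score of a structure under ``config``.

    Shared by the folder and by enumeration-based oracles so both score the
    same objective.
    """
    seq = structure.sequence
    total = 0
    pairs = set(structure.pairing)
    for i, j in pairs:
        s = config.score_of(seq[i], seq[j])
        if s is None:
            raise InputError(f"non-canonical pair {seq[i]}-{seq[j]} at ({i},{j})")
        total += s
        if (i + 1, j - 1) in pairs:
            total += config.stack_bonus
    return total


def fold_min_energy(sequence: str,
                    config: FoldConfig = FoldConfig()) -> SecondaryStructure:
    """Deterministic maximum-scoring pseudoknot-free fold.

    Dynamic program over ``V`` (best score given ``(i, j)`` paired), ``U``
    (best score on ``[i, j]`` with ``i`` and ``j`` not paired to each other)
    and ``W = max(U, V)``; ties in the traceback are broken toward the pair
    with the smallest opening index. N never pairs.
    """
    seq = _normalize(sequence)
    n = len(seq)
    if n == 0:
        raise InputError("cannot fold an empty sequence")
    theta = config.min_hairpin
    NEG = float("-inf")

    def pair_score(i: int, j: int):
        return config.score_of(seq[i], seq[j])

    V = [[NEG] * n for _ in range(n)]
    W = [[0] * n for _ in range(n)]
    U = [[0] * n for _ in range(n)]

    def w(i: int, j: int) -> float:
        return W[i][j] if i <= j else 0

    for span in range(theta + 1, n):
        for i in range(0, n - span):
            j = i + span
            s = pair_score(i, j)
            if s is not None:
                inner = U[i + 1][j - 1]
                if V[i + 1][j - 1] != NEG:
                    inner = max(inner, V[i + 1][j - 1] + config.stack_bonus)
                V[i][j] = s + inner
            best_u = W[i][j - 1]
            for k in range(i + 1, j - theta):
                if V[k][j] != NEG:
                    cand = w(i, k - 1) + V[k][j]
                    if cand > best_u:
                        best_u = cand
            U[i][j] = best_u
            W[i][j] = max(best_u, V[i][j])

    pairs: list[tuple[int, int]] = []

    def trace_W(i: int, j: int) -> None:
        if j - i < theta + 1:
            return
        # prefer pairing j with the smallest opening index
        for k in range(i, j - theta):
            if V[k][j] != NEG and w(i, k - 1) + V[k][j] == W[i][j]:
                if k > i:
                    trace_W(i, k - 1)
                trace_V(k, j)
                return
        trace_W(i, j - 1)

    def trace_U(i: int, j: int) -> None:
        if j - i < theta + 1:
            return
        for k in range(i + 1, j - theta):
            if V[k][j] != NEG and w(i, k - 1) + V[k][j] == U[i][j]:
                trace_W(i, k - 1)
                trace_V(k, j)
                return
        trace_W(i, j - 1)

    def trace_V(i: int, j: int) -> None:
        pairs.append((i, j))
        s = pair_score(i, j)
        if (V[i + 1][j - 1] != NEG
                and s + V[i + 1][j - 1] + config.stack_bonus == V[i][j]):
            trace_V(i + 1, j - 1)
        else:
            trace_U(i + 1, j - 1)

    if n > theta + 1:
        trace_W(0, n - 1)
    return SecondaryStructure(seq, tuple(pairs))


def enumerate_structures(sequence: str,
                         config: FoldConfig = FoldConfig()
                         ) -> Iterator[SecondaryStructure]:
    """Exhaustively enumerate every nested structure of a short sequence.

    Exponential; intended as a brute-force oracle for the folder at small n.
    """
    seq = _normalize(sequence)
    n = len(seq)
    theta = config.min_hairpin

    def enum(i: int, j: int) -> Iterator[tuple]:
        if j - i < theta + 1:
            yield ()
            return
        for rest in enum(i + 1, j):
            yield rest
        for k in range(i + theta + 1, j + 1):
            if config.score_of(seq[i], seq[k]) is not None:
                for inner in enum(i + 1, k - 1):
                    for outer in enum(k + 1, j):
                        yield ((i, k),) + inner + outer

    for pairing in enum(0, n - 1):
        yield SecondaryStructure(seq, pairing)
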