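"""Systematic nucleotide-exchange ("swinger") rules and transcript detection.

A swinger rule is a non-identity permutation of {A, C, G, T} applied
positionwise over the whole length of a sequence. There are exactly 23 such
rules: 9 symmetric (involutions, written ``X<->Y`` or ``X<->Y-Z<->W``) and
14 asymmetric (3- or 4-cycles, written ``X->Y->Z->X``). A swinger
transcript is a read that fails to map on the regular genome but maps on at
least one rule-transformed version of it.

Conjugating a rule by the Watson-Crick complement (``comp o rule o comp``)
links the two strands: a read produced by rule R from the minus strand is
detected on the conjugate(R)-transformed plus-strand genome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass(frozen=True)
class SwingerRule:
    """A non-identity permutation of {A, C, G, T}.

    ``images`` gives the image of A, C, G, T in that order. Symmetric rules
    are involutions (cycle type 2 or 2+2); asymmetric rules are single 3-
    or 4-cycles.
    """

    images: tuple[str, str, str, str]

    def __post_init__(self):
        if sorted(self.images) != list(BASES):
            raise InputError(f"not a permutation of ACGT: {self.images}")
        if tuple(self.images) == tuple(BASES):
            raise InputError("the identity is not a swinger rule")

    def __getitem__(self, base: str) -> str:
        return self.images[BASES.index(base)]

    @property
    def mapping(self) -> dict:
        return dict(zip(BASES, self.images))

    def _cycles(self) -> list[tuple[str, ...]]:
        seen, cycles = set(), []
        for start in BASES:
            if start in seen:
                continue
            cyc, b = [start], self[start]
            seen.add(start)
            while b != start:
                cyc.append(b)
                seen.add(b)
                b = self[b]
            if len(cyc) > 1:
                cycles.append(tuple(cyc))
        return cycles

    @property
    def name(self) -> str:
        """Canonical name: ``X<->Y`` swaps (joined by ``-``), or a cycle
        ``X->Y->Z->X`` starting at its alphabetically first member."""
        cycles = self._cycles()
        if all(len(c) == 2 for c in cycles):
            return "-".join(
                "<->".join(sorted(c)) for c in sorted(cycles, key=min)
            )
        (cyc,) = cycles
        k = cyc.index(min(cyc))
        rot = cyc[k:] + cyc[:k]
        return "->".join(rot + (rot[0],))

    @property
    def rule_class(self) -> str:
        return "symmetric" if self.is_involution else "asymmetric"

    @property
    def is_involution(self) -> bool:
        return all(self[self[b]] == b for b in BASES)

    def compose(self, other: "SwingerRule | None") -> "SwingerRule | None":
        """self o other (apply ``other`` first); None stands for identity."""
        images = tuple(
            self[b] if other is None else self[other[b]] for b in BASES
        )
        return None if images == tuple(BASES) else SwingerRule(images)

    def apply(self, sequence: str) -> str:
        return apply_rule(sequence, self)

    def __str__(self) -> str:
        return self.name


@lru_cache(maxsize=1)
def enumerate_rules() -> tuple[SwingerRule, ...]:
    """All 23 non-identity permutations of ACGT, ordered as single swaps,
    double swaps, 3-cycles, then 4-cycles, each alphabetically by name."""
    rules = [
        SwingerRule(p)
        for p in itertools.permutations(BASES)
        if p != tuple(BASES)
    ]

    def key(rule: SwingerRule):
        cycles = rule._cycles()
        if all(len(c) == 2 for c in cycles):
            order = 0 if len(cycles) == 1 else 1
        else:
            order = 2 if len(cycles[0]) == 3 else 3
        return (order, rule.name)

    return tuple(sorted(rules, key=key))


def parse_rule(name: str) -> SwingerRule:
    """Parse a canonical rule name (``A<->C``, ``A<->C-G<->T``,
    ``C->T->G->C``, ``A->C->G->T->A``)."""
    text = name.strip()
    mapping = dict(zip(BASES, BASES))

    def assign(src: str, dst: str) -> None:
        if src not in _COMPLEMENT or dst not in _COMPLEMENT:
            raise InputError(f"malformed rule name {name!r}")
        if mapping[src] != src:
            raise InputError(f"base {src} mapped twice in {name!r}")
        mapping[src] = dst

    if "<->" in text:
        # swaps are separated by a single "-", but "-" also occurs inside
        # "<->": accumulate chunks until a complete "X<->Y" token forms
        tokens, buf = [], ""
        for chunk in text.split("-"):
            buf = buf + "-" + chunk if buf else chunk
            if buf.count("<->") == 1 and not buf.endswith("<") \
                    and not buf.endswith(">"):
                a, b = buf.split("<->")
                if len(a) == 1 and len(b) == 1:
                    tokens.append((a, b))
                    buf = ""
        if buf or not tokens:
            raise InputError(f"malformed rule name {name!r}")
        for a, b in tokens:
            if a == b:
                raise InputError(f"degenerate swap in {name!r}")
            assign(a, b)
            assign(b, a)
    elif "->" in text:
        cyc = text.split("->")
        if len(cyc) < 4 or cyc[0] != cyc[-1]:
            raise InputError(
                f"cycle in {name!r} must close on its first base"
            )
        body = cyc[:-1]
        if len(set(body)) != len(body):
            raise InputError(f"repeated base in cycle {name!r}")
        for a, b in zip(body, body[1:] + [body[0]]):
            assign(a, b)
    else:
        raise InputError(f"malformed rule name {name!r}")
    images = tuple(mapping[b] for b in BASES)
    if images == tuple(BASES):
        raise InputError("rule name denotes the identity")
    return SwingerRule(images)


def apply_rule(sequence: str, rule: "SwingerRule | str") -> str:
    """Positionwise application of a rule; U is normalised to T first and
    N (or any non-ACGT symbol) passes through unchanged."""
    if isinstance(rule, str):
        rule = parse_rule(rule)
    seq = sequence.upper().replace("U", "T")
    table = str.maketrans(BASES, "".join(rule.images))
    return seq.translate(table)


def conjugate_by_complement(rule: "SwingerRule | str") -> SwingerRule:
    """comp o rule o comp: the rule detected on the opposite strand."""
    if isinstance(rule, str):
        rule = parse_rule(rule)
    images = tuple(
        _COMPLEMENT[rule[_COMPLEMENT[b]]] for b in BASES
    )
    if images == tuple(BASES):  # cannot happen: conjugation preserves order
        raise InputError("conjugate collapsed to identity")
    return SwingerRule(images)


# --------------------------------------------------------------------------
# Detection


@dataclass(frozen=True)
class SwingerHit:
    """An ungapped local match of a read on a (possibly transformed) genome.

    ``start``/``end`` are 1-based inclusive genome coordinates on the plus
    strand; ``rule`` is "identity" for matches on the untransformed genome,
    otherwise the swinger rule relative to the strand the read came from.
    """

    read_id: str
    rule: str
    strand: str
    start: int
    end: int
    aligned_fraction: float
    identity: float


class GenomeIndex:
    """Exact k-mer index of one genome with ungapped seed-and-extend search.

    A match is the longest window on a seeded diagonal whose identity stays
    at or above ``identity_min`` while covering at least ``coverage_min``
    of the read (and at least one seed length).
    """

    def __init__(self, genome: str, seed_k: int = 12):
        if not genome:
            raise InputError("genome is empty")
        if seed_k < 1:
            raise ConfigError("seed_k must be positive")
        self.genome = genome.upper().replace("U", "T")
        self.seed_k = seed_k
        k = seed_k
        self._index: dict[str, list[int]] = {}
        for pos in range(len(self.genome) - k + 1):
            self._index.setdefault(self.genome[pos:pos + k], []).append(pos)

    def _align_diagonal(self, query: str, diag: int, coverage_min: float,
                        identity_min: float, read_len: int):
        """Best feasible window on one diagonal as (qstart, qend, mm),
        or None. Longest window wins; among equals, fewest mismatches,
        then leftmost."""
        genome = self.genome
        L = len(query)
        q0 = max(0, -diag)
        q1 = min(L, len(genome) - diag)
        if q1 - q0 <= 0:
            return None
        mm = np.fromiter(
            (query[p] != genome[p + diag] for p in range(q0, q1)),
            dtype=np.int32, count=q1 - q0,
        )
        pref = np.concatenate(([0], np.cumsum(mm)))
        min_len = max(self.seed_k, int(np.ceil(coverage_min * read_len)))
        span = q1 - q0
        for length in range(span, min_len - 1, -1):
            window_mm = pref[length:] - pref[: span - length + 1]
            allowed = (1.0 - identity_min) * length
            ok = np.nonzero(window_mm <= allowed + 1e-9)[0]
            if ok.size:
                best = ok[np.argmin(window_mm[ok])]
                return (q0 + int(best), q0 + int(best) + length,
                        int(window_mm[best]))
        return None

    def search(self, query: str, *, coverage_min: float = 0.5,
               identity_min: float = 0.8,
               read_len: int | None = None) -> list[tuple[int, int, int, int]]:
        """All per-diagonal matches as (qstart, qend, mismatches, diag)."""
        read_len = len(query) if read_len is None else read_len
        k = self.seed_k
        diagonals: set[int] = set()
        for qpos in range(0, len(query) - k + 1):
            for gpos in self._index.get(query[qpos:qpos + k], ()):
                diagonals.add(gpos - qpos)
        out = []
        for diag in sorted(diagonals):
            res = self._align_diagonal(query, diag, coverage_min,
                                       identity_min, read_len)
            if res is not None:
                out.append((*res, diag))
        return out


class SwingerDetector:
    """k-mer seeded, ungapped swinger-transcript detector.

    The genome and its 23 rule-transformed versions are indexed once by
    exact k-mers (default k = 12). A read is first mapped on the regular
    genome (both strands); only reads without a regular hit are searched
    against the transformed genomes. A hit requires an aligned fraction of
    at least ``coverage_min`` of the read at ``identity_min`` identity or
    better (defaults 0.5 and 0.8, the published mapping criteria).

    Minus-strand hits on a Q-transformed genome are reported under the rule
    conjugate(Q) — the exchange rule relative to the strand that templated
    the read.
    """

    def __init__(self, genome: str, *, coverage_min: float = 0.5,
                 identity_min: float = 0.8, seed_k: int = 12):
        if not genome:
            raise InputError("genome is empty")
        if not (0 < coverage_min <= 1 and 0 < identity_min <= 1):
            raise ConfigError("thresholds must lie in (0, 1]")
        if seed_k < 1:
            raise ConfigError("seed_k must be positive")
        self.genome = genome.upper().replace("U", "T")
        self.coverage_min = coverage_min
        self.identity_min = identity_min
        self.seed_k = seed_k
        self._targets: list[tuple[SwingerRule | None, GenomeIndex]] = []
        for rule in (None, *enumerate_rules()):
            g = self.genome if rule is None else rule.apply(self.genome)
            self._targets.append((rule, GenomeIndex(g, seed_k)))

    def _search(self, query: str, target_idx: int, read_id: str,
                rule_name: str, strand: str, read_len: int) -> list[SwingerHit]:
        _, index = self._targets[target_idx]
        hits = []
        for qs, qe, mm, diag in index.search(
            query, coverage_min=self.coverage_min,
            identity_min=self.identity_min, read_len=read_len,
        ):
            length = qe - qs
            hits.append(SwingerHit(
                read_id=read_id, rule=rule_name, strand=strand,
                start=qs + diag + 1, end=qe + diag,
                aligned_fraction=length / read_len,
                identity=(length - mm) / length,
            ))
        return hits

    def detect(self, read: str, read_id: str = "read") -> list[SwingerHit]:
        """All hits for one read: regular-genome hits if any exist,
        otherwise swinger hits sorted by identity then aligned fraction."""
        fwd = read.upper().replace("U", "T")
        if len(fwd) < self.seed_k:
            raise InputError(
                f"read shorter than seed_k={self.seed_k}"
            )
        rev = revcomp(fwd)
        L = len(fwd)
        identity_hits = (
            self._search(fwd, 0, read_id, "identity", "+", L)
            + self._search(rev, 0, read_id, "identity", "-", L)
        )
        if identity_hits:
            return self._sorted(identity_hits)
        hits: list[SwingerHit] = []
        for t, (rule, _) in enumerate(self._targets[1:], start=1):
            hits.extend(self._search(fwd, t, read_id, rule.name, "+", L))
            hits.extend(self._search(
                rev, t, read_id, conjugate_by_complement(rule).name, "-", L
            ))
        return self._sorted(hits)

    @staticmethod
    def _sorted(hits: list[SwingerHit]) -> list[SwingerHit]:
        return sorted(
            hits,
            key=lambda h: (-h.identity, -h.aligned_fraction, h.rule,
                           h.strand, h.start),
        )

    def detect_all(self, reads: Iterable[tuple[str, str]]) -> pd.DataFrame:
        """Best hit per read over an iterable of (read_id, sequence).

        Reads with no hit get rule "unmapped". Returns a hits table with
        one row per read.
        """
        rows = []
        for read_id, seq in reads:
            hits = self.detect(seq, read_id)
            if hits:
                h = hits[0]
                rows.append({
                    "read_id": read_id, "rule": h.rule, "strand": h.strand,
                    "start": h.start, "end": h.end,
                    "coverage": h.aligned_fraction, "identity": h.identity,
                    "read_length": len(seq),
                })
            else:
                rows.append({
                    "read_id": read_id, "rule": "unmapped", "strand": ".",
                    "start": 0, "end": 0, "coverage": 0.0, "identity": 0.0,
                    "read_length": len(seq),
                })
        return pd.DataFrame(rows, columns=[
            "read_id", "rule", "strand", "start", "end", "coverage",
            "identity", "read_length",
        ])


def detect_swinger(read: str, genome: str, *, coverage_min: float = 0.5,
                   identity_min: float = 0.8, seed_k: int = 12,
                   read_id: str = "read") -> list[SwingerHit]:
    """One-shot detection of a single read (builds a throwaway index)."""
    det = SwingerDetector(genome, coverage_min=coverage_min,
                          identity_min=identity_min, seed_k=seed_k)
    return det.detect(read, read_id)


def summarize_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-rule summary (rule, N, mean read length) over a hits table.

    Always reports identity plus all 23 rules in canonical order, zero-
    filled, mirroring the shape of the published abundance table.
    """
    order = ["identity"] + [r.name for r in enumerate_rules()]
    grouped = (
        hits[hits["rule"].isin(order)]
        .groupby("rule")
        .agg(n=("read_id", "nunique"), mean_read_length=("read_length", "mean"))
        if len(hits)
        else pd.DataFrame(columns=["n", "mean_read_length"])
    )
    rows = []
    for name in order:
        if name in grouped.index:
            rows.append({
                "rule": name,
                "n": int(grouped.loc[name, "n"]),
                "mean_read_length": float(grouped.loc[name, "mean_read_length"]),
            })
        else:
            rows.append({"rule": name, "n": 0, "mean_read_length": float("nan")})
    return pd.DataFrame(rows)
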