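"""Seed-deterministic synthetic inputs for every pipeline stage.

Three generators cover the three analysis settings:

- :func:`make_hairpin_rna` — hairpin RNAs of rod (one long stem, one
  terminal loop) or branched (several stems meeting at a junction)
  topology with controllable GC content;
- :func:`simulate_swinger_reads` — a toy genome with reads, a configurable
  fraction of which are swinger-transformed substrings (either strand)
  with substitution noise, plus a truth table;
- :func:`make_profile_set` — separable labelled clusters in descriptor
  space for classifier-recovery experiments.

Defaults emulate the published study's scale where it states one: read
length 40 nt (near the SOLiD mean read length of about 36), mapping-grade
genomes of 10 kb with uniform base composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .swinger import (GenomeIndex, SwingerRule, apply_rule,
                      conjugate_by_complement, parse_rule, revcomp)
from .structures import StructureProfile

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the read/hairpin simulators; same seed, same output."""

    seed: int = 0
    genome_length: int = 10_000
    read_length: int = 40
    n_reads: int = 1000
    planted_rule: str | None = None
    swinger_fraction: float = 0.5
    minus_fraction: float = 0.5
    error_rate: float = 0.0
    gc_target: float = 0.5
    topology: str = "rod"
    stem_length: int = 10
    loop_length: int = 4
    n_arms: int = 2

    def __post_init__(self):
        for name in ("swinger_fraction", "minus_fraction", "error_rate",
                     "gc_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in ("genome_length", "read_length", "n_reads",
                     "stem_length", "loop_length"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.topology not in ("rod", "branched"):
            raise ConfigError(f"unknown topology {self.topology!r}")


def _with_gc_count(rng: np.random.Generator, length: int,
                   gc_count: int) -> str:
    """Random sequence of given length with exactly ``gc_count`` G/C."""
    strong = rng.choice(list("GC"), size=gc_count)
    weak = rng.choice(list("AT"), size=length - gc_count)
    seq = np.concatenate([strong, weak])
    rng.shuffle(seq)
    return "".join(seq)


def _loop_seq(rng: np.random.Generator, length: int, gc_target: float) -> str:
    """Loop filler over {A, C} (non-pairing alphabet) matching GC roughly."""
    n_c = round(gc_target * length)
    seq = np.array(["C"] * n_c + ["A"] * (length - n_c))
    rng.shuffle(seq)
    return "".join(seq)


def make_hairpin_rna(config: SimulationConfig) -> str:
    """One rod or branched hairpin sequence (DNA alphabet).

    Rod: stem arm + terminal loop + reverse-complement arm. Branched:
    ``n_arms`` such hairpins joined by short unpaired spacers. Realised GC
    lands within 5 points of ``gc_target`` (stem arms carry an exact GC
    count; loops use a non-self-pairing A/C alphabet).
    """
    if config.loop_length < 3:
        raise ConfigError(
            "loop_length must be >= 3 so the hairpin can close"
        )
    if config.topology == "branched" and config.n_arms < 2:
        raise ConfigError("branched topology needs n_arms >= 2")
    rng = np.random.default_rng(config.seed)
    n_arms = 1 if config.topology == "rod" else config.n_arms
    gc_arm = round(config.gc_target * config.stem_length)
    parts = []
    for arm in range(n_arms):
        stem = _with_gc_count(rng, config.stem_length, gc_arm)
        loop = _loop_seq(rng, config.loop_length, config.gc_target)
        parts.append(stem + loop + revcomp(stem))
    spacer = "AAA" if config.gc_target < 0.5 else "AAC"
    return spacer.join(parts)


@dataclass(frozen=True)
class SwingerReadSet:
    """Genome, reads and the planted truth of one simulation."""

    genome: str
    reads: tuple[tuple[str, str], ...]  # (read_id, sequence)
    truth: pd.DataFrame
    config: SimulationConfig


def simulate_swinger_reads(config: SimulationConfig) -> SwingerReadSet:
    """Toy genome plus reads, a fraction of them swinger-transformed.

    Each read is a ``read_length`` substring of the genome; with
    probability ``swinger_fraction`` the planted rule is applied, with
    probability ``minus_fraction`` the read is then reverse-complemented
    (a minus-strand read). Substitutions are sprinkled at ``error_rate``
    per base. The truth table records, per read, the rule a detector
    should report (the conjugate rule for minus-strand swinger reads),
    the strand and the 1-based inclusive genome interval.

    Planted truth is unambiguous by construction: a transformed read that
    would coincidentally still match the *untransformed* genome at the
    standard mapping criteria (half the read at 80% identity) is re-drawn
    at a different position, since such a read is by definition a regular
    transcript and no detector applying those criteria could attribute it
    to the rule.
    """
    if config.planted_rule is None:
        raise ConfigError("simulate_swinger_reads needs planted_rule")
    if config.read_length > config.genome_length:
        raise ConfigError("read_length exceeds genome_length")
    rule = parse_rule(config.planted_rule)
    conj = conjugate_by_complement(rule)
    rng = np.random.default_rng(config.seed)
    genome = "".join(rng.choice(BASES, size=config.genome_length))

    regular_index = GenomeIndex(genome)

    def spurious_regular_match(seq: str) -> bool:
        return bool(
            regular_index.search(seq)
            or regular_index.search(revcomp(seq))
        )

    reads, rows = [], []
    max_start = config.genome_length - config.read_length
    for i in range(config.n_reads):
        read_id = f"read{i:05d}"
        is_swinger = bool(rng.random() < config.swinger_fraction)
        minus = bool(rng.random() < config.minus_fraction)
        for _attempt in range(100):
            start = int(rng.integers(0, max_start + 1))
            sub = genome[start:start + config.read_length]
            seq = rule.apply(sub) if is_swinger else sub
            if minus:
                seq = revcomp(seq)
            if not (is_swinger and spurious_regular_match(seq)):
                break
        else:
            raise ConfigError(
                "could not place an unambiguous swinger read; the genome "
                "is too repetitive for the requested read length"
            )
        if is_swinger:
            truth_rule = conj.name if minus else rule.name
        else:
            truth_rule = "identity"
        n_err = rng.binomial(config.read_length, config.error_rate)
        seq_arr = np.array(list(seq))
        if n_err:
            pos = rng.choice(config.read_length, size=n_err, replace=False)
            for p in pos:
                choices = [b for b in "ACGT" if b != seq_arr[p]]
                seq_arr[p] = choices[int(rng.integers(0, 3))]
        seq = "".join(seq_arr)
        reads.append((read_id, seq))
        rows.append({
            "read_id": read_id, "rule": truth_rule,
            "strand": "-" if minus else "+",
            "start": start + 1, "end": start + config.read_length,
            "n_errors": int(n_err),
        })
    return SwingerReadSet(genome, tuple(reads), pd.DataFrame(rows), config)


# --------------------------------------------------------------------------
# Profile clusters


@dataclass(frozen=True)
class ProfileSet:
    """Cluster centers, labelled reference profiles, and a query sampler."""

    centers: pd.DataFrame
    references: tuple[StructureProfile, ...]
    seed: int
    within_sd: float

    def sample_queries(self, n_queries: int, *, seed: int | None = None,
                       within_sd: float | None = None
                       ) -> tuple[tuple[StructureProfile, ...], pd.DataFrame]:
        """Noisy clones of the cluster centers plus their truth labels."""
        rng = np.random.default_rng(self.seed + 1 if seed is None else seed)
        sd = self.within_sd if within_sd is None else within_sd
        names = list(self.centers["cluster"])
        queries, rows = [], []
        for i in range(n_queries):
            c = names[int(rng.integers(0, len(names)))]
            center = self.centers.loc[
                self.centers["cluster"] == c,
                ["loop", "eloop", "stem_gc", "loop_gc"],
            ].to_numpy()[0]
            vec = np.clip(center + rng.normal(0, sd, size=4), 0, 100)
            queries.append(StructureProfile(
                f"query{i:04d}", 100, *map(float, vec)
            ))
            rows.append({"label": f"query{i:04d}", "true_cluster": c})
        return tuple(queries), pd.DataFrame(rows)


def make_profile_set(*, seed: int = 0, n_clusters: int = 4,
                     members_per_cluster: int = 5, within_sd: float = 2.0,
                     cluster_names: Sequence[str] | None = None,
                     max_center_r: float = 0.5) -> ProfileSet:
    """Labelled reference profiles around well-separated cluster centers.

    Centers are drawn uniformly in descriptor space and re-drawn until all
    pairwise Pearson correlations between center 4-vectors stay below
    ``max_center_r`` — Pearson similarity is location/scale free, so
    separation must be in the *shape* of the vectors, not their mean.
    Members are centers plus N(0, within_sd) noise clipped to [0, 100].
    """
    if n_clusters < 1 or members_per_cluster < 1:
        raise ConfigError("need at least one cluster with one member")
    names = (list(cluster_names) if cluster_names
             else [f"S{i + 1}" for i in range(n_clusters)])
    if len(names) != n_clusters:
        raise ConfigError("cluster_names length must equal n_clusters")
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    attempts = 0
    # greedy placement can wedge on an unlucky early draw, so restart the
    # whole set every 500 failed candidates
    since_success = 0
    while len(centers) < n_clusters:
        cand = rng.uniform(5, 95, size=4)
        attempts += 1
        since_success += 1
        if attempts > 100_000:
            raise ConfigError(
                "could not place separated centers; lower n_clusters or "
                "raise max_center_r"
            )
        if since_success > 500:
            centers.clear()
            since_success = 0
            continue
        if np.ptp(cand) < 1e-6:
            continue
        if all(
            abs(np.corrcoef(cand, c)[0, 1]) < max_center_r for c in centers
        ):
            centers.append(cand)
            since_success = 0
    center_df = pd.DataFrame(
        centers, columns=["loop", "eloop", "stem_gc", "loop_gc"]
    )
    center_df.insert(0, "cluster", names)
    refs = []
    for c, center in zip(names, centers):
        for m in range(members_per_cluster):
            vec = np.clip(center + rng.normal(0, within_sd, size=4), 0, 100)
            refs.append(StructureProfile(
                f"{c}_ref{m}", 100, *map(float, vec), cluster=c
            ))
    return ProfileSet(center_df, tuple(refs), seed, within_sd)
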