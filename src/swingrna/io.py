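"""Readers/writers for the package's file formats, bundled fixtures, and
the end-to-end pipeline driver.

Formats: FASTA/FASTQ (via Biopython), Vienna-style dot-bracket records,
profile TSV (columns ``label  n  loop  eloop  stem_gc  loop_gc  cluster``),
hits TSV, and JSON report bundles. Every writer's output re-parses to an
equal in-memory value.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import classify_all, cluster_enrichment
from .errors import ConfigError, FixtureError, InputError
from .structures import SecondaryStructure, StructureProfile, parse_dot_bracket
from .swinger import SwingerDetector, summarize_hits
from .synthetic_data import SimulationConfig, simulate_swinger_reads

log = logging.getLogger("swingrna")

PROFILE_COLUMNS = ["label", "n", "loop", "eloop", "stem_gc", "loop_gc",
                   "cluster"]
HITS_COLUMNS = ["read_id", "rule", "strand", "start", "end", "coverage",
                "identity", "read_length"]

#: SHA-256 digests of the bundled fixture files; load_fixture verifies them.
FIXTURE_SHA256 = {
    "table1.tsv": "893df757b1588655175e25d3de967cdf5fd6f52aaf008dd2f04fe5983ef7add9",
    "table2.tsv": "8ca94c9b3a17f4f0ea817ae6536c92a447fc51b8ca3a63896fb8426417747aa8",
    "table4.tsv": "97df65542890f60d65c4e4d1888bbd57a5bee50ff29d1f56d9b7b383dd6e4996",
    "mimivirus_42nt.fasta": "a33fa8d8bd5e03d7546ec08caf3dea36d8a2776592af9c286433c5630b8876ad",
}


@dataclass(frozen=True)
class FixtureTable:
    """A bundled data table (or sequence) with its provenance note."""

    name: str
    table: pd.DataFrame | None
    sequence: str | None
    note: str


_FIXTURE_NOTES = {
    "table1": "descriptor profiles and cluster labels of 72 published "
              "hairpin RNAs (reference set for classification)",
    "table2": "descriptor profiles of 10 rod-shaped viroids",
    "table4": "per-rule swinger transcript abundances and mean read "
              "lengths from 454 and SOLiD sequencing",
    "mimivirus_42nt": "the 42-nt template-free RNA persisting in the "
                      "Mimivirus transcriptome",
}

_FIXTURE_FILES = {
    "table1": "table1.tsv",
    "table2": "table2.tsv",
    "table4": "table4.tsv",
    "mimivirus_42nt": "mimivirus_42nt.fasta",
}


def _fixture_bytes(filename: str) -> bytes:
    ref = importlib.resources.files("swingrna.fixtures") / filename
    return ref.read_bytes()


def load_fixture(name: str) -> FixtureTable:
    """Load and validate a bundled fixture by short name
    (``table1``, ``table2``, ``table4``, ``mimivirus_42nt``)."""
    if name not in _FIXTURE_FILES:
        raise FixtureError(
            f"unknown fixture {name!r}; known: {sorted(_FIXTURE_FILES)}"
        )
    filename = _FIXTURE_FILES[name]
    raw = _fixture_bytes(filename)
    expected = FIXTURE_SHA256.get(filename)
    digest = hashlib.sha256(raw).hexdigest()
    if expected is not None and digest != expected:
        raise FixtureError(
            f"checksum mismatch for {filename}: {digest} != {expected}"
        )
    note = _FIXTURE_NOTES[name]
    if filename.endswith(".fasta"):
        text = raw.decode()
        seq = "".join(
            line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith(">")
        )
        return FixtureTable(name, None, seq, note)
    import io as _io
    frame = pd.read_csv(_io.BytesIO(raw), sep="\t")
    _validate_fixture(name, frame)
    return FixtureTable(name, frame, None, note)


def _validate_fixture(name: str, frame: pd.DataFrame) -> None:
    if name in ("table1", "table2"):
        missing = set(PROFILE_COLUMNS) - set(frame.columns)
        if missing:
            raise FixtureError(f"{name} missing columns {sorted(missing)}")
        if frame["cluster"].isna().any():
            raise FixtureError(f"{name} has unlabeled rows")
    elif name == "table4":
        if list(frame.columns) != ["rule", "n_454", "mean_454", "n_solid",
                                   "mean_solid"]:
            raise FixtureError("table4 has unexpected columns")
        if len(frame) != 23:
            raise FixtureError(f"table4 must have 23 rows, got {len(frame)}")


# --------------------------------------------------------------------------
# Sequences


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path), "fasta",
    )


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(records: Iterable[tuple[str, str]], path) -> None:
    recs = []
    for name, seq in records:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def read_dot_bracket_file(path, *, min_hairpin: int = 3,
                          validate_hairpin: bool = True
                          ) -> list[tuple[str, SecondaryStructure]]:
    """Read a Vienna-style file of ``>name`` / sequence / bracket records."""
    text = Path(path).read_text()
    records: list[tuple[str, SecondaryStructure]] = []
    name, buf = "", []
    blocks: list[tuple[str, list[str]]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if buf:
                blocks.append((name, buf))
            name, buf = line[1:].split()[0] if len(line) > 1 else "", []
        else:
            buf.append(line)
    if buf:
        blocks.append((name, buf))
    for name, lines in blocks:
        if len(lines) != 2:
            raise InputError(
                f"record {name!r}: expected sequence + structure lines"
            )
        records.append((name, parse_dot_bracket(
            "\n".join(lines), min_hairpin=min_hairpin,
            validate_hairpin=validate_hairpin,
        )))
    return records


def write_dot_bracket_file(records: Iterable[tuple[str, SecondaryStructure]],
                           path) -> None:
    with open(path, "w") as fh:
        for name, st in records:
            fh.write(f">{name}\n{st.sequence}\n{st.to_dot_bracket()}\n")


# --------------------------------------------------------------------------
# Profile tables


def profiles_to_frame(profiles: Sequence[StructureProfile]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "label": p.label, "n": p.n, "loop": p.loop_pct,
            "eloop": p.eloop_pct, "stem_gc": p.stem_gc,
            "loop_gc": p.loop_gc, "cluster": p.cluster,
        }
        for p in profiles
    ], columns=PROFILE_COLUMNS)


def frame_to_profiles(frame: pd.DataFrame) -> list[StructureProfile]:
    missing = set(PROFILE_COLUMNS) - {"cluster"} - set(frame.columns)
    if missing:
        raise InputError(f"profile table missing columns {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        cluster = row.get("cluster", "none")
        if pd.isna(cluster) or cluster == "":
            cluster = "none"
        out.append(StructureProfile(
            str(row["label"]), int(row["n"]), float(row["loop"]),
            float(row["eloop"]), float(row["stem_gc"]),
            float(row["loop_gc"]), str(cluster),
        ))
    return out


def read_profiles(path) -> list[StructureProfile]:
    return frame_to_profiles(pd.read_csv(path, sep="\t"))


def write_profiles(profiles: Sequence[StructureProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False,
                                       float_format="%.6f")


def write_hits(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def read_hits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --------------------------------------------------------------------------
# Pipeline driver


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, outdir) -> dict:
    """Run one of the two end-to-end pipelines and write a report bundle.

    ``config['mode']`` selects ``"classify"`` (profiles -> comparisons ->
    cluster calls + enrichment) or ``"swinger"`` (simulate or load reads ->
    detect -> per-rule summary). Outputs are deterministic for a given
    config and seed: TSV tables, a JSON report with the package version,
    config hash and seed, and stage timings on stderr.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mode = config.get("mode")
    seed = int(config.get("seed", 0))
    report: dict = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": seed,
        "mode": mode,
    }
    t0 = time.time()
    if mode == "classify":
        queries = (fixture_profiles(config["queries"])
                   if str(config.get("queries", "")).startswith("table")
                   else read_profiles(config["queries"]))
        refs = (fixture_profiles(config["references"])
                if str(config.get("references", "")).startswith("table")
                else read_profiles(config["references"]))
        alpha = float(config.get("alpha", 0.05))
        assignments, matrix = classify_all(
            queries, refs, alpha=alpha,
            r_threshold=float(config.get("r_threshold", 0.95)),
            bh=config.get("bh", "global"),
        )
        enrich = cluster_enrichment(queries, refs, alpha=alpha)
        calls = pd.DataFrame([
            {
                "query": a.query_label, "assigned_cluster": a.assigned_cluster,
                "best_reference": a.best_reference_label, "best_r": a.best_r,
            }
            for a in assignments
        ])
        calls.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        matrix.to_csv(outdir / "comparisons.tsv", sep="\t", index=False)
        enrich.table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        report["n_queries"] = len(queries)
        report["n_references"] = len(refs)
        report["n_comparisons"] = int(len(matrix))
        report["non_comparable"] = list(map(list, enrich.non_comparable))
    elif mode == "swinger":
        if "reads" in config:
            genome = read_fasta(config["genome"])[0][1]
            reads = (read_fastq(config["reads"])
                     if str(config["reads"]).endswith(("fastq", "fq"))
                     else read_fasta(config["reads"]))
        else:
            sim = simulate_swinger_reads(SimulationConfig(
                seed=seed,
                planted_rule=config.get("planted_rule", "C->T->G->C"),
                n_reads=int(config.get("n_reads", 500)),
                read_length=int(config.get("read_length", 40)),
                error_rate=float(config.get("error_rate", 0.0)),
            ))
            genome, reads = sim.genome, list(sim.reads)
            sim.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        det = SwingerDetector(
            genome,
            coverage_min=float(config.get("min_coverage", 0.5)),
            identity_min=float(config.get("min_identity", 0.8)),
            seed_k=int(config.get("seed_k", 12)),
        )
        hits = det.detect_all(reads)
        summary = summarize_hits(hits)
        write_hits(hits, outdir / "hits.tsv")
        summary.to_csv(outdir / "rule_summary.tsv", sep="\t", index=False)
        report["n_reads"] = len(reads)
        report["n_rules_reported"] = int(len(summary))
        report["n_swinger_reads"] = int(
            (~hits["rule"].isin(["identity", "unmapped"])).sum()
        )
    else:
        raise ConfigError(f"unknown pipeline mode {mode!r}")
    report["elapsed_s"] = round(time.time() - t0, 3)
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    log.info("pipeline %s finished in %.2fs", mode, report["elapsed_s"])
    return report


def _fixture_profiles(fix: FixtureTable) -> list[StructureProfile]:
    return frame_to_profiles(fix.table)


def fixture_profiles(name: str) -> list[StructureProfile]:
    """Profiles of a bundled descriptor table (``table1`` or ``table2``)."""
    return _fixture_profiles(load_fixture(name))
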