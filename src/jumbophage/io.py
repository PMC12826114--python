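"""Domain records and readers/writers for every external format.

Conventions (documented and tested):

* gene tables are 1-based, inclusive on both ends (GFF-like);
* per-base coverage rows are 1-based positions; interval coverage rows follow
  the bedtools ``genomecov -bga`` dialect (0-based, half-open);
* FASTA sequences are upper-cased on input and ``U`` is mapped to ``T``;
* ``N`` never matches any base in any downstream comparison.

All writers emit a deterministic column order so that write→read round-trips
are exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A malformed input file; the message names the offending record."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass
class GenomeRecord:
    """A nucleotide contig/genome with provenance."""

    genome_id: str
    sequence: str
    sample_id: str | None = None
    country: str | None = None

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise FormatError("genome with empty identifier")
        if not self.sequence:
            raise FormatError(f"genome {self.genome_id!r} has empty sequence")

    def reverse_complement(self) -> str:
        return str(Seq(self.sequence).reverse_complement())


@dataclass
class GeneAnnotation:
    """One gene on a genome: coordinates (1-based inclusive), strand,
    protein product, free-text product name and database-hit labels."""

    genome_id: str
    gene_index: int
    start: int
    end: int
    strand: str
    protein: str
    product_text: str = ""
    hit_labels: frozenset[str] = frozenset()
    busco_hit: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.genome_id}:{self.gene_index}: unknown strand "
                f"{self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise FormatError(
                f"gene {self.genome_id}:{self.gene_index}: invalid "
                f"coordinates {self.start}..{self.end}")
        if self.gene_index < 1:
            raise FormatError(
                f"gene {self.genome_id}:{self.gene_index}: index must be >=1")
        self.hit_labels = frozenset(self.hit_labels)


@dataclass
class CoverageTrack:
    """Per-base read depth of one genome in one sample."""

    genome_id: str
    sample_id: str
    depth: np.ndarray  # int vector, one entry per genome position

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise FormatError("depth must be a 1-D vector")
        if (self.depth < 0).any():
            raise FormatError(
                f"coverage {self.genome_id}/{self.sample_id}: negative depth")


@dataclass
class HostPrediction:
    """Predicted host lineage (domain…genus) for a phage genome."""

    genome_id: str
    host_lineage: tuple[str, ...]
    confidence: float | None = None

    def __post_init__(self) -> None:
        self.host_lineage = tuple(self.host_lineage)
        if not self.host_lineage:
            raise FormatError(f"{self.genome_id}: empty host lineage")
        if self.host_lineage[0] not in ("Bacteria", "Archaea"):
            raise FormatError(
                f"{self.genome_id}: host domain must be Bacteria or Archaea, "
                f"got {self.host_lineage[0]!r}")

    @property
    def domain(self) -> str:
        return self.host_lineage[0]

    @property
    def phylum(self) -> str | None:
        return self.host_lineage[1] if len(self.host_lineage) > 1 else None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_VALID_NT = set("ACGTN")


def read_fasta(path) -> list[GenomeRecord]:
    """Read nucleotide FASTA into GenomeRecords (upper-cased, U→T)."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA entry with empty header")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        bad = set(seq) - _VALID_NT
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} has invalid characters "
                f"{sorted(bad)}")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate genome id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeRecord(genome_id=rec.id, sequence=seq))
    return records


def write_fasta(records, path, width: int = 80) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.genome_id, description="")
            for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_protein_fasta(path) -> dict[str, str]:
    """Protein FASTA → id→sequence map (order-preserving)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate protein id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_protein_fasta(proteins: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n{seq}\n")


# ---------------------------------------------------------------------------
# gene annotation table (TSV)
# ---------------------------------------------------------------------------

_ANNOT_COLUMNS = ["genome_id", "gene_index", "start", "end", "strand",
                  "protein", "product_text", "hit_labels", "busco_hit"]


def read_annotation_table(path) -> list[GeneAnnotation]:
    """Read the TSV gene table (header required, columns as documented)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_ANNOT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        labels = frozenset(
            s for s in str(row.hit_labels).split(",") if s and s != "none")
        try:
            genes.append(GeneAnnotation(
                genome_id=row.genome_id,
                gene_index=int(row.gene_index),
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                protein=row.protein,
                product_text=row.product_text,
                hit_labels=labels,
                busco_hit=str(row.busco_hit).lower() in ("true", "1", "yes"),
            ))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    _check_unique_gene_index(genes, path)
    return genes


def _check_unique_gene_index(genes, source) -> None:
    seen = set()
    for g in genes:
        key = (g.genome_id, g.gene_index)
        if key in seen:
            raise FormatError(f"{source}: duplicate gene index {key}")
        seen.add(key)


def write_annotation_table(genes, path) -> None:
    rows = [{
        "genome_id": g.genome_id,
        "gene_index": g.gene_index,
        "start": g.start,
        "end": g.end,
        "strand": g.strand,
        "protein": g.protein,
        "product_text": g.product_text,
        "hit_labels": ",".join(sorted(g.hit_labels)) or "none",
        "busco_hit": str(g.busco_hit).lower(),
    } for g in genes]
    pd.DataFrame(rows, columns=_ANNOT_COLUMNS).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# coverage (per-base or bedtools -bga interval dialect)
# ---------------------------------------------------------------------------

def read_coverage_table(path, genome_lengths: dict[str, int],
                        dialect: str = "auto") -> list[CoverageTrack]:
    """Read depth rows into dense per-base tracks.

    ``per_base`` rows: genome_id, sample_id, position (1-based), depth.
    ``interval`` rows: genome_id, sample_id, start, end, depth with 0-based
    half-open [start, end) coordinates (bedtools ``genomecov -bga``).
    ``auto`` picks by column count (4 → per_base, 5 → interval).
    Positions absent from the file are depth 0.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     keep_default_na=False)
    if df.empty:
        return []
    ncol = df.shape[1]
    if dialect == "auto":
        dialect = {4: "per_base", 5: "interval"}.get(ncol, "")
    if dialect not in ("per_base", "interval"):
        raise FormatError(f"{path}: cannot infer coverage dialect "
                          f"({ncol} columns)")
    tracks: dict[tuple[str, str], np.ndarray] = {}

    def vec(genome_id: str, sample_id: str) -> np.ndarray:
        key = (genome_id, sample_id)
        if key not in tracks:
            if genome_id not in genome_lengths:
                raise FormatError(f"{path}: unknown genome {genome_id!r}")
            tracks[key] = np.zeros(genome_lengths[genome_id], dtype=np.int64)
        return tracks[key]

    if dialect == "per_base":
        for g, s, pos, depth in df.itertuples(index=False):
            v = vec(str(g), str(s))
            pos, depth = int(pos), int(depth)
            if not 1 <= pos <= len(v):
                raise FormatError(
                    f"{path}: position {pos} outside genome {g} "
                    f"(length {len(v)})")
            v[pos - 1] = depth
    else:
        for g, s, start, end, depth in df.itertuples(index=False):
            v = vec(str(g), str(s))
            start, end, depth = int(start), int(end), int(depth)
            if not 0 <= start < end <= len(v):
                raise FormatError(
                    f"{path}: interval [{start},{end}) outside genome {g} "
                    f"(length {len(v)})")
            v[start:end] = depth
    return [CoverageTrack(g, s, v) for (g, s), v in sorted(tracks.items())]


def write_coverage_table(tracks, path, dialect: str = "interval") -> None:
    """Write tracks as run-length intervals (default) or per-base rows."""
    with open(path, "w") as fh:
        for t in tracks:
            if dialect == "per_base":
                for i, d in enumerate(t.depth):
                    fh.write(f"{t.genome_id}\t{t.sample_id}\t{i + 1}\t{d}\n")
                continue
            # run-length encode, emitting every run (bga-style, incl. zeros)
            d = t.depth
            boundaries = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(d)]])
            for s0, e0 in zip(starts, ends):
                fh.write(f"{t.genome_id}\t{t.sample_id}\t{s0}\t{e0}\t{d[s0]}\n")


# ---------------------------------------------------------------------------
# host predictions and lifestyle scores
# ---------------------------------------------------------------------------

def read_host_predictions(path) -> list[HostPrediction]:
    """TSV with columns genome_id, host_lineage (semicolon-joined), confidence."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"genome_id", "host_lineage"}
    if needed - set(df.columns):
        raise FormatError(f"{path}: missing columns "
                          f"{sorted(needed - set(df.columns))}")
    preds = []
    for row in df.itertuples(index=False):
        conf = getattr(row, "confidence", "")
        try:
            preds.append(HostPrediction(
                genome_id=row.genome_id,
                host_lineage=tuple(
                    t for t in row.host_lineage.split(";") if t),
                confidence=float(conf) if conf not in ("", None) else None,
            ))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return preds


def write_host_predictions(preds, path) -> None:
    rows = [{
        "genome_id": p.genome_id,
        "host_lineage": ";".join(p.host_lineage),
        "confidence": "" if p.confidence is None else p.confidence,
    } for p in preds]
    pd.DataFrame(rows, columns=["genome_id", "host_lineage", "confidence"]
                 ).to_csv(path, sep="\t", index=False)


def read_lifestyle_scores(path) -> dict[str, tuple[float, bool]]:
    """TSV genome_id, score, provirus_flag → {genome: (score, flag)}."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"genome_id", "score", "provirus_flag"}
    if needed - set(df.columns):
        raise FormatError(f"{path}: missing columns "
                          f"{sorted(needed - set(df.columns))}")
    return {row.genome_id: (float(row.score),
                            str(row.provirus_flag).lower() in
                            ("true", "1", "yes"))
            for row in df.itertuples(index=False)}


def write_lifestyle_scores(scores: dict[str, tuple[float, bool]], path) -> None:
    rows = [{"genome_id": g, "score": s, "provirus_flag": str(f).lower()}
            for g, (s, f) in scores.items()]
    pd.DataFrame(rows, columns=["genome_id", "score", "provirus_flag"]
                 ).to_csv(path, sep="\t", index=False)


def proteomes_from_annotations(genes) -> dict[str, dict[str, str]]:
    """Group gene proteins by genome: genome_id → {gene_key: protein}."""
    out: dict[str, dict[str, str]] = {}
    for g in genes:
        out.setdefault(g.genome_id, {})[f"{g.genome_id}|{g.gene_index}"] = \
            g.protein
    return out
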