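"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats owned by this module:

* BLAST tabular (outfmt 6, 12 columns:
  ``qseqid sseqid pident length mismatch gapopen qstart qend sstart send
  evalue bitscore``) — contig-vs-reference alignments.
* Pileup TSV (``ref  pos  depth  A  C  G  T``) — per-position base counts.
  Counts are assumed to be base-quality filtered upstream (Q>30); the
  pipeline trusts them as-is.
* Gene presence/absence CSV — genomes x gene families binary matrix with
  ``supergroup`` and optional ``lineage`` metadata columns.
* Contig-lengths TSV sidecar (BLAST tabular does not carry query length).
* QC report TSV — one row per genome, one column per quality criterion.
* FASTA via Biopython.

All readers validate and raise :class:`FormatError` on malformed input
rather than silently coercing. Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "AlignmentRecord",
    "PileupColumn",
    "GenePresenceMatrix",
    "read_blast_tabular",
    "read_contig_lengths",
    "write_contig_lengths",
    "read_pileup",
    "write_pileup",
    "read_presence_matrix",
    "write_presence_matrix",
    "read_fasta",
    "write_fasta",
    "write_report",
    "read_report",
    "load_config",
]

BASES = ("A", "C", "G", "T")


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment of a query (contig or gene) against a reference.

    ``aligned_length`` is the alignment length column of BLAST outfmt 6
    (includes gaps); ``query_start``/``query_end`` are 1-based inclusive
    coordinates on the query, in the orientation BLAST reported them.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    aligned_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.aligned_length < 0:
            raise ValueError("aligned_length must be >= 0")

    def query_interval(self) -> tuple[int, int]:
        """Query span as a sorted (start, end), 1-based inclusive."""
        a, b = self.query_start, self.query_end
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PileupColumn:
    """Base counts at one reference position (quality-filtered upstream)."""

    reference_id: str
    position: int  # 1-based
    counts: Mapping[str, int]
    depth: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position {self.position} must be >= 1")
        total = sum(self.counts.get(b, 0) for b in BASES)
        if total != self.depth:
            raise ValueError(
                f"{self.reference_id}:{self.position}: depth {self.depth} "
                f"!= sum of base counts {total}"
            )

    def primary_count(self) -> int:
        return max(self.counts.get(b, 0) for b in BASES)


@dataclass
class GenePresenceMatrix:
    """Binary genomes x gene-families matrix with supergroup/lineage labels.

    ``values`` is a pandas DataFrame indexed by genome id with one column per
    family id; entries are 0/1.
    """

    values: pd.DataFrame
    supergroup_of: dict[str, str] = field(default_factory=dict)
    lineage_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate genome ids: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise FormatError(f"duplicate family ids: {dupes}")
        arr = self.values.to_numpy()
        if arr.size and not ((arr == 0) | (arr == 1)).all():
            raise FormatError("presence matrix values must be 0 or 1")
        self.values = self.values.astype("int8")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def family_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genomes(self) -> int:
        return self.values.shape[0]

    @property
    def n_families(self) -> int:
        return self.values.shape[1]

    def presence_counts(self) -> pd.Series:
        """Number of genomes carrying each family."""
        return self.values.sum(axis=0)

    def supergroup(self, genome_id: str) -> str:
        try:
            return self.supergroup_of[genome_id]
        except KeyError:
            raise ValueError(f"genome {genome_id!r} has no supergroup label") from None

    def genomes_in_lineage(self, lineage: str) -> list[str]:
        return [g for g in self.genome_ids if self.lineage_of.get(g) == lineage]

    def restrict_genomes(self, genome_ids: Sequence[str]) -> "GenePresenceMatrix":
        return GenePresenceMatrix(
            self.values.loc[list(genome_ids)].copy(),
            {g: s for g, s in self.supergroup_of.items() if g in set(genome_ids)},
            {g: s for g, s in self.lineage_of.items() if g in set(genome_ids)},
        )

    def restrict_families(self, family_ids: Sequence[str]) -> "GenePresenceMatrix":
        return GenePresenceMatrix(
            self.values[list(family_ids)].copy(),
            dict(self.supergroup_of),
            dict(self.lineage_of),
        )

    def equals(self, other: "GenePresenceMatrix") -> bool:
        return (
            self.values.equals(other.values)
            and self.supergroup_of == other.supergroup_of
            and self.lineage_of == other.lineage_of
        )


# ---------------------------------------------------------------------------
# BLAST tabular


def read_blast_tabular(path: str | Path) -> list[AlignmentRecord]:
    """Parse a 12-column BLAST outfmt-6 file, preserving row order.

    Query lengths are NOT in this format; supply them via
    :func:`read_contig_lengths` or the contig FASTA.
    """
    records: list[AlignmentRecord] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                records.append(
                    AlignmentRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        aligned_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        query_start=int(fields[6]),
                        query_end=int(fields[7]),
                        subject_start=int(fields[8]),
                        subject_end=int(fields[9]),
                        e_value=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_blast_tabular(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.query_id,
                        r.subject_id,
                        f"{r.percent_identity:.2f}",
                        r.aligned_length,
                        r.mismatches,
                        r.gap_opens,
                        r.query_start,
                        r.query_end,
                        r.subject_start,
                        r.subject_end,
                        f"{r.e_value:.2e}",
                        f"{r.bit_score:.1f}",
                    )
                )
                + "\n"
            )


def read_contig_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV sidecar: contig id, length in bp."""
    lengths: dict[str, int] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            cid, raw = fields
            try:
                length = int(raw)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad length {raw!r}") from None
            if cid in lengths:
                raise FormatError(f"{path}:{lineno}: duplicate contig id {cid!r}")
            lengths[cid] = length
    return lengths


def write_contig_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for cid, length in lengths.items():
            fh.write(f"{cid}\t{length}\n")


# ---------------------------------------------------------------------------
# Pileup TSV

_PILEUP_HEADER = ["ref", "pos", "depth", "A", "C", "G", "T"]


def read_pileup(path: str | Path) -> list[PileupColumn]:
    path = Path(path)
    columns: list[PileupColumn] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PILEUP_HEADER:
            raise FormatError(
                f"{path}:1: expected header {_PILEUP_HEADER}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns")
            try:
                col = PileupColumn(
                    reference_id=fields[0],
                    position=int(fields[1]),
                    counts={b: int(v) for b, v in zip(BASES, fields[3:7])},
                    depth=int(fields[2]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            columns.append(col)
    return columns


def write_pileup(columns: Iterable[PileupColumn], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_PILEUP_HEADER) + "\n")
        for c in columns:
            counts = "\t".join(str(c.counts.get(b, 0)) for b in BASES)
            fh.write(f"{c.reference_id}\t{c.position}\t{c.depth}\t{counts}\n")


# ---------------------------------------------------------------------------
# Presence/absence CSV

_META_COLS = ("supergroup", "lineage")


def read_presence_matrix(path: str | Path) -> GenePresenceMatrix:
    """CSV with genome ids in the first column, optional ``supergroup`` and
    ``lineage`` metadata columns, then one binary column per gene family."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0, dtype=str)
    supergroup_of: dict[str, str] = {}
    lineage_of: dict[str, str] = {}
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate genome ids {dupes}")
    if "supergroup" in df.columns:
        supergroup_of = df["supergroup"].dropna().to_dict()
    if "lineage" in df.columns:
        lineage_of = df["lineage"].dropna().to_dict()
    fam_cols = [c for c in df.columns if c not in _META_COLS]
    fam = df[fam_cols]
    bad = ~fam.isin(["0", "1"])
    if bad.to_numpy().any():
        r, c = next(zip(*bad.to_numpy().nonzero()))
        raise FormatError(
            f"{path}: non-binary cell {fam.iat[r, c]!r} at genome "
            f"{fam.index[r]!r}, family {fam.columns[c]!r}"
        )
    return GenePresenceMatrix(fam.astype("int8"), supergroup_of, lineage_of)


def write_presence_matrix(matrix: GenePresenceMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    meta = pd.DataFrame(index=out.index)
    if matrix.supergroup_of:
        meta["supergroup"] = pd.Series(matrix.supergroup_of)
    if matrix.lineage_of:
        meta["lineage"] = pd.Series(matrix.lineage_of)
    pd.concat([meta, out], axis=1).to_csv(path, index_label="genome")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """id → uppercase sequence; tolerates wrapped lines and mixed case."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# QC report TSV

_REPORT_COLS = [
    "genome",
    "coverage",
    "core_fraction",
    "length",
    "polymorphic_rate",
    "dominance",
    "status",
    "reasons",
]


def write_report(verdicts: Iterable, path: str | Path) -> None:
    """One row per genome, one column per QC metric plus the overall verdict.

    ``verdicts`` are :class:`wolbmag.strainqc.QCVerdict` objects (duck-typed
    to avoid a circular import).
    """
    rows = []
    for v in verdicts:
        rows.append(
            {
                "genome": v.genome_id,
                "coverage": v.coverage,
                "core_fraction": v.core_fraction,
                "length": v.length,
                "polymorphic_rate": v.polymorphic_rate,
                "dominance": v.dominance,
                "status": v.status,
                "reasons": ",".join(v.reasons),
            }
        )
    pd.DataFrame(rows, columns=_REPORT_COLS).to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"reasons": str})
    missing = set(_REPORT_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing report columns {sorted(missing)}")
    df["reasons"] = df["reasons"].fillna("")
    return df


def load_config(path: str | Path) -> dict:
    """YAML key-value configuration file."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return data
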