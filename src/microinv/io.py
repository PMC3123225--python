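"""Readers/writers for the external formats the pipeline touches.

Coordinate convention: every interval held in memory is 0-based,
half-open ``[start, end)``.  Every interval written to a human-facing
table is 1-based, inclusive.  :func:`to_report_interval` and
:func:`from_report_interval` are the only two places the conversion
happens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

#: Characters accepted in alignment rows (upper case).
IUPAC_CHARS = set("ACGTUNRYSWKMBDHV-")


class FormatError(ValueError):
    """Unparseable or empty input file."""


class AlignmentShapeError(ValueError):
    """Rows of an alignment differ in length."""


class LabelError(ValueError):
    """Duplicate or unknown sequence labels."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


# ---------------------------------------------------------------------------
# coordinate conventions
# ---------------------------------------------------------------------------

def to_report_interval(interval: tuple[int, int]) -> tuple[int, int]:
    """0-based half-open ``[s, e)`` -> 1-based inclusive ``(s+1, e)``."""
    s, e = interval
    if e <= s:
        raise ValueError(f"empty interval {interval!r}")
    return s + 1, e


def from_report_interval(interval: tuple[int, int]) -> tuple[int, int]:
    """1-based inclusive ``(first, last)`` -> 0-based half-open ``[first-1, last)``."""
    first, last = interval
    if first < 1 or last < first:
        raise ValueError(f"invalid 1-based inclusive interval {interval!r}")
    return first - 1, last


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A gapped multiple sequence alignment for one locus.

    Rows are equal-length upper-case strings over the IUPAC alphabet
    plus ``-``; ``U`` is normalised to ``T`` on construction.
    """

    locus_id: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError(f"{self.locus_id}: alignment has no sequences")
        if len(self.taxa) != len(self.rows):
            raise AlignmentShapeError(
                f"{self.locus_id}: {len(self.taxa)} labels vs {len(self.rows)} rows")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise LabelError(f"{self.locus_id}: duplicate labels {dupes}")
        n = len(self.rows[0])
        if n < 1:
            raise AlignmentShapeError(f"{self.locus_id}: zero-length alignment")
        self.rows = [r.upper().replace("U", "T") for r in self.rows]
        for taxon, row in zip(self.taxa, self.rows):
            if len(row) != n:
                raise AlignmentShapeError(
                    f"{self.locus_id}: row '{taxon}' has length {len(row)}, expected {n}")
            bad = set(row) - IUPAC_CHARS
            if bad:
                raise FormatError(
                    f"{self.locus_id}: row '{taxon}' contains invalid characters {sorted(bad)}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise LabelError(f"{self.locus_id}: no taxon '{taxon}'") from None

    def drop_empty_columns(self) -> "Alignment":
        """Return a copy without all-gap columns (logged; indices shift)."""
        keep = [j for j in range(self.n_cols)
                if any(r[j] != "-" for r in self.rows)]
        if len(keep) < self.n_cols:
            logger.info("%s: dropped %d all-gap columns",
                        self.locus_id, self.n_cols - len(keep))
        rows = ["".join(r[j] for j in keep) for r in self.rows]
        return Alignment(self.locus_id, list(self.taxa), rows)


def read_alignment(path: str | Path, format: str = "fasta",
                   locus_id: str | None = None) -> Alignment:
    """Read a gapped FASTA alignment with >=2 records."""
    if format != "fasta":
        raise FormatError(f"unsupported alignment format: {format}")
    path = Path(path)
    taxa: list[str] = []
    rows: list[str] = []
    current: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                taxa.append(line[1:].split()[0])
                current = []
                rows.append(current)  # type: ignore[arg-type]
            else:
                if current is None:
                    raise FormatError(f"{path}: sequence data before first header")
                current.append(line.strip())
    if not taxa:
        raise FormatError(f"{path}: no FASTA records")
    if len(taxa) < 2:
        raise FormatError(f"{path}: an alignment needs >=2 records, got {len(taxa)}")
    seqs = ["".join(parts) for parts in rows]  # type: ignore[arg-type]
    return Alignment(locus_id or path.stem, taxa, seqs)


def write_alignment(aln: Alignment, path: str | Path, width: int = 70) -> None:
    """Write FASTA with sequence lines wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for taxon, row in zip(aln.taxa, aln.rows):
            fh.write(f">{taxon}\n")
            for i in range(0, len(row), width):
                fh.write(row[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class Phylo:
    """A rooted phylogeny with branch lengths in million years (MY).

    Wraps a :class:`dendropy.Tree`; multifurcations are allowed.
    """

    tree: dendropy.Tree

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def treelength(self) -> float:
        """Sum of all branch lengths, MY."""
        total = 0.0
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise ValidationError("tree has branches without lengths")
            total += edge.length
        return total

    @property
    def terminal_fraction(self) -> float:
        """Fraction of treelength made up of terminal (leaf) branches."""
        term = sum(lf.edge.length or 0.0 for lf in self.tree.leaf_node_iter())
        total = self.treelength
        if total <= 0:
            raise ValidationError("treelength must be > 0")
        return term / total

    def require_positive_treelength(self) -> None:
        if self.treelength <= 0:
            raise ValidationError("treelength must be > 0 for rate/simulation work")


def read_tree(path: str | Path, require_branch_lengths: bool = True) -> Phylo:
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    if require_branch_lengths:
        missing = [e for e in tree.preorder_edge_iter()
                   if e.head_node is not tree.seed_node and e.length is None]
        if missing:
            raise ValidationError(
                f"{path}: {len(missing)} branches lack lengths; "
                "lengths in MY are required (no silent zero)")
    return Phylo(tree)


def parse_tree(newick: str, require_branch_lengths: bool = True) -> Phylo:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    if require_branch_lengths:
        missing = [e for e in tree.preorder_edge_iter()
                   if e.head_node is not tree.seed_node and e.length is None]
        if missing:
            raise ValidationError("newick string has branches without lengths")
    return Phylo(tree)


def write_tree(phylo: Phylo, path: str | Path) -> None:
    phylo.tree.write(path=str(path), schema="newick",
                     suppress_rooting=True, unquoted_underscores=True)


# ---------------------------------------------------------------------------
# locus tables
# ---------------------------------------------------------------------------

@dataclass
class LocusRecord:
    """One row of the per-locus summary table.

    ``mean_noncoding_length`` is in bp, ``treelength`` in MY; together
    they set the exposure (bp/1e6 * MY) against which the inversion
    count is a Poisson draw under the homogeneous-rate model.
    """

    locus_id: str
    mean_noncoding_length: float
    treelength: float
    inversion_count: int
    chromosome: str | None = None

    def __post_init__(self) -> None:
        if self.mean_noncoding_length <= 0:
            raise ValidationError(
                f"{self.locus_id}: mean_noncoding_length must be > 0")
        if self.treelength <= 0:
            raise ValidationError(f"{self.locus_id}: treelength must be > 0")
        if self.inversion_count < 0 or self.inversion_count != int(self.inversion_count):
            raise ValidationError(
                f"{self.locus_id}: inversion_count must be a non-negative integer")
        self.inversion_count = int(self.inversion_count)


REQUIRED_LOCUS_COLUMNS = ("locus", "mean_noncoding_length_bp",
                          "treelength_my", "inversion_count")


def read_locus_table(path: str | Path) -> list[LocusRecord]:
    """Read a TSV with the per-locus (length, treelength, count) schema."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_LOCUS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(LocusRecord(
                locus_id=str(row["locus"]),
                mean_noncoding_length=float(row["mean_noncoding_length_bp"]),
                treelength=float(row["treelength_my"]),
                inversion_count=int(row["inversion_count"]),
                chromosome=(str(row["chromosome"])
                            if "chromosome" in df.columns and pd.notna(row["chromosome"])
                            else None),
            ))
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: row {idx} ({row.get('locus')}): {exc}") from exc
    return records


def write_locus_table(records: Sequence[LocusRecord], path: str | Path) -> None:
    df = pd.DataFrame({
        "locus": [r.locus_id for r in records],
        "chromosome": [r.chromosome or "" for r in records],
        "mean_noncoding_length_bp": [r.mean_noncoding_length for r in records],
        "treelength_my": [r.treelength for r in records],
        "inversion_count": [r.inversion_count for r in records],
    })
    df.to_csv(path, sep="\t", index=False)


def packaged_locus_table() -> list[LocusRecord]:
    """The avian 17-locus summary table shipped with the package."""
    with resources.as_file(resources.files("microinv.data") / "avian_loci.tsv") as p:
        return read_locus_table(p)


def packaged_locus_frame() -> pd.DataFrame:
    with resources.as_file(resources.files("microinv.data") / "avian_loci.tsv") as p:
        return pd.read_csv(p, sep="\t")


# ---------------------------------------------------------------------------
# hit / call tables
# ---------------------------------------------------------------------------

HIT_COLUMNS = ["query", "subject", "q_start", "q_end", "s_start", "s_end",
               "score", "identity", "msa_first", "msa_last", "overlap_mark"]


def write_hit_table(hits: Iterable, path: str | Path) -> None:
    """Write scan hits; all intervals 1-based inclusive."""
    rows = []
    for h in hits:
        qf, ql = to_report_interval(h.query_interval)
        sf, sl = to_report_interval(h.subject_interval)
        mf, ml = to_report_interval(h.msa_interval)
        rows.append([h.query_taxon, h.subject_taxon, qf, ql, sf, sl,
                     round(h.score, 3), round(h.identity, 4), mf, ml,
                     "" if h.overlap_mark is None else h.overlap_mark])
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


CALL_COLUMNS = ["locus", "msa_first", "msa_last", "carriers", "length_bp",
                "delta", "status", "overlap_group", "palindrome_flag"]


def write_call_table(calls: Iterable, path: str | Path) -> None:
    rows = []
    for c in calls:
        mf, ml = to_report_interval(c.msa_interval)
        rows.append([c.locus_id, mf, ml, ",".join(sorted(c.carrier_taxa)),
                     min(c.carrier_lengths.values()),
                     round(c.validation_delta, 4), c.status,
                     "" if c.overlap_group is None else c.overlap_group,
                     int(c.palindrome_flag)])
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_call_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing call-table columns {missing}")
    return df


# ---------------------------------------------------------------------------
# character matrices
# ---------------------------------------------------------------------------

def write_character_matrix_tsv(matrix, path: str | Path) -> None:
    """TSV: one row per taxon, one column per character, states 0/1/?."""
    df = pd.DataFrame(
        {cid: [matrix.state_symbol(t, i) for t in matrix.taxa]
         for i, cid in enumerate(matrix.character_ids)},
        index=pd.Index(matrix.taxa, name="taxon"))
    df.to_csv(path, sep="\t")


def write_character_matrix_nexus(matrix, path: str | Path) -> None:
    """NEXUS standard-datatype block (SYMBOLS 01, MISSING ?)."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={len(matrix.taxa)} "
                 f"NCHAR={len(matrix.character_ids)};\n")
        fh.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
        fh.write("    MATRIX\n")
        pad = max((len(t) for t in matrix.taxa), default=0) + 2
        for t in matrix.taxa:
            states = "".join(matrix.state_symbol(t, i)
                             for i in range(len(matrix.character_ids)))
            fh.write(f"    {t:<{pad}}{states}\n")
        fh.write("    ;\nEND;\n")
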