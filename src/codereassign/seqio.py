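"""Input/output and core data model for coding alignments and trees.

The analyses in this package operate on in-frame codon alignments of
nuclear protein-coding genes, a rooted reference phylogeny with branch
lengths, and small tabular side inputs (reference-taxon lists, observed
3' terminal stop codons).  This module reads the standard external
formats (FASTA, NEXUS, Newick, TSV) into validated containers and writes
results back out deterministically.

Conventions
-----------
* Codon columns are 0-based internally and 1-based in every report.
* ``U`` is normalised to ``T`` at parse time (EST/mRNA inputs).
* A fully gapped codon cell is exactly ``"---"``; cells containing any
  character outside ``ACGT`` (gaps, ``N``, partial gaps) are ignored by
  all counting operations downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "GeneticCodeTable",
    "STANDARD_CODE",
    "TAR_GLN_CODE",
    "CodingAlignment",
    "NucleotideAlignment",
    "PhyloTree",
    "read_alignment",
    "read_tree",
    "read_terminal_stops",
    "read_taxon_list",
    "write_table",
    "AlignmentFormatError",
    "FrameError",
    "TreeFormatError",
]

_VALID_CHARS = set("ACGTN-")
_BASES = ("A", "C", "G", "T")


class AlignmentFormatError(ValueError):
    """Raised for malformed alignment input (duplicate labels, bad symbols...)."""


class FrameError(AlignmentFormatError):
    """Raised when a sequence length is incompatible with the reading frame."""


class TreeFormatError(ValueError):
    """Raised for malformed or invalid Newick input."""


# ---------------------------------------------------------------------------
# Genetic code tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticCodeTable:
    """A complete 64-codon translation table.

    ``mapping`` sends every codon over {A,C,G,T} to a one-letter amino
    acid or ``"*"`` for a stop.  Two instances are provided:
    :data:`STANDARD_CODE` and :data:`TAR_GLN_CODE`, the non-canonical
    nuclear code of several ulvophycean green algae in which TAG and TAA
    are read as glutamine and only TGA terminates translation.
    """

    name: str
    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        codons = {a + b + c for a in _BASES for b in _BASES for c in _BASES}
        if set(self.mapping) != codons:
            raise ValueError(f"genetic code {self.name!r} must cover all 64 codons")

    def translate(self, codon: str) -> str:
        """Translate one codon; returns ``"X"`` for ambiguous/gapped codons."""
        return self.mapping.get(codon, "X")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.mapping.items() if aa == "*")


def _standard_mapping() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


STANDARD_CODE = GeneticCodeTable("standard", _standard_mapping())

_tar_gln = _standard_mapping()
_tar_gln["TAG"] = "Q"
_tar_gln["TAA"] = "Q"
TAR_GLN_CODE = GeneticCodeTable("TAR_GLN", _tar_gln)


# ---------------------------------------------------------------------------
# Alignment containers
# ---------------------------------------------------------------------------


@dataclass
class CodingAlignment:
    """An in-frame codon matrix: rows are taxa, columns are codon positions.

    Parameters
    ----------
    taxa
        Unique taxon labels, one per row.
    codons
        2-D array (or nested sequence) of 3-character strings over
        ``{A,C,G,T,N,-}``; a fully gapped cell is exactly ``"---"``.
    gene_id
        Identifier of the gene the alignment covers.
    terminal_stop
        Optional per-taxon codon observed immediately after the final
        sense codon (the putative stop), when the 3' end was sequenced.
    """

    taxa: list[str]
    codons: np.ndarray
    gene_id: str = "gene"
    terminal_stop: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype="U3")
        if self.codons.ndim != 2:
            raise AlignmentFormatError("codon matrix must be 2-D")
        if len(self.taxa) != self.codons.shape[0]:
            raise AlignmentFormatError("row count does not match taxon count")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentFormatError(f"duplicate taxon labels in {self.gene_id!r}")
        if self.codons.shape[1] < 1:
            raise AlignmentFormatError("alignment must have at least one codon column")
        flat = self.codons.ravel()
        lengths = np.char.str_len(flat)
        if not np.all(lengths == 3):
            raise AlignmentFormatError("every codon cell must have length 3")
        bad = {ch for cell in flat for ch in cell} - _VALID_CHARS
        if bad:
            raise AlignmentFormatError(f"invalid characters in alignment: {sorted(bad)}")
        for taxon, stop in self.terminal_stop.items():
            if taxon not in self.taxa:
                raise AlignmentFormatError(f"terminal stop for unknown taxon {taxon!r}")
            if len(stop) != 3:
                raise AlignmentFormatError(f"terminal stop {stop!r} is not a codon")

    @property
    def n_taxa(self) -> int:
        return self.codons.shape[0]

    @property
    def n_columns(self) -> int:
        return self.codons.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        """Codon row for one taxon."""
        try:
            i = self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment {self.gene_id!r}") from None
        return self.codons[i]

    def to_nucleotides(self) -> "NucleotideAlignment":
        """Flatten codon columns into a per-site nucleotide alignment."""
        n, m = self.codons.shape
        mat = self.codons.view("U1").reshape(n, 3 * m)
        return NucleotideAlignment(list(self.taxa), mat.copy())

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for taxon in self.taxa:
                fh.write(f">{taxon}\n{''.join(self.row(taxon))}\n")


@dataclass
class NucleotideAlignment:
    """A plain per-site nucleotide matrix (taxa x sites)."""

    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="U1")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise AlignmentFormatError("matrix shape does not match taxa")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class PhyloTree:
    """A rooted phylogeny with branch lengths, backed by dendropy.

    Tip labels must be unique; branch lengths must be nonnegative
    (``None`` is treated as 0).  The dendropy tree is exposed as
    ``.dtree`` for traversal; helper accessors cover the common needs of
    the analysis modules.
    """

    def __init__(self, dtree: dendropy.Tree):
        self.dtree = dtree
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise TreeFormatError("duplicate tip labels in tree")
        for edge in dtree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeFormatError(f"negative branch length {edge.length}")

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.dtree.leaf_nodes())

    @property
    def root(self) -> dendropy.Node:
        return self.dtree.seed_node

    def branch_length(self, node: dendropy.Node) -> float:
        return float(node.edge.length or 0.0)

    def height(self) -> float:
        """Maximum root-to-tip path length."""
        best = 0.0
        for leaf in self.dtree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += self.branch_length(node)
                node = node.parent_node
            best = max(best, d)
        return best

    def clade_tips(self, node: dendropy.Node) -> frozenset[str]:
        """Tip labels descending from ``node`` (the clade its stem subtends)."""
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def clone(self) -> "PhyloTree":
        return PhyloTree(self.dtree.clone(depth=1))

    def prune_to(self, keep: Iterable[str]) -> "PhyloTree":
        """A copy restricted to ``keep`` tips (unifurcations suppressed)."""
        keep = set(keep)
        t = self.dtree.clone(depth=1)
        t.retain_taxa_with_labels(sorted(keep))
        return PhyloTree(t)

    def write(self, path: str | Path) -> None:
        self.dtree.write(path=str(path), schema="newick", suppress_rooting=True)

    def as_newick(self) -> str:
        return self.dtree.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeFormatError(f"invalid Newick: {exc}") from exc
        return cls(dtree)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _records_from_path(path: str | Path, fmt: str) -> list[tuple[str, str]]:
    fmt = fmt.lower()
    if fmt not in {"fasta", "nexus"}:
        raise ValueError(f"unsupported alignment format {fmt!r}")
    records = []
    with open(path) as fh:
        if fmt == "fasta":
            for rec in SeqIO.parse(fh, "fasta"):
                records.append((rec.id, str(rec.seq)))
        else:
            text = fh.read()
            records = _parse_simple_nexus(text)
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")
    return records


def _parse_simple_nexus(text: str) -> list[tuple[str, str]]:
    """Parse the simple NEXUS DATA/MATRIX dialect (non-interleaved or interleaved)."""
    lower = text.lower()
    start = lower.find("matrix")
    if start == -1:
        raise AlignmentFormatError("NEXUS file has no MATRIX block")
    end = lower.find(";", start)
    if end == -1:
        raise AlignmentFormatError("NEXUS MATRIX block not terminated by ';'")
    body = text[start + len("matrix"): end]
    seqs: dict[str, str] = {}
    order: list[str] = []
    for line in body.splitlines():
        line = line.strip()
        if not line or line.startswith("["):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise AlignmentFormatError(f"unparseable NEXUS matrix line: {line!r}")
        name = parts[0].strip("'\"")
        seq = parts[1].replace(" ", "")
        if name in seqs:
            seqs[name] += seq
        else:
            seqs[name] = seq
            order.append(name)
    return [(name, seqs[name]) for name in order]


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    frame_offset: int = 0,
    gene_id: str | None = None,
) -> CodingAlignment:
    """Read an in-frame coding alignment from FASTA or NEXUS.

    ``frame_offset`` columns are discarded from the 5' end before codon
    splitting; the remaining length must be divisible by 3.  ``U`` is
    normalised to ``T`` and all symbols upper-cased.
    """
    if frame_offset < 0:
        raise ValueError("frame_offset must be >= 0")
    records = _records_from_path(path, format)
    names = [n for n, _ in records]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise AlignmentFormatError(f"duplicate sequence labels: {sorted(dupes)}")

    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise AlignmentFormatError("aligned sequences differ in length")
    (length,) = lengths
    if length <= frame_offset:
        raise FrameError("frame_offset leaves no sequence")
    if (length - frame_offset) % 3 != 0:
        offender = names[0]
        raise FrameError(
            f"alignment length {length} minus frame offset {frame_offset} is not a "
            f"multiple of 3 (first record: {offender!r})"
        )

    rows = []
    for name, seq in records:
        seq = seq.upper().replace("U", "T")[frame_offset:]
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise AlignmentFormatError(
                f"record {name!r} contains invalid characters {sorted(bad)}"
            )
        rows.append([seq[i: i + 3] for i in range(0, len(seq), 3)])
    gid = gene_id if gene_id is not None else Path(path).stem
    return CodingAlignment(taxa=names, codons=np.array(rows, dtype="U3"), gene_id=gid)


def read_tree(path: str | Path) -> PhyloTree:
    """Read a rooted Newick tree; rejects negative branch lengths."""
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def read_terminal_stops(path: str | Path) -> dict[str, list[str]]:
    """Read a TSV of observed 3' terminal codons: columns taxon, stop_codon.

    A taxon may appear on several rows (one per gene); values are pooled.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"taxon", "stop_codon"} <= set(df.columns):
        raise AlignmentFormatError("terminal stop table needs columns taxon, stop_codon")
    out: dict[str, list[str]] = {}
    for taxon, stop in zip(df["taxon"], df["stop_codon"]):
        out.setdefault(taxon, []).append(stop.upper().replace("U", "T"))
    return out


def read_taxon_list(path: str | Path) -> list[str]:
    """Read one taxon label per line, ignoring blanks and '#' comments."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_table(
    records: Sequence[Mapping[str, object]] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write tabular results as TSV with a deterministic column order.

    ``columns`` pins the order explicitly; otherwise the order of first
    appearance across records is used.  An empty record list still
    produces a header-only file when ``columns`` is given.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        if columns is None:
            columns = []
            for rec in records:
                for key in rec:
                    if key not in columns:
                        columns.append(key)
        df = pd.DataFrame(list(records), columns=list(columns) if columns else None)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV produced by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
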