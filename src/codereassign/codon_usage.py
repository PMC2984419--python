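"""Glutamine codon usage profiles (CAG/CAA/TAG/TAA) per taxon.

CAA and CAG encode glutamine under both the standard and the TAR->Gln
code, so they are counted across the whole coding region for every
taxon.  TAG and TAA encode glutamine only under the reassigned code;
for taxa with a ``TAR_GLN`` verdict they are counted anywhere in the
region (internally they cannot terminate translation under that code),
while for standard-code taxa they are never glutamine and their counts
are zero by construction.  Frequencies live on the 3-simplex and feed
the Brownian-motion ancestral reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .code_inference import CodeAssignment, Verdict
from .seqio import CodingAlignment

__all__ = ["GLN_CODONS", "GlnUsageProfile", "gln_usage", "usage_ordering", "gc3_fraction"]

GLN_CODONS = ("CAG", "CAA", "TAG", "TAA")
_BASES = set("ACGT")


@dataclass
class GlnUsageProfile:
    """Counts and relative frequencies of the four glutamine codons."""

    taxon: str
    counts: dict[str, int]
    per_gene: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def missing(self) -> bool:
        """True when no glutamine codon was observed (frequencies undefined)."""
        return self.total == 0

    @property
    def freqs(self) -> np.ndarray:
        """Frequencies in GLN_CODONS order; NaN when no codon was observed."""
        if self.missing:
            return np.full(4, np.nan)
        return np.array([self.counts[c] for c in GLN_CODONS], dtype=float) / self.total


def gln_usage(
    alignments: Sequence[CodingAlignment],
    taxon: str,
    assignment: CodeAssignment,
    restrict_to_columns: Mapping[str, Sequence[int]] | None = None,
) -> GlnUsageProfile:
    """Pool glutamine codon counts for ``taxon`` across genes.

    ``restrict_to_columns`` optionally limits counting to given 0-based
    codon columns per gene_id (e.g. the conserved Gln columns); by
    default the whole coding region is scanned.  TAR codons count only
    when the taxon's verdict is ``TAR_GLN``.
    """
    count_tar = assignment.verdict == Verdict.TAR_GLN
    counts = {c: 0 for c in GLN_CODONS}
    per_gene: dict[str, dict[str, int]] = {}
    for aln in alignments:
        if taxon not in aln.taxa:
            continue
        row = aln.row(taxon)
        if restrict_to_columns is not None:
            cols = restrict_to_columns.get(aln.gene_id, ())
            row = row[list(cols)]
        gene_counts = {c: 0 for c in GLN_CODONS}
        for codon in row:
            codon = str(codon)
            if set(codon) - _BASES:
                continue
            if codon in ("CAG", "CAA") or (count_tar and codon in ("TAG", "TAA")):
                gene_counts[codon] += 1
        per_gene[aln.gene_id] = gene_counts
        for c in GLN_CODONS:
            counts[c] += gene_counts[c]
    return GlnUsageProfile(taxon, counts, per_gene)


def usage_ordering(
    profiles: Iterable[GlnUsageProfile],
) -> list[tuple[float, list[str]]]:
    """Rank the four glutamine codons by mean frequency across profiles.

    Profiles with no observed glutamine codons are excluded.  Returns a
    descending list of (mean frequency, codons at that frequency); ties
    are grouped, so a 4-way tie comes back as a single entry.
    """
    freqs = [p.freqs for p in profiles if not p.missing]
    if not freqs:
        raise ValueError("usage_ordering needs at least one non-empty profile")
    mean = np.mean(freqs, axis=0)
    order: dict[float, list[str]] = {}
    for codon, f in zip(GLN_CODONS, mean):
        order.setdefault(round(float(f), 12), []).append(codon)
    return sorted(order.items(), key=lambda kv: -kv[0])


def gc3_fraction(aln: CodingAlignment, taxon: str) -> float:
    """G+C share at resolved third codon positions (descriptive only)."""
    row = aln.row(taxon)
    thirds = [c[2] for c in row if not (set(str(c)) - _BASES)]
    if not thirds:
        return float("nan")
    gc = sum(1 for b in thirds if b in "GC")
    return gc / len(thirds)
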