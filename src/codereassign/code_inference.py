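"""Screening coding alignments for TAR->Gln stop-codon reassignment.

The screening logic classifies each taxon's nuclear genetic code from
two lines of evidence:

1. **TAR codons at conserved glutamine positions.**  Columns where a
   panel of reference taxa (asserted to use the standard code) encode
   glutamine with high support are identified; a query taxon showing
   TAG/TAA at several such columns is inferred to read TAR as glutamine,
   since under the standard code those codons would terminate
   translation mid-protein.
2. **Terminal stop-codon usage.**  Taxa with the reassigned code can
   only terminate with TGA; observing all three stop codons at the 3'
   ends of genes corroborates the standard code, while exclusive TGA
   usage corroborates reassignment.

Verdicts are ``STANDARD``, ``TAR_GLN`` or ``AMBIGUOUS``; evidence is
pooled additively across genes with per-gene detail retained for audit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .seqio import CodingAlignment, STANDARD_CODE

__all__ = [
    "Verdict",
    "ConservedGlnColumn",
    "ScreenResult",
    "CodeAssignment",
    "find_conserved_gln_columns",
    "screen_taxon",
    "classify_code",
    "infer_codes",
    "InferenceResult",
    "codon_transition_distance",
    "Substitution",
]

_BASES = set("ACGT")
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
TAR_CODONS = ("TAG", "TAA")
CAR_CODONS = ("CAG", "CAA")
STOP_CODONS = ("TAA", "TAG", "TGA")


class Verdict(str, Enum):
    STANDARD = "STANDARD"
    TAR_GLN = "TAR_GLN"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class ConservedGlnColumn:
    """A codon column conserved for glutamine across the reference panel.

    ``column_index`` is 0-based; ``support`` is the fraction of
    informative references translating to Q under the standard code;
    ``n_ref_observed`` counts references with a fully resolved (ACGT-only)
    codon at the column.
    """

    column_index: int
    support: float
    n_ref_observed: int


@dataclass
class ScreenResult:
    """Per-gene TAR/CAR counts for one taxon at conserved Gln columns."""

    taxon: str
    gene_id: str
    n_tar: int
    n_car: int
    detail: list[tuple[int, str, str]] = field(default_factory=list)
    # detail rows: (0-based column, codon, category in {TAR, CAR, other, uninformative})


@dataclass
class CodeAssignment:
    """Pooled verdict for one taxon with its supporting evidence."""

    taxon: str
    verdict: Verdict
    n_tar_at_gln: int
    n_car_at_gln: int
    stop_usage: Counter
    genes_supporting: list[str]
    warnings: list[str] = field(default_factory=list)


def _is_resolved(codon: str) -> bool:
    return len(codon) == 3 and set(codon) <= _BASES


def find_conserved_gln_columns(
    aln: CodingAlignment,
    reference_taxa: Iterable[str],
    support_threshold: float = 0.9,
    min_ref: int = 3,
) -> list[ConservedGlnColumn]:
    """Find codon columns conserved for glutamine among reference taxa.

    A column qualifies when at least ``min_ref`` references carry a
    resolved codon there and the fraction of those translating to Q
    under the standard code is >= ``support_threshold``.  Columns are
    returned sorted by index.
    """
    refs = [t for t in reference_taxa if t in aln.taxa]
    missing = set(reference_taxa) - set(refs)
    if not refs:
        raise ValueError(
            f"none of the reference taxa are present in alignment {aln.gene_id!r}"
        )
    if missing:
        # partial panels are usable; the min_ref floor still applies
        pass
    rows = [aln.row(t) for t in refs]
    out = []
    for j in range(aln.n_columns):
        n_obs = 0
        n_q = 0
        for row in rows:
            codon = row[j]
            if _is_resolved(codon):
                n_obs += 1
                if STANDARD_CODE.translate(codon) == "Q":
                    n_q += 1
        if n_obs >= min_ref and n_q / n_obs >= support_threshold:
            out.append(ConservedGlnColumn(j, n_q / n_obs, n_obs))
    return out


def screen_taxon(
    aln: CodingAlignment,
    taxon: str,
    gln_columns: Sequence[ConservedGlnColumn],
) -> ScreenResult:
    """Count TAR vs CAR codons of ``taxon`` at the conserved Gln columns.

    Codons containing gaps or ambiguity symbols contribute to neither
    count.  An empty column list yields zero counts.
    """
    row = aln.row(taxon)
    n_tar = n_car = 0
    detail = []
    for col in gln_columns:
        codon = str(row[col.column_index])
        if not _is_resolved(codon):
            category = "uninformative"
        elif codon in TAR_CODONS:
            n_tar += 1
            category = "TAR"
        elif codon in CAR_CODONS:
            n_car += 1
            category = "CAR"
        else:
            category = "other"
        detail.append((col.column_index, codon, category))
    return ScreenResult(taxon, aln.gene_id, n_tar, n_car, detail)


def classify_code(
    screens: Sequence[ScreenResult],
    terminal_stops: Iterable[str] = (),
    min_tar_evidence: int = 2,
    require_terminal_consistency: bool = True,
) -> CodeAssignment:
    """Pool per-gene screens for one taxon into a code verdict.

    ``TAR_GLN`` requires at least ``min_tar_evidence`` TAR observations at
    conserved Gln columns and, when ``require_terminal_consistency`` and
    terminal stops were observed, that all of them are TGA.  ``STANDARD``
    requires zero TAR observations.  Conflicting evidence (TAR both at
    Gln columns and as a terminal stop) yields ``AMBIGUOUS`` with a
    warning, as does sub-threshold TAR evidence.
    """
    if not screens:
        raise ValueError("classify_code needs at least one screened gene")
    taxa = {s.taxon for s in screens}
    if len(taxa) != 1:
        raise ValueError(f"screens mix multiple taxa: {sorted(taxa)}")
    (taxon,) = taxa
    n_tar = sum(s.n_tar for s in screens)
    n_car = sum(s.n_car for s in screens)
    stops = Counter(str(s).upper() for s in terminal_stops)
    genes = sorted({s.gene_id for s in screens if s.n_tar or s.n_car})
    warnings: list[str] = []

    tar_as_stop = any(s in TAR_CODONS for s in stops)
    only_tga = set(stops) <= {"TGA"}

    if n_tar >= min_tar_evidence and tar_as_stop:
        warnings.append(
            "internal conflict: TAR observed both at conserved Gln columns and as a "
            "terminal stop"
        )
        verdict = Verdict.AMBIGUOUS
    elif n_tar >= min_tar_evidence and (only_tga or not require_terminal_consistency):
        verdict = Verdict.TAR_GLN
    elif n_tar == 0:
        verdict = Verdict.STANDARD
    else:
        if 0 < n_tar < min_tar_evidence:
            warnings.append(
                f"{n_tar} TAR observation(s) below evidence threshold {min_tar_evidence}"
            )
        verdict = Verdict.AMBIGUOUS
    return CodeAssignment(taxon, verdict, n_tar, n_car, stops, genes, warnings)


@dataclass
class InferenceResult:
    """Pooled multi-gene screening outcome for a whole taxon panel."""

    assignments: dict[str, CodeAssignment]
    gln_columns: dict[str, list[ConservedGlnColumn]]  # gene_id -> columns
    screens: dict[str, list[ScreenResult]]  # taxon -> per-gene screens


def infer_codes(
    alignments: Sequence[CodingAlignment],
    reference_taxa: Iterable[str],
    terminal_stops: Mapping[str, Sequence[str]] | None = None,
    support_threshold: float = 0.9,
    min_ref: int = 3,
    min_tar_evidence: int = 2,
    require_terminal_consistency: bool = True,
) -> InferenceResult:
    """Run the full screen over a set of gene alignments.

    Conserved Gln columns are located per gene from the reference panel;
    every taxon (references included) is screened at those columns and
    the evidence pooled additively across genes.  Terminal stop codons
    are gathered from the alignments' ``terminal_stop`` fields plus the
    optional ``terminal_stops`` mapping.
    """
    reference_taxa = list(reference_taxa)
    gln_columns: dict[str, list[ConservedGlnColumn]] = {}
    screens: dict[str, list[ScreenResult]] = {}
    stops: dict[str, list[str]] = {}
    for aln in alignments:
        cols = find_conserved_gln_columns(aln, reference_taxa, support_threshold, min_ref)
        gln_columns[aln.gene_id] = cols
        for taxon in aln.taxa:
            screens.setdefault(taxon, []).append(screen_taxon(aln, taxon, cols))
        for taxon, stop in aln.terminal_stop.items():
            stops.setdefault(taxon, []).append(stop)
    if terminal_stops:
        for taxon, observed in terminal_stops.items():
            stops.setdefault(taxon, []).extend(observed)
    assignments = {
        taxon: classify_code(
            taxon_screens,
            stops.get(taxon, ()),
            min_tar_evidence,
            require_terminal_consistency,
        )
        for taxon, taxon_screens in screens.items()
    }
    return InferenceResult(assignments, gln_columns, screens)


@dataclass(frozen=True)
class Substitution:
    """One nucleotide difference between two codons (1-based position)."""

    position: int
    from_base: str
    to_base: str
    kind: str  # "transition" | "transversion"


def codon_transition_distance(
    codon_a: str, codon_b: str
) -> tuple[int, list[Substitution]]:
    """Positionwise differences between two resolved codons.

    Returns the Hamming distance and, per differing position, whether the
    change is a transition (purine<->purine or pyrimidine<->pyrimidine)
    or a transversion.  The canonical->non-canonical glutamine pairs
    CAG->TAG and CAA->TAA each differ by a single C->T transition at
    codon position 1.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for codon in (codon_a, codon_b):
        if not _is_resolved(codon):
            raise ValueError(f"codon {codon!r} contains ambiguous characters")
    subs = []
    for i, (x, y) in enumerate(zip(codon_a, codon_b), start=1):
        if x != y:
            same_class = ({x, y} <= _PURINES) or ({x, y} <= _PYRIMIDINES)
            subs.append(Substitution(i, x, y, "transition" if same_class else "transversion"))
    return len(subs), subs
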