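"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the statistical structure of the study system —
in-frame coding alignments with conserved glutamine columns, taxa that
use either the standard or the TAR->Gln nuclear code, GC3-biased
glutamine codon choice, 3' terminal stop codons constrained by the code
(only TGA can terminate under reassignment), Brownian-motion trait
evolution on a tree, Gamma-distributed site rates, and per-topology
site log-likelihood matrices for bootstrap calibration.  Every draw is
logged in a :class:`SimTruth` so downstream estimates can be checked
against ground truth.

Default parameters mirror the study conditions: ~11 lineages, 8 genes
pooled per taxon, a handful of conserved glutamine columns per gene, and
a glutamine codon bias with CAG > CAA and TAG > TAA (the GC3 bias of
these genomes).  Two hard guarantees hold by construction: simulated
standard-code taxa never carry an internal TAR codon, and no codon at a
background column translates to glutamine, so the designated Gln columns
are exactly the conserved-Q columns a screen should find.

The shipped fixture tree (``fig1_prose``) encodes the green-plant
reference phylogeny as described in prose — (Trentepohliales,
((Dasycladales, Bryopsidales), (Cladophorales, Blastophysa))) nested
within standard-code relatives — with invented plausible branch
lengths; it is a reconstruction from text, not published data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import dendropy
import numpy as np

from .phylo_likelihood import SiteLnLMatrix, SubstitutionModel
from .seqio import CodingAlignment, NucleotideAlignment, PhyloTree

__all__ = [
    "SimConfig",
    "SimTruth",
    "fig1_tree",
    "fig1_code_states",
    "simulate_tree",
    "simulate_coding_alignment",
    "simulate_bm_on_tree",
    "simulate_site_lnl",
    "simulate_nucleotide_alignment",
]

GLN_CODONS = ("CAG", "CAA", "TAG", "TAA")
_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"

# Root codons for background columns: no stops, no glutamine codons.
_BACKGROUND_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS and a + b + c not in ("CAA", "CAG")
)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def fig1_tree() -> PhyloTree:
    """The prose-reconstructed reference topology with plausible lengths."""
    text = resources.files("codereassign.data").joinpath("fig1_prose.nwk").read_text()
    return PhyloTree.from_newick(text)


def fig1_code_states() -> dict[str, int]:
    """Tip code states for the fixture: 1 = TAR->Gln, 0 = standard."""
    text = resources.files("codereassign.data").joinpath("code_states.tsv").read_text()
    out = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        taxon, code = line.split("\t")
        out[taxon.strip()] = 1 if code.strip() == "TAR_GLN" else 0
    return out


# ---------------------------------------------------------------------------
# Configuration and provenance
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Parameters of the coding-alignment generator.

    ``codes`` maps taxon -> ``"STANDARD"`` | ``"TAR_GLN"``.
    ``gln_codon_probs`` optionally overrides, per taxon, the distribution
    over (CAG, CAA, TAG, TAA); standard-code taxa must put zero mass on
    the TAR codons.  When ``codes`` or ``tree`` are omitted, the fixture
    taxa and topology are used.  ``conservation_level`` is the fraction
    of background columns held invariant across taxa; the rest evolve
    along the tree at Gamma(``site_rate_shape``)-distributed rates times
    ``background_rate``.
    """

    tree: PhyloTree | None = None
    codes: dict[str, str] | None = None
    n_genes: int = 8
    n_codon_columns: int = 60
    n_gln_columns: int = 8
    gln_codon_probs: dict[str, Sequence[float]] | None = None
    standard_gln_probs: tuple[float, ...] = (0.6, 0.4, 0.0, 0.0)
    tar_gln_probs: tuple[float, ...] = (0.45, 0.2, 0.25, 0.1)
    conservation_level: float = 0.4
    site_rate_shape: float = 0.5
    background_rate: float = 0.5
    terminal_stops: bool = True

    def resolved(self) -> tuple[PhyloTree, dict[str, str], dict[str, np.ndarray]]:
        tree = self.tree if self.tree is not None else fig1_tree()
        if self.codes is not None:
            codes = dict(self.codes)
        else:
            codes = {
                t: ("TAR_GLN" if s == 1 else "STANDARD")
                for t, s in fig1_code_states().items()
            }
        probs = {}
        for taxon, code in codes.items():
            if self.gln_codon_probs and taxon in self.gln_codon_probs:
                p = np.asarray(self.gln_codon_probs[taxon], dtype=float)
            elif code == "TAR_GLN":
                p = np.asarray(self.tar_gln_probs, dtype=float)
            else:
                p = np.asarray(self.standard_gln_probs, dtype=float)
            if not np.isclose(p.sum(), 1.0) or np.any(p < 0):
                raise ValueError(f"gln codon probs for {taxon!r} are not a distribution")
            if code == "STANDARD" and p[2:].sum() > 0:
                raise ValueError(f"standard-code taxon {taxon!r} has TAR codon mass")
            probs[taxon] = p
        if set(codes) != set(tree.tip_labels):
            raise ValueError("codes must cover exactly the tree tips")
        if self.n_gln_columns > self.n_codon_columns:
            raise ValueError("more Gln columns than codon columns")
        return tree, codes, probs


@dataclass
class SimTruth:
    """Complete provenance of one simulated dataset."""

    codes: dict[str, str]
    gln_columns: dict[str, list[int]]  # gene_id -> 0-based codon columns
    emission_counts: dict[str, dict[str, int]]  # taxon -> gln codon -> count
    terminal_stops: dict[str, list[str]]  # taxon -> stop codon per gene
    background_rates: dict[str, np.ndarray] = field(default_factory=dict)
    invariant_columns: dict[str, list[int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def simulate_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    rng: np.random.Generator | int | None = None,
    labels: Sequence[str] | None = None,
) -> PhyloTree:
    """A random Yule (pure-birth) tree with exponential waiting times."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(rng)
    if labels is None:
        labels = [f"t{i}" for i in range(n_tips)]
    elif len(labels) != n_tips:
        raise ValueError("label count must equal n_tips")

    tree = dendropy.Tree()
    root = tree.seed_node
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        active.append(child)
    while len(active) < n_tips:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.edge.length += wait
        i = int(rng.integers(0, len(active)))
        parent = active.pop(i)
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            active.append(child)
    wait = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.edge.length += wait

    ns = dendropy.TaxonNamespace()
    for label, leaf in zip(labels, active):
        leaf.taxon = ns.new_taxon(label)
    tree.taxon_namespace = ns
    return PhyloTree(tree)


# ---------------------------------------------------------------------------
# Coding alignments
# ---------------------------------------------------------------------------


def _evolve_codon_column(
    tree: PhyloTree,
    root_codon: str,
    rate: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Evolve one codon column along the tree, nucleotide by nucleotide.

    Substitutions follow a Jukes-Cantor kernel: on a branch of length t a
    site changes with probability (3/4)(1 - exp(-4/3 * rate * t)),
    uniformly to one of the other bases.
    """
    out: dict[str, str] = {}
    codons = {id(tree.root): root_codon}
    for node in tree.dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_codon = codons[id(node.parent_node)]
        t = tree.branch_length(node)
        p_change = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * t))
        codon = list(parent_codon)
        for pos in range(3):
            if rng.random() < p_change:
                codon[pos] = rng.choice([b for b in _BASES if b != codon[pos]])
        codons[id(node)] = "".join(codon)
        if node.is_leaf():
            out[node.taxon.label] = codons[id(node)]
    return out


def _sanitize_background(codon: str, code: str) -> str:
    """Remap background codons so hard guarantees hold.

    Stops (and TAR for standard taxa) get a C at the third position;
    CAR codons (glutamine) get an A at the first position (-> Lys).
    """
    if codon in _STOPS:
        codon = codon[:2] + "C"
    if codon in ("CAA", "CAG"):
        codon = "A" + codon[1:]
    return codon


def simulate_coding_alignment(
    cfg: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[CodingAlignment], SimTruth]:
    """Simulate in-frame coding alignments for every gene in the config.

    Designated glutamine columns are filled per taxon from its glutamine
    codon distribution; background columns are either invariant or
    evolve along the tree at Gamma-distributed rates, with stop and
    glutamine codons remapped away.  A terminal stop codon is drawn per
    gene and taxon: uniformly from {TAA, TAG, TGA} for standard-code
    taxa, always TGA under reassignment.
    """
    rng = np.random.default_rng(rng)
    tree, codes, probs = cfg.resolved()
    taxa = tree.tip_labels

    truth = SimTruth(
        codes=dict(codes),
        gln_columns={},
        emission_counts={t: {c: 0 for c in GLN_CODONS} for t in taxa},
        terminal_stops={t: [] for t in taxa},
    )
    alignments = []
    for g in range(cfg.n_genes):
        gene_id = f"gene{g + 1}"
        gln_cols = sorted(
            rng.choice(cfg.n_codon_columns, size=cfg.n_gln_columns, replace=False).tolist()
        )
        truth.gln_columns[gene_id] = gln_cols
        gln_set = set(gln_cols)
        rates = rng.gamma(cfg.site_rate_shape, 1.0 / cfg.site_rate_shape, cfg.n_codon_columns)
        truth.background_rates[gene_id] = rates
        invariant: list[int] = []

        columns: dict[int, dict[str, str]] = {}
        for j in range(cfg.n_codon_columns):
            if j in gln_set:
                col = {}
                for t in taxa:
                    codon = GLN_CODONS[rng.choice(4, p=probs[t])]
                    col[t] = codon
                    truth.emission_counts[t][codon] += 1
                columns[j] = col
            elif rng.random() < cfg.conservation_level:
                codon = str(rng.choice(_BACKGROUND_CODONS))
                columns[j] = {t: codon for t in taxa}
                invariant.append(j)
            else:
                root_codon = str(rng.choice(_BACKGROUND_CODONS))
                col = _evolve_codon_column(tree, root_codon, rates[j] * cfg.background_rate, rng)
                columns[j] = {t: _sanitize_background(col[t], codes[t]) for t in taxa}
        truth.invariant_columns[gene_id] = invariant

        matrix = np.array(
            [[columns[j][t] for j in range(cfg.n_codon_columns)] for t in taxa],
            dtype="U3",
        )
        terminal = {}
        if cfg.terminal_stops:
            for t in taxa:
                stop = "TGA" if codes[t] == "TAR_GLN" else str(rng.choice(_STOPS))
                terminal[t] = stop
                truth.terminal_stops[t].append(stop)
        alignments.append(
            CodingAlignment(taxa=list(taxa), codons=matrix, gene_id=gene_id, terminal_stop=terminal)
        )
    return alignments, truth


# ---------------------------------------------------------------------------
# Continuous traits
# ---------------------------------------------------------------------------


def simulate_bm_on_tree(
    tree: PhyloTree,
    root_value: Sequence[float] | float,
    sigma2: float | Sequence[float],
    rng: np.random.Generator | int | None = None,
) -> tuple[dict[str, np.ndarray], dict[frozenset, np.ndarray]]:
    """Brownian motion along the tree: child = parent + N(0, sigma2 * t).

    Returns (tip values by label, internal node values keyed by clade tip
    set, root included).  ``sigma2`` may be scalar or per-trait.
    """
    rng = np.random.default_rng(rng)
    root = np.atleast_1d(np.asarray(root_value, dtype=float))
    s2 = np.broadcast_to(np.asarray(sigma2, dtype=float), root.shape)
    values: dict[int, np.ndarray] = {id(tree.root): root.copy()}
    tips: dict[str, np.ndarray] = {}
    nodes: dict[frozenset, np.ndarray] = {tree.clade_tips(tree.root): root.copy()}
    for node in tree.dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = tree.branch_length(node)
        step = rng.normal(0.0, np.sqrt(s2 * t))
        val = values[id(node.parent_node)] + step
        values[id(node)] = val
        if node.is_leaf():
            tips[node.taxon.label] = val
        else:
            nodes[tree.clade_tips(node)] = val
    return tips, nodes


# ---------------------------------------------------------------------------
# Site log-likelihood matrices and sequence simulation
# ---------------------------------------------------------------------------


def simulate_site_lnl(
    n_sites: int,
    n_topologies: int = 2,
    mu: Sequence[float] | float = 0.0,
    sd: float = 1.0,
    rng: np.random.Generator | int | None = None,
    baseline_mean: float = -5.0,
    baseline_sd: float = 1.0,
) -> SiteLnLMatrix:
    """IID-normal site log-likelihoods with configured per-topology means.

    A shared per-site baseline is drawn once, then each topology adds an
    independent N(mu_k, sd) offset, so per-site differences between
    topologies are iid normal with mean mu_i - mu_j and variance 2*sd^2.
    With all means equal this is the least-favourable null of the AU
    test.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(rng)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n_topologies,))
    base = rng.normal(baseline_mean, baseline_sd, size=n_sites)
    lnl = base[None, :] + rng.normal(mu[:, None], sd, size=(n_topologies, n_sites))
    return SiteLnLMatrix([f"topo{i + 1}" for i in range(n_topologies)], lnl)


def simulate_nucleotide_alignment(
    tree: PhyloTree,
    n_sites: int,
    model: SubstitutionModel,
    rng: np.random.Generator | int | None = None,
    site_rates: np.ndarray | None = None,
) -> tuple[NucleotideAlignment, np.ndarray]:
    """Simulate nucleotides along the tree under a GTR model.

    ``site_rates`` (default: draws from the model's mean-1 Gamma) scale
    each site's branch lengths.  Returns the alignment and the true
    per-site rates.
    """
    rng = np.random.default_rng(rng)
    if site_rates is None:
        a = model.gamma_shape
        site_rates = rng.gamma(a, 1.0 / a, size=n_sites)
    site_rates = np.asarray(site_rates, dtype=float)
    w, left, right = model.eigendecomposition()
    states: dict[int, np.ndarray] = {
        id(tree.root): rng.choice(4, size=n_sites, p=model.base_freqs)
    }
    taxa = []
    rows = []
    # group sites by identical rate is pointless for continuous rates; build
    # transition matrices per unique branch and apply per site via gumbel-free
    # categorical sampling from P[state] rows
    for node in tree.dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = tree.branch_length(node)
        parent_state = states[id(node.parent_node)]
        child_state = np.empty(n_sites, dtype=np.int64)
        # P depends on site rate; vectorise by computing P for each site's
        # scaled length via eigen-decomposition applied in batch
        scaled = t * site_rates
        expwt = np.exp(np.outer(scaled, w))  # (S, 4)
        # P_s = right @ diag(expwt_s) @ left ; need row parent_state of each
        R = right[parent_state, :]  # (S, 4)
        probs = (R * expwt) @ left  # (S, 4)
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum(axis=1)[:, None]
        u = rng.random(n_sites)
        child_state = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        states[id(node)] = child_state
        if node.is_leaf():
            taxa.append(node.taxon.label)
            rows.append(child_state)
    base = np.array(list(_BASES))
    matrix = base[np.vstack(rows)]
    return NucleotideAlignment(taxa, matrix), site_rates
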