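"""Fixed-topology GTR+Gamma likelihood engine and site-rate utilities.

Computes per-site log-likelihoods on a given rooted tree by Felsenstein's
pruning algorithm under a GTR substitution model with discrete-Gamma rate
variation (default 8 equal-probability categories, category rate = the
category mean, scaled so the mean rate is 1).  These per-site vectors are
the raw material of the RELL-based topology tests.  The module also
provides per-edge branch-length optimisation on a fixed topology,
per-site evolutionary-rate scores (4-state parsimony steps or the
posterior-mean Gamma rate), and slow-site stripping: retaining the
slowest fraction of columns to reduce the erosion of ancient signal by
fast-evolving sites.

Gaps and ambiguity codes are treated as missing data (all-ones partial
likelihood), the standard convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc, gammaincinv

from .seqio import NucleotideAlignment, PhyloTree

__all__ = [
    "SubstitutionModel",
    "jc_model",
    "SiteLnLMatrix",
    "SiteRateProfile",
    "site_loglikelihoods",
    "total_loglikelihood",
    "optimize_branch_lengths",
    "fit_gtr_gamma",
    "estimate_site_rates",
    "strip_fast_sites",
    "empirical_base_freqs",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_EXCH_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")


@dataclass
class SubstitutionModel:
    """GTR+Gamma model parameters.

    ``exchangeabilities`` follow the order AC, AG, AT, CG, CT, GT; the
    rate matrix is rescaled to one expected substitution per unit branch
    length at stationarity.  ``gamma_shape`` is the shape alpha of the
    mean-1 Gamma distribution of site rates, discretised into
    ``n_rate_categories`` equal-probability categories.
    """

    exchangeabilities: np.ndarray
    base_freqs: np.ndarray
    gamma_shape: float = 1.0
    n_rate_categories: int = 8

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.exchangeabilities.shape != (6,) or np.any(self.exchangeabilities < 0):
            raise ValueError("need 6 nonnegative exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if self.base_freqs.shape != (4,) or not np.isclose(self.base_freqs.sum(), 1.0):
            raise ValueError("base_freqs must be 4 frequencies summing to 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.n_rate_categories < 1:
            raise ValueError("need at least one rate category")

    def rate_matrix(self) -> np.ndarray:
        """GTR generator Q scaled to mean rate 1."""
        s = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for r, (i, j) in zip(self.exchangeabilities, pairs):
            s[i, j] = s[j, i] = r
        Q = s * self.base_freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(self.base_freqs, np.diag(Q))
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        return Q / mu

    def category_rates(self) -> np.ndarray:
        """Mean-1 discrete-Gamma category rates (equal-probability bins)."""
        k = self.n_rate_categories
        if k == 1:
            return np.ones(1)
        a = self.gamma_shape
        # bin boundaries as quantiles of Gamma(a, scale=1/a)
        probs = np.arange(1, k) / k
        bounds = gammaincinv(a, probs) / a
        upper = np.concatenate([bounds, [np.inf]])
        lower = np.concatenate([[0.0], bounds])
        # mean within each bin of a mean-1 gamma: k * (I(a+1, a*u) - I(a+1, a*l))
        hi = np.where(np.isinf(upper), 1.0, gammainc(a + 1, a * upper))
        lo = gammainc(a + 1, a * lower)
        rates = k * (hi - lo)
        return rates / rates.mean()

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eigenvalues, left, right) so that P(t) = right @ diag(e^{wt}) @ left."""
        Q = self.rate_matrix()
        pi = self.base_freqs
        d = np.sqrt(pi)
        A = (Q * d[:, None]) / d[None, :]
        w, U = np.linalg.eigh((A + A.T) / 2.0)
        right = U / d[:, None]
        left = U.T * d[None, :]
        return w, left, right


def jc_model(n_rate_categories: int = 1, gamma_shape: float = 1.0) -> SubstitutionModel:
    """Jukes-Cantor special case: equal exchangeabilities, uniform frequencies."""
    return SubstitutionModel(
        np.ones(6), np.full(4, 0.25), gamma_shape, n_rate_categories
    )


def empirical_base_freqs(aln: NucleotideAlignment, pseudocount: float = 0.0) -> np.ndarray:
    counts = np.array(
        [np.count_nonzero(aln.matrix == b) for b in "ACGT"], dtype=float
    ) + pseudocount
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


@dataclass
class SiteLnLMatrix:
    """Per-topology vectors of per-site log-likelihoods."""

    topology_ids: list[str]
    site_lnl: np.ndarray  # shape (n_topologies, n_sites)
    partition_of_site: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.site_lnl = np.atleast_2d(np.asarray(self.site_lnl, dtype=float))
        if len(self.topology_ids) != self.site_lnl.shape[0]:
            raise ValueError("topology_ids and site_lnl row count differ")
        if not np.all(np.isfinite(self.site_lnl)):
            raise ValueError("site log-likelihoods must be finite")

    @property
    def n_sites(self) -> int:
        return self.site_lnl.shape[1]

    @property
    def totals(self) -> np.ndarray:
        return self.site_lnl.sum(axis=1)


@dataclass
class SiteRateProfile:
    """Per-site nonnegative rate scores plus the raw statistic they derive from."""

    rates: np.ndarray
    method: str
    steps: np.ndarray | None = None  # raw parsimony step counts when applicable


def _encode(aln: NucleotideAlignment, taxa_order: Sequence[str]) -> np.ndarray:
    codes = np.full((len(taxa_order), aln.n_sites), -1, dtype=np.int8)
    for r, taxon in enumerate(taxa_order):
        row = aln.row(taxon)
        for base, idx in _BASE_INDEX.items():
            codes[r, row == base] = idx
    return codes


def _per_category_site_lnl(
    aln: NucleotideAlignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    sites: np.ndarray | None = None,
) -> np.ndarray:
    """Log-likelihood per (rate category, site) by pruning with rescaling."""
    tips = tree.tip_labels
    missing = set(tips) - set(aln.taxa)
    if missing:
        raise ValueError(f"tree tips absent from alignment: {sorted(missing)}")
    codes = _encode(aln, tips)
    if sites is not None:
        codes = codes[:, sites]
    n_sites = codes.shape[1]
    w, left, right = model.eigendecomposition()
    rates = model.category_rates()
    pi = model.base_freqs

    tip_row = {t: r for r, t in enumerate(tips)}
    out = np.empty((len(rates), n_sites))
    for k, rate in enumerate(rates):
        partial: dict[dendropy.Node, np.ndarray] = {}
        logscale = np.zeros(n_sites)
        for node in tree.dtree.postorder_node_iter():
            if node.is_leaf():
                c = codes[tip_row[node.taxon.label]]
                L = np.ones((n_sites, 4))
                obs = c >= 0
                L[obs] = 0.0
                L[np.where(obs)[0], c[obs]] = 1.0
            else:
                L = np.ones((n_sites, 4))
                for child in node.child_nodes():
                    t = tree.branch_length(child) * rate
                    P = right @ (np.exp(w * t)[:, None] * left)
                    L *= partial.pop(child) @ P.T
                mx = L.max(axis=1)
                mx = np.where(mx > 0, mx, 1.0)
                L /= mx[:, None]
                logscale += np.log(mx)
            partial[node] = L
        root_L = partial[tree.root]
        out[k] = np.log(np.clip(root_L @ pi, 1e-300, None)) + logscale
    return out


def site_loglikelihoods(
    aln: NucleotideAlignment,
    tree: PhyloTree,
    model: SubstitutionModel | Mapping[object, SubstitutionModel],
    partitions: Mapping[object, Sequence[int]] | None = None,
) -> np.ndarray:
    """Per-site log-likelihoods, averaged over Gamma categories.

    With ``partitions`` (partition id -> 0-based site indices, jointly
    covering every site exactly once) each partition may use its own
    model: pass a mapping of partition id -> model, or a single model to
    share.  Branch lengths are those of ``tree`` in every partition.
    """
    if partitions is None:
        per_cat = _per_category_site_lnl(aln, tree, model, None)
        return _logmeanexp(per_cat)
    cover = np.concatenate([np.asarray(ix, dtype=int) for ix in partitions.values()])
    if sorted(cover.tolist()) != list(range(aln.n_sites)):
        raise ValueError("partitions must cover every site exactly once")
    out = np.empty(aln.n_sites)
    for pid, ix in partitions.items():
        m = model[pid] if isinstance(model, Mapping) else model
        ix = np.asarray(ix, dtype=int)
        out[ix] = _logmeanexp(_per_category_site_lnl(aln, tree, m, ix))
    return out


def _logmeanexp(per_cat: np.ndarray) -> np.ndarray:
    mx = per_cat.max(axis=0)
    return mx + np.log(np.mean(np.exp(per_cat - mx[None, :]), axis=0))


def total_loglikelihood(
    aln: NucleotideAlignment,
    tree: PhyloTree,
    model: SubstitutionModel | Mapping[object, SubstitutionModel],
    partitions: Mapping[object, Sequence[int]] | None = None,
) -> float:
    return float(site_loglikelihoods(aln, tree, model, partitions).sum())


def optimize_branch_lengths(
    aln: NucleotideAlignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_sweeps: int = 20,
    max_length: float = 20.0,
) -> tuple[PhyloTree, float, bool]:
    """Coordinate-ascent branch-length optimisation on a fixed topology.

    Each sweep optimises every edge in turn with bounded Brent search;
    sweeps stop when the total log-likelihood improves by less than
    ``tol``.  Returns (tree with optimised lengths, final lnL, converged).
    The likelihood is non-decreasing across sweeps by construction.
    """
    work = tree.clone()
    edges = [n for n in work.dtree.preorder_node_iter() if n.parent_node is not None]
    current = total_loglikelihood(aln, work, model)
    converged = False
    for _ in range(max_sweeps):
        before = current
        for node in edges:
            def neg(t: float, node=node) -> float:
                node.edge.length = t
                return -total_loglikelihood(aln, work, model)

            res = minimize_scalar(
                neg, bounds=(1e-9, max_length), method="bounded",
                options={"xatol": 1e-9},
            )
            node.edge.length = float(res.x)
            current = -float(res.fun)
        if current - before < tol:
            converged = True
            break
    return work, current, converged


def fit_gtr_gamma(
    aln: NucleotideAlignment,
    tree: PhyloTree,
    n_rate_categories: int = 8,
    optimize_lengths: bool = True,
    base_freqs: np.ndarray | None = None,
) -> tuple[SubstitutionModel, PhyloTree, float]:
    """Fit GTR exchangeabilities and Gamma shape by ML on a fixed topology.

    Base frequencies are empirical (pseudocount 1) unless supplied.
    Exchangeabilities (GT fixed at 1) and alpha are optimised on the log
    scale with L-BFGS-B, alternating once with branch-length
    optimisation when requested.
    """
    if base_freqs is None:
        base_freqs = empirical_base_freqs(aln, pseudocount=1.0)
    work = tree.clone()

    def build(theta: np.ndarray) -> SubstitutionModel:
        ex = np.append(np.exp(theta[:5]), 1.0)
        return SubstitutionModel(ex, base_freqs, float(np.exp(theta[5])), n_rate_categories)

    def neg(theta: np.ndarray) -> float:
        try:
            return -total_loglikelihood(aln, work, build(theta))
        except (ValueError, FloatingPointError):
            return 1e12

    theta0 = np.zeros(6)
    rounds = 2 if optimize_lengths else 1
    res = None
    for _ in range(rounds):
        res = minimize(neg, theta0, method="L-BFGS-B", options={"maxiter": 200})
        theta0 = res.x
        if optimize_lengths:
            work, _, _ = optimize_branch_lengths(aln, work, build(theta0), max_sweeps=5)
    model = build(theta0)
    return model, work, -float(res.fun)


# ---------------------------------------------------------------------------
# Site rates and stripping
# ---------------------------------------------------------------------------


def _fitch_steps(aln: NucleotideAlignment, tree: PhyloTree) -> np.ndarray:
    """Minimum substitutions per site by 4-state Fitch; gaps are missing."""
    tips = tree.tip_labels
    codes = _encode(aln, tips)
    masks = np.where(codes >= 0, np.left_shift(1, np.clip(codes, 0, 3)), 15).astype(np.int8)
    tip_row = {t: r for r, t in enumerate(tips)}
    steps = np.zeros(aln.n_sites, dtype=int)
    sets: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.dtree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = masks[tip_row[node.taxon.label]].copy()
        else:
            children = node.child_nodes()
            cur = sets.pop(children[0])
            for child in children[1:]:
                nxt = sets.pop(child)
                inter = cur & nxt
                empty = inter == 0
                steps += empty.astype(int)
                cur = np.where(empty, cur | nxt, inter)
            sets[node] = cur
    return steps


def estimate_site_rates(
    aln: NucleotideAlignment,
    tree: PhyloTree,
    method: str = "parsimony_steps",
    model: SubstitutionModel | None = None,
) -> SiteRateProfile:
    """Per-site evolutionary rate scores.

    ``parsimony_steps``: minimum changes per site (Fitch over the 4
    nucleotide states), normalised by the maximum step count observed so
    scores fall in [0, 1]; invariant sites score 0.
    ``gamma_posterior_mean``: posterior mean discrete-Gamma category rate
    per site under ``model`` (required), with equal category priors.
    """
    if method == "parsimony_steps":
        steps = _fitch_steps(aln, tree)
        denom = max(int(steps.max()), 1)
        return SiteRateProfile(steps / denom, method, steps=steps)
    if method == "gamma_posterior_mean":
        if model is None:
            raise ValueError("gamma_posterior_mean requires a substitution model")
        per_cat = _per_category_site_lnl(aln, tree, model, None)
        mx = per_cat.max(axis=0)
        post = np.exp(per_cat - mx[None, :])
        post /= post.sum(axis=0)[None, :]
        rates = model.category_rates() @ post
        return SiteRateProfile(rates, method)
    raise ValueError(f"unknown rate method {method!r}")


def strip_fast_sites(
    aln: NucleotideAlignment,
    rates: SiteRateProfile,
    keep_fraction: float = 0.75,
) -> tuple[NucleotideAlignment, np.ndarray]:
    """Retain exactly ceil(keep_fraction * n_sites) slowest sites.

    Ties are broken by original column order (stable sort), so with
    all-equal rates the leading columns are kept.  Returns the stripped
    alignment and the kept 0-based column indices (the provenance map).
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    n = aln.n_sites
    if len(rates.rates) != n:
        raise ValueError("rate profile length does not match alignment")
    n_keep = int(np.ceil(keep_fraction * n))
    order = np.argsort(rates.rates, kind="stable")
    kept = np.sort(order[:n_keep])
    return NucleotideAlignment(list(aln.taxa), aln.matrix[:, kept]), kept
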