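"""Model-based evolutionary distances, NJ trees and substitution-model choice.

Distances between sequences are maximum-likelihood style closed forms:
Jukes-Cantor (JC69), Kimura two-parameter (K2P) and Tamura-Nei (TN93),
each with an optional gamma rate-heterogeneity correction in which every
``-ln(x)`` term becomes ``a * (x**(-1/a) - 1)`` for shape ``a``.  HKY85 has
no closed-form distance and is routed through the TN93 form in which it is
nested.  Trees are built by neighbor joining (Saitou & Nei agglomeration
with the Studier-Keppler Q criterion) with deterministic tie-breaking, and
site-resampling bootstrap supports can be attached and used to collapse
weakly supported edges into polytomies.

Substitution-model selection fixes the topology to the K2P neighbor-joining
tree, maximises the pruning-algorithm likelihood over branch lengths and
model parameters for each candidate (JC69/K2P/HKY85/TN93, each with and
without gamma), and returns the candidate minimising
``BIC = -2 lnL + k ln(sites)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import linalg, optimize, stats

from .dataio import ValidationError
from .diversity import encode

logger = logging.getLogger("invadiv")

MODEL_NAMES = ("JC69", "K2P", "HKY85", "TN93")

# purines A(0), G(2); pyrimidines C(1), T(3)
_PURINES = (0, 2)
_PYRIMIDINES = (1, 3)


class SaturationError(ValidationError):
    """Observed divergence too large for the closed-form distance."""


@dataclass
class SubstitutionModel:
    """A nucleotide substitution model with fitted parameters."""

    name: str                           # JC69 | K2P | HKY85 | TN93
    gamma: bool = False
    gamma_shape: float | None = None    # 4 discrete categories when set
    params: dict = field(default_factory=dict)   # kappa / kappa1 / kappa2
    frequencies: np.ndarray | None = None
    lnL: float | None = None
    bic: float | None = None

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValidationError(f"unknown substitution model {self.name!r}")
        if self.frequencies is not None:
            self.frequencies = np.asarray(self.frequencies, dtype=float)
            if not math.isclose(self.frequencies.sum(), 1.0, abs_tol=1e-6):
                raise ValidationError("base frequencies must sum to 1")

    @property
    def label(self) -> str:
        return self.name + ("+G" if self.gamma else "")


@dataclass
class PhyloTree:
    """A tree with optional bootstrap supports on internal edges."""

    tree: dendropy.Tree

    @property
    def newick(self) -> str:
        return self.tree.as_string(schema="newick",
                                   suppress_rooting=True).strip()

    def leaf_labels(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}


# ---------------------------------------------------------------------------
# Closed-form distances
# ---------------------------------------------------------------------------

def _w(x: float, a: float | None) -> float:
    """-ln(x), or its gamma-corrected analogue a*(x^(-1/a)-1)."""
    if x <= 0.0:
        raise SaturationError(
            f"distance formula log argument {x:.4g} <= 0 (saturated pair)"
        )
    if a is None:
        return -math.log(x)
    return a * (x ** (-1.0 / a) - 1.0)


def pair_counts(s1: np.ndarray, s2: np.ndarray) -> tuple[int, int, int]:
    """(valid sites, transitions, transversions) between two coded sequences."""
    valid = (s1 >= 0) & (s2 >= 0)
    a, b = s1[valid], s2[valid]
    diff = a != b
    ts = diff & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0)) |
                 ((a == 1) & (b == 3)) | ((a == 3) & (b == 1)))
    return int(valid.sum()), int(ts.sum()), int((diff & ~ts).sum())


def jc_distance(p: float, gamma_shape: float | None = None) -> float:
    return 0.75 * _w(1.0 - 4.0 * p / 3.0, gamma_shape)


def k2p_distance(P: float, Q: float,
                 gamma_shape: float | None = None) -> float:
    return 0.5 * _w(1.0 - 2 * P - Q, gamma_shape) + 0.25 * _w(1.0 - 2 * Q, gamma_shape)


def tn93_distance(P1: float, P2: float, Q: float, freqs: np.ndarray,
                  gamma_shape: float | None = None) -> float:
    """Tamura-Nei distance; P1 = A<->G, P2 = C<->T proportions."""
    pa, pc, pg, pt = freqs
    pr, py = pa + pg, pc + pt
    k1 = 2 * pa * pg / pr
    k2 = 2 * pc * pt / py
    k3 = 2 * (pr * py - pa * pg * py / pr - pc * pt * pr / py)
    w1 = 1.0 - P1 / k1 - Q / (2 * pr)
    w2 = 1.0 - P2 / k2 - Q / (2 * py)
    w3 = 1.0 - Q / (2 * pr * py)
    return k1 * _w(w1, gamma_shape) + k2 * _w(w2, gamma_shape) + k3 * _w(w3, gamma_shape)


def pairwise_model_distance(seq1: str, seq2: str,
                            model: SubstitutionModel) -> float:
    """Model-corrected distance between two equal-length sequences.

    Sites where either sequence carries a gap or ambiguity are excluded
    for the pair.  A saturated pair raises :class:`SaturationError`.
    """
    arr = encode([seq1, seq2])
    return _distance_from_codes(arr[0], arr[1], model)


def _distance_from_codes(s1: np.ndarray, s2: np.ndarray,
                         model: SubstitutionModel) -> float:
    n, ts, tv = pair_counts(s1, s2)
    if n == 0:
        raise ValidationError("no comparable sites for the pair")
    a = model.gamma_shape if model.gamma else None
    if model.name == "JC69":
        return jc_distance((ts + tv) / n, a)
    if model.name == "K2P":
        return k2p_distance(ts / n, tv / n, a)
    # HKY85 and TN93: TN93 closed form with (empirical) frequencies
    valid = (s1 >= 0) & (s2 >= 0)
    if model.frequencies is not None:
        freqs = model.frequencies
    else:
        both = np.concatenate([s1[valid], s2[valid]])
        freqs = np.bincount(both, minlength=4) / both.size
    if np.any(freqs <= 0):
        raise SaturationError("a base is absent; TN93 frequencies degenerate")
    ag = int(np.sum(((s1 == 0) & (s2 == 2)) | ((s1 == 2) & (s2 == 0))))
    ct = int(np.sum(((s1 == 1) & (s2 == 3)) | ((s1 == 3) & (s2 == 1))))
    return tn93_distance(ag / n, ct / n, tv / n, freqs, a)


def distance_matrix(sequences: list[str], model: SubstitutionModel,
                    saturation_value: float | None = None) -> np.ndarray:
    """All pairwise model distances; optionally cap saturated pairs."""
    arr = encode(sequences)
    k = len(sequences)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                d[i, j] = d[j, i] = _distance_from_codes(arr[i], arr[j], model)
            except SaturationError:
                if saturation_value is None:
                    raise
                d[i, j] = d[j, i] = saturation_value
    return d


def mean_between_population_distance(pop_a: list[str], pop_b: list[str],
                                     model: SubstitutionModel,
                                     net: bool = False) -> float:
    """Mean model distance over all inter-population sequence pairs.

    Saturated pairs are excluded with a warning; with ``net=True`` the
    mean within-population distances are subtracted (net between-group
    distance).
    """
    def _mean(pairs):
        vals, skipped = [], 0
        for x, y in pairs:
            try:
                vals.append(pairwise_model_distance(x, y, model))
            except SaturationError:
                skipped += 1
        if skipped:
            logger.warning("%d saturated pair(s) excluded from mean distance",
                           skipped)
        if not vals:
            raise SaturationError("all sequence pairs saturated")
        return float(np.mean(vals))

    between = _mean((x, y) for x in pop_a for y in pop_b)
    if not net:
        return between
    within_a = 0.0 if len(pop_a) < 2 else _mean(
        (pop_a[i], pop_a[j]) for i in range(len(pop_a))
        for j in range(i + 1, len(pop_a)))
    within_b = 0.0 if len(pop_b) < 2 else _mean(
        (pop_b[i], pop_b[j]) for i in range(len(pop_b))
        for j in range(i + 1, len(pop_b)))
    return between - 0.5 * (within_a + within_b)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dist: np.ndarray, labels: list[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lowest (i, j) label index
    pair.  Negative branch-length estimates are clamped to zero (they can
    only arise on non-additive input).  The returned tree is unrooted with
    a trifurcating seed node.
    """
    dist = np.asarray(dist, dtype=float)
    k = len(labels)
    if dist.shape != (k, k):
        raise ValidationError("distance matrix does not match labels")
    if not np.allclose(dist, dist.T):
        raise ValidationError("distance matrix is not symmetric")
    if k < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")

    tns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(node)
    active = list(range(k))
    D = dist.copy()

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        bi = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        bj = D[i, j] - bi
        parent = dendropy.Node()
        nodes[i].edge.length = bi if bi > 0 else 0.0
        nodes[j].edge.length = bj if bj > 0 else 0.0
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_idx = len(nodes)
        nodes.append(parent)
        D = np.pad(D, ((0, 1), (0, 1)))
        for m in active:
            if m in (i, j):
                continue
            D[new_idx, m] = D[m, new_idx] = 0.5 * (D[i, m] + D[j, m] - D[i, j])
        active = [m for m in active if m not in (i, j)] + [new_idx]

    root = dendropy.Node()
    if len(active) == 3:
        u, v, w = active
        bu = 0.5 * (D[u, v] + D[u, w] - D[v, w])
        bv = 0.5 * (D[u, v] + D[v, w] - D[u, w])
        bw = 0.5 * (D[u, w] + D[v, w] - D[u, v])
        for idx, b in zip((u, v, w), (bu, bv, bw)):
            nodes[idx].edge.length = b if b > 0 else 0.0
            root.add_child(nodes[idx])
    else:  # 2 remaining: single edge
        u, v = active
        nodes[u].edge.length = D[u, v] / 2
        nodes[v].edge.length = D[u, v] / 2
        root.add_child(nodes[u])
        root.add_child(nodes[v])

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return PhyloTree(tree=tree)


def _bipartitions(tree: dendropy.Tree, all_labels: frozenset) -> dict:
    """Map canonical leaf bipartition -> internal node, for internal edges."""
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_labels - below
        if not other:
            continue
        canon = min((below, other),
                    key=lambda s: (len(s), tuple(sorted(s))))
        out[canon] = node
    return out


def bootstrap_condense(sequences: list[str], labels: list[str],
                       model: SubstitutionModel, n_boot: int = 1000,
                       threshold: float = 75.0,
                       seed: int | None = None) -> PhyloTree:
    """NJ tree with site-resampling bootstrap supports, condensed.

    Alignment columns are resampled with replacement ``n_boot`` times; the
    support of an internal edge is the percentage of replicate trees
    containing the same leaf bipartition.  Edges with support below
    ``threshold`` (percent) are collapsed into polytomies.  Replicate
    distance computations cap saturated pairs at 10 substitutions/site so
    that a rare degenerate resample cannot abort the run.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    arr = encode(sequences)
    L = arr.shape[1]
    base = distance_matrix(sequences, model, saturation_value=10.0)
    main = nj_tree(base, labels)
    all_labels = frozenset(labels)
    parts = _bipartitions(main.tree, all_labels)
    counts = {part: 0 for part in parts}

    rng = np.random.default_rng(seed)
    k = len(sequences)
    for _ in range(n_boot):
        idx = rng.integers(0, L, size=L)
        sub = arr[:, idx]
        d = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                try:
                    d[i, j] = d[j, i] = _distance_from_codes(
                        sub[i], sub[j], model)
                except SaturationError:
                    d[i, j] = d[j, i] = 10.0
        rep = nj_tree(d, labels)
        rep_parts = _bipartitions(rep.tree, all_labels)
        for part in counts:
            if part in rep_parts:
                counts[part] += 1

    to_collapse = []
    for part, node in parts.items():
        support = 100.0 * counts[part] / n_boot
        node.label = f"{support:.0f}"
        # zero-length internal edges carry no signal: deterministic
        # tie-breaking would otherwise give them spurious 100% support
        if support < threshold or not (node.edge.length or 0.0) > 0.0:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return main


# ---------------------------------------------------------------------------
# Likelihood machinery and model selection
# ---------------------------------------------------------------------------

def _rate_matrix(name: str, freqs: np.ndarray, params: dict) -> np.ndarray:
    """Reversible rate matrix, normalised to one expected change per unit."""
    if name == "JC69":
        pi = np.full(4, 0.25)
        R = np.ones((4, 4))
    elif name == "K2P":
        pi = np.full(4, 0.25)
        R = np.ones((4, 4))
        kappa = params["kappa"]
        R[0, 2] = R[2, 0] = R[1, 3] = R[3, 1] = kappa
    elif name == "HKY85":
        pi = freqs
        R = np.ones((4, 4))
        kappa = params["kappa"]
        R[0, 2] = R[2, 0] = R[1, 3] = R[3, 1] = kappa
    elif name == "TN93":
        pi = freqs
        R = np.ones((4, 4))
        R[0, 2] = R[2, 0] = params["kappa1"]
        R[1, 3] = R[3, 1] = params["kappa2"]
    else:
        raise ValidationError(f"unknown model {name!r}")
    Q = R * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(np.dot(pi, np.diag(Q)))
    return Q / scale


def _gamma_rates(shape: float, k: int = 4) -> np.ndarray:
    """Median discrete-gamma category rates, normalised to mean 1."""
    quantiles = (2 * np.arange(k) + 1) / (2 * k)
    rates = stats.gamma.ppf(quantiles, a=shape, scale=1.0 / shape)
    return rates / rates.mean()


def _site_patterns(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Complete-deletion columns collapsed into unique patterns + counts."""
    cols = arr[:, (arr >= 0).all(axis=0)].T
    if cols.shape[0] == 0:
        raise ValidationError("no complete columns for likelihood computation")
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    return patterns.T, counts


class _TreeLik:
    """Pruning-algorithm log-likelihood on a fixed topology."""

    def __init__(self, tree: dendropy.Tree, labels: list[str],
                 patterns: np.ndarray, counts: np.ndarray):
        self.patterns = patterns        # (ntaxa, npat)
        self.counts = counts
        self.postorder = []             # (node_index, [(child_index, branch_index)])
        self.leaf_row = {}
        index = {}
        self.n_branches = 0
        for node in tree.postorder_node_iter():
            index[id(node)] = len(index)
            if node.is_leaf():
                self.leaf_row[index[id(node)]] = labels.index(node.taxon.label)
            else:
                children = []
                for ch in node.child_nodes():
                    children.append((index[id(ch)], self.n_branches))
                    self.n_branches += 1
                self.postorder.append((index[id(node)], children))
        self.n_nodes = len(index)
        self.root_index = self.postorder[-1][0]

    def branch_init(self, tree: dendropy.Tree) -> np.ndarray:
        """Initial branch lengths read off the tree, floored at 1e-6."""
        out = np.empty(self.n_branches)
        i = 0
        for node in tree.postorder_node_iter():
            if not node.is_leaf():
                for ch in node.child_nodes():
                    out[i] = max(ch.edge.length or 0.0, 1e-6)
                    i += 1
        return out

    def loglik(self, branches: np.ndarray, Q: np.ndarray, pi: np.ndarray,
               gamma_shape: float | None, n_categories: int = 4) -> float:
        rates = (np.array([1.0]) if gamma_shape is None
                 else _gamma_rates(gamma_shape, n_categories))
        # reversible Q: symmetrize with sqrt(pi) for a stable eigen-system
        d = np.sqrt(pi)
        B = Q * d[:, None] / d[None, :]
        evals, U = linalg.eigh(0.5 * (B + B.T))
        evecs = U / d[:, None]
        inv = U.T * d[None, :]
        npat = self.patterns.shape[1]
        site_lik = np.zeros(npat)
        eye = np.eye(4)
        for rate in rates:
            # transition matrices for every branch at once
            ew = np.exp(np.outer(branches * rate, evals))      # (B, 4)
            P = np.einsum("ij,bj,jk->bik", evecs, ew, inv)
            P = np.clip(P, 1e-300, None)
            partial = np.empty((self.n_nodes, 4, npat))
            for leaf_idx, row in self.leaf_row.items():
                partial[leaf_idx] = eye[:, self.patterns[row]]
            for node_idx, children in self.postorder:
                acc = np.ones((4, npat))
                for child_idx, b_idx in children:
                    acc *= P[b_idx] @ partial[child_idx]
                partial[node_idx] = acc
            site_lik += pi @ partial[self.root_index] / len(rates)
        return float(np.sum(self.counts * np.log(np.clip(site_lik, 1e-300, None))))


def _empirical_freqs(arr: np.ndarray) -> np.ndarray:
    valid = arr[arr >= 0]
    freqs = np.bincount(valid, minlength=4).astype(float)
    if np.any(freqs == 0):
        freqs += 1.0          # pseudo-count keeps the TN93 forms defined
    return freqs / freqs.sum()


_MODEL_PARAM_NAMES = {
    "JC69": [], "K2P": ["kappa"], "HKY85": ["kappa"],
    "TN93": ["kappa1", "kappa2"],
}
# frequency parameters counted for unequal-frequency models
_FREQ_PARAMS = {"JC69": 0, "K2P": 0, "HKY85": 3, "TN93": 3}


def fit_model(sequences: list[str], labels: list[str], name: str,
              gamma: bool, tree: PhyloTree | None = None,
              n_categories: int = 4) -> SubstitutionModel:
    """Maximum-likelihood fit of one candidate model on a fixed topology."""
    arr = encode(sequences)
    patterns, counts = _site_patterns(arr)
    freqs = (_empirical_freqs(arr) if name in ("HKY85", "TN93")
             else np.full(4, 0.25))
    if tree is None:
        tree = nj_tree(distance_matrix(sequences,
                                       SubstitutionModel("K2P", params={"kappa": 2.0}),
                                       saturation_value=10.0), labels)
    lik = _TreeLik(tree.tree, labels, patterns, counts)
    b0 = lik.branch_init(tree.tree)

    pnames = _MODEL_PARAM_NAMES[name]
    x0 = list(np.log(b0)) + [math.log(4.0)] * len(pnames)
    if gamma:
        x0.append(math.log(0.5))
    nb = lik.n_branches

    def neg_loglik(x):
        branches = np.exp(x[:nb])
        params = {p: math.exp(v) for p, v in zip(pnames, x[nb:nb + len(pnames)])}
        shape = math.exp(x[-1]) if gamma else None
        Q = _rate_matrix(name, freqs, params)
        return -lik.loglik(branches, Q, freqs, shape, n_categories)

    bounds = [(math.log(1e-8), math.log(10.0))] * nb
    bounds += [(math.log(0.05), math.log(200.0))] * len(pnames)
    if gamma:
        bounds.append((math.log(0.05), math.log(10.0)))
    res = optimize.minimize(neg_loglik, np.array(x0), method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": 200, "ftol": 1e-7})
    lnL = -float(res.fun)
    k_free = lik.n_branches + len(pnames) + _FREQ_PARAMS[name] + (1 if gamma else 0)
    n_sites = int(counts.sum())
    bic = -2.0 * lnL + k_free * math.log(n_sites)
    params = {p: math.exp(v)
              for p, v in zip(pnames, res.x[nb:nb + len(pnames)])}
    shape = float(math.exp(res.x[-1])) if gamma else None
    return SubstitutionModel(name=name, gamma=gamma, gamma_shape=shape,
                             params=params, frequencies=freqs,
                             lnL=lnL, bic=bic)


def select_model(sequences: list[str], labels: list[str] | None = None,
                 candidates: tuple[str, ...] = MODEL_NAMES,
                 gamma_options: tuple[bool, ...] = (False, True),
                 ) -> SubstitutionModel:
    """Choose the substitution model minimising BIC on a fixed NJ topology.

    With fewer than three distinct haplotypes there is nothing to fit and
    JC69 is returned with a warning.
    """
    if labels is None:
        labels = [f"t{i}" for i in range(len(sequences))]
    # collapse duplicate haplotypes: they contribute nothing to the fit
    distinct: dict[str, str] = {}
    for lab, seq in zip(labels, sequences):
        if seq not in distinct:
            distinct[seq] = lab
    dseqs = list(distinct.keys())
    dlabels = list(distinct.values())
    if len(dseqs) < 3:
        logger.warning("fewer than 3 distinct haplotypes: falling back to JC69")
        return SubstitutionModel(name="JC69", frequencies=np.full(4, 0.25))
    tree = nj_tree(distance_matrix(dseqs,
                                   SubstitutionModel("K2P", params={"kappa": 2.0}),
                                   saturation_value=10.0), dlabels)
    best: SubstitutionModel | None = None
    for name in candidates:
        for gamma in gamma_options:
            fit = fit_model(dseqs, dlabels, name, gamma, tree=tree)
            if best is None or fit.bic < best.bic - 1e-9:
                best = fit
    return best


# ---------------------------------------------------------------------------
# Forward simulation (used to exercise the estimators)
# ---------------------------------------------------------------------------

def _sample_markov(parent: np.ndarray, P: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Evolve a coded sequence through one transition matrix."""
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent.size)
    return (u[:, None] > cum[parent]).sum(axis=1).astype(np.int8)


def evolve_pair(distance: float, length: int, model: SubstitutionModel,
                seed: int | None = None) -> tuple[str, str]:
    """Two sequences whose ancestor sits ``distance/2`` from each tip."""
    rng = np.random.default_rng(seed)
    freqs = (model.frequencies if model.frequencies is not None
             else np.full(4, 0.25))
    Q = _rate_matrix(model.name, freqs, model.params)
    P = linalg.expm(Q * distance / 2.0)
    root = rng.choice(4, size=length, p=freqs).astype(np.int8)
    alphabet = np.array(list("ACGT"))
    return tuple("".join(alphabet[_sample_markov(root, P, rng)])
                 for _ in range(2))


def simulate_alignment(n_taxa: int, length: int, model: SubstitutionModel,
                       tree_scale: float = 0.05,
                       seed: int | None = None) -> tuple[list[str], list[str]]:
    """Sequences evolved on a random single-population coalescent tree.

    Branch lengths (coalescent units) are multiplied by ``tree_scale`` to
    give expected substitutions per site.  Returns (sequences, labels).
    """
    rng = np.random.default_rng(seed)
    freqs = (model.frequencies if model.frequencies is not None
             else np.full(4, 0.25))
    Q = _rate_matrix(model.name, freqs, model.params)

    # Kingman coalescent: times then random joins
    parent = {}
    blen = {}
    active = list(range(n_taxa))
    times = {i: 0.0 for i in active}
    t = 0.0
    nxt = n_taxa
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        for child in (a, b):
            parent[child] = nxt
            blen[child] = t - times[child]
        times[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1

    root = active[0]
    seqs = {root: rng.choice(4, size=length, p=freqs).astype(np.int8)}
    children: dict[int, list[int]] = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)
    stack = [root]
    while stack:
        node = stack.pop()
        for child in children.get(node, []):
            P = linalg.expm(Q * blen[child] * tree_scale)
            seqs[child] = _sample_markov(seqs[node], P, rng)
            stack.append(child)
    alphabet = np.array(list("ACGT"))
    out = ["".join(alphabet[seqs[i]]) for i in range(n_taxa)]
    return out, [f"t{i}" for i in range(n_taxa)]
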