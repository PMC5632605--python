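"""Pairwise F_ST from haplotype frequencies, with permutation tests.

Differentiation between two sampling localities is measured on haplotype
identity alone (no sequence distances):

    F_ST = (H_b - H_w) / H_b

where H_w is the probability that two sequences drawn within the same
population carry different haplotypes (the two within-population values are
pooled with weights n(n-1)/2, i.e. by their number of pairs) and H_b the
probability that one sequence from each population differ.  The estimator is
exactly computable from haplotype counts, which gives every test a
brute-force oracle.  Significance comes from permuting individuals between
the two localities; the add-one rule keeps p-values strictly positive.

Raw estimates may be slightly negative by sampling noise; they are kept as
computed and only clamped to zero in range summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .dataio import AlignedPopulationSet, LabeledDistanceMatrix, ValidationError
from .diversity import encode


@dataclass
class FstResult:
    """One unordered population pair: estimate, permutation p, significance."""

    pop_a: str
    pop_b: str
    fst: float
    p_value: float
    n_permutations: int
    significant: bool | None = None


def haplotype_labels(pop_a: list[str], pop_b: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Integer haplotype labels over the pooled pair alignment.

    Columns carrying a gap/ambiguity in *any* sequence of the pooled pair
    are removed first, so both populations are compared on the same sites.
    """
    if len(pop_a) < 2 or len(pop_b) < 2:
        raise ValidationError("each population needs at least 2 sequences")
    arr = encode(pop_a + pop_b)
    arr = arr[:, (arr >= 0).all(axis=0)]
    _, labels = np.unique(arr, axis=0, return_inverse=True)
    return labels[: len(pop_a)], labels[len(pop_a):]


def _fst_from_labels(labels_a: np.ndarray, labels_b: np.ndarray,
                     weighting: str = "pairs") -> float:
    na, nb = len(labels_a), len(labels_b)
    k = int(max(labels_a.max(initial=0), labels_b.max(initial=0))) + 1
    ca = np.bincount(labels_a, minlength=k).astype(float)
    cb = np.bincount(labels_b, minlength=k).astype(float)

    same_a = float(np.sum(ca * (ca - 1)) / 2.0)
    same_b = float(np.sum(cb * (cb - 1)) / 2.0)
    pairs_a = na * (na - 1) / 2.0
    pairs_b = nb * (nb - 1) / 2.0
    if weighting == "pairs":
        h_w = 1.0 - (same_a + same_b) / (pairs_a + pairs_b)
    elif weighting == "unweighted":
        h_w = 1.0 - 0.5 * (same_a / pairs_a + same_b / pairs_b)
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")

    h_b = 1.0 - float(ca @ cb) / (na * nb)
    if h_b == 0.0:
        return 0.0
    return (h_b - h_w) / h_b


def pairwise_fst(pop_a: list[str], pop_b: list[str],
                 weighting: str = "pairs") -> float:
    """Haplotype-frequency F_ST between two populations of sequences.

    Symmetric in its arguments and invariant to haplotype relabelling.
    Both populations fixed for the same haplotype (H_b = 0) give 0.
    """
    la, lb = haplotype_labels(pop_a, pop_b)
    return _fst_from_labels(la, lb, weighting=weighting)


def pairwise_fst_brute_force(pop_a: list[str], pop_b: list[str]) -> float:
    """Independent oracle: enumerate every sequence pair explicitly."""
    la, lb = haplotype_labels(pop_a, pop_b)
    within = [(x, y) for grp in (la, lb) for x, y in combinations(grp, 2)]
    h_w = sum(x != y for x, y in within) / len(within)
    between = [(x, y) for x in la for y in lb]
    h_b = sum(x != y for x, y in between) / len(between)
    if h_b == 0.0:
        return 0.0
    return (h_b - h_w) / h_b


def permutation_test(pop_a: list[str], pop_b: list[str],
                     n_perm: int = 10000, seed: int | None = None,
                     weighting: str = "pairs") -> FstResult:
    """Permutation p-value for F_ST between two populations.

    Individual sequences are pooled and randomly re-partitioned into the
    original sample sizes ``n_perm`` times;
    p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    la, lb = haplotype_labels(pop_a, pop_b)
    obs = _fst_from_labels(la, lb, weighting=weighting)
    pooled = np.concatenate([la, lb])
    na = len(la)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if _fst_from_labels(perm[:na], perm[na:], weighting=weighting) >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return FstResult(pop_a="", pop_b="", fst=obs, p_value=p,
                     n_permutations=n_perm)


def permutation_test_exhaustive(pop_a: list[str], pop_b: list[str],
                                weighting: str = "pairs") -> float:
    """Exact p-value by enumerating every re-partition (tiny samples only)."""
    la, lb = haplotype_labels(pop_a, pop_b)
    obs = _fst_from_labels(la, lb, weighting=weighting)
    pooled = np.concatenate([la, lb])
    n = len(pooled)
    na = len(la)
    hits = total = 0
    for idx_a in combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx_a)] = True
        stat = _fst_from_labels(pooled[mask], pooled[~mask], weighting=weighting)
        total += 1
        if stat >= obs - 1e-12:
            hits += 1
    return hits / total


def fst_components(popset: AlignedPopulationSet) -> tuple[float, float]:
    """(H_w, H_b) diversity components pooled over all demes of a set.

    H_w is the pair-weighted probability that two sequences from the same
    population differ; H_b the probability over all cross-population
    pairs.  Components from replicate datasets can be summed before taking
    the ratio (the multilocus form), which removes the per-replicate
    ratio bias when validating against analytic F_ST expectations.
    """
    pops = popset.population_names
    if len(pops) < 2:
        raise ValidationError("need at least 2 populations")
    seqs: list[str] = []
    sizes: list[int] = []
    for pop in pops:
        s = popset.sequences(pop)
        seqs += s
        sizes.append(len(s))
    arr = encode(seqs)
    arr = arr[:, (arr >= 0).all(axis=0)]
    _, labels = np.unique(arr, axis=0, return_inverse=True)
    k = int(labels.max()) + 1
    counts = []
    start = 0
    for sz in sizes:
        counts.append(np.bincount(labels[start:start + sz],
                                  minlength=k).astype(float))
        start += sz
    same_w = pairs_w = same_b = pairs_b = 0.0
    for c in counts:
        same_w += float(np.sum(c * (c - 1)) / 2.0)
        n = c.sum()
        pairs_w += n * (n - 1) / 2.0
    for i in range(len(counts)):
        for j in range(i + 1, len(counts)):
            same_b += float(counts[i] @ counts[j])
            pairs_b += counts[i].sum() * counts[j].sum()
    return 1.0 - same_w / pairs_w, 1.0 - same_b / pairs_b


def global_fst(popset: AlignedPopulationSet) -> float:
    """Dataset-level F_ST: ratio of the pooled diversity components."""
    h_w, h_b = fst_components(popset)
    if h_b == 0.0:
        return 0.0
    return (h_b - h_w) / h_b


def apply_significance(results: list[FstResult], rule: str = "p01",
                       alpha: float = 0.05) -> list[FstResult]:
    """Flag significant pairwise comparisons.

    ``rule="p01"`` applies the fixed p < .01 criterion used for reporting;
    ``rule="by"`` applies the Benjamini-Yekutieli false-discovery-rate
    control recommended for pairwise F_ST tables.
    """
    if not results:
        return []
    pvals = np.array([r.p_value for r in results])
    if rule == "p01":
        flags = pvals < 0.01
    elif rule == "by":
        flags = multipletests(pvals, alpha=alpha, method="fdr_by")[0]
    else:
        raise ValidationError(f"unknown significance rule {rule!r}")
    for r, f in zip(results, flags):
        r.significant = bool(f)
    return results


def fst_matrix(popset: AlignedPopulationSet, n_perm: int = 10000,
               seed: int | None = None, rule: str = "p01",
               weighting: str = "pairs",
               ) -> tuple[LabeledDistanceMatrix, pd.DataFrame, float]:
    """All pairwise F_ST of one species with permutation significance.

    Returns the raw (unclamped) symmetric matrix, a long-format table
    (pair, fst, p, significant) and the percentage of significant
    comparisons rounded to the nearest integer.
    """
    pops = popset.population_names
    if len(pops) < 2:
        raise ValidationError("need at least 2 populations for an F_ST matrix")
    k = len(pops)
    values = np.zeros((k, k))
    results: list[FstResult] = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(k * (k - 1) // 2)
    idx = 0
    for i in range(k):
        for j in range(i + 1, k):
            res = permutation_test(
                popset.sequences(pops[i]), popset.sequences(pops[j]),
                n_perm=n_perm, seed=child_seeds[idx], weighting=weighting)
            idx += 1
            res.pop_a, res.pop_b = pops[i], pops[j]
            values[i, j] = values[j, i] = res.fst
            results.append(res)
    apply_significance(results, rule=rule)
    percent = round(100.0 * sum(r.significant for r in results) / len(results))
    table = pd.DataFrame([{
        "pop_a": r.pop_a, "pop_b": r.pop_b, "fst": r.fst,
        "fst_clamped": max(r.fst, 0.0), "p_value": r.p_value,
        "significant": r.significant,
    } for r in results])
    matrix = LabeledDistanceMatrix(labels=pops, values=values, kind="fst")
    return matrix, table, float(percent)
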