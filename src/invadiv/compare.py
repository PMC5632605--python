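"""Group comparisons and distance models for differentiation.

The headline question is whether species that have invaded outside their
native range carry less population structure at home than species that
never spread.  Three ingredients:

* Mann-Whitney-Wilcoxon rank tests (midranks for ties) comparing diversity
  indices, and distance-normalised pairwise F_ST, between the invasive and
  non-invasive species groups over native-range populations.  The reported
  W is the U statistic of the first (invasive) group.
* Per-species normalisation of F_ST by the mean log10 geographic distance
  of that species' matrix, so that species sampled over different spatial
  extents become comparable.
* Ordinary least squares ``F_ST ~ evolutionary distance + log10 geographic
  distance`` over population pairs, fitted within geographically coherent
  subsets (species spanning a large break are split by region first).

Pairwise observations are not independent, so OLS p-values are
anti-conservative; a Mantel-style permutation p-value for the geographic
term is available via ``mantel_permutations``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .dataio import (LabeledDistanceMatrix, PopulationMetadata,
                     ValidationError, load_study_indices)

logger = logging.getLogger("invadiv")

#: Range-label corrections applied before the invasive/non-invasive
#: comparison: these two G. tigrinus sites (Saint John, Canada and the
#: Neuse River, North Carolina) lie on the Atlantic coast of North America,
#: inside the species' documented native range, so their bundled
#: "non_native" labels are treated as typesetting errors.
NATIVE_RANGE_CORRECTIONS = {
    ("G. tigrinus", "St.John"): "native",
    ("G. tigrinus", "Neuse"): "native",
}


def study_table(apply_range_corrections: bool = True) -> pd.DataFrame:
    """The bundled per-population diversity table of the seven-species study.

    With ``apply_range_corrections=True`` the two distribution labels in
    :data:`NATIVE_RANGE_CORRECTIONS` are replaced; the raw table is
    returned otherwise.
    """
    df = load_study_indices()
    if apply_range_corrections:
        for (species, population), label in NATIVE_RANGE_CORRECTIONS.items():
            mask = (df.species == species) & (df.population == population)
            df.loc[mask, "distribution"] = label
    return df


@dataclass
class GroupComparisonResult:
    """Mann-Whitney comparison of one quantity between two groups."""

    index_name: str
    n_first: int
    n_second: int
    U: float               # rank-based U of the first group (reported as W)
    U_second: float
    z: float
    p_value: float
    mean_first: float
    mean_second: float
    method: str


@dataclass
class RegressionResult:
    """OLS fit of F_ST against evolutionary and geographic distance."""

    terms: pd.DataFrame    # index: term; columns: estimate, se, t, p
    r_squared: float
    model_p: float
    n_pairs: int


def mann_whitney(x, y, index_name: str = "",
                 alternative: str = "two-sided") -> GroupComparisonResult:
    """Mann-Whitney-Wilcoxon rank-sum test with midranks for ties.

    The exact null distribution is used when n1*n2 <= 400 and there are no
    ties; otherwise the normal approximation with tie-corrected variance
    and continuity correction.  ``U`` is the statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)           # midranks
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u2 = n1 * n2 - u1

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    method = "exact" if (n1 * n2 <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)

    n = n1 + n2
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    mu = n1 * n2 / 2.0
    if sigma2 > 0:
        cc = 0.5 * np.sign(u1 - mu)
        z = (u1 - mu - cc) / np.sqrt(sigma2)
    else:
        z = 0.0
    return GroupComparisonResult(
        index_name=index_name, n_first=n1, n_second=n2,
        U=u1, U_second=u2, z=float(z), p_value=float(res.pvalue),
        mean_first=float(x.mean()), mean_second=float(y.mean()),
        method=method,
    )


def compare_invasive_vs_noninvasive(table: pd.DataFrame, index_name: str,
                                    native_only: bool = True,
                                    ) -> GroupComparisonResult:
    """Compare one diversity index between invasive and non-invasive species.

    ``table`` needs columns ``status``, ``distribution`` and the index.
    Only native-range populations enter by default.  The invasive group is
    first (its U is the reported W).
    """
    df = table
    if native_only:
        df = df[df.distribution == "native"]
    inv = df[df.status == "invasive"][index_name]
    non = df[df.status == "non_invasive"][index_name]
    if inv.empty or non.empty:
        raise ValidationError(
            f"a group has no native populations for index {index_name!r}"
        )
    return mann_whitney(inv.to_numpy(), non.to_numpy(), index_name=index_name)


# ---------------------------------------------------------------------------
# Distance-normalised structure comparison
# ---------------------------------------------------------------------------

def normalize_fst_by_distance(fst: LabeledDistanceMatrix,
                              geo_log: LabeledDistanceMatrix,
                              ) -> tuple[dict[tuple[str, str], float], float]:
    """Divide every pairwise F_ST by the species' mean log10 distance.

    The scalar m is the mean of the upper-triangle log10 geographic
    distances of the same population set; each species is normalised
    independently.  Returns (pair -> normalised value, m).
    """
    if fst.labels != geo_log.labels:
        raise ValidationError("F_ST and geographic matrices have different labels")
    if geo_log.kind != "geographic_log10":
        raise ValidationError("normalisation expects a log10 geographic matrix")
    tri = [v for _, _, v in geo_log.pairs()]
    m = float(np.mean(tri))
    if m <= 0:
        raise ValidationError(
            f"mean log10 distance m={m:.3f} <= 0: sites too close together"
        )
    return {(a, b): v / m for a, b, v in fst.pairs()}, m


def compare_structure(normalized_by_species: dict[str, dict],
                      status_by_species: dict[str, str],
                      pooling: str = "pairs",
                      alternative: str = "two-sided") -> GroupComparisonResult:
    """Compare normalised F_ST between invasive and non-invasive species.

    ``pooling="pairs"`` pools every per-pair normalised value within each
    group; ``pooling="species_means"`` compares one mean per species.
    The invasive group is first.
    """
    groups = {"invasive": [], "non_invasive": []}
    for species, pairs in normalized_by_species.items():
        status = status_by_species[species]
        vals = list(pairs.values())
        if pooling == "pairs":
            groups[status].extend(vals)
        elif pooling == "species_means":
            groups[status].append(float(np.mean(vals)))
        else:
            raise ValidationError(f"unknown pooling {pooling!r}")
    if not groups["invasive"] or not groups["non_invasive"]:
        raise ValidationError("a group contributes no F_ST pairs")
    return mann_whitney(groups["invasive"], groups["non_invasive"],
                        index_name=f"normalized_fst[{pooling}]",
                        alternative=alternative)


# ---------------------------------------------------------------------------
# Regional partitioning and distance models
# ---------------------------------------------------------------------------

def partition_by_region(metadata: list[PopulationMetadata],
                        keep_whole: set[str] = frozenset(),
                        known_regions: dict[str, list[str]] | None = None,
                        min_populations: int = 4,
                        ) -> dict[tuple[str, str], dict]:
    """Split each species' populations into geographically coherent subsets.

    Species in ``keep_whole`` (e.g. one whose sites are linked by a
    stepping-stone locality) are not split and keep the region label
    ``"all"``.  ``known_regions`` optionally declares the admissible region
    labels per species; an undeclared label raises.  Subsets with fewer
    than ``min_populations`` populations are flagged ``regressable=False``
    (too few pairs to fit an intercept plus two predictors).
    """
    out: dict[tuple[str, str], dict] = {}
    for meta in metadata:
        if known_regions is not None and meta.species in known_regions:
            if meta.region not in known_regions[meta.species]:
                raise ValidationError(
                    f"unknown region label {meta.region!r} for species "
                    f"{meta.species!r}"
                )
        region = "all" if meta.species in keep_whole else meta.region
        key = (meta.species, region)
        out.setdefault(key, {"populations": []})["populations"].append(
            meta.population)
    for key, subset in out.items():
        subset["regressable"] = len(subset["populations"]) >= min_populations
    return out


def fit_ibd_ibe_model(fst_pairs, d_pairs, geolog_pairs) -> RegressionResult:
    """OLS of pairwise F_ST on evolutionary and log10 geographic distance.

    All three vectors are aligned by population pair.  Per-term t and
    two-sided p use normal-theory OLS; the overall F-test p and R^2 are
    also reported.  A rank-deficient design (collinear predictors) raises.
    """
    y = np.asarray(fst_pairs, dtype=float)
    d = np.asarray(d_pairs, dtype=float)
    g = np.asarray(geolog_pairs, dtype=float)
    if not (y.size == d.size == g.size):
        raise ValidationError("pair vectors have different lengths")
    if y.size < 4:
        raise ValidationError(
            f"need at least 4 pairs to fit 3 parameters, got {y.size}"
        )
    X = sm.add_constant(np.column_stack([d, g]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            "collinear design: evolutionary and geographic distances "
            "(with intercept) are linearly dependent"
        )
    fit = sm.OLS(y, X).fit()
    terms = pd.DataFrame({
        "estimate": fit.params,
        "se": fit.bse,
        "t": fit.tvalues,
        "p": fit.pvalues,
    })
    terms.index = ["intercept", "evolutionary_distance", "geographic_distance"]
    return RegressionResult(terms=terms, r_squared=float(fit.rsquared),
                            model_p=float(fit.f_pvalue), n_pairs=int(y.size))


def ibd_regression(fst_pairs, geolog_pairs) -> RegressionResult:
    """OLS of pairwise F_ST on log10 geographic distance alone.

    This is the classical isolation-by-distance test.  It is the right
    form for power checks on spatially explicit simulations: adding the
    evolutionary-distance covariate there is uninformative, because that
    covariate is computed from the same realized genealogy as F_ST itself
    and absorbs the geographic signal.
    """
    y = np.asarray(fst_pairs, dtype=float)
    g = np.asarray(geolog_pairs, dtype=float)
    if y.size != g.size:
        raise ValidationError("pair vectors have different lengths")
    if y.size < 3:
        raise ValidationError("need at least 3 pairs for a slope")
    X = sm.add_constant(g)
    fit = sm.OLS(y, X).fit()
    terms = pd.DataFrame({
        "estimate": fit.params, "se": fit.bse,
        "t": fit.tvalues, "p": fit.pvalues,
    })
    terms.index = ["intercept", "geographic_distance"]
    return RegressionResult(terms=terms, r_squared=float(fit.rsquared),
                            model_p=float(fit.f_pvalue), n_pairs=int(y.size))


def mantel_permutations(fst: LabeledDistanceMatrix,
                        predictor: LabeledDistanceMatrix,
                        n_perm: int = 999,
                        seed: int | None = None) -> float:
    """Mantel permutation p-value for the correlation of two pair matrices.

    Population labels of one matrix are permuted jointly over rows and
    columns, which respects the dependence structure that plain OLS on
    pairs ignores.
    """
    if fst.labels != predictor.labels:
        raise ValidationError("matrices have different labels")
    k = len(fst.labels)
    iu = np.triu_indices(k, 1)
    obs = np.corrcoef(fst.values[iu], predictor.values[iu])[0, 1]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        r = np.corrcoef(fst.values[np.ix_(perm, perm)][iu],
                        predictor.values[iu])[0, 1]
        if r >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def pair_vectors(*matrices: LabeledDistanceMatrix) -> list[np.ndarray]:
    """Aligned upper-triangle value vectors from label-matched matrices."""
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise ValidationError("matrices have different labels")
    k = len(labels)
    iu = np.triu_indices(k, 1)
    return [m.values[iu] for m in matrices]
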