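"""Coalescent generator for multi-population haplotype datasets with truth.

Samples are haploid (one mtDNA sequence per individual) and drawn from a
structured coalescent: within a deme two lineages coalesce at rate 1 (time
in units of the deme size), and each lineage migrates according to a
per-deme rate matrix.  Mutations are laid on the genealogy as
Poisson(theta * branch length) events, each hitting a uniformly chosen
site and substituting one of the three other bases (Jukes-Cantor); multiple
hits are allowed, so tests should use the realized rather than the nominal
divergence.

Two spatial arrangements are provided.  The *island* model migrates every
lineage to a uniformly chosen other deme at total rate M (d-1)/d, the
finite-deme calibration under which the classical low-mutation expectation

    F_ST = 1 / (1 + 2 M)

holds for any number of demes.  The *stepping-stone* arrangement places
demes on a line with migration only between neighbours, which generates
isolation by distance.  An optional deep split partitions demes among
divergent ancestral lineages, mimicking the deep intraspecific clades
typical of gammarid mtDNA.

A deterministic worked-example builder constructs tiny alignments with
exact haplotype counts and pairwise differences for analytic tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dataio import (AlignedPopulationSet, PopulationMetadata, SequenceRecord,
                     ValidationError)

logger = logging.getLogger("invadiv")

_ALPHABET = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    theta is the scaled mutation rate per locus per unit coalescent time;
    migration is the island-model M (stepping stone: the per-neighbour
    rate); lineage_divergence is the expected per-site difference between
    the ancestral sequences of deep clades.
    """

    n_populations: int = 6
    n_per_population: int = 10
    sequence_length: int = 509
    theta: float = 0.5
    migration: float = 1.0
    n_lineages: int = 1
    lineage_divergence: float = 0.0
    latitude: float = 54.0
    longitude: float = 10.0
    deme_spacing_km: float = 100.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_populations < 1 or self.n_per_population < 1:
            raise ValidationError("population counts must be >= 1")
        if self.sequence_length < 1:
            raise ValidationError("sequence_length must be >= 1")
        if self.theta < 0 or self.migration < 0 or self.lineage_divergence < 0:
            raise ValidationError("rates must be >= 0")
        if self.n_lineages < 1 or self.n_lineages > self.n_populations:
            raise ValidationError(
                "n_lineages must be between 1 and n_populations")


@dataclass
class SyntheticTruth:
    """Generator-side truth retained for parameter-recovery tests."""

    config: SimulationConfig
    expected_fst: float
    realized_lineage_divergence: dict = field(default_factory=dict)
    genealogy: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.expected_fst < 1.0:
            raise ValidationError("expected_fst must be in [0, 1)")


# ---------------------------------------------------------------------------
# Structured coalescent
# ---------------------------------------------------------------------------

def _simulate_genealogy(samples_per_deme: list[int], mig: np.ndarray,
                        rng: np.random.Generator):
    """Coalescent genealogy for one connected set of demes.

    ``mig[i, j]`` is the per-lineage rate of moving from deme i to deme j.
    Returns (parent, blen, n_leaves, height, total_length); leaves are
    numbered deme-major.
    """
    d = len(samples_per_deme)
    lineages: list[tuple[int, int]] = []       # (node id, deme)
    nid = 0
    for deme, k in enumerate(samples_per_deme):
        for _ in range(k):
            lineages.append((nid, deme))
            nid += 1
    n_leaves = nid
    times = dict.fromkeys(range(n_leaves), 0.0)
    parent: dict[int, int] = {}
    blen: dict[int, float] = {}
    t = 0.0
    total_length = 0.0
    out_rate = mig.sum(axis=1)

    while len(lineages) > 1:
        per_deme = np.zeros(d, dtype=int)
        for _, deme in lineages:
            per_deme[deme] += 1
        coal = per_deme * (per_deme - 1) / 2.0
        mig_rates = np.array([out_rate[deme] for _, deme in lineages])
        total = coal.sum() + mig_rates.sum()
        if total <= 0:
            raise ValidationError(
                "genealogy cannot complete: isolated lineages with no "
                "migration path")
        dt = rng.exponential(1.0 / total)
        t += dt
        total_length += dt * len(lineages)
        u = rng.random() * total
        if u < coal.sum():
            # coalescence in the deme selected proportionally to its pairs
            deme = int(np.searchsorted(np.cumsum(coal), u, side="right"))
            idx = [i for i, (_, dm) in enumerate(lineages) if dm == deme]
            pick = rng.choice(len(idx), size=2, replace=False)
            i, j = sorted((idx[pick[0]], idx[pick[1]]), reverse=True)
            (a, _), (b, _) = lineages[i], lineages[j]
            new = nid
            nid += 1
            times[new] = t
            for child in (a, b):
                parent[child] = new
                blen[child] = t - times[child]
            del lineages[i], lineages[j]
            lineages.append((new, deme))
        else:
            u -= coal.sum()
            k = int(np.searchsorted(np.cumsum(mig_rates), u, side="right"))
            node, deme = lineages[k]
            dest_p = mig[deme] / out_rate[deme]
            dest = int(rng.choice(d, p=dest_p))
            lineages[k] = (node, dest)
    root = lineages[0][0]
    return parent, blen, n_leaves, root, times[root], total_length


def _drop_mutations(parent, blen, n_leaves, root, root_seq, theta,
                    rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor mutations: Poisson(theta * branch length) per branch."""
    L = root_seq.size
    children: dict[int, list[int]] = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)
    seqs = {root: root_seq}
    stack = [root]
    while stack:
        node = stack.pop()
        for child in sorted(children.get(node, [])):
            seq = seqs[node].copy()
            n_mut = rng.poisson(theta * blen[child])
            for _ in range(n_mut):
                site = rng.integers(L)
                seq[site] = (seq[site] + 1 + rng.integers(3)) % 4
            seqs[child] = seq
            stack.append(child)
    return np.stack([seqs[i] for i in range(n_leaves)])


def _line_coordinates(config: SimulationConfig) -> list[tuple[float, float]]:
    """Demes placed on an east-west line with the configured spacing."""
    km_per_deg = 111.195 * math.cos(math.radians(config.latitude))
    step = config.deme_spacing_km / km_per_deg
    return [(config.latitude, config.longitude + i * step)
            for i in range(config.n_populations)]


def _assemble(config: SimulationConfig, matrix: np.ndarray,
              species: str) -> AlignedPopulationSet:
    records = []
    row = 0
    for deme in range(config.n_populations):
        pop = f"pop{deme + 1:02d}"
        for i in range(config.n_per_population):
            records.append(SequenceRecord(
                id=f"{species}_{pop}_{i + 1:03d}", population=pop,
                sequence="".join(_ALPHABET[matrix[row]])))
            row += 1
    return AlignedPopulationSet(species=species, records=records,
                                alignment_length=config.sequence_length)


#: Migration rate beyond which the strong-migration (panmictic) limit is
#: simulated directly, keeping the event count bounded.
PANMICTIC_MIGRATION = 1000.0


def _simulate(config: SimulationConfig, mig: np.ndarray, expected_fst: float,
              species: str, panmictic: bool = False,
              ) -> tuple[AlignedPopulationSet, SyntheticTruth]:
    rng = np.random.default_rng(config.seed)
    d = config.n_populations
    L = config.sequence_length
    # warn (via truth) when theta implies heavy multiple hits
    clades = np.array_split(np.arange(d), config.n_lineages)
    base = rng.integers(0, 4, size=L).astype(np.int8)
    ancestors = []
    for _ in clades:
        anc = base.copy()
        n_sub = rng.binomial(L, min(config.lineage_divergence / 2.0, 1.0))
        sites = rng.choice(L, size=n_sub, replace=False)
        anc[sites] = (anc[sites] + 1 + rng.integers(3, size=n_sub)) % 4
        ancestors.append(anc)
    realized = {}
    for a in range(len(clades)):
        for b in range(a + 1, len(clades)):
            realized[(a, b)] = float(np.mean(ancestors[a] != ancestors[b]))

    blocks = []
    genealogy = {}
    for ci, demes in enumerate(clades):
        if panmictic:
            sub_mig = np.zeros((1, 1))
            samples = [config.n_per_population * len(demes)]
        else:
            sub_mig = mig[np.ix_(demes, demes)]
            samples = [config.n_per_population] * len(demes)
        parent, blen, n_leaves, root, height, tot = _simulate_genealogy(
            samples, sub_mig, rng)
        blocks.append(_drop_mutations(parent, blen, n_leaves, root,
                                      ancestors[ci], config.theta, rng))
        genealogy[f"clade{ci}"] = {
            "demes": [int(x) for x in demes], "tmrca": height,
            "tree_length": tot,
        }
    matrix = np.vstack(blocks)
    expected_mutations = config.theta * sum(
        g["tree_length"] for g in genealogy.values())
    if expected_mutations > 0.5 * L:
        logger.warning(
            "theta=%g implies ~%.0f mutations over %d sites: heavy multiple "
            "hits; realized divergence will undershoot the nominal rate",
            config.theta, expected_mutations, L)
    truth = SyntheticTruth(config=config, expected_fst=expected_fst,
                           realized_lineage_divergence=realized,
                           genealogy=genealogy)
    return _assemble(config, matrix, species), truth


def simulate_island_model(config: SimulationConfig, species: str = "sim",
                          ) -> tuple[AlignedPopulationSet, SyntheticTruth]:
    """Symmetric island-model dataset with analytic F_ST expectation.

    Every lineage leaves its deme at total rate M (d-1)/d toward a uniform
    other deme (within its ancestral clade when a deep split is
    configured), so that the haploid expectation F_ST = 1/(1+2M) holds in
    the low-mutation limit regardless of the number of demes.
    """
    d = config.n_populations
    mig = np.zeros((d, d))
    if d > 1:
        per_pair = config.migration / d     # row sum = M (d-1)/d
        mig[:] = per_pair
        np.fill_diagonal(mig, 0.0)
    expected = 1.0 / (1.0 + 2.0 * config.migration) if config.migration > 0 else 1.0 - 1e-12
    if config.migration == 0 and (d > config.n_lineages):
        raise ValidationError(
            "migration 0 disconnects demes within a clade; genealogy "
            "cannot complete")
    return _simulate(config, mig, min(expected, 1.0 - 1e-12), species,
                     panmictic=config.migration >= PANMICTIC_MIGRATION)


def simulate_ibd_landscape(config: SimulationConfig, species: str = "sim",
                           ) -> tuple[AlignedPopulationSet, SyntheticTruth,
                                      list[PopulationMetadata]]:
    """Stepping-stone dataset: demes on a line, migration between neighbours.

    Pairwise F_ST increases with separation along the line, so the dataset
    correlates positively with log10 geographic distance.  Returns the
    alignment, the truth record and per-deme metadata with coordinates.
    """
    d = config.n_populations
    if d < 3:
        raise ValidationError("isolation by distance needs >= 3 populations")
    if config.migration <= 0:
        raise ValidationError("stepping-stone migration must be > 0")
    mig = np.zeros((d, d))
    for i in range(d - 1):
        mig[i, i + 1] = mig[i + 1, i] = config.migration
    popset, truth = _simulate(config, mig, 1.0 / (1.0 + 2.0 * config.migration),
                              species)
    coords = _line_coordinates(config)
    metadata = [
        PopulationMetadata(
            population=f"pop{i + 1:02d}", species=species, status="invasive",
            distribution="native", region="all", latitude=lat, longitude=lon,
            n=config.n_per_population)
        for i, (lat, lon) in enumerate(coords)
    ]
    return popset, truth, metadata


# ---------------------------------------------------------------------------
# Deterministic worked examples
# ---------------------------------------------------------------------------

def make_worked_example(spec: dict[str, list[tuple[int, int]]] | list[tuple[int, int]],
                        length: int = 509,
                        species: str = "worked") -> AlignedPopulationSet:
    """Alignment realizing exact haplotype counts and site differences.

    ``spec`` maps population name -> list of (copies, n_diff) where
    ``n_diff`` is the number of sites at which that haplotype differs from
    a common all-A backbone; a bare list means a single population.  Within
    each population the haplotypes occupy consecutive disjoint site blocks
    starting at site 0, so two haplotypes of one population differ at
    ``n_diff_i + n_diff_j`` sites, and haplotypes with the same (cumulative
    block, n_diff) are shared across populations.  Two zero-difference
    haplotypes in one population would coincide, which is an inconsistent
    specification and raises.
    """
    if isinstance(spec, list):
        spec = {"pop1": spec}
    records = []
    for pop, haps in spec.items():
        if not haps:
            raise ValidationError(f"population {pop!r} has no haplotypes")
        if sum(1 for _, n_diff in haps if n_diff == 0) > 1:
            raise ValidationError(
                f"population {pop!r}: two haplotypes with 0 differing "
                "sites coincide (inconsistent specification)")
        offset = 0
        for h, (copies, n_diff) in enumerate(haps):
            if copies < 1:
                raise ValidationError("haplotype copy number must be >= 1")
            if offset + n_diff > length:
                raise ValidationError(
                    f"haplotype spec needs {offset + n_diff} variant sites "
                    f"but length is {length}")
            seq = ["A"] * length
            for s in range(offset, offset + n_diff):
                seq[s] = "C"
            offset += n_diff
            for c in range(copies):
                records.append(SequenceRecord(
                    id=f"{pop}_h{h + 1}_{c + 1:03d}", population=pop,
                    sequence="".join(seq)))
    return AlignedPopulationSet(species=species, records=records,
                                alignment_length=length)


def metadata_for(popset: AlignedPopulationSet, status: str = "invasive",
                 distribution: str = "native", region: str = "all",
                 latitude: float = 54.0, longitude: float = 10.0,
                 spacing_km: float = 100.0) -> list[PopulationMetadata]:
    """Convenience metadata for a simulated set: demes on an east-west line."""
    km_per_deg = 111.195 * math.cos(math.radians(latitude))
    out = []
    for i, pop in enumerate(popset.population_names):
        out.append(PopulationMetadata(
            population=pop, species=popset.species, status=status,
            distribution=distribution, region=region, latitude=latitude,
            longitude=longitude + i * spacing_km / km_per_deg,
            n=len(popset.populations[pop])))
    return out


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """A copy of ``config`` with a different seed (replicate helper)."""
    return replace(config, seed=seed)
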