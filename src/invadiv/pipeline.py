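"""End-to-end orchestration: trim -> indices -> F_ST -> distances -> trees
-> group comparisons -> distance models, per species, from one config.

Every quantity in the report is produced by a module operation; the
orchestrator only wires stages together, derives per-stage RNG seeds from
the root seed by stable hashing, and records every exclusion decision in
the log.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import compare, dataio, diversity, evolution, fst, geo

logger = logging.getLogger("invadiv")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending species."""

    def __init__(self, stage: str, species: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for species {species!r}: {cause}")
        self.stage = stage
        self.species = species
        self.cause = cause


@dataclass
class RunConfig:
    """One pipeline run.  Defaults mirror the study protocol:
    10,000 F_ST permutations, 1,000 bootstraps condensed at 75%."""

    fasta: list[str] = field(default_factory=list)
    metadata: str = ""
    outdir: str = "invadiv_out"
    min_n: int = 5
    min_coverage: float = 0.9
    permutations: int = 10000
    bootstraps: int = 1000
    condense_threshold: float = 75.0
    significance_rule: str = "p01"
    model: str = "auto"
    seed: int = 0
    keep_whole: list[str] = field(default_factory=list)
    known_regions: dict | None = None
    min_populations_regression: int = 4

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise dataio.ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


def stage_seed(root_seed: int, stage: str, species: str = "") -> np.random.SeedSequence:
    """Deterministic per-stage seed derived from the root seed by hashing."""
    tag = zlib.crc32(f"{stage}:{species}".encode("utf-8"))
    return np.random.SeedSequence([int(root_seed), int(tag)])


def _species_model(popset, model_name: str):
    if model_name == "auto":
        seqs = [r.sequence for r in popset.records]
        return evolution.select_model(seqs, [r.id for r in popset.records])
    gamma = model_name.endswith("+G")
    base = model_name[:-2] if gamma else model_name
    params = {}
    if base in ("K2P", "HKY85"):
        params = {"kappa": 2.0}
    elif base == "TN93":
        params = {"kappa1": 2.0, "kappa2": 2.0}
    return evolution.SubstitutionModel(
        name=base, gamma=gamma, gamma_shape=0.5 if gamma else None,
        params=params)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full per-species workflow plus the cross-species block.

    Returns the report dict (also written to ``<outdir>/report.json``
    together with per-species TSV/newick artifacts).  Any stage error is
    re-raised as :class:`PipelineError` naming the stage and species;
    artifacts of completed stages are preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metadata = dataio.read_metadata(config.metadata)
    meta_by_species: dict[str, list] = {}
    for m in metadata:
        meta_by_species.setdefault(m.species, []).append(m)

    report: dict = {"seed": config.seed, "species": {}, "comparisons": {}}
    normalized: dict[str, dict] = {}
    status_by_species: dict[str, str] = {}
    indices_frames = []
    per_species_matrices: dict[str, dict] = {}

    for fasta_path in config.fasta:
        species = Path(fasta_path).stem
        sdir = outdir / species
        sdir.mkdir(exist_ok=True)
        try:
            records = dataio.read_fasta(fasta_path)
            popset = dataio.trim_to_common_window(
                records, species=species, min_coverage=config.min_coverage,
                min_n=config.min_n)
            dataio.reconcile_with_metadata(popset, metadata)
        except Exception as exc:
            raise PipelineError("ingest", species, exc)

        smeta = [m for m in meta_by_species.get(species, [])
                 if m.population in popset.populations]
        if smeta:
            status_by_species[species] = smeta[0].status

        try:
            div = diversity.diversity_table(popset)
            meta_lookup = {m.population: m for m in smeta}
            div["status"] = [getattr(meta_lookup.get(p), "status", "")
                             for p in div.population]
            div["distribution"] = [getattr(meta_lookup.get(p), "distribution", "")
                                   for p in div.population]
            dataio.write_indices(div, sdir / "indices.tsv")
            indices_frames.append(div)
        except Exception as exc:
            raise PipelineError("diversity", species, exc)

        species_report: dict = {
            "populations": popset.population_names,
            "alignment_length": popset.alignment_length,
        }
        try:
            if len(popset.populations) >= 2:
                seed = stage_seed(config.seed, "fst", species)
                matrix, table, percent = fst.fst_matrix(
                    popset, n_perm=config.permutations,
                    seed=seed.generate_state(1)[0] & 0x7FFFFFFF,
                    rule=config.significance_rule)
                dataio.write_matrix(matrix, sdir / "fst_matrix.tsv")
                table.to_csv(sdir / "fst_pairs.tsv", sep="\t", index=False)
                clamped = np.maximum(matrix.values, 0.0)
                species_report["fst"] = {
                    "percent_significant": percent,
                    "range": [float(clamped[np.triu_indices_from(clamped, 1)].min()),
                              float(clamped[np.triu_indices_from(clamped, 1)].max())],
                }
                per_species_matrices.setdefault(species, {})["fst"] = matrix
        except Exception as exc:
            raise PipelineError("fst", species, exc)

        try:
            model = _species_model(popset, config.model)
            species_report["model"] = {
                "name": model.label, "params": model.params,
                "gamma_shape": model.gamma_shape, "bic": model.bic,
            }
            pops = popset.population_names
            if len(pops) >= 2:
                k = len(pops)
                dmat = np.zeros((k, k))
                for i in range(k):
                    for j in range(i + 1, k):
                        dmat[i, j] = dmat[j, i] = \
                            evolution.mean_between_population_distance(
                                popset.sequences(pops[i]),
                                popset.sequences(pops[j]), model)
                dmatrix = dataio.LabeledDistanceMatrix(
                    labels=pops, values=dmat, kind="evolutionary")
                dataio.write_matrix(dmatrix, sdir / "d_matrix.tsv")
                per_species_matrices.setdefault(species, {})["d"] = dmatrix
        except Exception as exc:
            raise PipelineError("evolution", species, exc)

        try:
            if len(popset.records) >= 3:
                seed = stage_seed(config.seed, "bootstrap", species)
                tree = evolution.bootstrap_condense(
                    [r.sequence for r in popset.records],
                    [r.id for r in popset.records], model,
                    n_boot=config.bootstraps,
                    threshold=config.condense_threshold,
                    seed=seed.generate_state(1)[0] & 0x7FFFFFFF)
                dataio.write_tree(tree.newick, sdir / "tree.nwk")
        except Exception as exc:
            raise PipelineError("tree", species, exc)

        try:
            if smeta and len(smeta) >= 2:
                ordered = sorted(smeta, key=lambda m: popset.population_names.index(m.population))
                gkm = geo.geographic_matrix(ordered)
                glog = geo.log10_transform(gkm)
                dataio.write_matrix(gkm, sdir / "geo_km.tsv")
                dataio.write_matrix(glog, sdir / "geo_log10.tsv")
                per_species_matrices.setdefault(species, {})["geo_log"] = glog
                if "fst" in per_species_matrices.get(species, {}):
                    fmat = per_species_matrices[species]["fst"]
                    # align label order before normalising
                    if fmat.labels == glog.labels:
                        norm, m = compare.normalize_fst_by_distance(fmat, glog)
                        normalized[species] = norm
                        species_report["mean_log10_distance"] = m
        except Exception as exc:
            raise PipelineError("geography", species, exc)

        report["species"][species] = species_report

    # ----- cross-species comparison block -----
    if indices_frames:
        import pandas as pd
        all_idx = pd.concat(indices_frames, ignore_index=True)
        mw = {}
        for col in ("S", "Hd", "pi"):
            try:
                res = compare.compare_invasive_vs_noninvasive(all_idx, col)
                mw[col] = dataclasses.asdict(res)
            except dataio.ValidationError as exc:
                logger.warning("diversity comparison for %s skipped: %s",
                               col, exc)
        report["comparisons"]["diversity_mann_whitney"] = mw

    if normalized and status_by_species:
        contrasts = {}
        for pooling in ("pairs", "species_means"):
            try:
                res = compare.compare_structure(normalized, status_by_species,
                                                pooling=pooling)
                contrasts[pooling] = dataclasses.asdict(res)
            except dataio.ValidationError as exc:
                logger.warning("structure contrast (%s) skipped: %s",
                               pooling, exc)
        report["comparisons"]["normalized_fst_contrast"] = contrasts

    regressions = {}
    partitions = compare.partition_by_region(
        metadata, keep_whole=set(config.keep_whole),
        known_regions=config.known_regions,
        min_populations=config.min_populations_regression)
    for (species, region), subset in partitions.items():
        mats = per_species_matrices.get(species)
        if not subset["regressable"] or not mats:
            continue
        needed = {"fst", "d", "geo_log"}
        if not needed <= set(mats):
            continue
        pops = [p for p in mats["fst"].labels if p in subset["populations"]]
        if len(pops) < config.min_populations_regression:
            continue
        def _sub(mat):
            idx = [mat.labels.index(p) for p in pops]
            return dataio.LabeledDistanceMatrix(
                labels=pops, values=mat.values[np.ix_(idx, idx)],
                kind=mat.kind)
        fv, dv, gv = compare.pair_vectors(_sub(mats["fst"]), _sub(mats["d"]),
                                          _sub(mats["geo_log"]))
        try:
            res = compare.fit_ibd_ibe_model(fv, dv, gv)
        except dataio.ValidationError as exc:
            logger.warning("regression (%s, %s) skipped: %s",
                           species, region, exc)
            continue
        regressions[f"{species}|{region}"] = {
            "terms": res.terms.to_dict(orient="index"),
            "r_squared": res.r_squared, "model_p": res.model_p,
            "n_pairs": res.n_pairs,
        }
    report["comparisons"]["regressions"] = regressions

    dataio.write_report(report, outdir / "report.json")
    return report


def reproduce_study(manifest: str | None = None, metadata: str | None = None,
                    outdir: str = "invadiv_reproduce", seed: int = 0) -> dict:
    """Re-run the study protocol on user-supplied sequence data.

    The study's sequences live in a public archive and are not bundled;
    without a ``manifest`` (TSV with columns ``species`` and ``fasta``
    pointing at downloaded per-species FASTA files) this runs in
    fixture-only mode: it recomputes the invasive versus non-invasive
    Mann-Whitney comparisons from the bundled per-population index table
    and reports them.
    """
    if manifest is None:
        logger.info("no manifest supplied: running fixture-only mode "
                    "(bundled index table; supply downloaded sequences to "
                    "recompute everything else)")
        table = compare.study_table()
        out = {"mode": "fixture-only", "mann_whitney": {}}
        for col in ("S", "Hd", "pi"):
            res = compare.compare_invasive_vs_noninvasive(table, col)
            out["mann_whitney"][col] = dataclasses.asdict(res)
        Path(outdir).mkdir(parents=True, exist_ok=True)
        dataio.write_report(out, Path(outdir) / "reproduce.json")
        return out

    import pandas as pd
    man = pd.read_csv(manifest, sep="\t")
    if not {"species", "fasta"} <= set(man.columns):
        raise dataio.ValidationError(
            "manifest needs tab-separated columns 'species' and 'fasta'")
    fastas = [row.fasta for row in man.itertuples()]
    if metadata is None:
        raise dataio.ValidationError(
            "reproduction from sequences needs a metadata table with "
            "coordinates (not printed in the study; user-supplied)")
    config = RunConfig(fasta=fastas, metadata=metadata, outdir=outdir,
                       seed=seed)
    report = run_pipeline(config)
    # cross-check computed indices against the bundled study table
    table = dataio.load_study_indices()
    mismatches = []
    for sdir in Path(outdir).iterdir():
        idx_path = sdir / "indices.tsv"
        if not idx_path.exists():
            continue
        computed = dataio.read_indices(idx_path)
        for row in computed.itertuples():
            ref = table[(table.species == row.species)
                        & (table.population == row.population)]
            if ref.empty:
                continue
            for col in ("n", "S", "nHap", "Hd", "pi"):
                want = float(ref.iloc[0][col])
                got = float(getattr(row, col))
                if abs(got - want) > 5e-4 + 1e-9:
                    mismatches.append({
                        "species": row.species, "population": row.population,
                        "index": col, "computed": got, "reference": want,
                    })
    report["reference_mismatches"] = mismatches
    dataio.write_report(report, Path(outdir) / "report.json")
    return report
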