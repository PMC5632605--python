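"""Input/output and core containers for population sequence datasets.

Sequences arrive as per-species multi-FASTA files whose headers carry the
sampling locality, together with a tab-separated metadata table (species,
invasiveness status, native/non-native distribution, region, coordinates).
This module validates those inputs, trims each species to the common
alignment window, and reads/writes every result artifact (index tables,
labelled distance matrices, newick trees, JSON reports) so that each file
round-trips through its reader.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("invadiv")

VALID_STATUS = {"invasive", "non_invasive"}
VALID_DISTRIBUTION = {"native", "non_native"}

#: Characters treated as unambiguous nucleotides throughout the package.
ACGT = frozenset("ACGT")
#: Additional symbols tolerated on read (IUPAC ambiguity, missing, gap).
IUPAC_EXTRA = frozenset("RYSWKMBDHVN-?")

METADATA_COLUMNS = [
    "population", "species", "status", "distribution",
    "region", "latitude", "longitude", "n",
]


class ValidationError(ValueError):
    """Raised when an input file is syntactically readable but invalid."""


@dataclass(frozen=True)
class SequenceRecord:
    """One sequenced individual: identifier, sampling population, sequence."""

    id: str
    population: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence record with empty id")
        if not self.sequence:
            raise ValidationError(f"record {self.id!r} has empty sequence")
        bad = set(self.sequence) - ACGT - IUPAC_EXTRA
        if bad:
            raise ValidationError(
                f"record {self.id!r} contains invalid symbols {sorted(bad)}"
            )


@dataclass(frozen=True)
class PopulationMetadata:
    """Sampling locality attributes used by the comparative analyses."""

    population: str
    species: str
    status: str           # invasive | non_invasive
    distribution: str     # native | non_native
    region: str
    latitude: float
    longitude: float
    n: int

    def __post_init__(self):
        if self.status not in VALID_STATUS:
            raise ValidationError(
                f"population {self.population!r}: unknown status {self.status!r}"
            )
        if self.distribution not in VALID_DISTRIBUTION:
            raise ValidationError(
                f"population {self.population!r}: unknown distribution "
                f"{self.distribution!r}"
            )
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(
                f"population {self.population!r}: latitude {self.latitude} "
                "outside [-90, 90]"
            )
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(
                f"population {self.population!r}: longitude {self.longitude} "
                "outside [-180, 180]"
            )
        if self.n < 1:
            raise ValidationError(
                f"population {self.population!r}: sample size n={self.n} < 1"
            )


@dataclass
class AlignedPopulationSet:
    """Equal-length sequences of one species grouped by sampling population."""

    species: str
    records: list[SequenceRecord]
    alignment_length: int
    populations: dict[str, list[SequenceRecord]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.populations:
            self.populations = {}
            for rec in self.records:
                self.populations.setdefault(rec.population, []).append(rec)
        for rec in self.records:
            if len(rec.sequence) != self.alignment_length:
                raise ValidationError(
                    f"record {rec.id!r} length {len(rec.sequence)} != "
                    f"alignment length {self.alignment_length}"
                )

    @property
    def population_names(self) -> list[str]:
        return list(self.populations)

    def sequences(self, population: str) -> list[str]:
        return [r.sequence for r in self.populations[population]]


@dataclass
class LabeledDistanceMatrix:
    """Symmetric pairwise matrix keyed by population labels.

    ``kind`` is one of ``fst``, ``evolutionary``, ``geographic`` (km) or
    ``geographic_log10``.
    """

    labels: list[str]
    values: np.ndarray
    kind: str

    KINDS = ("fst", "evolutionary", "geographic", "geographic_log10")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{k} labels"
            )
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValidationError("matrix is not symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def pairs(self) -> list[tuple[str, str, float]]:
        """Upper-triangle entries as (label_a, label_b, value)."""
        out = []
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                out.append((self.labels[i], self.labels[j],
                            float(self.values[i, j])))
        return out


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_fasta(path, header_delimiter: str = "|",
               population_index: int = 1) -> list[SequenceRecord]:
    """Read a multi-FASTA file into :class:`SequenceRecord` objects.

    The sampling population is parsed from the FASTA header, which is split
    on ``header_delimiter``; token ``population_index`` is the population
    name (default: ``>id|population``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValidationError(
                    f"{path}: line {lineno}: expected FASTA header, "
                    f"got {line.strip()[:40]!r}"
                )
            break
        else:
            raise ValidationError(f"{path}: no records")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    missing_pop: list[str] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        tokens = entry.description.split(header_delimiter)
        if len(tokens) <= population_index:
            missing_pop.append(tokens[0].strip())
            continue
        rec_id = tokens[0].strip()
        if rec_id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {rec_id!r}")
        seen.add(rec_id)
        records.append(SequenceRecord(
            id=rec_id,
            population=tokens[population_index].strip(),
            sequence=str(entry.seq).upper(),
        ))
    if missing_pop:
        raise ValidationError(
            f"{path}: headers lacking a population token "
            f"(delimiter {header_delimiter!r}): {missing_pop}"
        )
    if not records:
        raise ValidationError(f"{path}: no records")
    return records


def read_metadata(path) -> list[PopulationMetadata]:
    """Read the tab-separated population metadata table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing metadata column(s) {missing}")
    rows = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        try:
            meta = PopulationMetadata(
                population=row["population"],
                species=row["species"],
                status=row["status"],
                distribution=row["distribution"],
                region=row["region"],
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                n=int(row["n"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx + 1}: {exc}") from None
        key = (meta.species, meta.population)
        if key in seen:
            raise ValidationError(
                f"{path}: duplicate (species, population) {key}"
            )
        seen.add(key)
        rows.append(meta)
    return rows


def load_study_indices() -> pd.DataFrame:
    """Per-population diversity indices of the seven-species study dataset.

    Returns the packaged table with columns species, population, n, S, nHap,
    Hd, pi, distribution (native/non_native as printed) and status
    (invasive/non_invasive by species).
    """
    with resources.files("invadiv.data").joinpath("study_indices.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------

def _span(seq: str) -> tuple[int, int] | None:
    """Half-open [start, stop) covered by non-gap, non-missing symbols."""
    stripped = seq.strip("-?")
    if not stripped:
        return None
    start = len(seq) - len(seq.lstrip("-?"))
    stop = len(seq) - (len(seq) - len(seq.rstrip("-?")))
    return start, stop


def trim_to_common_window(records: Sequence[SequenceRecord],
                          species: str = "",
                          min_coverage: float = 0.9,
                          min_n: int = 5) -> AlignedPopulationSet:
    """Trim aligned records of one species to their common sequence window.

    Records are padded with trailing gaps to the longest aligned length L.
    Records whose covered span is shorter than ``min_coverage * L`` are
    dropped (with a logged reason); the output window is the intersection of
    the retained records' spans.  Populations left with fewer than ``min_n``
    records after the drops are excluded, because small samples give
    unreliable frequency-based statistics.
    """
    if not records:
        raise ValidationError("no records to trim")
    L = max(len(r.sequence) for r in records)
    padded = [(r, r.sequence + "-" * (L - len(r.sequence))) for r in records]

    kept: list[tuple[SequenceRecord, str]] = []
    for rec, seq in padded:
        span = _span(seq)
        if span is None or (span[1] - span[0]) < min_coverage * L:
            cov = 0 if span is None else span[1] - span[0]
            logger.info("dropping record %s: covers %d/%d bp (< %.0f%%)",
                        rec.id, cov, L, 100 * min_coverage)
            continue
        kept.append((rec, seq))
    if not kept:
        raise ValidationError("no common window: all records dropped")

    start = max(_span(seq)[0] for _, seq in kept)
    stop = min(_span(seq)[1] for _, seq in kept)
    if stop <= start:
        raise ValidationError("no common window shared by all retained records")

    by_pop: dict[str, list[SequenceRecord]] = {}
    for rec, seq in kept:
        trimmed = SequenceRecord(rec.id, rec.population, seq[start:stop])
        by_pop.setdefault(rec.population, []).append(trimmed)

    out_records: list[SequenceRecord] = []
    populations: dict[str, list[SequenceRecord]] = {}
    for pop, recs in by_pop.items():
        if len(recs) < min_n:
            logger.info("excluding population %s: %d record(s) < min_n=%d",
                        pop, len(recs), min_n)
            continue
        populations[pop] = recs
        out_records.extend(recs)
    if not populations:
        raise ValidationError(
            f"no population retains at least min_n={min_n} records"
        )
    return AlignedPopulationSet(
        species=species or "", records=out_records,
        alignment_length=stop - start, populations=populations,
    )


def reconcile_with_metadata(popset: AlignedPopulationSet,
                            metadata: Iterable[PopulationMetadata]) -> None:
    """Warn when retained sample sizes disagree with the metadata table."""
    meta = {m.population: m for m in metadata if m.species == popset.species}
    for pop, recs in popset.populations.items():
        if pop not in meta:
            logger.warning("population %s absent from metadata", pop)
        elif meta[pop].n != len(recs):
            logger.warning(
                "population %s: %d sequences retained but metadata n=%d",
                pop, len(recs), meta[pop].n,
            )


# ---------------------------------------------------------------------------
# Writers (every writer round-trips through a reader above/below)
# ---------------------------------------------------------------------------

def write_fasta(records: Sequence[SequenceRecord], path,
                header_delimiter: str = "|") -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}{header_delimiter}{rec.population}\n")
            fh.write(rec.sequence + "\n")


def write_metadata(rows: Sequence[PopulationMetadata], path) -> None:
    df = pd.DataFrame([{
        "population": m.population, "species": m.species,
        "status": m.status, "distribution": m.distribution,
        "region": m.region, "latitude": m.latitude,
        "longitude": m.longitude, "n": m.n,
    } for m in rows])
    df.to_csv(path, sep="\t", index=False)


def write_indices(df: pd.DataFrame, path) -> None:
    """Write a per-population diversity table (column order n,S,nHap,Hd,pi)."""
    lead = [c for c in ("species", "population") if c in df.columns]
    order = lead + ["n", "S", "nHap", "Hd", "pi"]
    extra = [c for c in df.columns if c not in order]
    df[order + extra].to_csv(path, sep="\t", index=False)


def read_indices(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(matrix: LabeledDistanceMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.labels,
                      columns=matrix.labels)
    with open(path, "w") as fh:
        fh.write(f"# kind: {matrix.kind}\n")
        df.to_csv(fh, sep="\t", index_label="population")


def read_matrix(path) -> LabeledDistanceMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# kind:"):
            raise ValidationError(f"{path}: missing matrix kind header")
        kind = header.split(":", 1)[1].strip()
        df = pd.read_csv(fh, sep="\t", index_col="population")
    return LabeledDistanceMatrix(labels=list(df.index),
                                 values=df.to_numpy(), kind=kind)


def write_tree(newick: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip() + "\n")


def write_report(report: Mapping, path) -> None:
    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"cannot serialise {type(obj)}")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_default,
                  ensure_ascii=False)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
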