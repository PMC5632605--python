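"""Great-circle distances between sampling sites and their log10 transform.

Distances use the haversine formula on a sphere of radius 6371.0 km.
Against an ellipsoidal geodesic this is accurate to about 0.5%, which is
negligible relative to the uncertainty of assigning a single coordinate to
a sampled shoreline.  Distances are log10-transformed before use as a
regression predictor, which normalises their distribution and brings them
to the order of magnitude of F_ST and evolutionary distances.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .dataio import LabeledDistanceMatrix, PopulationMetadata, ValidationError

logger = logging.getLogger("invadiv")

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in kilometres between two decimal-degree points."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValidationError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not math.isfinite(lon):
            raise ValidationError(f"longitude {lon} is not finite")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = math.radians(lat2 - lat1)
    dlam = math.radians(lon2 - lon1)
    a = (math.sin(dphi / 2.0) ** 2
         + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def geographic_matrix(metadata: list[PopulationMetadata]) -> LabeledDistanceMatrix:
    """Pairwise great-circle distance matrix (km) for a set of populations."""
    labels = [m.population for m in metadata]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate population names in coordinate set")
    k = len(labels)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            values[i, j] = values[j, i] = haversine_km(
                metadata[i].latitude, metadata[i].longitude,
                metadata[j].latitude, metadata[j].longitude)
    return LabeledDistanceMatrix(labels=labels, values=values,
                                 kind="geographic")


def log10_transform(geo: LabeledDistanceMatrix) -> LabeledDistanceMatrix:
    """Element-wise log10 of an off-diagonal distance matrix in km.

    Co-located distinct populations (distance 0) would be undefined; such
    entries are replaced by ``log10(min_positive_distance / 10)`` with a
    logged warning so one degenerate pair does not abort a run.  The
    diagonal is kept at 0 by convention and never used downstream (only
    off-diagonal pairs enter any analysis).
    """
    if geo.kind != "geographic":
        raise ValidationError(
            f"log10 transform expects a geographic (km) matrix, got {geo.kind!r}"
        )
    values = geo.values.copy()
    k = len(geo.labels)
    off = ~np.eye(k, dtype=bool)
    positives = values[off & (values > 0)]
    out = np.zeros((k, k))
    zero_pairs = np.argwhere(off & (values == 0))
    if zero_pairs.size and positives.size == 0:
        raise ValidationError("all populations co-located; log10 undefined")
    floor = math.log10(positives.min() / 10.0) if positives.size else 0.0
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            if values[i, j] > 0:
                out[i, j] = math.log10(values[i, j])
            else:
                logger.warning(
                    "co-located pair (%s, %s): substituting log10 distance %.3f",
                    geo.labels[i], geo.labels[j], floor)
                out[i, j] = floor
    return LabeledDistanceMatrix(labels=list(geo.labels), values=out,
                                 kind="geographic_log10")
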