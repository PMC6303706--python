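"""Per-female scalar sensilla phenotypes and population aggregation.

Traits per plate: sensilla count (broken sockets included), plate area,
sensilla-region area (convex hull of the sensilla — the polygon through the
outermost sensilla), coverage proportion (hull / plate), density
(sensilla per 1000 um^2 of hull), and mean/median nearest-neighbor distance.
Technical replicates are averaged field-wise; populations are summarized by
the mean over their females so each population contributes one value to the
between-group statistics.

``tactile_pattern_capacity`` gives the combinatorial number of distinct
on/off stimulation patterns a set of n mechanoreceptors can encode
(states**n), the quantity motivating counts as a sensory-resolution proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import convex_hull, nearest_neighbor_distances, polygon_area
from .io import PlateRecord, StudyManifest

__all__ = [
    "TraitRecord",
    "TRAIT_COLUMNS",
    "compute_traits",
    "average_replicates",
    "replicate_concordance",
    "aggregate_populations",
    "tactile_pattern_capacity",
]

#: numeric trait columns used in tables and aggregation
TRAIT_COLUMNS = (
    "sensilla_count",
    "plate_area",
    "sensilla_region_area",
    "coverage_proportion",
    "density",
    "mean_nnd",
    "median_nnd",
    "abdomen_length_mm",
)


@dataclass
class TraitRecord:
    """Scalar phenotypes for one plate (or replicate-averaged female).

    Areas in um^2, distances in um, density in sensilla per 1000 um^2.
    Area-based traits are NaN when fewer than 3 non-collinear sensilla exist.
    """

    specimen_id: str
    species: str | None = None
    population_id: str | None = None
    sensilla_count: float = np.nan
    plate_area: float = np.nan
    sensilla_region_area: float = np.nan
    coverage_proportion: float = np.nan
    density: float = np.nan
    mean_nnd: float = np.nan
    median_nnd: float = np.nan
    abdomen_length_mm: float = np.nan
    n_broken: float = 0.0
    counts_only: bool = False


def compute_traits(rec: PlateRecord) -> TraitRecord:
    """All scalar traits for one (right-orientation) plate record.

    Broken sockets count as sensilla.  With <2 sensilla the NND summaries
    are NaN; with <3 non-collinear sensilla the hull-based traits are NaN
    (missing propagates through aggregation rather than biasing it to 0).
    Plates flagged ``counts_only`` get only the count (their geometry was
    distorted at imaging).
    """
    if rec.side != "right":
        raise ValueError("compute_traits expects a right-orientation plate; mirror first")
    n = rec.sensilla_count
    if n < 1:
        raise ValueError("plate with zero sensilla is not supported")
    tr = TraitRecord(
        specimen_id=rec.specimen_id,
        species=rec.species,
        population_id=rec.population_id,
        sensilla_count=float(n),
        n_broken=float(np.count_nonzero(rec.broken)),
        abdomen_length_mm=(
            float(rec.abdomen_length_mm) if rec.abdomen_length_mm is not None else np.nan
        ),
        counts_only=rec.counts_only,
    )
    if rec.counts_only:
        return tr
    tr.plate_area = polygon_area(rec.outline)
    if n >= 2:
        nnd = nearest_neighbor_distances(rec.sensilla)
        tr.mean_nnd = float(np.mean(nnd))
        tr.median_nnd = float(np.median(nnd))
    if n >= 3:
        try:
            hull = convex_hull(rec.sensilla)
        except ValueError:
            hull = None  # collinear sensilla: hull-based traits stay missing
        if hull is not None:
            tr.sensilla_region_area = polygon_area(hull)
            tr.coverage_proportion = tr.sensilla_region_area / tr.plate_area
            tr.density = 1000.0 * n / tr.sensilla_region_area
    return tr


_MEAN_FIELDS = tuple(
    f.name
    for f in fields(TraitRecord)
    if f.name not in ("specimen_id", "species", "population_id", "counts_only")
)


def average_replicates(r1: TraitRecord, r2: TraitRecord) -> TraitRecord:
    """Field-wise mean of two technical replicates of the same specimen.

    A field missing (NaN) in either replicate is missing in the result;
    averaged counts may be non-integer and are kept as real numbers.
    """
    if r1.specimen_id != r2.specimen_id:
        raise ValueError(
            f"replicates from different specimens: {r1.specimen_id!r} vs {r2.specimen_id!r}"
        )
    out = TraitRecord(
        specimen_id=r1.specimen_id,
        species=r1.species,
        population_id=r1.population_id,
        counts_only=r1.counts_only or r2.counts_only,
    )
    for name in _MEAN_FIELDS:
        a, b = getattr(r1, name), getattr(r2, name)
        setattr(out, name, (a + b) / 2.0)  # NaN propagates
    return out


def replicate_concordance(pairs) -> float:
    """Pearson correlation between replicate-1 and replicate-2 measurements.

    Used as a QC gate on digitization repeatability.
    """
    arr = np.asarray(pairs, dtype=float)
    arr = arr[~np.isnan(arr).any(axis=1)]
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("need >=3 complete (value1, value2) pairs")
    if np.var(arr[:, 0]) == 0.0 or np.var(arr[:, 1]) == 0.0:
        raise ValueError("zero variance in one replicate series")
    r, _ = sps.pearsonr(arr[:, 0], arr[:, 1])
    return float(r)


def trait_table(records: list[TraitRecord]) -> pd.DataFrame:
    """One row per record with the fixed trait column set."""
    rows = []
    for r in records:
        row = {"specimen_id": r.specimen_id, "species": r.species, "population_id": r.population_id}
        row.update({c: getattr(r, c) for c in TRAIT_COLUMNS})
        row["n_broken"] = r.n_broken
        row["counts_only"] = r.counts_only
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_populations(
    records: list[TraitRecord],
    manifest: StudyManifest,
    min_n: int | None = None,
) -> pd.DataFrame:
    """Population-mean trait table: one row per (species, population).

    Every female must map to a manifest population.  NaN trait values are
    excluded field-wise (``mean`` over available females).  ``min_n``
    optionally drops populations below a female count, for the
    better-sampled-subset sensitivity analysis.
    """
    known = {(p.population_id, p.species) for p in manifest.populations}
    for r in records:
        if (r.population_id, r.species) not in known:
            raise KeyError(f"record {r.specimen_id!r} maps to unknown population "
                           f"({r.population_id!r}, {r.species!r})")
    df = trait_table(records)
    patry = {p.population_id: p.patry for p in manifest.populations}
    grouped = (
        df.groupby(["species", "population_id"], as_index=False)
        .agg(
            n_females=("specimen_id", "nunique"),
            **{c: (c, "mean") for c in TRAIT_COLUMNS},
        )
    )
    grouped["patry"] = grouped["population_id"].map(patry)
    if min_n is not None:
        grouped = grouped[grouped["n_females"] >= min_n].reset_index(drop=True)
    return grouped


def tactile_pattern_capacity(n_sensilla: int, states: int = 2) -> tuple[int, str]:
    """Number of distinct tactile patterns n mechanoreceptors can encode.

    Each sensillum contributes ``states`` response states (default binary
    contacted / not contacted), so the capacity is ``states**n`` exactly.
    Returns the exact integer and a 2-significant-figure scientific string.
    """
    if n_sensilla < 0:
        raise ValueError("n_sensilla must be >= 0")
    if states < 2:
        raise ValueError("states must be >= 2")
    exact = states**n_sensilla
    if exact >= 10:
        exponent = int(math.floor(math.log10(exact)))
        mantissa = round(exact / 10**exponent, 1)
        if mantissa >= 10:  # rounding bumped the decade
            mantissa /= 10
            exponent += 1
        sci = f"{mantissa:.1f} x 10^{exponent}"
    else:
        sci = str(exact)
    return exact, sci
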