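"""Study data model and plain-text I/O.

A study consists of per-female digitized plate records (an ordered outline
polygon plus a set of sensilla points, two technical replicates per female)
and a manifest assigning each female's population to a species and a
patry class (sympatric / locally allopatric / allopatric).

Coordinate files are delimited text (comma or tab), two numeric columns
``x,y`` with an optional single header row; sensilla files may carry a third
0/1 column flagging broken sockets (a sensillum that broke off leaves a
distinctive socket which is still counted).  Coordinates are stored in
micrometres; a per-file ``scale_um_per_unit`` factor converts raw units.

All downstream analyses receive right-orientation plates only: left plates
are mirrored about their bounding-box vertical midline on ingestion
(``standardize_plate_orientation``), which preserves all pairwise
inter-point distances.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry import Polygon as _ShPolygon

from .geometry import polygon_is_simple

__all__ = [
    "SPECIES",
    "PATRY_CLASSES",
    "PlateRecord",
    "Population",
    "StudyManifest",
    "load_coordinate_file",
    "write_coordinate_file",
    "load_manifest",
    "load_table1_manifest",
    "standardize_plate_orientation",
    "write_plate_record",
    "read_plate_record",
]

SPECIES = ("E_anna", "E_carunculatum")
PATRY_CLASSES = ("sympatric", "locally_allopatric", "allopatric")


@dataclass
class PlateRecord:
    """One female's digitized mesostigmal plate (one technical replicate)."""

    specimen_id: str
    species: str
    population_id: str
    side: str  # "left" | "right"
    outline: np.ndarray  # (V, 2) ordered vertices, um
    sensilla: np.ndarray  # (S, 2) points, um
    broken: np.ndarray | None = None  # (S,) bool, broken-socket flags
    replicate_id: int = 1
    abdomen_length_mm: float | None = None
    counts_only: bool = False  # imaged at an angle: counts usable, geometry not
    mirrored: bool = False
    corner_indices: tuple[int, int] | None = None  # (lower medial, upper medial)

    def __post_init__(self) -> None:
        self.outline = np.asarray(self.outline, dtype=float)
        self.sensilla = np.asarray(self.sensilla, dtype=float).reshape(-1, 2)
        if self.broken is None:
            self.broken = np.zeros(len(self.sensilla), dtype=bool)
        else:
            self.broken = np.asarray(self.broken, dtype=bool)

    @property
    def sensilla_count(self) -> int:
        return len(self.sensilla)

    def validate(self, tol: float = 1e-6) -> None:
        """Raise ``ValueError`` on any violated record invariant."""
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown plate side {self.side!r}")
        if len(self.outline) < 3:
            raise ValueError("outline needs >=3 vertices")
        if not polygon_is_simple(self.outline):
            raise ValueError("outline is self-intersecting")
        if len(self.broken) != len(self.sensilla):
            raise ValueError("broken-flag length mismatch")
        if self.replicate_id < 1:
            raise ValueError("replicate_id must be >= 1")
        if len(self.sensilla):
            poly = _ShPolygon(self.outline)
            for i, (x, y) in enumerate(self.sensilla):
                if poly.distance(Point(x, y)) > tol:
                    raise ValueError(
                        f"sensillum {i} at ({x:.3g}, {y:.3g}) lies outside the outline"
                    )


@dataclass
class Population:
    population_id: str
    site_name: str
    species: str
    latitude: float
    longitude: float
    patry: str
    year: int | None = None
    n_specimens: int = 1
    site_number: int | None = None


@dataclass
class StudyManifest:
    """Table of sampled populations (species, site, patry class, N)."""

    populations: list[Population] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for pop in self.populations:
            key = (pop.population_id, pop.species)
            if key in seen:
                raise ValueError(f"duplicate population {key}")
            seen.add(key)
            if pop.patry not in PATRY_CLASSES:
                raise ValueError(f"unknown patry label {pop.patry!r}")
            if pop.n_specimens < 1:
                raise ValueError("n_specimens must be >= 1")

    def __len__(self) -> int:
        return len(self.populations)

    def subset(self, species: str | None = None, min_n: int | None = None) -> "StudyManifest":
        pops = self.populations
        if species is not None:
            pops = [p for p in pops if p.species == species]
        if min_n is not None:
            pops = [p for p in pops if p.n_specimens >= min_n]
        return StudyManifest(list(pops))

    def total_specimens(self) -> int:
        return sum(p.n_specimens for p in self.populations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(p) for p in self.populations])

    def lookup(self, population_id: str) -> Population:
        for p in self.populations:
            if p.population_id == population_id:
                return p
        raise KeyError(f"unknown population {population_id!r}")


def _read_delimited(path: Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited text file with an optional header row."""
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    sep = "\t" if "\t" in lines[0] else ","
    first = lines[0].split(sep)

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = 0 if not all(_numeric(t) for t in first if t.strip()) else None
    from io import StringIO

    return pd.read_csv(StringIO(text), sep=sep, header=header)


def load_coordinate_file(
    path, kind: str = "sensilla", scale_um_per_unit: float = 1.0
):
    """Read an outline or sensilla coordinate file.

    Returns ``points`` (um) for outlines, ``(points, broken)`` for sensilla.
    """
    if kind not in ("outline", "sensilla"):
        raise ValueError(f"kind must be 'outline' or 'sensilla', got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns (x, y)")
    try:
        xy = df.iloc[:, :2].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric coordinate rows") from exc
    if not np.all(np.isfinite(xy)):
        raise ValueError(f"{path}: non-numeric coordinate rows")
    xy = xy * scale_um_per_unit
    if kind == "outline":
        if len(xy) < 3:
            raise ValueError(f"{path}: outline needs >=3 vertices")
        return xy
    if len(xy) == 0:
        raise ValueError(f"{path}: empty sensilla file")
    if df.shape[1] >= 3:
        broken = df.iloc[:, 2].to_numpy(dtype=float).astype(bool)
    else:
        broken = np.zeros(len(xy), dtype=bool)
    return xy, broken


def write_coordinate_file(path, points, broken=None, header: bool = True) -> None:
    path = Path(path)
    pts = np.asarray(points, dtype=float)
    cols = {"x": pts[:, 0], "y": pts[:, 1]}
    if broken is not None:
        cols["broken"] = np.asarray(broken).astype(int)
    pd.DataFrame(cols).to_csv(path, index=False, header=header, float_format="%.12g")


def load_manifest(path) -> StudyManifest:
    """Read a study manifest (CSV/TSV or JSON) into a :class:`StudyManifest`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text(encoding="utf-8"))
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, sep="\t" if path.suffix.lower() in (".tsv", ".tab") else ",")
    required = {"population_id", "site_name", "species", "latitude", "longitude", "patry", "n_specimens"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    pops = []
    for _, row in df.iterrows():
        pops.append(
            Population(
                population_id=str(row["population_id"]),
                site_name=str(row["site_name"]),
                species=str(row["species"]),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                patry=str(row["patry"]),
                year=int(row["year"]) if "year" in df.columns and pd.notna(row["year"]) else None,
                n_specimens=int(row["n_specimens"]),
                site_number=int(row["site_number"]) if "site_number" in df.columns else None,
            )
        )
    return StudyManifest(pops)


def load_table1_manifest() -> StudyManifest:
    """The bundled two-species study design (28 sites, 103 females)."""
    with resources.as_file(
        resources.files("platemorph.data") / "table1_manifest.csv"
    ) as p:
        return load_manifest(p)


def standardize_plate_orientation(rec: PlateRecord) -> PlateRecord:
    """Mirror left plates into right orientation; right plates pass through.

    Left plates are reflected about the vertical midline of the outline's
    bounding box (x -> xmin + xmax - x), which preserves all pairwise
    distances; the particular vertical axis is irrelevant because any
    translation is removed downstream by centroid standardization.
    """
    if rec.side == "right":
        return rec
    if rec.side != "left":
        raise ValueError(f"unknown plate side {rec.side!r}")
    lo, hi = rec.outline[:, 0].min(), rec.outline[:, 0].max()
    mid2 = lo + hi

    def _flip(pts: np.ndarray) -> np.ndarray:
        out = pts.copy()
        out[:, 0] = mid2 - out[:, 0]
        return out

    return dataclasses.replace(
        rec,
        outline=_flip(rec.outline),
        sensilla=_flip(rec.sensilla) if len(rec.sensilla) else rec.sensilla,
        side="right",
        mirrored=not rec.mirrored,
    )


def write_plate_record(rec: PlateRecord, directory) -> dict:
    """Write one record as a pair of coordinate files; returns file metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{rec.specimen_id}_rep{rec.replicate_id}"
    outline_path = directory / f"{stem}_outline.csv"
    sensilla_path = directory / f"{stem}_sensilla.csv"
    write_coordinate_file(outline_path, rec.outline)
    write_coordinate_file(sensilla_path, rec.sensilla, broken=rec.broken)
    meta = {
        "specimen_id": rec.specimen_id,
        "species": rec.species,
        "population_id": rec.population_id,
        "side": rec.side,
        "replicate_id": rec.replicate_id,
        "abdomen_length_mm": rec.abdomen_length_mm,
        "counts_only": rec.counts_only,
        "corner_indices": list(rec.corner_indices) if rec.corner_indices else None,
        "outline_file": outline_path.name,
        "sensilla_file": sensilla_path.name,
    }
    return meta


def read_plate_record(meta: dict, directory) -> PlateRecord:
    directory = Path(directory)
    outline = load_coordinate_file(directory / meta["outline_file"], "outline")
    sensilla, broken = load_coordinate_file(directory / meta["sensilla_file"], "sensilla")
    corners = meta.get("corner_indices")
    return PlateRecord(
        specimen_id=meta["specimen_id"],
        species=meta["species"],
        population_id=meta["population_id"],
        side=meta["side"],
        outline=outline,
        sensilla=sensilla,
        broken=broken,
        replicate_id=int(meta["replicate_id"]),
        abdomen_length_mm=meta.get("abdomen_length_mm"),
        counts_only=bool(meta.get("counts_only", False)),
        corner_indices=tuple(corners) if corners else None,
    )
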