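"""Synthetic two-species sensilla studies with the structure the analysis assumes.

The generator emulates the study design end-to-end: a manifest of
populations in three patry classes, per-female plate outlines (superellipse
with low-order radial perturbation, 600–1100 digitized vertices, two
designated medial corner vertices), sensilla placed by a truncated
bivariate Gaussian mixture in the unit-area plate frame, and two noisy
digitization replicates per female.  Species templates default to the
observed regime: E. anna with ~49 sensilla per plate placed medially over a
large fraction of the plate, E. carunculatum with ~28 sensilla placed
laterally and more densely.  Sympatry effects (count shift, placement
shift) are plantable and default to zero — the no-displacement condition.

Every stochastic draw flows from named seeds derived deterministically from
a master seed and the population id, so studies are exactly reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gamma
from shapely import contains_xy
from shapely.geometry import Polygon as _ShPolygon

from .geometry import polygon_area, polygon_centroid
from .io import PlateRecord, Population, StudyManifest, load_table1_manifest

__all__ = [
    "GENERATOR_VERSION",
    "SpeciesTemplate",
    "EffectConfig",
    "SyntheticStudy",
    "default_templates",
    "make_plate_outline",
    "sample_sensilla",
    "generate_female",
    "generate_study",
]

GENERATOR_VERSION = "1.0"


@dataclass
class SpeciesTemplate:
    """Generative model for one species' plates and sensilla.

    Outline: superellipse |x/a|^p + |y/b|^p = 1 (area scaled to
    ``plate_area_um2``) whose radius is modulated by low-order cosine
    perturbations.  Placement: K-component truncated Gaussian mixture in the
    unit-area standardized frame, shifted along x by ``medial_offset``
    (negative = medial).  Counts: truncated normal (>= 3), rounded.
    """

    name: str
    count_mean: float
    count_sd: float  # within-population SD of female counts
    plate_area_um2: float
    aspect: float = 0.45  # b/a of the superellipse
    exponent: float = 3.0
    perturb_amplitudes: tuple = (0.03, 0.02)  # cosine orders 2, 3
    mixture_weights: tuple = (0.5, 0.5)
    mixture_means: tuple = (((-0.18, 0.0)), ((0.12, 0.0)))  # unit-area frame
    mixture_sds: tuple = (((0.16, 0.11)), ((0.14, 0.10)))  # per-component (sx, sy)
    medial_offset: float = 0.0  # additional signed x shift of all components
    digitization_noise_um: float = 1.5
    count_noise_sd: float = 2.5
    broken_rate: float = 0.02
    abdomen_mean_mm: float = 25.0
    abdomen_sd_mm: float = 1.2
    n_vertices_range: tuple = (600, 1100)

    def __post_init__(self) -> None:
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.count_mean < 3:
            raise ValueError("count mean must be >= 3")
        if any(s <= 0 for pair in self.mixture_sds for s in pair):
            raise ValueError("mixture SDs must be positive")


def default_templates() -> dict[str, SpeciesTemplate]:
    """Study-condition templates: ~49 vs ~28 sensilla, medial vs lateral."""
    ea = SpeciesTemplate(
        name="E_anna",
        count_mean=49.0,
        count_sd=10.0,
        plate_area_um2=44000.0,
        mixture_means=((-0.38, 0.02), (0.08, -0.02)),
        mixture_sds=((0.34, 0.26), (0.36, 0.28)),
        medial_offset=-0.05,
        abdomen_mean_mm=26.0,
    )
    ec = SpeciesTemplate(
        name="E_carunculatum",
        count_mean=28.0,
        count_sd=8.0,
        plate_area_um2=30000.0,
        mixture_means=((0.10, 0.03), (0.35, -0.03)),
        mixture_sds=((0.19, 0.15), (0.17, 0.13)),
        medial_offset=0.05,
        abdomen_mean_mm=24.0,
    )
    return {"E_anna": ea, "E_carunculatum": ec}


@dataclass
class EffectConfig:
    """Plantable sympatry effects; zero by default (the null condition)."""

    sympatry_count_shift: float = 0.0
    sympatry_location_shift: tuple = (0.0, 0.0)
    between_population_count_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.between_population_count_sd < 0:
            raise ValueError("SDs must be >= 0")


@dataclass
class FemaleLatent:
    """Ground truth for one simulated female (pre-digitization)."""

    specimen_id: str
    outline: np.ndarray
    sensilla: np.ndarray
    broken: np.ndarray
    count: int
    corner_indices: tuple[int, int]
    side: str


@dataclass
class SyntheticStudy:
    manifest: StudyManifest
    records: list  # PlateRecord, two replicates per female
    latents: dict = field(default_factory=dict)  # specimen_id -> FemaleLatent
    master_seed: int | None = None
    generator_version: str = GENERATOR_VERSION

    def records_by_female(self) -> dict[str, list]:
        out: dict[str, list] = {}
        for rec in self.records:
            out.setdefault(rec.specimen_id, []).append(rec)
        return out


def _superellipse_area(a: float, b: float, p: float) -> float:
    return 4.0 * a * b * gamma(1.0 + 1.0 / p) ** 2 / gamma(1.0 + 2.0 / p)


def make_plate_outline(template: SpeciesTemplate, seed=None) -> tuple[np.ndarray, tuple[int, int]]:
    """A simple closed plate outline with designated medial corner vertices.

    Returns ``(vertices, (lower_medial_index, upper_medial_index))``.  The
    vertex count is drawn uniformly from the template's digitization range;
    with zero perturbation amplitudes the polygon is an exact superellipse
    whose area matches the closed-form value.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(template.n_vertices_range[0], template.n_vertices_range[1] + 1))
    p = template.exponent
    # choose a so that the unperturbed superellipse has the template area
    a = np.sqrt(
        template.plate_area_um2 / (_superellipse_area(1.0, template.aspect, p))
    )
    b = template.aspect * a
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    x = a * np.sign(ct) * np.abs(ct) ** (2.0 / p)
    y = b * np.sign(st) * np.abs(st) ** (2.0 / p)
    mod = np.ones(n)
    for k, amp in enumerate(template.perturb_amplitudes, start=2):
        if amp:
            mod += amp * np.cos(k * theta + rng.uniform(0.0, 2.0 * np.pi))
    verts = np.column_stack([x * mod, y * mod])
    # medial side = negative x; corners nearest the (-a, -b) / (-a, +b) diagonals
    lower = int(np.argmin(np.hypot(verts[:, 0] + a, verts[:, 1] + b)))
    upper = int(np.argmin(np.hypot(verts[:, 0] + a, verts[:, 1] - b)))
    return verts, (lower, upper)


def _mixture_params_um(
    template: SpeciesTemplate, outline: np.ndarray, loc_shift=(0.0, 0.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Map mixture means/SDs from the unit-area frame to the plate's um frame."""
    area = polygon_area(outline)
    centroid = polygon_centroid(outline)
    s = np.sqrt(area)
    means = np.asarray(template.mixture_means, dtype=float).copy()
    means[:, 0] += template.medial_offset + loc_shift[0]
    means[:, 1] += loc_shift[1]
    sds = np.asarray(template.mixture_sds, dtype=float)
    return centroid + s * means, s * sds


def sample_sensilla(
    template: SpeciesTemplate,
    outline: np.ndarray,
    n: int,
    seed=None,
    loc_shift=(0.0, 0.0),
    return_components: bool = False,
):
    """Draw n sensilla from the placement mixture, rejected against the outline."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    means, sds = _mixture_params_um(template, outline, loc_shift)
    poly = _ShPolygon(outline)
    weights = np.asarray(template.mixture_weights, dtype=float)
    pts = np.empty((0, 2))
    comps = np.empty(0, dtype=int)
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 200:
            frac = np.array([
                contains_xy(poly, *((means[k] + sds[k] * rng.standard_normal((64, 2))).T)).mean()
                for k in range(len(weights))
            ])
            worst = int(np.argmin(frac))
            raise RuntimeError(
                f"rejection sampling failed: mixture component {worst} of "
                f"template {template.name!r} has most of its mass outside the plate"
            )
        batch = max(2 * (n - len(pts)), 16)
        k = rng.choice(len(weights), size=batch, p=weights)
        cand = means[k] + sds[k] * rng.standard_normal((batch, 2))
        inside = contains_xy(poly, cand[:, 0], cand[:, 1])
        pts = np.vstack([pts, cand[inside]])
        comps = np.concatenate([comps, k[inside]])
    pts, comps = pts[:n], comps[:n]
    if return_components:
        return pts, comps
    return pts


def _smooth_outline_jitter(n: int, sd: float, rng) -> np.ndarray:
    """Spatially correlated (low-frequency) tracing error along the outline.

    Independent per-vertex noise would self-intersect a densely digitized
    trace; hand-tracing error drifts smoothly along the stroke instead.
    """
    t = np.arange(n) / n
    noise = np.zeros((n, 2))
    n_modes = 8
    for k in range(1, n_modes + 1):
        amp = rng.normal(0.0, 1.0, (2, 2))  # cos/sin x two coordinates
        noise += np.outer(np.cos(2 * np.pi * k * t), amp[0]) + np.outer(
            np.sin(2 * np.pi * k * t), amp[1]
        )
    # each coordinate is a sum of 2*n_modes unit-variance terms with
    # cos/sin weights averaging 1/2, so its variance is n_modes
    return noise * (sd / np.sqrt(n_modes))


def _nudge_inside(points: np.ndarray, outline: np.ndarray) -> np.ndarray:
    """Pull any point that jitter pushed outside back toward the centroid."""
    poly = _ShPolygon(outline)
    inside = contains_xy(poly, points[:, 0], points[:, 1])
    if inside.all():
        return points
    centroid = polygon_centroid(outline)
    out = points.copy()
    for i in np.flatnonzero(~inside):
        p = out[i]
        for _ in range(60):
            p = centroid + 0.97 * (p - centroid)
            if contains_xy(poly, p[0], p[1]):
                break
        out[i] = p
    return out


def generate_female(
    template: SpeciesTemplate,
    specimen_id: str,
    population_id: str,
    seed=None,
    count_shift: float = 0.0,
    loc_shift=(0.0, 0.0),
    side: str = "right",
    counts_only: bool = False,
) -> tuple[PlateRecord, PlateRecord, FemaleLatent]:
    """One latent female plus two digitization replicates.

    Replicates share the latent truth and differ by independent coordinate
    jitter (``digitization_noise_um``) and count noise (points dropped or
    re-drawn, ``count_noise_sd``); broken-socket flags live on the latent
    sensilla, so they agree between replicates up to count noise.  With all
    noise SDs zero the replicates are identical.
    """
    rng = np.random.default_rng(seed)
    outline, corners = make_plate_outline(template, rng.integers(2**31))
    count = max(3, int(round(rng.normal(template.count_mean + count_shift, template.count_sd))))
    sensilla = sample_sensilla(template, outline, count, rng.integers(2**31), loc_shift)
    broken = rng.random(count) < template.broken_rate
    abdomen = float(rng.normal(template.abdomen_mean_mm, template.abdomen_sd_mm))
    latent = FemaleLatent(
        specimen_id=specimen_id, outline=outline, sensilla=sensilla,
        broken=broken, count=count, corner_indices=corners, side=side,
    )

    def _replicate(rep: int) -> PlateRecord:
        sd = template.digitization_noise_um
        out = (
            outline + _smooth_outline_jitter(len(outline), sd, rng)
            if sd > 0
            else outline.copy()
        )
        pts = sensilla.copy()
        brk = broken.copy()
        if template.count_noise_sd > 0:
            delta = int(round(rng.normal(0.0, template.count_noise_sd)))
            if delta < 0 and len(pts) + delta >= 3:
                keep = rng.choice(len(pts), size=len(pts) + delta, replace=False)
                keep.sort()
                pts, brk = pts[keep], brk[keep]
            elif delta > 0:
                extra = sample_sensilla(template, outline, delta, rng.integers(2**31), loc_shift)
                pts = np.vstack([pts, extra])
                brk = np.concatenate([brk, rng.random(delta) < template.broken_rate])
        if sd > 0:
            pts = _nudge_inside(pts + rng.normal(0.0, sd, pts.shape), out)
        rec = PlateRecord(
            specimen_id=specimen_id,
            species=template.name,
            population_id=population_id,
            side="right",
            outline=out,
            sensilla=pts,
            broken=brk,
            replicate_id=rep,
            abdomen_length_mm=abdomen + float(rng.normal(0.0, 0.05)) if sd > 0 else abdomen,
            counts_only=counts_only,
            corner_indices=corners,
        )
        if side == "left":  # emit in left orientation; ingestion mirrors it back
            lo, hi = rec.outline[:, 0].min(), rec.outline[:, 0].max()
            rec.outline[:, 0] = lo + hi - rec.outline[:, 0]
            rec.sensilla[:, 0] = lo + hi - rec.sensilla[:, 0]
            rec.side = "left"
        return rec

    return _replicate(1), _replicate(2), latent


def _derived_seed(master_seed: int, tag: str) -> int:
    return zlib.crc32(f"{master_seed}:{tag}".encode()) & 0x7FFFFFFF


def generate_study(
    manifest: StudyManifest | None = None,
    templates: dict[str, SpeciesTemplate] | None = None,
    effects: EffectConfig | None = None,
    master_seed: int = 0,
    left_plate_rate: float = 0.2,
) -> SyntheticStudy:
    """A complete synthetic study over a manifest design.

    Defaults to the bundled two-species design (103 females over 28 sites)
    with the default species templates and zero planted patry effects.
    Per-population seeds derive from ``master_seed`` and the population id;
    a fraction of females are digitized from the left plate (emitted in
    left orientation) to exercise the mirroring path.
    """
    manifest = load_table1_manifest() if manifest is None else manifest
    templates = default_templates() if templates is None else templates
    effects = EffectConfig() if effects is None else effects
    records: list[PlateRecord] = []
    latents: dict[str, FemaleLatent] = {}
    for pop in manifest.populations:
        if pop.species not in templates:
            raise KeyError(f"no template for species {pop.species!r}")
        template = templates[pop.species]
        rng = np.random.default_rng(_derived_seed(master_seed, pop.population_id))
        pop_count_dev = float(rng.normal(0.0, effects.between_population_count_sd))
        count_shift, loc_shift = pop_count_dev, (0.0, 0.0)
        if pop.patry == "sympatric":
            count_shift += effects.sympatry_count_shift
            loc_shift = tuple(effects.sympatry_location_shift)
        for i in range(pop.n_specimens):
            sid = f"{pop.population_id}_f{i + 1:02d}"
            side = "left" if rng.random() < left_plate_rate else "right"
            r1, r2, latent = generate_female(
                template, sid, pop.population_id,
                seed=rng.integers(2**31),
                count_shift=count_shift, loc_shift=loc_shift, side=side,
            )
            records.extend([r1, r2])
            latents[sid] = latent
    return SyntheticStudy(
        manifest=manifest, records=records, latents=latents, master_seed=master_seed
    )
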