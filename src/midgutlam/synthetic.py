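"""Seeded generator of synthetic midgut samples.

Produces nucleus-object tables (one row per segmented nucleus: 3D centroid,
maximum cross-sectional area, per-channel mean intensities) with the regional
and dietary effect structure of the adult *Drosophila* midgut:

* a curved tubular organ laid out along a planar sinusoidal centerline,
  partitioned into five main regions (R1..R5) by arc-length proportions;
* region-specific tube radius, scaled up under the fed condition;
* a bimodal nucleus-area distribution (large polyploid enterocytes vs small
  diploid progenitors/enteroendocrine cells);
* region-specific cell-type composition, with feeding-induced fold changes in
  enteroblast (EB) and enteroendocrine (EE) density and intestinal stem cell
  (ISC) nucleus area applied only in the regions where they act;
* marker intensity channels (Delta, Prospero, escargot, GFP, p4E-BP and the
  two FUCCI cell-cycle reporters) with phase-, diet- and region-dependent
  levels and multiplicative lognormal noise;
* progenitor doublets: paired ISC-ISC (symmetric), ISC-EB (asymmetric) and
  ISC-preEE cells placed a few micrometers apart.

Every record carries ground-truth columns (``true_region``, ``true_type``,
``true_phase``, doublet identity/class/partner) and each sample is accompanied
by a :class:`GroundTruth` object holding the true border positions and the
true width profile, enabling parameter-recovery tests downstream.

The in-plane offset from the centerline emulates the projected appearance of
a dissected monolayer tube: most nuclei sit at the silhouette walls,
±(regional radius + Gaussian jitter), while a configurable minority is seen
en face anywhere across the lumen, with an independent smaller spread along
z. Keeping the wall fraction above one half makes 2 × median in-plane offset
a consistent estimator of the tube width, while the filled interior keeps
the slice-median axis anchored to the centerline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "CELL_TYPES",
    "PHASES",
    "CONDITIONS",
    "ConfigError",
    "MarkerModel",
    "SynthConfig",
    "GroundTruth",
    "generate_sample",
    "generate_cohort",
    "generate_null_cohort",
]

REGIONS = ("R1", "R2", "R3", "R4", "R5")
CELL_TYPES = ("ISC", "EB", "EE", "EC", "preEE")
PHASES = ("G1", "S", "G2M")
CONDITIONS = ("starved", "fed")

DOUBLET_CLASSES = ("symmetric_ISC_ISC", "asymmetric_ISC_EB", "ISC_preEE")


class ConfigError(ValueError):
    """Raised when a generator configuration field is invalid."""


@dataclass(frozen=True)
class MarkerModel:
    """Intensity model for a single marker channel.

    The drawn intensity is ``level × region × diet × phase × type`` effects
    with multiplicative lognormal noise ``exp(N(0, sigma))``. ``level`` is
    ``pos_level`` for records matching ``positive_types`` / ``positive_phases``
    and ``neg_level`` (background) otherwise; modulating effects apply to the
    positive (expressing) population only, unless the marker is ubiquitous
    (both selectors ``None``), in which case they apply to every record.
    """

    pos_level: float = 100.0
    neg_level: float = 10.0
    sigma: float = 0.3
    positive_types: tuple[str, ...] | None = None
    positive_phases: tuple[str, ...] | None = None
    phase_mult: Mapping[str, float] | None = None
    fed_mult: float | tuple[float, ...] = 1.0
    region_mult: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    type_mult: Mapping[str, float] | None = None


def _default_intensity_model() -> dict[str, MarkerModel]:
    return {
        # mTORC1 activity readout: ubiquitous, low in G1 and gradually
        # elevated through S and G2-M, boosted by feeding, region-modulated.
        "p4ebp": MarkerModel(
            pos_level=50.0,
            sigma=0.3,
            phase_mult={"G1": 1.0, "S": 1.6, "G2M": 2.4},
            fed_mult=1.8,
            region_mult=(1.0, 1.2, 0.9, 1.3, 1.1),
        ),
        # Notch ligand: ISC marker; regionally patterned (low R1/R3/R5,
        # high R2/R4) and feeding-activated mostly in R2 and R4. preEE
        # cells express it weakly.
        "delta": MarkerModel(
            pos_level=150.0,
            neg_level=12.0,
            sigma=0.3,
            positive_types=("ISC", "preEE"),
            region_mult=(0.7, 1.3, 0.8, 1.3, 0.8),
            fed_mult=(1.0, 1.4, 1.0, 1.4, 1.0),
            type_mult={"preEE": 0.5},
        ),
        # Prospero: EE / pre-EE marker.
        "pros": MarkerModel(
            pos_level=150.0,
            neg_level=12.0,
            sigma=0.3,
            positive_types=("EE", "preEE"),
        ),
        # escargot: progenitor (ISC + EB) marker.
        "esg": MarkerModel(
            pos_level=120.0,
            neg_level=10.0,
            sigma=0.3,
            positive_types=("ISC", "EB", "preEE"),
        ),
        # clone marker (progenitor-derived cells).
        "gfp": MarkerModel(
            pos_level=100.0,
            neg_level=8.0,
            sigma=0.4,
            positive_types=("ISC", "EB", "preEE"),
        ),
        # FUCCI reporters: E2F1 degron reporter present in G1 and G2-M,
        # CycB degron reporter present in S and G2-M.
        "e2f1": MarkerModel(
            pos_level=100.0,
            neg_level=10.0,
            sigma=0.3,
            positive_phases=("G1", "G2M"),
        ),
        "cycb": MarkerModel(
            pos_level=100.0,
            neg_level=10.0,
            sigma=0.3,
            positive_phases=("S", "G2M"),
        ),
    }


def _default_densities() -> dict[str, tuple[float, ...]]:
    # cells per 100 µm of axis, per region R1..R5
    return {
        "EC": (80.0, 80.0, 90.0, 80.0, 75.0),
        "ISC": (15.0, 18.0, 12.0, 18.0, 15.0),
        "EB": (12.0, 14.0, 10.0, 14.0, 12.0),
        "EE": (8.0, 8.0, 12.0, 8.0, 8.0),
    }


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic midgut.

    Region-indexed tuples run anterior to posterior over R1..R5. Dietary
    effects are applied only in the ``fed`` condition; the ``starved``
    condition is the baseline.
    """

    region_proportions: tuple[float, ...] = (0.20, 0.25, 0.10, 0.30, 0.15)
    region_radius_um: tuple[float, ...] = (90.0, 70.0, 100.0, 75.0, 60.0)
    radius_fed_scale: float = 1.6
    cells_per_100um: dict[str, tuple[float, ...]] = field(
        default_factory=_default_densities
    )
    # polyploid EC nucleus area: lognormal with region-specific median (µm²)
    ec_area_median_um2: tuple[float, ...] = (65.0, 60.0, 40.0, 55.0, 50.0)
    ec_area_sigma: float = 0.25
    # diploid nucleus area: lognormal, shared log-sd
    diploid_area_median_um2: float = 12.0
    diploid_area_sigma: float = 0.25
    eb_area_fold: float = 1.6     # EBs grow toward EC fate
    ee_area_fold: float = 0.85    # EEs are slightly smaller
    isc_area_fed_fold_by_region: tuple[float, ...] = (1.0, 1.3, 1.0, 1.3, 1.3)
    eb_count_fed_fold_by_region: tuple[float, ...] = (1.0, 1.8, 1.0, 1.8, 1.0)
    ee_count_fed_fold_by_region: tuple[float, ...] = (1.0, 1.0, 1.6, 1.0, 1.0)
    ee_flank_width: float = 0.10  # fraction of axis flanking R3 sharing its fold
    intensity_model: dict[str, MarkerModel] = field(
        default_factory=_default_intensity_model
    )
    doublet_fraction: dict[str, float] = field(
        default_factory=lambda: {"starved": 0.15, "fed": 0.15}
    )
    symmetric_fraction: dict[str, float] = field(
        default_factory=lambda: {"starved": 0.6, "fed": 0.3}
    )
    pre_ee_fraction: float = 0.05
    # planar sinusoidal centerline y = A sin(2π x / λ), x ∈ [0, L]
    centerline_length_um: float = 3000.0
    centerline_amplitude_um: float = 300.0
    centerline_wavelength_um: float = 3000.0
    wall_jitter_sd_um: float = 2.0
    interior_fraction: float = 0.40  # nuclei seen en face across the lumen
    z_spread_frac: float = 0.30   # z sd as fraction of local radius
    phase_probs: tuple[float, ...] = (0.5, 0.25, 0.25)  # ISC G1/S/G2M
    doublet_spacing_um: float = 3.0
    seed: int = 0

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        p = np.asarray(self.region_proportions, dtype=float)
        if p.shape != (5,) or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ConfigError(
                "region_proportions must be 5 fractions summing to 1, got "
                f"{self.region_proportions!r}"
            )
        if np.any(p <= 0):
            raise ConfigError("region_proportions must be strictly positive")
        for name in ("region_radius_um", "ec_area_median_um2",
                     "isc_area_fed_fold_by_region",
                     "eb_count_fed_fold_by_region",
                     "ee_count_fed_fold_by_region"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (5,) or np.any(v <= 0):
                raise ConfigError(f"{name} must be 5 strictly positive values")
        for name in ("radius_fed_scale", "ec_area_sigma",
                     "diploid_area_median_um2", "diploid_area_sigma",
                     "eb_area_fold", "ee_area_fold", "wall_jitter_sd_um",
                     "z_spread_frac", "centerline_length_um",
                     "centerline_wavelength_um", "doublet_spacing_um"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        for ct, dens in self.cells_per_100um.items():
            d = np.asarray(dens, dtype=float)
            if d.shape != (5,) or np.any(d < 0):
                raise ConfigError(
                    f"cells_per_100um[{ct!r}] must be 5 non-negative densities"
                )
        if not 0.0 <= self.interior_fraction < 0.5:
            raise ConfigError(
                "interior_fraction must lie in [0, 0.5) so the silhouette "
                "walls keep the majority of the radial-offset mass"
            )
        for name in ("doublet_fraction", "symmetric_fraction"):
            m = getattr(self, name)
            for cond in CONDITIONS:
                if cond not in m:
                    raise ConfigError(f"{name} missing condition {cond!r}")
                if not 0.0 <= m[cond] <= 1.0:
                    raise ConfigError(f"{name}[{cond!r}] must lie in [0, 1]")
        q = np.asarray(self.phase_probs, dtype=float)
        if q.shape != (3,) or not np.isclose(q.sum(), 1.0) or np.any(q < 0):
            raise ConfigError("phase_probs must be 3 probabilities summing to 1")
        if not 0.0 <= self.pre_ee_fraction <= 0.5:
            raise ConfigError("pre_ee_fraction must lie in [0, 0.5]")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d, default=list, sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.md5(blob.encode()).hexdigest()

    def with_updates(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)

    @property
    def border_u(self) -> np.ndarray:
        """True internal border positions B1..B4 in normalized axis units."""
        return np.cumsum(np.asarray(self.region_proportions, float))[:4]


@dataclass
class GroundTruth:
    """Per-sample ground truth: borders, geometry, provenance."""

    sample_id: str
    condition: str
    seed: int
    config_hash: str
    borders_u: np.ndarray              # 4 internal borders in (0, 1)
    region_radius_um: np.ndarray       # condition-scaled radii R1..R5
    arc_length_um: float               # true centerline arc length

    def region_of(self, u: np.ndarray) -> np.ndarray:
        """Region index 0..4 for normalized positions ``u``."""
        return np.searchsorted(self.borders_u, np.asarray(u, float), side="right")

    def true_width(self, u: np.ndarray) -> np.ndarray:
        """True tube width (2 × radius) at normalized positions ``u``."""
        return 2.0 * self.region_radius_um[self.region_of(u)]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _centerline(config: SynthConfig, n_grid: int = 4001):
    """Arc-length parameterization of the planar sinusoidal centerline."""
    x = np.linspace(0.0, config.centerline_length_um, n_grid)
    y = config.centerline_amplitude_um * np.sin(
        2.0 * np.pi * x / config.centerline_wavelength_um
    )
    ds = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(ds)])
    dydx = (
        config.centerline_amplitude_um
        * 2.0 * np.pi / config.centerline_wavelength_um
        * np.cos(2.0 * np.pi * x / config.centerline_wavelength_um)
    )
    norm = np.hypot(1.0, dydx)
    return {
        "x": x, "y": y, "s": s,
        "tx": 1.0 / norm, "ty": dydx / norm,
        "total": float(s[-1]),
    }


def _positions_on_wall(u, radius, geom, config, rng):
    """3D centroids at the tube wall for normalized axis positions ``u``."""
    s = np.asarray(u, float) * geom["total"]
    xc = np.interp(s, geom["s"], geom["x"])
    yc = np.interp(s, geom["s"], geom["y"])
    tx = np.interp(s, geom["s"], geom["tx"])
    ty = np.interp(s, geom["s"], geom["ty"])
    # unit normal of the planar curve
    nx, ny = -ty, tx
    n = len(s)
    side = rng.choice([-1.0, 1.0], size=n)
    wall = radius + rng.normal(0.0, config.wall_jitter_sd_um, size=n)
    # projected-monolayer offset profile: most nuclei sit at the silhouette
    # walls, the rest are seen en face anywhere across the lumen
    interior = rng.random(n) < config.interior_fraction
    offset = np.where(interior, radius * rng.uniform(-1.0, 1.0, size=n),
                      side * wall)
    x = xc + offset * nx
    y = yc + offset * ny
    z = rng.normal(0.0, config.z_spread_frac * radius)
    return x, y, z


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_areas(types, regions, fed, config, rng):
    """Nucleus areas (µm²) by cell type; ISC fed fold applied per region."""
    n = len(types)
    mu = np.empty(n)
    sigma = np.empty(n)
    ec = types == "EC"
    mu[ec] = np.log(np.asarray(config.ec_area_median_um2))[regions[ec]]
    sigma[ec] = config.ec_area_sigma
    base = np.log(config.diploid_area_median_um2)
    for ct, fold in (("ISC", 1.0), ("EB", config.eb_area_fold),
                     ("EE", config.ee_area_fold),
                     ("preEE", config.ee_area_fold)):
        m = types == ct
        mu[m] = base + np.log(fold)
        sigma[m] = config.diploid_area_sigma
    if fed:
        isc = types == "ISC"
        mu[isc] += np.log(np.asarray(config.isc_area_fed_fold_by_region))[
            regions[isc]
        ]
    return np.exp(mu + sigma * rng.standard_normal(n))


def _draw_intensities(types, phases, regions, fed, config, rng):
    """One intensity column per marker, in sorted marker order."""
    out = {}
    for name in sorted(config.intensity_model):
        mm = config.intensity_model[name]
        n = len(types)
        if mm.positive_types is None and mm.positive_phases is None:
            pos = np.ones(n, dtype=bool)
        else:
            pos = np.zeros(n, dtype=bool)
            if mm.positive_types is not None:
                pos |= np.isin(types, mm.positive_types)
            if mm.positive_phases is not None:
                pos |= np.isin(phases, mm.positive_phases)
        level = np.where(pos, mm.pos_level, mm.neg_level)
        mult = np.ones(n)
        mult *= np.asarray(mm.region_mult, float)[regions]
        if fed:
            fm = np.asarray(mm.fed_mult, float)
            mult *= fm[regions] if fm.ndim else float(fm)
        if mm.phase_mult is not None:
            pm = np.ones(n)
            for ph, f in mm.phase_mult.items():
                pm[phases == ph] = f
            mult *= pm
        if mm.type_mult is not None:
            tm = np.ones(n)
            for ct, f in mm.type_mult.items():
                tm[types == ct] = f
            mult *= tm
        # modulations act on the expressing population only (background is
        # staining noise), unless the marker is ubiquitous
        mult = np.where(pos, mult, 1.0)
        out[f"int_{name}"] = level * mult * np.exp(
            mm.sigma * rng.standard_normal(n)
        )
    return out


def generate_sample(
    config: SynthConfig,
    condition: str,
    seed: int,
    sample_id: str | None = None,
    n_segments: int = 600,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one synthetic midgut sample.

    Parameters
    ----------
    config : SynthConfig
        Study-condition parameters; validated before use.
    condition : {"starved", "fed"}
        Dietary condition. ``fed`` applies the radius scale and the
        region-specific ISC-area / EB-count / EE-count folds.
    seed : int
        Seed of the per-sample random generator. The same
        (config, condition, seed) yields a byte-identical table.
    sample_id : str, optional
        Defaults to ``"{condition}_{seed}"``.
    n_segments : int
        Axis discretization used for inhomogeneous Poisson cell placement.

    Returns
    -------
    (table, truth)
        ``table`` is one row per nucleus with columns ``sample_id``,
        ``object_id``, ``x_um``, ``y_um``, ``z_um``, ``area_um2``, one
        ``int_<marker>`` column per channel, and ``true_*`` ground-truth
        columns. ``truth`` records borders, scaled radii and arc length.
    """
    config.validate()
    if condition not in CONDITIONS:
        raise ConfigError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    if not (isinstance(seed, (int, np.integer)) and seed >= 0):
        raise ConfigError("seed must be a non-negative integer")
    if sample_id is None:
        sample_id = f"{condition}_{seed}"

    rng = np.random.default_rng(seed)
    geom = _centerline(config)
    fed = condition == "fed"
    borders_u = config.border_u

    # --- inhomogeneous Poisson placement along the axis ------------------
    edges = np.linspace(0.0, 1.0, n_segments + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    seg_region = np.searchsorted(borders_u, mid, side="right")
    ds_um = geom["total"] / n_segments

    u_parts, type_parts = [], []
    for ct in ("EC", "EE", "EB", "ISC"):       # fixed order for determinism
        dens = np.asarray(config.cells_per_100um[ct], float)[seg_region].copy()
        if fed and ct == "EB":
            dens *= np.asarray(config.eb_count_fed_fold_by_region)[seg_region]
        if fed and ct == "EE":
            mult = np.asarray(config.ee_count_fed_fold_by_region)[seg_region]
            window = (mid >= borders_u[1] - config.ee_flank_width) & (
                mid <= borders_u[2] + config.ee_flank_width
            )
            mult = np.where(window, np.maximum(mult, config.ee_count_fed_fold_by_region[2]), mult)
            dens = dens * mult
        counts = rng.poisson(dens * ds_um / 100.0)
        total = int(counts.sum())
        u = np.repeat(edges[:-1], counts) + rng.random(total) / n_segments
        u_parts.append(u)
        type_parts.append(np.full(total, ct, dtype=object))

    u = np.concatenate(u_parts)
    types = np.concatenate(type_parts)
    regions = np.searchsorted(borders_u, u, side="right")

    # ISC cell-cycle phases; other types are non-cycling here
    phases = np.full(len(u), "NA", dtype=object)
    isc_mask = types == "ISC"
    phases[isc_mask] = rng.choice(PHASES, size=int(isc_mask.sum()),
                                  p=config.phase_probs)

    radii = np.asarray(config.region_radius_um, float) * (
        config.radius_fed_scale if fed else 1.0
    )
    radius = radii[regions]
    x, y, z = _positions_on_wall(u, radius, geom, config, rng)

    # --- doublets: anchors among base ISCs, partners appended ------------
    n_base = len(u)
    anchor_idx = np.flatnonzero(isc_mask)
    is_anchor = rng.random(len(anchor_idx)) < config.doublet_fraction[condition]
    anchor_idx = anchor_idx[is_anchor]
    n_doub = len(anchor_idx)
    s_frac = config.symmetric_fraction[condition]
    p_pre = config.pre_ee_fraction
    cls = rng.choice(
        np.arange(3),
        size=n_doub,
        p=[s_frac, (1.0 - s_frac) * (1.0 - p_pre), (1.0 - s_frac) * p_pre],
    )
    cls_names = np.array(["symmetric_ISC_ISC", "asymmetric_ISC_EB",
                          "ISC_preEE"], dtype=object)[cls]
    partner_types = np.array(["ISC", "EB", "preEE"], dtype=object)[cls]

    # partner placement: random 3D direction, ~3 µm apart
    direction = rng.standard_normal((n_doub, 3))
    direction /= np.maximum(
        np.linalg.norm(direction, axis=1, keepdims=True), 1e-12
    )
    dist = np.maximum(config.doublet_spacing_um + rng.normal(0, 0.5, n_doub), 1.0)
    px = x[anchor_idx] + direction[:, 0] * dist
    py = y[anchor_idx] + direction[:, 1] * dist
    pz = z[anchor_idx] + direction[:, 2] * dist
    p_u = u[anchor_idx]
    p_region = regions[anchor_idx]
    p_phase = np.full(n_doub, "NA", dtype=object)
    part_isc = partner_types == "ISC"
    p_phase[part_isc] = rng.choice(PHASES, size=int(part_isc.sum()),
                                   p=config.phase_probs)

    types_all = np.concatenate([types, partner_types])
    regions_all = np.concatenate([regions, p_region])
    phases_all = np.concatenate([phases, p_phase])
    u_all = np.concatenate([u, p_u])
    x_all = np.concatenate([x, px])
    y_all = np.concatenate([y, py])
    z_all = np.concatenate([z, pz])
    n_total = len(u_all)

    areas = _draw_areas(types_all, regions_all, fed, config, rng)
    intensities = _draw_intensities(types_all, phases_all, regions_all, fed,
                                    config, rng)

    # doublet bookkeeping
    doublet_id = np.full(n_total, -1, dtype=int)
    doublet_class = np.full(n_total, "", dtype=object)
    partner_of = np.full(n_total, -1, dtype=int)
    partner_ids = n_base + np.arange(n_doub)
    doublet_id[anchor_idx] = np.arange(n_doub)
    doublet_id[partner_ids] = np.arange(n_doub)
    doublet_class[anchor_idx] = cls_names
    doublet_class[partner_ids] = cls_names
    partner_of[anchor_idx] = partner_ids
    partner_of[partner_ids] = anchor_idx

    table = pd.DataFrame(
        {
            "sample_id": sample_id,
            "object_id": np.arange(n_total, dtype=int),
            "x_um": x_all,
            "y_um": y_all,
            "z_um": z_all,
            "area_um2": areas,
            **intensities,
            "true_region": np.array(REGIONS, dtype=object)[regions_all],
            "true_type": types_all,
            "true_phase": phases_all,
            "true_doublet_id": doublet_id,
            "true_doublet_class": doublet_class,
            "true_partner": partner_of,
        }
    )
    truth = GroundTruth(
        sample_id=sample_id,
        condition=condition,
        seed=int(seed),
        config_hash=config.config_hash(),
        borders_u=borders_u,
        region_radius_um=radii,
        arc_length_um=geom["total"],
    )
    return table, truth


def generate_cohort(
    config: SynthConfig,
    n_per_group: int,
    seed: int,
    conditions: Sequence[str] = CONDITIONS,
) -> dict[str, list[tuple[pd.DataFrame, GroundTruth]]]:
    """Generate ``n_per_group`` samples per dietary condition.

    Per-sample seeds are drawn from a generator seeded with ``seed``, so the
    whole cohort is reproducible from one integer.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list] = {}
    for cond in conditions:
        seeds = rng.integers(0, 2**31 - 1, size=n_per_group)
        out[cond] = [
            generate_sample(config, cond, int(s), sample_id=f"{cond}_{i}")
            for i, s in enumerate(seeds)
        ]
    return out


def generate_null_cohort(
    config: SynthConfig, n_per_group: int, seed: int
) -> tuple[list[tuple[pd.DataFrame, GroundTruth]],
           list[tuple[pd.DataFrame, GroundTruth]]]:
    """Two groups from the *identical* configuration (no injected effect).

    Both groups are generated under the starved baseline and differ only in
    their RNG streams; any downstream group difference is a false positive.
    Used to measure empirical type-I error of the bin-wise tests.
    """
    if n_per_group < 3:
        raise ConfigError("n_per_group must be >= 3 (tests undefined below)")
    rng = np.random.default_rng(seed)
    groups = []
    for gname in ("A", "B"):
        seeds = rng.integers(0, 2**31 - 1, size=n_per_group)
        groups.append(
            [
                generate_sample(config, "starved", int(s),
                                sample_id=f"null{gname}_{i}")
                for i, s in enumerate(seeds)
            ]
        )
    return groups[0], groups[1]
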