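"""Ground-truth synthetic inputs for every analysis stage.

The study's raw data (EM stacks, plate exports, abundance tables) are not
deposited, so this module generates statistically comparable stand-ins with
known ground truth:

* voxel **phantoms** (sphere, ellipsoid, capsule, branched) rasterized by
  pixel-center inclusion at the acquisition spacing, with closed-form
  volume, surface area and maximal extent;
* young/aged morphometry **cohorts** (default 3 animals x 175 mitochondria
  per group, matching the study design) with log-normal per-mitochondrion
  heterogeneity, a log-normal per-animal random effect, and known aged
  multipliers (aged mitochondria smaller and rounder);
* 2D **TEM scenes** of elliptical mitochondria with stripe cristae;
* **qPCR plates** (n = 6 biological samples per group, triplicate technical
  replicates) with known per-gene fold changes;
* **OCR traces** as piecewise-constant phase plateaus plus Gaussian noise;
* **lipidomes** (n = 4 per group) with valid ``CLS xx:x/yy:y`` names and
  chosen classes shifted in the aged group.

Every generator is a pure function of (parameters, seed). The single seed
is fanned out through ``numpy`` ``SeedSequence`` spawn keys, one fixed key
per generator, so adding a generator never perturbs the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BoundsError, CapacityError, ValidationError
from .volume_io import LabelVolume, VoxelSpacing

__all__ = [
    "PhantomTruth",
    "CohortConfig",
    "make_phantom",
    "make_cohort",
    "make_tem_scene",
    "make_qpcr",
    "make_ocr",
    "make_lipidome",
]

# fixed per-generator stream ids for SeedSequence spawn keys
_STREAMS = {
    "phantom": 1,
    "cohort": 2,
    "tem": 3,
    "qpcr": 4,
    "ocr": 5,
    "lipidome": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


# ---------------------------------------------------------------------------
# phantoms


@dataclass(frozen=True)
class PhantomTruth:
    kind: str
    volume_um3: float
    surface_um2: float
    extent_um: float
    params: dict
    seed: int
    approximate: bool = False


def _phantom_field(kind: str, params: dict):
    """Return (inside(z, y, x) predicate over nm coordinates, half-extents nm,
    analytic truth in nm units)."""
    if kind == "sphere":
        r = float(params["r_nm"])
        return (
            lambda z, y, x: z * z + y * y + x * x < r * r,
            (r, r, r),
            (4.0 / 3.0 * math.pi * r**3, 4.0 * math.pi * r**2, 2 * r),
            False,
        )
    if kind == "ellipsoid":
        az, ay, ax_ = (float(params[k]) for k in ("a_z_nm", "a_y_nm", "a_x_nm"))

        def inside(z, y, x):
            return (z / az) ** 2 + (y / ay) ** 2 + (x / ax_) ** 2 < 1.0

        v = 4.0 / 3.0 * math.pi * az * ay * ax_
        # Thomsen approximation for ellipsoid surface area (error < 1.1%)
        p = 1.6075
        sa = (
            4.0
            * math.pi
            * ((az**p * ay**p + az**p * ax_**p + ay**p * ax_**p) / 3.0) ** (1.0 / p)
        )
        return inside, (az, ay, ax_), (v, sa, 2 * max(az, ay, ax_)), True
    if kind == "capsule":
        L = float(params["length_nm"])  # cylinder section length
        r = float(params["r_nm"])

        def inside(z, y, x):
            ax_clamped = np.clip(np.abs(x) - L / 2.0, 0.0, None)
            return ax_clamped**2 + y * y + z * z < r * r

        v = math.pi * r * r * L + 4.0 / 3.0 * math.pi * r**3
        sa = 2.0 * math.pi * r * L + 4.0 * math.pi * r**2
        return inside, (r, r, L / 2.0 + r), (v, sa, L + 2 * r), False
    if kind == "branched":
        # union of capsules radiating from the origin along given unit axes
        arms = params["arms"]  # list of dicts: length_nm, r_nm, axis (3-vector)

        def inside(z, y, x):
            hit = np.zeros(np.broadcast(z, y, x).shape, dtype=bool)
            for arm in arms:
                L, r = float(arm["length_nm"]), float(arm["r_nm"])
                u = np.asarray(arm["axis"], dtype=float)
                u = u / np.linalg.norm(u)
                t = np.clip(z * u[0] + y * u[1] + x * u[2], 0.0, L)
                d2 = (z - t * u[0]) ** 2 + (y - t * u[1]) ** 2 + (x - t * u[2]) ** 2
                hit |= d2 < r * r
            return hit

        v = sum(
            math.pi * a["r_nm"] ** 2 * a["length_nm"] + 2.0 / 3.0 * math.pi * a["r_nm"] ** 3
            for a in arms
        )  # overlap at the junction not subtracted: flagged approximate
        sa = sum(
            2 * math.pi * a["r_nm"] * a["length_nm"] + 2 * math.pi * a["r_nm"] ** 2
            for a in arms
        )
        ext = 2 * max(a["length_nm"] + a["r_nm"] for a in arms)
        half = max(a["length_nm"] + a["r_nm"] for a in arms)
        return inside, (half, half, half), (v, sa, ext), True
    raise ValidationError(f"unknown phantom kind {kind!r}")


def make_phantom(
    kind: str,
    params: dict,
    spacing: VoxelSpacing | None = None,
    seed: int = 0,
    margin_voxels: int = 6,
    grid_shape: tuple[int, int, int] | None = None,
    label: int = 1,
) -> tuple[LabelVolume, PhantomTruth]:
    """Rasterize an analytic phantom by voxel-center inclusion.

    The grid is auto-sized to the shape plus ``margin_voxels`` unless
    ``grid_shape`` is given, in which case the shape must fit or a
    :class:`BoundsError` is raised.
    """
    sp = spacing or VoxelSpacing()
    inside, half_extents, (v_nm3, sa_nm2, ext_nm), approx = _phantom_field(kind, params)
    need = (
        2 * (int(np.ceil(half_extents[0] / sp.dz)) + margin_voxels) + 1,
        2 * (int(np.ceil(half_extents[1] / sp.dy)) + margin_voxels) + 1,
        2 * (int(np.ceil(half_extents[2] / sp.dx)) + margin_voxels) + 1,
    )
    shape = grid_shape or need
    if any(s < n for s, n in zip(shape, need)):
        raise BoundsError(f"phantom needs grid {need}, got {shape}")
    nz, ny, nx = shape
    cz, cy, cx = (nz // 2) * sp.dz, (ny // 2) * sp.dy, (nx // 2) * sp.dx
    z = (np.arange(nz) * sp.dz - cz)[:, None, None]
    y = (np.arange(ny) * sp.dy - cy)[None, :, None]
    x = (np.arange(nx) * sp.dx - cx)[None, None, :]
    mask = inside(z, y, x)
    labels = np.where(mask, np.int32(label), np.int32(0))
    truth = PhantomTruth(
        kind=kind,
        volume_um3=v_nm3 / 1e9,
        surface_um2=sa_nm2 / 1e6,
        extent_um=ext_nm / 1e3,
        params=dict(params),
        seed=seed,
        approximate=approx,
    )
    return LabelVolume(labels=labels, spacing=sp, provenance=f"phantom:{kind}"), truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortConfig:
    """Study-scale cohort: 3 animals per age group, ~175 mitochondria each.

    Young metric scales are geometric means of log-normal per-mitochondrion
    distributions; ``animal_sigma`` is the SD of the log-normal per-animal
    random effect. Aged values are the young draws scaled by the multipliers
    (< 1 for size metrics, > 1 for sphericity, matching the observed aging
    direction).
    """

    animals_per_group: int = 3
    mito_per_animal: int = 175
    volume_log_mu: float = math.log(0.4)  # geometric mean 0.4 um^3
    volume_log_sigma: float = 0.8
    surface_log_mu: float = math.log(4.5)  # um^2
    surface_log_sigma: float = 0.6
    perimeter_log_mu: float = math.log(1.2)  # um
    perimeter_log_sigma: float = 0.5
    sphericity_log_mu: float = math.log(0.55)
    sphericity_log_sigma: float = 0.15
    # between-animal CV: age-group differences in this design reach four-star
    # significance with three animals per group, which requires animal-level
    # replicate variation well under 10%
    animal_sigma: float = 0.08
    aged_multipliers: dict = field(
        default_factory=lambda: {
            "volume_um3": 0.6,
            "surface_um2": 0.7,
            "perimeter_um": 0.75,
            "sphericity": 1.15,
        }
    )
    tissue: str = "gastrocnemius"


_COHORT_METRICS = {
    "volume_um3": ("volume_log_mu", "volume_log_sigma"),
    "surface_um2": ("surface_log_mu", "surface_log_sigma"),
    "perimeter_um": ("perimeter_log_mu", "perimeter_log_sigma"),
    "sphericity": ("sphericity_log_mu", "sphericity_log_sigma"),
}


def make_cohort(config: CohortConfig | None = None, seed: int = 0):
    """Simulate a tidy young/aged cohort table with known true multipliers.

    Returns ``(table, truth)`` where the table has the cohort columns
    (animal_id, tissue, group, metric, value) and truth records the aged
    multipliers and the per-animal random effects.
    """
    cfg = config or CohortConfig()
    if cfg.animals_per_group < 1 or cfg.mito_per_animal < 1:
        raise ValidationError("counts must be positive")
    rng = _rng(seed, "cohort")
    rows = []
    animal_effects = {}
    for group in ("young", "aged"):
        for a in range(cfg.animals_per_group):
            animal = f"{group}_{a + 1}"
            effect = rng.lognormal(0.0, cfg.animal_sigma)
            animal_effects[animal] = effect
            for metric, (mu_key, sig_key) in _COHORT_METRICS.items():
                mu = getattr(cfg, mu_key)
                sigma = getattr(cfg, sig_key)
                vals = rng.lognormal(mu, sigma, size=cfg.mito_per_animal) * effect
                if group == "aged":
                    vals = vals * cfg.aged_multipliers[metric]
                if metric == "sphericity":
                    vals = np.minimum(vals, 1.0)
                rows.append(
                    pd.DataFrame(
                        {
                            "animal_id": animal,
                            "tissue": cfg.tissue,
                            "group": group,
                            "metric": metric,
                            "value": vals,
                        }
                    )
                )
    table = pd.concat(rows, ignore_index=True)
    truth = {
        "aged_multipliers": dict(cfg.aged_multipliers),
        "animal_effects": animal_effects,
    }
    return table, truth


# ---------------------------------------------------------------------------
# TEM scenes


def make_tem_scene(
    n_mito: int = 8,
    cristae_per_mito: int = 4,
    pixel_size_nm: float = 10.0,
    seed: int = 0,
    image_shape: tuple[int, int] = (512, 512),
    axis_range_px: tuple[float, float] = (14.0, 40.0),
    aspect_range: tuple[float, float] = (1.2, 2.5),
    max_tries: int = 200,
):
    """Place non-overlapping elliptical mitochondria with stripe cristae.

    Returns ``(mito_labels, cristae_labels, truth)`` where truth is a list
    of per-object dicts: semi-axes, analytic aspect ratio, cristae count and
    the measured fraction of cross-section area lacking cristae.
    """
    rng = _rng(seed, "tem")
    ny, nx = image_shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    mito = np.zeros(image_shape, dtype=np.int32)
    cristae = np.zeros(image_shape, dtype=np.int32)
    truth = []
    crista_label = 0
    for obj in range(1, n_mito + 1):
        for attempt in range(max_tries):
            b = rng.uniform(*axis_range_px)
            ar = rng.uniform(*aspect_range)
            a = b * ar
            theta = rng.uniform(0, math.pi)
            cy = rng.uniform(a + 2, ny - a - 2)
            cx = rng.uniform(a + 2, nx - a - 2)
            ct, st = math.cos(theta), math.sin(theta)
            u = (yy - cy) * ct + (xx - cx) * st
            v = -(yy - cy) * st + (xx - cx) * ct
            mask = (u / a) ** 2 + (v / b) ** 2 < 1.0
            if not (mito[mask] != 0).any():
                break
        else:
            raise CapacityError(
                f"could not place object {obj} after {max_tries} tries; "
                "reduce n_mito or axis range"
            )
        mito[mask] = obj
        # stripe cristae: bands along the major axis coordinate u
        count = 0
        if cristae_per_mito > 0:
            band_centers = np.linspace(-a * 0.7, a * 0.7, cristae_per_mito)
            width = max(2.0, a / (3 * cristae_per_mito))
            for bc in band_centers:
                band = mask & (np.abs(u - bc) < width / 2.0)
                if band.any():
                    crista_label += 1
                    count += 1
                    cristae[band] = crista_label
        area = int(mask.sum())
        lacking = 1.0 - (cristae[mask] > 0).sum() / area
        truth.append(
            {
                "object_id": obj,
                "semi_major_px": a,
                "semi_minor_px": b,
                "aspect_ratio": a / b,
                "area_um2": math.pi * a * b * (pixel_size_nm / 1000.0) ** 2,
                "cristae_count": count,
                "fraction_area_lacking": float(lacking),
            }
        )
    return mito, cristae, truth


# ---------------------------------------------------------------------------
# qPCR plates


def make_qpcr(
    true_fcs: dict[str, float],
    ct_noise_sd: float = 0.2,
    n_per_group: int = 6,
    n_replicates: int = 3,
    seed: int = 0,
    reference_gene: str = "reference",
    control_group: str = "control",
    experimental_group: str = "experimental",
    reference_ct: float = 18.0,
    base_offset: float = 5.0,
) -> pd.DataFrame:
    """Simulate a qPCR plate with known per-gene fold changes.

    Per sample and gene the true Ct is ``reference_ct + base_offset`` in the
    control group and lower by ``log2(FC)`` cycles in the experimental group
    (more transcript = earlier threshold crossing). Each technical replicate
    carries a loading offset shared by every gene in that replicate (template
    amount / pipetting), which is exactly what reference-gene normalization
    removes, plus independent gene-specific cycle noise on the targets.
    """
    rng = _rng(seed, "qpcr")
    rows = []
    for group in (control_group, experimental_group):
        for s in range(n_per_group):
            sample = f"{group}_{s + 1}"
            for rep in range(n_replicates):
                loading = rng.normal(0.0, ct_noise_sd)
                ref_ct = reference_ct + loading
                rows.append(
                    {
                        "sample_id": sample,
                        "group": group,
                        "gene": reference_gene,
                        "replicate": rep + 1,
                        "ct": ref_ct,
                    }
                )
                for gene, fc in true_fcs.items():
                    ct = ref_ct + base_offset + rng.normal(0.0, ct_noise_sd)
                    if group == experimental_group:
                        ct -= math.log2(fc)
                    rows.append(
                        {
                            "sample_id": sample,
                            "group": group,
                            "gene": gene,
                            "replicate": rep + 1,
                            "ct": ct,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# OCR traces


def make_ocr(
    plateaus: tuple[float, float, float, float] = (100.0, 40.0, 160.0, 10.0),
    noise_sd: float = 2.0,
    points_per_phase: int = 3,
    wells: int = 1,
    seed: int = 0,
    dt_min: float = 6.5,
):
    """Piecewise-constant stress-test traces with injection annotations.

    ``plateaus`` are the true (basal, oligomycin, FCCP, rotenone/antimycin)
    OCR levels. Returns ``(measurements, injections, truth)``; truth holds
    the six noiseless summary values implied by the plateaus.
    """
    if len(plateaus) != 4:
        raise ValidationError("need exactly four phase plateaus")
    rng = _rng(seed, "ocr")
    n = 4 * points_per_phase
    times = np.arange(1, n + 1) * dt_min
    rows = []
    for w in range(1, wells + 1):
        level = np.repeat(plateaus, points_per_phase)
        ocr = level + rng.normal(0.0, noise_sd, size=n)
        rows.append(pd.DataFrame({"well": f"W{w}", "time_min": times, "ocr": ocr}))
    measurements = pd.concat(rows, ignore_index=True)
    inj_times = [times[points_per_phase * k - 1] + dt_min / 2.0 for k in (1, 2, 3)]
    injections = pd.DataFrame(
        {"time_min": inj_times, "agent": ["oligomycin", "fccp", "rotenone_antimycin"]}
    )
    b, o, f, r = plateaus
    truth = {
        "non_mito": r,
        "basal": b - r,
        "proton_leak": o - r,
        "atp_linked": (b - r) - (o - r),
        "maximal": f - r,
        "reserve": f - b,
    }
    return measurements, injections, truth


# ---------------------------------------------------------------------------
# lipidomes


_DEFAULT_CLASSES = {"PC": 8, "PE": 8, "TG": 8, "Cer": 6, "CAR": 6, "PS": 6, "PG": 5}


def make_lipidome(
    class_sizes: dict[str, int] | None = None,
    shifted_classes: dict[str, float] | None = None,
    n_per_group: int = 4,
    noise_sd: float = 0.5,
    seed: int = 0,
    base_log_abundance: float = math.log(1e6),
):
    """Simulate a lipid abundance matrix with class-level aged shifts.

    ``shifted_classes`` maps class code -> log2 effect applied to aged
    samples. Returns ``(matrix, groups, truth)``: features x samples raw
    abundances (log-normal), a sample->group Series, and the truth dict.
    Generated names follow the ``CLS xx:x/yy:y`` scheme and all parse.
    """
    sizes = dict(_DEFAULT_CLASSES if class_sizes is None else class_sizes)
    shifts = dict(shifted_classes or {})
    for cls, size in sizes.items():
        if size < 1:
            raise ValidationError(f"class {cls!r} has size {size} < 1")
    rng = _rng(seed, "lipidome")
    features = []
    for cls, size in sizes.items():
        seen = set()
        while len(seen) < size:
            nchains = 3 if cls == "TG" else 2
            chains = "/".join(
                f"{int(rng.integers(6, 12)) * 2}:{int(rng.integers(0, 7))}"
                for _ in range(nchains)
            )
            name = f"{cls} {chains}"
            if name not in seen:
                seen.add(name)
        features.extend(sorted(seen))
    samples = [f"young_{i + 1}" for i in range(n_per_group)] + [
        f"aged_{i + 1}" for i in range(n_per_group)
    ]
    groups = pd.Series(
        ["young"] * n_per_group + ["aged"] * n_per_group, index=samples, name="group"
    )
    base = rng.normal(base_log_abundance, 1.0, size=len(features))
    data = np.exp(
        base[:, None] + rng.normal(0.0, noise_sd * math.log(2), size=(len(features), len(samples)))
    )
    matrix = pd.DataFrame(data, index=features, columns=samples)
    for cls, effect in shifts.items():
        sel = [f for f in features if f.split(" ")[0] == cls]
        matrix.loc[sel, groups == "aged"] *= 2.0**effect
    truth = {"class_sizes": sizes, "shifted_classes": shifts}
    return matrix, groups, truth
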