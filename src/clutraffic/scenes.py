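"""Seeded synthetic fluorescence micrographs with ground-truth masks.

Renders fields of HeLa-like cells expressing an EGFP-tagged secretory
reporter together with the four counter-stains used for quantification
(Golgi marker, ER marker, nuclear stain, F-actin cell outline).  Geometry is
deliberately schematic — smooth blob cells, elliptical nuclei, a perinuclear
crescent of Golgi ribbons, a reticular ER web, Poisson-placed vesicle
puncta — because the purpose is testing intensity-ratio and colocalization
estimators against known truth, not optical realism.

Reporter pixel expectation (per cell, phenotype ``p``)::

    background_level
      + cytoplasm_level * er_unit            on plain cytoplasm
      + p.er_retention * er_unit             on the ER web
      + p.golgi_enrichment * p.er_retention * er_unit   on the Golgi
      + vesicle_amplitude                    on vesicle puncta (additive)

ER and Golgi truth masks are disjoint by construction, so a phenotype with
``golgi_enrichment == 1`` renders the ER∪Golgi union at one constant level.
Noise is scaled-Poisson shot noise plus additive Gaussian read noise,
clipped at zero; an optional Gaussian blur stands in for the PSF.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .exceptions import ParameterError, PlacementError
from .phenotypes import GenotypePhenotype

__all__ = [
    "NoiseParams",
    "RenderParams",
    "SceneTruth",
    "SyntheticScene",
    "make_scene",
    "write_scene",
    "read_scene",
    "read_image_with_rois",
]

#: Fixed channel order for in-memory dicts and multi-page TIFF output.
CHANNEL_ORDER = ("reporter", "golgi", "er", "nucleus", "actin")
#: Fixed page order of the truth-mask TIFF.
TRUTH_ORDER = ("cell", "nucleus", "er", "golgi", "vesicle")


@dataclass(frozen=True)
class NoiseParams:
    """Acquisition noise model.

    ``shot_scale`` converts expected intensity to photon counts: observed =
    Poisson(E/shot_scale) * shot_scale.  0 disables shot noise.  ``blur_sigma``
    (px) applies a Gaussian blur to the expectation before noise; default off.
    """

    background_level: float = 100.0
    background_sd: float = 5.0
    shot_scale: float = 1.0
    blur_sigma: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"noise parameter {f.name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class RenderParams:
    """Intensity amplitudes (arbitrary 16-bit-range units)."""

    er_unit: float = 400.0  # reporter amplitude at er_retention == 1
    cytoplasm_level: float = 0.0  # diffuse reporter, in er_unit multiples
    vesicle_amplitude: float = 1500.0
    marker_amplitude: float = 3000.0  # counter-stain amplitude
    cell_radius: float = 28.0  # mean cell radius, px


@dataclass
class SceneTruth:
    """Ground-truth label masks; 0 = background, value = owning cell id."""

    cell: np.ndarray
    nucleus: np.ndarray
    er: np.ndarray
    golgi: np.ndarray
    vesicle: np.ndarray

    def as_stack(self) -> np.ndarray:
        return np.stack([getattr(self, name) for name in TRUTH_ORDER])


@dataclass
class SyntheticScene:
    """One rendered field: channel images plus the truth that generated them."""

    channels: dict[str, np.ndarray]
    pixel_size: float
    truth: SceneTruth
    seed: int
    phenotype_by_cell: dict[int, str]
    phenotypes: dict[str, GenotypePhenotype] = field(default_factory=dict)

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.phenotype_by_cell)

    def cell_mask(self, cell_id: int) -> np.ndarray:
        return self.truth.cell == cell_id


# ---------------------------------------------------------------------------
# geometry

def _blob_mask(shape, center, r0, rng):
    """Fourier-perturbed ellipse rasterised into the full frame."""
    amps = rng.uniform(0.02, 0.08, size=4)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    half = int(r0 * 1.5) + 3
    r0i, c0i = int(round(center[0])), int(round(center[1]))
    rs = slice(max(r0i - half, 0), min(r0i + half + 1, shape[0]))
    cs = slice(max(c0i - half, 0), min(c0i + half + 1, shape[1]))
    yy, xx = np.mgrid[rs, cs]
    dy, dx = yy - center[0], xx - center[1]
    theta = np.arctan2(dy, dx)
    radius = r0 * (
        1.0
        + sum(a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amps, phases)))
    )
    mask = np.zeros(shape, dtype=bool)
    mask[rs, cs] = np.hypot(dy, dx) <= radius
    return mask


def _ellipse_mask(shape, center, axes, angle):
    half = int(max(axes)) + 2
    r0i, c0i = int(round(center[0])), int(round(center[1]))
    rs = slice(max(r0i - half, 0), min(r0i + half + 1, shape[0]))
    cs = slice(max(c0i - half, 0), min(c0i + half + 1, shape[1]))
    yy, xx = np.mgrid[rs, cs]
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dy * ca + dx * sa
    v = -dy * sa + dx * ca
    mask = np.zeros(shape, dtype=bool)
    mask[rs, cs] = (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0
    return mask


def _golgi_mask(shape, nuc_center, nuc_radius, toward, rng, cell_mask, nucleus_mask):
    """Perinuclear crescent of 2–4 concentric cisterna ribbons."""
    n_ribbons = int(rng.integers(2, 5))
    width = rng.uniform(0.75, 1.1)  # angular half-width, rad
    theta0 = toward + rng.normal(0, 0.25)
    half = int(nuc_radius + 4 + 3.2 * n_ribbons) + 2
    r0i, c0i = int(round(nuc_center[0])), int(round(nuc_center[1]))
    rs = slice(max(r0i - half, 0), min(r0i + half + 1, shape[0]))
    cs = slice(max(c0i - half, 0), min(c0i + half + 1, shape[1]))
    yy, xx = np.mgrid[rs, cs]
    dy, dx = yy - nuc_center[0], xx - nuc_center[1]
    dist = np.hypot(dy, dx)
    dang = np.angle(np.exp(1j * (np.arctan2(dy, dx) - theta0)))
    local = np.zeros_like(dist, dtype=bool)
    for j in range(n_ribbons):
        rj = nuc_radius + 2.5 + 3.2 * j
        local |= (np.abs(dist - rj) <= 1.3) & (np.abs(dang) <= width * (1 - 0.08 * j))
    mask = np.zeros(shape, dtype=bool)
    mask[rs, cs] = local
    return mask & cell_mask & ~nucleus_mask


def _er_mask(bandpass_field, cytoplasm, quantile=0.55):
    """Reticular web: upper tail of a band-pass noise field within cytoplasm."""
    if not cytoplasm.any():
        return np.zeros_like(cytoplasm)
    vals = bandpass_field[cytoplasm]
    thr = np.quantile(vals, quantile)
    return cytoplasm & (bandpass_field > thr)


def _place_centers(shape, radii, rng, margin=4.0, max_attempts=5000):
    centers = []
    for i, r in enumerate(radii):
        lo_r, hi_r = r + 2, shape[0] - r - 2
        lo_c, hi_c = r + 2, shape[1] - r - 2
        if hi_r <= lo_r or hi_c <= lo_c:
            raise PlacementError(i, 0)
        for _ in range(max_attempts):
            cand = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
            if all(
                np.hypot(cand[0] - c[0], cand[1] - c[1]) > r + radii[j] + margin
                for j, c in enumerate(centers)
            ):
                centers.append(cand)
                break
        else:
            raise PlacementError(i, max_attempts)
    return centers


# ---------------------------------------------------------------------------
# noise

def _apply_noise(expectation, rng, noise):
    img = expectation
    if noise.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, noise.blur_sigma)
    if noise.shot_scale > 0:
        img = rng.poisson(img / noise.shot_scale).astype(float) * noise.shot_scale
    if noise.background_sd > 0:
        img = img + rng.normal(0.0, noise.background_sd, size=img.shape)
    return np.clip(img, 0.0, None)


# ---------------------------------------------------------------------------
# main entry point

def make_scene(
    n_cells: int,
    phenotypes: list[GenotypePhenotype],
    image_shape: tuple[int, int] = (420, 420),
    noise: NoiseParams | None = None,
    seed: int = 0,
    render: RenderParams | None = None,
    pixel_size: float = 0.106,
) -> SyntheticScene:
    """Generate one synthetic field of cells.

    Cells are assigned phenotypes by cycling through ``phenotypes`` in order
    (cell id 1 gets the first entry).  Identical arguments and seed reproduce
    the arrays bit for bit.

    Raises
    ------
    PlacementError
        If ``n_cells`` non-overlapping cells cannot be placed in the frame.
    """
    if n_cells < 1:
        raise ParameterError(f"n_cells must be >= 1, got {n_cells}")
    if not phenotypes:
        raise ParameterError("phenotypes must be non-empty")
    noise = noise or NoiseParams()
    render = render or RenderParams()
    rng = np.random.default_rng(seed)
    shape = tuple(image_shape)

    radii = render.cell_radius * rng.uniform(0.85, 1.15, size=n_cells)
    centers = _place_centers(shape, radii, rng)

    truth = SceneTruth(*(np.zeros(shape, dtype=np.uint16) for _ in TRUTH_ORDER))
    # one band-pass field drives every cell's ER web
    white = rng.normal(size=shape)
    bandpass = ndimage.gaussian_filter(white, 1.1) - ndimage.gaussian_filter(white, 3.5)

    phenotype_by_cell: dict[int, str] = {}
    assigned = {p.name: p for p in phenotypes}
    reporter = np.full(shape, float(noise.background_level))
    golgi_ch = np.full(shape, float(noise.background_level))
    er_ch = np.full(shape, float(noise.background_level))
    nuc_ch = np.full(shape, float(noise.background_level))
    actin_ch = np.full(shape, float(noise.background_level))

    for i, (center, r0) in enumerate(zip(centers, radii)):
        cell_id = i + 1
        pheno = phenotypes[i % len(phenotypes)]
        phenotype_by_cell[cell_id] = pheno.name

        cell = _blob_mask(shape, center, r0, rng)
        off_dir = rng.uniform(0, 2 * np.pi)
        nuc_center = (
            center[0] + 0.22 * r0 * np.sin(off_dir),
            center[1] + 0.22 * r0 * np.cos(off_dir),
        )
        nuc_axes = (0.42 * r0, 0.33 * r0)
        nucleus = _ellipse_mask(shape, nuc_center, nuc_axes, rng.uniform(0, np.pi))
        nucleus &= ndimage.binary_erosion(cell, iterations=2)

        toward = np.arctan2(center[0] - nuc_center[0], center[1] - nuc_center[1])
        toward = np.arctan2(np.sin(toward), np.cos(toward))
        golgi = _golgi_mask(
            shape, nuc_center, max(nuc_axes), toward, rng, cell, nucleus
        )
        cytoplasm = cell & ~nucleus & ~golgi
        er = _er_mask(bandpass, cytoplasm)

        n_ves = rng.poisson(pheno.vesicle_density)
        vesicle = np.zeros(shape, dtype=bool)
        cyto_idx = np.flatnonzero(cytoplasm)
        if n_ves > 0 and cyto_idx.size:
            picks = rng.choice(cyto_idx, size=n_ves, replace=False if n_ves <= cyto_idx.size else True)
            seeds = np.zeros(shape, dtype=bool)
            seeds.flat[picks] = True
            vesicle = ndimage.binary_dilation(seeds, structure=ndimage.generate_binary_structure(2, 2), iterations=2)
            vesicle &= cell

        truth.cell[cell] = cell_id
        truth.nucleus[nucleus] = cell_id
        truth.er[er] = cell_id
        truth.golgi[golgi] = cell_id
        truth.vesicle[vesicle] = cell_id

        er_amp = pheno.er_retention * render.er_unit
        reporter[cytoplasm & ~er] += render.cytoplasm_level * render.er_unit
        reporter[er] += er_amp
        reporter[golgi] += pheno.golgi_enrichment * er_amp
        reporter[vesicle] += render.vesicle_amplitude

        golgi_ch[golgi] += render.marker_amplitude
        er_ch[er] += render.marker_amplitude
        nuc_ch[nucleus] += render.marker_amplitude
        actin_ch[cell] += 0.4 * render.marker_amplitude

    expectations = {
        "reporter": reporter,
        "golgi": golgi_ch,
        "er": er_ch,
        "nucleus": nuc_ch,
        "actin": actin_ch,
    }
    channels = {
        name: _apply_noise(expectations[name], rng, noise) for name in CHANNEL_ORDER
    }
    return SyntheticScene(
        channels=channels,
        pixel_size=pixel_size,
        truth=truth,
        seed=seed,
        phenotype_by_cell=phenotype_by_cell,
        phenotypes=assigned,
    )


# ---------------------------------------------------------------------------
# on-disk format: multi-page 16-bit TIFF + JSON sidecar

def write_scene(scene: SyntheticScene, directory: str | Path, stem: str = "scene") -> dict[str, Path]:
    """Write channels, truth labels and a JSON sidecar; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_path = directory / f"{stem}.tif"
    truth_path = directory / f"{stem}_truth.tif"
    meta_path = directory / f"{stem}.json"

    stack = np.stack([scene.channels[name] for name in CHANNEL_ORDER])
    tifffile.imwrite(img_path, np.clip(stack, 0, 65535).astype(np.uint16))
    tifffile.imwrite(truth_path, scene.truth.as_stack().astype(np.uint16))
    meta = {
        "seed": scene.seed,
        "pixel_size_um": scene.pixel_size,
        "channel_order": list(CHANNEL_ORDER),
        "truth_order": list(TRUTH_ORDER),
        "phenotype_by_cell": {str(k): v for k, v in scene.phenotype_by_cell.items()},
        "phenotypes": {
            name: dataclasses.asdict(p) for name, p in scene.phenotypes.items()
        },
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return {"image": img_path, "truth": truth_path, "meta": meta_path}


def read_scene(directory: str | Path, stem: str = "scene") -> SyntheticScene:
    """Read a scene written by :func:`write_scene` (intensities as float)."""
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}.json").read_text())
    stack = tifffile.imread(directory / f"{stem}.tif").astype(float)
    truth_stack = tifffile.imread(directory / f"{stem}_truth.tif")
    channels = {name: stack[i] for i, name in enumerate(meta["channel_order"])}
    truth = SceneTruth(*(truth_stack[i] for i in range(len(TRUTH_ORDER))))
    phenos = {
        name: GenotypePhenotype(**kw) for name, kw in meta.get("phenotypes", {}).items()
    }
    return SyntheticScene(
        channels=channels,
        pixel_size=meta["pixel_size_um"],
        truth=truth,
        seed=meta["seed"],
        phenotype_by_cell={int(k): v for k, v in meta["phenotype_by_cell"].items()},
        phenotypes=phenos,
    )


def read_image_with_rois(
    image_path: str | Path,
    roi_path: str | Path,
    meta_path: str | Path | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray, dict[int, str]]:
    """Read a channel TIFF plus a cell label-mask TIFF (manual delineations).

    Returns (channels, cell_labels, genotype_by_cell); the genotype map is
    empty when no sidecar JSON is given.
    """
    stack = tifffile.imread(image_path).astype(float)
    order = CHANNEL_ORDER
    genotype_by_cell: dict[int, str] = {}
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())
        order = tuple(meta.get("channel_order", CHANNEL_ORDER))
        genotype_by_cell = {
            int(k): v for k, v in meta.get("phenotype_by_cell", {}).items()
        }
    channels = {name: stack[i] for i, name in enumerate(order)}
    rois = tifffile.imread(roi_path)
    if rois.ndim == 3:  # truth stack: first page is the cell labels
        rois = rois[0]
    return channels, rois.astype(np.int64), genotype_by_cell
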