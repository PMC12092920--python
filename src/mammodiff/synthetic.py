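"""Synthetic mammogram-like cases and simulated reader panels.

Real screening mammograms and reader ratings from educational test-set
programmes are restricted data, so this module fabricates a population
with the same shape and a *known* planted signal:

* breast-shaped binary masks (half-ellipse with a perturbed boundary,
  chest wall on the image edge);
* four views per case (LCC, RCC, LMLO, RMLO), right views generated in
  right orientation so the preprocessing flip is exercised;
* class-dependent texture in exactly two respects — hardest-to-interpret
  cases carry bright/dark blob clusters symmetric about the parenchymal
  mean (thickening both gray-level tails, which the fourth GLCM co-moment,
  cluster prominence, picks up on the inscribed square) and a per-block
  intensity-range jitter (raising the across-block SD of the first-order
  range without moving any block's quantised gray levels) — while every
  other texture parameter is class-independent, and the parenchymal
  field's amplitude and grain vary per case as class-independent nuisance;
* a reader panel whose per-case probability of a false-positive call
  equals a latent difficulty on the logistic scale, with Normal reader
  bias.

Every output is a pure function of (config, seed).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import BreastMask, GrayImage

VIEW_NAMES = ("LCC", "RCC", "LMLO", "RMLO")

HARDEST, EASIEST, MIDDLE = "hardest", "easiest", "middle"


@dataclass(frozen=True)
class TextureParams:
    """Texture recipe for one image.

    base_intensity / field_sd / field_scale describe the smooth parenchymal
    random field (8-bit units; field_scale is the Gaussian correlation
    length in pixels). The two *planted*, difficulty-dependent parameters
    are ``blob_count`` (bright/dark Gaussian blob clusters of spatial scale
    ``blob_sigma``, dealt evenly across the lattice cells, with intensity
    targets symmetric about the field mean) and ``range_jitter_sd`` (the SD
    of a one-sided multiplicative darkening applied per lattice cell outside
    the inscribed square, which scales each block's intensity range without
    moving its min-max-quantised gray levels).

    When ``range_markers`` is on (the default) every lattice cell receives
    a tiny zero-valued marker dot and a ``bright_target`` dot: the dots pin
    each block's minimum and maximum so that block ranges respond cleanly
    to the jitter and the quantisation bins are stable across images.
    """

    base_intensity: float = 172.0
    field_sd: float = 16.0
    field_scale: float = 9.0
    blob_count: int = 0
    blob_sigma: float = 8.0
    extreme_offset: float = 65.0
    range_jitter_sd: float = 0.0
    range_jitter_floor: float = 0.88
    jitter_cell: int = 214
    range_markers: bool = True

    @property
    def bright_target(self) -> float:
        return self.base_intensity + self.extreme_offset

    @property
    def dark_target(self) -> float:
        return self.base_intensity - self.extreme_offset



#: class-dependent defaults: only blob_count and range_jitter_sd differ.
EASIEST_TEXTURE = TextureParams(blob_count=0, range_jitter_sd=0.030)
HARDEST_TEXTURE = TextureParams(blob_count=22, blob_sigma=10.0, range_jitter_sd=0.044)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped defaults: 280 cases read by 137 trainees, 4 views/case."""

    image_height: int = 1600
    image_width: int = 640
    easiest_texture: TextureParams = EASIEST_TEXTURE
    hardest_texture: TextureParams = HARDEST_TEXTURE
    #: proportions of (hardest, easiest, middle) difficulty classes
    class_proportions: tuple[float, float, float] = (0.25, 0.25, 0.5)
    #: P(BI-RADS A, B, C, D)
    density_proportions: tuple[float, float, float, float] = (0.1, 0.4, 0.4, 0.1)
    #: added to base_intensity for high-density (C/D) cases; C/D fields are
    #: also finer-grained (field_scale scaled by density_scale_factor)
    density_intensity_boost: float = 18.0
    density_scale_factor: float = 0.7
    #: class-independent per-case nuisance: the parenchymal field's SD and
    #: correlation length are drawn uniformly from these ranges, emulating
    #: the natural case-to-case variability of breast texture
    field_sd_range: tuple[float, float] = (13.0, 16.0)
    field_scale_range: tuple[float, float] = (7.0, 11.0)
    reader_bias_sd: float = 0.4
    missing_rate: float = 0.0


@dataclass(frozen=True)
class CaseSpec:
    case_id: str
    latent_difficulty: float
    difficulty_class: str
    density_class: str
    seed: int


@dataclass
class SyntheticDataset:
    cases: list[CaseSpec]
    #: case_id -> view name -> (image, mask)
    images: dict[str, dict[str, tuple[GrayImage, BreastMask]]]
    #: readers x cases rating matrix (values 1..5, NaN where missing)
    ratings: pd.DataFrame
    #: per-case ground truth: latent_difficulty, difficulty_class, density_class
    truth: pd.DataFrame
    config: GeneratorConfig = field(default_factory=GeneratorConfig)


def make_breast_mask(height: int, width: int, laterality: str, seed: int) -> BreastMask:
    """A connected, hole-free half-elliptical breast shape.

    The chest wall runs along the left edge for laterality L, the right
    edge for R (the R mask is the exact mirror of the L mask for the same
    seed). The boundary is mildly perturbed by smooth row-wise noise.
    """
    if height < 64 or width < 64:
        raise ValueError(f"mask dimensions must be >= 64, got {height}x{width}")
    if laterality not in ("L", "R"):
        raise ValueError(f"laterality must be L or R, got {laterality!r}")
    rng = np.random.default_rng(seed)
    b = 0.42 * height  # vertical semi-axis
    a = 0.88 * width   # horizontal semi-axis
    centre = height / 2.0
    rows = np.arange(height)
    rel = (rows - centre) / b
    inside = np.abs(rel) < 1.0
    extent = np.zeros(height)
    extent[inside] = a * np.sqrt(1.0 - rel[inside] ** 2)
    wobble = ndimage.gaussian_filter1d(rng.standard_normal(height), 25.0)
    wobble /= max(np.abs(wobble).max(), 1e-12)
    extent[inside] *= 1.0 + 0.06 * wobble[inside]
    cols = np.arange(width)
    mask = cols[None, :] < np.clip(extent, 0, width)[:, None]
    if laterality == "R":
        mask = mask[:, ::-1]
    return BreastMask(pixels=np.ascontiguousarray(mask))


def make_texture(mask: BreastMask, params: TextureParams, seed: int) -> GrayImage:
    """Render the breast texture for one mask into an 8-bit image.

    Background is exactly 0. The foreground is a smoothed Gaussian random
    field. The lattice grid is anchored at the mask's bounding-box origin
    (so it coincides with the block grid a downstream crop would use).
    Blob clusters pull pixels alternately towards ``bright_target`` and
    ``dark_target`` (symmetric about the field mean, thickening both tails
    of the gray-level distribution) and are dealt round-robin across the
    lattice cells so every block carries the same expected blob mass.
    Marker dots then pin every cell's minimum at 0 and maximum at
    ``bright_target``, and cells outside the inscribed square are darkened
    by a per-cell factor 1 - |N(0, range_jitter_sd)| — a pure rescaling
    that leaves each block's min-max-quantised gray levels untouched while
    scaling its intensity range to g * bright_target exactly.
    """
    from .roi import largest_inscribed_square

    m = mask.pixels
    if not m.any():
        raise ValueError("mask is empty")
    rng = np.random.default_rng(seed)
    h, w = m.shape
    field = np.full((h, w), params.base_intensity)
    if params.field_sd > 0:
        noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), params.field_scale)
        noise /= noise.std()
        # clip rare excursions so the foreground always clears the
        # segmentation threshold (100) even after the darkest range jitter
        noise = np.clip(noise, -3.2, 3.2)
        field = field + params.field_sd * noise

    sq = largest_inscribed_square(mask)
    fg_rows = np.flatnonzero(m.any(axis=1))
    fg_cols = np.flatnonzero(m.any(axis=0))
    anchor_r, anchor_c = int(fg_rows[0]), int(fg_cols[0])
    cell = params.jitter_cell

    # enumerate lattice cells once (row-major, deterministic)
    cells = []
    for r0 in range(anchor_r, h, cell):
        for c0 in range(anchor_c, w, cell):
            sl = np.s_[r0:r0 + cell, c0:c0 + cell]
            cell_fg = m[sl]
            if not cell_fg.any():
                continue
            r1, c1 = min(r0 + cell, h), min(c0 + cell, w)
            in_sq = not (
                r1 <= sq.row0 or r0 >= sq.row0 + sq.size
                or c1 <= sq.col0 or c0 >= sq.col0 + sq.size
            )
            eroded = ndimage.binary_erosion(cell_fg, np.ones((5, 5), dtype=bool))
            cells.append((r0, c0, sl, cell_fg, in_sq, np.nonzero(eroded)))

    if params.blob_count > 0:
        half = int(np.ceil(3 * params.blob_sigma))
        span = np.arange(-half, half + 1)
        bump = np.exp(-(span[:, None] ** 2 + span[None, :] ** 2) / (2 * params.blob_sigma**2))
        usable = [c for c in cells if c[5][0].size > 0]
        for k in range(params.blob_count):
            r0, c0, _, _, _, (er, ec) = usable[k % len(usable)]
            j = int(rng.integers(er.size))
            r, c = r0 + int(er[j]), c0 + int(ec[j])
            target = params.bright_target if k % 2 == 0 else params.dark_target
            pr0, pr1 = max(0, r - half), min(h, r + half + 1)
            pc0, pc1 = max(0, c - half), min(w, c + half + 1)
            patch = bump[pr0 - (r - half):pr1 - (r - half),
                         pc0 - (c - half):pc1 - (c - half)]
            psl = np.s_[pr0:pr1, pc0:pc1]
            field[psl] = (1.0 - patch) * field[psl] + patch * target

    for r0, c0, sl, cell_fg, in_sq, (er, ec) in cells:
        if params.range_markers and er.size >= 2:
            # marker dots overwrite any blob pixels and go in before the
            # jitter so they scale with the cell: every block's range
            # becomes g * bright_target exactly
            mid, alt = er.size // 2, er.size // 4
            if abs(int(er[mid]) - int(er[alt])) + abs(int(ec[mid]) - int(ec[alt])) < 4:
                alt = 0
            rz, cz = r0 + int(er[mid]), c0 + int(ec[mid])
            rb, cb = r0 + int(er[alt]), c0 + int(ec[alt])
            field[rz:rz + 2, cz:cz + 2] = 0.0
            field[rb:rb + 2, cb:cb + 2] = params.bright_target
        if not in_sq and params.range_jitter_sd > 0:
            g = max(1.0 - abs(rng.normal(0.0, params.range_jitter_sd)),
                    params.range_jitter_floor)
            field[sl][cell_fg] *= g  # pure scale: quantised levels unchanged

    out = np.zeros((h, w))
    out[m] = field[m]
    out = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    out[~m] = 0
    return GrayImage(pixels=out, bits_stored=8, photometric="MONO2")


def _texture_for_case(config: GeneratorConfig, spec: CaseSpec) -> TextureParams:
    """Class texture parameters: hardest and easiest cases use their class
    presets; middle cases interpolate the two planted parameters
    (blob_count, range_jitter_sd) by latent difficulty. All other texture
    parameters are identical across classes."""
    e, hrd = config.easiest_texture, config.hardest_texture
    if spec.difficulty_class == HARDEST:
        return hrd
    if spec.difficulty_class == EASIEST:
        return e
    t = float(np.clip(spec.latent_difficulty, 0.0, 1.0))
    return replace(
        e,
        blob_count=int(round(e.blob_count + t * (hrd.blob_count - e.blob_count))),
        range_jitter_sd=e.range_jitter_sd + t * (hrd.range_jitter_sd - e.range_jitter_sd),
    )


def make_case(
    spec: CaseSpec,
    config: GeneratorConfig = GeneratorConfig(),
) -> dict[str, tuple[GrayImage, BreastMask]]:
    """The four view images (+ masks) of one case.

    Right-laterality views are generated in right orientation (chest wall
    at the right edge). High-density cases (BI-RADS C/D) get a brighter,
    finer-grained parenchymal field than low-density (A/B) cases.
    """
    params = _texture_for_case(config, spec)
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(VIEW_NAMES) + 1)
    nuisance_rng = np.random.default_rng(children[0])
    params = replace(
        params,
        field_sd=nuisance_rng.uniform(*config.field_sd_range),
        field_scale=nuisance_rng.uniform(*config.field_scale_range),
    )
    if spec.density_class in ("C", "D"):
        params = replace(
            params,
            base_intensity=params.base_intensity + config.density_intensity_boost,
            field_scale=params.field_scale * config.density_scale_factor,
        )
    out: dict[str, tuple[GrayImage, BreastMask]] = {}
    for child, view_name in zip(children[1:], VIEW_NAMES):
        mask_seed, tex_seed = (int(s) for s in child.generate_state(2) >> 1)
        laterality, view = view_name[0], view_name[1:]
        # render in left orientation, mirror right views afterwards: the
        # preprocessing flip then restores the rendered grid exactly
        mask = make_breast_mask(config.image_height, config.image_width, "L", mask_seed)
        img = make_texture(mask, params, tex_seed)
        pixels, mpix = img.pixels, mask.pixels
        if laterality == "R":
            pixels = np.ascontiguousarray(pixels[:, ::-1])
            mpix = np.ascontiguousarray(mpix[:, ::-1])
        out[view_name] = (
            GrayImage(pixels=pixels, view=view, laterality=laterality,
                      bits_stored=8, photometric="MONO2"),
            BreastMask(pixels=mpix),
        )
    return out


def simulate_ratings(
    latent_difficulties,
    n_readers: int,
    reader_bias_sd: float = 0.4,
    seed: int = 0,
    missing_rate: float = 0.0,
    case_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulated 1-5 ratings of a reader panel (readers x cases).

    Reader r misclassifies case c (rating in {3,4,5}, uniformly) with
    probability logistic(logit(d_c) + b_r), b_r ~ Normal(0, reader_bias_sd);
    otherwise the rating is uniform on {1,2}. Latent difficulties of
    exactly 0 or 1 force the corresponding side.
    """
    d = np.asarray(latent_difficulties, dtype=np.float64)
    if ((d < 0) | (d > 1)).any():
        raise ValueError("latent difficulties must lie in [0, 1]")
    if n_readers < 1:
        raise ValueError("n_readers must be >= 1")
    rng = np.random.default_rng(seed)
    bias = rng.normal(0.0, reader_bias_sd, size=n_readers) if reader_bias_sd > 0 else np.zeros(n_readers)
    with np.errstate(divide="ignore"):
        logit = np.log(d) - np.log1p(-d)  # +/- inf at the boundaries
    p = 1.0 / (1.0 + np.exp(-(logit[None, :] + bias[:, None])))
    p = np.where(d[None, :] == 0.0, 0.0, np.where(d[None, :] == 1.0, 1.0, p))
    miss = rng.random(p.shape) < p
    low = rng.integers(1, 3, size=p.shape)
    high = rng.integers(3, 6, size=p.shape)
    scores = np.where(miss, high, low).astype(np.float64)
    if missing_rate > 0:
        scores[rng.random(p.shape) < missing_rate] = np.nan
    if case_ids is None:
        case_ids = [f"case{i:04d}" for i in range(d.size)]
    return pd.DataFrame(
        scores,
        index=[f"reader{r:03d}" for r in range(n_readers)],
        columns=case_ids,
    )


_DIFFICULTY_CLASSES = (HARDEST, EASIEST, MIDDLE)


def _draw_latent_difficulty(rng: np.random.Generator, cls: str) -> float:
    """Class-conditional latent difficulty on disjoint supports.

    Beta shapes follow the easiest-leaning Beta(2,5) / hardest-leaning
    Beta(5,2) convention, affinely mapped so that any hardest draw strictly
    exceeds any easiest draw: easiest in (0, 0.35), middle in (0.35, 0.45),
    hardest in (0.45, 0.95).
    """
    if cls == EASIEST:
        return float(0.35 * rng.beta(2, 5))
    if cls == HARDEST:
        return float(0.45 + 0.5 * rng.beta(5, 2))
    return float(0.35 + 0.10 * rng.beta(2, 2))


def make_dataset(
    n_cases: int = 280,
    n_readers: int = 137,
    config: GeneratorConfig = GeneratorConfig(),
    seed: int = 0,
    generate_images: bool = True,
) -> SyntheticDataset:
    """A full synthetic study: cases, 4-view images, ratings, ground truth.

    Difficulty classes are assigned by ``config.class_proportions`` (the
    default quarters mirror an upper/lower-quartile retention design);
    density classes are drawn independently. ``generate_images=False``
    skips pixel synthesis when only ratings/truth are needed.
    """
    if n_cases < 8:
        raise ValueError("n_cases must be >= 8")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD1F]))
    props = np.asarray(config.class_proportions, dtype=np.float64)
    counts = np.floor(props / props.sum() * n_cases).astype(int)
    while counts.sum() < n_cases:
        counts[int(np.argmin(counts / np.maximum(props, 1e-12)))] += 1
    classes = np.repeat(_DIFFICULTY_CLASSES, counts)
    rng.shuffle(classes)
    densities = rng.choice(list("ABCD"), size=n_cases, p=config.density_proportions)

    cases = [
        CaseSpec(
            case_id=f"case{i:04d}",
            latent_difficulty=_draw_latent_difficulty(rng, cls),
            difficulty_class=str(cls),
            density_class=str(dens),
            seed=int(rng.integers(2**31 - 1)),
        )
        for i, (cls, dens) in enumerate(zip(classes, densities))
    ]
    images = {c.case_id: make_case(c, config) for c in cases} if generate_images else {}
    ratings = simulate_ratings(
        [c.latent_difficulty for c in cases],
        n_readers,
        reader_bias_sd=config.reader_bias_sd,
        seed=int(rng.integers(2**31 - 1)),
        missing_rate=config.missing_rate,
        case_ids=[c.case_id for c in cases],
    )
    truth = pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "latent_difficulty": [c.latent_difficulty for c in cases],
            "difficulty_class": [c.difficulty_class for c in cases],
            "density_class": [c.density_class for c in cases],
        }
    ).set_index("case_id")
    return SyntheticDataset(cases=cases, images=images, ratings=ratings,
                            truth=truth, config=config)


def planted_dataset(
    n_cases: int = 140,
    n_readers: int = 137,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    generate_images: bool = True,
) -> SyntheticDataset:
    """The default planted-signal benchmark: a balanced hardest/easiest set."""
    base = config or GeneratorConfig()
    cfg = replace(base, class_proportions=(0.5, 0.5, 0.0))
    return make_dataset(n_cases, n_readers, cfg, seed, generate_images=generate_images)


# ---------------------------------------------------------------------------
# on-disk round trip


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write images (8-bit TIFF), a manifest, tidy ratings, and ground truth.

    Layout: images/<case>_<view>.tiff, masks/<case>_<view>.tiff,
    manifest.csv (case_id, view, laterality, path), ratings.csv
    (reader_id, case_id, score), truth.csv, generator.json.
    """
    import tifffile

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    manifest = []
    for case_id, views in dataset.images.items():
        for view_name, (img, mask) in views.items():
            rel = f"images/{case_id}_{view_name}.tiff"
            tifffile.imwrite(out / rel, img.pixels)
            tifffile.imwrite(out / f"masks/{case_id}_{view_name}.tiff",
                             mask.pixels.astype(np.uint8) * 255)
            manifest.append((case_id, img.view, img.laterality, rel))
    pd.DataFrame(manifest, columns=["case_id", "view", "laterality", "path"]).to_csv(
        out / "manifest.csv", index=False
    )
    tidy = (
        dataset.ratings.stack()
        .rename_axis(["reader_id", "case_id"])
        .rename("score")
        .reset_index()
    )
    tidy["score"] = tidy["score"].astype(int)
    tidy.to_csv(out / "ratings.csv", index=False)
    dataset.truth.to_csv(out / "truth.csv")
    (out / "generator.json").write_text(json.dumps(asdict(dataset.config), indent=2))
    return out


def write_dicom(img: GrayImage, path: str | Path) -> Path:
    """Minimal secondary-capture DICOM writer (for reader round trips)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MG"
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.SamplesPerPixel = 1
    ds.ImageLaterality = img.laterality if img.laterality in ("L", "R") else "L"
    ds.ViewPosition = img.view
    pixels = np.ascontiguousarray(img.pixels)
    if pixels.dtype != np.uint8:
        pixels = pixels.astype(np.uint16)
    ds.Rows, ds.Columns = pixels.shape
    ds.BitsAllocated = 8 * pixels.dtype.itemsize
    ds.BitsStored = img.bits_stored
    ds.HighBit = img.bits_stored - 1
    ds.PixelRepresentation = 0
    ds.PixelData = pixels.tobytes()
    pydicom.dcmwrite(path, ds)
    return Path(path)
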