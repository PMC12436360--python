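"""Synthetic orbital-radiograph phantoms with ground-truth fracture labels.

Real orbital-rim-view radiographs are not redistributable, so studies of
the pairing/training/evaluation pipeline run on phantoms that keep the
ingredients the method actually needs: a global image (head outline on a
background gradient), an informative ROI (the head/orbit region), and a
localized class signal (a fracture-like discontinuity in one orbital rim).

A phantom is an elliptical "skull" outline with two bright annular
orbital rims on a vertical background gradient plus white noise.  A
positive sample interrupts one rim with a gap of amplitude
``fracture_contrast`` over an angular sector whose position encodes the
fracture site (floor = inferior, medial = nasal, superior, lateral, or
two sectors for "multiple").  The negative render from the same seed is
identical outside the fracture sector, including the noise realization.

Default class balance mirrors the clinical population the generator
emulates: 18% prevalence, and fracture sites distributed as
floor 116/330, medial 91/330, superior 16/330, lateral 3/330,
multiple 104/330.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SITES",
    "RadiographSample",
    "PhantomConfig",
    "ManifestRecord",
    "DatasetManifest",
    "render_phantom",
    "generate_phantom_dataset",
    "crop_roi",
    "split_dataset",
    "subsample_negatives",
    "save_png",
    "load_image",
    "read_dicom_image",
    "materialize",
]

SITES = ("floor", "medial", "superior", "lateral", "multiple")
#: Fracture-site distribution of the emulated population (counts /330).
DEFAULT_SITE_PROBS = (116 / 330, 91 / 330, 16 / 330, 3 / 330, 104 / 330)

MANIFEST_COLUMNS = [
    "sample_id", "path", "label",
    "row_min", "col_min", "row_max", "col_max", "site", "split",
]


@dataclass
class RadiographSample:
    """One grayscale radiograph-like image with its ground truth.

    roi is a 0-based half-open box (row_min, col_min, row_max, col_max).
    ``fracture_boxes`` records the pixel extent of each injected rim
    discontinuity (empty for negatives) — ground truth for localization
    studies, not part of what a classifier sees.
    """

    sample_id: str
    pixels: np.ndarray
    label: int
    roi: tuple[int, int, int, int]
    site: str  # "none" or one of SITES
    seed: int
    fracture_boxes: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        r0, c0, r1, c1 = self.roi
        h, w = self.pixels.shape
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"invalid roi {self.roi} for image shape {self.pixels.shape}")
        if (self.site == "none") != (self.label == 0):
            raise ValueError("site must be 'none' exactly when label is 0")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("pixel intensities must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings; the defaults define the emulated study population."""

    n_samples: int = 200
    prevalence: float = 0.18
    site_probs: tuple[float, ...] = DEFAULT_SITE_PROBS
    image_size: int = 128
    fracture_contrast: float = 0.45
    noise_sd: float = 0.02
    exact_counts: bool = False
    roi_tightness: str = "head"  # "head" or "orbits"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if abs(sum(self.site_probs) - 1.0) > 1e-9:
            raise ValueError("site_probs must sum to 1")
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.fracture_contrast <= 0.0:
            raise ValueError("fracture_contrast must be positive")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be non-negative")
        if self.roi_tightness not in ("head", "orbits"):
            raise ValueError("roi_tightness must be 'head' or 'orbits'")


# Site -> angular center of the rim discontinuity, in radians measured
# from the +col axis with rows increasing downward ("floor" = inferior rim).
# Medial/lateral flip with the affected orbit side.
_SITE_ANGLES = {"floor": math.pi / 2, "superior": -math.pi / 2}
_SECTOR_HALF_WIDTH = math.radians(28.0)


def _geometry(size: int, anat_rng: np.random.Generator):
    """Head/orbit layout, mirror-symmetric about the image column center."""
    s = float(size)
    cc = (s - 1.0) / 2.0  # exact mirror axis
    head_r = (0.52 + 0.01 * anat_rng.uniform(-1, 1)) * s
    head_a = (0.42 + 0.01 * anat_rng.uniform(-1, 1)) * s
    head_b = (0.355 + 0.01 * anat_rng.uniform(-1, 1)) * s
    orbit_r = (0.42 + 0.008 * anat_rng.uniform(-1, 1)) * s
    orbit_off = (0.155 + 0.006 * anat_rng.uniform(-1, 1)) * s
    orbit_rad = (0.105 + 0.004 * anat_rng.uniform(-1, 1)) * s
    return {
        "head_center": (head_r, cc),
        "head_axes": (head_a, head_b),
        "orbit_centers": ((orbit_r, cc - orbit_off), (orbit_r, cc + orbit_off)),
        "orbit_radius": orbit_rad,
    }


def _sector_mask(rr, cc_grid, center, radius, angle_center, half_width, ring_sigma):
    """Boolean mask of a rim sector: within the annulus and angular window."""
    dr = rr - center[0]
    dc = cc_grid - center[1]
    rho = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    dtheta = np.abs((theta - angle_center + math.pi) % (2 * math.pi) - math.pi)
    return (np.abs(rho - radius) < 3.0 * ring_sigma) & (dtheta < half_width)


def _fracture_sectors(site: str, orbit_side: int, jitter: float) -> list[float]:
    """Angular centers of the discontinuities for a given site.

    orbit_side: 0 = image-left orbit, 1 = image-right orbit.  "medial"
    faces the midline: +col for the left orbit, -col (pi) for the right.
    """
    medial = 0.0 if orbit_side == 0 else math.pi
    lateral = math.pi if orbit_side == 0 else 0.0
    table = {
        "floor": [_SITE_ANGLES["floor"]],
        "superior": [_SITE_ANGLES["superior"]],
        "medial": [medial],
        "lateral": [lateral],
        "multiple": [_SITE_ANGLES["floor"], medial],
    }
    return [a + jitter for a in table[site]]


def render_phantom(seed: int, label: int, site: str, config: PhantomConfig) -> RadiographSample:
    """Render one phantom; a pure function of (seed, label, site, config).

    The noise field and anatomy are drawn from streams independent of the
    label, so the positive and negative renders of the same seed differ
    only inside the fracture sector(s).
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    if (site == "none") != (label == 0):
        raise ValueError("site must be 'none' exactly when label is 0")
    if label == 1 and site not in SITES:
        raise ValueError(f"unknown site {site!r}")
    if config.image_size <= 0:
        raise ValueError("image_size must be positive")

    s = config.image_size
    ss = np.random.SeedSequence(entropy=(int(seed) & 0x7FFFFFFF, 0xC5))
    anat_seed, noise_seed, geom_seed = ss.spawn(3)
    anat_rng = np.random.default_rng(anat_seed)
    noise_rng = np.random.default_rng(noise_seed)
    geom_rng = np.random.default_rng(geom_seed)

    geo = _geometry(s, anat_rng)
    rr, cc = np.mgrid[0:s, 0:s].astype(np.float64)

    img = 0.08 + 0.10 * (rr / s)  # background gradient
    hr, hc = geo["head_center"]
    ha, hb = geo["head_axes"]
    d = np.sqrt(((rr - hr) / ha) ** 2 + ((cc - hc) / hb) ** 2)
    img += 0.10 * (d <= 1.0)  # soft-tissue fill
    edge_sigma = 0.018
    img += 0.30 * np.exp(-((d - 1.0) / edge_sigma) ** 2)  # skull outline

    ring_sigma = max(1.0, 0.016 * s)
    rim_amp = 0.55
    rim_layers = []
    for oc in geo["orbit_centers"]:
        rho = np.hypot(rr - oc[0], cc - oc[1])
        rim_layers.append(rim_amp * np.exp(-((rho - geo["orbit_radius"]) / ring_sigma) ** 2))
    img += rim_layers[0] + rim_layers[1]

    # geometry stream consumed identically for both labels -> matched renders
    orbit_side = int(geom_rng.integers(0, 2))
    jitter = geom_rng.uniform(-math.radians(8.0), math.radians(8.0))
    fracture_boxes: list[tuple[int, int, int, int]] = []
    if label == 1:
        oc = geo["orbit_centers"][orbit_side]
        for angle in _fracture_sectors(site, orbit_side, jitter):
            mask = _sector_mask(rr, cc, oc, geo["orbit_radius"], angle,
                                _SECTOR_HALF_WIDTH, ring_sigma)
            img = img - config.fracture_contrast * rim_layers[orbit_side] / rim_amp * mask
            rows, cols = np.nonzero(mask)
            if rows.size:
                fracture_boxes.append(
                    (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
                )

    if config.noise_sd > 0:
        img = img + noise_rng.normal(0.0, config.noise_sd, (s, s))
    img = np.clip(img, 0.0, 1.0)

    if config.roi_tightness == "head":
        r0 = max(0, int(math.floor(hr - ha)) - 1)
        r1 = min(s, int(math.ceil(hr + ha)) + 1)
        c0 = max(0, int(math.floor(hc - hb)) - 1)
        c1 = min(s, int(math.ceil(hc + hb)) + 1)
    else:  # tight orbital-area box
        rad = geo["orbit_radius"] + 3.0 * ring_sigma
        ocs = geo["orbit_centers"]
        r0 = max(0, int(math.floor(min(o[0] for o in ocs) - rad)))
        r1 = min(s, int(math.ceil(max(o[0] for o in ocs) + rad)))
        c0 = max(0, int(math.floor(min(o[1] for o in ocs) - rad)))
        c1 = min(s, int(math.ceil(max(o[1] for o in ocs) + rad)))

    return RadiographSample(
        sample_id=f"ph{seed:08d}",
        pixels=img,
        label=label,
        roi=(r0, c0, r1, c1),
        site=site,
        seed=int(seed),
        fracture_boxes=fracture_boxes,
    )


@dataclass
class ManifestRecord:
    sample_id: str
    path: str  # empty until materialized
    label: int
    roi: tuple[int, int, int, int]
    site: str
    split: str = "unassigned"


@dataclass
class DatasetManifest:
    """Ordered sample records plus the provenance needed to regenerate them."""

    records: list[ManifestRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")

    def __len__(self):
        return len(self.records)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(
            [r for r in self.records if r.split == split],
            {**self.provenance, "subset": split},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": r.sample_id, "path": r.path, "label": r.label,
                "row_min": r.roi[0], "col_min": r.roi[1],
                "row_max": r.roi[2], "col_max": r.roi[3],
                "site": r.site, "split": r.split,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None) -> "DatasetManifest":
        records = [
            ManifestRecord(
                sample_id=str(row.sample_id), path=str(row.path) if pd.notna(row.path) else "",
                label=int(row.label),
                roi=(int(row.row_min), int(row.col_min), int(row.row_max), int(row.col_max)),
                site=str(row.site), split=str(row.split),
            )
            for row in df.itertuples()
        ]
        return cls(records, provenance or {})

    @classmethod
    def read_csv(cls, path) -> "DatasetManifest":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))


def generate_phantom_dataset(
    config: PhantomConfig,
) -> tuple[DatasetManifest, dict[str, RadiographSample]]:
    """Draw labels and sites, render every phantom; reproducible from config.

    Returns the manifest and a dict sample_id -> RadiographSample.  With
    ``exact_counts`` the positive count is exactly round(n * prevalence)
    (positions still randomized); otherwise labels are i.i.d. Bernoulli.
    """
    if config.n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(config.seed & 0x7FFFFFFF, 0xDA)))
    n = config.n_samples
    if config.exact_counts:
        n_pos = int(round(n * config.prevalence))
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=n_pos, replace=False)] = 1
    else:
        labels = (rng.random(n) < config.prevalence).astype(int)
    sites = np.where(
        labels == 1,
        rng.choice(SITES, size=n, p=np.asarray(config.site_probs)),
        "none",
    )
    seeds = rng.integers(0, 2**31 - 1, size=n)
    records, samples = [], {}
    for i in range(n):
        sample = render_phantom(int(seeds[i]), int(labels[i]), str(sites[i]), config)
        sample.sample_id = f"ph{i:05d}_{seeds[i]:08d}"
        records.append(ManifestRecord(sample.sample_id, "", sample.label, sample.roi, sample.site))
        samples[sample.sample_id] = sample
    manifest = DatasetManifest(
        records,
        provenance={
            "generator": "crossrad.phantom",
            "seed": config.seed,
            "n_samples": n,
            "prevalence": config.prevalence,
            "image_size": config.image_size,
            "fracture_contrast": config.fracture_contrast,
            "noise_sd": config.noise_sd,
        },
    )
    return manifest, samples


def crop_roi(sample: RadiographSample) -> np.ndarray:
    """The ROI sub-image; the label of the crop is that of the source."""
    r0, c0, r1, c1 = sample.roi
    h, w = sample.pixels.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"roi {sample.roi} outside image bounds {sample.pixels.shape}")
    return sample.pixels[r0:r1, c0:c1]


def split_dataset(
    manifest: DatasetManifest,
    ratios: tuple[float, float, float] = (7.0, 1.0, 2.0),
    seed: int = 0,
) -> DatasetManifest:
    """Assign train/tune/test tags, stratified by label.

    Within each class, counts follow the ratios with largest-remainder
    rounding; assignment order is a seeded permutation.  If a class has
    fewer members than non-zero split parts a warning is attached to the
    returned manifest's provenance (never a silent empty part).
    """
    ratios = tuple(float(x) for x in ratios)
    if len(ratios) != 3 or any(x < 0 for x in ratios) or sum(ratios) <= 0:
        raise ValueError("ratios must be three non-negative reals with positive sum")
    names = ("train", "tune", "test")
    total = sum(ratios)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed & 0x7FFFFFFF, 0x5B)))
    labels = manifest.labels()
    assignment = np.empty(len(manifest), dtype=object)
    warnings_out = []
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        n_nonzero = sum(1 for x in ratios if x > 0)
        if idx.size < n_nonzero:
            warnings_out.append(
                f"class {cls} has {idx.size} samples for {n_nonzero} non-empty splits"
            )
        exact = [idx.size * r / total for r in ratios]
        counts = [int(math.floor(e)) for e in exact]
        remainder = idx.size - sum(counts)
        # largest fractional part first; ties favor the earlier split
        order = sorted(range(3), key=lambda j: (-(exact[j] - counts[j]), j))
        for j in order[:remainder]:
            counts[j] += 1
        perm = rng.permutation(idx)
        pos = 0
        for name, cnt in zip(names, counts):
            assignment[perm[pos:pos + cnt]] = name
            pos += cnt
    records = [replace(r, split=str(assignment[i])) for i, r in enumerate(manifest.records)]
    prov = {**manifest.provenance, "split_ratios": ratios, "split_seed": seed}
    if warnings_out:
        prov["split_warnings"] = warnings_out
    return DatasetManifest(records, prov)


def subsample_negatives(
    manifest: DatasetManifest, neg_pos_ratio: float = 1.0, seed: int = 0
) -> DatasetManifest:
    """Balance train and tune splits by dropping random negatives.

    After the call, (#negatives)/(#positives) <= neg_pos_ratio within the
    train and tune splits; the test split is left untouched so evaluation
    keeps the natural prevalence.
    """
    if neg_pos_ratio <= 0:
        raise ValueError("neg_pos_ratio must be positive")
    splits = {r.split for r in manifest.records}
    if splits <= {"unassigned"}:
        raise ValueError("manifest must carry split tags; run split_dataset first")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed & 0x7FFFFFFF, 0x9E)))
    drop: set[str] = set()
    for split in ("train", "tune"):
        pos = [r for r in manifest.records if r.split == split and r.label == 1]
        neg = [r for r in manifest.records if r.split == split and r.label == 0]
        keep_n = int(math.floor(neg_pos_ratio * len(pos)))
        if len(neg) > keep_n:
            kept = rng.choice(len(neg), size=keep_n, replace=False)
            kept_ids = {neg[i].sample_id for i in kept}
            drop |= {r.sample_id for r in neg if r.sample_id not in kept_ids}
    records = [r for r in manifest.records if r.sample_id not in drop]
    prov = {**manifest.provenance, "neg_pos_ratio": neg_pos_ratio, "subsample_seed": seed}
    return DatasetManifest(records, prov)


def save_png(pixels: np.ndarray, path) -> None:
    """Write intensities in [0,1] as an 8-bit grayscale PNG."""
    from PIL import Image

    arr = np.clip(np.asarray(pixels), 0.0, 1.0)
    Image.fromarray((arr * 255.0).round().astype(np.uint8), mode="L").save(path)


def load_image(path) -> np.ndarray:
    """Read a grayscale image and min-max normalize to [0,1]."""
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("F"), dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    return arr


def read_dicom_image(path) -> np.ndarray:
    """Read-only DICOM ingestion: pixel data + rescale slope/intercept,
    then min-max normalized to [0,1]."""
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    lo, hi = arr.min(), arr.max()
    return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)


def materialize(manifest: DatasetManifest, samples: dict[str, RadiographSample], out_dir) -> DatasetManifest:
    """Write PNGs for every record and fill in paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    records = []
    for r in manifest.records:
        path = os.path.join(str(out_dir), f"{r.sample_id}.png")
        save_png(samples[r.sample_id].pixels, path)
        records.append(replace(r, path=path))
    return DatasetManifest(records, dict(manifest.provenance))
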