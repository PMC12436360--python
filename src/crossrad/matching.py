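"""Cross-sequence pairing of original radiographs with ROI crops.

Training pairs are built by a greedy without-replacement rule: walking
the originals in ascending index order, each original is paired with the
not-yet-used same-label crop whose raw-pixel cosine similarity to it is
LOWEST, which maximizes the diversity of (original, crop) inputs seen by
the dual-branch model.  A crop never pairs with its own original unless
it is the only candidate left in its class.  Validation and test always
use identity pairing (each original with its own crop).

Similarity is computed on raw pixel values after bilinear resampling to
a common square resolution; no per-image standardization is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityVector",
    "MatchPair",
    "MatchingPlan",
    "resize_bilinear",
    "flatten_for_similarity",
    "cosine_similarity",
    "build_cross_sequence_plan",
    "identity_plan",
]


@dataclass
class SimilarityVector:
    """Flat raw-pixel vector of one image at the similarity resolution."""

    sample_id: str
    label: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity vector must be finite")


@dataclass(frozen=True)
class MatchPair:
    original_index: int
    crop_index: int
    label: int
    similarity: float

    def __post_init__(self):
        if self.original_index < 0 or self.crop_index < 0:
            raise ValueError("indices must be non-negative")
        if not (-1.0 <= self.similarity <= 1.0):
            raise ValueError("similarity must lie in [-1, 1]")


@dataclass
class MatchingPlan:
    """One crop per original; within each label class the map is a permutation."""

    pairs: list[MatchPair]
    mode: str  # "cross_sequence" or "identity"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("cross_sequence", "identity"):
            raise ValueError("mode must be 'cross_sequence' or 'identity'")
        orig = [p.original_index for p in self.pairs]
        crop = [p.crop_index for p in self.pairs]
        if len(set(orig)) != len(orig) or len(set(crop)) != len(crop):
            raise ValueError("each original and each crop must appear exactly once")

    def __len__(self):
        return len(self.pairs)

    def crop_for(self, original_index: int) -> int:
        for p in self.pairs:
            if p.original_index == original_index:
                return p.crop_index
        raise KeyError(original_index)

    def to_frame(self, ids: list[str] | None = None) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            rows.append({
                "original_id": ids[p.original_index] if ids else p.original_index,
                "crop_id": ids[p.crop_index] if ids else p.crop_index,
                "label": p.label,
                "similarity": p.similarity,
            })
        return pd.DataFrame(rows, columns=["original_id", "crop_id", "label", "similarity"])

    def write_csv(self, path, ids: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("# " + json.dumps({"mode": self.mode, **self.provenance}) + "\n")
            self.to_frame(ids).to_csv(fh, index=False)


def resize_bilinear(image: np.ndarray, out_rows: int, out_cols: int) -> np.ndarray:
    """Bilinear resampling of a 2-D intensity grid (align-corners spacing)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    h, w = image.shape
    if (h, w) == (out_rows, out_cols):
        return image.copy()
    r = np.linspace(0.0, h - 1.0, out_rows)
    c = np.linspace(0.0, w - 1.0, out_cols)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = (r - r0)[:, None]
    fc = (c - c0)[None, :]
    top = image[np.ix_(r0, c0)] * (1 - fc) + image[np.ix_(r0, c1)] * fc
    bot = image[np.ix_(r1, c0)] * (1 - fc) + image[np.ix_(r1, c1)] * fc
    return top * (1 - fr) + bot * fr


def flatten_for_similarity(image: np.ndarray, resolution: int = 64) -> np.ndarray:
    """Resample to resolution x resolution and flatten row-major.

    Raw pixel values are kept as-is: no centering or scaling, so the cosine
    between two images reflects their actual intensity patterns.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    return resize_bilinear(image, resolution, resolution).ravel()


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|), clamped to [-1, 1] against floating-point rounding."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero-norm vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def _similarity_matrix(originals: list[SimilarityVector], crops: list[SimilarityVector]) -> np.ndarray:
    o = np.stack([x.values for x in originals])
    c = np.stack([x.values for x in crops])
    no = np.linalg.norm(o, axis=1)
    nc = np.linalg.norm(c, axis=1)
    if np.any(no == 0.0) or np.any(nc == 0.0):
        raise ValueError("cosine similarity undefined for a zero-norm vector")
    return np.clip((o @ c.T) / np.outer(no, nc), -1.0, 1.0)


def build_cross_sequence_plan(
    originals: list[SimilarityVector],
    crops: list[SimilarityVector],
    similarity: np.ndarray | None = None,
) -> MatchingPlan:
    """Greedy lowest-similarity matching without replacement.

    Originals are processed in ascending index order.  For original i the
    candidates are the unused crops with the same label, excluding crop i
    itself unless it is the only candidate remaining; the candidate with
    the lowest cosine similarity wins, ties broken by lowest crop index.

    A precomputed ``similarity`` matrix (rows = originals, cols = crops)
    may be supplied; otherwise it is computed from the vectors.
    """
    if len(originals) != len(crops):
        raise ValueError("originals and crops must be index-aligned")
    if len(originals) == 0:
        raise ValueError("cannot build a plan over zero samples")
    labels_o = [x.label for x in originals]
    labels_c = [x.label for x in crops]
    if labels_o != labels_c:
        raise ValueError("label sequences of originals and crops differ")
    sim = _similarity_matrix(originals, crops) if similarity is None else np.asarray(similarity, dtype=np.float64)
    if sim.shape != (len(originals), len(crops)):
        raise ValueError("similarity matrix shape mismatch")

    used: set[int] = set()
    pairs: list[MatchPair] = []
    for i in range(len(originals)):
        candidates = [
            j for j in range(len(crops))
            if j not in used and labels_c[j] == labels_o[i]
        ]
        if not candidates:
            raise ValueError(f"no remaining crop candidate for original {i}")
        non_self = [j for j in candidates if j != i]
        pool = non_self if non_self else candidates
        best = min(pool, key=lambda j: (sim[i, j], j))
        used.add(best)
        pairs.append(MatchPair(i, best, labels_o[i], float(sim[i, best])))
    return MatchingPlan(
        pairs,
        mode="cross_sequence",
        provenance={"order": "ascending_index", "tie_break": "lowest_crop_index"},
    )


def identity_plan(n: int, labels: list[int]) -> MatchingPlan:
    """Pair each original with its own crop; used at validation and test."""
    if n <= 0:
        raise ValueError("n must be positive")
    if len(labels) != n:
        raise ValueError("labels must have length n")
    pairs = [MatchPair(i, i, int(labels[i]), 1.0) for i in range(n)]
    return MatchingPlan(pairs, mode="identity", provenance={})
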