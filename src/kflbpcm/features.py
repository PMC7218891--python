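"""The k-FLBPCM feature core.

Texture is described by rotation-invariant uniform ("riu2") local binary
patterns computed with several (P, R) operators; shape is described by the
same LBP machinery applied to a thin contour band traced along the
segmented plant boundary.  Each operator's histogram has its single
dominant bin zeroed ("filtered" LBP) so that the near-constant regions that
dominate plant images do not swamp the informative minority patterns.  The
two branches are fused as ``k · pass_features + cmask_features``.

LBP definition used throughout
------------------------------
For a center pixel c and P neighbors sampled on a circle of radius R
(bilinear interpolation at non-integer offsets), the bit for neighbor n is
``n >= c`` (ties count as 1, the original convention).  A pattern with at
most two circular 0↔1 transitions is *uniform* and maps to its number of
set bits (0..P); every other pattern maps to the single non-uniform code
P+1, giving P+2 histogram bins per operator.  Interpolated neighbor values
are rounded to 6 decimals before the comparison so that exact ties in flat
regions are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, InvalidInputError, StateError
from .imaging import (
    BinaryMask,
    MorphologyConfig,
    PlantImage,
    contour_mask,
    open_close_rgb,
    segment_vegetation,
    to_grayscale,
)

__all__ = [
    "LBPConfig",
    "LBPHistogramSet",
    "FeatureVector",
    "FusionParams",
    "compute_lbp_codes",
    "lbp_histogram",
    "filter_dominant_bins",
    "normalize_histograms",
    "extract_pass_features",
    "extract_cmask_features",
    "extract_combined_features",
    "fuse_features",
    "mean_rgb_features",
    "features_to_csv",
    "features_from_csv",
]

#: Multiresolution operator set used by default: the canonical riu2 triple.
DEFAULT_OPERATORS: tuple[tuple[int, int], ...] = ((8, 1), (16, 2), (24, 3))

_BORDER_CODE = -1  # marks pixels within R of the border; never histogrammed
_INTERP_DECIMALS = 6


# ---------------------------------------------------------------------------
# Configuration and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LBPConfig:
    """Operator set and branch options for feature extraction.

    ``operators`` is an ordered list of (P, R) pairs; the feature dimension
    is ``sum(P + 2)`` over the list.  ``cmask_input`` selects what the right
    branch feeds to the LBP operators: the contour-band raster itself as a
    0/255 image (``"band"``, the default) or the smoothed grayscale image
    restricted to the band region (``"grayscale"``).  ``pass_region``
    optionally restricts the left branch's histograms to the vegetation
    mask (``"vegetation"``) instead of the whole interior (``"full"``).
    """

    operators: tuple[tuple[int, int], ...] = DEFAULT_OPERATORS
    mapping: str = "riu2"
    cmask_input: str = "band"
    pass_region: str = "full"

    def __post_init__(self) -> None:
        ops = tuple((int(p), int(r)) for p, r in self.operators)
        if not ops:
            raise ConfigError("operator list must be non-empty")
        for p, r in ops:
            if p < 4 or r < 1:
                raise ConfigError(f"each operator needs P >= 4 and R >= 1, got ({p}, {r})")
        object.__setattr__(self, "operators", ops)
        if self.mapping != "riu2":
            raise ConfigError(f"only the riu2 mapping is supported, got {self.mapping!r}")
        if self.cmask_input not in ("band", "grayscale"):
            raise ConfigError(f"cmask_input must be 'band' or 'grayscale', got {self.cmask_input!r}")
        if self.pass_region not in ("full", "vegetation"):
            raise ConfigError(f"pass_region must be 'full' or 'vegetation', got {self.pass_region!r}")

    @property
    def dim(self) -> int:
        return sum(p + 2 for p, _ in self.operators)


@dataclass
class LBPHistogramSet:
    """Per-operator riu2 histograms, before or after dominant-bin filtering."""

    histograms: list[np.ndarray]
    operators: tuple[tuple[int, int], ...]
    n_pixels: list[int]
    filtered: bool = False
    removed_counts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.histograms) != len(self.operators):
            raise InvalidInputError("one histogram per operator required")
        for h, (p, _) in zip(self.histograms, self.operators):
            if h.shape != (p + 2,):
                raise InvalidInputError(
                    f"riu2 histogram for P={p} must have {p + 2} bins, got {h.shape}"
                )


@dataclass
class FusionParams:
    """Branch-fusion coefficient and the band thickness it pairs with."""

    k: float = 0.2
    thickness: int = 2

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ConfigError(f"fusion coefficient k must be >= 0, got {self.k}")
        if self.thickness < 1:
            raise ConfigError(f"thickness must be >= 1, got {self.thickness}")


@dataclass
class FeatureVector:
    """A flattened, filtered, L1-normalized histogram concatenation."""

    values: np.ndarray
    branch: str

    _BRANCHES = ("pass", "cmask", "combined")

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("feature values must be finite")
        self.values = v
        if self.branch not in self._BRANCHES:
            raise InvalidInputError(f"unknown branch {self.branch!r}")

    @property
    def dim(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# LBP codes
# ---------------------------------------------------------------------------

def _neighbor_offsets(P: int, R: int) -> list[tuple[float, float]]:
    """(row, col) offsets of the P circle points, counter-clockwise."""
    offsets = []
    for p in range(P):
        a = 2.0 * np.pi * p / P
        dr, dc = -R * np.sin(a), R * np.cos(a)
        # snap near-integer offsets so axis-aligned neighbors are sampled exactly
        if abs(dr - round(dr)) < 1e-9:
            dr = float(round(dr))
        if abs(dc - round(dc)) < 1e-9:
            dc = float(round(dc))
        offsets.append((dr, dc))
    return offsets


def compute_lbp_codes(gray: np.ndarray, P: int, R: int) -> np.ndarray:
    """riu2 LBP code of every interior pixel of a 2-D raster.

    Returns an int array of the same shape as ``gray`` with codes in
    ``0..P+1`` on the interior and ``-1`` on the border of width R (those
    pixels have incomplete neighborhoods and are excluded from histograms).
    """
    g = np.asarray(gray, dtype=np.float64)
    if g.ndim != 2:
        raise InvalidInputError(f"expected a 2-D raster, got shape {g.shape}")
    H, W = g.shape
    if H < 2 * R + 1 or W < 2 * R + 1:
        raise InvalidInputError(
            f"raster {g.shape} smaller than the ({2 * R + 1})×({2 * R + 1}) neighborhood"
        )
    center = g[R:H - R, R:W - R]
    bits = np.empty((P,) + center.shape, dtype=bool)
    for p, (dr, dc) in enumerate(_neighbor_offsets(P, R)):
        r0, c0 = int(np.floor(dr)), int(np.floor(dc))
        fr, fc = dr - r0, dc - c0

        def block(dy: int, dx: int) -> np.ndarray:
            return g[R + dy:H - R + dy, R + dx:W - R + dx]

        if fr == 0.0 and fc == 0.0:
            sampled = block(r0, c0)
        else:
            sampled = ((1 - fr) * (1 - fc) * block(r0, c0)
                       + (1 - fr) * fc * block(r0, c0 + 1)
                       + fr * (1 - fc) * block(r0 + 1, c0)
                       + fr * fc * block(r0 + 1, c0 + 1))
            sampled = np.round(sampled, _INTERP_DECIMALS)
        bits[p] = sampled >= center
    transitions = (bits != np.roll(bits, 1, axis=0)).sum(axis=0)
    codes_interior = np.where(transitions <= 2, bits.sum(axis=0), P + 1)
    codes = np.full((H, W), _BORDER_CODE, dtype=np.int16)
    codes[R:H - R, R:W - R] = codes_interior
    return codes


def lbp_histogram(codes: np.ndarray, region: BinaryMask | np.ndarray | None,
                  P: int) -> np.ndarray:
    """Bin the interior codes of one operator into a (P+2)-bin count vector.

    ``region``, when given, restricts counting to the masked pixels; border
    pixels (code −1) are always excluded.  The histogram sums to the number
    of counted pixels.
    """
    c = np.asarray(codes)
    valid = c >= 0
    if region is not None:
        rv = region.values if isinstance(region, BinaryMask) else np.asarray(region, bool)
        if rv.shape != c.shape:
            raise InvalidInputError(
                f"region shape {rv.shape} does not match codes shape {c.shape}"
            )
        valid &= rv
    picked = c[valid]
    if picked.size and picked.max() > P + 1:
        raise InvalidInputError(f"codes exceed the riu2 range 0..{P + 1}")
    return np.bincount(picked, minlength=P + 2).astype(np.int64)


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------

def filter_dominant_bins(hists: LBPHistogramSet) -> LBPHistogramSet:
    """Zero each operator histogram's single highest-count bin.

    Plant images are dominated by one pattern (flat leaf/soil regions map
    to the all-ones code); removing that bin spreads discriminative mass
    over the remaining patterns.  Ties break toward the lowest bin index.
    The vector length is preserved so that branch dimensions stay equal.
    """
    if hists.filtered:
        raise StateError("histogram set is already filtered")
    out_h, removed = [], []
    for h in hists.histograms:
        h = h.copy()
        i = int(np.argmax(h))  # argmax takes the first maximum: lowest index
        removed.append(int(h[i]))
        h[i] = 0
        out_h.append(h)
    return LBPHistogramSet(out_h, hists.operators, list(hists.n_pixels),
                           filtered=True, removed_counts=removed)


def normalize_histograms(hists: LBPHistogramSet) -> list[np.ndarray]:
    """L1-normalize each histogram; an all-zero histogram stays zero."""
    out = []
    for h in hists.histograms:
        s = h.sum()
        out.append(h / s if s > 0 else np.zeros_like(h, dtype=np.float64))
    return out


# ---------------------------------------------------------------------------
# Feature branches
# ---------------------------------------------------------------------------

def _histogram_pipeline(raster: np.ndarray, region: BinaryMask | None,
                        lbp: LBPConfig) -> np.ndarray:
    hists, npix = [], []
    for P, R in lbp.operators:
        codes = compute_lbp_codes(raster, P, R)
        h = lbp_histogram(codes, region, P)
        hists.append(h)
        npix.append(int(h.sum()))
    hset = LBPHistogramSet(hists, lbp.operators, npix)
    return np.concatenate(normalize_histograms(filter_dominant_bins(hset)))


def extract_pass_features(image: PlantImage, lbp: LBPConfig | None = None) -> FeatureVector:
    """Left branch: filtered multi-operator LBP of the raw grayscale image.

    No morphological processing is applied; histograms cover the whole
    interior (or the vegetation mask when ``lbp.pass_region="vegetation"``).
    """
    lbp = lbp or LBPConfig()
    gray = to_grayscale(image)
    region = segment_vegetation(image) if lbp.pass_region == "vegetation" else None
    return FeatureVector(_histogram_pipeline(gray, region, lbp), branch="pass")


def extract_cmask_features(image: PlantImage, lbp: LBPConfig | None = None,
                           morph: MorphologyConfig | None = None) -> FeatureVector:
    """Right branch: filtered LBP of the contour-band mask.

    The image is smoothed with opening+closing, segmented with ExG−ExR,
    and a boundary band of the configured thickness is traced; the LBP
    operators then run on the band raster itself (0/255), so the codes
    describe local boundary geometry — the leaf-margin morphology.
    """
    lbp = lbp or LBPConfig()
    morph = morph or MorphologyConfig()
    smoothed = open_close_rgb(image.pixels, morph)
    veg = segment_vegetation(smoothed)
    band = contour_mask(veg, morph)
    if lbp.cmask_input == "band":
        raster = np.where(band.values, 255, 0).astype(np.uint8)
        values = _histogram_pipeline(raster, None, lbp)
    else:
        values = _histogram_pipeline(to_grayscale(smoothed), band, lbp)
    return FeatureVector(values, branch="cmask")


def fuse_features(pass_fv: FeatureVector, cmask_fv: FeatureVector,
                  params: FusionParams | None = None) -> FeatureVector:
    """Combine the branches as ``k · pass + cmask`` elementwise."""
    params = params or FusionParams()
    if pass_fv.branch != "pass" or cmask_fv.branch != "cmask":
        raise InvalidInputError(
            f"fusion needs (pass, cmask) branches, got ({pass_fv.branch}, {cmask_fv.branch})"
        )
    if pass_fv.dim != cmask_fv.dim:
        raise InvalidInputError(
            f"branch dimensions differ: {pass_fv.dim} vs {cmask_fv.dim}"
        )
    return FeatureVector(params.k * pass_fv.values + cmask_fv.values, branch="combined")


def extract_combined_features(image: PlantImage, lbp: LBPConfig | None = None,
                              morph: MorphologyConfig | None = None,
                              fusion: FusionParams | None = None) -> FeatureVector:
    """Full pipeline for one image: both branches, then coefficient-k fusion.

    ``fusion.thickness`` overrides ``morph.thickness`` so that the fusion
    parameters fully determine the combined feature.
    """
    lbp = lbp or LBPConfig()
    fusion = fusion or FusionParams()
    morph = morph or MorphologyConfig()
    if morph.thickness != fusion.thickness:
        morph = MorphologyConfig(morph.se_size, fusion.thickness, morph.band_style)
    p = extract_pass_features(image, lbp)
    c = extract_cmask_features(image, lbp, morph)
    return fuse_features(p, c, fusion)


def mean_rgb_features(image: PlantImage) -> np.ndarray:
    """Channel means in [0, 1] — the color-only control descriptor.

    Used to demonstrate that color alone cannot separate species of
    similar hue, the premise that motivates texture + contour features.
    """
    return image.pixels.reshape(-1, 3).mean(axis=0) / 255.0


# ---------------------------------------------------------------------------
# Feature-matrix exchange format
# ---------------------------------------------------------------------------

def features_to_csv(path: str | Path, vectors: Sequence[FeatureVector],
                    images: Sequence[PlantImage],
                    paths: Sequence[str] | None = None) -> pd.DataFrame:
    """Write one row per image: path, label, stage, then feature columns."""
    if len(vectors) != len(images):
        raise InvalidInputError("one feature vector per image required")
    if paths is None:
        paths = [f"image_{i:05d}" for i in range(len(images))]
    dim = vectors[0].dim if vectors else 0
    cols = [f"f{i:04d}" for i in range(dim)]
    df = pd.DataFrame([v.values for v in vectors], columns=cols)
    df.insert(0, "stage", [im.stage for im in images])
    df.insert(0, "label", [im.label for im in images])
    df.insert(0, "path", list(paths))
    df.to_csv(path, index=False)
    return df


def features_from_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Read a feature CSV back as (X, y, full frame)."""
    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    X = df[feat_cols].to_numpy(dtype=np.float64)
    y = df["label"].to_numpy()
    return X, y, df
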