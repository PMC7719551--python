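"""Color quantification: CIELAB centroids and dichromatism from images.

Each species/sex phenotype is the centroid (per-axis mean) of a large pixel
sample in CIELAB, a color space designed to be approximately perceptually
uniform for human vision: L is lightness (0-100), a runs green to red and b
blue to yellow. Euclidean distance in CIELAB (Delta E) is the perceptual
color difference, so the dichromatism of a species is the distance between
its male and female centroids, kept as a full 3-vector D = c_m - c_f so that
downstream analyses can use its direction as well as its magnitude.

The sRGB -> CIELAB conversion is implemented here with the D65 reference
white derived from the sRGB primaries themselves, so that neutral grays map
exactly onto the a = b = 0 axis (rounded published white points leave grays
a few 1e-3 off that line, which matters when asserting monochromatism).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats

__all__ = [
    "srgb_to_lab",
    "PixelSample",
    "ColorCentroid",
    "DimorphismRecord",
    "sample_pixels",
    "centroid",
    "dichromatism",
    "dichromatism_table",
    "palette_profile",
    "PaletteProfile",
    "structure_correlation",
    "read_centroid_table",
    "write_centroid_table",
]

# linear-RGB -> XYZ matrix for sRGB primaries, D65 (IEC 61966-2-1)
_M_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
# reference white consistent with the matrix: XYZ of RGB=(1,1,1)
_WHITE = _M_RGB2XYZ @ np.ones(3)
_DELTA = 6.0 / 29.0


def srgb_to_lab(pixels) -> np.ndarray:
    """Convert 8-bit sRGB pixels to CIELAB (D65, 2 degree observer).

    Parameters
    ----------
    pixels : array-like, shape (..., 3)
        R, G, B channels as integers in [0, 255].

    Returns
    -------
    ndarray of the same leading shape with (L, a, b) triples. Grays map to
    a = b = 0 exactly; white is (100, 0, 0) and black (0, 0, 0).
    """
    rgb = np.asarray(pixels, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("pixels must have a trailing RGB dimension of size 3")
    if rgb.min(initial=0.0) < 0 or rgb.max(initial=0.0) > 255:
        raise ValueError("RGB channels must lie in [0, 255]")
    c = rgb / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    xyz = lin @ _M_RGB2XYZ.T / _WHITE
    f = np.where(xyz > _DELTA**3, np.cbrt(xyz), xyz / (3 * _DELTA**2) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


@dataclass
class PixelSample:
    """A sample of CIELAB pixels for one species and sex."""

    species_id: str
    sex: str
    pixels: np.ndarray  # (n, 3) CIELAB

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float).reshape(-1, 3)
        if self.n < 1:
            raise ValueError("a pixel sample needs at least one pixel")

    @property
    def n(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class ColorCentroid:
    """Mean CIELAB color of a pixel sample; the species/sex phenotype."""

    L: float
    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass(frozen=True)
class DimorphismRecord:
    """Paired sex centroids with the dichromatism vector D = c_m - c_f.

    The vector points from the female to the male centroid, so that a
    positive scalar projection of (male - female) rate difference on D
    means dichromatism is increasing. Its magnitude is the Delta E
    dichromatism metric, symmetric under swapping the sexes.
    """

    species_id: str
    c_m: ColorCentroid
    c_f: ColorCentroid
    D_vec: np.ndarray = field(repr=False)
    D_mag: float = 0.0


def _as_centroid(c) -> ColorCentroid:
    if isinstance(c, ColorCentroid):
        return c
    arr = np.asarray(c, dtype=float).reshape(3)
    return ColorCentroid(*arr)


def centroid(sample: PixelSample) -> ColorCentroid:
    """Per-axis arithmetic mean of the sample's CIELAB pixels."""
    if sample.n < 1:
        raise ValueError("empty pixel sample")
    m = sample.pixels.mean(axis=0)
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite pixel values in sample")
    return ColorCentroid(*m)


def dichromatism(c_m, c_f, species_id: str = "") -> DimorphismRecord:
    """Dichromatism vector and magnitude from the two sex centroids."""
    cm, cf = _as_centroid(c_m), _as_centroid(c_f)
    d = cm.as_array() - cf.as_array()
    if not np.all(np.isfinite(d)):
        raise ValueError("centroids must be finite")
    return DimorphismRecord(species_id, cm, cf, d, float(np.linalg.norm(d)))


def _load_image(image) -> np.ndarray:
    if isinstance(image, (str, Path)):
        image = Image.open(image)
    if isinstance(image, Image.Image):
        image = np.asarray(image.convert("RGBA"))
    return np.asarray(image)


def sample_pixels(
    image,
    n: int,
    seed=None,
    *,
    species_id: str = "",
    sex: str = "",
    background=None,
) -> PixelSample:
    """Draw ``n`` foreground pixels uniformly at random and convert to CIELAB.

    Foreground pixels are those with nonzero alpha (when the image has an
    alpha channel) that do not exactly match ``background`` (an optional RGB
    triple, for color-keyed backgrounds such as a page behind a drawing).
    Sampling is without replacement when the foreground has at least ``n``
    pixels and with replacement otherwise, keeping the sample size fixed.
    """
    arr = _load_image(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    flat = arr.reshape(-1, arr.shape[-1])
    if flat.shape[1] >= 4:
        mask = flat[:, 3] > 0
        rgb = flat[:, :3]
    else:
        mask = np.ones(flat.shape[0], dtype=bool)
        rgb = flat[:, :3]
    if background is not None:
        bg = np.asarray(background, dtype=rgb.dtype).reshape(1, 3)
        mask &= ~np.all(rgb == bg, axis=1)
    fg = rgb[mask]
    if fg.shape[0] == 0:
        raise ValueError("image has no foreground pixels to sample")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(fg.shape[0], size=n, replace=fg.shape[0] < n)
    return PixelSample(species_id, sex, srgb_to_lab(fg[idx]))


# ---------------------------------------------------------------------------
# shared color palette (visualization support)
# ---------------------------------------------------------------------------


@dataclass
class PaletteProfile:
    """Shared k-means palette over all samples, with a 1-D display order.

    ``order`` arranges the k cluster centers along a tour through CIELAB so
    that perceptually similar palette entries sit next to each other in a
    color-profile plot; ``fractions`` rows (one per sample, columns in
    ``order``) sum to 1.
    """

    centers: np.ndarray  # (k, 3) CIELAB cluster centers
    fractions: pd.DataFrame  # samples x k, columns ordered by the tour
    order: list


def _tour_length(centers: np.ndarray, tour: list) -> float:
    pts = centers[tour]
    return float(np.linalg.norm(pts - np.roll(pts, -1, axis=0), axis=1).sum())


def _arbitrary_insertion(dist: np.ndarray) -> list:
    k = dist.shape[0]
    tour = [0] if k == 1 else [0, 1]
    for city in range(len(tour), k):
        best_pos, best_inc = 0, np.inf
        for pos in range(len(tour)):
            i, j = tour[pos], tour[(pos + 1) % len(tour)]
            inc = dist[i, city] + dist[city, j] - dist[i, j]
            if inc < best_inc - 1e-15:
                best_pos, best_inc = pos + 1, inc
        tour.insert(best_pos, city)
    return tour


def _two_opt(dist: np.ndarray, tour: list, max_rounds: int = 50) -> list:
    k = len(tour)
    for _ in range(max_rounds):
        improved = False
        for i in range(k - 1):
            for j in range(i + 2, k if i > 0 else k - 1):
                a, b = tour[i], tour[i + 1]
                c, d = tour[j], tour[(j + 1) % k]
                delta = dist[a, c] + dist[b, d] - dist[a, b] - dist[c, d]
                if delta < -1e-12:
                    tour[i + 1 : j + 1] = tour[i + 1 : j + 1][::-1]
                    improved = True
        if not improved:
            break
    return tour


def order_palette(centers: np.ndarray, *, two_opt: bool = True) -> list:
    """1-D ordering of palette colors: traveling-salesman tour through the
    cluster centers built by arbitrary insertion, then improved by two-edge
    exchange. Returned rotated to start at the darkest color."""
    centers = np.asarray(centers, dtype=float)
    dist = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    tour = _arbitrary_insertion(dist)
    if two_opt and len(tour) > 3:
        tour = _two_opt(dist, tour)
    start = tour.index(int(np.argmin(centers[:, 0])))
    tour = tour[start:] + tour[:start]
    if len(tour) > 2 and tour[1] > tour[-1]:  # deterministic orientation
        tour = [tour[0]] + tour[1:][::-1]
    return tour


def palette_profile(samples, k: int, seed=None) -> PaletteProfile:
    """Classify all pixels into a shared palette of k colors (k-means in
    CIELAB) and report each sample's fraction of pixels per palette color.

    Parameters
    ----------
    samples : mapping of sample id -> (n_i, 3) CIELAB pixel arrays,
        or an iterable of PixelSample (keyed ``species_id:sex``).
    """
    from sklearn.cluster import KMeans

    if not hasattr(samples, "items"):
        samples = {f"{s.species_id}:{s.sex}": s.pixels for s in samples}
    ids = list(samples.keys())
    stacks = [np.asarray(samples[i], dtype=float).reshape(-1, 3) for i in ids]
    allpix = np.vstack(stacks)
    n_distinct = np.unique(allpix, axis=0).shape[0]
    if k < 1 or k > n_distinct:
        raise ValueError(f"k must be in [1, {n_distinct}] (distinct colors)")
    km = KMeans(n_clusters=k, random_state=_kmeans_seed(seed), n_init=10)
    labels = km.fit_predict(allpix)
    fractions = np.zeros((len(ids), k))
    start = 0
    for row, pix in enumerate(stacks):
        lab = labels[start : start + pix.shape[0]]
        fractions[row] = np.bincount(lab, minlength=k) / pix.shape[0]
        start += pix.shape[0]
    order = order_palette(km.cluster_centers_) if k > 1 else [0]
    frame = pd.DataFrame(fractions[:, order], index=ids, columns=order)
    return PaletteProfile(km.cluster_centers_, frame, order)


def _kmeans_seed(seed):
    if seed is None:
        return None
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# centroid-set validation (e.g. drawings vs photographs)
# ---------------------------------------------------------------------------


def structure_correlation(set_a: pd.DataFrame, set_b: pd.DataFrame) -> pd.DataFrame:
    """Compare the color-space structure of two centroid sets of the same
    samples via all pairwise differences.

    For every axis, signed differences between all sample pairs (i, j) with
    i < j under lexicographic id order are computed within each set, then
    correlated (Pearson r) and regressed set-B-on-set-A. r near 1 means the
    two sets agree on which samples differ and in what direction; a slope
    below 1 means differences in B are compressed relative to A.
    """
    ids_a, ids_b = set(map(str, set_a.index)), set(map(str, set_b.index))
    if ids_a != ids_b:
        raise ValueError("the two sets must contain the same sample identifiers")
    ids = sorted(ids_a)
    if len(ids) < 3:
        raise ValueError("need at least 3 samples")
    axes = [c for c in ("L", "a", "b") if c in set_a.columns]
    i_idx, j_idx = zip(*itertools.combinations(range(len(ids)), 2))
    rows = {}
    for ax in axes:
        va = np.asarray(set_a.loc[ids, ax], dtype=float)
        vb = np.asarray(set_b.loc[ids, ax], dtype=float)
        da = va[list(i_idx)] - va[list(j_idx)]
        db = vb[list(i_idx)] - vb[list(j_idx)]
        res = stats.linregress(da, db)
        rows[ax] = {"r": stats.pearsonr(da, db)[0], "slope": res.slope,
                    "intercept": res.intercept, "n_pairs": len(da)}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# centroid table I/O
# ---------------------------------------------------------------------------

_CENTROID_COLS = ["species_id", "sex", "L", "a", "b"]


def read_centroid_table(path) -> pd.DataFrame:
    """Read a per-species, per-sex centroid CSV (species_id, sex, L, a, b)."""
    df = pd.read_csv(path)
    missing = set(_CENTROID_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"centroid table missing columns: {sorted(missing)}")
    df["species_id"] = df["species_id"].astype(str)
    df["sex"] = df["sex"].str.lower()
    if not set(df["sex"]) <= {"male", "female"}:
        raise ValueError("sex column must contain only 'male'/'female'")
    return df[_CENTROID_COLS]


def write_centroid_table(df: pd.DataFrame, path) -> None:
    df[_CENTROID_COLS].to_csv(path, index=False)


def centroid_matrix(centroids: pd.DataFrame, sex: str) -> pd.DataFrame:
    """(species x [L, a, b]) matrix for one sex, indexed by species_id."""
    sub = centroids[centroids["sex"] == sex]
    return sub.set_index("species_id")[["L", "a", "b"]]


def dichromatism_table(centroids: pd.DataFrame) -> pd.DataFrame:
    """Per-species dichromatism vector (male - female) and magnitude."""
    m = centroid_matrix(centroids, "male")
    f = centroid_matrix(centroids, "female")
    if set(m.index) != set(f.index):
        raise ValueError("every species needs exactly one male and one female row")
    f = f.loc[m.index]
    d = m.to_numpy() - f.to_numpy()
    out = pd.DataFrame(d, columns=["D_L", "D_a", "D_b"], index=m.index)
    out["D_mag"] = np.linalg.norm(d, axis=1)
    return out.reset_index()
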