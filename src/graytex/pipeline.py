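"""Natural-image preprocessing: log, downsample, whiten, ternarize, de-blur.

The pipeline converts an ensemble of luminance images into ternarized patches
and their texture coordinates:

1. logarithm of pixel intensities (skipped when the input encoding is
   already logarithmic),
2. downsampling by averaging over ``N x N`` pixel blocks,
3. splitting into non-overlapping ``R x R`` patches,
4. whitening with a single ensemble-derived frequency-domain filter that
   removes the average pairwise correlations,
5. rank-order ternarization to equal numbers of black, gray and white
   checks per patch,
6. texture analysis, and
7. rejection of blurred patches with a two-component Gaussian mixture in
   texture space, keeping the component whose members have the higher
   median Laplacian sharpness.

Sharpness is computed on the raw image region of each patch, before any of
the preprocessing steps, and only over pixels that do not border image edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import convolve2d

from .space import GrayPatch, InvalidParameterError, PatchSizeError, TextureVector, analyze

__all__ = [
    "PipelineConfig",
    "PatchRecord",
    "PipelineResult",
    "log_transform",
    "downsample",
    "patchify",
    "build_whitening_filter",
    "whiten",
    "ternarize",
    "sharpness",
    "remove_blurred",
    "run_pipeline",
    "independent_coords",
]

logger = logging.getLogger("graytex.pipeline")

LAPLACIAN = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)


@dataclass(frozen=True)
class PipelineConfig:
    """Preprocessing parameters; defaults N=2, R=32, G=3."""

    N: int = 2
    R: int = 32
    G: int = 3
    input_is_log: bool = False

    def __post_init__(self):
        if self.N < 1:
            raise InvalidParameterError("downsampling factor N must be >= 1")
        if self.R < 2:
            raise InvalidParameterError("patch size R must be >= 2")


@dataclass
class PatchRecord:
    """One analyzed patch: provenance, coordinates, sharpness and focus flag."""

    image_id: int
    row: int
    col: int
    patch: GrayPatch
    vector: TextureVector
    sharpness: float
    in_focus: bool = True


@dataclass
class PipelineResult:
    records: list
    whitening_filter: np.ndarray
    config: PipelineConfig
    kept_fraction: float

    @property
    def vectors(self) -> np.ndarray:
        """Flattened coordinate vectors of the in-focus patches."""
        return np.array([r.vector.flat for r in self.records if r.in_focus])

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.records:
            rows.append(
                {"image_id": r.image_id, "row": r.row, "col": r.col,
                 "sharpness": r.sharpness, "in_focus": r.in_focus,
                 **{f"c{i}": v for i, v in enumerate(r.vector.flat)}}
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Elementary stages
# ---------------------------------------------------------------------------


def log_transform(image: np.ndarray, input_is_log: bool = False) -> np.ndarray:
    """Natural log of intensities; identity when already log-encoded."""
    image = np.asarray(image, dtype=float)
    if input_is_log:
        return image
    n_bad = int(np.sum(image <= 0))
    if n_bad:
        raise InvalidParameterError(
            f"log transform requires positive intensities; {n_bad} pixels <= 0"
        )
    return np.log(image)


def downsample(image: np.ndarray, N: int) -> np.ndarray:
    """Average over N x N pixel blocks, dropping trailing partial blocks."""
    if N < 1:
        raise InvalidParameterError("N must be >= 1")
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    if H < N or W < N:
        raise PatchSizeError(f"image {image.shape} smaller than {N}x{N} block")
    if N == 1:
        return image.copy()
    Hq, Wq = H // N, W // N
    return image[: Hq * N, : Wq * N].reshape(Hq, N, Wq, N).mean(axis=(1, 3))


def patchify(image: np.ndarray, R: int) -> list[tuple[int, int, np.ndarray]]:
    """Non-overlapping R x R tiles in row-major order, partial edges dropped.

    Returns ``(row, col, tile)`` triples with the tile's grid position.
    """
    image = np.asarray(image)
    H, W = image.shape
    out = []
    for i in range(H // R):
        for j in range(W // R):
            out.append((i, j, image[i * R : (i + 1) * R, j * R : (j + 1) * R]))
    if not out:
        logger.info("patchify: image %s yields no %dx%d patches", image.shape, R, R)
    return out


def build_whitening_filter(patches) -> np.ndarray:
    """Reciprocal square root of the ensemble-mean power spectrum.

    The mean over patches of ``|FFT2|**2`` estimates the ensemble power
    spectrum; ``1/sqrt`` of it is the Fourier transform of the whitening
    filter.  The zero-frequency gain is set to 0 (the patch mean carries no
    texture information once patches are rank-ternarized, and its power is
    dominated by luminance rather than spatial structure).
    """
    patches = np.asarray(list(patches), dtype=float)
    if patches.ndim != 3 or patches.shape[0] < 1:
        raise InvalidParameterError("need at least one patch of uniform size")
    power = np.mean(np.abs(np.fft.fft2(patches, axes=(1, 2))) ** 2, axis=0)
    nondc = power.copy()
    nondc[0, 0] = 1.0  # DC handled separately
    if np.any(nondc <= 0):
        raise InvalidParameterError(
            "ensemble power spectrum has zero bins; degenerate ensemble"
        )
    filt = 1.0 / np.sqrt(nondc)
    filt[0, 0] = 0.0
    return filt


def whiten(patch: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Apply a frequency-domain filter: real part of IFFT(FFT(patch) * filt)."""
    patch = np.asarray(patch, dtype=float)
    if patch.shape != filt.shape:
        raise InvalidParameterError("patch and filter shapes differ")
    return np.fft.ifft2(np.fft.fft2(patch) * filt).real


def ternarize(patch: np.ndarray, rng=None, G: int = 3) -> GrayPatch:
    """Rank-order quantization into (nearly) equal thirds per patch.

    The lowest third of pixels becomes level 0, the middle third level 1 and
    the top third level 2; counts per level differ by at most one.  Ties are
    broken by a seeded pseudorandom permutation of the tied indices so the
    assignment is deterministic given ``rng`` and unbiased across levels.
    """
    patch = np.asarray(patch, dtype=float)
    n = patch.size
    if n < G:
        raise PatchSizeError("patch must have at least G pixels")
    rng = np.random.default_rng(rng)
    order = np.lexsort((rng.random(n), patch.ravel()))
    base, rem = divmod(n, G)
    counts = [base + (1 if lvl < rem else 0) for lvl in range(G)]
    levels = np.empty(n, dtype=np.int64)
    start = 0
    for lvl, cnt in enumerate(counts):
        levels[order[start : start + cnt]] = lvl
        start += cnt
    return GrayPatch(levels.reshape(patch.shape), G)


def sharpness(raw_patch: np.ndarray) -> float:
    """Median absolute Laplacian response of the median-normalized patch.

    The patch is divided by its median luminance, convolved with the 3x3
    Laplacian kernel, and the median absolute response over interior (valid)
    pixels is returned.  Invariant to overall intensity scaling.
    """
    raw_patch = np.asarray(raw_patch, dtype=float)
    if raw_patch.shape[0] < 3 or raw_patch.shape[1] < 3:
        raise PatchSizeError("sharpness needs at least a 3x3 patch")
    med = np.median(raw_patch)
    if med <= 0:
        raise InvalidParameterError("median luminance must be positive")
    resp = convolve2d(raw_patch / med, LAPLACIAN, mode="valid")
    return float(np.median(np.abs(resp)))


def independent_coords(flat: np.ndarray, G: int = 3) -> np.ndarray:
    """Drop each group's last probability: (n, groups*G) -> (n, groups*(G-1)).

    An affine bijection of the coordinates (the dropped entries are
    1 - sum of the rest); used where a full-rank representation is needed.
    """
    flat = np.atleast_2d(np.asarray(flat, dtype=float))
    n = flat.shape[0]
    return flat.reshape(n, -1, G)[:, :, : G - 1].reshape(n, -1)


def remove_blurred(vectors: np.ndarray, sharp: np.ndarray, seed=0,
                   reg_covar: float = 1e-6) -> np.ndarray:
    """Boolean mask of in-focus patches via a 2-component Gaussian mixture.

    A full-covariance (unshared) two-component mixture is fit to the texture
    coordinates; each patch is assigned to its maximum-responsibility
    component, and the component whose members have the higher median
    sharpness is kept.  Ties are broken in favor of the larger component.
    """
    from sklearn.mixture import GaussianMixture

    vectors = np.asarray(vectors, dtype=float)
    sharp = np.asarray(sharp, dtype=float)
    if vectors.shape[0] != sharp.shape[0]:
        raise InvalidParameterError("vectors and sharpness lengths differ")
    if vectors.shape[0] < 2:
        raise InvalidParameterError("need at least two patches")
    X = independent_coords(vectors) if vectors.ndim == 2 else vectors
    gmm = GaussianMixture(
        n_components=2, covariance_type="full", reg_covar=reg_covar,
        n_init=10, init_params="k-means++", random_state=np.random.default_rng(seed).integers(2**31),
    )
    labels = gmm.fit_predict(X)
    med = [np.median(sharp[labels == k]) if np.any(labels == k) else -np.inf
           for k in (0, 1)]
    if med[0] == med[1]:
        keep = int(np.sum(labels == 1) > np.sum(labels == 0))
    else:
        keep = int(np.argmax(med))
    mask = labels == keep
    logger.info("blur rejection: keeping %d/%d patches (component %d)",
                mask.sum(), mask.size, keep)
    return mask


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def run_pipeline(images, config: PipelineConfig | None = None, seed=0) -> PipelineResult:
    """Full pipeline over an ensemble of luminance images.

    Parameters
    ----------
    images : iterable of 2D arrays
        Linear luminance (or log-luminance if ``config.input_is_log``).
    config : PipelineConfig
    seed : int
        Drives ternarization tie-breaking and the blur-rejection mixture.

    Returns
    -------
    PipelineResult
        Per-patch records (with in-focus flags), the whitening filter and
        the kept fraction.  Deterministic given the seed.
    """
    config = config or PipelineConfig()
    images = [np.asarray(im, dtype=float) for im in images]
    ss = np.random.SeedSequence(seed)
    s_tern, s_gmm = ss.spawn(2)
    rng_tern = np.random.default_rng(s_tern)

    raw_regions, tiles, meta = [], [], []
    RN = config.R * config.N
    for idx, im in enumerate(images):
        down = downsample(log_transform(im, config.input_is_log), config.N)
        for i, j, tile in patchify(down, config.R):
            lin = im if not config.input_is_log else np.exp(im)
            raw_regions.append(lin[i * RN : (i + 1) * RN, j * RN : (j + 1) * RN])
            tiles.append(tile)
            meta.append((idx, i, j))
    logger.info("pipeline: %d images -> %d patches (N=%d, R=%d)",
                len(images), len(tiles), config.N, config.R)
    if not tiles:
        return PipelineResult([], np.zeros((0, 0)), config, 0.0)

    filt = build_whitening_filter(tiles)
    records = []
    for (idx, i, j), tile, raw in zip(meta, tiles, raw_regions):
        tern = ternarize(whiten(tile, filt), rng_tern, config.G)
        vec = analyze(tern, boundary="valid")
        records.append(PatchRecord(idx, i, j, tern, vec, sharpness(raw)))

    vectors = np.array([r.vector.flat for r in records])
    sharp = np.array([r.sharpness for r in records])
    mask = remove_blurred(vectors, sharp, seed=s_gmm.generate_state(1)[0] % (2**31))
    for r, keep in zip(records, mask):
        r.in_focus = bool(keep)
    kept = float(mask.mean())
    logger.info("pipeline: kept fraction %.3f", kept)
    return PipelineResult(records, filt, config, kept)


def plot_blur_projection(result: PipelineResult, group_x: str = "beta(+-)",
                         group_y: str = "alpha(+-+-)", h: int = 0, path=None):
    """Scatter of two texture coordinates colored by the focus flag.

    A diagnostic projection of the blur-rejection mixture (the in-focus
    component typically has the higher contrast, i.e. sits farther from the
    1/3 point).  Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = np.array([r.vector[group_x][h] for r in result.records])
    ys = np.array([r.vector[group_y][h] for r in result.records])
    focus = np.array([r.in_focus for r in result.records])
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(xs[~focus], ys[~focus], s=6, c="lightgray", label="rejected")
    ax.scatter(xs[focus], ys[focus], s=6, c="black", label="in focus")
    ax.axvline(1 / 3, color="C0", lw=0.5)
    ax.axhline(1 / 3, color="C0", lw=0.5)
    ax.set_xlabel(f"{group_x} p{h}")
    ax.set_ylabel(f"{group_y} p{h}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
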