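"""Image-contrast statistics and the empirical contrast ratio (ECR).

The fraction of two-photon fluorescence that originates from the focal plane
can be estimated from paired two-photon/three-photon movies of the same
field of view.  Out-of-focus fluorescence adds a spatially smooth pedestal
to the two-photon image, reducing its local contrast; three-photon
excitation is assumed background-free, so the ratio of local contrast
parameters

    gamma_{j,k} = (<Fbar>_j - min(Fbar)_j) / <Fbar>_j

computed over 32 x 32-pixel subregions ``j`` of the time-averaged movies of
modality ``k`` estimates the in-focus fraction

    ECR_j = gamma_{j,2P} / gamma_{j,3P} = Fbar_i / (Fbar_i + Fbar_oof),

under three assumptions: the time-averaged brightness is the sum of
in-focus and out-of-focus fluorescence; three-photon excitation generates
no out-of-focus fluorescence; and in-focus brightness is a
modality-independent concentration field times a modality gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "Movie",
    "MoviePair",
    "ECRResult",
    "read_movie",
    "preprocess",
    "time_average",
    "block_contrast",
    "subregion_gamma",
    "empirical_contrast_ratio",
    "ecr_depth_profile",
]

#: Side of the square subregions used for the contrast parameter gamma.
GAMMA_TILE = 32

#: Side of the square blocks used for whole-image contrast (nearest integer
#: tiling of the 22.5-pixel convention; trailing partial blocks included).
CONTRAST_BLOCK = 22


@dataclass(frozen=True)
class Movie:
    """A fluorescence movie of one modality at one depth.

    ``frames`` is a ``(T, H, W)`` array of nonnegative brightness values in
    digitizer units; ``dark_frames`` (optional) are frames acquired with no
    laser illumination, whose pixel-wise temporal mean is the dark current.
    """

    frames: np.ndarray
    modality: str = "2p"
    depth_um: Optional[float] = None
    dark_frames: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) stack with T >= 1")
        if not np.all(np.isfinite(frames)):
            raise ValueError("frames must be finite")
        object.__setattr__(self, "frames", frames)
        if self.modality not in ("2p", "3p"):
            raise ValueError("modality must be '2p' or '3p'")
        if self.dark_frames is not None:
            dark = np.asarray(self.dark_frames, dtype=float)
            if dark.ndim == 2:
                dark = dark[None]
            if dark.shape[1:] != frames.shape[1:]:
                raise ValueError("dark frames must match the movie geometry")
            object.__setattr__(self, "dark_frames", dark)

    @property
    def shape(self):
        return self.frames.shape


@dataclass(frozen=True)
class MoviePair:
    """Co-registered two-photon and three-photon movies of one field of view."""

    two_photon: Movie
    three_photon: Movie
    depth_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.two_photon.frames.shape[1:] != self.three_photon.frames.shape[1:]:
            raise ValueError("paired movies must share image geometry")


@dataclass(frozen=True)
class ECRResult:
    """Per-subregion and summary empirical contrast ratios at one depth.

    ``subregions`` holds one row per 32 x 32 tile with the gamma of both
    modalities, the (clipped) ECR, and whether the tile was retained.
    ``mean_ecr`` averages the clipped ECR over retained tiles and estimates
    the in-focus fluorescence fraction; ``mean_ecr_unclipped`` is reported
    alongside for diagnostics.
    """

    subregions: pd.DataFrame
    mean_ecr: float
    mean_ecr_unclipped: float
    n_retained: int
    n_excluded: int
    depth_um: Optional[float] = None


def read_movie(
    path,
    modality: str,
    depth_um: Optional[float] = None,
    dark_path=None,
) -> Movie:
    """Load a multi-page TIFF stack (any integer/float sample type)."""
    frames = np.asarray(tifffile.imread(path), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    dark = None
    if dark_path is not None:
        dark = np.asarray(tifffile.imread(dark_path), dtype=float)
    return Movie(frames=frames, modality=modality, depth_um=depth_um, dark_frames=dark)


def preprocess(movie: Movie, target_mean: float = 100.0) -> Movie:
    """Dark-subtract and normalize a movie to a common mean brightness.

    The pixel-wise temporal mean of the dark frames is subtracted from every
    frame (negative results are clipped to zero, with a log warning), and
    the movie is rescaled so its global mean equals ``target_mean``.  The
    contrast parameter gamma is invariant to the rescale; normalization only
    removes gain differences between movies.
    """
    if target_mean <= 0:
        raise ValueError("target mean must be positive")
    frames = movie.frames
    if movie.dark_frames is not None:
        dark = movie.dark_frames.mean(axis=0)
        frames = frames - dark[None]
        n_neg = int((frames < 0).sum())
        if n_neg:
            logger.warning(
                "dark subtraction clipped %d negative pixel values to 0", n_neg
            )
            frames = np.clip(frames, 0.0, None)
    mean = frames.mean()
    if mean <= 0:
        raise ValueError("movie has nonpositive mean after dark subtraction")
    frames = frames * (target_mean / mean)
    return replace(movie, frames=frames, dark_frames=None)


def time_average(movie: Movie) -> np.ndarray:
    """Temporal mean projection of a movie."""
    return movie.frames.mean(axis=0)


def block_contrast(image: np.ndarray, block: int = CONTRAST_BLOCK) -> float:
    """Whole-image contrast: mean over blocks of ``1 - min/max``.

    The time-averaged image is tiled into ``block x block`` squares
    (trailing partial blocks included); each block contributes
    ``1 - min/max`` and blocks with ``max = 0`` are skipped.  Ranges from 0
    (every block constant) to 1.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if np.any(image < 0):
        raise ValueError("image must be nonnegative")
    h, w = image.shape
    if block > h or block > w:
        raise ValueError("block size exceeds image size")
    values = []
    skipped = 0
    for i in range(0, h, block):
        for j in range(0, w, block):
            tile = image[i : i + block, j : j + block]
            mx = tile.max()
            if mx == 0:
                skipped += 1
                continue
            values.append(1.0 - tile.min() / mx)
    if skipped:
        logger.info("block_contrast skipped %d empty blocks", skipped)
    if not values:
        raise ValueError("no nonempty blocks in image")
    return float(np.mean(values))


def subregion_gamma(image: np.ndarray, tile: int = GAMMA_TILE) -> pd.DataFrame:
    """Contrast parameter gamma over a grid of ``tile x tile`` subregions.

    Returns a frame with one row per subregion: grid position, the minimum
    and mean of the time-averaged brightness, and
    ``gamma = (mean - min) / mean``.  Trailing partial tiles are dropped
    (the native 256 x 512 geometry tiles exactly); subregions with zero
    mean have undefined gamma and are marked excluded.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    h, w = image.shape
    n_rows, n_cols = h // tile, w // tile
    if n_rows == 0 or n_cols == 0:
        raise ValueError("image smaller than one subregion")
    if h % tile or w % tile:
        logger.info(
            "image %dx%d does not tile exactly into %d-pixel subregions; "
            "trailing partial tiles dropped",
            h, w, tile,
        )
    rows = []
    for i in range(n_rows):
        for j in range(n_cols):
            sub = image[i * tile : (i + 1) * tile, j * tile : (j + 1) * tile]
            mean = sub.mean()
            mn = sub.min()
            ok = mean > 0
            rows.append(
                {
                    "row": i,
                    "col": j,
                    "min": mn,
                    "mean": mean,
                    "gamma": (mean - mn) / mean if ok else np.nan,
                    "excluded": not ok,
                }
            )
    return pd.DataFrame(rows)


def empirical_contrast_ratio(
    pair: MoviePair,
    tile: int = GAMMA_TILE,
    gamma_floor: float = 0.05,
    clip: bool = True,
) -> ECRResult:
    """Estimate the in-focus fluorescence fraction from a 2P/3P movie pair.

    Computes gamma per subregion of the time-averaged movies, forms
    ``ECR_j = gamma_2P / gamma_3P``, excludes subregions whose three-photon
    gamma is below ``gamma_floor`` (the ratio is unstable there) or whose
    mean is zero, clips per-subregion values above 1 (noise) to 1, and
    averages over the retained subregions.  The unclipped mean is reported
    alongside.
    """
    g2 = subregion_gamma(time_average(pair.two_photon), tile)
    g3 = subregion_gamma(time_average(pair.three_photon), tile)
    df = g2[["row", "col"]].copy()
    df["gamma_2p"] = g2["gamma"]
    df["gamma_3p"] = g3["gamma"]
    reasons = np.full(len(df), "", dtype=object)
    reasons[(g2["excluded"] | g3["excluded"]).to_numpy()] = "zero-mean subregion"
    low = (df["gamma_3p"] < gamma_floor).to_numpy() & (reasons == "")
    reasons[low] = "gamma_3p below floor"
    df["retained"] = reasons == ""
    df["exclusion_reason"] = reasons
    with np.errstate(divide="ignore", invalid="ignore"):
        ecr = df["gamma_2p"] / df["gamma_3p"]
    df["ecr_unclipped"] = ecr
    df["ecr"] = np.clip(ecr, None, 1.0) if clip else ecr
    kept = df[df["retained"]]
    if kept.empty:
        raise ValueError("no subregions retained for the ECR average")
    n_clipped = int((kept["ecr_unclipped"] > 1.0).sum())
    if n_clipped:
        logger.info("clipped %d subregion ECR values above 1", n_clipped)
    return ECRResult(
        subregions=df,
        mean_ecr=float(kept["ecr"].mean()),
        mean_ecr_unclipped=float(kept["ecr_unclipped"].mean()),
        n_retained=int(len(kept)),
        n_excluded=int(len(df) - len(kept)),
        depth_um=pair.depth_um,
    )


def ecr_depth_profile(
    pairs: Sequence[MoviePair],
    tile: int = GAMMA_TILE,
    gamma_floor: float = 0.05,
) -> pd.DataFrame:
    """Mean ECR per movie pair, one row per pair, sorted by depth.

    The resulting (depth, mean ECR) table is the measured analogue of the
    model contrast-ratio-versus-depth curve.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one movie pair")
    rows = []
    for pair in pairs:
        res = empirical_contrast_ratio(pair, tile=tile, gamma_floor=gamma_floor)
        rows.append(
            {
                "depth_um": pair.depth_um,
                "mean_ecr": res.mean_ecr,
                "mean_ecr_unclipped": res.mean_ecr_unclipped,
                "n_retained": res.n_retained,
                "n_excluded": res.n_excluded,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("depth_um", kind="stable").reset_index(drop=True)
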