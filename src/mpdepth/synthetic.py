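"""Synthetic paired two-photon/three-photon movies with known ground truth.

The generator renders a shared in-focus scene (disk-shaped somata over a
neuropil background, driven by direction-tuned calcium transients) and
images it in two modalities:

* the three-photon channel sees only the in-focus scene (three-photon
  excitation is treated as background-free),
* the two-photon channel mixes the scene with a spatially uniform
  out-of-focus background at a chosen *in-focus fraction* ``f``:
  ``2P = gain * (f * S(t) + (1 - f) * B(t))``.  The background is either
  constant (the time-mean of the spatial mean of the scene, so the
  time-averaged in-focus fraction is exactly ``f``) or *activity-driven*
  (proportional to the instantaneous population-mean brightness — the
  mechanism by which out-of-focus fluorescence contaminates deep two-photon
  traces with a common population signal).

``f`` can be set directly or taken from the optics model's contrast ratio
at a given depth, enabling end-to-end emulation of a depth series.
Poisson-Gaussian sensor noise and a dark offset complete the model; every
random draw comes from one seeded generator recorded in the manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import optics
from .contrast import Movie, MoviePair
from .tuning import DIRECTIONS_DEG, StimulusSchedule

__all__ = [
    "SceneSpec",
    "AcquisitionSpec",
    "SyntheticDataset",
    "generate_schedule",
    "calcium_kernel",
    "simulate_traces",
    "render_scene_frames",
    "render_movie_pair",
    "generate_dataset",
    "generate_depth_series",
]


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and tuning of the in-focus scene.

    ``rois`` holds one row per soma: center (``y``, ``x``, pixels), disk
    ``radius_px``, ``baseline`` brightness (digitizer units), preferred
    direction (deg), von Mises concentration ``kappa`` and peak dF/F
    ``amplitude``.  ``neuropil`` is the uniform background brightness of
    the scene itself (in focus, distinct from out-of-focus background).
    """

    shape: tuple = (256, 512)
    rois: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    neuropil: float = 10.0
    field_of_view_um: float = 360.0
    texture_sd: float = 0.25
    texture_seed: int = 0

    def __post_init__(self) -> None:
        r = self.rois
        required = {"y", "x", "radius_px", "baseline", "preferred_deg", "kappa", "amplitude"}
        if r is None or not required.issubset(r.columns):
            raise ValueError(f"rois needs columns {sorted(required)}")
        h, w = self.shape
        if np.any((r["y"] < 0) | (r["y"] >= h) | (r["x"] < 0) | (r["x"] >= w)):
            raise ValueError("ROI centers must lie within the image")
        if np.any(r["radius_px"] <= 0) or np.any(r["amplitude"] < 0):
            raise ValueError("radii must be positive and amplitudes nonnegative")

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    def texture_field(self) -> np.ndarray:
        """Static multiplicative texture of the tissue, shape ``(H, W)``.

        Real neuropil is not optically flat: per-pixel structural variation
        (processes, boutons, vasculature shadows) dominates sensor noise in
        the time-averaged image and anchors the per-tile minimum used by the
        contrast statistics.  Modeled as ``1 + texture_sd * N(0, 1)`` per
        pixel (clipped at 0.05), drawn once from ``texture_seed``.
        """
        if self.texture_sd == 0:
            return np.ones(self.shape)
        rng = np.random.default_rng(self.texture_seed)
        return np.clip(
            1.0 + self.texture_sd * rng.standard_normal(self.shape), 0.05, None
        )

    def label_image(self) -> np.ndarray:
        """Integer label mask: 0 background, k = ROI k (row order)."""
        h, w = self.shape
        yy, xx = np.mgrid[0:h, 0:w]
        labels = np.zeros((h, w), dtype=np.int32)
        for k, roi in enumerate(self.rois.itertuples(), start=1):
            disk = (yy - roi.y) ** 2 + (xx - roi.x) ** 2 <= roi.radius_px**2
            labels[disk] = k
        return labels

    @classmethod
    def random(
        cls,
        seed: int,
        shape: tuple = (256, 512),
        n_rois: Optional[int] = None,
        radius_px: tuple = (6.0, 9.0),
        baseline: tuple = (60.0, 120.0),
        amplitude: tuple = (0.5, 1.5),
        kappa: tuple = (2.0, 5.0),
        neuropil: float = 10.0,
        min_separation_factor: float = 1.5,
        allow_overlap: bool = False,
        max_tries: int = 20000,
    ) -> "SceneSpec":
        """Scene with randomly placed, randomly tuned somata.

        The ROI count defaults to a uniform draw from 50-90 (the typical
        per-field count at this field of view).  Placement uses rejection
        sampling with a minimum center separation of
        ``min_separation_factor`` times the summed radii, unless
        ``allow_overlap``.
        """
        rng = np.random.default_rng(seed)
        h, w = shape
        if n_rois is None:
            n_rois = int(rng.integers(50, 91))
        centers, radii = [], []
        tries = 0
        margin = radius_px[1]
        while len(centers) < n_rois:
            tries += 1
            if tries > max_tries:
                raise RuntimeError("could not place ROIs; reduce count or allow overlap")
            r = rng.uniform(*radius_px)
            y = rng.uniform(margin, h - margin)
            x = rng.uniform(margin, w - margin)
            if not allow_overlap and any(
                (y - cy) ** 2 + (x - cx) ** 2
                < (min_separation_factor * (r + cr)) ** 2
                for (cy, cx), cr in zip(centers, radii)
            ):
                continue
            centers.append((y, x))
            radii.append(r)
        rois = pd.DataFrame(
            {
                "y": [c[0] for c in centers],
                "x": [c[1] for c in centers],
                "radius_px": radii,
                "baseline": rng.uniform(*baseline, n_rois),
                "preferred_deg": rng.choice(DIRECTIONS_DEG, n_rois),
                "kappa": rng.uniform(*kappa, n_rois),
                "amplitude": rng.uniform(*amplitude, n_rois),
            }
        )
        return cls(shape=shape, rois=rois, neuropil=neuropil)

    @classmethod
    def tiled(
        cls,
        shape: tuple = (256, 512),
        tile: int = 32,
        radius_px: float = 6.0,
        baseline: float = 90.0,
        amplitude: float = 0.0,
        kappa: float = 3.0,
        preferred_deg: float = 0.0,
        neuropil: float = 10.0,
    ) -> "SceneSpec":
        """Calibration scene: one identical ROI at the center of every tile.

        Every ``tile x tile`` subregion has exactly the same content, so the
        subregion means are spatially uniform and the ECR estimator recovers
        the rendered in-focus fraction exactly (the estimator is unbiased
        only up to spatial heterogeneity of the subregion means).  By
        default the scene is static (``amplitude = 0``).
        """
        h, w = shape
        if h % tile or w % tile:
            raise ValueError("shape must be a multiple of the tile size")
        ys = np.arange(tile // 2, h, tile, dtype=float)
        xs = np.arange(tile // 2, w, tile, dtype=float)
        yy, xx = np.meshgrid(ys, xs, indexing="ij")
        n = yy.size
        rois = pd.DataFrame(
            {
                "y": yy.ravel(),
                "x": xx.ravel(),
                "radius_px": radius_px,
                "baseline": baseline,
                "preferred_deg": preferred_deg,
                "kappa": kappa,
                "amplitude": amplitude,
            }
        )
        # texture off: every tile must be exactly identical
        return cls(shape=shape, rois=rois, neuropil=neuropil, texture_sd=0.0)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Imaging parameters shared by the rendered movie pair.

    ``in_focus_fraction`` applies to the two-photon channel only; the
    three-photon channel is background-free by construction.  With
    ``noise=True`` each pixel is drawn as
    ``Poisson(value * photons_per_unit) / photons_per_unit`` plus Gaussian
    read noise, then offset by the dark level.
    """

    frame_rate: float = 8.0
    gain_2p: float = 1.0
    gain_3p: float = 1.0
    in_focus_fraction: float = 1.0
    background: str = "constant"
    noise: bool = True
    photons_per_unit: float = 2.0
    read_noise_sd: float = 0.5
    dark_level: float = 10.0
    n_dark_frames: int = 40

    def __post_init__(self) -> None:
        if not 0.0 <= self.in_focus_fraction <= 1.0:
            raise ValueError("in-focus fraction must lie in [0, 1]")
        if self.background not in ("constant", "activity"):
            raise ValueError("background must be 'constant' or 'activity'")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")


@dataclass(frozen=True)
class SyntheticDataset:
    """A rendered movie pair with complete ground truth."""

    pair: MoviePair
    labels: np.ndarray
    traces_dff: np.ndarray
    schedule: Optional[StimulusSchedule]
    preferred_deg: np.ndarray
    in_focus_fraction: float
    manifest: dict

    def save(self, out_dir) -> None:
        """Write TIFF movies/masks, CSV traces/schedule, and a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, movie in (
            ("movie_2p", self.pair.two_photon),
            ("movie_3p", self.pair.three_photon),
        ):
            tifffile.imwrite(out / f"{name}.tif", movie.frames.astype(np.float32))
            if movie.dark_frames is not None:
                tifffile.imwrite(
                    out / f"dark_{name[-2:]}.tif", movie.dark_frames.astype(np.float32)
                )
        tifffile.imwrite(out / "labels.tif", self.labels.astype(np.int32))
        pd.DataFrame(self.traces_dff).to_csv(out / "traces_dff.csv", index=False)
        pd.DataFrame({"preferred_deg": self.preferred_deg}).to_csv(
            out / "preferred.csv", index=False
        )
        if self.schedule is not None:
            self.schedule.to_csv(out / "schedule.csv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=float)


def generate_schedule(
    seed: int,
    repeats: int = 8,
    stimulus_s: float = 2.0,
    gray_s: float = 1.0,
) -> StimulusSchedule:
    """Randomly ordered grating schedule: 12 directions x ``repeats``.

    Presentations of ``stimulus_s`` are separated by ``gray_s`` of gray
    screen; the first onset follows an initial gray period.  With the
    native 8 repeats this gives 96 presentations over 96 x 3 s.
    """
    rng = np.random.default_rng(seed)
    dirs = np.repeat(DIRECTIONS_DEG, repeats)
    rng.shuffle(dirs)
    onsets = gray_s + np.arange(len(dirs)) * (stimulus_s + gray_s)
    table = pd.DataFrame(
        {"direction_deg": dirs, "onset_s": onsets, "duration_s": stimulus_s}
    )
    return StimulusSchedule(table=table, gray_s=gray_s)


def calcium_kernel(
    frame_rate: float,
    rise_s: float = 0.2,
    decay_s: float = 1.5,
    duration_s: float = 8.0,
) -> np.ndarray:
    """Calcium-indicator impulse response (fast rise, slow decay), peak 1.

    The defaults approximate a slow indicator such as GCaMP6s; only
    round-trip recovery properties, not kinetics, are asserted anywhere.
    """
    t = np.arange(0.0, duration_s, 1.0 / frame_rate)
    k = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    return k / k.max()


def simulate_traces(
    scene: SceneSpec,
    schedule: StimulusSchedule,
    frame_rate: float,
    seed: int,
    trial_gain_sd: float = 0.15,
    rise_s: float = 0.2,
    decay_s: float = 1.5,
) -> np.ndarray:
    """Ground-truth dF/F traces, shape ``(n_roi, T)``.

    Each presentation drives ROI ``i`` with amplitude
    ``amplitude_i * exp(kappa_i (cos(dir - preferred_i) - 1))`` times a
    trial gain drawn from ``N(1, trial_gain_sd)`` (clipped at 0); the
    2-s boxcar drive is convolved with the calcium kernel and normalized so
    a unit-amplitude trial peaks at dF/F = 1.  The argmax over the
    direction grid of the noise-free mean response equals the specified
    preferred direction.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(np.ceil(schedule.total_s * frame_rate))
    kernel = calcium_kernel(frame_rate, rise_s, decay_s)
    # normalization: peak of a unit boxcar of one stimulus convolved with kernel
    stim_frames = int(round(schedule.table["duration_s"].iloc[0] * frame_rate))
    unit = np.convolve(np.ones(stim_frames), kernel)
    norm = unit.max()
    rois = scene.rois
    traces = np.zeros((scene.n_rois, n_frames))
    onsets = (schedule.table["onset_s"].to_numpy() * frame_rate).round().astype(int)
    dirs = schedule.table["direction_deg"].to_numpy()
    gains = np.clip(
        rng.normal(1.0, trial_gain_sd, size=(scene.n_rois, len(onsets))), 0.0, None
    )
    if trial_gain_sd == 0:
        gains[:] = 1.0
    for i, roi in enumerate(rois.itertuples()):
        amp = roi.amplitude * np.exp(
            roi.kappa * (np.cos(np.deg2rad(dirs - roi.preferred_deg)) - 1.0)
        )
        drive = np.zeros(n_frames)
        for j, on in enumerate(onsets):
            drive[on : on + stim_frames] += amp[j] * gains[i, j]
        traces[i] = np.convolve(drive, kernel)[:n_frames] / norm
    return traces


def render_scene_frames(scene: SceneSpec, traces_dff: np.ndarray) -> np.ndarray:
    """In-focus scene movie ``S(t)``, shape ``(T, H, W)``, float32.

    Textured neuropil plus each soma at ``baseline * (1 + dF/F(t))``, all
    modulated by the static texture field.
    """
    traces_dff = np.atleast_2d(np.asarray(traces_dff, dtype=float))
    if traces_dff.shape[0] != scene.n_rois:
        raise ValueError("one trace per ROI required")
    h, w = scene.shape
    t = traces_dff.shape[1]
    texture = scene.texture_field().astype(np.float32)
    base = np.full((h, w), scene.neuropil, dtype=np.float32)
    labels = scene.label_image()
    for k, roi in enumerate(scene.rois.itertuples(), start=1):
        base[labels == k] = roi.baseline
    base = base * texture
    frames = np.repeat(base[None], t, axis=0)
    for k, roi in enumerate(scene.rois.itertuples(), start=1):
        mask = labels == k
        frames[:, mask] += (
            roi.baseline * texture[mask]
        ) * traces_dff[k - 1].astype(np.float32)[:, None]
    return frames


def _apply_noise(frames: np.ndarray, acq: AcquisitionSpec, rng) -> np.ndarray:
    out = np.asarray(frames, dtype=float)
    if acq.noise:
        counts = rng.poisson(np.clip(out, 0, None) * acq.photons_per_unit)
        out = counts / acq.photons_per_unit + rng.normal(
            0.0, acq.read_noise_sd, size=out.shape
        )
    return (out + acq.dark_level).astype(np.float32)


def render_movie_pair(
    scene: SceneSpec,
    traces_dff: np.ndarray,
    acq: AcquisitionSpec,
    seed: int,
    schedule: Optional[StimulusSchedule] = None,
    depth_um: Optional[float] = None,
) -> SyntheticDataset:
    """Render the 2P/3P movie pair for a scene and its ground-truth traces.

    The three-photon channel is ``gain_3p * S(t)``; the two-photon channel
    is ``gain_2p * (f * S(t) + (1 - f) * B(t))`` with ``B`` the uniform
    out-of-focus background (constant, or tracking the population-mean
    activity).  In both background modes the time-averaged two-photon image
    equals ``gain_2p * (f * Sbar + (1 - f) * mean(Sbar))``, so the rendered
    time-averaged in-focus fraction is exactly ``f``.
    """
    rng = np.random.default_rng(seed)
    scene_frames = render_scene_frames(scene, traces_dff)
    f = acq.in_focus_fraction
    pop = scene_frames.mean(axis=(1, 2))
    background = pop if acq.background == "activity" else np.full_like(pop, pop.mean())
    two = acq.gain_2p * (f * scene_frames + (1.0 - f) * background[:, None, None])
    three = acq.gain_3p * scene_frames
    h, w = scene.shape
    darks = {}
    movies = {}
    for name, frames, gain in (("2p", two, acq.gain_2p), ("3p", three, acq.gain_3p)):
        dark = np.full((acq.n_dark_frames, h, w), float(acq.dark_level))
        if acq.noise:
            dark = dark + rng.normal(0.0, acq.read_noise_sd, size=dark.shape)
        darks[name] = dark.astype(np.float32)
        movies[name] = Movie(
            frames=_apply_noise(frames, acq, rng),
            modality=name,
            depth_um=depth_um,
            dark_frames=darks[name],
        )
    manifest = {
        "seed": int(seed),
        "shape": list(scene.shape),
        "neuropil": scene.neuropil,
        "rois": scene.rois.to_dict(orient="list"),
        "acquisition": asdict(acq),
        "depth_um": depth_um,
    }
    return SyntheticDataset(
        pair=MoviePair(
            two_photon=movies["2p"], three_photon=movies["3p"], depth_um=depth_um
        ),
        labels=scene.label_image(),
        traces_dff=np.asarray(traces_dff, dtype=float),
        schedule=schedule,
        preferred_deg=scene.rois["preferred_deg"].to_numpy(),
        in_focus_fraction=f,
        manifest=manifest,
    )


def generate_dataset(
    scene: SceneSpec,
    acq: AcquisitionSpec,
    seed: int,
    repeats: int = 8,
    trial_gain_sd: float = 0.15,
    depth_um: Optional[float] = None,
) -> SyntheticDataset:
    """Schedule + traces + rendered pair from a single seed (one-stop shop).

    Sub-seeds for the schedule order, trace variability and sensor noise
    are derived deterministically from ``seed``; regenerating with the same
    arguments reproduces the dataset bit-for-bit.
    """
    children = np.random.SeedSequence(seed).spawn(3)
    subseeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    schedule = generate_schedule(subseeds[0], repeats=repeats)
    traces = simulate_traces(
        scene, schedule, acq.frame_rate, subseeds[1], trial_gain_sd=trial_gain_sd
    )
    ds = render_movie_pair(
        scene, traces, acq, subseeds[2], schedule=schedule, depth_um=depth_um
    )
    ds.manifest["root_seed"] = int(seed)
    ds.manifest["repeats"] = int(repeats)
    ds.manifest["trial_gain_sd"] = float(trial_gain_sd)
    return ds


def generate_depth_series(
    depths_um: Sequence[float],
    params: optics.OpticalParameters,
    scene: SceneSpec,
    acq: AcquisitionSpec,
    seed: int,
    repeats: int = 8,
    quad: optics.QuadratureSettings = optics.DEFAULT_QUADRATURE,
) -> list:
    """One dataset per depth, with ``f`` set to the model CR at that depth.

    Emulates a two-photon/three-photon depth series: the rendered in-focus
    fraction of the two-photon channel follows the optics model's contrast
    ratio, so the measured ECR profile should fall with depth the way the
    model curve does.
    """
    depths = np.asarray(depths_um, dtype=float)
    if np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be strictly ascending")
    out = []
    for i, z in enumerate(depths):
        cr = optics.contrast_ratio(params.replace(focal_depth_um=float(z)), quad).contrast
        acq_z = AcquisitionSpec(**{**asdict(acq), "in_focus_fraction": float(cr)})
        out.append(
            generate_dataset(
                scene, acq_z, seed + i, repeats=repeats, depth_um=float(z)
            )
        )
    return out
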