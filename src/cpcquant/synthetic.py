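"""Ground-truthed synthetic inputs for the imaging and mass-photometry analyses.

Emulates wide-field immunofluorescence of mitotic cells and chromosome
spreads: centromere/kinetochore foci are isotropic 2-D Gaussian spots on a
noisy cytoplasmic background, imaged in up to four channels (ACA reference,
a marker such as Borealin/Aurora B/Sgo1, GFP, DNA).  The marker channel can
follow three localization patterns along the inter-kinetochore axis:
a single inner-centromere pool, a dual kinetochore-proximal pool, or their
combination.  Every generated focus is recorded in a truth table, including
the analytic full width at half maximum of the marker profile for spreads,
so downstream detection, quantification and profile code can be scored
against known answers.

Also generates mass-photometry event lists as draws from a Gaussian mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.optimize import brentq

__all__ = [
    "ImageScene",
    "SpotTruth",
    "MassMixture",
    "generate_cell_image",
    "generate_spread_image",
    "generate_mass_events",
    "write_scene_tiff",
    "read_scene_tiff",
    "write_truth_csv",
    "write_scene_yaml",
    "read_scene_yaml",
]

CHANNELS = ("ACA", "marker", "GFP", "DNA")

#: Camera pixel pitch at the sample for a 6.45-um CCD behind a 100x objective.
DEFAULT_PIXEL_SIZE_UM = 0.0645

GAUSS_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass
class SpotTruth:
    """One ground-truth focus: position, width and per-channel amplitude."""

    centroid_um: tuple[float, float]
    sigma_um: float
    amplitude: dict[str, float]
    pair_id: int | None = None
    pool_model: str | None = None  # inner_only | dual_pool | both

    def validate(self, channels) -> None:
        if self.sigma_um <= 0:
            raise ValueError("sigma_um must be positive")
        for ch, a in self.amplitude.items():
            if ch not in channels:
                raise ValueError(f"amplitude channel {ch!r} not in scene channels")
            if a < 0:
                raise ValueError("amplitudes must be nonnegative")
        if self.pool_model is not None and self.pool_model not in (
            "inner_only", "dual_pool", "both",
        ):
            raise ValueError(f"unknown pool_model {self.pool_model!r}")


@dataclass
class ImageScene:
    """Specification of one synthetic multi-channel field of view."""

    width_px: int = 256
    height_px: int = 256
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    channels: tuple[str, ...] = ("ACA", "marker")
    spots: list[SpotTruth] = field(default_factory=list)
    background_level: dict[str, float] | float = 100.0
    gaussian_sd: dict[str, float] | float = 0.0
    poisson: bool = False
    seed: int = 0

    def background(self, channel: str) -> float:
        if isinstance(self.background_level, dict):
            return float(self.background_level.get(channel, 0.0))
        return float(self.background_level)

    def noise_sd(self, channel: str) -> float:
        if isinstance(self.gaussian_sd, dict):
            return float(self.gaussian_sd.get(channel, 0.0))
        return float(self.gaussian_sd)

    @property
    def extent_um(self) -> tuple[float, float]:
        return (self.width_px * self.pixel_size_um, self.height_px * self.pixel_size_um)

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        wx, wy = self.extent_um
        pair_counts: dict[int, int] = {}
        for s in self.spots:
            s.validate(self.channels)
            x, y = s.centroid_um
            if not (0.0 <= x <= wx and 0.0 <= y <= wy):
                raise ValueError(
                    f"spot centroid ({x:g}, {y:g}) um lies outside the "
                    f"{wx:g} x {wy:g} um image"
                )
            if s.pair_id is not None:
                pair_counts[s.pair_id] = pair_counts.get(s.pair_id, 0) + 1
        bad = {k: v for k, v in pair_counts.items() if v != 2}
        if bad:
            raise ValueError(f"pair_ids must group exactly 2 spots; got {bad}")


@dataclass
class MassMixture:
    """Gaussian mixture of molecular masses (kD) for mass-photometry events."""

    components: list[tuple[float, float, float]]  # (mean_kD, sd_kD, weight)
    n_events: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        w = np.array([c[2] for c in self.components], dtype=float)
        if np.any(np.array([c[1] for c in self.components]) < 0):
            raise ValueError("component sd must be nonnegative")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError(f"component weights must sum to 1, got {w.sum():g}")


def _render(scene: ImageScene) -> dict[str, np.ndarray]:
    """Noise-free per-channel rendering: background + sum of 2-D Gaussians.

    Images are sampled at pixel centers; pixel (row r, col c) covers
    [c, c+1) x [r, r+1) px, so its center sits at ((c+0.5), (r+0.5)) px.
    """
    yy, xx = np.mgrid[0 : scene.height_px, 0 : scene.width_px]
    x_um = (xx + 0.5) * scene.pixel_size_um
    y_um = (yy + 0.5) * scene.pixel_size_um
    out = {
        ch: np.full((scene.height_px, scene.width_px), scene.background(ch), dtype=float)
        for ch in scene.channels
    }
    for s in scene.spots:
        x0, y0 = s.centroid_um
        g = np.exp(-((x_um - x0) ** 2 + (y_um - y0) ** 2) / (2.0 * s.sigma_um**2))
        for ch, amp in s.amplitude.items():
            if amp:
                out[ch] += amp * g
    return out


def _truth_frame(scene: ImageScene) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(scene.spots):
        rows.append(
            {
                "spot_id": i,
                "x_um": s.centroid_um[0],
                "y_um": s.centroid_um[1],
                # array-index coordinates (pixel centers at integers)
                "x_px": s.centroid_um[0] / scene.pixel_size_um - 0.5,
                "y_px": s.centroid_um[1] / scene.pixel_size_um - 0.5,
                "sigma_um": s.sigma_um,
                "pair_id": s.pair_id if s.pair_id is not None else -1,
                "pool_model": s.pool_model or "",
                **{f"amp_{ch}": s.amplitude.get(ch, 0.0) for ch in scene.channels},
            }
        )
    cols = (
        ["spot_id", "x_um", "y_um", "x_px", "y_px", "sigma_um", "pair_id", "pool_model"]
        + [f"amp_{ch}" for ch in scene.channels]
    )
    return pd.DataFrame(rows, columns=cols)


def generate_cell_image(scene: ImageScene) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Render a multi-channel cell image and its ground-truth spot table.

    Deterministic for identical (scene, seed).  Noise is additive Gaussian
    per channel, with optional Poisson shot noise applied to the noise-free
    expectation first.
    """
    scene.validate()
    images = _render(scene)
    rng = np.random.default_rng(scene.seed)
    for ch in scene.channels:
        img = images[ch]
        if scene.poisson:
            img = rng.poisson(np.maximum(img, 0.0)).astype(float)
        sd = scene.noise_sd(ch)
        if sd > 0:
            img = img + rng.normal(0.0, sd, size=img.shape)
        images[ch] = img
    return images, _truth_frame(scene)


# ---------------------------------------------------------------------------
# Chromosome spreads


def _axis_profile_fwhm(offsets: np.ndarray, amps: np.ndarray, sigma_um: float,
                       half_window_um: float = 1.0) -> float:
    """Outermost-crossing FWHM of a 1-D sum of Gaussians, analytically.

    ``offsets`` are peak positions along the pair axis relative to the pair
    midpoint.  Baseline is the profile minimum on [-w, +w]; the half level is
    (max + baseline)/2 and crossings are located with a root finder on the
    continuous profile, so the value is exact up to root-finder tolerance.
    """

    def f(x):
        return np.sum(amps * np.exp(-((x - offsets) ** 2) / (2.0 * sigma_um**2)))

    xs = np.linspace(-half_window_um, half_window_um, 4001)
    vals = np.array([f(x) for x in xs])
    fmax, fmin = vals.max(), vals.min()
    half = 0.5 * (fmax + fmin)
    above = vals >= half
    idx = np.nonzero(above)[0]
    if idx[0] == 0 or idx[-1] == len(xs) - 1:
        raise ValueError("profile does not fall to half maximum inside the window")
    left = brentq(lambda x: f(x) - half, xs[idx[0] - 1], xs[idx[0]])
    right = brentq(lambda x: f(x) - half, xs[idx[-1]], xs[idx[-1] + 1])
    return right - left


def generate_spread_image(
    scene: ImageScene,
    inter_kt_sep_um: float,
    n_pairs: int = 10,
    pool_model: str = "inner_only",
    aca_sigma_um: float = 0.12,
    marker_sigma_um: float = 0.15,
    aca_amplitude: float = 1000.0,
    marker_amplitude: float = 800.0,
    dual_offset_frac: float = 0.8,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Render a chromosome-spread field of kinetochore pairs with truth.

    Each pair contributes two ACA foci separated by ``inter_kt_sep_um`` at a
    random position and orientation.  The marker channel follows
    ``pool_model``: ``inner_only`` places one Gaussian at the pair midpoint,
    ``dual_pool`` two Gaussians flanking the midpoint at ``dual_offset_frac``
    of the ACA half-separation (kinetochore-proximal), and ``both`` their
    combination.  The returned pair table carries the analytic marker-profile
    FWHM along the pair axis as ground truth.

    ``scene`` supplies the canvas, noise model and seed; its ``spots`` list
    is replaced by the generated layout.
    """
    scene.validate()
    if not 0.0 < inter_kt_sep_um <= 1.5:
        raise ValueError("inter_kt_sep_um must lie in (0, 1.5] um (pairing cap)")
    wx, wy = scene.extent_um
    if inter_kt_sep_um >= min(wx, wy):
        raise ValueError("pair separation exceeds the image extent")
    if pool_model not in ("inner_only", "dual_pool", "both"):
        raise ValueError(f"unknown pool_model {pool_model!r}")
    if "ACA" not in scene.channels or "marker" not in scene.channels:
        raise ValueError("spread scenes need ACA and marker channels")

    rng = np.random.default_rng(scene.seed)
    half = inter_kt_sep_um / 2.0
    margin = half + 5.0 * max(aca_sigma_um, marker_sigma_um)
    if 2 * margin >= min(wx, wy):
        raise ValueError("image too small for the requested separation and PSF")

    spots: list[SpotTruth] = []
    pair_rows = []
    for pid in range(n_pairs):
        cx = rng.uniform(margin, wx - margin)
        cy = rng.uniform(margin, wy - margin)
        theta = rng.uniform(0.0, np.pi)
        ux, uy = np.cos(theta), np.sin(theta)
        a = (cx - half * ux, cy - half * uy)
        b = (cx + half * ux, cy + half * uy)
        for pt in (a, b):
            spots.append(
                SpotTruth(centroid_um=pt, sigma_um=aca_sigma_um,
                          amplitude={"ACA": aca_amplitude}, pair_id=pid,
                          pool_model=pool_model)
            )
        if pool_model == "inner_only":
            offsets = np.array([0.0])
        elif pool_model == "dual_pool":
            offsets = np.array([-dual_offset_frac * half, dual_offset_frac * half])
        else:
            offsets = np.array([-dual_offset_frac * half, 0.0, dual_offset_frac * half])
        for off in offsets:
            spots.append(
                SpotTruth(
                    centroid_um=(cx + off * ux, cy + off * uy),
                    sigma_um=marker_sigma_um,
                    amplitude={"marker": marker_amplitude},
                    pool_model=pool_model,
                )
            )
        fwhm = _axis_profile_fwhm(
            offsets, np.full(len(offsets), marker_amplitude), marker_sigma_um
        )
        pair_rows.append(
            {
                "pair_id": pid,
                "ax_um": a[0], "ay_um": a[1],
                "bx_um": b[0], "by_um": b[1],
                "mid_x_um": cx, "mid_y_um": cy,
                "separation_um": inter_kt_sep_um,
                "pool_model": pool_model,
                "true_marker_fwhm_um": fwhm,
            }
        )

    layout = ImageScene(
        width_px=scene.width_px, height_px=scene.height_px,
        pixel_size_um=scene.pixel_size_um, channels=scene.channels,
        spots=spots, background_level=scene.background_level,
        gaussian_sd=scene.gaussian_sd, poisson=scene.poisson, seed=scene.seed,
    )
    images, spot_truth = generate_cell_image(layout)
    pairs = pd.DataFrame(pair_rows)
    pairs.attrs["spot_truth"] = spot_truth
    return images, pairs


def generate_phenotype_counts(
    rates: dict[str, float], n_per_group: int, seed: int = 0
) -> tuple[np.ndarray, list[str]]:
    """Binomial phenotype counts per condition (e.g. anaphase-error cells).

    Returns a 2 x k contingency table (rows: phenotype present / absent,
    columns: groups in the given order) with one binomial draw per group at
    its true rate.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    labels = list(rates)
    pos = np.array([rng.binomial(n_per_group, rates[g]) for g in labels])
    table = np.vstack([pos, n_per_group - pos])
    return table, labels


def generate_mass_events(mix: MassMixture) -> np.ndarray:
    """Draw per-particle masses (kD) from a Gaussian mixture, seeded."""
    mix.validate()
    rng = np.random.default_rng(mix.seed)
    means = np.array([c[0] for c in mix.components])
    sds = np.array([c[1] for c in mix.components])
    weights = np.array([c[2] for c in mix.components], dtype=float)
    comp = rng.choice(len(means), size=mix.n_events, p=weights / weights.sum())
    return rng.normal(means[comp], sds[comp])


# ---------------------------------------------------------------------------
# File formats


def write_scene_tiff(images: dict[str, np.ndarray], path) -> None:
    """Write channels as TIFF pages, channel name in each page description."""
    with tifffile.TiffWriter(path) as tif:
        for ch, img in images.items():
            tif.write(img.astype(np.float32), description=ch)


def read_scene_tiff(path) -> dict[str, np.ndarray]:
    images = {}
    with tifffile.TiffFile(path) as tif:
        for page in tif.pages:
            name = (page.description or f"ch{len(images)}").strip()
            images[name] = page.asarray().astype(float)
    return images


def write_truth_csv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)


def write_scene_yaml(scene: ImageScene, path) -> None:
    data = {
        "width_px": scene.width_px,
        "height_px": scene.height_px,
        "pixel_size_um": scene.pixel_size_um,
        "channels": list(scene.channels),
        "background_level": scene.background_level,
        "gaussian_sd": scene.gaussian_sd,
        "poisson": scene.poisson,
        "seed": scene.seed,
        "spots": [
            {
                "centroid_um": list(s.centroid_um),
                "sigma_um": s.sigma_um,
                "amplitude": s.amplitude,
                "pair_id": s.pair_id,
                "pool_model": s.pool_model,
            }
            for s in scene.spots
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def read_scene_yaml(path) -> ImageScene:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    spots = [
        SpotTruth(
            centroid_um=tuple(s["centroid_um"]),
            sigma_um=s["sigma_um"],
            amplitude=s["amplitude"],
            pair_id=s.get("pair_id"),
            pool_model=s.get("pool_model"),
        )
        for s in data.pop("spots", [])
    ]
    data["channels"] = tuple(data.get("channels", ("ACA", "marker")))
    scene = ImageScene(spots=spots, **data)
    scene.validate()
    return scene
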