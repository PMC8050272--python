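"""SMLM training-data simulation and localisation post-processing.

The simulator produces raw single-molecule localisation microscopy movies with
known ground truth: per frame, an emitter count is drawn from a Normal law on
density (emitters/µm²), positions are uniform over the field of view, each
emitter gets a photon budget and a Gaussian PSF width from (truncated) Normal
laws, the expected photon image is a sum of pixel-integrated 2D Gaussians, and
the camera converts it as

    ADU = offset + Poisson(photons) / conversion_factor + Normal(0, read_noise)

clipped at zero.  The conversion factor is photoelectrons per A/D count
(ThunderSTORM camera convention); pass ``adu_per_photon=True`` for the
reciprocal convention.

The toolbox then mirrors a standard SMLM post-processing chain: histogram
rendering, localisation extraction from a reconstruction (local maxima +
intensity-weighted centroid), merging of emission events split over
consecutive frames (distance threshold, dark-frame gap), and drift
estimation/correction by cross-correlation of time-binned renderings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, ndimage
from scipy.special import erf

from .core_io import ImageStack, LocalisationTable

__all__ = [
    "SimulationParameters",
    "TABLE_PRESETS",
    "DriftTrace",
    "MergeConfig",
    "simulate_stack",
    "render_histogram",
    "extract_localisations",
    "merge_events",
    "estimate_drift",
    "apply_drift",
]


@dataclass
class SimulationParameters:
    """Simulator parameter block (units in field names or docid).

    Defaults are the BIN4 acquisition condition: a 10,240 nm field of view at
    160 nm camera pixels, 2.8 emitters/µm² with no frame-to-frame density
    spread, 20 frames, 153 +/- 29 nm PSF sigma and 3500 +/- 850 photons per
    emitter, conversion factor 16 e-/ADU, 1040 ADU read noise, 10,550 ADU
    offset.
    """

    fov_size_nm: float = 10240.0
    pixel_size_nm: float = 160.0
    adc_per_photon: float = 16.0
    readout_noise_adc: float = 1040.0
    offset_adc: float = 10550.0
    density_mean: float = 2.8
    density_std: float = 0.0
    n_frames: int = 20
    psf_sigma_nm: float = 153.0
    psf_sigma_std_nm: float = 29.0
    photons_mean: float = 3500.0
    photons_std: float = 850.0
    seed: int = 0
    adu_per_photon: bool = False  # reciprocal conversion convention
    poisson_density: bool = False  # draw per-frame emitter count from Poisson

    def __post_init__(self) -> None:
        for name in ("fov_size_nm", "pixel_size_nm", "adc_per_photon", "density_mean",
                     "psf_sigma_nm", "photons_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("readout_noise_adc", "offset_adc", "density_std",
                     "psf_sigma_std_nm", "photons_std"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if round(self.fov_size_nm / self.pixel_size_nm) * self.pixel_size_nm != self.fov_size_nm:
            raise ValueError("fov_size_nm must divide into whole pixels")

    @property
    def n_pixels(self) -> int:
        return int(round(self.fov_size_nm / self.pixel_size_nm))

    @property
    def area_um2(self) -> float:
        return (self.fov_size_nm / 1000.0) ** 2


#: Published acquisition conditions, keyed by dataset name.
TABLE_PRESETS: dict[str, SimulationParameters] = {
    "BIN4": SimulationParameters(),
    "BIN10": SimulationParameters(
        fov_size_nm=10240.0, pixel_size_nm=160.0, adc_per_photon=16.0,
        readout_noise_adc=1800.0, offset_adc=26500.0, density_mean=4.0,
        density_std=0.8, n_frames=20, psf_sigma_nm=150.0, psf_sigma_std_nm=25.0,
        photons_mean=5500.0, photons_std=2000.0,
    ),
    "TUB": SimulationParameters(
        fov_size_nm=15800.0, pixel_size_nm=158.0, adc_per_photon=12.7,
        readout_noise_adc=370.0, offset_adc=4090.0, density_mean=3.0,
        density_std=0.5, n_frames=20, psf_sigma_nm=160.0, psf_sigma_std_nm=30.0,
        photons_mean=2800.0, photons_std=900.0,
    ),
}


@dataclass
class DriftTrace:
    """Per-frame (dx, dy) displacement in nm relative to frame 1."""

    dx_nm: np.ndarray
    dy_nm: np.ndarray
    low_confidence_bins: list[int] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.dx_nm = np.asarray(self.dx_nm, dtype=float)
        self.dy_nm = np.asarray(self.dy_nm, dtype=float)
        if self.dx_nm.shape != self.dy_nm.shape:
            raise ValueError("dx and dy traces must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.dx_nm)

    def negated(self) -> "DriftTrace":
        return DriftTrace(-self.dx_nm, -self.dy_nm, list(self.low_confidence_bins))


@dataclass
class MergeConfig:
    """Event-merging rule: linking radius and allowed dark-frame gap.

    Defaults follow the published post-processing: 40 nm distance threshold
    with no dark frame allowed.
    """

    radius_nm: float = 40.0
    max_dark_frames: int = 0

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("radius_nm must be positive")
        if self.max_dark_frames < 0:
            raise ValueError("max_dark_frames must be >= 0")


def _truncated_normal(rng: np.random.Generator, mean, std, size) -> np.ndarray:
    """Normal draws resampled until positive (<= 100 rounds, then clamped)."""
    out = rng.normal(mean, std, size)
    if np.isscalar(std) and std == 0:
        return out
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad] if not np.isscalar(mean) else mean,
                              std, bad.sum())
    return np.maximum(out, np.finfo(float).tiny)


def _integrated_gaussian_image(
    n_pixels: int, pixel_nm: float, x_nm: np.ndarray, y_nm: np.ndarray,
    photons: np.ndarray, sigma_nm: np.ndarray,
) -> np.ndarray:
    """Expected photon image: sum of pixel-integrated 2D Gaussian spots.

    The flux in pixel [i, i+1) (nm edges i*px, (i+1)*px) is the difference of
    the Gaussian CDF at the pixel edges, evaluated per axis and multiplied.
    """
    img = np.zeros((n_pixels, n_pixels))
    edges = np.arange(n_pixels + 1) * pixel_nm
    for x, y, n_ph, sig in zip(x_nm, y_nm, photons, sigma_nm):
        denom = sig * np.sqrt(2.0)
        cdf_x = 0.5 * (1 + erf((edges - x) / denom))
        cdf_y = 0.5 * (1 + erf((edges - y) / denom))
        img += n_ph * np.outer(np.diff(cdf_y), np.diff(cdf_x))
    return img


def simulate_stack(params: SimulationParameters) -> tuple[ImageStack, LocalisationTable]:
    """Simulate a raw SMLM movie and its ground-truth localisation table.

    Fully reproducible from ``params.seed``; the returned stack is float32 ADU,
    the table holds every simulated emitter (frame, x, y in nm, photons,
    sigma in nm).
    """
    rng = np.random.default_rng(params.seed)
    n_px = params.n_pixels
    frames = np.empty((params.n_frames, n_px, n_px), dtype=np.float32)
    rec_frame: list[int] = []
    rec_x: list[float] = []
    rec_y: list[float] = []
    rec_ph: list[float] = []
    rec_sig: list[float] = []
    for f in range(params.n_frames):
        if params.poisson_density:
            n_emitters = int(rng.poisson(params.density_mean * params.area_um2))
        else:
            density = rng.normal(params.density_mean, params.density_std)
            n_emitters = int(round(max(0.0, density) * params.area_um2))
        x = rng.uniform(0, params.fov_size_nm, n_emitters)
        y = rng.uniform(0, params.fov_size_nm, n_emitters)
        photons = _truncated_normal(rng, params.photons_mean, params.photons_std, n_emitters)
        sigma = _truncated_normal(rng, params.psf_sigma_nm, params.psf_sigma_std_nm, n_emitters)
        photon_img = _integrated_gaussian_image(n_px, params.pixel_size_nm, x, y, photons, sigma)
        counted = rng.poisson(photon_img)
        if params.adu_per_photon:
            signal = counted * params.adc_per_photon
        else:
            signal = counted / params.adc_per_photon
        adu = params.offset_adc + signal + rng.normal(0.0, params.readout_noise_adc, photon_img.shape)
        frames[f] = np.clip(adu, 0, None)
        rec_frame.extend([f + 1] * n_emitters)
        rec_x.extend(x.tolist())
        rec_y.extend(y.tolist())
        rec_ph.extend(photons.tolist())
        rec_sig.extend(sigma.tolist())
    table = LocalisationTable.from_arrays(rec_frame, rec_x, rec_y, rec_ph, rec_sig)
    return ImageStack(frames=frames, pixel_size_nm=params.pixel_size_nm), table


def render_histogram(
    table: LocalisationTable,
    render_pixel_nm: float,
    blur_sigma_px: float = 0.0,
    extent_nm: tuple[float, float] | None = None,
) -> np.ndarray:
    """2D localisation count histogram at the rendering pitch.

    ``extent_nm`` fixes the (width, height) of the canvas; by default it is the
    ceiling of the maximum coordinate.  Total counts are preserved before the
    optional Gaussian blur (localisations outside the extent are clipped into
    the edge bins so nothing is lost).
    """
    if len(table) == 0:
        return np.zeros((1, 1))
    x, y = table.x_nm, table.y_nm
    if extent_nm is None:
        extent_nm = (float(x.max()) + render_pixel_nm, float(y.max()) + render_pixel_nm)
    w = max(1, int(np.ceil(extent_nm[0] / render_pixel_nm)))
    h = max(1, int(np.ceil(extent_nm[1] / render_pixel_nm)))
    cols = np.clip((x / render_pixel_nm).astype(int), 0, w - 1)
    rows = np.clip((y / render_pixel_nm).astype(int), 0, h - 1)
    img = np.zeros((h, w))
    np.add.at(img, (rows, cols), 1.0)
    if blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_px)
    return img


def extract_localisations(
    reconstruction: np.ndarray,
    pixel_size_nm: float,
    threshold_fraction: float = 0.2,
    window_radius_px: int = 2,
    frame: int = 1,
) -> LocalisationTable:
    """Extract localisation coordinates from a reconstructed image.

    Candidates are strict local maxima within the (2r+1)^2 neighbourhood whose
    value reaches ``threshold_fraction * max(image)``.  Each candidate's
    position is the intensity-weighted centroid over its window, in nm via the
    pixel-centre convention; its intensity is the window sum.
    """
    img = np.asarray(reconstruction, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("reconstruction must be a 2D raster")
    if (img < 0).any():
        raise ValueError("reconstruction must be non-negative")
    peak = img.max()
    if peak <= 0:
        return LocalisationTable.empty()
    r = window_radius_px
    size = 2 * r + 1
    local_max = ndimage.maximum_filter(img, size=size, mode="constant", cval=0.0)
    is_peak = (img == local_max) & (img >= threshold_fraction * peak) & (img > 0)
    # exact-tie plateaus (emitter centred on a pixel boundary) collapse to one
    # candidate each: the rounded centroid of the connected maximum region
    labelled, n_plateaus = ndimage.label(is_peak)
    rows, cols = [], []
    for prow, pcol in ndimage.center_of_mass(is_peak, labelled, range(1, n_plateaus + 1)):
        rows.append(int(round(prow)))
        cols.append(int(round(pcol)))
    fr, xs, ys, intens = [], [], [], []
    h, w = img.shape
    for row, col in zip(rows, cols):
        r0, r1 = max(0, row - r), min(h, row + r + 1)
        c0, c1 = max(0, col - r), min(w, col + r + 1)
        window = img[r0:r1, c0:c1]
        total = window.sum()
        rr, cc = np.mgrid[r0:r1, c0:c1]
        cy = (window * rr).sum() / total
        cx = (window * cc).sum() / total
        fr.append(frame)
        xs.append((cx + 0.5) * pixel_size_nm)
        ys.append((cy + 0.5) * pixel_size_nm)
        intens.append(total)
    return LocalisationTable.from_arrays(fr, xs, ys, intens)


def merge_events(table: LocalisationTable, cfg: MergeConfig | None = None) -> LocalisationTable:
    """Merge emission events split over consecutive frames into single records.

    A localisation in frame f links to the active track whose last position is
    within ``radius_nm`` and whose last frame is >= f - 1 - max_dark_frames
    (nearest neighbour, one-to-one per frame; ties to the lowest track index).
    Each finished track emits one record with the photon-weighted mean
    position, the summed photons and the first frame of the track.
    """
    cfg = cfg or MergeConfig()
    if len(table) == 0:
        return LocalisationTable.empty()
    df = table.df.sort_values("frame", kind="stable").reset_index(drop=True)
    frames = df["frame"].to_numpy(int)
    x = df["x [nm]"].to_numpy(float)
    y = df["y [nm]"].to_numpy(float)
    photons = (
        df["intensity [photon]"].to_numpy(float)
        if "intensity [photon]" in df.columns
        else np.ones(len(df))
    )
    sigma = df["sigma [nm]"].to_numpy(float) if "sigma [nm]" in df.columns else None

    # tracks: list of dicts with running photon-weighted sums
    tracks: list[dict] = []
    active: list[int] = []  # indices into tracks
    for f in np.unique(frames):
        active = [t for t in active if tracks[t]["last_frame"] >= f - 1 - cfg.max_dark_frames]
        idxs = np.nonzero(frames == f)[0]
        # candidate (distance, track, localisation) pairs within the radius
        pairs = []
        for t in active:
            tx, ty = tracks[t]["last_x"], tracks[t]["last_y"]
            for i in idxs:
                d = np.hypot(x[i] - tx, y[i] - ty)
                if d <= cfg.radius_nm:
                    pairs.append((d, t, i))
        pairs.sort(key=lambda p: (p[0], p[1]))
        used_tracks: set[int] = set()
        used_locs: set[int] = set()
        for d, t, i in pairs:
            if t in used_tracks or i in used_locs:
                continue
            used_tracks.add(t)
            used_locs.add(int(i))
            tr = tracks[t]
            tr["sum_wx"] += photons[i] * x[i]
            tr["sum_wy"] += photons[i] * y[i]
            tr["sum_w"] += photons[i]
            if sigma is not None:
                tr["sum_wsig"] += photons[i] * sigma[i]
            tr["last_x"], tr["last_y"], tr["last_frame"] = x[i], y[i], int(f)
        new_active = list(used_tracks)
        for i in idxs:
            if int(i) in used_locs:
                continue
            tracks.append(
                {
                    "first_frame": int(f),
                    "last_frame": int(f),
                    "last_x": x[i],
                    "last_y": y[i],
                    "sum_wx": photons[i] * x[i],
                    "sum_wy": photons[i] * y[i],
                    "sum_w": photons[i],
                    "sum_wsig": photons[i] * (sigma[i] if sigma is not None else 0.0),
                }
            )
            new_active.append(len(tracks) - 1)
        # keep previously active but unmatched tracks eligible for dark-frame gaps
        new_active.extend(t for t in active if t not in used_tracks)
        active = sorted(set(new_active))

    out_frame = [tr["first_frame"] for tr in tracks]
    out_x = [tr["sum_wx"] / tr["sum_w"] for tr in tracks]
    out_y = [tr["sum_wy"] / tr["sum_w"] for tr in tracks]
    out_ph = [tr["sum_w"] for tr in tracks]
    out_sig = [tr["sum_wsig"] / tr["sum_w"] for tr in tracks] if sigma is not None else None
    return LocalisationTable.from_arrays(out_frame, out_x, out_y, out_ph, out_sig)


def _xcorr_shift(ref: np.ndarray, img: np.ndarray) -> tuple[float, float]:
    """Shift (drow, dcol) of ``img`` relative to ``ref`` from the circular
    cross-correlation peak, refined by a 3x3 centroid around the peak."""
    f_ref = np.fft.fft2(ref)
    f_img = np.fft.fft2(img)
    corr = np.real(np.fft.ifft2(f_img * np.conj(f_ref)))
    h, w = corr.shape
    pr, pc = np.unravel_index(np.argmax(corr), corr.shape)
    # 3x3 centroid with wraparound, on background-subtracted weights
    rows = np.arange(pr - 1, pr + 2)
    cols = np.arange(pc - 1, pc + 2)
    patch = corr[np.ix_(rows % h, cols % w)]
    weights = np.clip(patch - patch.min(), 0, None)
    total = weights.sum()
    if total > 0:
        dr = float((weights * rows[:, None]).sum() / total)
        dc = float((weights * cols[None, :]).sum() / total)
    else:
        dr, dc = float(pr), float(pc)
    if dr > h / 2:
        dr -= h
    if dc > w / 2:
        dc -= w
    return dr, dc


def estimate_drift(
    table: LocalisationTable,
    n_time_bins: int = 5,
    render_pixel_nm: float = 20.0,
    blur_sigma_px: float = 1.0,
    min_bin_localisations: int = 10,
) -> DriftTrace:
    """Estimate lateral drift by cross-correlating time-binned renderings.

    Localisations are split (frame-ordered) into ``n_time_bins`` equal-count
    temporal bins; the shift of each bin's rendering against the first bin's is
    read off the cross-correlation peak with 3x3 centroid sub-pixel refinement,
    and the per-frame trace is the linear interpolation between bin-centre
    frames, anchored at (0, 0) for frame 1.
    """
    if n_time_bins < 2:
        raise ValueError("n_time_bins must be >= 2")
    if len(np.unique(table.frame)) < n_time_bins:
        raise ValueError("table must span at least n_time_bins distinct frames")
    order = np.argsort(table.frame, kind="stable")
    frames = table.frame[order]
    x = table.x_nm[order]
    y = table.y_nm[order]
    extent = (float(x.max()) + render_pixel_nm, float(y.max()) + render_pixel_nm)

    splits = np.array_split(np.arange(len(frames)), n_time_bins)
    low_conf = [k for k, idx in enumerate(splits) if len(idx) < min_bin_localisations]
    renders = []
    centres = []
    for idx in splits:
        sub = LocalisationTable.from_arrays(frames[idx], x[idx], y[idx])
        renders.append(render_histogram(sub, render_pixel_nm, blur_sigma_px, extent))
        centres.append(float(frames[idx].mean()))

    max_frame = int(frames.max())
    shifts_x = [0.0]
    shifts_y = [0.0]
    for img in renders[1:]:
        dr, dc = _xcorr_shift(renders[0], img)
        shifts_x.append(dc * render_pixel_nm)
        shifts_y.append(dr * render_pixel_nm)
    all_frames = np.arange(1, max_frame + 1, dtype=float)
    # linear interpolation between bin centres, extrapolated at the stack ends
    fx = interpolate.interp1d(centres, shifts_x, fill_value="extrapolate")
    fy = interpolate.interp1d(centres, shifts_y, fill_value="extrapolate")
    dx = fx(all_frames)
    dy = fy(all_frames)
    dx -= dx[0]
    dy -= dy[0]
    return DriftTrace(dx, dy, low_conf)


def apply_drift(table: LocalisationTable, trace: DriftTrace) -> LocalisationTable:
    """Subtract the per-frame drift from every localisation's coordinates."""
    if len(table) == 0:
        return table
    frames = table.frame
    if frames.max() > trace.n_frames:
        raise ValueError(
            f"trace covers {trace.n_frames} frames but table reaches frame {frames.max()}"
        )
    df = table.df.copy()
    df["x [nm]"] = table.x_nm - trace.dx_nm[frames - 1]
    df["y [nm]"] = table.y_nm - trace.dy_nm[frames - 1]
    return LocalisationTable(df)
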