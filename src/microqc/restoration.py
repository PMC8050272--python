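"""Grey-scale restoration quality control.

Compares a model prediction against ground truth (the "target") and, for
context, against the raw input (the "source"): mean structural similarity
(mSSIM) with a per-pixel SSIM map, normalised root-mean-square error (NRMSE)
with a per-pixel root-squared-error (RSE) map, and PSNR.  Intensity scales are
made comparable first: the target is percentile-normalised and the other two
images are least-squares affine-matched onto it, so all metrics are invariant
to affine rescaling of the compared image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

__all__ = [
    "NormalizationParams",
    "SSIMParams",
    "RestorationReport",
    "percentile_normalize",
    "affine_match",
    "ssim_map",
    "rse_map",
    "psnr",
    "restoration_report",
]


@dataclass
class NormalizationParams:
    """Record of the normalisation applied before metric computation."""

    pmin: float = 1.0
    pmax: float = 99.9
    alpha: float = 1.0
    beta: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.pmin < self.pmax <= 100):
            raise ValueError("need 0 <= pmin < pmax <= 100")


@dataclass
class SSIMParams:
    """Structural-similarity parameters (Wang et al. defaults).

    ``L`` is the data range; the stabilisation constants are
    C1 = (K1*L)^2 and C2 = (K2*L)^2.
    """

    K1: float = 0.01
    K2: float = 0.03
    L: float = 1.0
    window_sigma: float = 1.5
    window_size: int = 11

    def __post_init__(self) -> None:
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("K1 and K2 must be positive")
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")

    @property
    def C1(self) -> float:
        return (self.K1 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (self.K2 * self.L) ** 2


@dataclass
class RestorationReport:
    """Scalar metrics plus per-pixel maps for a source/target/prediction triple."""

    mssim_ts: float
    psnr_ts: float
    nrmse_ts: float
    mssim_tp: float
    psnr_tp: float
    nrmse_tp: float
    ssim_map: np.ndarray
    rse_map: np.ndarray
    nrmse_mode: str = "sd"
    normalization: NormalizationParams = field(default_factory=NormalizationParams)

    @property
    def improved(self) -> bool:
        """True when the prediction beats the raw source on both metrics."""
        return self.mssim_tp > self.mssim_ts and self.nrmse_tp < self.nrmse_ts

    def scalars(self) -> dict[str, float]:
        return {
            "mssim_target_vs_source": self.mssim_ts,
            "psnr_target_vs_source": self.psnr_ts,
            "nrmse_target_vs_source": self.nrmse_ts,
            "mssim_target_vs_prediction": self.mssim_tp,
            "psnr_target_vs_prediction": self.psnr_tp,
            "nrmse_target_vs_prediction": self.nrmse_tp,
        }


def percentile_normalize(image: np.ndarray, pmin: float = 1.0, pmax: float = 99.9) -> np.ndarray:
    """Map the pmin/pmax percentiles of ``image`` to 0 and 1 (no clipping).

    A constant image (zero percentile span) maps to all zeros.
    """
    if not pmin < pmax:
        raise ValueError("pmin must be < pmax")
    image = np.asarray(image, dtype=np.float64)
    lo, hi = np.percentile(image, [pmin, pmax])
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def affine_match(
    reference: np.ndarray, image: np.ndarray
) -> tuple[np.ndarray, NormalizationParams]:
    """Return ``alpha * image + beta`` minimising the MSE to ``reference``.

    Closed-form least squares: alpha = cov(image, reference) / var(image).
    A zero-variance image yields alpha = 0, beta = mean(reference), flagged.
    """
    reference = np.asarray(reference, dtype=np.float64)
    image = np.asarray(image, dtype=np.float64)
    if reference.shape != image.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {image.shape}")
    var = image.var()
    if var == 0:
        params = NormalizationParams(alpha=0.0, beta=float(reference.mean()), degenerate=True)
    else:
        alpha = float(((image - image.mean()) * (reference - reference.mean())).mean() / var)
        beta = float(reference.mean() - alpha * image.mean())
        params = NormalizationParams(alpha=alpha, beta=beta)
    return params.alpha * image + params.beta, params


def ssim_map(
    reference: np.ndarray,
    image: np.ndarray,
    params: SSIMParams | None = None,
) -> tuple[np.ndarray, float]:
    """Per-pixel SSIM map (Gaussian-weighted local statistics) and its mean.

    Inputs are assumed normalised to the data range ``params.L``.
    """
    params = params or SSIMParams()
    reference = np.asarray(reference, dtype=np.float64)
    image = np.asarray(image, dtype=np.float64)
    if reference.shape != image.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {image.shape}")
    mssim, full = structural_similarity(
        reference,
        image,
        data_range=params.L,
        gaussian_weights=True,
        sigma=params.window_sigma,
        win_size=params.window_size,
        use_sample_covariance=False,
        K1=params.K1,
        K2=params.K2,
        full=True,
    )
    return full, float(mssim)


def rse_map(
    reference: np.ndarray,
    image: np.ndarray,
    mode: str = "sd",
) -> tuple[np.ndarray, float]:
    """Root-squared-error map (|reference - image|) and scalar NRMSE.

    ``mode`` selects the NRMSE denominator: ``sd`` (reference standard
    deviation, default), ``range`` or ``mean``.  A degenerate denominator
    (constant reference) yields NaN NRMSE; the map is still valid.
    """
    reference = np.asarray(reference, dtype=np.float64)
    image = np.asarray(image, dtype=np.float64)
    if reference.shape != image.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {image.shape}")
    diff = reference - image
    m = np.abs(diff)
    rmse = float(np.sqrt((diff**2).mean()))
    denom = {
        "sd": float(reference.std()),
        "range": float(reference.max() - reference.min()),
        "mean": float(reference.mean()),
    }.get(mode)
    if denom is None:
        raise ValueError(f"unknown NRMSE mode {mode!r}")
    nrmse = rmse / denom if denom > 0 else math.nan
    return m, nrmse


def psnr(reference: np.ndarray, image: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio, ``20*log10(L) - 10*log10(MSE)`` in dB.

    Identical images give +inf (an explicit sentinel the caller may flag).
    """
    reference = np.asarray(reference, dtype=np.float64)
    image = np.asarray(image, dtype=np.float64)
    if reference.shape != image.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {image.shape}")
    mse = float(((reference - image) ** 2).mean())
    if mse == 0:
        return math.inf
    return 20 * math.log10(data_range) - 10 * math.log10(mse)


def restoration_report(
    source: np.ndarray,
    target: np.ndarray,
    prediction: np.ndarray,
    ssim_params: SSIMParams | None = None,
    pmin: float = 1.0,
    pmax: float = 99.9,
    nrmse_mode: str = "sd",
) -> RestorationReport:
    """Full restoration QC: normalise, then score target-vs-source and
    target-vs-prediction; maps are returned for the prediction comparison.
    """
    source = np.asarray(source, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    prediction = np.asarray(prediction, dtype=np.float64)
    if not (source.shape == target.shape == prediction.shape):
        raise ValueError("source, target and prediction must share one shape")
    ssim_params = ssim_params or SSIMParams()

    # 3D data is scored slice-wise; scalars are averaged, maps stacked per slice.
    if source.ndim == 3:
        reports = [
            restoration_report(
                source[k], target[k], prediction[k], ssim_params, pmin, pmax, nrmse_mode
            )
            for k in range(source.shape[0])
        ]
        return RestorationReport(
            mssim_ts=float(np.mean([r.mssim_ts for r in reports])),
            psnr_ts=float(np.mean([r.psnr_ts for r in reports])),
            nrmse_ts=float(np.mean([r.nrmse_ts for r in reports])),
            mssim_tp=float(np.mean([r.mssim_tp for r in reports])),
            psnr_tp=float(np.mean([r.psnr_tp for r in reports])),
            nrmse_tp=float(np.mean([r.nrmse_tp for r in reports])),
            ssim_map=np.stack([r.ssim_map for r in reports]),
            rse_map=np.stack([r.rse_map for r in reports]),
            nrmse_mode=nrmse_mode,
            normalization=reports[0].normalization,
        )

    tgt = percentile_normalize(target, pmin, pmax)
    src, _ = affine_match(tgt, source)
    pred, norm = affine_match(tgt, prediction)
    norm.pmin, norm.pmax = pmin, pmax

    _, mssim_ts = ssim_map(tgt, src, ssim_params)
    smap, mssim_tp = ssim_map(tgt, pred, ssim_params)
    _, nrmse_ts = rse_map(tgt, src, nrmse_mode)
    rmap, nrmse_tp = rse_map(tgt, pred, nrmse_mode)

    return RestorationReport(
        mssim_ts=mssim_ts,
        psnr_ts=psnr(tgt, src, ssim_params.L),
        nrmse_ts=nrmse_ts,
        mssim_tp=mssim_tp,
        psnr_tp=psnr(tgt, pred, ssim_params.L),
        nrmse_tp=nrmse_tp,
        ssim_map=smap,
        rse_map=rmap,
        nrmse_mode=nrmse_mode,
        normalization=norm,
    )
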