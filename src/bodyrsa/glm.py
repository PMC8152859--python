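"""First-level general linear model for the block design.

Boxcar regressors convolved with the canonical double-gamma HRF,
discrete-cosine high-pass filtering (1/128 Hz), six rigid-body motion
regressors, optional whitening by a single pooled AR(1) coefficient,
linear contrasts, and sphere-ROI activation detection.

Data arrays are oriented volumes x voxels throughout this module; the
forward simulator emits voxels x volumes and the pipeline transposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal, stats

from .design import StimulusSchedule

__all__ = [
    "GlmError",
    "DesignMatrix",
    "BetaEstimates",
    "ContrastMap",
    "RoiDefinition",
    "ActivationResult",
    "canonical_hrf",
    "condition_regressors",
    "build_design_matrix",
    "global_scale",
    "fit_glm",
    "compute_contrast",
    "make_sphere_roi",
    "detect_activation",
    "extract_roi_betas",
]


class GlmError(ValueError):
    pass


def canonical_hrf(dt: float) -> np.ndarray:
    """Canonical double-gamma HRF sampled at step ``dt`` seconds.

    Response gamma peaking near 5 s (shape 6), undershoot gamma (shape
    16), response:undershoot ratio 6, 32-s support, unit dispersions.
    The kernel is normalized to peak 1.
    """
    if dt <= 0:
        raise GlmError("dt must be positive")
    t = np.arange(0.0, 32.0 + dt / 2, dt)
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    return h / h.max()


def condition_regressors(
    schedule: StimulusSchedule, oversample: int = 30
) -> tuple[np.ndarray, list[str]]:
    """Boxcar-convolved-with-HRF regressors, one column per condition.

    Boxcars are built on an oversampled grid (``tr / oversample``),
    convolved with the canonical HRF and sampled at volume acquisition
    times. Condition order follows first appearance order sorted by the
    schedule's canonical label ordering (alphabetical of unique labels is
    avoided: order of first definition in the schedule's events is
    unstable across runs, so labels are sorted).
    """
    labels = sorted({e.condition for e in schedule.events})
    dt = schedule.tr / oversample
    n_fine = int(round(schedule.total_duration / dt))
    hrf = canonical_hrf(dt)
    # unit-area kernel: a sustained boxcar converges to plateau 1, so
    # betas are amplitudes in data units
    hrf = hrf / hrf.sum()
    X = np.zeros((schedule.n_volumes, len(labels)))
    vol_idx = (np.arange(schedule.n_volumes) * schedule.tr / dt).astype(int)
    for j, lab in enumerate(labels):
        box = np.zeros(n_fine)
        for e in schedule.events:
            if e.condition != lab:
                continue
            a = int(round(e.onset / dt))
            b = int(round((e.onset + e.duration) / dt))
            box[a:b] = 1.0
        conv = np.convolve(box, hrf)[:n_fine]
        X[:, j] = conv[vol_idx]
    return X, labels


def dct_highpass_basis(n_volumes: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine basis spanning drifts slower than ``cutoff_s``.

    Number of components K = floor(2 * n * tr / cutoff); columns are the
    standard DCT-II regressors (unit norm, excluding the constant).
    """
    k = int(np.floor(2.0 * n_volumes * tr / cutoff_s))
    n = np.arange(n_volumes)
    basis = np.empty((n_volumes, k))
    for j in range(1, k + 1):
        basis[:, j - 1] = np.sqrt(2.0 / n_volumes) * np.cos(
            np.pi * (2 * n + 1) * j / (2.0 * n_volumes)
        )
    return basis


@dataclass
class DesignMatrix:
    """Volumes x regressors design with named columns.

    ``condition_idx`` indexes the condition-of-interest columns;
    everything else (motion, cosine drift, intercept) is nuisance.
    """

    matrix: np.ndarray
    names: list[str]
    tr: float
    condition_idx: np.ndarray
    dof: int

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def condition_names(self) -> list[str]:
        return [self.names[i] for i in self.condition_idx]


def build_design_matrix(
    schedule: StimulusSchedule,
    motion: np.ndarray | None = None,
    hpf_cutoff: float = 128.0,
    n_dummy_volumes: int = 0,
) -> DesignMatrix:
    """Assemble the first-level design matrix for one run.

    If ``n_dummy_volumes`` > 0, the timeline is shifted so the matrix
    covers only the analyzed volumes (onsets move earlier by the dummy
    duration); ``motion`` must then match the reduced volume count.
    Motion columns are mean-centered; all-zero motion columns (an exactly
    still trace) are dropped. Raises on rank deficiency.
    """
    if n_dummy_volumes:
        schedule = schedule.shifted(n_dummy_volumes * schedule.tr)
    Xc, cond_names = condition_regressors(schedule)
    cols = [Xc]
    names = list(cond_names)
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != schedule.n_volumes:
            raise GlmError(
                f"motion has {motion.shape[0]} rows, expected "
                f"{schedule.n_volumes} analyzed volumes"
            )
        centered = motion - motion.mean(axis=0)
        keep = np.ptp(centered, axis=0) > 0
        if keep.any():
            cols.append(centered[:, keep])
            names += [f"motion_{i}" for i in np.flatnonzero(keep)]
    hp = dct_highpass_basis(schedule.n_volumes, schedule.tr, hpf_cutoff)
    if hp.shape[1]:
        cols.append(hp)
        names += [f"cosine_{j}" for j in range(hp.shape[1])]
    cols.append(np.ones((schedule.n_volumes, 1)))
    names.append("intercept")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the diagnostic
        bad = []
        seen = np.empty((X.shape[0], 0))
        for j in range(X.shape[1]):
            trial = np.column_stack([seen, X[:, j]])
            if np.linalg.matrix_rank(trial) == seen.shape[1]:
                bad.append(names[j])
            else:
                seen = trial
        raise GlmError(f"design matrix is rank deficient; dependent columns: {bad}")
    return DesignMatrix(
        matrix=X,
        names=names,
        tr=schedule.tr,
        condition_idx=np.arange(len(cond_names)),
        dof=X.shape[0] - X.shape[1],
    )


def global_scale(Y: np.ndarray, target: float = 100.0) -> np.ndarray:
    """Proportionally rescale a run so its grand mean equals ``target``."""
    Y = np.asarray(Y, dtype=float)
    g = Y.mean()
    if g <= 0:
        raise GlmError(f"global mean must be positive, got {g}")
    return Y * (target / g)


@dataclass
class BetaEstimates:
    """Per-run GLM estimates.

    ``betas``: condition x voxel amplitudes; ``nuisance_betas`` the
    remaining regressors; ``resid_var`` the unbiased residual variance
    per voxel; ``cond_cov_unit`` the (X'X)^-1 block of the condition
    columns, so Var(c'beta) = c' cond_cov_unit c * resid_var.
    """

    condition_names: list[str]
    betas: np.ndarray
    nuisance_betas: np.ndarray
    resid_var: np.ndarray
    dof: int
    cond_cov_unit: np.ndarray
    ar1_coeff: float = 0.0


def _pooled_ar1(resid: np.ndarray) -> float:
    """Lag-1 autocorrelation of residuals pooled (summed) over voxels."""
    r0 = resid[:-1]
    r1 = resid[1:]
    num = np.sum(r0 * r1)
    den = np.sum(resid * resid)
    return float(num / den) if den > 0 else 0.0


def fit_glm(
    Y: np.ndarray, X: DesignMatrix, whitening: str = "ar1_global"
) -> BetaEstimates:
    """Fit the GLM by (optionally AR(1)-whitened) least squares.

    ``whitening='ar1_global'`` runs a first OLS pass, estimates a single
    AR(1) coefficient from the lag-1 autocorrelation of the residuals
    pooled over all voxels, applies the corresponding first-difference
    whitening filter to data and design, and refits.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.n_volumes:
        raise GlmError(f"Y has {Y.shape[0]} volumes, design has {X.n_volumes}")
    if not np.all(np.isfinite(Y)):
        raise GlmError("non-finite values in data")
    if whitening not in ("none", "ar1_global"):
        raise GlmError(f"unknown whitening {whitening!r}")

    M = X.matrix
    rho = 0.0
    if whitening == "ar1_global":
        beta0, *_ = np.linalg.lstsq(M, Y, rcond=None)
        rho = _pooled_ar1(Y - M @ beta0)
        # correct the projection-induced bias: OLS residuals of white
        # noise have expected lag-1 autocovariance -tr(A H) where A is
        # the symmetrized lag-1 shift, so add tr(A H) / (n - p) back
        H = M @ np.linalg.solve(M.T @ M, M.T)
        n, p = M.shape
        rho += np.trace(H[1:, :-1]) / (n - p)
        rho = float(np.clip(rho, -0.99, 0.99))
        Mw = np.empty_like(M)
        Yw = np.empty_like(Y)
        s = np.sqrt(1.0 - rho**2)
        Mw[0], Yw[0] = s * M[0], s * Y[0]
        Mw[1:] = M[1:] - rho * M[:-1]
        Yw[1:] = Y[1:] - rho * Y[:-1]
        M, Y = Mw, Yw

    beta, *_ = np.linalg.lstsq(M, Y, rcond=None)
    resid = Y - M @ beta
    dof = M.shape[0] - M.shape[1]
    resid_var = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(M.T @ M)
    ci = X.condition_idx
    nuis = np.delete(np.arange(M.shape[1]), ci)
    return BetaEstimates(
        condition_names=X.condition_names,
        betas=beta[ci],
        nuisance_betas=beta[nuis],
        resid_var=resid_var,
        dof=dof,
        cond_cov_unit=xtx_inv[np.ix_(ci, ci)],
        ar1_coeff=rho,
    )


@dataclass
class ContrastMap:
    """Per-voxel effect and t statistic for one linear contrast."""

    effect: np.ndarray
    t: np.ndarray
    dof: int
    undefined: np.ndarray  # voxels where the variance is zero


def compute_contrast(
    betas: BetaEstimates | Sequence[BetaEstimates], contrast: np.ndarray
) -> ContrastMap:
    """Linear contrast of condition amplitudes, fixed-effects over runs.

    For a sequence of per-run estimates, the effect is the run mean of
    c'beta and the variance the run-mean variance (runs independent);
    degrees of freedom pool additively.
    """
    runs = [betas] if isinstance(betas, BetaEstimates) else list(betas)
    c = np.asarray(contrast, dtype=float)
    if c.shape[0] != runs[0].betas.shape[0]:
        raise GlmError("contrast length does not match condition count")
    effects = np.stack([c @ b.betas for b in runs])
    variances = np.stack([(c @ b.cond_cov_unit @ c) * b.resid_var for b in runs])
    n = len(runs)
    effect = effects.mean(axis=0)
    var = variances.sum(axis=0) / n**2
    undefined = var <= 0
    t = np.full_like(effect, np.nan)
    np.divide(effect, np.sqrt(var, where=~undefined, out=np.ones_like(var)), out=t, where=~undefined)
    return ContrastMap(
        effect=effect, t=t, dof=sum(b.dof for b in runs), undefined=undefined
    )


@dataclass
class RoiDefinition:
    """A set of voxels, either abstract flat indices or a lattice sphere."""

    indices: np.ndarray
    grid_spacing_mm: float = 2.0
    coords: np.ndarray | None = None  # N x 3 integer grid coordinates
    sphere_center_mm: tuple[float, float, float] | None = None
    sphere_radius_mm: float | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise GlmError("ROI is empty")
        if len(np.unique(self.indices)) != self.indices.size:
            raise GlmError("ROI indices must be unique")

    @property
    def n_voxels(self) -> int:
        return int(self.indices.size)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.grid_spacing_mm**3)

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3


def make_sphere_roi(
    center_mm: Sequence[float],
    radius_mm: float = 8.0,
    grid_spacing_mm: float = 2.0,
) -> RoiDefinition:
    """All lattice voxels whose centers lie within ``radius_mm`` of center.

    The boundary is inclusive. An 8-mm sphere on a 2-mm grid centered on
    a grid point holds 257 voxels (2056 mm^3).
    """
    if radius_mm <= 0:
        raise GlmError("radius must be positive")
    center = np.asarray(center_mm, dtype=float)
    lo = np.floor((center - radius_mm) / grid_spacing_mm).astype(int)
    hi = np.ceil((center + radius_mm) / grid_spacing_mm).astype(int)
    axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d2 = ((grid * grid_spacing_mm - center) ** 2).sum(axis=1)
    coords = grid[d2 <= radius_mm**2 + 1e-9]
    if coords.shape[0] == 0:
        raise GlmError("sphere contains no voxel centers")
    return RoiDefinition(
        indices=np.arange(coords.shape[0]),
        grid_spacing_mm=grid_spacing_mm,
        coords=coords,
        sphere_center_mm=tuple(center),
        sphere_radius_mm=radius_mm,
    )


@dataclass
class ActivationResult:
    activated: bool
    n_suprathreshold_voxels: int
    volume_mm3: float
    threshold: float
    peak_t: float
    peak_index: int


def detect_activation(
    tmap: ContrastMap,
    roi: RoiDefinition | None = None,
    p_uncorrected: float = 0.01,
) -> ActivationResult:
    """One-sided suprathreshold detection within an ROI.

    The threshold is the upper-tail t quantile at ``p_uncorrected`` with
    the contrast's pooled dof; any ROI voxel above it counts the region
    as activated, and activation size is suprathreshold voxels times
    voxel volume.
    """
    t = tmap.t
    if roi is None:
        idx = np.arange(t.size)
        vox_vol = 8.0
    else:
        idx = roi.indices
        vox_vol = roi.voxel_volume_mm3
        if idx.max() >= t.size:
            raise GlmError("ROI extends beyond the t map")
    thr = float(stats.t.ppf(1.0 - p_uncorrected, tmap.dof))
    tv = np.where(np.isfinite(t[idx]), t[idx], -np.inf)
    supra = tv > thr
    n = int(supra.sum())
    peak = int(np.argmax(tv))
    return ActivationResult(
        activated=n >= 1,
        n_suprathreshold_voxels=n,
        volume_mm3=n * vox_vol,
        threshold=thr,
        peak_t=float(tv[peak]),
        peak_index=int(idx[peak]),
    )


def extract_roi_betas(betas: BetaEstimates, roi: RoiDefinition) -> np.ndarray:
    """Condition x ROI-voxel subset of the amplitude matrix (a copy)."""
    if roi.indices.max() >= betas.betas.shape[1]:
        raise GlmError("ROI extends beyond the beta array")
    return betas.betas[:, roi.indices].copy()
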