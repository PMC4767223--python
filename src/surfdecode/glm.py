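"""Per-voxel GLM, contrast t-maps, and voxel selection.

Runs are concatenated in time; the design matrix holds one HRF-convolved
boxcar regressor per condition (shared across runs) and one intercept
column per run to absorb run-wise baselines. Ordinary least squares is
fit voxel-wise, and contrast t statistics follow

    t = c'beta / sqrt(sigma2 * c' (X'X)^-1 c),   dof = N - rank(X).

Two selection modes mirror the two ROI flavours: ``top_positive`` keeps
the up-to-n voxels with t > 0 ranked by t (visual ROIs, all-conditions
vs fixation contrast); ``significant`` keeps voxels passing a two-sided
p < alpha on the contrast (somatosensory ROIs, air-on vs air-off), then
the top n by t. Ties are broken by voxel index for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hrf import hrf_kernel
from .synth import AIR_OFF, AIR_ON, FIXATION, BlockSchedule, RunData

DEFAULT_N_VOXELS = 250


@dataclass
class GLMResult:
    """Voxel-wise OLS fit over concatenated runs."""

    betas: np.ndarray            # voxels x regressors
    residual_variance: np.ndarray  # per voxel, dof-corrected
    dof: int
    xtx_inv: np.ndarray
    columns: list[str]

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(len(self.columns))
        for name, w in weights.items():
            if name not in self.columns:
                raise KeyError(f"no regressor named {name!r}; have {self.columns}")
            c[self.columns.index(name)] = w
        return c

    def t_map(self, contrast: dict[str, float] | np.ndarray) -> np.ndarray:
        """Per-voxel t statistic for a contrast (dict of column weights
        or a raw weight vector)."""
        c = (
            self.contrast_vector(contrast)
            if isinstance(contrast, dict)
            else np.asarray(contrast, dtype=float)
        )
        if c.shape != (len(self.columns),):
            raise ValueError("contrast length does not match the design")
        num = self.betas @ c
        denom = np.sqrt(self.residual_variance * (c @ self.xtx_inv @ c))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, num / denom, np.sign(num) * np.inf)
        return t


@dataclass
class ROISelection:
    roi_name: str
    voxel_indices: np.ndarray  # ordered by descending t
    t_values: np.ndarray

    @property
    def n_selected(self) -> int:
        return len(self.voxel_indices)


def _condition_labels(schedules: list[BlockSchedule]) -> list[str]:
    labels: set[str] = set()
    for s in schedules:
        labels |= {b.label for b in s.blocks}
    return sorted(labels - {FIXATION, AIR_OFF})


def build_design_matrix(
    schedules: list[BlockSchedule],
    tr: float = 2.0,
    hrf: str = "double_gamma",
) -> tuple[np.ndarray, list[str]]:
    """HRF-convolved condition regressors + per-run intercepts, runs
    stacked in time. Returns (X, column names)."""
    conds = _condition_labels(schedules)
    kernel = hrf_kernel(tr, hrf)
    blocks_x = []
    for s in schedules:
        T = s.n_volumes
        xr = np.zeros((T, len(conds) + len(schedules)))
        for j, cond in enumerate(conds):
            box = np.zeros(T)
            for b in s.blocks_with_label(cond):
                box[b.onset_volume : b.onset_volume + b.n_volumes] = 1.0
            xr[:, j] = np.convolve(box, kernel)[:T]
        blocks_x.append(xr)
    X = np.vstack(blocks_x)
    # per-run intercepts
    offset = 0
    for i, s in enumerate(schedules):
        X[offset : offset + s.n_volumes, len(conds) + i] = 1.0
        offset += s.n_volumes
    names = conds + [f"run{i}_intercept" for i in range(len(schedules))]
    return X, names


def ols_fit(X: np.ndarray, Y: np.ndarray, columns: list[str] | None = None) -> GLMResult:
    """Voxel-wise OLS of Y (volumes x voxels) on X (volumes x regressors)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the offending columns via the QR pivot
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [i for i, d in enumerate(diag) if d < 1e-10 * max(diag.max(), 1.0)]
        names = columns or [f"col{i}" for i in range(p)]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"collinear columns: {[names[i] for i in bad]}"
        )
    xtx_inv = np.linalg.inv(X.T @ X)
    betas = (xtx_inv @ X.T @ Y).T  # voxels x regressors
    resid = Y - X @ betas.T
    dof = n - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    return GLMResult(
        betas=betas,
        residual_variance=sigma2,
        dof=dof,
        xtx_inv=xtx_inv,
        columns=columns or [f"col{i}" for i in range(p)],
    )


def fit_glm(
    runs: list[RunData],
    tr: float = 2.0,
    hrf: str = "double_gamma",
) -> GLMResult:
    """Concatenate runs and fit the voxel-wise GLM."""
    if not runs:
        raise ValueError("no runs to fit")
    nv = runs[0].n_voxels
    if any(r.n_voxels != nv for r in runs):
        raise ValueError("runs do not share a voxel grid")
    X, names = build_design_matrix([r.schedule for r in runs], tr=tr, hrf=hrf)
    Y = np.hstack([r.signal for r in runs]).T  # volumes x voxels
    return ols_fit(X, Y, columns=names)


def task_vs_baseline_contrast(glm: GLMResult) -> dict[str, float]:
    """Equal-weight average of all condition regressors vs the implicit
    fixation baseline."""
    conds = [c for c in glm.columns if not c.endswith("_intercept")]
    return {c: 1.0 / len(conds) for c in conds}


def air_contrast(glm: GLMResult) -> dict[str, float]:
    """Air-on vs (implicit) air-off localiser contrast."""
    if AIR_ON not in glm.columns:
        raise KeyError("GLM has no air-on regressor; not a localiser fit")
    return {AIR_ON: 1.0}


def select_voxels(
    glm: GLMResult,
    contrast: dict[str, float] | np.ndarray,
    mode: str = "top_positive",
    n: int = DEFAULT_N_VOXELS,
    alpha: float = 0.05,
    roi_name: str = "roi",
) -> ROISelection:
    """Select voxels for decoding from a contrast t-map.

    ``top_positive``: up to ``n`` voxels with t > 0, ranked by t.
    ``significant``: voxels with two-sided p < ``alpha``, then top-n by t.
    Returns an empty selection (with a warning) if no voxel qualifies.
    """
    t = glm.t_map(contrast)
    if mode == "top_positive":
        ok = np.flatnonzero(t > 0)
    elif mode == "significant":
        p = 2.0 * stats.t.sf(np.abs(t), glm.dof)
        ok = np.flatnonzero(p < alpha)
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    if len(ok) == 0:
        warnings.warn(
            f"no voxels satisfy the {mode!r} criterion; empty selection",
            stacklevel=2,
        )
        return ROISelection(roi_name, np.array([], dtype=int), np.array([]))
    # sort by descending t, ties broken by ascending voxel index
    order = np.lexsort((ok, -t[ok]))
    chosen = ok[order][:n]
    return ROISelection(roi_name, chosen, t[chosen])
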