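"""Quantitative susceptibility mapping from multi-echo complex data.

Three stages, mirroring the usual QSM pipeline:

1. ``fit_complex_field`` — per-voxel nonlinear least squares of the complex
   mono-exponential signal model ``S(TE) = A exp((i 2 pi f - R2*) TE + i phi0)``,
   giving the total field map (plus M0, R2* and phi0 as by-products).
2. ``remove_background_lbv`` — Laplacian boundary value background removal:
   fields from sources outside the brain are harmonic inside it, so the
   background is the solution of Laplace's equation on the (eroded) mask
   interior with Dirichlet boundary values taken from the total field.
3. ``invert_dipole_medi`` — morphology-enabled dipole inversion: the local
   field is inverted for susceptibility by minimizing
   ``|| M_G . grad(chi) ||_1 + lambda || W (D * chi - f) ||_2^2``
   where M_G keeps gradients away from magnitude edges and W is the
   normalized magnitude weight, solved by IRLS with conjugate-gradient inner
   iterations.

No susceptibility referencing is applied by default (no reference region),
so maps carry an arbitrary but consistent offset fixed by the D(0)=0
convention of the dipole kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, sparse
from scipy.fft import irfftn, rfftn
from scipy.sparse.linalg import cg as sparse_cg

from .phantom import GAMMA_BAR_HZ_PER_T, EchoSeries, dipole_kernel

__all__ = [
    "FieldMap",
    "FieldFitResult",
    "SusceptibilityMap",
    "StageError",
    "fit_complex_field",
    "remove_background_lbv",
    "invert_dipole_medi",
    "reconstruct_qsm",
]


@dataclass
class FieldMap:
    """Scalar field-shift map in ppm of B0, with validity mask and provenance."""

    values: np.ndarray  # ppm
    mask: np.ndarray
    kind: str = "total"  # total | background | local
    b0_tesla: float = 3.0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_dir: np.ndarray = dc_field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    @property
    def values_hz(self) -> np.ndarray:
        return self.values * GAMMA_BAR_HZ_PER_T * self.b0_tesla * 1e-6


@dataclass
class FieldFitResult:
    """Joint complex-model fit: total field plus M0, R2*, phi0 and residuals."""

    field: FieldMap
    m0: np.ndarray
    r2s: np.ndarray  # Hz, clamped to [0, 1000]
    phi0: np.ndarray  # radians
    residual: np.ndarray  # normalized per-voxel residual, >= 0
    converged: np.ndarray  # bool per voxel
    r2s_clamped: np.ndarray | None = None  # voxels where clamping fired


@dataclass
class SusceptibilityMap:
    """Susceptibility map (ppm) with the inversion's parameter/convergence record."""

    values: np.ndarray
    mask: np.ndarray
    params: dict = dc_field(default_factory=dict)
    convergence: dict = dc_field(default_factory=dict)


class StageError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Stage 1: complex-field fitting
# ---------------------------------------------------------------------------

R2S_CLAMP_HZ = (0.0, 1000.0)


def _gauss_newton_complex(sv, te, a0, r0, f0, p0, max_iter=25):
    """Vectorized damped Gauss-Newton on (ln A, R2*, f, phi0) per voxel.

    ``sv`` is (N, E) complex data, parameters are (N,) arrays.  Returns the
    refined parameters and the residual norm per voxel.
    """
    n = sv.shape[0]
    p = np.stack([a0, r0, f0, p0], axis=1)  # (N, 4)

    def model(p):
        ex = p[:, 0:1] - p[:, 1:2] * te[None, :]
        ph = 2 * np.pi * p[:, 2:3] * te[None, :] + p[:, 3:4]
        return np.exp(ex) * np.exp(1j * ph)

    def rnorm(p, data=None):
        return np.linalg.norm(model(p) - (sv if data is None else data), axis=1)

    res = rnorm(p)
    for _ in range(max_iter):
        s = model(p)
        r = s - sv  # (N, E) complex residual
        # complex Jacobian columns wrt (lnA, R2*, f, phi0)
        j = np.stack(
            [s, -te[None, :] * s, 1j * 2 * np.pi * te[None, :] * s, 1j * s], axis=2
        )  # (N, E, 4)
        jhj = np.real(np.einsum("nek,nel->nkl", np.conj(j), j))
        jhr = np.real(np.einsum("nek,ne->nk", np.conj(j), r))
        jhj += 1e-12 * np.eye(4)[None, :, :]
        try:
            step = np.linalg.solve(jhj, jhr[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - singular fallback
            step = np.einsum("nkl,nl->nk", np.linalg.pinv(jhj), jhr)
        # backtracking: halve the step where the residual would grow
        scale = np.ones(n)
        new = p - step
        new_res = rnorm(new)
        for _ in range(6):
            worse = new_res > res + 1e-15
            if not worse.any():
                break
            scale[worse] *= 0.5
            new[worse] = p[worse] - scale[worse, None] * step[worse]
            new_res[worse] = rnorm(new[worse], sv[worse])
        improved = new_res <= res
        p[improved] = new[improved]
        res[improved] = new_res[improved]
        if np.max(np.abs(step)) < 1e-12:
            break
    return p, res


def fit_complex_field(
    echoes: EchoSeries,
    mask: np.ndarray | None = None,
    max_iter: int = 25,
    n_aliases: int = 1,
) -> FieldFitResult:
    """Fit ``S(TE) = A exp((i 2 pi f - R2*) TE + i phi0)`` voxelwise.

    Initialization uses magnitude log-linear regression for (A, R2*) and the
    amplitude-weighted mean of echo-to-echo phase differences for f (temporal
    unwrapping).  Because the phase-difference estimate of f is periodic with
    period 1/dTE, the fit is repeated from ``2*n_aliases + 1`` aliased
    frequency starts and the lowest-residual solution kept per voxel.

    Requires >= 3 echoes (4-parameter model); all-zero voxels are masked out
    rather than raising.
    """
    if echoes.n_echoes < 3:
        raise ValueError(
            "fit_complex_field needs >= 3 echoes for the 4-parameter model; "
            "use a 2-echo phase-difference estimator for dual-echo data"
        )
    te = echoes.echo_times
    sig = echoes.signal
    grid = sig.shape[:-1]
    mag = np.abs(sig)
    nonzero = mag.max(axis=-1) > 0
    m = nonzero if mask is None else (np.asarray(mask, bool) & nonzero)
    if not m.any():
        raise ValueError("mask is empty (or all voxel signals are zero)")

    sv = sig[m]  # (N, E)
    mv = mag[m]
    w = mv**2

    # log-linear init for (ln A, R2*) on positive magnitudes
    with np.errstate(divide="ignore"):
        y = np.log(np.maximum(mv, 1e-300))
    sw = w.sum(axis=1)
    tbar = (w * te[None, :]).sum(axis=1) / sw
    ybar = (w * y).sum(axis=1) / sw
    stt = (w * (te[None, :] - tbar[:, None]) ** 2).sum(axis=1)
    slope = (w * (te[None, :] - tbar[:, None]) * (y - ybar[:, None])).sum(axis=1) / np.maximum(
        stt, 1e-300
    )
    r0 = -slope
    a0 = ybar - slope * tbar

    # phase-difference init for f (wraps within +-pi per echo pair)
    prod = sv[:, 1:] * np.conj(sv[:, :-1])
    dphi = np.angle(prod)
    wp = np.abs(prod)
    dte = np.diff(te)
    f0 = (wp * dphi).sum(axis=1) / np.maximum((wp * dte[None, :]).sum(axis=1), 1e-300) / (
        2 * np.pi
    )
    p0 = np.angle(sv[:, 0] * np.exp(-1j * 2 * np.pi * f0 * te[0]))

    # Fit from the base (phase-difference band) start; voxels whose residual
    # stays high are refit from aliased starts f0 + k/dTE.  With exactly
    # uniform echo spacing the aliases are an exact model symmetry (phi0
    # absorbs the constant phase offset), so ties are broken toward the base
    # band; non-uniform spacing breaks the symmetry and the alias search then
    # genuinely recovers wrapped frequencies.
    alias_step = 1.0 / float(np.mean(dte))
    best_p, best_res = _gauss_newton_complex(sv, te, a0.copy(), r0.copy(), f0, p0, max_iter)
    norm = np.linalg.norm(sv, axis=1)
    if n_aliases > 0:
        rel = best_res / np.maximum(norm, 1e-300)
        retry = np.flatnonzero(rel > min(0.1, max(1e-6, 3.0 * float(np.median(rel)))))
        if retry.size:
            for k in range(-n_aliases, n_aliases + 1):
                if k == 0:
                    continue
                fk = f0[retry] + k * alias_step
                pk = np.angle(sv[retry, 0] * np.exp(-1j * 2 * np.pi * fk * te[0]))
                p, res = _gauss_newton_complex(
                    sv[retry], te, a0[retry].copy(), r0[retry].copy(), fk, pk, max_iter
                )
                better = res < best_res[retry] * (1.0 - 1e-9)
                idx_b = retry[better]
                best_p[idx_b] = p[better]
                best_res[idx_b] = res[better]

    rel_res = best_res / np.maximum(norm, 1e-300)

    f_hz = np.zeros(grid)
    m0 = np.zeros(grid)
    r2s = np.zeros(grid)
    phi0 = np.zeros(grid)
    residual = np.zeros(grid)
    f_hz[m] = best_p[:, 2]
    m0[m] = np.exp(best_p[:, 0])
    r2s_raw = best_p[:, 1]
    clamped_v = (r2s_raw < R2S_CLAMP_HZ[0]) | (r2s_raw > R2S_CLAMP_HZ[1])
    r2s[m] = np.clip(r2s_raw, *R2S_CLAMP_HZ)
    phi0[m] = np.angle(np.exp(1j * best_p[:, 3]))
    residual[m] = rel_res
    converged = np.zeros(grid, dtype=bool)
    converged[m] = rel_res < 0.2
    clamped = np.zeros(grid, dtype=bool)
    clamped[m] = clamped_v

    ppm = f_hz / (GAMMA_BAR_HZ_PER_T * echoes.b0_tesla * 1e-6)
    fmap = FieldMap(ppm, m, "total", echoes.b0_tesla, echoes.voxel_size, echoes.b0_dir)
    return FieldFitResult(fmap, m0, r2s, phi0, residual, converged, clamped)


# ---------------------------------------------------------------------------
# Stage 2: Laplacian boundary value background removal
# ---------------------------------------------------------------------------


def remove_background_lbv(
    total: FieldMap,
    mask: np.ndarray | None = None,
    erode_voxels: int = 1,
    tol: float = 1e-6,
    maxiter: int = 10_000,
) -> FieldMap:
    """Remove the harmonic background field by solving Laplace's equation.

    The mask is reduced to its largest connected component (smaller ones are
    dropped with a warning) and eroded by ``erode_voxels``.  A 7-point
    Laplacian Dirichlet problem is solved by conjugate gradients on the
    eroded interior, with boundary values taken from the total field; the
    returned local field is ``total - background`` on the solved region.
    """
    m = np.asarray(total.mask if mask is None else mask, dtype=bool)
    lab, ncomp = ndimage.label(m)
    if ncomp > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, ncomp + 1))
        keep = int(np.argmax(sizes)) + 1
        warnings.warn(
            f"mask has {ncomp} connected components; keeping the largest", stacklevel=2
        )
        m = lab == keep
    interior = ndimage.binary_erosion(m, iterations=erode_voxels)
    if not interior.any():
        raise ValueError("mask interior is empty after erosion")

    f = np.asarray(total.values, dtype=np.float64)
    h2 = [1.0 / (h * h) for h in total.voxel_size]
    idx = -np.ones(m.shape, dtype=np.int64)
    pts = np.flatnonzero(interior.ravel())
    idx.ravel()[pts] = np.arange(pts.size)
    n = pts.size

    diag = np.full(n, 2.0 * sum(h2))
    rows, cols, vals = [], [], []
    b = np.zeros(n)
    ii = np.arange(n)
    coords = np.array(np.unravel_index(pts, m.shape)).T
    for axis in range(3):
        for step in (-1, 1):
            nb = coords.copy()
            nb[:, axis] += step
            nb[:, axis] = np.clip(nb[:, axis], 0, m.shape[axis] - 1)
            flat_nb = np.ravel_multi_index(tuple(nb.T), m.shape)
            j = idx.ravel()[flat_nb]
            inner = j >= 0
            rows.append(ii[inner])
            cols.append(j[inner])
            vals.append(np.full(inner.sum(), -h2[axis]))
            # neighbours on the boundary layer contribute Dirichlet data
            bd = ~inner
            b[ii[bd]] += h2[axis] * f.ravel()[flat_nb[bd]]
    a_mat = sparse.csr_matrix(
        (
            np.concatenate([diag] + vals),
            (np.concatenate([ii] + rows), np.concatenate([ii] + cols)),
        ),
        shape=(n, n),
    )
    x, info = sparse_cg(a_mat, b, rtol=tol, maxiter=maxiter)
    if info != 0:
        resid = float(np.linalg.norm(a_mat @ x - b))
        raise RuntimeError(
            f"LBV conjugate-gradient solver did not converge (info={info}, "
            f"final residual norm {resid:.3e})"
        )
    background = f.copy()
    background.ravel()[pts] = x
    local = np.where(interior, f - background, 0.0)
    return FieldMap(local, interior, "local", total.b0_tesla, total.voxel_size, total.b0_dir)


# ---------------------------------------------------------------------------
# Stage 3: morphology-enabled dipole inversion (IRLS + CG)
# ---------------------------------------------------------------------------


def _grad(x, h):
    out = []
    for a in range(3):
        g = np.diff(x, axis=a, append=np.take(x, [-1], axis=a)) / h[a]
        out.append(g)
    return out


def _last_slice(x, axis):
    sl = [slice(None)] * x.ndim
    sl[axis] = -1
    return tuple(sl)


def _div_adjoint(gs, h):
    """Adjoint of the forward-difference gradient with replicate-end padding."""
    out = np.zeros_like(gs[0])
    for a, g in enumerate(gs):
        gg = g.copy()
        gg[_last_slice(gg, a)] = 0.0  # last forward diff is identically zero
        shifted = np.roll(gg, 1, axis=a)
        first = [slice(None)] * 3
        first[a] = 0
        shifted[tuple(first)] = 0.0
        out += (shifted - gg) / h[a]
    return out


class _DipoleOp:
    """Padded FFT forward dipole operator and its (self-) adjoint."""

    def __init__(self, shape, voxel_size, b0_dir, pad_factor=2):
        self.shape = tuple(shape)
        self.padded = tuple(int(n * pad_factor) for n in shape)
        self.kernel = dipole_kernel(self.padded, tuple(voxel_size), np.asarray(b0_dir, float))
        self._crop = tuple(slice(0, n) for n in self.shape)

    def __call__(self, x):
        buf = np.zeros(self.padded)
        buf[self._crop] = x
        return irfftn(self.kernel * rfftn(buf), s=self.padded)[self._crop]

    adjoint = __call__  # real symmetric kernel, pad/crop are mutual adjoints


def invert_dipole_medi(
    local: FieldMap,
    magnitude: np.ndarray,
    mask: np.ndarray | None = None,
    lambda_reg: float = 1000.0,
    edge_fraction: float = 0.3,
    eps: float = 1e-6,
    max_outer: int = 50,
    outer_tol: float = 1e-3,
    cg_maxiter: int = 40,
    cg_tol: float = 1e-2,
    diverge_patience: int = 5,
) -> SusceptibilityMap:
    """Morphology-enabled dipole inversion of a local field map (ppm -> ppm).

    Minimizes ``sum_a || M_a . grad_a(chi) ||_1 + lambda || W (D chi - f) ||^2``
    with the L1 term smoothed as ``sqrt(|g|^2 + eps)``, by iteratively
    reweighted least squares; each outer iteration solves the reweighted
    normal equations with conjugate gradients (FFT-based dipole operator).
    ``M_a`` keeps the ``1 - edge_fraction`` smallest magnitude-gradient voxels
    per axis, so chi edges are only allowed where the magnitude has edges.
    """
    if lambda_reg <= 0:
        raise ValueError("lambda_reg must be > 0")
    m = np.asarray(local.mask if mask is None else mask, bool)
    if magnitude.shape != local.values.shape:
        raise ValueError("magnitude and field grids differ")
    f = np.where(m, local.values, 0.0)
    h = local.voxel_size

    w = np.where(m, magnitude, 0.0)
    mean_w = w[m].mean() if m.any() else 1.0
    w = w / max(mean_w, 1e-300)
    w2 = w * w

    grads_mag = _grad(np.where(m, magnitude, 0.0), h)
    edge_masks = []
    for g in grads_mag:
        ga = np.abs(g)[m]
        thr = np.percentile(ga, (1.0 - edge_fraction) * 100.0) if ga.size else 0.0
        edge_masks.append((np.abs(g) <= thr) & m)

    dop = _DipoleOp(f.shape, h, local.b0_dir)
    dtw2f = 2.0 * lambda_reg * dop.adjoint(w2 * f)

    chi = np.zeros_like(f)

    def objective(x):
        gs = _grad(x, h)
        l1 = sum(np.sqrt(g[em] ** 2 + eps).sum() for g, em in zip(gs, edge_masks))
        resid = w * (dop(x) - f)
        return l1 + lambda_reg * float((resid**2).sum())

    obj_trace = [objective(chi)]
    cg_iters = []
    n_worse = 0
    for outer in range(max_outer):
        gs = _grad(chi, h)
        weights = [
            em / np.sqrt(g**2 + eps) for g, em in zip(gs, edge_masks)
        ]

        def apply_a(x):
            out = 2.0 * lambda_reg * dop.adjoint(w2 * dop(x))
            gx = _grad(x, h)
            out += _div_adjoint([wt * g for wt, g in zip(weights, gx)], h)
            return out

        # CG on the SPD normal operator
        x = chi.copy()
        r = dtw2f - apply_a(x)
        p = r.copy()
        rs = float((r * r).sum())
        b_norm = float(np.sqrt((dtw2f**2).sum())) or 1.0
        it = 0
        while it < cg_maxiter and np.sqrt(rs) / b_norm > cg_tol:
            ap = apply_a(p)
            alpha = rs / max(float((p * ap).sum()), 1e-300)
            x += alpha * p
            r -= alpha * ap
            rs_new = float((r * r).sum())
            p = r + (rs_new / max(rs, 1e-300)) * p
            rs = rs_new
            it += 1
        cg_iters.append(it)
        chi = x
        obj = objective(chi)
        obj_trace.append(obj)
        rel = abs(obj_trace[-2] - obj) / max(abs(obj_trace[-2]), 1e-300)
        if obj > obj_trace[-2] * 1.01:
            n_worse += 1
            if n_worse >= diverge_patience:
                raise RuntimeError(
                    f"MEDI objective diverging for {n_worse} consecutive outer "
                    f"iterations; trace={obj_trace}"
                )
        else:
            n_worse = 0
        if rel < outer_tol:
            break

    chi = np.where(m, chi, 0.0)
    return SusceptibilityMap(
        chi,
        m,
        params={
            "lambda_reg": lambda_reg,
            "edge_fraction": edge_fraction,
            "eps": eps,
            "outer_tol": outer_tol,
        },
        convergence={
            "objective": obj_trace,
            "outer_iterations": len(obj_trace) - 1,
            "cg_iterations": cg_iters,
        },
    )


def tv_seminorm(chi_map: SusceptibilityMap, magnitude: np.ndarray, edge_fraction: float = 0.3):
    """Edge-masked L1 gradient seminorm ``sum_a || M_a . grad_a chi ||_1``."""
    m = chi_map.mask
    h = (1.0, 1.0, 1.0)
    grads_mag = _grad(np.where(m, magnitude, 0.0), h)
    total = 0.0
    for a, g in enumerate(_grad(chi_map.values, h)):
        ga = np.abs(grads_mag[a])[m]
        thr = np.percentile(ga, (1.0 - edge_fraction) * 100.0) if ga.size else 0.0
        em = (np.abs(grads_mag[a]) <= thr) & m
        total += float(np.abs(g[em]).sum())
    return total


# ---------------------------------------------------------------------------
# End-to-end reconstruction
# ---------------------------------------------------------------------------


def reconstruct_qsm(
    echoes: EchoSeries,
    mask: np.ndarray,
    params: dict | None = None,
    keep_intermediates: bool = False,
):
    """Chain field fitting, LBV and MEDI into a susceptibility map.

    ``params`` may override stage keyword arguments under the keys
    ``field_fit``, ``lbv`` and ``medi``.  Stage failures re-raise as
    :class:`StageError` with the stage name attached.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    p = params or {}
    try:
        fit = fit_complex_field(echoes, mask, **p.get("field_fit", {}))
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise StageError("field_fit", str(e)) from e
    try:
        local = remove_background_lbv(fit.field, mask, **p.get("lbv", {}))
    except Exception as e:  # noqa: BLE001
        raise StageError("lbv", str(e)) from e
    try:
        chi = invert_dipole_medi(local, fit.m0, **p.get("medi", {}))
    except Exception as e:  # noqa: BLE001
        raise StageError("medi", str(e)) from e
    if keep_intermediates:
        return chi, {"field_fit": fit, "local_field": local}
    return chi
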