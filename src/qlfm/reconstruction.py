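"""Phase-space deconvolution and joint emission/scattering estimation.

The emission update is a Richardson-Lucy (RL) multiplicative scheme cycled
over angular components (centre-out spiral), which preserves
non-negativity by construction; with axial scanning, each angular focal
stack (one angle, all scan positions) is the unit over which the error map
is computed. The scattering potential is updated by projected gradient
steps on the data misfit, and the two unknowns alternate inside an ADMM
consensus splitting whose non-negativity subproblems are trivially
satisfied at every iterate (the multiplicative and projected updates never
leave the feasible set, so the scaled duals stay at zero; the penalty rho
is kept for generality). A monitored data misfit must not increase over
accepted steps: a cycle that would increase it is replaced by a joint
(all-angle) EM update, which is monotone for the Poisson likelihood.

Out-of-focus background is handled by the coarse complete-space slabs of
the multiscale grid, not by a constant background term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import ReconstructionOptions
from .errors import ContractError
from .grid import MultiscaleGrid, MultiscaleVolume, ResolutionModel, build_grid
from .phase_space import PhaseSpaceViews
from .projection import ProjectionOperator, psf_for_grid
from .psf import PhaseSpacePSF, PSFSimulator
from .scattering import ScatterOperator, ScatteringPotential, update_potential

__all__ = [
    "ReconstructionResult",
    "phase_space_deconvolve",
    "admm_reconstruct",
    "reconstruct_axial_scan",
    "spiral_order",
]


def spiral_order(nu: int, nv: int) -> list[tuple[int, int]]:
    """Angular indices ordered centre-out (radius, then azimuth)."""
    cu, cv = (nu - 1) / 2.0, (nv - 1) / 2.0
    idx = [(iu, iv) for iu in range(nu) for iv in range(nv)]
    idx.sort(key=lambda p: ((p[0] - cu) ** 2 + (p[1] - cv) ** 2, np.arctan2(p[0] - cu, p[1] - cv)))
    return idx


@dataclass
class ReconstructionResult:
    """Joint reconstruction output: emission, scattering potential, diagnostics."""

    emission: MultiscaleVolume
    potential: ScatteringPotential
    misfit_history: list[float] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0

    def __iter__(self):
        return iter((self.emission, self.potential))


def _as_array(views) -> np.ndarray:
    if isinstance(views, PhaseSpaceViews):
        return views.views
    return np.asarray(views, dtype=float)


class _AugmentedOperator:
    """Projection of I + S(F, I) through the PSF, linear in I for fixed F."""

    def __init__(self, op: ProjectionOperator, scatter: ScatterOperator | None, F: ScatteringPotential | None):
        self.op = op
        self.scatter = scatter
        self.F = F
        self._active = scatter is not None and F is not None and F.max() > 0

    def total_field(self, I: MultiscaleVolume) -> MultiscaleVolume:
        if not self._active:
            return I
        return I + self.scatter.apply_product(I * self.F)

    def forward(self, I: MultiscaleVolume) -> np.ndarray:
        return self.op.forward(self.total_field(I))

    def forward_angle(self, T: MultiscaleVolume, iu: int, iv: int) -> np.ndarray:
        # caller passes the precomputed total field
        return self.op.forward_angle(T, iu, iv)

    def _augment_adjoint(self, v: MultiscaleVolume) -> MultiscaleVolume:
        if not self._active:
            return v
        return v + self.F * self.scatter.adjoint_product(v)

    def adjoint(self, views: np.ndarray) -> MultiscaleVolume:
        return self._augment_adjoint(self.op.adjoint(views))

    def adjoint_angle(self, view: np.ndarray, iu: int, iv: int) -> MultiscaleVolume:
        return self._augment_adjoint(self.op.adjoint_angle(view, iu, iv))

    def adjoint_ones(self) -> MultiscaleVolume:
        return self._augment_adjoint(self.op.adjoint_ones())

    def adjoint_ones_angle(self, iu: int, iv: int) -> MultiscaleVolume:
        return self._augment_adjoint(self.op.adjoint_ones_angle(iu, iv))


def _poisson_misfit(aug_ops, views_list, I, eps) -> float:
    total = 0.0
    for aug, y in zip(aug_ops, views_list):
        f = aug.forward(I)
        total += float(np.sum(f - y * np.log(f + eps)))
    return total


def _safe_ratio(num: MultiscaleVolume, den: MultiscaleVolume, tiny: float) -> MultiscaleVolume:
    out = []
    for a, b in zip(num.slab_data, den.slab_data):
        r = np.ones_like(a)
        m = b > tiny
        r[m] = a[m] / b[m]
        out.append(r)
    return MultiscaleVolume(num.grid, out)


def _joint_update(aug_ops, views_list, I, eps, tiny):
    num = None
    den = None
    for aug, y in zip(aug_ops, views_list):
        f = aug.forward(I)
        n = aug.adjoint(y / (f + eps))
        d = aug.adjoint_ones()
        num = n if num is None else num + n
        den = d if den is None else den + d
    return (I * _safe_ratio(num, den, tiny)).clip_nonneg()


def _cycle_update(aug_ops, views_list, I, eps, tiny, order):
    for iu, iv in order:
        num = None
        den = None
        for aug, y in zip(aug_ops, views_list):
            T = aug.total_field(I)
            f = aug.forward_angle(T, iu, iv)
            n = aug.adjoint_angle(y[iu, iv] / (f + eps), iu, iv)
            d = aug.adjoint_ones_angle(iu, iv)
            num = n if num is None else num + n
            den = d if den is None else den + d
        I = (I * _safe_ratio(num, den, tiny)).clip_nonneg()
    return I


def _rl_cycles(aug_ops, views_list, I, eps, opts, n_cycles, history):
    nu, nv = aug_ops[0].op.n_angles
    order = spiral_order(nu, nv)
    tiny = 1e-12 * max(1.0, max(float(y.max()) for y in views_list))
    loss = _poisson_misfit(aug_ops, views_list, I, eps)
    for _ in range(n_cycles):
        if opts.angular_order == "spiral":
            cand = _cycle_update(aug_ops, views_list, I, eps, tiny, order)
            cand_loss = _poisson_misfit(aug_ops, views_list, cand, eps)
            if cand_loss > loss + 1e-9 * abs(loss):
                # ordered-subset cycle overshot: fall back to the monotone
                # joint EM update from the pre-cycle iterate
                cand = _joint_update(aug_ops, views_list, I, eps, tiny)
                cand_loss = _poisson_misfit(aug_ops, views_list, cand, eps)
        else:
            cand = _joint_update(aug_ops, views_list, I, eps, tiny)
            cand_loss = _poisson_misfit(aug_ops, views_list, cand, eps)
        if cand_loss > loss + 1e-9 * abs(loss):
            break  # numerically converged; do not accept an increase
        I, loss = cand, cand_loss
        history.append(loss)
    return I, loss


def _initial_emission(ops, views_list) -> MultiscaleVolume:
    num = None
    den = None
    for op, y in zip(ops, views_list):
        n = op.adjoint(y)
        d = op.adjoint_ones()
        num = n if num is None else num + n
        den = d if den is None else den + d
    init = _safe_ratio(num, den, 1e-12)
    scale = max(init.max(), 1e-12)
    return init.map(lambda a: np.clip(a, 1e-6 * scale, None))


def phase_space_deconvolve(
    views,
    psf: PhaseSpacePSF,
    grid: MultiscaleGrid,
    opts: ReconstructionOptions | None = None,
    cycles: int | None = None,
    history: list | None = None,
) -> MultiscaleVolume:
    """Richardson-Lucy phase-space deconvolution (no scattering term).

    Multiplicative updates cycled over angular components; the Poisson data
    loss is non-increasing over accepted full cycles and the iterate stays
    non-negative. All-zero views return a zero volume with a warning.
    """
    opts = opts or ReconstructionOptions()
    y = _as_array(views)
    if not np.any(y > 0):
        warnings.warn("all-zero views: returning a zero volume", stacklevel=2)
        return MultiscaleVolume.zeros(grid)
    op = ProjectionOperator(psf, grid)
    aug = _AugmentedOperator(op, None, None)
    eps = opts.epsilon_scale * float(y.max())
    I = _initial_emission([op], [y])
    hist = history if history is not None else []
    n_cycles = cycles if cycles is not None else opts.outer_iterations * opts.inner_rl_iterations
    I, _ = _rl_cycles([aug], [y], I, eps, opts, n_cycles, hist)
    return I


def _joint_reconstruct(
    views_list: list[np.ndarray],
    ops: list[ProjectionOperator],
    grid: MultiscaleGrid,
    opts: ReconstructionOptions,
    with_scattering: bool = True,
) -> ReconstructionResult:
    ymax = max(float(y.max()) for y in views_list)
    if ymax <= 0:
        warnings.warn("all-zero views: returning zero emission and potential", stacklevel=2)
        return ReconstructionResult(
            MultiscaleVolume.zeros(grid), ScatteringPotential(grid), [], True, 0
        )
    eps = opts.epsilon_scale * ymax
    scatter = ScatterOperator(grid) if with_scattering else None
    I = _initial_emission(ops, views_list)
    F = ScatteringPotential(grid)
    t_F = None
    misfits: list[float] = []
    rl_hist: list[float] = []
    converged = False
    n_diverge = 0
    prev_norm = None
    outer_done = 0
    for outer in range(opts.outer_iterations):
        aug_ops = [_AugmentedOperator(op, scatter, F) for op in ops]
        I, loss = _rl_cycles(aug_ops, views_list, I, eps, opts, opts.inner_rl_iterations, rl_hist)
        if with_scattering:
            # single-frame potential update against the pooled residual
            def poisson_ok(cand):
                aug_c = [_AugmentedOperator(op, scatter, cand) for op in ops]
                return _poisson_misfit(aug_c, views_list, I, eps) <= loss + 1e-9 * abs(loss)

            F_new = F
            for op, y in zip(ops, views_list):
                F_new, t_F = update_potential(
                    I, y, op, F_new,
                    lambda_f=opts.lambda_f,
                    n_steps=opts.potential_steps,
                    scatter_op=scatter,
                    step_init=t_F,
                )
            if poisson_ok(F_new):
                F = F_new
        # consensus projection (non-negativity); iterates are already
        # feasible so the scaled duals remain zero
        I = I.clip_nonneg()
        F = ScatteringPotential(F.grid, F.clip_nonneg().slab_data)
        aug_ops = [_AugmentedOperator(op, scatter, F) for op in ops]
        misfit = _poisson_misfit(aug_ops, views_list, I, eps)
        if misfits and misfit > misfits[-1] + 1e-9 * abs(misfits[-1]):
            n_diverge += 1
            if n_diverge >= 3:
                raise RuntimeError(
                    f"reconstruction diverging: misfit history {misfits + [misfit]}"
                )
        else:
            n_diverge = 0
        misfits.append(misfit)
        outer_done = outer + 1
        norm = I.norm()
        if prev_norm is not None:
            delta = (I - prev_I).norm() / max(norm, 1e-12)
            if delta < opts.convergence_tol:
                converged = True
                break
        prev_norm, prev_I = norm, I.copy()
    return ReconstructionResult(I, F, misfits, converged, outer_done)


def admm_reconstruct(
    views,
    psf: PhaseSpacePSF,
    grid: MultiscaleGrid,
    opts: ReconstructionOptions | None = None,
    with_scattering: bool = True,
) -> ReconstructionResult:
    """Joint estimation of emission fluorescence and scattering potential.

    Alternates RL emission updates (with the current scattered contribution
    inside the forward model) with projected-gradient potential updates,
    under non-negativity; reports the per-iteration data misfit.
    """
    opts = opts or ReconstructionOptions()
    y = _as_array(views)
    op = ProjectionOperator(psf, grid)
    return _joint_reconstruct([y], [op], grid, opts, with_scattering)


def reconstruct_axial_scan(
    frames,
    scan_positions,
    simulator: PSFSimulator,
    model: ResolutionModel,
    opts: ReconstructionOptions | None = None,
    z_min: float | None = None,
    z_max: float | None = None,
    grid: MultiscaleGrid | None = None,
    with_scattering: bool = True,
) -> ReconstructionResult:
    """Joint reconstruction of an axial scan on one global multiscale grid.

    Each scan position contributes an angular focal stack; the forward model
    for scan position s uses depth-shifted kernels (z -> z - s) on the same
    global grid, so the whole volume is updated jointly and no sub-volume
    stitching occurs. The scan step should be comparable to the snapshot
    high-resolution axial range (warned otherwise).
    """
    opts = opts or ReconstructionOptions()
    positions = np.asarray(scan_positions, dtype=float)
    if positions.ndim != 1 or len(positions) != len(frames):
        raise ContractError("scan_positions must match the number of frames")
    if len(positions) > 1:
        d = np.diff(positions)
        if np.any(d <= 0):
            raise ContractError("scan positions must be strictly increasing and unique")
        if np.max(d) > 2.5 * model.high_res_half_range:
            warnings.warn(
                "scan step exceeds the high-resolution axial range; coverage will be uneven",
                stacklevel=2,
            )
    cfg = simulator.config
    if grid is None:
        hr = model.high_res_half_range
        lo = z_min if z_min is not None else positions.min() - 3.0 * hr
        hi = z_max if z_max is not None else positions.max() + 3.0 * hr
        grid = build_grid(lo, hi, model, cfg, scan_positions=positions)
    views_list = [_as_array(f) for f in frames]
    ops = [
        ProjectionOperator(psf_for_grid(simulator, grid, depth_shift=s), grid)
        for s in positions
    ]
    return _joint_reconstruct(views_list, ops, grid, opts, with_scattering)
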