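"""Maximum-likelihood fitting of binding models to selection count tables.

The loss l_total = -l_data + l_reg is minimized jointly over all count
tables of an experiment with L-BFGS on the full free-parameter vector:
the non-frozen specific-mode coefficients, the non-specific coefficients
and positional bias, and the logs of the per-table depth and activity
parameters (positivity enforced by the log transform).  Gradients are
analytic; an optional multi-start scheme guards against poor local optima.

The enrichment model has an exact gauge freedom — adding a constant to a
full column of the specific matrix while rescaling alpha_S leaves every
predicted enrichment unchanged — so fitted matrices are reported after
mean-centering each free column and absorbing the shift into the
activities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .energy_model import (
    N_AA,
    BindingModel,
    EnergyMatrix,
    NonSpecificMode,
    RegularizationConfig,
    nonspecific_window_indices,
    specific_window_indices,
)
from .seqio import AA_INDEX, CountTable, LibraryDesign, encode_peptides

logger = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Configuration of a model fit.

    ``constrain_center`` freezes the central specific-matrix column to the
    anchoring residue (0 for ``center_residue``, -10 otherwise), focusing
    the specific mode on phosphotyrosine-anchored sites; disable it to let
    the fit discover the anchor position itself.  ``w_ns`` of 3 suits most
    domains; 1 prevents the non-specific mode from absorbing short motifs.
    """

    constrain_center: bool = True
    center_residue: str = "Y"
    w_ns: int = 3
    f_s: int = 5
    w_s: int = 11
    max_iter: int = 1000
    tol: float = 1e-7
    n_starts: int = 1
    seed: int = 0
    init_scale: float = 0.1
    regularization: RegularizationConfig = field(default_factory=RegularizationConfig)


@dataclass
class FitLog:
    start_losses: list[float]
    best_start: int
    n_iterations: int
    final_loss: float
    converged: bool


def apply_central_constraint(matrix: EnergyMatrix, residue: str = "Y") -> EnergyMatrix:
    """Freeze the central column to 0 for ``residue`` and -10 otherwise.

    The frozen column is excluded from optimization and regularization.
    Idempotent; requires an odd matrix width so a center exists.
    """
    if matrix.width % 2 == 0:
        raise ValueError("central constraint requires an odd matrix width")
    out = matrix.copy()
    center = matrix.width // 2
    out.coeffs[:, center] = -10.0
    out.coeffs[AA_INDEX[residue], center] = 0.0
    out.center_index = center
    out.constrained = True
    return out


class _TableData:
    """Precomputed per-table arrays for fast loss/gradient evaluation."""

    def __init__(self, table: CountTable, skeleton: BindingModel):
        kept = table.drop_empty_rows()
        enc = encode_peptides(kept.sequences)
        w_s = skeleton.specific.width
        w_ns = skeleton.nonspecific.matrix.width
        win_s = specific_window_indices(enc, skeleton).astype(np.int64)
        win_ns = nonspecific_window_indices(enc, skeleton).astype(np.int64)
        self.flat_s = (win_s * w_s + np.arange(w_s)).astype(np.int32)
        self.flat_ns = (win_ns * w_ns + np.arange(w_ns)).astype(np.int32)
        self.k_i = kept.input_counts.astype(float)
        self.k_b = kept.bound_counts.astype(float)
        self.k_total = float(kept.total_reads)
        self.round_label = table.round_label


class _Parameterization:
    """Maps between the flat optimizer vector and model structures."""

    def __init__(self, skeleton: BindingModel, n_tables: int):
        self.skeleton = skeleton
        self.n_tables = n_tables
        self.free_cols = np.flatnonzero(skeleton.specific.free_column_mask())
        self.w_s = skeleton.specific.width
        self.w_ns = skeleton.nonspecific.matrix.width
        self.n_gamma = skeleton.var_len - self.w_ns + 1
        self.n_bs = N_AA * len(self.free_cols)
        self.n_bns = N_AA * self.w_ns
        self.n_coeffs = self.n_bs + self.n_bns + self.n_gamma
        self.n_params = self.n_coeffs + 3 * n_tables

    def split(self, theta: np.ndarray):
        i = 0
        beta_s_free = theta[i : i + self.n_bs].reshape(N_AA, len(self.free_cols)); i += self.n_bs
        beta_ns = theta[i : i + self.n_bns].reshape(N_AA, self.w_ns); i += self.n_bns
        gamma = theta[i : i + self.n_gamma]; i += self.n_gamma
        log_eta = theta[i : i + self.n_tables]; i += self.n_tables
        log_a_ns = theta[i : i + self.n_tables]; i += self.n_tables
        log_a_s = theta[i : i + self.n_tables]
        return beta_s_free, beta_ns, gamma, log_eta, log_a_ns, log_a_s

    def full_specific(self, beta_s_free: np.ndarray) -> np.ndarray:
        coeffs = self.skeleton.specific.coeffs.copy()
        coeffs[:, self.free_cols] = beta_s_free
        return coeffs

    def to_model(self, theta: np.ndarray) -> BindingModel:
        beta_s_free, beta_ns, gamma, log_eta, log_a_ns, log_a_s = self.split(theta)
        spec = self.skeleton.specific.copy()
        spec.coeffs = self.full_specific(beta_s_free)
        ns = NonSpecificMode(EnergyMatrix(self.w_ns, beta_ns.copy()), gamma.copy())
        return BindingModel(
            spec,
            ns,
            self.skeleton.flank_left,
            self.skeleton.flank_right,
            self.skeleton.flank_overlap,
            self.skeleton.var_len,
            [(float(np.exp(log_a_ns[c])), float(np.exp(log_a_s[c]))) for c in range(self.n_tables)],
            [(float(np.exp(log_eta[c])), 1.0) for c in range(self.n_tables)],
        )


def _loss_and_grad(
    theta: np.ndarray,
    param: _Parameterization,
    tables: list[_TableData],
    reg: RegularizationConfig,
) -> tuple[float, np.ndarray]:
    beta_s_free, beta_ns, gamma, log_eta, log_a_ns, log_a_s = param.split(theta)
    coeffs_s = param.full_specific(beta_s_free).ravel()
    coeffs_ns = beta_ns.ravel()

    l_data = 0.0
    g_bs = np.zeros(N_AA * param.w_s)
    g_bns = np.zeros(N_AA * param.w_ns)
    g_gamma = np.zeros(param.n_gamma)
    g_eta = np.zeros(param.n_tables)
    g_ans = np.zeros(param.n_tables)
    g_as = np.zeros(param.n_tables)

    for c, td in enumerate(tables):
        e_s = coeffs_s[td.flat_s].sum(axis=-1)
        ln_a_s_tot = logsumexp(e_s, axis=-1)
        e_ns = coeffs_ns[td.flat_ns].sum(axis=-1) + gamma[None, :]
        ln_a_ns_tot = logsumexp(e_ns, axis=-1)

        ln_spec = log_a_s[c] + ln_a_s_tot
        ln_nons = log_a_ns[c] + ln_a_ns_tot
        ln_kappa = np.logaddexp(ln_spec, ln_nons)
        phi_s = np.exp(ln_spec - ln_kappa)
        phi_ns = 1.0 - phi_s

        ln_denom = np.logaddexp(log_eta[c], ln_kappa)
        sigma = np.exp(ln_kappa - ln_denom)  # predicted bound fraction

        l_data += (
            td.k_i @ (log_eta[c] - ln_denom) + td.k_b @ (ln_kappa - ln_denom)
        ) / td.k_total

        u = (td.k_b - (td.k_i + td.k_b) * sigma) / td.k_total  # d l_data / d ln kappa
        g_as[c] = u @ phi_s
        g_ans[c] = u @ phi_ns
        g_eta[c] = (td.k_i.sum() - (td.k_i + td.k_b) @ (1.0 - sigma)) / td.k_total

        w_spec = (u * phi_s)[:, None] * np.exp(e_s - ln_a_s_tot[:, None])
        g_bs += np.bincount(
            td.flat_s.ravel(),
            weights=np.broadcast_to(w_spec[:, :, None], td.flat_s.shape).ravel(),
            minlength=N_AA * param.w_s,
        )
        w_nons = (u * phi_ns)[:, None] * np.exp(e_ns - ln_a_ns_tot[:, None])
        g_gamma += w_nons.sum(axis=0)
        g_bns += np.bincount(
            td.flat_ns.ravel(),
            weights=np.broadcast_to(w_nons[:, :, None], td.flat_ns.shape).ravel(),
            minlength=N_AA * param.w_ns,
        )

    # regularization (free coefficients only)
    g_bs = g_bs.reshape(N_AA, param.w_s)[:, param.free_cols].ravel()
    coeff_vec = np.concatenate([beta_s_free.ravel(), coeffs_ns, gamma])
    barrier_hi = np.exp(coeff_vec - reg.barrier_bound)
    barrier_lo = np.exp(-coeff_vec - reg.barrier_bound)
    l_reg = reg.l2_weight * float(coeff_vec @ coeff_vec) + float(barrier_hi.sum() + barrier_lo.sum())
    g_reg_coeff = 2.0 * reg.l2_weight * coeff_vec + barrier_hi - barrier_lo

    a_ns = np.exp(log_a_ns)
    a_s = np.exp(log_a_s)
    frac_ns = a_ns / (a_ns + a_s)
    l_reg -= reg.dirichlet_count * float(np.log(frac_ns).sum() + np.log(1.0 - frac_ns).sum())
    g_reg_ans = -reg.dirichlet_count * (1.0 - 2.0 * frac_ns)
    g_reg_as = -reg.dirichlet_count * (1.0 - 2.0 * (1.0 - frac_ns))

    loss = -l_data + l_reg
    grad = np.concatenate(
        [
            -np.concatenate([g_bs, g_bns, g_gamma]) + g_reg_coeff,
            -g_eta,
            -g_ans + g_reg_ans,
            -g_as + g_reg_as,
        ]
    )
    return loss, grad


def _make_skeleton(design: LibraryDesign, config: FitConfig) -> BindingModel:
    spec = EnergyMatrix(config.w_s)
    if config.constrain_center:
        spec = apply_central_constraint(spec, config.center_residue)
    ns = NonSpecificMode(
        EnergyMatrix(config.w_ns), np.zeros(design.var_len_aa - config.w_ns + 1)
    )
    return BindingModel(
        spec,
        ns,
        design.left_flank_aa,
        design.right_flank_aa,
        config.f_s,
        design.var_len_aa,
        [(1.0, 1.0)],
        [(1.0, 1.0)],
    )


def _initial_theta(
    param: _Parameterization, tables: list[_TableData], config: FitConfig, rng: np.random.Generator
) -> np.ndarray:
    theta = np.zeros(param.n_params)
    theta[: param.n_coeffs - param.n_gamma] = rng.normal(0.0, config.init_scale, param.n_coeffs - param.n_gamma)
    n_c = param.n_tables
    # eta_I from the observed input/bound read split at kappa ~ typical scale
    for c, td in enumerate(tables):
        f_in = max(td.k_i.sum(), 1.0) / td.k_total
        f_bn = max(td.k_b.sum(), 1.0) / td.k_total
        kappa0 = 0.5 * (param.skeleton.n_specific_offsets() + param.n_gamma)
        theta[param.n_coeffs + c] = np.log(kappa0 * f_in / f_bn)
    theta[param.n_coeffs + n_c :] = np.log(0.5)  # equal activities
    return theta


def gauge_fix_model(model: BindingModel) -> BindingModel:
    """Mean-center free specific columns, absorbing the shift into alpha_S.

    Legal because every specific-mode window covers every matrix column
    exactly once, so the predicted enrichment of every sequence is
    unchanged.
    """
    out = model.copy()
    free = out.specific.free_column_mask()
    shifts = out.specific.coeffs[:, free].mean(axis=0)
    out.specific.coeffs[:, free] -= shifts[None, :]
    total = float(shifts.sum())
    out.activities = [(a_ns, a_s * float(np.exp(total))) for a_ns, a_s in out.activities]
    return out


def fit_model(
    experiment: list[CountTable],
    design: LibraryDesign,
    config: FitConfig | None = None,
    gauge_fix: bool = True,
) -> BindingModel:
    """Fit a two-mode binding model jointly to all count tables.

    Minimizes -l_data + l_reg over all free parameters with L-BFGS using
    analytic gradients; the best of ``config.n_starts`` seeded restarts is
    returned, with its optimization history attached as ``.fit_log``.
    """
    if not experiment:
        raise ValueError("need at least one count table")
    config = config or FitConfig()
    skeleton = _make_skeleton(design, config)
    tables = [_TableData(t, skeleton) for t in experiment]
    param = _Parameterization(skeleton, len(tables))

    rng = np.random.default_rng(config.seed)
    best = None
    start_losses = []
    for start in range(config.n_starts):
        theta0 = _initial_theta(param, tables, config, rng)
        loss0, _ = _loss_and_grad(theta0, param, tables, config.regularization)
        scale = 1.0
        while not np.isfinite(loss0) and scale > 1e-6:
            scale *= 0.1
            theta0[: param.n_coeffs] *= 0.1
            loss0, _ = _loss_and_grad(theta0, param, tables, config.regularization)
        if not np.isfinite(loss0):
            start_losses.append(float("inf"))
            continue
        res = minimize(
            _loss_and_grad,
            theta0,
            args=(param, tables, config.regularization),
            method="L-BFGS-B",
            jac=True,
            options={"maxiter": config.max_iter, "gtol": config.tol, "ftol": 1e-13},
        )
        start_losses.append(float(res.fun))
        logger.info("start %d: loss %.6f after %d iterations", start, res.fun, res.nit)
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("all optimization starts failed with non-finite loss")

    model = param.to_model(best.x)
    model.round_labels = [td.round_label for td in tables]
    if gauge_fix:
        model = gauge_fix_model(model)
    model.fit_log = FitLog(
        start_losses=start_losses,
        best_start=int(np.argmin(start_losses)),
        n_iterations=int(best.nit),
        final_loss=float(best.fun),
        converged=bool(best.success),
    )
    return model


def loss_and_grad_for_model(
    model_theta: np.ndarray,
    experiment: list[CountTable],
    design: LibraryDesign,
    config: FitConfig,
) -> tuple[float, np.ndarray]:
    """Evaluate the loss and analytic gradient at an arbitrary parameter vector.

    Exposed for gradient verification against finite differences.
    """
    skeleton = _make_skeleton(design, config)
    tables = [_TableData(t, skeleton) for t in experiment]
    param = _Parameterization(skeleton, len(tables))
    if model_theta.shape != (param.n_params,):
        raise ValueError(f"expected {param.n_params} parameters")
    return _loss_and_grad(model_theta, param, tables, config.regularization)


def n_free_parameters(experiment_size: int, design: LibraryDesign, config: FitConfig) -> int:
    skeleton = _make_skeleton(design, config)
    return _Parameterization(skeleton, experiment_size).n_params
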