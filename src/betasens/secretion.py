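"""Insulin secretion and the beta cell dose–response model for one MMTT.

Given a mixed-meal test's paired glucose and C-peptide series, this module

* reconstructs the insulin secretion rate (ISR) by regularized nonnegative
  deconvolution of C-peptide against its two-exponential kinetics, and
* fits the beta cell model in which ISR is the sum of a dose–response
  component ``p(t) * f(G(t))`` — a piecewise-linear dose–response ``f``
  modulated by a mean-1 potentiation factor ``p`` — and an early-release
  component proportional to the positive rate of change of glucose.

Beta cell glucose sensitivity (βGS) is the mean slope of ``f`` over the
observed glucose range, in pmol min⁻¹ m⁻² per mmol/l.  All fitting is a
deterministic sequence of nonnegativity-constrained penalized linear least
squares problems (no random initialisation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.stats import spearmanr

from .kinetics import CPeptideKinetics

__all__ = [
    "FitOptions",
    "SecretionProfile",
    "BetaCellFit",
    "auc_trapezium",
    "incremental_auc_trapezium",
    "deconvolve",
    "fit_beta_cell_model",
    "flag_discordant",
]

_PMOL_TO_NMOL = 1e-3


# ---------------------------------------------------------------------------
# containers


@dataclass
class SecretionProfile:
    """ISR(t) on a uniform time grid, pmol min⁻¹ m⁻²."""

    times_min: np.ndarray
    isr: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.isr = np.asarray(self.isr, dtype=float)
        if self.isr.min(initial=0.0) < -1e-9:
            raise ValueError("ISR must be nonnegative on the grid")


@dataclass
class FitOptions:
    """Tuning knobs of the beta cell model fit (all deterministic).

    Smoothing weights were calibrated once on the synthetic suite and are
    frozen here; they are expressed on the C-peptide residual scale so the
    same numbers work across kinetics and units.
    """

    bsa_m2: float = 1.73
    fine_dt_min: float = 1.0
    n_interior_knots: int = 3
    smoothing_dose_response: float = 30.0
    smoothing_potentiation: float = 1.0
    relative_weighting: bool = True  # weight residuals ~ 1/C for CV-type noise
    potentiation_curvature: bool = True  # allow a curved (3-node) p after profiling
    tilt_range: float = 0.8  # half-width of the potentiation-tilt search
    tilt_coarse_step: float = 0.05
    tilt_fine_step: float = 0.005
    tilt_temperature_df: float = 2.0  # residual d.o.f. scaling the tilt posterior
    r2_flag_threshold: float = 0.7
    corr_flag_threshold: float = -0.5
    min_glucose_span: float = 0.5  # mmol/l below which βGS is unidentifiable


@dataclass
class BetaCellFit:
    """Model outputs for one MMTT."""

    beta_gs: float  # pmol min⁻¹ m⁻² per mmol/l
    rate_sensitivity: float  # pmol m⁻² per mmol/l
    potentiation_ratio: float  # p(end)/p(0)
    basal_isr: float  # pmol min⁻¹ m⁻²
    total_output: float  # nmol m⁻²
    auc_cp: float  # nmol/l·min
    incremental_auc_cp: float
    fit_r2: float
    flagged: bool
    flag_reason: str
    dose_response_glucose: np.ndarray = field(default_factory=lambda: np.array([]))
    dose_response_isr: np.ndarray = field(default_factory=lambda: np.array([]))
    potentiation_times: np.ndarray = field(default_factory=lambda: np.array([]))
    potentiation: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# small numerics


def _validate_series(minutes, values, min_len, name="values"):
    minutes = np.asarray(minutes, dtype=float)
    values = np.asarray(values, dtype=float)
    if minutes.ndim != 1 or values.shape != minutes.shape:
        raise ValueError(f"minutes and {name} must be 1-D arrays of equal length")
    if minutes.size < min_len:
        raise ValueError(f"need at least {min_len} samples, got {minutes.size}")
    if np.any(np.diff(minutes) <= 0):
        raise ValueError("sample minutes must be strictly increasing")
    return minutes, values


def auc_trapezium(minutes, values) -> float:
    """Area under the curve by the trapezium rule."""
    minutes, values = _validate_series(minutes, values, 2)
    return float(np.trapezoid(values, minutes))


def incremental_auc_trapezium(minutes, values) -> float:
    """Trapezium AUC above the baseline (t=0) value; may be negative."""
    minutes, values = _validate_series(minutes, values, 2)
    return float(np.trapezoid(values, minutes) - values[0] * (minutes[-1] - minutes[0]))


def _second_difference_matrix(x: np.ndarray) -> np.ndarray:
    """Rows approximate the second derivative at interior nodes of a
    (possibly non-uniform) grid; exactly zero on affine functions."""
    n = x.size
    if n < 3:
        return np.zeros((0, n))
    d = np.zeros((n - 2, n))
    for i in range(1, n - 1):
        h1 = x[i] - x[i - 1]
        h2 = x[i + 1] - x[i]
        d[i - 1, i - 1] = 2.0 / (h1 * (h1 + h2))
        d[i - 1, i] = -2.0 / (h1 * h2)
        d[i - 1, i + 1] = 2.0 / (h2 * (h1 + h2))
    return d


def _hat_basis(nodes: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Piecewise-linear nodal ("hat") basis evaluated at x; shape (n_nodes, len(x)).
    Values outside the node range are clamped to the end nodes."""
    xc = np.clip(x, nodes[0], nodes[-1])
    out = np.empty((nodes.size, x.size))
    for j in range(nodes.size):
        e = np.zeros(nodes.size)
        e[j] = 1.0
        out[j] = np.interp(xc, nodes, e)
    return out


def _convolve_to_obs(
    x_fine: np.ndarray,
    h_fine: np.ndarray,
    kinetics: CPeptideKinetics,
    dt: float,
    obs_idx: np.ndarray,
    tail: np.ndarray,
) -> np.ndarray:
    """Plasma response at observation indices to secretion history ``x_fine``
    (held at ``x_fine[0]`` for all t<0, i.e. pre-test steady state)."""
    n = x_fine.size
    conv = np.convolve(x_fine, h_fine)[:n]
    conv = dt * (conv - 0.5 * (x_fine[0] * h_fine + h_fine[0] * x_fine))
    full = conv + x_fine[0] * tail
    return full[obs_idx]


# ---------------------------------------------------------------------------
# deconvolution


def deconvolve(
    minutes,
    cpeptide_nmol_l,
    kinetics: CPeptideKinetics,
    smoothing_weight: float = 0.1,
    bsa_m2: float = 1.0,
    grid_step_min: float = 5.0,
) -> SecretionProfile:
    """Reconstruct ISR from a C-peptide series.

    Solves ``min ||C - H s||^2 + w ||D2 s||^2`` subject to ``s >= 0``, where
    ``H`` is the discrete convolution of the impulse response with a
    piecewise-linear secretion profile on a ``grid_step_min`` grid (with the
    profile held at its t=0 value before the test), and ``D2`` penalizes
    curvature.  Returns ISR per m² of body surface area.
    """
    minutes, cp = _validate_series(minutes, cpeptide_nmol_l, 4, "cpeptide")
    if np.any(cp < 0):
        raise ValueError("C-peptide concentrations must be >= 0")
    t0, t_end = minutes[0], minutes[-1]
    grid = np.arange(t0, t_end + 1e-9, grid_step_min)
    if grid[-1] < t_end - 1e-9:
        grid = np.append(grid, t_end)

    dt = 1.0
    t_fine = np.arange(t0, t_end + 1e-9, dt)
    if t_fine[-1] < t_end - 1e-9:
        t_fine = np.append(t_fine, t_end)
    h_fine = kinetics.a1 * np.exp(-kinetics.lam1 * (t_fine - t0)) + kinetics.a2 * np.exp(
        -kinetics.lam2 * (t_fine - t0)
    )
    tail = kinetics.tail_area(t_fine - t0)
    obs_idx = np.searchsorted(t_fine, minutes - 1e-9)

    basis = _hat_basis(grid, t_fine)
    H = np.column_stack(
        [_convolve_to_obs(basis[j], h_fine, kinetics, dt, obs_idx, tail) for j in range(grid.size)]
    )
    d2 = _second_difference_matrix(grid) * kinetics.area()
    A = np.vstack([H, np.sqrt(smoothing_weight) * d2])
    b = np.concatenate([cp, np.zeros(d2.shape[0])])
    sol, _ = nnls(A, b)
    return SecretionProfile(times_min=grid, isr=sol / bsa_m2)


# ---------------------------------------------------------------------------
# beta cell model


def _positive_glucose_rate(minutes: np.ndarray, glucose: np.ndarray) -> np.ndarray:
    """max(dG/dt, 0) at the sample nodes, by central differences."""
    return np.maximum(np.gradient(glucose, minutes), 0.0)


def fit_beta_cell_model(
    minutes,
    glucose_mmol_l,
    cpeptide_nmol_l,
    kinetics: CPeptideKinetics,
    options: FitOptions | None = None,
) -> BetaCellFit:
    """Fit the beta cell dose–response model to one MMTT.

    The model is ``ISR(t) = p(t) f(G(t)) + k max(dG/dt, 0)`` with ``f``
    piecewise linear over the observed glucose range (interior knots at
    quantiles), ``p`` piecewise linear in time and smoothness-penalized, and
    ``k`` the rate sensitivity.  Every parameter pass is a nonnegativity-
    constrained penalized linear least squares problem matching
    model-implied C-peptide — model ISR convolved with the impulse response,
    assuming pre-test steady state — to the observed series.

    A short MMTT carries few C-peptide samples, so a free joint fit of
    dose–response and potentiation is under-determined (many exact-fit
    decompositions exist).  Identification therefore proceeds in stages:
    the affine component (tilt) of the potentiation factor is profiled on a
    deterministic coarse-then-fine grid, solving the linear subproblem for
    the dose–response nodes and rate sensitivity at each candidate and
    keeping the tilt with the lowest penalized objective; one alternation
    cycle then allows smoothness-penalized curvature in ``p`` and re-solves
    the dose–response.  Finally ``p`` is rescaled so its time-average over
    the test is exactly 1, with ``f`` rescaled inversely (the ISR product
    is unchanged).
    """
    opt = options or FitOptions()
    minutes, glucose = _validate_series(minutes, glucose_mmol_l, 4, "glucose")
    _, cp = _validate_series(minutes, cpeptide_nmol_l, 4, "cpeptide")
    if np.any(cp < 0) or np.any(glucose <= 0):
        raise ValueError("glucose must be > 0 and C-peptide >= 0")

    auc = auc_trapezium(minutes, cp)
    iauc = incremental_auc_trapezium(minutes, cp)
    bsa = opt.bsa_m2

    g_min, g_max = float(glucose.min()), float(glucose.max())
    if g_max - g_min < opt.min_glucose_span:
        # Unidentifiable slope: report what is still defined.
        profile = deconvolve(minutes, cp, kinetics, bsa_m2=bsa)
        total = float(np.trapezoid(profile.isr, profile.times_min)) * _PMOL_TO_NMOL
        return BetaCellFit(
            beta_gs=np.nan,
            rate_sensitivity=np.nan,
            potentiation_ratio=np.nan,
            basal_isr=float(profile.isr[0]),
            total_output=total,
            auc_cp=auc,
            incremental_auc_cp=iauc,
            fit_r2=np.nan,
            flagged=True,
            flag_reason="degenerate_glucose_range",
        )

    # --- grids and bases -------------------------------------------------
    t0, t_end = minutes[0], minutes[-1]
    dt = opt.fine_dt_min
    t_fine = np.arange(t0, t_end + 1e-9, dt)
    if t_fine[-1] < t_end - 1e-9:
        t_fine = np.append(t_fine, t_end)
    h_fine = kinetics.a1 * np.exp(-kinetics.lam1 * (t_fine - t0)) + kinetics.a2 * np.exp(
        -kinetics.lam2 * (t_fine - t0)
    )
    tail = kinetics.tail_area(t_fine - t0)
    obs_idx = np.searchsorted(t_fine, minutes - 1e-9)

    g_fine = np.interp(t_fine, minutes, glucose)
    rate_nodes = _positive_glucose_rate(minutes, glucose)
    r_fine = np.interp(t_fine, minutes, rate_nodes)

    qs = np.linspace(0.0, 1.0, opt.n_interior_knots + 2)
    g_knots = np.unique(np.quantile(glucose, qs))
    if g_knots.size < 2:  # pragma: no cover - guarded by span check
        g_knots = np.array([g_min, g_max])
    hat_g = _hat_basis(g_knots, g_fine)  # (m, n_fine)

    duration = t_end - t0
    p_nodes_t = np.array([t0, t0 + duration / 2.0, t_end])
    hat_t = _hat_basis(p_nodes_t, t_fine)  # (3, n_fine)
    tilt_fine = (t_fine - t0 - duration / 2.0) / duration  # mean-0 over the test

    d2_f = _second_difference_matrix(g_knots)
    # p-curvature measured per unit of normalized test time, so the penalty
    # weight is dimensionless and actually binds on a minutes grid
    d2_p = _second_difference_matrix(p_nodes_t) * duration**2
    kappa = kinetics.area() * bsa  # C scale of a unit ISR
    c_scale = max(float(np.mean(cp)), 1e-12)

    def conv(x: np.ndarray) -> np.ndarray:
        return _convolve_to_obs(x, h_fine, kinetics, dt, obs_idx, tail) * bsa

    m = g_knots.size
    n_p = p_nodes_t.size
    w_f = np.sqrt(opt.smoothing_dose_response) * kappa
    w_p = np.sqrt(opt.smoothing_potentiation) * c_scale
    pen_f = np.hstack([w_f * d2_f, np.zeros((d2_f.shape[0], 1))])

    # assay noise is multiplicative, so weight each observation ~ 1/C
    # (normalized to mean 1 to keep the penalty scales unchanged)
    if opt.relative_weighting:
        obs_w = c_scale / np.maximum(cp, 0.1 * c_scale)
        obs_w /= obs_w.mean()
    else:
        obs_w = np.ones(minutes.size)
    cp_w = cp * obs_w
    b_stack = np.concatenate([cp_w, np.zeros(pen_f.shape[0])])

    # Design is affine in the tilt: column_j(phi) = conv(hat_g_j) + phi*conv(tilt*hat_g_j)
    base_cols = obs_w[:, None] * np.column_stack(
        [conv(hat_g[j]) for j in range(m)] + [conv(r_fine)]
    )
    tilt_cols = obs_w[:, None] * np.column_stack(
        [conv(tilt_fine * hat_g[j]) for j in range(m)] + [np.zeros(minutes.size)]
    )

    def solve_at_tilt(phi: float):
        A = np.vstack([base_cols + phi * tilt_cols, pen_f])
        sol, rnorm = nnls(A, b_stack)
        return rnorm, sol

    # Profile the tilt on a coarse grid, refine around the optimum, then take
    # the quadrature-weighted posterior mean over every evaluated tilt
    # (Gaussian likelihood with temperature set by the minimum residual):
    # this keeps the zero-noise solution exact while averaging away the
    # noise-driven flat directions of the profile objective.
    span = opt.tilt_range
    evaluated: dict[float, tuple[float, np.ndarray]] = {}
    for phi in np.arange(-span, span + 1e-12, opt.tilt_coarse_step):
        evaluated[round(float(phi), 6)] = solve_at_tilt(phi)
    best_phi = min(evaluated, key=lambda p: evaluated[p][0])
    for phi in np.arange(
        best_phi - opt.tilt_coarse_step,
        best_phi + opt.tilt_coarse_step + 1e-12,
        opt.tilt_fine_step,
    ):
        key = round(float(phi), 6)
        if key not in evaluated and abs(key) <= span + opt.tilt_coarse_step:
            evaluated[key] = solve_at_tilt(phi)
    grid = np.array(sorted(evaluated))
    rn2 = np.array([evaluated[p][0] for p in grid]) ** 2
    sols = np.array([evaluated[p][1] for p in grid])
    temperature = max(float(rn2.min()), 1e-20) / opt.tilt_temperature_df
    log_w = -(rn2 - rn2.min()) / (2.0 * temperature)
    weights = np.exp(log_w - log_w.max()) * np.gradient(grid)
    weights /= weights.sum()
    sol = weights @ sols
    tilt = float(weights @ grid)
    f_vals, k_rate = sol[:m], float(sol[m])

    p_vals = 1.0 + tilt * (p_nodes_t - t0 - duration / 2.0) / duration
    if opt.potentiation_curvature:
        # refine p only: smoothness-penalized curvature given the fitted
        # dose-response and rate sensitivity
        f_fine = np.interp(g_fine, g_knots, f_vals)
        target = obs_w * (cp - conv(k_rate * r_fine))
        A2 = obs_w[:, None] * np.column_stack([conv(hat_t[i] * f_fine) for i in range(n_p)])
        p_curved, _ = nnls(
            np.vstack([A2, w_p * d2_p]), np.concatenate([target, np.zeros(d2_p.shape[0])])
        )
        if np.max(p_curved) > 1e-9:
            p_vals = p_curved
    p_fine = hat_t.T @ p_vals

    # --- mean-1 normalization of the potentiation factor ------------------
    p_mean = float(np.trapezoid(p_fine, t_fine)) / duration
    if p_mean <= 1e-9:  # pragma: no cover - guarded above
        p_vals = np.ones(n_p)
        p_mean = 1.0
    p_vals = p_vals / p_mean
    f_vals = f_vals * p_mean
    p_fine = hat_t.T @ p_vals

    f_fine = np.interp(g_fine, g_knots, f_vals)
    isr_fine = p_fine * f_fine + k_rate * r_fine
    c_model = _convolve_to_obs(isr_fine, h_fine, kinetics, dt, obs_idx, tail) * bsa

    ss_res = float(np.sum((cp - c_model) ** 2))
    ss_tot = float(np.sum((cp - cp.mean()) ** 2))
    fit_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-12 else 0.0)

    beta_gs = float((f_vals[-1] - f_vals[0]) / (g_knots[-1] - g_knots[0]))
    pot_ratio = float(p_vals[-1] / p_vals[0]) if p_vals[0] > 1e-9 else np.nan
    basal = float(isr_fine[0])
    total = float(np.trapezoid(isr_fine, t_fine)) * _PMOL_TO_NMOL

    fit = BetaCellFit(
        beta_gs=beta_gs,
        rate_sensitivity=k_rate,
        potentiation_ratio=pot_ratio,
        basal_isr=basal,
        total_output=total,
        auc_cp=auc,
        incremental_auc_cp=iauc,
        fit_r2=fit_r2,
        flagged=False,
        flag_reason="",
        dose_response_glucose=g_knots,
        dose_response_isr=f_vals,
        potentiation_times=p_nodes_t,
        potentiation=p_vals,
    )
    fit.flagged, fit.flag_reason = flag_discordant(minutes, glucose, cp, fit, opt)
    return fit


def flag_discordant(
    minutes,
    glucose,
    cpeptide,
    fit: BetaCellFit,
    options: FitOptions | None = None,
) -> tuple[bool, str]:
    """Quality-control rule for glucose/C-peptide discordance.

    A test is flagged when the model fit is poor (R² below threshold) or the
    rank correlation between the glucose and C-peptide excursions is strongly
    negative — both signatures of a measurement or labelling error rather
    than physiology.
    """
    opt = options or FitOptions()
    reasons = []
    if np.isfinite(fit.fit_r2) and fit.fit_r2 < opt.r2_flag_threshold:
        reasons.append(f"low_fit_r2({fit.fit_r2:.2f})")
    glucose = np.asarray(glucose, dtype=float)
    cpeptide = np.asarray(cpeptide, dtype=float)
    if glucose.size >= 4 and np.std(glucose) > 0 and np.std(cpeptide) > 0:
        rho = spearmanr(glucose, cpeptide).statistic
        if np.isfinite(rho) and rho < opt.corr_flag_threshold:
            reasons.append(f"negative_glucose_cpeptide_correlation({rho:.2f})")
    return (len(reasons) > 0, "; ".join(reasons))
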