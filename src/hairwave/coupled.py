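"""Two-group positively/negatively coupled mean-field phase oscillators.

The model assigns each oscillator to a positively or a negatively coupled
group.  Every oscillator feels the ensemble only through the first-order
mean field Z = R exp(i Theta):

    dtheta_j/dt = omega_j + K_sigma(j) * R * sin(Theta - theta_j),

with intrinsic frequencies omega_j drawn from a Lorentzian (Cauchy)
distribution of center omega0 and half-width gamma, and group couplings
K_+ = K > 0, K_- = -rho K < 0.  Positively coupled oscillators are drawn
toward the mean field, negatively coupled ones pushed away; with a fraction
p positive the system can spontaneously form two synchronized clusters
locked 180 degrees apart.

For Lorentzian frequencies the Ott-Antonsen ansatz reduces the dynamics
exactly (as N -> infinity) to one complex ODE per group for the group order
parameters z_+/-, here written in the frame rotating at omega0:

    dz_s/dt = -gamma z_s + (K_s / 2) (W - conj(W) z_s^2),
    W = p z_+ + (1 - p) z_-.

Steady states of the reduced system invert exactly to model parameters
given the observed cluster radii: the two real fixed-point equations
determine both the rate ratio gamma / K_+ and the coupling-magnitude ratio
rho = |K_-| / K_+, leaving only the overall rate scale (the time units)
free.  A scan over p then yields the bifurcation sequence
incoherent -> traveling wave -> pi-state, the wave state appearing when the
negative coupling is weaker in magnitude than the positive one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp


class ParameterError(ValueError):
    """A model parameter is outside its physical domain."""


class IntegrationError(RuntimeError):
    """The ODE solver produced a non-finite or out-of-domain state."""


class UnidentifiableError(ValueError):
    """The steady-state equations do not determine the parameters."""


CONFIG1 = "config1"  # cluster 1 negatively coupled (the smaller cluster)
CONFIG2 = "config2"  # cluster 1 positively coupled


@dataclass(frozen=True)
class CoupledModelParams:
    """Parameters of the two-group mean-field model.

    ``p`` is the fraction of positively coupled oscillators; ``K`` the
    positive coupling strength (rad/day) with K_+ = +K and
    K_- = -coupling_ratio * K; ``gamma`` the Lorentzian half-width of the
    intrinsic frequencies (rad/day); ``omega0`` their mean (rad/day).  A
    physical fit requires K > 0, coupling_ratio > 0 and gamma > 0.
    """

    K: float
    gamma: float
    p: float
    omega0: float = 0.0
    coupling_ratio: float = 1.0
    n_oscillators: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ParameterError("p must lie in [0, 1]")
        if self.n_oscillators < 1:
            raise ParameterError("need at least one oscillator")
        if self.coupling_ratio <= 0:
            raise ParameterError("coupling_ratio must be positive")

    @property
    def k_minus(self) -> float:
        return -self.coupling_ratio * self.K


def sample_lorentzian(omega0: float, gamma: float, n: int, seed: int) -> np.ndarray:
    """Draw intrinsic frequencies omega0 + gamma * tan(pi (u - 1/2))."""
    if gamma <= 0:
        raise ParameterError("gamma must be positive")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=n)
    return omega0 + gamma * np.tan(np.pi * (u - 0.5))


def simulate_full(
    params: CoupledModelParams,
    init_phases: np.ndarray,
    t_span: tuple[float, float],
    seed: int,
    n_eval: int = 201,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Integrate all N oscillators of the mean-field model.

    The first ceil(p N) oscillators are positively coupled.  Returns
    ``(t, theta(t), Z1(t), Z2(t))`` with theta of shape (N, T).
    """
    theta0 = np.asarray(init_phases, dtype=float)
    n = len(theta0)
    if n < 2:
        raise ParameterError("need at least 2 oscillators")
    omega = sample_lorentzian(params.omega0, params.gamma, n, seed)
    n_pos = int(np.ceil(params.p * n))
    k_vec = np.where(np.arange(n) < n_pos, params.K, params.k_minus)

    def rhs(_t, theta):
        z = np.exp(1j * theta).mean()
        r, big_theta = np.abs(z), np.angle(z)
        return omega + k_vec * r * np.sin(big_theta - theta)

    t_eval = np.linspace(*t_span, n_eval)
    sol = solve_ivp(rhs, t_span, theta0, t_eval=t_eval, rtol=rtol, atol=atol, method="RK45")
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(f"full-model integration failed: {sol.message}")
    z1 = np.exp(1j * sol.y).mean(axis=0)
    z2 = np.exp(2j * sol.y).mean(axis=0)
    return sol.t, sol.y, z1, z2


def _reduced_rhs(params: CoupledModelParams):
    k_plus, k_minus = params.K, params.k_minus
    gamma, p = params.gamma, params.p

    def rhs(_t, s):
        zp = s[0] + 1j * s[1]
        zm = s[2] + 1j * s[3]
        w = p * zp + (1.0 - p) * zm
        dzp = -gamma * zp + 0.5 * k_plus * (w - np.conj(w) * zp**2)
        dzm = -gamma * zm + 0.5 * k_minus * (w - np.conj(w) * zm**2)
        return [dzp.real, dzp.imag, dzm.real, dzm.imag]

    return rhs


def simulate_reduced(
    params: CoupledModelParams,
    z_plus0: complex,
    z_minus0: complex,
    t_span: tuple[float, float],
    n_eval: int = 401,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Integrate the Ott-Antonsen reduced model in the omega0-rotating frame.

    Returns ``(t, z_plus(t), z_minus(t))``.  Group order parameters must stay
    inside the closed unit disk; escape beyond a small tolerance aborts.
    """
    if abs(z_plus0) > 1.0 or abs(z_minus0) > 1.0:
        raise ParameterError("initial order parameters must lie in the unit disk")
    y0 = [z_plus0.real, z_plus0.imag, z_minus0.real, z_minus0.imag]
    t_eval = np.linspace(*t_span, n_eval)
    sol = solve_ivp(
        _reduced_rhs(params), t_span, y0, t_eval=t_eval, rtol=rtol, atol=atol, method="RK45"
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(f"reduced-model integration failed: {sol.message}")
    zp = sol.y[0] + 1j * sol.y[1]
    zm = sol.y[2] + 1j * sol.y[3]
    if np.any(np.abs(zp) > 1.0 + 1e-6) or np.any(np.abs(zm) > 1.0 + 1e-6):
        raise IntegrationError("order parameter escaped the unit disk")
    return sol.t, zp, zm


@dataclass
class SteadyFit:
    K: float
    gamma: float
    p: float
    coupling_ratio: float  # rho = |K_-| / K_+
    configuration: str
    realizable: bool
    residual: float
    gamma_over_k: float  # identifiable rate ratio gamma / K_+

    def params(self, omega0: float = 0.0, n_oscillators: int = 1000) -> CoupledModelParams:
        return CoupledModelParams(
            K=self.K, gamma=self.gamma, p=self.p, omega0=omega0,
            coupling_ratio=self.coupling_ratio, n_oscillators=n_oscillators,
        )


def solve_steady_parameters(
    r_plus: float,
    r_minus: float,
    p: float,
    configuration: str = CONFIG1,
    k_value: float = 1.0,
) -> SteadyFit:
    """Invert the reduced model's out-of-phase fixed point for the parameters.

    At a quasi-steady out-of-phase state the group order parameters can be
    taken on the real axis, z_+ = r_+ and z_- = -r_-, which turns the two
    complex fixed-point equations into two real ones:

        gamma r_+ = (K_+ / 2) W (1 - r_+^2),
        gamma r_- = (|K_-| / 2) W (1 - r_-^2),

    with W = p r_+ - (1 - p) r_-.  These determine the rate ratio
    gamma / K_+ = W (1 - r_+^2) / (2 r_+) and the coupling-magnitude ratio
    rho = |K_-| / K_+ = r_- (1 - r_+^2) / (r_+ (1 - r_-^2)) exactly; the
    overall rate scale only sets the time units and is fixed by the
    convention K_+ = ``k_value`` (rad/day).  Equal radii give rho = 1 (equal
    coupling magnitudes).  Realizability requires gamma > 0; with the
    smaller cluster positively coupled W flips sign and gamma comes out
    negative, which is not physical.
    """
    if not (0.0 < r_plus < 1.0 and 0.0 < r_minus < 1.0):
        raise ParameterError("cluster radii must lie strictly between 0 and 1")
    if not (0.0 < p < 1.0):
        raise ParameterError("p must lie strictly between 0 and 1")
    w = p * r_plus - (1.0 - p) * r_minus
    if w == 0.0:
        raise UnidentifiableError("degenerate symmetric state: W = 0")
    gamma_over_k = w * (1.0 - r_plus**2) / (2.0 * r_plus)
    rho = r_minus * (1.0 - r_plus**2) / (r_plus * (1.0 - r_minus**2))
    K = float(k_value)
    gamma = gamma_over_k * K
    # residual of both fixed-point equations (zero by construction)
    residual = float(
        abs(gamma * r_plus - 0.5 * K * w * (1.0 - r_plus**2))
        + abs(gamma * r_minus - 0.5 * rho * K * w * (1.0 - r_minus**2))
    )
    return SteadyFit(
        K=K,
        gamma=float(gamma),
        p=float(p),
        coupling_ratio=float(rho),
        configuration=configuration,
        realizable=bool(K > 0 and gamma > 0),
        residual=residual,
        gamma_over_k=float(gamma_over_k),
    )


def pi_state_radius(K: float, gamma: float, p: float) -> float:
    """Closed-form symmetric pi-state radius r^2 = 1 - 2 gamma / (K (2p - 1))."""
    r2 = 1.0 - 2.0 * gamma / (K * (2.0 * p - 1.0))
    if r2 <= 0:
        raise ParameterError("no pi-state for these parameters")
    return float(np.sqrt(r2))


@dataclass
class ConfigurationVerdict:
    fits: dict
    stable_configuration: str | None
    details: dict = field(default_factory=dict)


def check_configuration(
    r_cluster1: float,
    r_cluster2: float,
    cluster1_fraction: float,
    k_value: float = 1.0,
    perturbation: float = 1e-3,
    return_tol: float = 1e-4,
    t_settle: float = 400.0,
) -> ConfigurationVerdict:
    """Decide which coupling configuration is physical and dynamically stable.

    ``config1`` couples cluster 1 negatively (so the positively coupled
    fraction is the cluster-2 fraction); ``config2`` the reverse.  Each
    configuration is solved for (K, gamma); a realizable fit (both positive)
    is then integrated from a perturbed fixed point and called stable if the
    trajectory returns to it.
    """
    q1 = float(cluster1_fraction)
    fits = {}
    details = {}
    stable = None
    for cfg_name, (r_pos, r_neg, p) in {
        CONFIG1: (r_cluster2, r_cluster1, 1.0 - q1),
        CONFIG2: (r_cluster1, r_cluster2, q1),
    }.items():
        fit = solve_steady_parameters(r_pos, r_neg, p, cfg_name, k_value=k_value)
        fits[cfg_name] = fit
        if not fit.realizable:
            details[cfg_name] = "unrealizable (negative rate)"
            continue
        params = fit.params()
        zp0 = (r_pos + perturbation) + 0.0j
        zm0 = -(r_neg - perturbation) + 0.0j
        _, zp, zm = simulate_reduced(params, zp0, zm0, (0.0, t_settle))
        err = abs(abs(zp[-1]) - r_pos) + abs(abs(zm[-1]) - r_neg)
        if err < return_tol:
            details[cfg_name] = "stable"
            stable = cfg_name if stable is None else stable
        else:
            details[cfg_name] = f"perturbation did not decay (err={err:.3g})"
    return ConfigurationVerdict(fits=fits, stable_configuration=stable, details=details)


INCOHERENT = "incoherent"
PI_STATE = "pi_state"
TRAVELING_WAVE = "traveling_wave"
UNRESOLVED = "unresolved"


@dataclass
class BifurcationResult:
    p_grid: np.ndarray
    steady_r1: np.ndarray
    state: np.ndarray  # labels per p
    rotation: np.ndarray  # mean-field rotation rate in the rotating frame
    period_days: np.ndarray  # full-frame system period 2 pi / (omega0 + Omega)
    boundaries: dict


def bifurcation_diagram(
    K: float,
    gamma: float,
    p_grid: np.ndarray,
    omega0: float,
    coupling_ratio: float = 1.0,
    t_long: float = 600.0,
    tol_incoherent: float = 0.01,
    tol_sync: float = 0.1,
    tol_phase: float = 0.1,
    tol_rotation: float = 1e-3,
    seed: int = 0,
) -> BifurcationResult:
    """Long-time attractor of the reduced model across the positive fraction.

    For each p the reduced ODEs are integrated from a small fixed random
    start; the trailing quarter of the trajectory is classified as
    incoherent (|Z1| ~ 0), pi-state (both groups synchronized, locked 180
    degrees apart, no mean-field drift in the rotating frame) or traveling
    wave (persistent drift Omega, shortening the full-frame period
    2 pi / (omega0 + |Omega|)).  Non-stationary trajectories that fit none of
    these are labeled unresolved rather than silently binned.
    """
    rng = np.random.default_rng(seed)
    a0, a1 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    zp0 = 0.01 * np.exp(1j * a0)
    zm0 = 0.01 * np.exp(1j * a1)

    p_grid = np.asarray(p_grid, dtype=float)
    r1 = np.empty_like(p_grid)
    rot = np.empty_like(p_grid)
    period = np.full_like(p_grid, np.nan)
    state = np.empty(len(p_grid), dtype=object)

    for i, p in enumerate(p_grid):
        params = CoupledModelParams(
            K=K, gamma=gamma, p=float(p), coupling_ratio=coupling_ratio
        )
        t, zp, zm = simulate_reduced(params, zp0, zm0, (0.0, t_long), n_eval=801)
        tail = t >= 0.75 * t_long
        w = p * zp + (1.0 - p) * zm
        r_tail = np.abs(w[tail])
        r1[i] = r_tail.mean()
        # rotation rate of the mean field in the rotating frame
        ang = np.unwrap(np.angle(w[tail][np.abs(w[tail]) > 1e-12]))
        tt = t[tail][np.abs(w[tail]) > 1e-12]
        omega_drift = np.polyfit(tt, ang, 1)[0] if len(ang) > 10 else 0.0
        rot[i] = omega_drift

        if r1[i] < tol_incoherent:
            state[i] = INCOHERENT
            rot[i] = 0.0
            continue
        rp, rm = np.abs(zp[tail]), np.abs(zm[tail])
        stationary = max(rp.std(), rm.std(), r_tail.std()) < 0.02
        if not stationary:
            state[i] = UNRESOLVED
            continue
        dphi = np.angle(np.exp(1j * (np.angle(zp[tail]) - np.angle(zm[tail]) - np.pi)))
        locked_pi = np.abs(dphi).mean() < tol_phase
        synced = rp.mean() > tol_sync and rm.mean() > tol_sync
        if synced and locked_pi and abs(omega_drift) < tol_rotation:
            state[i] = PI_STATE
            period[i] = 2.0 * np.pi / omega0 if omega0 > 0 else np.nan
        elif abs(omega_drift) > tol_rotation:
            state[i] = TRAVELING_WAVE
            if omega0 > 0:
                period[i] = 2.0 * np.pi / (omega0 + abs(omega_drift))
        else:
            state[i] = UNRESOLVED

    boundaries = {}
    labels = list(state)
    for i in range(len(labels) - 1):
        if labels[i] != labels[i + 1]:
            boundaries[f"{labels[i]}->{labels[i + 1]}"] = float(
                0.5 * (p_grid[i] + p_grid[i + 1])
            )
    return BifurcationResult(
        p_grid=p_grid, steady_r1=r1, state=state, rotation=rot, period_days=period,
        boundaries=boundaries,
    )
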