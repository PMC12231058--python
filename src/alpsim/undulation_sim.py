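"""Monte Carlo diffusion inside sinusoidal (undulating) tubes.

An axon is modelled as a tube of diameter ``d`` swept along the centerline
``x(z) = A sin(2 pi z / L)`` in the x-z plane (circular cross-section normal
to the local tangent, infinite and periodic in z).  Walkers perform Gaussian
random-walk steps with elastic reflection at the wall; a PGSE experiment
with finite rectangular pulses is synthesised from the position integrals
over the two gradient pulses, and a diffusion tensor is fit per shell.

The mechanism probed: undulation in the x-z plane adds apparent diffusivity
along x but not y, so even a single, radially symmetric axon produces
lambda2/lambda3 > 1 — radial asymmetry with no perivascular compartment.

Units: micrometres, milliseconds, um^2/ms (1 um^2/ms = 1e-3 mm^2/s); b is
carried in s/mm^2 externally and converted to ms/um^2 internally.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from numba import njit

from .io_formats import GradientScheme, preset_scheme

__all__ = [
    "UndulationSubstrate",
    "WalkerParams",
    "PGSEProtocol",
    "build_substrate",
    "simulate_walk",
    "synthesize_pgse_signal",
    "undulation_asymmetry",
    "MICRO_SUBSTRATE",
    "MACRO_SUBSTRATE",
]

#: gyromagnetic ratio of 1H, rad / (ms * T)
GAMMA_MS = 2.675221874e5

#: default intrinsic (axoplasmic) diffusivity, um^2/ms
D0_DEFAULT = 2.0

#: default HCP-style PGSE timings, ms
DELTA_SMALL_DEFAULT = 10.6  # pulse duration (delta)
DELTA_BIG_DEFAULT = 43.1  # pulse separation (Delta)


# ---------------------------------------------------------------------------
# substrate geometry
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class UndulationSubstrate:
    """Sinusoidal tube: diameter ``d``, wavelength ``L``, amplitude ``A`` (um).

    A point is inside iff its distance to the centerline curve
    ``c(t) = (A sin(2 pi t / L), 0, t)`` is at most ``d/2``.  This swept-tube
    membership is exact as long as the tube radius stays below the minimum
    radius of curvature of the centerline (checked at construction).
    """

    d: float
    L: float
    A: float

    def __post_init__(self) -> None:
        if self.d <= 0 or self.L <= 0:
            raise ValueError("diameter and wavelength must be positive")
        if self.A < 0:
            raise ValueError("amplitude must be non-negative")
        # max curvature of x = A sin(w z) is A w^2 (at the crests)
        kappa_max = self.A * self.omega**2
        if kappa_max * self.radius >= 1.0:
            raise ValueError(
                "tube radius exceeds the centerline radius of curvature; "
                "the swept tube would self-intersect"
            )

    @property
    def radius(self) -> float:
        return self.d / 2.0

    @property
    def omega(self) -> float:
        return 2.0 * math.pi / self.L

    def centerline(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.stack(
            [self.A * np.sin(self.omega * t), np.zeros_like(t), t], axis=-1
        )

    def distance_to_centerline(self, points: np.ndarray) -> np.ndarray:
        """Exact distance from points (N, 3) to the centerline curve.

        The nearest parameter t* satisfies (z - t*)^2 <= f(t*) <= f(z), so a
        bracketed scan of half-width sqrt(f(z)) around each point's z always
        contains the minimiser; Newton polish finishes the job.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        half = np.sqrt((x - self.A * np.sin(self.omega * z)) ** 2 + y * y) + 1e-9
        n_scan = 41
        offs = np.linspace(-1.0, 1.0, n_scan)
        tt = z[:, None] + half[:, None] * offs[None, :]
        ff = (x[:, None] - self.A * np.sin(self.omega * tt)) ** 2 + (
            z[:, None] - tt
        ) ** 2
        t = tt[np.arange(len(p)), np.argmin(ff, axis=1)]
        for _ in range(40):
            s = self.A * np.sin(self.omega * t)
            c = self.A * self.omega * np.cos(self.omega * t)
            dx = x - s
            g = -dx * c - (z - t)
            h = c * c + dx * self.A * self.omega**2 * np.sin(self.omega * t) + 1.0
            h = np.maximum(h, 1e-9)
            t = t - np.clip(g / h, -half, half)
        dmin = np.sqrt(
            (x - self.A * np.sin(self.omega * t)) ** 2 + y * y + (z - t) ** 2
        )
        return dmin

    def inside(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership test (distance to centerline <= radius)."""
        return self.distance_to_centerline(points) <= self.radius + 1e-12


def build_substrate(d: float, L: float, A: float) -> UndulationSubstrate:
    return UndulationSubstrate(d=d, L=L, A=A)


MICRO_SUBSTRATE = dict(d=1.0, L=24.0, A=4.0)
MACRO_SUBSTRATE = dict(d=1.0, L=300.0, A=50.0)


@dataclasses.dataclass(frozen=True)
class WalkerParams:
    """Random-walk discretisation.

    ``dt`` is chosen (if None) as the largest value keeping the RMS step
    length sqrt(6 D0 dt) at or below d/4.
    """

    n_walkers: int = 100_000
    d0: float = D0_DEFAULT  # um^2/ms
    dt: float | None = None  # ms
    seed: int = 0

    def resolve_dt(self, substrate: UndulationSubstrate) -> float:
        if self.dt is not None:
            step = math.sqrt(6.0 * self.d0 * self.dt)
            if step > substrate.d / 4.0 + 1e-12:
                raise ValueError(
                    f"RMS step {step:.3g} um exceeds d/4 = {substrate.d / 4:.3g} um"
                )
            return self.dt
        return (substrate.d / 4.0) ** 2 / (6.0 * self.d0)


@dataclasses.dataclass(frozen=True)
class PGSEProtocol:
    """Finite-pulse PGSE: per-volume (b, g) plus shared timings delta/Delta.

    b = gamma^2 G^2 delta^2 (Delta - delta/3); q = gamma G delta is derived
    from b and the timings, so the gradient amplitude per shell follows.
    """

    scheme: GradientScheme
    delta: float = DELTA_SMALL_DEFAULT  # ms
    Delta: float = DELTA_BIG_DEFAULT  # ms

    def __post_init__(self) -> None:
        if not (0 < self.delta <= self.Delta):
            raise ValueError("need 0 < delta <= Delta")

    @property
    def duration(self) -> float:
        return self.Delta + self.delta

    @property
    def b_ms_um2(self) -> np.ndarray:
        """b converted from s/mm^2 to ms/um^2."""
        return self.scheme.bvals / 1000.0

    @property
    def q_per_um(self) -> np.ndarray:
        """q = gamma G delta (rad/um) per volume."""
        return np.sqrt(self.b_ms_um2 / (self.Delta - self.delta / 3.0))

    @property
    def gradient_amplitude_mT_per_m(self) -> np.ndarray:
        """Derived G per volume, in mT/m (provenance/reporting only)."""
        g_t_per_um = self.q_per_um / (GAMMA_MS * self.delta)  # T/um
        return g_t_per_um * 1e9

    @staticmethod
    def hcp_ya(
        delta: float = DELTA_SMALL_DEFAULT, Delta: float = DELTA_BIG_DEFAULT
    ) -> "PGSEProtocol":
        return PGSEProtocol(preset_scheme("hcp-ya"), delta, Delta)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _nearest_t(x, y, z, t0, A, omega):
    """Newton refinement of the nearest centerline parameter from t0."""
    t = t0
    for _ in range(12):
        s = A * math.sin(omega * t)
        c = A * omega * math.cos(omega * t)
        dx = x - s
        g = -dx * c - (z - t)
        h = c * c + dx * A * omega * omega * math.sin(omega * t) + 1.0
        if h < 1e-9:
            h = 1e-9
        dt_ = g / h
        if dt_ > 0.5:
            dt_ = 0.5
        elif dt_ < -0.5:
            dt_ = -0.5
        t -= dt_
        if abs(dt_) < 1e-10:
            break
    return t


@njit(cache=True, fastmath=True)
def _dist2(x, y, z, t, A, omega):
    dx = x - A * math.sin(omega * t)
    dz = z - t
    return dx * dx + y * y + dz * dz


@njit(cache=True, fastmath=True)
def _init_walkers(n, A, omega, L, radius, seed):
    """Uniform positions inside the tube by rejection in the bounding box."""
    np.random.seed(seed)
    pos = np.empty((n, 3))
    tnear = np.empty(n)
    xmax = A + radius
    count = 0
    while count < n:
        x = (2.0 * np.random.random() - 1.0) * xmax
        y = (2.0 * np.random.random() - 1.0) * radius
        z = np.random.random() * L
        # nearest parameter must lie within `radius` of z for inside points
        best_t = z
        best_f = _dist2(x, y, z, z, A, omega)
        for k in range(-6, 7):
            tk = z + k * radius / 6.0
            fk = _dist2(x, y, z, tk, A, omega)
            if fk < best_f:
                best_f = fk
                best_t = tk
        t = _nearest_t(x, y, z, best_t, A, omega)
        if _dist2(x, y, z, t, A, omega) <= radius * radius:
            pos[count, 0] = x
            pos[count, 1] = y
            pos[count, 2] = z
            tnear[count] = t
            count += 1
    return pos, tnear


@njit(cache=True, fastmath=True)
def _walk_and_integrate(
    pos,
    tnear,
    n_steps,
    sigma,
    A,
    omega,
    radius,
    i1_end,
    i2_start,
    i2_end,
    dt,
    seed,
    record_msd,
):
    """Advance all walkers n_steps; accumulate position-time integrals over
    the two gradient-pulse windows [0, i1_end) and [i2_start, i2_end).

    Elastic reflection: a step crossing the wall is split at the wall, the
    remainder mirrored about the local surface normal, up to 10 times; a
    step that still ends outside is rejected (walker stays put).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    s1 = np.zeros((n, 3))
    s2 = np.zeros((n, 3))
    n_reject = 0
    r2 = radius * radius
    msd = np.zeros((n_steps, 2)) if record_msd else np.zeros((1, 2))
    for w in range(n):
        x = pos[w, 0]
        y = pos[w, 1]
        z = pos[w, 2]
        t = tnear[w]
        x0 = x
        y0 = y
        z0 = z
        for step in range(n_steps):
            vx = np.random.normal() * sigma
            vy = np.random.normal() * sigma
            vz = np.random.normal() * sigma
            ox = x
            oy = y
            oz = z
            px = x
            py = y
            pz = z
            pt = t
            ok = True
            for _ in range(10):
                nx = px + vx
                ny = py + vy
                nz = pz + vz
                # distance at the stale parameter upper-bounds the true
                # distance; a cheap certain-inside test for most steps
                f_quick = _dist2(nx, ny, nz, pt, A, omega)
                if f_quick <= r2:
                    px = nx
                    py = ny
                    pz = nz
                    # one Newton refresh keeps the warm start current
                    s_ = A * math.sin(omega * pt)
                    c_ = A * omega * math.cos(omega * pt)
                    dx_ = px - s_
                    g_ = -dx_ * c_ - (pz - pt)
                    h_ = c_ * c_ + dx_ * A * omega * omega * math.sin(omega * pt) + 1.0
                    if h_ < 1e-9:
                        h_ = 1e-9
                    pt -= g_ / h_
                    ok = True
                    break
                nt = _nearest_t(nx, ny, nz, pt, A, omega)
                f = _dist2(nx, ny, nz, nt, A, omega)
                if f <= r2:
                    px = nx
                    py = ny
                    pz = nz
                    pt = nt
                    ok = True
                    break
                # locate wall crossing along the sub-step by secant + check
                rho0 = math.sqrt(_dist2(px, py, pz, pt, A, omega))
                rho1 = math.sqrt(f)
                denom = rho1 - rho0
                if denom < 1e-12:
                    ok = False
                    break
                s = (radius - rho0) / denom
                if s < 0.0:
                    s = 0.0
                elif s > 1.0:
                    s = 1.0
                cx = px + s * vx
                cy = py + s * vy
                cz = pz + s * vz
                ct = _nearest_t(cx, cy, cz, pt, A, omega)
                # surface normal = radial direction from centerline
                ex = cx - A * math.sin(omega * ct)
                ey = cy
                ez = cz - ct
                en = math.sqrt(ex * ex + ey * ey + ez * ez)
                if en < 1e-12:
                    ok = False
                    break
                ex /= en
                ey /= en
                ez /= en
                # pull the crossing point just inside the wall
                cxi = cx - 1e-9 * ex
                cyi = cy - 1e-9 * ey
                czi = cz - 1e-9 * ez
                # mirror the remaining displacement
                rx = (1.0 - s) * vx
                ry = (1.0 - s) * vy
                rz = (1.0 - s) * vz
                dot = rx * ex + ry * ey + rz * ez
                vx = rx - 2.0 * dot * ex
                vy = ry - 2.0 * dot * ey
                vz = rz - 2.0 * dot * ez
                px = cxi
                py = cyi
                pz = czi
                pt = ct
                ok = False  # not yet accepted; loop places the remainder
            if ok or _dist2(px, py, pz, pt, A, omega) <= r2:
                x = px
                y = py
                z = pz
                t = pt
            else:
                n_reject += 1
            # trapezoid rule: the walker path is piecewise linear in time,
            # so the position-time integral over a step is the midpoint
            if step < i1_end:
                s1[w, 0] += 0.5 * (ox + x) * dt
                s1[w, 1] += 0.5 * (oy + y) * dt
                s1[w, 2] += 0.5 * (oz + z) * dt
            elif i2_start <= step < i2_end:
                s2[w, 0] += 0.5 * (ox + x) * dt
                s2[w, 1] += 0.5 * (oy + y) * dt
                s2[w, 2] += 0.5 * (oz + z) * dt
            if record_msd:
                dxm = x - x0
                dzm = z - z0
                msd[step, 0] += dzm * dzm
                msd[step, 1] += dxm * dxm + (y - y0) * (y - y0)
        pos[w, 0] = x
        pos[w, 1] = y
        pos[w, 2] = z
        tnear[w] = t
    if record_msd:
        msd /= n
    return s1, s2, n_reject, msd


# ---------------------------------------------------------------------------
# public simulation API
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class WalkResult:
    """Final positions plus per-walker position integrals over the pulses."""

    positions: np.ndarray  # (n, 3) final positions, um
    s1: np.ndarray  # (n, 3) integral of r(t) dt over pulse 1, um*ms
    s2: np.ndarray  # (n, 3) integral over pulse 2
    dt: float  # ms
    delta_eff: float  # ms, pulse duration on the step grid
    Delta_eff: float  # ms, pulse separation on the step grid
    n_rejected: int
    n_steps: int
    msd: np.ndarray | None = None  # optional (n_steps, 2): axial, transverse


def simulate_walk(
    substrate: UndulationSubstrate,
    params: WalkerParams,
    protocol: PGSEProtocol | None = None,
    total_time: float | None = None,
    record_msd: bool = False,
) -> WalkResult:
    """Run the restricted random walk and accumulate PGSE phase integrals.

    If ``protocol`` is given, the step grid is aligned with the pulse
    timings (dt divides delta; Delta is rounded to the step grid and the
    effective value reported).  Otherwise walkers run for ``total_time``
    with no phase accumulation (used by the diffusion-propagator checks).
    """
    dt_max = params.resolve_dt(substrate)
    if protocol is not None:
        m1 = max(1, math.ceil(protocol.delta / dt_max))
        dt = protocol.delta / m1
        i1_end = m1
        i2_start = int(round(protocol.Delta / dt))
        i2_end = i2_start + m1
        n_steps = i2_end
        delta_eff = m1 * dt
        Delta_eff = i2_start * dt
    else:
        if total_time is None:
            raise ValueError("need protocol or total_time")
        n_steps = max(1, math.ceil(total_time / dt_max))
        dt = total_time / n_steps
        i1_end = i2_start = i2_end = 0
        delta_eff = Delta_eff = 0.0
    sigma = math.sqrt(2.0 * params.d0 * dt)

    seed = int(params.seed) % (2**31 - 1)
    pos, tnear = _init_walkers(
        params.n_walkers,
        substrate.A,
        substrate.omega,
        substrate.L,
        substrate.radius,
        seed,
    )
    s1, s2, n_rej, msd = _walk_and_integrate(
        pos,
        tnear,
        n_steps,
        sigma,
        substrate.A,
        substrate.omega,
        substrate.radius,
        i1_end,
        i2_start,
        i2_end,
        dt,
        seed + 1,
        record_msd,
    )
    if n_rej > 0.001 * params.n_walkers * n_steps:
        import warnings

        warnings.warn(
            f"{n_rej} rejected steps (> 0.1% of proposals); reflections "
            "failed to converge unusually often",
            stacklevel=2,
        )
    return WalkResult(
        positions=pos,
        s1=s1,
        s2=s2,
        dt=dt,
        delta_eff=delta_eff,
        Delta_eff=Delta_eff,
        n_rejected=int(n_rej),
        n_steps=n_steps,
        msd=msd if record_msd else None,
    )


def synthesize_pgse_signal(walk: WalkResult, protocol: PGSEProtocol) -> np.ndarray:
    """Per-(b, g) signal attenuation E = |mean_w exp(i phi_w)|.

    Finite rectangular pulses: phi = (q / delta) * g . (S1 - S2), with S1/S2
    the position-time integrals over the two pulses.
    """
    if walk.s1 is None or walk.delta_eff <= 0:
        raise ValueError("walk was run without a protocol; no phase integrals")
    q = np.sqrt(protocol.b_ms_um2 / (walk.Delta_eff - walk.delta_eff / 3.0))
    diff = walk.s1 - walk.s2  # (n, 3)
    proj = diff @ protocol.scheme.bvecs.T  # (n, N)
    phases = proj * (q / walk.delta_eff)[None, :]
    e = np.abs(np.exp(1j * phases).mean(axis=0))
    return e


def undulation_asymmetry(
    substrate: UndulationSubstrate,
    protocol: PGSEProtocol | None = None,
    params: WalkerParams | None = None,
    snr: float | None = None,
    n_noisy: int = 200,
    seed: int = 0,
):
    """Per-shell lambda2/lambda3 from the Monte Carlo signal.

    Returns a DataFrame with one row per shell: noise-free asymmetry, the
    angular deviation of V1 from z and V2 from x (the undulation plane), and
    (if ``snr`` is given) the mean fitted asymmetry over ``n_noisy`` Rician
    noise realisations.
    """
    import pandas as pd

    from .crossing_sim import add_rician_noise
    from .tensor_metrics import fit_dti_iwls, radial_asymmetry

    protocol = protocol or PGSEProtocol.hcp_ya()
    params = params or WalkerParams(seed=seed)
    walk = simulate_walk(substrate, params, protocol=protocol)
    signal = synthesize_pgse_signal(walk, protocol)

    scheme = protocol.scheme
    rng = np.random.default_rng(seed + 17)
    rows = []
    for b in scheme.shells:
        t = fit_dti_iwls(signal[None, :], scheme, shell=b)
        asym = float(radial_asymmetry(t)[0])
        v1 = t.v(1)[0]
        v2 = t.v(2)[0]
        ang1 = math.degrees(math.acos(min(1.0, abs(v1[2]))))
        ang2 = math.degrees(math.acos(min(1.0, abs(v2[0]))))
        row = {
            "b": float(b),
            "asymmetry": asym,
            "v1_from_z_deg": ang1,
            "v2_from_x_deg": ang2,
            "n_rejected": walk.n_rejected,
        }
        if snr is not None:
            noisy = np.stack(
                [add_rician_noise(signal, snr, rng) for _ in range(n_noisy)]
            )
            tn = fit_dti_iwls(noisy, scheme, shell=b)
            row["asymmetry_noisy"] = float(np.nanmean(radial_asymmetry(tn)))
        rows.append(row)
    return pd.DataFrame(rows)
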