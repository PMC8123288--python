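"""Rate laws, parameter set and state containers for HCC dynamics under TKI therapy.

The model couples five processes in a patient with advanced hepatocellular
carcinoma (HCC) treated with an oral tyrosine-kinase inhibitor (TKI,
sorafenib or regorafenib):

* cancer-cell abundance ``C`` growing with a sub-linear power law
  ``xi1 * C**xi2`` (per-cell productivity falls as the mass grows) and
  first-order death ``xi4 * C``;
* relative tumor vasculature ``V`` (1.0 = pre-therapy equilibrium), whose
  neo-angiogenesis is throttled by the drug and whose decay can be
  accelerated by the drug (``alpha3`` term);
* serum alpha-fetoprotein ``A`` (AFP, ng/mL), produced at ``omega1 * C``;
* serum PIVKA-II (mAU/mL), decomposed into a cell-derived pool
  (``pi1 * C**pi2`` production), an ischemia "spike" pool and a
  drug-toxicity pool, all decaying at ``pi3``;
* plasma drug level ``F`` driven by the daily oral dose ``D(t)`` (mg/day)
  with first-order elimination, plus a delayed effective level ``G``
  (first-order lag) that mediates pharmacodynamics.

Drug effectiveness enters through two saturating fractions,

    eps_v = 1 / (1 + theta1 * G)     (remaining neo-angiogenesis)
    eps_r = 1 / (1 + psi1  * G)      (remaining cell replication)

so ``1 - eps`` is the fractional reduction caused by the drug.

Units throughout: time in days, AFP in ng/mL, PIVKA-II in mAU/mL, dose in
mg/day, drug level in mg/mL, cancer cells in "cell-units" anchored to CT
tumor volume via :func:`estimate_initial_cells`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence, Union

import numpy as np

__all__ = [
    "ModelParameters",
    "StateVector",
    "DoseSchedule",
    "STATE_NAMES",
    "PARAM_KEYS",
    "TABLE_PARAM_KEYS",
    "epsilon_vascular",
    "epsilon_replication",
    "steady_state_drug",
    "mean_lifetime",
    "growth_rate",
    "closed_form_growth",
    "time_to_reach",
    "tox_production_rate",
    "spike_production_rate",
    "rhs",
    "estimate_initial_cells",
    "tumor_vascular_index",
    "pretherapy_state",
]

#: parameter keys printed in the per-patient best-fit table
TABLE_PARAM_KEYS = (
    "xi1", "xi2", "xi4", "omega1", "omega2", "pi1", "pi2", "pi3",
    "mu1", "mu2", "theta1", "alpha2", "alpha3", "psi1",
)

#: implementation keys (effectiveness lag, alpha3 normalization, spike and
#: toxicity shape, cell density, CT volume-to-cell conversion)
EXTRA_PARAM_KEYS = (
    "mu3", "g_ref", "pi4", "pi5", "sigma_sp", "t_sp", "tau_sp", "R", "kappa",
)

PARAM_KEYS = TABLE_PARAM_KEYS + EXTRA_PARAM_KEYS

_STRICTLY_POSITIVE = ("xi4", "omega2", "pi3", "mu2", "mu3", "g_ref", "tau_sp")


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set for one patient.

    Attributes
    ----------
    xi1
        Rate constant of cancer-cell production, C x day^-1.
    xi2
        Cell-count exponent of production (dimensionless, < 1 means per-cell
        productivity declines with tumor mass).
    xi4
        Decay constant of cancer cells, day^-1.
    omega1, omega2
        AFP production rate per cell-unit and AFP decay constant, day^-1.
    pi1, pi2, pi3
        PIVKA-II production rate per cell-unit, cell-count exponent of
        production, and decay constant (day^-1).
    mu1
        Plasma-drug increase per 1 mg/day oral intake, (mg/mL) x day^-1 per
        (mg/day).
    mu2
        Plasma-drug decay constant, day^-1.
    mu3
        First-order rate of the lag between drug bioavailability and actual
        effectiveness, day^-1.  The default 0.15/day makes the combined
        PK + lag reach ~95% of its steady effect about three weeks after the
        start of treatment.
    theta1, psi1
        Anti-vascular and anti-replicative drug effectiveness coefficients,
        per unit of (delayed) drug level.
    alpha2
        Natural decay constant of tumor vasculature, day^-1.
    alpha3
        Additional drug-dependent vasculature decay (dimensionless
        multiplier).  ``alpha3 = 0`` makes vasculature decay independent of
        drug level.
    g_ref
        Reference drug level normalizing the ``alpha3`` term; the
        drug-dependent decay rate is ``alpha3 * G / g_ref``.
    pi4, pi5
        Toxicity-driven PIVKA-II production ``pi4 * F * t**pi5``.
    sigma_sp, t_sp, tau_sp
        Amplitude (day^-1), onset delay (days) and pulse time-scale (days)
        of the ischemic PIVKA-II spike after therapy start.
    R
        Cancer-cell density in the tumor mass (cell-units per cm^3 scale
        factor of the spike amplitude).
    kappa
        Cell-units per cm^3 of tumor used to convert CT total tumor volume
        into an initial cell count (patient-specific; see
        :func:`estimate_initial_cells`).
    """

    xi1: float
    xi2: float
    xi4: float
    omega1: float
    omega2: float
    pi1: float
    pi2: float
    pi3: float
    mu1: float
    mu2: float
    theta1: float
    psi1: float
    alpha2: float
    alpha3: float
    mu3: float = 0.15
    g_ref: float = 0.09
    pi4: float = 0.0
    pi5: float = 0.0
    sigma_sp: float = 0.0
    t_sp: float = 0.0
    tau_sp: float = 14.0
    R: float = 1.0
    kappa: float = 2.561e4

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name!r} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name!r} must be >= 0, got {v!r}")
        for name in _STRICTLY_POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be > 0")
        if not 0 < self.xi2 <= 1.3:
            raise ValueError(f"xi2 must be in (0, 1.3], got {self.xi2}")
        if not 0 < self.pi2 <= 1.3:
            raise ValueError(f"pi2 must be in (0, 1.3], got {self.pi2}")

    # -- convenience -------------------------------------------------------

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        """Flat key -> value mapping using the transliterated symbol names."""
        return {k: float(getattr(self, k)) for k in PARAM_KEYS}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        unknown = set(d) - set(PARAM_KEYS)
        if unknown:
            raise ValueError(f"unknown parameter key(s): {sorted(unknown)}")
        missing = set(TABLE_PARAM_KEYS) - set(d)
        if missing:
            raise ValueError(f"missing required parameter key(s): {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @property
    def carrying_capacity(self) -> float:
        """Drug-free fixed point ``(xi1/xi4)**(1/(1-xi2))`` (requires xi2 < 1).

        Returns ``inf`` when the fixed point overflows a double (xi2 very
        close to 1 with xi1 > xi4).
        """
        if self.xi2 >= 1:
            raise ValueError("carrying capacity defined only for xi2 < 1")
        try:
            return (self.xi1 / self.xi4) ** (1.0 / (1.0 - self.xi2))
        except OverflowError:
            return math.inf


STATE_NAMES = ("C", "V", "A", "P_c", "P_sp", "P_tox", "F", "G")


@dataclass
class StateVector:
    """Instantaneous model state.

    ``C`` cancer cells (cell-units); ``V`` relative vasculature (1.0 =
    pre-therapy equilibrium); ``A`` serum AFP (ng/mL); ``P_c``/``P_sp``/
    ``P_tox`` cell-derived, spike and toxicity PIVKA-II pools (mAU/mL);
    ``F`` plasma drug level; ``G`` delayed effective drug level (mg/mL).
    """

    C: float = 0.0
    V: float = 1.0
    A: float = 0.0
    P_c: float = 0.0
    P_sp: float = 0.0
    P_tox: float = 0.0
    F: float = 0.0
    G: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"state component {name!r} must be >= 0")

    @property
    def pivka_total(self) -> float:
        """Observed PIVKA-II = cell-derived + spike + toxicity pools."""
        return self.P_c + self.P_sp + self.P_tox

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "StateVector":
        y = np.maximum(np.asarray(y, dtype=float), 0.0)
        return cls(**dict(zip(STATE_NAMES, y)))


class DoseSchedule:
    """Piecewise-constant daily drug intake ``D(t)`` in mg/day.

    Segments are half-open intervals ``[start, end)``; the dose is zero
    outside all segments.  Cyclic regimens (e.g. regorafenib given daily for
    three weeks followed by one week off) expand deterministically into
    explicit segments via :meth:`cycled`.
    """

    def __init__(self, segments: Iterable[Sequence[float]] = ()):  # noqa: D107
        segs = sorted((float(a), float(b), float(d)) for a, b, d in segments)
        for a, b, d in segs:
            if not b > a:
                raise ValueError(f"segment end must exceed start: [{a}, {b})")
            if d < 0:
                raise ValueError(f"dose must be >= 0, got {d}")
        for (a0, b0, _), (a1, _, _) in zip(segs, segs[1:]):
            if a1 < b0:
                raise ValueError(
                    f"overlapping dose segments: [{a0}, {b0}) and starting {a1}"
                )
        self.segments = tuple(segs)

    @classmethod
    def constant(cls, dose: float, start: float = 0.0, end: float = math.inf) -> "DoseSchedule":
        """A single constant dose from ``start`` (default therapy start) onward."""
        if dose == 0:
            return cls()
        return cls([(start, end, dose)])

    @classmethod
    def cycled(
        cls,
        dose: float,
        days_on: float,
        days_off: float,
        start: float = 0.0,
        end: float = 1825.0,
    ) -> "DoseSchedule":
        """Expand an on/off cycling regimen into explicit segments."""
        if days_on <= 0 or days_off < 0:
            raise ValueError("days_on must be > 0 and days_off >= 0")
        segs = []
        t = start
        period = days_on + days_off
        while t < end:
            segs.append((t, min(t + days_on, end), dose))
            t += period
        return cls(segs)

    def dose_at(self, t):
        """Dose (mg/day) at time(s) ``t``; 0 outside all segments."""
        t_arr = np.asarray(t, dtype=float)
        out = np.zeros_like(t_arr)
        for a, b, d in self.segments:
            out = np.where((t_arr >= a) & (t_arr < b), d, out)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def breakpoints(self, t0: float, t1: float) -> list:
        """Segment edges strictly inside ``(t0, t1)`` (integration restarts)."""
        pts = set()
        for a, b, _ in self.segments:
            for x in (a, b):
                if t0 < x < t1 and math.isfinite(x):
                    pts.add(x)
        return sorted(pts)

    def __eq__(self, other) -> bool:
        return isinstance(other, DoseSchedule) and self.segments == other.segments

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DoseSchedule({list(self.segments)!r})"


# ---------------------------------------------------------------------------
# drug-effectiveness algebra and closed forms
# ---------------------------------------------------------------------------

def epsilon_vascular(G, theta1):
    """Remaining fraction of neo-angiogenesis, ``1 / (1 + theta1 * G)``.

    Equals 1 with no drug and decreases strictly with the delayed drug
    level ``G``; ``100 * (1 - eps)`` is the percent reduction.
    """
    G = np.asarray(G, dtype=float)
    if np.any(G < 0) or theta1 < 0:
        raise ValueError("drug level and theta1 must be >= 0")
    out = 1.0 / (1.0 + theta1 * G)
    return float(out) if out.ndim == 0 else out


def epsilon_replication(G, psi1):
    """Remaining fraction of cancer-cell replication, ``1 / (1 + psi1 * G)``."""
    G = np.asarray(G, dtype=float)
    if np.any(G < 0) or psi1 < 0:
        raise ValueError("drug level and psi1 must be >= 0")
    out = 1.0 / (1.0 + psi1 * G)
    return float(out) if out.ndim == 0 else out


def steady_state_drug(mu1: float, mu2: float, dose_mg_per_day: float) -> float:
    """Fixed point ``mu1 * D / mu2`` of ``dF/dt = mu1*D - mu2*F``."""
    if mu2 <= 0:
        raise ValueError("mu2 must be > 0")
    if mu1 < 0 or dose_mg_per_day < 0:
        raise ValueError("mu1 and dose must be >= 0")
    return mu1 * dose_mg_per_day / mu2


def mean_lifetime(decay_constant: float) -> float:
    """Mean lifetime 1/k (days) of a first-order decay with constant ``k``."""
    if decay_constant <= 0:
        raise ValueError("decay constant must be > 0")
    return 1.0 / decay_constant


def growth_rate(C: float, p: ModelParameters) -> float:
    """Per-capita net growth rate ``xi1 * C**(xi2-1) - xi4`` (drug-free, V=1)."""
    if C <= 0:
        raise ValueError("C must be > 0")
    return p.xi1 * C ** (p.xi2 - 1.0) - p.xi4


def closed_form_growth(C_init: float, t, p: ModelParameters):
    """Exact drug-free solution of ``dC/dt = xi1*C**xi2 - xi4*C``.

    Uses the substitution ``u = C**(1-xi2)``, which turns the power-law
    growth into a linear ODE:

        u(t) = xi1/xi4 + (u0 - xi1/xi4) * exp(-(1-xi2) * xi4 * t)

    Valid for ``xi2 < 1``; negative ``t`` runs the growth backwards.
    """
    if C_init <= 0:
        raise ValueError("C_init must be > 0")
    if p.xi2 >= 1:
        raise ValueError("closed form requires xi2 < 1; integrate numerically")
    t = np.asarray(t, dtype=float)
    q = 1.0 - p.xi2
    u_inf = p.xi1 / p.xi4
    u = u_inf + (C_init ** q - u_inf) * np.exp(-q * p.xi4 * t)
    if np.any(u <= 0):
        raise ValueError("trajectory leaves the positive domain (t too negative)")
    out = u ** (1.0 / q)
    return float(out) if out.ndim == 0 else out


def time_to_reach(C_init: float, C_target: float, p: ModelParameters) -> float:
    """Days for the drug-free tumor to grow from ``C_init`` to ``C_target``.

    Analytic inversion of :func:`closed_form_growth`; only targets strictly
    below the carrying capacity are reachable.
    """
    if not 0 < C_init <= C_target:
        raise ValueError("require 0 < C_init <= C_target")
    if C_init == C_target:
        return 0.0
    if p.xi2 >= 1:
        raise ValueError("closed form requires xi2 < 1")
    q = 1.0 - p.xi2
    u_inf = p.xi1 / p.xi4
    # reachability in u-space avoids overflowing the capacity itself
    if C_target ** q >= u_inf:
        raise ValueError(
            f"C_target {C_target:g} unreachable: at or above carrying capacity"
        )
    num = C_target ** q - u_inf
    den = C_init ** q - u_inf
    return -math.log(num / den) / (q * p.xi4)


def tox_production_rate(t, F, pi4: float, pi5: float):
    """Toxicity-driven PIVKA-II production ``pi4 * F * t**pi5`` (mAU/mL/day).

    Models drug anti-vascular toxicity on non-neoplastic hepatocytes; zero
    before therapy start (t < 0 is clamped) and zero at t = 0 when pi5 > 0.
    """
    t = np.asarray(t, dtype=float)
    F = np.asarray(F, dtype=float)
    tt = np.maximum(t, 0.0)
    # 0**pi5 is 0 for pi5 > 0 and 1 for pi5 == 0, matching the t = 0 limit
    out = np.where(t >= 0, pi4 * F * tt ** pi5, 0.0)
    return float(out) if out.ndim == 0 else out


def _pulse(s, tau: float):
    """Normalized delayed pulse ``(s/tau) * exp(1 - s/tau)``, peak 1 at s = tau."""
    s = np.maximum(s, 0.0)
    x = s / tau
    return x * np.exp(1.0 - x)


def spike_production_rate(t, P0: float, p: ModelParameters):
    """Ischemic PIVKA-II spike production (mAU/mL/day) after therapy start.

    The spike amplitude is proportional to the PIVKA-II level at the start
    of therapy ``P0`` and to the cell density ``R``; its time course is a
    delayed unimodal pulse with onset ``t_sp`` and scale ``tau_sp``
    (peak production ``sigma_sp * P0 * R`` at ``t = t_sp + tau_sp``).
    """
    if P0 < 0:
        raise ValueError("P0 must be >= 0")
    t = np.asarray(t, dtype=float)
    out = p.sigma_sp * P0 * p.R * _pulse(t - p.t_sp, p.tau_sp)
    return float(out) if out.ndim == 0 else out


DoseLike = Union[float, DoseSchedule, Callable[[float], float]]


def rhs(t: float, y, p: ModelParameters, dose: DoseLike, P0: float = 0.0) -> np.ndarray:
    """Time derivative of the full state ``(C, V, A, P_c, P_sp, P_tox, F, G)``.

    ``dose`` may be a constant (mg/day), a :class:`DoseSchedule`, or a
    callable ``t -> mg/day``.  Components are clamped at zero before
    evaluating the rate laws (positivity floor), so the integrator cannot be
    driven by spurious small negative values.
    """
    C, V, A, Pc, Psp, Ptox, F, G = np.maximum(np.asarray(y, dtype=float), 0.0)
    if isinstance(dose, DoseSchedule):
        D = dose.dose_at(t)
    elif callable(dose):
        D = float(dose(t))
    else:
        D = float(dose)
    ev = 1.0 / (1.0 + p.theta1 * G)
    er = 1.0 / (1.0 + p.psi1 * G)
    dF = p.mu1 * D - p.mu2 * F
    dG = p.mu3 * (F - G)
    dV = p.alpha2 * ev - (p.alpha2 + p.alpha3 * G / p.g_ref) * V
    dC = p.xi1 * er * V * C ** p.xi2 - p.xi4 * C
    dA = p.omega1 * C - p.omega2 * A
    dPc = p.pi1 * C ** p.pi2 - p.pi3 * Pc
    dPsp = spike_production_rate(t, P0, p) - p.pi3 * Psp
    dPtox = tox_production_rate(t, F, p.pi4, p.pi5) - p.pi3 * Ptox
    return np.array([dC, dV, dA, dPc, dPsp, dPtox, dF, dG])


# ---------------------------------------------------------------------------
# imaging conversions
# ---------------------------------------------------------------------------

def estimate_initial_cells(TTV: float, occupancy: float, kappa: float) -> float:
    """Cancer-cell count anchored to CT total tumor volume (cm^3).

    ``occupancy`` is the fraction of the tumor volume occupied by HCC cells
    (0.5 under the assumption that HCC cells have the volume of normal
    hepatocytes and occupy half of the tumor volume); ``kappa`` converts
    occupied cm^3 to cell-units and is patient-specific.
    """
    if TTV <= 0:
        raise ValueError("TTV must be > 0")
    if not 0 < occupancy <= 1:
        raise ValueError("occupancy must be in (0, 1]")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    return occupancy * TTV * kappa


def tumor_vascular_index(tumor_HU_arterial: float, liver_HU_arterial: float) -> float:
    """Arterial-phase HU difference between tumor and non-tumor liver.

    Negative values indicate hypo-vascular lesions.
    """
    return float(tumor_HU_arterial) - float(liver_HU_arterial)


def pretherapy_state(p: ModelParameters, C0: float) -> StateVector:
    """Pre-therapy state on the growing drug-free trajectory at cell count ``C0``.

    Vasculature sits at its drug-free equilibrium (V = 1) and the serum
    biomarkers at the quasi-steady level of a linear pool fed by an
    exponentially growing source: a pool with decay ``k`` fed at rate
    ``u(t)`` growing at per-capita rate ``g`` settles at ``u / (k + g)``.
    """
    if C0 <= 0:
        raise ValueError("C0 must be > 0")
    g = growth_rate(C0, p)
    ga = max(p.omega2 + g, 0.1 * p.omega2)
    gp = max(p.pi3 + p.pi2 * g, 0.1 * p.pi3)
    A = p.omega1 * C0 / ga
    P = p.pi1 * C0 ** p.pi2 / gp
    return StateVector(C=C0, V=1.0, A=A, P_c=P)
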