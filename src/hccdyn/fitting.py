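"""Per-patient parameter estimation and cohort-level summaries.

Fitting minimizes a weighted sum of squared log10 residuals of the model
AFP and PIVKA-II trajectories against the observed serum levels (the
biomarkers span three or more decades, so log-scale residuals make the
objective scale-invariant), plus an optional linear residual on
baseline-normalized tumor vascularization index (TVI) against the model
vasculature when at least three TVI points exist.

The optimizer is a bounded simplex (Nelder-Mead) local search run from a
Latin-hypercube set of multi-starts in log10 parameter space; results are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .cases import RESPONSE_GROUPS, load_case_fixtures, response_group
from .model import (
    DoseSchedule,
    ModelParameters,
    PARAM_KEYS,
    TABLE_PARAM_KEYS,
    closed_form_growth,
    pretherapy_state,
)
from .simulate import SimulationError, simulate

__all__ = [
    "AssayLimits",
    "PatientDataset",
    "FitSpec",
    "FitResult",
    "CohortSummary",
    "objective",
    "fit_patient",
    "cohort_medians",
    "load_case_fixtures",
]

#: number of TVI observations required before the TVI series joins the fit
MIN_TVI_POINTS = 3

#: minimum on-therapy observations per fitted biomarker series
MIN_ON_THERAPY_OBS = 3

#: weight applied to below-detection values replaced by LOD/2
LOD_DOWNWEIGHT = 0.25


@dataclass(frozen=True)
class AssayLimits:
    """Dynamic range of the serum immunoassays.

    The PIVKA-II chemiluminescent enzyme immunoassay reports values between
    1.37 and 75,000 mAU/mL; AFP limits default to a 1 ng/mL detection limit
    with an effectively unbounded upper range after autodilution.
    """

    afp_lower: float = 1.0
    afp_upper: float = math.inf
    pivka_lower: float = 1.37
    pivka_upper: float = 75000.0


DEFAULT_ASSAY = AssayLimits()


def _prepare_series(times, values, lod: float):
    """Sort a series and apply the below-LOD rule (LOD/2 value, down-weight)."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise ValueError("times and values must have the same length")
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    if np.any(v <= 0):
        raise ValueError("observed biomarker values must be > 0 (LOD handling "
                         "replaces censored values before construction)")
    w = np.ones_like(v)
    below = v < lod
    v = np.where(below, lod / 2.0, v)
    w[below] = LOD_DOWNWEIGHT
    return t, v, w


@dataclass
class PatientDataset:
    """Observed serum/imaging time series for one patient.

    Times are days relative to therapy start (negative = pre-therapy).
    ``c0`` is the cancer-cell count at therapy start (anchored to CT tumor
    volume); ``baseline_pivka`` is the PIVKA-II level at therapy start,
    required whenever the ischemic-spike amplitude is fitted.
    """

    afp_times: np.ndarray
    afp: np.ndarray
    pivka_times: np.ndarray
    pivka: np.ndarray
    schedule: DoseSchedule
    c0: float
    tvi_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    tvi: np.ndarray = field(default_factory=lambda: np.empty(0))
    ttv_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    ttv: np.ndarray = field(default_factory=lambda: np.empty(0))
    baseline_afp: float | None = None
    baseline_pivka: float | None = None
    baseline_ttv: float | None = None
    response: str | None = None
    afp_weights: np.ndarray | None = None
    pivka_weights: np.ndarray | None = None
    assay: AssayLimits = field(default_factory=AssayLimits)

    def __post_init__(self) -> None:
        self.afp_times, self.afp, w_a = _prepare_series(
            self.afp_times, self.afp, self.assay.afp_lower)
        self.pivka_times, self.pivka, w_p = _prepare_series(
            self.pivka_times, self.pivka, self.assay.pivka_lower)
        if self.afp_weights is None:
            self.afp_weights = w_a
        if self.pivka_weights is None:
            self.pivka_weights = w_p
        self.tvi_times = np.asarray(self.tvi_times, dtype=float)
        self.tvi = np.asarray(self.tvi, dtype=float)
        if self.c0 <= 0:
            raise ValueError("c0 must be > 0")
        if self.baseline_pivka is None and len(self.pivka):
            at0 = np.argmin(np.abs(self.pivka_times))
            if abs(self.pivka_times[at0]) <= 7:
                self.baseline_pivka = float(self.pivka[at0])
        if self.baseline_afp is None and len(self.afp):
            at0 = np.argmin(np.abs(self.afp_times))
            if abs(self.afp_times[at0]) <= 7:
                self.baseline_afp = float(self.afp[at0])

    def n_on_therapy(self, series: str) -> int:
        t = getattr(self, f"{series}_times")
        return int(np.sum(t >= 0))

    @property
    def use_tvi(self) -> bool:
        return len(self.tvi) >= MIN_TVI_POINTS

    def to_frame(self) -> pd.DataFrame:
        """Wide observation table (blank = missing), one row per time point."""
        frames = []
        for name, col in (("afp", "afp_ng_ml"), ("pivka", "pivka_mau_ml"),
                          ("tvi", "tvi_hu"), ("ttv", "ttv_cm3")):
            t = getattr(self, f"{name}_times")
            v = getattr(self, name)
            if len(t):
                frames.append(pd.DataFrame({"time_days": t, col: v}))
        if not frames:
            return pd.DataFrame(columns=["time_days"])
        df = frames[0]
        for f2 in frames[1:]:
            df = df.merge(f2, on="time_days", how="outer")
        return df.sort_values("time_days").reset_index(drop=True)

    @classmethod
    def from_frame(
        cls,
        obs: pd.DataFrame,
        schedule: DoseSchedule,
        c0: float,
        **kwargs,
    ) -> "PatientDataset":
        """Build from the observation-table dialect (columns ``time_days``,
        ``afp_ng_ml``, ``pivka_mau_ml``, ``tvi_hu``, ``ttv_cm3``)."""
        def series(col):
            if col not in obs.columns:
                return np.empty(0), np.empty(0)
            sub = obs[["time_days", col]].dropna()
            return sub["time_days"].to_numpy(float), sub[col].to_numpy(float)

        t_a, v_a = series("afp_ng_ml")
        t_p, v_p = series("pivka_mau_ml")
        t_v, v_v = series("tvi_hu")
        t_t, v_t = series("ttv_cm3")
        return cls(
            afp_times=t_a, afp=v_a, pivka_times=t_p, pivka=v_p,
            tvi_times=t_v, tvi=v_v, ttv_times=t_t, ttv=v_t,
            schedule=schedule, c0=c0, **kwargs,
        )


@dataclass
class FitSpec:
    """What to fit and how.

    ``free`` maps parameter names (any model key, plus ``"c0"``) to finite
    positive ``(lower, upper)`` bounds; everything else is fixed at the
    values of ``base`` (optionally overridden through ``fixed``).
    """

    base: ModelParameters
    free: dict
    fixed: dict = field(default_factory=dict)
    weights: dict = field(default_factory=lambda: {"afp": 1.0, "pivka": 1.0, "tvi": 1.0})
    multi_start: int = 16
    seed: int = 20210425
    rtol: float = 1e-8
    atol: float = 1e-10
    max_evals: int = 600

    def __post_init__(self) -> None:
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        valid = set(PARAM_KEYS) | {"c0"}
        for name, (lo, hi) in self.free.items():
            if name not in valid:
                raise ValueError(f"unknown free parameter {name!r}")
            if not (0 < lo < hi < math.inf):
                raise ValueError(f"bounds for {name!r} must be finite and positive")
        if self.fixed:
            self.base = self.base.replace(**{k: v for k, v in self.fixed.items()
                                             if k != "c0"})

    def build(self, theta: dict, c0_default: float):
        """Assemble (ModelParameters, c0) from a free-parameter dict."""
        c0 = float(theta.pop("c0")) if "c0" in theta else float(
            self.fixed.get("c0", c0_default))
        return self.base.replace(**theta), c0


@dataclass
class FitResult:
    """Best-fit parameters with diagnostics."""

    params: ModelParameters
    c0: float
    objective: float
    residual_rms: dict
    status: str
    seed: int
    n_starts: int
    n_evals: int
    free_names: tuple
    degenerate: bool = False
    degeneracy_note: str = ""

    def estimates(self) -> dict:
        out = {k: getattr(self.params, k) for k in self.free_names if k != "c0"}
        if "c0" in self.free_names:
            out["c0"] = self.c0
        return out


def _initial_state(p: ModelParameters, c0: float, t_start: float):
    """Model state at the earliest observation time (pre-therapy growth)."""
    if t_start < 0:
        c_start = closed_form_growth(c0, t_start, p)
    else:
        c_start = c0
    return pretherapy_state(p, c_start)


def _model_at(p, dataset, c0, rtol, atol):
    """Simulate and return model values at every observation time."""
    times = [np.zeros(1)]
    for name in ("afp", "pivka", "tvi"):
        times.append(getattr(dataset, f"{name}_times"))
    grid = np.unique(np.concatenate(times))
    t_start = min(grid[0], 0.0)
    if grid[0] > t_start:
        grid = np.concatenate(([t_start], grid))
    init = _initial_state(p, c0, t_start)
    P0 = dataset.baseline_pivka
    if P0 is None:
        P0 = init.pivka_total if t_start == 0 else float(
            pretherapy_state(p, c0).pivka_total)
    traj = simulate(p, dataset.schedule, init, grid, P0=P0, rtol=rtol, atol=atol)
    idx = {t: i for i, t in enumerate(traj.t)}
    def pick(ts, arr):
        return np.array([arr[idx[t]] for t in ts])
    A = pick(dataset.afp_times, traj.A)
    P = pick(dataset.pivka_times, traj.pivka_total)
    V = pick(dataset.tvi_times, traj.V) if dataset.use_tvi else np.empty(0)
    V0 = traj.V[idx[0.0]]
    return A, P, V, V0


_LOG_FLOOR = 1e-12


def objective(
    p: ModelParameters,
    dataset: PatientDataset,
    spec: FitSpec | None = None,
    *,
    c0: float | None = None,
    return_parts: bool = False,
):
    """Weighted sum of squared log10 residuals (AFP, PIVKA-II, optional TVI).

    TVI residuals are linear on baseline-normalized values (TVI can be
    negative for hypo-vascular lesions, so a log scale does not apply).
    Model predictions are clipped to the assay dynamic range before the
    comparison, because the observations are reported that way too (a
    trajectory far below the detection limit should match a censored
    observation, not be penalized for its unobservable depth).
    A failed simulation yields ``inf`` so optimizers can step over it.
    """
    weights = spec.weights if spec is not None else {"afp": 1.0, "pivka": 1.0, "tvi": 1.0}
    rtol = spec.rtol if spec is not None else 1e-8
    atol = spec.atol if spec is not None else 1e-10
    c0 = dataset.c0 if c0 is None else c0
    try:
        A, P, V, V0 = _model_at(p, dataset, c0, rtol, atol)
    except (SimulationError, ValueError, OverflowError, FloatingPointError):
        return math.inf if not return_parts else (math.inf, {})
    parts = {}
    total = 0.0
    assay = dataset.assay
    if len(A) and weights.get("afp", 0) > 0:
        A_rep = np.clip(A, assay.afp_lower, assay.afp_upper)
        r = np.log10(np.maximum(A_rep, _LOG_FLOOR)) - np.log10(dataset.afp)
        sq = weights["afp"] * dataset.afp_weights * r ** 2
        parts["afp"] = float(np.sqrt(np.mean(r ** 2)))
        total += float(np.sum(sq))
    if len(P) and weights.get("pivka", 0) > 0:
        P_rep = np.clip(P, assay.pivka_lower, assay.pivka_upper)
        r = np.log10(np.maximum(P_rep, _LOG_FLOOR)) - np.log10(dataset.pivka)
        sq = weights["pivka"] * dataset.pivka_weights * r ** 2
        parts["pivka"] = float(np.sqrt(np.mean(r ** 2)))
        total += float(np.sum(sq))
    if len(V) and weights.get("tvi", 0) > 0:
        tvi0 = dataset.tvi[np.argmin(np.abs(dataset.tvi_times))]
        if tvi0 != 0 and V0 > 0:
            r = V / V0 - dataset.tvi / tvi0
            parts["tvi"] = float(np.sqrt(np.mean(r ** 2)))
            total += float(weights["tvi"] * np.sum(r ** 2))
    if not math.isfinite(total):
        total = math.inf
    return (total, parts) if return_parts else total


def fit_patient(dataset: PatientDataset, spec: FitSpec) -> FitResult:
    """Bounded multi-start simplex fit of the free parameters.

    Starts are drawn from a Latin hypercube in log10 space of the bounds
    (seeded, so the result is reproducible bit-for-bit), refined with
    Nelder-Mead, and the best of all starts is returned.
    """
    for series in ("afp", "pivka"):
        if spec.weights.get(series, 0) > 0 and len(getattr(dataset, series)):
            n_on = dataset.n_on_therapy(series)
            if n_on < MIN_ON_THERAPY_OBS:
                raise ValueError(
                    f"need >= {MIN_ON_THERAPY_OBS} on-therapy {series} "
                    f"observations, got {n_on}")
    if ("sigma_sp" in spec.free or spec.fixed.get("sigma_sp", 0) > 0) \
            and dataset.baseline_pivka is None:
        raise ValueError("baseline PIVKA-II (P0) required when fitting the spike")

    names = tuple(spec.free)
    lo = np.log10([spec.free[k][0] for k in names])
    hi = np.log10([spec.free[k][1] for k in names])

    n_evals = 0

    def fun(z):
        nonlocal n_evals
        n_evals += 1
        theta = {k: 10.0 ** v for k, v in zip(names, z)}
        try:
            p, c0 = spec.build(theta, dataset.c0)
        except ValueError:
            return math.inf
        return objective(p, dataset, spec, c0=c0)

    sampler = qmc.LatinHypercube(d=len(names), seed=spec.seed)
    starts = lo + sampler.random(spec.multi_start) * (hi - lo)

    best = None
    # infinite objective values (failed simulations) are legitimate inside
    # the simplex; silence the inf-inf comparison warning they trigger
    with np.errstate(invalid="ignore"):
        for z0 in starts:
            res = optimize.minimize(
                fun, z0, method="Nelder-Mead",
                bounds=list(zip(lo, hi)),
                options={"xatol": 1e-5, "fatol": 1e-12,
                         "maxfev": spec.max_evals, "adaptive": len(names) > 2},
            )
            if best is None or res.fun < best.fun:
                best = res
    if best is None or not math.isfinite(best.fun):
        raise RuntimeError(
            f"all {spec.multi_start} starts failed (last status: "
            f"{getattr(best, 'message', 'n/a')})")

    theta = {k: 10.0 ** v for k, v in zip(names, best.x)}
    p_hat, c0_hat = spec.build(dict(theta), dataset.c0)
    obj, parts = objective(p_hat, dataset, spec, c0=c0_hat, return_parts=True)

    result = FitResult(
        params=p_hat, c0=c0_hat, objective=float(obj), residual_rms=parts,
        status="converged" if best.success else str(best.message),
        seed=spec.seed, n_starts=spec.multi_start, n_evals=n_evals,
        free_names=names,
    )
    _flag_product_degeneracy(result, dataset, spec)
    return result


def _flag_product_degeneracy(result: FitResult, dataset, spec) -> None:
    """Detect the omega1 * C(0) ridge when only AFP data constrain the fit.

    With AFP alone, essentially only the product omega1 * C(0) is
    identified: scaling one up and the other down leaves the predicted AFP
    nearly unchanged (pre-therapy samples spanning a wide growth range can
    break the ridge, because the power-law growth rate depends on the
    absolute cell level).  The probe compares the objective increase along
    the ridge against the increase for the same-size move in omega1 alone;
    a ratio below 5% (parameter correlation above ~0.97) flags a flat
    profile.
    """
    if not {"omega1", "c0"} <= set(result.free_names):
        return
    pivka_active = spec.weights.get("pivka", 0) > 0 and len(dataset.pivka) > 0
    if pivka_active:
        return
    k = 2.0
    p_ridge = result.params.replace(omega1=result.params.omega1 * k)
    obj_ridge = objective(p_ridge, dataset, spec, c0=result.c0 / k)
    obj_ortho = objective(p_ridge, dataset, spec, c0=result.c0)
    d_ridge = obj_ridge - result.objective
    d_ortho = obj_ortho - result.objective
    if d_ortho > 0 and d_ridge < 0.05 * d_ortho:
        result.degenerate = True
        result.degeneracy_note = (
            "omega1 and C(0) are not separately identifiable from AFP alone "
            f"(ridge/orthogonal objective increase = {d_ridge:.3g}/{d_ortho:.3g})")


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Per response-group medians and ranges of the fitted parameters.

    ``table`` has one row per parameter and columns ``<group>_median``,
    ``<group>_min``, ``<group>_max`` for each of CR, PR-SD and PD.
    """

    table: pd.DataFrame
    groups: dict

    def median(self, param: str, group: str) -> float:
        return float(self.table.loc[param, f"{group}_median"])

    def to_csv(self, path, **kwargs) -> None:
        self.table.to_csv(path, index_label="parameter", **kwargs)


def cohort_medians(case_table, parameters=TABLE_PARAM_KEYS) -> CohortSummary:
    """Group medians/ranges over a per-case parameter table.

    ``case_table`` is an iterable of ``(params, response_label)`` pairs or a
    mapping of case id to such pairs (CaseFixture objects also work).
    Groups are CR, PR-SD (PR and SD merged) and PD; the median of an
    even-sized group is the midpoint of the two central order statistics.
    """
    records = []
    if isinstance(case_table, dict):
        case_table = list(case_table.values())
    for item in case_table:
        if hasattr(item, "params") and hasattr(item, "response"):
            p, label = item.params, item.response
        else:
            p, label = item
        records.append((p, response_group(label)))
    if not records:
        raise ValueError("case table is empty")

    groups = {}
    for p, g in records:
        groups.setdefault(g, []).append(p)

    cols = {}
    for g in ("CR", "PR-SD", "PD"):
        if g not in groups:
            continue
        mat = np.array([[getattr(p, k) for k in parameters] for p in groups[g]])
        cols[f"{g}_median"] = np.median(mat, axis=0)
        cols[f"{g}_min"] = mat.min(axis=0)
        cols[f"{g}_max"] = mat.max(axis=0)
    table = pd.DataFrame(cols, index=list(parameters))
    return CohortSummary(table=table, groups={g: len(v) for g, v in groups.items()})
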