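"""Coupled-assay enzyme kinetics: rates, Michaelis-Menten fits, effectors.

The assay modelled here is the classical PEPC coupled assay: carboxylase
activity is read through malate dehydrogenase consuming NADH, monitored
as a decrease in absorbance at 340 nm.  One unit of activity is the
consumption of 1 µmol NADH per minute; with the standard extinction
coefficient ε = 6.22 mM⁻¹·cm⁻¹ and a 1 mL, 1 cm cuvette, a velocity in
units is |dA340/dt| / 6.22 (µmol/min).

Michaelis-Menten parameters are estimated two ways: by the classical
Lineweaver-Burk double-reciprocal regression (1/v on 1/[S]; intercepts
1/Vmax and -1/Km), and by direct nonlinear least squares, which is the
statistically preferred estimator and serves as a cross-check.  Effector
action is summarised as relative activity (% of a mock assay) with a
paired t-test, and classified into inhibition modes from the relative
changes of Vmax and Km.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .errors import DataError, DegenerateDataError, FitError
from .stats import mean_sd, paired_t_test

#: NADH extinction coefficient at 340 nm, mM^-1 cm^-1.
EPSILON_NADH_340 = 6.22

MOCK = "MOCK"


@dataclass
class Condition:
    """Assay condition metadata shared by traces and rate measurements."""

    variant: str = ""
    effector: str = MOCK
    effector_mM: float = 0.0
    substrate: str = "PEP"
    substrate_mM: float = 0.0
    pH: float = 7.3
    temperature_C: float = 30.0
    replicate: int = 1


@dataclass
class AssayTrace:
    time_s: np.ndarray
    A340: np.ndarray
    condition: Condition = field(default_factory=Condition)
    volume_mL: float = 1.0
    path_cm: float = 1.0
    protein_pmol: float | None = None
    protein_ug: float | None = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.A340 = np.asarray(self.A340, dtype=float)
        if self.time_s.shape != self.A340.shape or self.time_s.size < 4:
            raise DataError("trace needs >= 4 (time, A340) pairs of equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise DataError("trace times must be strictly increasing")
        if np.any(self.A340 < 0) or np.any(self.A340 > 3):
            raise DataError("A340 outside the measurable range [0, 3]")


@dataclass
class RateMeasurement:
    substrate_mM: float
    velocity_units: float  # µmol NADH / min
    condition: Condition = field(default_factory=Condition)

    def __post_init__(self):
        # NaN marks fixed-substrate assays (pH/temperature profiles) where
        # the titration concentration is not meaningful
        if not np.isnan(self.substrate_mM) and self.substrate_mM <= 0:
            raise DataError("substrate concentration must be positive")
        if self.velocity_units < 0:
            raise DataError("velocity must be non-negative")


@dataclass
class KineticFit:
    Vmax: float  # same units as input velocities
    Km: float  # mM
    method: str  # "LB" or "NLS"
    r_squared: float
    n_points: int
    Vmax_per_mg: float | None = None
    Vmax_per_pmol: float | None = None


@dataclass
class EffectorEffect:
    effector: str
    concentration_mM: float
    relative_activity: float  # % of mock, mean
    sd: float | None
    n: int
    p_value: float | None
    replicate_relative: list[float] = field(default_factory=list)
    mode: str | None = None
    pH: float | None = None


@dataclass
class ActivityProfile:
    axis: str  # "pH" or "temperature"
    grid: np.ndarray
    mean_activity: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.mean_activity = np.asarray(self.mean_activity, dtype=float)
        if self.grid.size < 3:
            raise DataError("profile needs >= 3 grid points")
        if np.any(np.diff(self.grid) <= 0):
            raise DataError("profile grid must be strictly increasing")
        if self.grid.shape != self.mean_activity.shape:
            raise DataError("grid and activity shapes differ")


def _linfit(t_min: np.ndarray, a: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and r^2; a perfectly flat segment counts as a
    perfect linear fit (r^2 = 1)."""
    slope, intercept = np.polyfit(t_min, a, 1)
    resid = a - (slope * t_min + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), r2


def initial_rate(
    trace: AssayTrace,
    window: str | int = "max-linear",
    min_points: int = 4,
    r2_threshold: float = 0.99,
) -> RateMeasurement:
    """Initial velocity (units = µmol/min) from an A340 trace.

    window: an integer k uses the first k points; "max-linear" (default)
    uses the longest prefix whose linear fit keeps r² >= r2_threshold,
    never fewer than `min_points`.  A rising trace means no NADH is being
    consumed (or the trace is inverted); it yields velocity 0 with a
    warning rather than a negative rate.
    """
    t_min = trace.time_s / 60.0
    a = trace.A340
    if isinstance(window, int):
        if window < 3:
            raise DataError("window must cover at least 3 points")
        k = min(window, len(a))
    else:
        k = len(a)
        for end in range(min_points, len(a) + 1):
            _, r2 = _linfit(t_min[:end], a[:end])
            if r2 < r2_threshold:
                k = max(end - 1, min_points)
                break
    slope, _ = _linfit(t_min[:k], a[:k])
    if abs(slope) < 1e-12:  # flat within numerical noise: no reaction
        slope = 0.0
    if slope > 0:
        warnings.warn(
            "A340 increases over the initial window; expected a decreasing "
            "trace for a coupled NADH assay. Reporting velocity 0."
        )
        velocity = 0.0
    else:
        velocity = abs(slope) / (EPSILON_NADH_340 * trace.path_cm) * trace.volume_mL
    return RateMeasurement(
        substrate_mM=trace.condition.substrate_mM or float("nan"),
        velocity_units=velocity,
        condition=trace.condition,
    )


def specific_activity(
    velocity_units: float, protein_pmol: float, protein_ug: float
) -> tuple[float, float, float]:
    """(units/mg, units/pmol, implied subunit mass in kDa).

    The implied mass (µg/pmol = g/µmol, i.e. MDa·10⁻³... reported in kDa)
    is a consistency check on the stated protein amounts.
    """
    if protein_pmol <= 0 or protein_ug <= 0:
        raise DataError("protein amounts must be positive")
    per_mg = velocity_units / (protein_ug / 1000.0)
    per_pmol = velocity_units / protein_pmol
    implied_kda = protein_ug * 1e6 / protein_pmol / 1000.0
    return per_mg, per_pmol, implied_kda


def _michaelis_menten(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(
    measurements: list[RateMeasurement],
    method: str = "LB",
    average_replicates: bool = True,
    protein_pmol: float | None = None,
    protein_ug: float | None = None,
) -> KineticFit:
    """Estimate (Vmax, Km) from substrate-velocity data.

    "LB": unweighted ordinary least squares of 1/v on 1/[S]; Vmax is the
    reciprocal of the intercept and Km = slope/intercept, exactly as read
    off a double-reciprocal plot.  Non-positive velocities cannot be
    reciprocal-transformed and are dropped with a warning.  A
    non-positive intercept (no saturation / inactive enzyme) is a fit
    failure.

    "NLS": nonlinear least squares of v = Vmax·[S]/(Km+[S]), initialized
    from the LB estimate when available.

    Replicates at the same substrate concentration are averaged on the
    velocity scale before any transformation (set
    average_replicates=False to pool them instead).  If protein amounts
    are given, Vmax is also reported per mg and per pmol.
    """
    if method not in ("LB", "NLS"):
        raise DataError(f"unknown fit method {method!r}")
    s = np.array([m.substrate_mM for m in measurements], dtype=float)
    v = np.array([m.velocity_units for m in measurements], dtype=float)
    if average_replicates:
        df = pd.DataFrame({"s": s, "v": v}).groupby("s", as_index=False).mean()
        s, v = df["s"].to_numpy(), df["v"].to_numpy()
    if len(np.unique(s)) < 3:
        raise DataError("need >= 3 distinct substrate concentrations")

    def _lb(s_arr, v_arr):
        keep = v_arr > 0
        if not np.all(keep):
            warnings.warn(
                f"dropping {int((~keep).sum())} non-positive velocities for the "
                "double-reciprocal fit"
            )
        s_arr, v_arr = s_arr[keep], v_arr[keep]
        if len(np.unique(s_arr)) < 3:
            raise FitError("fewer than 3 usable points for the double-reciprocal fit")
        res = sps.linregress(1.0 / s_arr, 1.0 / v_arr)
        if res.intercept <= 0:
            raise FitError(
                "non-positive double-reciprocal intercept: no saturating "
                "behaviour (enzyme inactive or data inadequate)"
            )
        vmax = 1.0 / res.intercept
        km = res.slope / res.intercept
        if km <= 0:
            raise FitError("non-positive fitted Km")
        return vmax, km, float(res.rvalue**2), len(s_arr)

    if method == "LB":
        vmax, km, r2, n_used = _lb(s, v)
    else:
        try:
            v0, k0, _, _ = _lb(s, v)
        except (FitError, DataError):
            v0, k0 = float(np.max(v)), float(np.median(s))
        try:
            popt, _ = optimize.curve_fit(
                _michaelis_menten, s, v, p0=(v0, k0), maxfev=10000
            )
        except RuntimeError as exc:
            raise FitError(f"nonlinear fit did not converge: {exc}") from exc
        vmax, km = float(popt[0]), float(popt[1])
        if vmax <= 0 or km <= 0:
            raise FitError("nonlinear fit produced non-positive parameters")
        resid = v - _michaelis_menten(s, vmax, km)
        ss_tot = float(np.sum((v - v.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        n_used = len(s)

    fit = KineticFit(Vmax=vmax, Km=km, method=method, r_squared=r2, n_points=n_used)
    if protein_pmol is not None and protein_ug is not None:
        per_mg, per_pmol, _ = specific_activity(vmax, protein_pmol, protein_ug)
        fit.Vmax_per_mg = per_mg
        fit.Vmax_per_pmol = per_pmol
    return fit


def relative_activity(
    effector_reps: list[float],
    mock_reps: list[float],
    effector: str = "",
    concentration_mM: float = 0.0,
    pH: float | None = None,
) -> EffectorEffect:
    """Activity relative to the mock mean, in percent.

    Each effector replicate is divided by the mock mean (x100); the
    report carries mean ± sample SD and, when replicate counts match, a
    paired two-tailed t-test of effector vs mock velocities.  A
    zero-variance pairing (e.g. noiseless reconstructions) has no
    defensible p-value and reports p = None.
    """
    eff = np.asarray(effector_reps, dtype=float)
    mock = np.asarray(mock_reps, dtype=float)
    if eff.size < 1 or mock.size < 1:
        raise DataError("need at least one replicate per group")
    mock_mean = float(mock.mean())
    if mock_mean <= 0:
        raise DataError("mock mean velocity must be positive")
    rel = eff / mock_mean * 100.0
    if rel.size >= 2:
        mean, sd = mean_sd(rel.tolist())
    else:
        mean, sd = float(rel[0]), None
    p_value = None
    if eff.size == mock.size and eff.size >= 2:
        try:
            p_value = paired_t_test(eff.tolist(), mock.tolist()).p_value
        except DegenerateDataError:
            p_value = None
    return EffectorEffect(
        effector=effector,
        concentration_mM=concentration_mM,
        relative_activity=float(mean),
        sd=sd,
        n=int(eff.size),
        p_value=p_value,
        replicate_relative=[float(x) for x in rel],
        pH=pH,
    )


MALATE_FUMARATE_TYPE = "Km-and-Vmax-increase (malate/fumarate-type)"


def classify_inhibition_mode(
    fit_mock: KineticFit, fit_effector: KineticFit, rel_tol: float = 0.15
) -> str:
    """Label the effector's kinetic signature from relative Vmax/Km changes.

    Changes smaller than rel_tol (default 15%) count as "unchanged".
    Km up, Vmax unchanged -> competitive-like; Vmax down, Km unchanged ->
    noncompetitive-like; both down -> uncompetitive-like; both up -> the
    mixed Km-and-Vmax increase seen for malate/fumarate on PEPC; neither
    -> no-effect.
    """
    dv = (fit_effector.Vmax - fit_mock.Vmax) / fit_mock.Vmax
    dk = (fit_effector.Km - fit_mock.Km) / fit_mock.Km
    v_up, v_down = dv > rel_tol, dv < -rel_tol
    k_up, k_down = dk > rel_tol, dk < -rel_tol
    if k_up and not (v_up or v_down):
        return "competitive-like"
    if v_down and not (k_up or k_down):
        return "noncompetitive-like"
    if v_down and k_down:
        return "uncompetitive-like"
    if v_up and k_up:
        return MALATE_FUMARATE_TYPE
    if not (v_up or v_down or k_up or k_down):
        return "no-effect"
    return "mixed"


def find_optimum(profile: ActivityProfile) -> tuple[float, float]:
    """Grid value with the highest mean activity (no interpolation).

    Ties resolve to the lower grid value; a boundary optimum triggers a
    warning since the true peak may lie outside the measured range.
    """
    i = int(np.argmax(profile.mean_activity))  # argmax takes first (lowest) on ties
    n_ties = int(np.sum(profile.mean_activity == profile.mean_activity[i]))
    if n_ties > 1:
        warnings.warn(f"{n_ties}-way tie for the optimum; reporting the lowest {profile.axis}")
    if i in (0, len(profile.grid) - 1):
        warnings.warn(
            f"optimum at the {profile.axis} grid boundary; the measured range "
            "may not bracket the true optimum"
        )
    return float(profile.grid[i]), float(profile.mean_activity[i])


def inhibition_vs_ph(effects: list[EffectorEffect]) -> pd.DataFrame:
    """Compare one effector's relative activity across pH values.

    All entries must share effector and concentration and carry a pH.
    Returns a table sorted by pH with the difference from the lowest-pH
    entry, a paired t-test between the replicate relative activities of
    the extreme pH values (when available), and an `enhanced_at_higher_ph`
    flag set when relative activity is lower at the higher pH.
    """
    if len(effects) < 2:
        raise DataError("need effects at >= 2 pH values")
    names = {e.effector for e in effects}
    concs = {e.concentration_mM for e in effects}
    if len(names) != 1 or len(concs) != 1:
        raise DataError("mismatched effector/concentration across pH entries")
    if any(e.pH is None for e in effects):
        raise DataError("every entry needs a pH")
    ordered = sorted(effects, key=lambda e: e.pH)
    base = ordered[0]
    lo, hi = ordered[0], ordered[-1]
    p_value = None
    if (
        lo.replicate_relative
        and hi.replicate_relative
        and len(lo.replicate_relative) == len(hi.replicate_relative)
        and len(lo.replicate_relative) >= 2
    ):
        try:
            p_value = paired_t_test(hi.replicate_relative, lo.replicate_relative).p_value
        except DegenerateDataError:
            p_value = None
    enhanced = hi.relative_activity < lo.relative_activity
    return pd.DataFrame(
        {
            "pH": [e.pH for e in ordered],
            "relative_activity_pct": [e.relative_activity for e in ordered],
            "sd": [e.sd for e in ordered],
            "n": [e.n for e in ordered],
            "delta_vs_lowest_pH": [
                e.relative_activity - base.relative_activity for e in ordered
            ],
            "enhanced_at_higher_ph": [enhanced] * len(ordered),
            "paired_p_extremes": [p_value] * len(ordered),
        }
    )


# ---------------------------------------------------------------------------
# long-format table I/O

TRACE_COLUMNS = [
    "variant", "effector", "effector_mM", "substrate", "substrate_mM",
    "pH", "temp_C", "replicate", "time_s", "A340",
]
RATE_COLUMNS = TRACE_COLUMNS[:-2] + ["velocity_units"]


def read_assay_table(path) -> pd.DataFrame:
    """Read a long-format assay CSV/TSV (comma or tab sniffed).

    Accepts either trace rows (time_s, A340) or pre-reduced rows
    (velocity_units); validates column names.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = set(df.columns)
    if set(TRACE_COLUMNS) <= cols or set(RATE_COLUMNS) <= cols:
        return df
    missing = sorted(set(RATE_COLUMNS) - cols - {"velocity_units"})
    raise DataError(
        f"assay table {path} is missing required columns; expected either "
        f"{TRACE_COLUMNS} or {RATE_COLUMNS} (missing at least {missing or ['velocity_units or time_s/A340']})"
    )


def measurements_from_table(df: pd.DataFrame, **trace_kwargs) -> list[RateMeasurement]:
    """Convert a long-format table into RateMeasurements, reducing traces
    through initial_rate when needed."""
    meas: list[RateMeasurement] = []
    key_cols = RATE_COLUMNS[:-1]
    if "velocity_units" in df.columns:
        for _, row in df.iterrows():
            meas.append(
                RateMeasurement(
                    substrate_mM=float(row["substrate_mM"]),
                    velocity_units=float(row["velocity_units"]),
                    condition=_condition_from_row(row),
                )
            )
        return meas
    for _, grp in df.groupby(key_cols, sort=False):
        grp = grp.sort_values("time_s")
        cond = _condition_from_row(grp.iloc[0])
        trace = AssayTrace(
            time_s=grp["time_s"].to_numpy(),
            A340=grp["A340"].to_numpy(),
            condition=cond,
            **trace_kwargs,
        )
        meas.append(initial_rate(trace))
    return meas


def _condition_from_row(row) -> Condition:
    return Condition(
        variant=str(row["variant"]),
        effector=str(row["effector"]),
        effector_mM=float(row["effector_mM"]),
        substrate=str(row["substrate"]),
        substrate_mM=float(row["substrate_mM"]),
        pH=float(row["pH"]),
        temperature_C=float(row["temp_C"]),
        replicate=int(row["replicate"]),
    )
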