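"""Variance-based (Sobol) global sensitivity of pulse wave velocity to the
wall structural parameters, plus Pearson correlation / regression summaries.

The PWV of the carotid model is treated as a scalar function of the eight
structural parameters (H, R_i, omega, k0, k1, k2, alpha, phi); the net
axial stretch is held at its in-vivo value of 1.4. Parameters vary
independently and uniformly inside a box of ±5% around the reference
values (alpha, already near its upper bound of 1, varies in [0.95, 1.00]).

First-order and total indices are estimated with the classical
pick-freeze Monte-Carlo scheme: two independent low-discrepancy sample
matrices A and B (Sobol' sequences, scrambled, drawn as one 2k-dimensional
stream and split) and the k column-swapped hybrids AB_i. The default
estimator is Jansen's (numerically robust); the original Sobol'
covariance form is available. Cost: n*(k+2) model evaluations.

Two PWV models are provided for the carotid application:

* ``static`` — the intrinsic wave speed c = sqrt(A/(rho*C_A)) at the
  diastolic working point (the area where the wall's tube law balances
  the reference diastolic pressure). This is the quantity a foot-to-foot
  transit measurement tracks, at a per-evaluation cost of milliseconds;
  it is the desk-scale route to the sensitivity ranking.
* ``simulation`` — the full transient 1D run with foot-to-foot PWV
  extraction (optionally with reduced cycle count for ranking studies;
  such runs are scaled-down and labelled as such).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .units import MMHG
from .wall import FluidProperties, HyperelasticTubeLaw, WallParameters

logger = logging.getLogger(__name__)

PARAM_NAMES = ("H", "R_i", "omega", "k0", "k1", "k2", "alpha", "phi")


@dataclass(frozen=True)
class ParameterBox:
    """Independent uniform bounds for the eight structural parameters."""

    names: tuple
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.shape != upper.shape or len(self.names) != lower.size:
            raise ValueError("names, lower and upper must align")
        if np.any(lower >= upper):
            raise ValueError("require lower < upper elementwise")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def dim(self) -> int:
        return len(self.names)


def default_box(
    wall: WallParameters,
    rel: float = 0.05,
    alpha_range: tuple = (0.95, 1.00),
) -> ParameterBox:
    """±``rel`` box around a reference wall; alpha gets ``alpha_range``.

    ``omega`` and ``phi`` bounds are applied to the magnitudes (in
    radians); the two fibre families stay symmetric at ±phi.
    """
    import math

    ref = np.array([
        wall.H, wall.R_i, wall.omega, wall.k0, wall.k1, wall.k2,
        wall.alpha, abs(wall.phi[0]),
    ])
    lower = ref * (1 - rel)
    upper = ref * (1 + rel)
    lower[6], upper[6] = alpha_range
    return ParameterBox(names=PARAM_NAMES, lower=lower, upper=upper)


def wall_from_row(row: np.ndarray, template: WallParameters) -> WallParameters:
    """Build a virtual artery from one sample row (order PARAM_NAMES)."""
    H, R_i, omega, k0, k1, k2, alpha, phi = (float(v) for v in row)
    return template.replace(
        H=H, R_i=R_i, omega=omega, k0=k0, k1=k1, k2=k2, alpha=alpha,
        phi=(phi, -phi),
    )


@dataclass
class SobolResult:
    """Variance decomposition of a scalar model output (Table layout:
    one column per parameter)."""

    names: tuple
    D_total: float  # global variance (model-output units squared)
    D_y: np.ndarray  # first-order variances
    D_yt: np.ndarray  # total variances
    n: int  # sample size per matrix
    n_discarded: int = 0
    convergence: pd.DataFrame | None = None

    @property
    def S_y(self) -> np.ndarray:
        return self.D_y / self.D_total

    @property
    def S_yt(self) -> np.ndarray:
        return self.D_yt / self.D_total

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self.S_y, self.S_yt, self.D_y, self.D_yt],
            index=["S_y", "S_yt", "D_y", "D_yt"],
            columns=list(self.names),
        )


def sobol_sample(box: ParameterBox, n: int, seed: int = 0):
    """Two n x d low-discrepancy matrices scaled into the box.

    One scrambled Sobol' stream of dimension 2d is drawn and split into
    the A and B blocks (the standard construction guaranteeing
    independence between blocks while keeping each low-discrepancy).
    Deterministic for a given seed. ``n`` need not be a power of two,
    but powers of two preserve the sequence's balance properties.
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    d = box.dim
    eng = qmc.Sobol(d=2 * d, scramble=True, rng=np.random.default_rng(seed))
    if n & (n - 1):  # not a power of two
        u = eng.random(n)
    else:
        u = eng.random_base2(int(np.log2(n)))
    span = box.upper - box.lower
    a = box.lower + u[:, :d] * span
    b = box.lower + u[:, d:] * span
    return a, b


def sobol_indices(
    model,
    box: ParameterBox,
    n: int = 1024,
    seed: int = 0,
    estimator: str = "jansen",
    n_trace: int = 8,
    max_failed_frac: float = 0.01,
) -> SobolResult:
    """Pick-freeze estimate of first-order and total Sobol indices.

    ``model`` maps an (m, d) array of parameter rows to m scalar outputs
    (NaN marks a failed evaluation; failed rows are discarded pairwise
    across all matrices, aborting if more than ``max_failed_frac`` fail).

    Estimators ('jansen' default, 'sobol' available):

    * first-order variance D_y[i]:
        jansen:  V - (1/2n) sum (f_B - f_AB_i)^2
        sobol:   (1/n) sum f_B * (f_AB_i - f_A)
    * total variance D_yt[i]:
        jansen:  (1/2n) sum (f_A - f_AB_i)^2
        sobol:   V - [(1/n) sum f_A * f_AB_i - f0^2]

    where AB_i is A with column i replaced from B, V the pooled variance
    of (f_A, f_B). Running estimates on nested sub-samples are returned
    as a convergence trace.
    """
    if estimator not in ("jansen", "sobol"):
        raise ValueError(f"unknown estimator {estimator!r}")
    d = box.dim
    a, b = sobol_sample(box, n, seed)
    f_a = np.asarray(model(a), dtype=float)
    f_b = np.asarray(model(b), dtype=float)
    f_ab = np.empty((d, n))
    for i in range(d):
        ab = a.copy()
        ab[:, i] = b[:, i]
        f_ab[i] = np.asarray(model(ab), dtype=float)

    ok = np.isfinite(f_a) & np.isfinite(f_b) & np.all(np.isfinite(f_ab), axis=0)
    n_bad = int(np.sum(~ok))
    if n_bad > max_failed_frac * n:
        raise RuntimeError(
            f"{n_bad}/{n} model evaluations failed (> "
            f"{max_failed_frac:.0%}); aborting sensitivity analysis"
        )
    if n_bad:
        logger.warning("discarding %d failed sample pairs", n_bad)
        f_a, f_b, f_ab = f_a[ok], f_b[ok], f_ab[:, ok]

    def estimate(fa, fb, fab):
        m = fa.size
        pooled = np.concatenate([fa, fb])
        V = float(np.var(pooled, ddof=0))
        f0 = float(np.mean(pooled))
        if estimator == "jansen":
            D_y = V - 0.5 * np.mean((fb[None, :] - fab) ** 2, axis=1)
            D_yt = 0.5 * np.mean((fa[None, :] - fab) ** 2, axis=1)
        else:
            D_y = np.mean(fb[None, :] * (fab - fa[None, :]), axis=1)
            D_yt = V - (np.mean(fa[None, :] * fab, axis=1) - f0**2)
        return V, D_y, D_yt

    V, D_y, D_yt = estimate(f_a, f_b, f_ab)

    m = f_a.size
    trace_n = np.unique(
        np.geomspace(max(8, m // 2**n_trace), m, n_trace).astype(int)
    )
    rows = []
    for mn in trace_n:
        Vm, Dym, Dytm = estimate(f_a[:mn], f_b[:mn], f_ab[:, :mn])
        rows.append({"n": mn, "D": Vm,
                     **{f"D_y[{nm}]": v for nm, v in zip(box.names, Dym)},
                     **{f"D_yt[{nm}]": v for nm, v in zip(box.names, Dytm)}})
    return SobolResult(
        names=tuple(box.names), D_total=V, D_y=D_y, D_yt=D_yt,
        n=n, n_discarded=n_bad, convergence=pd.DataFrame(rows),
    )


def correlation_regression(samples, outputs, names=PARAM_NAMES) -> pd.DataFrame:
    """Per-parameter variance, Pearson correlation with the output and
    univariate least-squares slope (plus the output's own row)."""
    samples = np.asarray(samples, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    if samples.ndim != 2 or samples.shape[0] != outputs.size:
        raise ValueError("samples must be (n, d) matching outputs")
    if outputs.size < 2:
        raise ValueError("need at least 2 samples")
    rows = []
    for i, nm in enumerate(names):
        x = samples[:, i]
        var = float(np.var(x, ddof=1))
        if var == 0.0:
            logger.warning("parameter %s has zero variance; r undefined", nm)
            rows.append({"parameter": nm, "variance": 0.0,
                         "std": 0.0, "r": np.nan, "slope": np.nan})
            continue
        r = float(stats.pearsonr(x, outputs).statistic)
        slope = float(np.polyfit(x, outputs, 1)[0])
        rows.append({"parameter": nm, "variance": var,
                     "std": float(np.sqrt(var)), "r": r, "slope": slope})
    var_y = float(np.var(outputs, ddof=1))
    rows.append({"parameter": "PWV", "variance": var_y,
                 "std": float(np.sqrt(var_y)), "r": 1.0, "slope": 1.0})
    return pd.DataFrame(rows).set_index("parameter")


def make_pwv_model(
    template: WallParameters,
    fluid: FluidProperties | None = None,
    kind: str = "static",
    p_d_ref: float = 79.07 * MMHG,
    quad_n: int = 21,
    simulation_kwargs: dict | None = None,
):
    """Callable mapping sample rows -> PWV in cm/s for the carotid model.

    ``static``: intrinsic wave speed at the diastolic working point (the
    lumen area solving the wall's tube law at ``p_d_ref``); fast and
    deterministic. ``simulation``: full transient run with foot-to-foot
    extraction (``simulation_kwargs`` forwards inflow/windkessel/mesh
    settings to :func:`elastotube.bench.simulate_wall`); each evaluation
    is a complete 1D simulation. Failed evaluations return NaN.
    """
    fluid = fluid or FluidProperties()
    if kind == "static":

        def model(rows: np.ndarray) -> np.ndarray:
            rows = np.atleast_2d(np.asarray(rows, dtype=float))
            out = np.empty(rows.shape[0])
            for j, row in enumerate(rows):
                try:
                    w = wall_from_row(row, template)
                    law = HyperelasticTubeLaw(w, quad_n=quad_n)
                    A_d = law.area_from_pressure(p_d_ref)
                    out[j] = float(law.wave_speed(np.asarray([A_d]),
                                                  fluid.rho)[0])
                except Exception:  # noqa: BLE001 - failures become NaN
                    out[j] = np.nan
            return out

        return model

    if kind == "simulation":
        from .bench import simulate_wall

        kw = dict(simulation_kwargs or {})

        def model(rows: np.ndarray) -> np.ndarray:  # pragma: no cover - slow
            rows = np.atleast_2d(np.asarray(rows, dtype=float))
            out = np.empty(rows.shape[0])
            for j, row in enumerate(rows):
                try:
                    w = wall_from_row(row, template)
                    summary, _ = simulate_wall(w, fluid=fluid, **kw)
                    out[j] = summary.PWV_foot * 100.0  # m/s -> cm/s
                except Exception:  # noqa: BLE001
                    out[j] = np.nan
            return out

        return model

    raise ValueError(f"unknown PWV model kind {kind!r}")
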