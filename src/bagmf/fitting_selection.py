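"""Weighted least-squares model fitting and AICc model selection.

Each residue contributes a fit vector of 1 + 2G spectral density values
(mean J(0), then J(wN) and J(0.87 wH) at each field).  Every candidate
model is fitted by bounded multi-start nonlinear least squares; candidates
are ranked by the small-sample Akaike criterion

    AICc = chi2 + 2k + 2k(k + 1) / (n - k - 1),

treating measurement variances as known.  Models 2 and 3 share a single
functional form (one order parameter, one internal time); they are fitted
once with the internal time free over its full range and the result is
labelled Model 2 if the fitted time is below the fast/slow threshold
(0.15 ns by default) and Model 3 otherwise.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from . import _lm
from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .jw_mapping import SpectralDensitySet
from .modelfree import (
    PARAM_NAMES,
    ModelFreeParams,
    ModelSpec,
    model_param_vector,
    model_spec,
    spectral_density,
    spectral_density_grad,
)

logger = logging.getLogger(__name__)

MODEL_IDS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class FitVector:
    """Fit-ready data for one residue: values, errors, frequencies."""

    y: np.ndarray
    err: np.ndarray
    omega: np.ndarray
    G: int

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (len(self.err) == len(self.omega) == n):
            raise ValueError("y, err, omega must have equal length")
        if n != 1 + 2 * self.G:
            raise ValueError(f"expected {1 + 2 * self.G} entries, got {n}")

    @property
    def n(self) -> int:
        return len(self.y)

    @classmethod
    def from_sd_set(
        cls,
        sd_set: SpectralDensitySet,
        const: PhysicalConstants = DEFAULT_CONSTANTS,
    ) -> "FitVector":
        y, err, omega = sd_set.fit_arrays(const)
        return cls(y=y, err=err, omega=omega, G=sd_set.G)


@dataclass(frozen=True)
class FitOptions:
    """Optimizer and selection settings (times in seconds)."""

    tau_m_bounds: tuple[float, float] = (1e-9, 100e-9)
    tau_threshold: float = 0.15e-9
    chi2_tol: float = 1e-10
    max_iter: int = 500
    s2_starts: tuple[float, ...] = (0.5, 0.9)
    tau_starts: tuple[float, ...] = (10e-12, 50e-12, 500e-12)
    tau_m_scan_points: int = 40


@dataclass
class FitResult:
    """One model's optimized fit."""

    model_id: int
    params: ModelFreeParams
    chi2: float
    k: int
    aicc: float
    n_data: int
    converged: bool
    free_params: tuple[str, ...] = ()


@dataclass
class SelectionResult:
    """AICc comparison across the candidate models for one residue."""

    per_model: dict[int, FitResult | None]
    best: int
    skipped: list[int] = field(default_factory=list)

    @property
    def best_fit(self) -> FitResult:
        fit = self.per_model[self.best]
        assert fit is not None
        return fit


def chi2(y: Sequence[float], err: Sequence[float], model: Sequence[float]) -> float:
    """Weighted residual sum of squares sum((y - model)^2 / err^2)."""
    y = np.asarray(y, dtype=float)
    err = np.asarray(err, dtype=float)
    model = np.asarray(model, dtype=float)
    if not (y.shape == err.shape == model.shape):
        raise ValueError("y, err, model must have identical shapes")
    if np.any(err <= 0):
        raise ValueError("all uncertainties must be > 0")
    return float(np.sum(((y - model) / err) ** 2))


def aicc(chi2_value: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion chi2 + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return chi2_value + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def argmin_aicc(aicc_by_model: Mapping[int, float], k_by_model: Mapping[int, int] | None = None) -> int:
    """Best model id: lowest AICc, exact ties broken toward smaller k.

    ``None``/NaN entries mark non-applicable models and are ignored.
    """
    candidates = [
        (v, (k_by_model or {}).get(m, m), m)
        for m, v in aicc_by_model.items()
        if v is not None and not math.isnan(v)
    ]
    if not candidates:
        raise ValueError("no applicable models")
    return min(candidates)[2]


def _param_bounds(
    spec: ModelSpec,
    options: FitOptions,
    single_timescale: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Box bounds for the free parameters of one model."""
    lo, hi = [], []
    tau_m_lo, tau_m_hi = options.tau_m_bounds
    for name in spec.free_params:
        if name == "tau_m":
            lo.append(tau_m_lo)
            hi.append(tau_m_hi)
        elif name in ("Sf2", "Ss2"):
            lo.append(0.0)
            hi.append(1.0)
        elif name == "tau_f":
            lo.append(0.0)
            hi.append(tau_m_hi if single_timescale else options.tau_threshold)
        elif name == "tau_s":
            lo.append(options.tau_threshold)
            hi.append(tau_m_hi)
    return np.array(lo), np.array(hi)


def _scan_tau_m(fv: FitVector, options: FitOptions) -> float:
    """Coarse 1-D scan for tau_m via the closed-form Model 1 amplitude.

    For fixed tau_m, Model 1 reads J = Sf2 * g(omega); the weighted
    least-squares amplitude has a closed form, so the scan is cheap.
    """
    lo, hi = options.tau_m_bounds
    grid = np.geomspace(lo, hi, options.tau_m_scan_points)
    g = 0.4 * grid[:, None] / (1.0 + (fv.omega[None, :] * grid[:, None]) ** 2)
    w = 1.0 / fv.err**2
    amp = np.sum(w * g * fv.y, axis=1) / np.sum(w * g * g, axis=1)
    amp = np.clip(amp, 0.0, 1.0)
    cost = np.sum(w * (amp[:, None] * g - fv.y) ** 2, axis=1)
    return float(grid[np.argmin(cost)])


def default_starts(
    fv: FitVector,
    spec: ModelSpec,
    options: FitOptions,
    single_timescale: bool = False,
) -> list[np.ndarray]:
    """Multi-start grid: S2 in {0.5, 0.9}, internal tau over three decades,
    tau_m seeded from the coarse Model 1 scan."""
    lb, ub = _param_bounds(spec, options, single_timescale)
    tau_m0 = _scan_tau_m(fv, options) if "tau_m" in spec.free_params else None

    per_param: list[list[float]] = []
    for name in spec.free_params:
        if name == "tau_m":
            per_param.append([tau_m0])
        elif name in ("Sf2", "Ss2"):
            per_param.append(list(options.s2_starts))
        else:
            per_param.append(list(options.tau_starts))
    starts: list[np.ndarray] = []
    seen = set()
    for combo in np.array(np.meshgrid(*per_param)).T.reshape(-1, spec.k):
        x = np.clip(combo, lb, ub)
        key = tuple(x.tolist())
        if key not in seen:
            seen.add(key)
            starts.append(x)
    return starts


def fit_model(
    fv: FitVector,
    spec: ModelSpec,
    options: FitOptions = FitOptions(),
    tau_m_fixed: float | None = None,
    starts: list[np.ndarray] | None = None,
    single_timescale: bool = False,
) -> FitResult:
    """Bounded multi-start weighted least squares for one candidate model."""
    if np.any(fv.err <= 0):
        raise ValueError("fit vector has non-positive uncertainties")
    lb, ub = _param_bounds(spec, options, single_timescale)
    if starts is None:
        starts = default_starts(fv, spec, options, single_timescale)

    x_scale = np.array(
        [1e-8 if n == "tau_m" else (1e-10 if n.startswith("tau") else 1.0)
         for n in spec.free_params]
    )

    def residuals(x: np.ndarray) -> np.ndarray:
        p = _embed(x, spec, tau_m_fixed)
        return (spectral_density(fv.omega, *p) - fv.y) / fv.err

    def jac(x: np.ndarray) -> np.ndarray:
        p = _embed(x, spec, tau_m_fixed)
        _, dJ = spectral_density_grad(fv.omega, *p)
        idx = [PARAM_NAMES.index(n) for n in spec.free_params]
        return dJ[:, idx] / fv.err[:, None]

    best = None
    any_converged = False
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lb, ub)
        try:
            sol = least_squares(
                residuals,
                x0,
                jac=jac,
                bounds=(lb, ub),
                x_scale=x_scale,
                ftol=options.chi2_tol,
                xtol=1e-12,
                gtol=1e-12,
                max_nfev=options.max_iter,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        cost = 2.0 * sol.cost
        any_converged = any_converged or sol.success
        if best is None or cost < best[0]:
            best = (cost, sol.x)
    if best is None:
        raise RuntimeError(f"model {spec.model_id}: all starts failed")

    chi2_value, x = best
    params = model_param_vector(spec, x, tau_m_fixed)
    n = fv.n
    k = spec.k
    aicc_value = aicc(chi2_value, k, n) if n - k - 1 > 0 else math.nan
    return FitResult(
        model_id=spec.model_id,
        params=params,
        chi2=float(chi2_value),
        k=k,
        aicc=aicc_value,
        n_data=n,
        converged=any_converged,
        free_params=spec.free_params,
    )


def _embed(x: np.ndarray, spec: ModelSpec, tau_m_fixed: float | None):
    values = dict(zip(spec.free_params, x))
    values.update(spec.fixed_values)
    if "tau_m" not in values:
        values["tau_m"] = tau_m_fixed
    return [float(values[n]) for n in PARAM_NAMES]


def single_timescale_spec(local_tau_m: bool = True) -> ModelSpec:
    """The shared Model 2/3 functional form: one S2, one internal time.

    Parameterized internally via (Sf2, tau_f) with Ss2 = 1, tau_s = 0;
    the internal time floats over the full range and the fit is labelled
    Model 2 or Model 3 afterwards.
    """
    free = ("Sf2", "tau_f")
    if local_tau_m:
        free = ("tau_m",) + free
    return ModelSpec(
        model_id=2,
        free_params=free,
        fixed_values={"Ss2": 1.0, "tau_s": 0.0},
        tau_m_policy="local" if local_tau_m else "fixed",
    )


def classify_single_timescale(
    fit: FitResult, options: FitOptions
) -> FitResult:
    """Label a single-timescale fit as Model 2 (fast) or Model 3 (slow)."""
    p = fit.params
    if p.tau_f < options.tau_threshold:
        return FitResult(
            model_id=2, params=p, chi2=fit.chi2, k=fit.k, aicc=fit.aicc,
            n_data=fit.n_data, converged=fit.converged,
            free_params=fit.free_params,
        )
    relabelled = ModelFreeParams(
        tau_m=p.tau_m, Sf2=1.0, Ss2=p.Sf2, tau_f=0.0, tau_s=p.tau_f
    )
    return FitResult(
        model_id=3, params=relabelled, chi2=fit.chi2, k=fit.k, aicc=fit.aicc,
        n_data=fit.n_data, converged=fit.converged,
        free_params=fit.free_params,
    )


def select_model(
    fv: FitVector,
    options: FitOptions = FitOptions(),
    tau_m_fixed: float | None = None,
) -> SelectionResult:
    """Fit the candidate models and pick the AICc-optimal one.

    The single-timescale form is optimized once and labelled Model 2 or 3
    by the threshold; the unlabelled twin is reported as non-applicable,
    as are models with too few degrees of freedom for AICc.
    """
    local = tau_m_fixed is None
    n = fv.n
    per_model: dict[int, FitResult | None] = {m: None for m in MODEL_IDS}
    skipped: list[int] = []

    def applicable(k: int) -> bool:
        return n - k - 1 > 0

    spec1 = model_spec(1, local_tau_m=local)
    if applicable(spec1.k):
        per_model[1] = fit_model(fv, spec1, options, tau_m_fixed)
    else:
        skipped.append(1)

    st_spec = single_timescale_spec(local_tau_m=local)
    if applicable(st_spec.k):
        st_fit = fit_model(
            fv, st_spec, options, tau_m_fixed, single_timescale=True
        )
        st_fit = classify_single_timescale(st_fit, options)
        per_model[st_fit.model_id] = st_fit
        skipped.append(3 if st_fit.model_id == 2 else 2)
    else:
        skipped.extend([2, 3])

    for mid in (4, 5):
        spec = model_spec(mid, local_tau_m=local)
        if applicable(spec.k):
            per_model[mid] = fit_model(fv, spec, options, tau_m_fixed)
        else:
            skipped.append(mid)

    aiccs = {
        m: r.aicc for m, r in per_model.items() if r is not None and r.converged
    }
    if not aiccs:  # fall back to non-converged fits rather than failing
        aiccs = {m: r.aicc for m, r in per_model.items() if r is not None}
    ks = {m: per_model[m].k for m in aiccs}  # type: ignore[union-attr]
    best = argmin_aicc(aiccs, ks)
    return SelectionResult(per_model=per_model, best=best, skipped=sorted(skipped))


def monte_carlo_uncertainties(
    fv: FitVector,
    fit: FitResult,
    n_sims: int,
    rng: np.random.Generator,
    options: FitOptions = FitOptions(),
    tau_m_fixed: float | None = None,
) -> dict[str, float]:
    """Parametric (Monte Carlo) uncertainties for a fixed selected model.

    Each replicate perturbs every fit-vector entry with independent
    Gaussian noise of its stated uncertainty and refits the fixed model,
    warm-started at the original optimum.  Returns the sample standard
    deviation per parameter (0.0 for parameters the model pins).
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    if np.all(fv.err == 0):
        return {n: 0.0 for n in PARAM_NAMES}

    local = tau_m_fixed is None
    spec = model_spec(fit.model_id, local_tau_m=local)
    lb, ub = _param_bounds(spec, options)

    Y = fv.y[None, :] + rng.normal(0.0, 1.0, (n_sims, fv.n)) * fv.err[None, :]
    ERR = np.broadcast_to(fv.err, (n_sims, fv.n))
    OMEGA = np.broadcast_to(fv.omega, (n_sims, fv.n))
    x0 = _free_values(fit, spec)
    X, _, converged = _lm.lm_fit_batch(
        Y, ERR, OMEGA, spec, x0, lb, ub, tau_m_fixed=tau_m_fixed
    )
    X = X[converged]
    dropped = n_sims - X.shape[0]
    if dropped:
        logger.info("Monte Carlo: dropped %d non-converged replicates", dropped)
        if dropped > 0.1 * n_sims:
            warnings.warn(
                f"Monte Carlo dropped {dropped}/{n_sims} replicates",
                RuntimeWarning,
            )
    sds = X.std(axis=0, ddof=1)
    out = {n: 0.0 for n in PARAM_NAMES}
    out.update({name: float(s) for name, s in zip(spec.free_params, sds)})
    return out


def _free_values(fit: FitResult, spec: ModelSpec) -> np.ndarray:
    p = fit.params
    values = {
        "tau_m": p.tau_m, "Sf2": p.Sf2, "Ss2": p.Ss2,
        "tau_f": p.tau_f, "tau_s": p.tau_s,
    }
    return np.array([values[n] for n in spec.free_params])
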