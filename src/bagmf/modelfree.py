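"""Extended model-free spectral density function and the five nested models.

The spectral density is a sum of four Lorentzians whose amplitudes are
products of the fast and slow squared order parameters:

    J(w) = (2/5) [ Sf2*Ss2 * L(tau_m) + Sf2*(1-Ss2) * L(tau_1)
                   + (1-Sf2)*Ss2 * L(tau_2) + (1-Sf2)*(1-Ss2) * L(tau_3) ]

with L(tau) = tau / (1 + w^2 tau^2) and effective times
1/tau_1 = 1/tau_m + 1/tau_s, 1/tau_2 = 1/tau_m + 1/tau_f,
1/tau_3 = 1/tau_m + 1/tau_s + 1/tau_f.  A Lorentzian with tau = 0
contributes exactly 0 (the limit convention), so fixing an internal
correlation time to zero removes its term.

Models 1-5 are generated from the full five-parameter form by fixing
subsets of {Sf2, Ss2, tau_f, tau_s}:

    Model 1: {tau_m, Sf2, 1, 0, 0}
    Model 2: {tau_m, Sf2, 1, tau_f, 0}
    Model 3: {tau_m, 1, Ss2, 0, tau_s}
    Model 4: {tau_m, Sf2, Ss2, 0, tau_s}
    Model 5: {tau_m, Sf2, Ss2, tau_f, tau_s}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

PARAM_NAMES: tuple[str, ...] = ("tau_m", "Sf2", "Ss2", "tau_f", "tau_s")

#: parameters fixed (removed) by each model
MODEL_FIXED: dict[int, dict[str, float]] = {
    1: {"Ss2": 1.0, "tau_f": 0.0, "tau_s": 0.0},
    2: {"Ss2": 1.0, "tau_s": 0.0},
    3: {"Sf2": 1.0, "tau_f": 0.0},
    4: {"tau_f": 0.0},
    5: {},
}


@dataclass(frozen=True)
class ModelFreeParams:
    """Full five-parameter set; times in seconds."""

    tau_m: float
    Sf2: float
    Ss2: float
    tau_f: float
    tau_s: float

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        for name in ("Sf2", "Ss2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.tau_f < 0 or self.tau_s < 0:
            raise ValueError("internal correlation times must be >= 0")
        if self.tau_f > 0 and self.tau_s > 0 and self.tau_f > self.tau_s:
            # fast motion must not be slower than the slow motion
            raise ValueError("tau_f must not exceed tau_s")

    @property
    def S2(self) -> float:
        return self.Sf2 * self.Ss2

    @property
    def tau1(self) -> float:
        return _combine_times(self.tau_m, self.tau_s)

    @property
    def tau2(self) -> float:
        return _combine_times(self.tau_m, self.tau_f)

    @property
    def tau3(self) -> float:
        return _combine_times(self.tau_m, self.tau_s, self.tau_f)

    def as_array(self) -> np.ndarray:
        return np.array([self.tau_m, self.Sf2, self.Ss2, self.tau_f, self.tau_s])


def _combine_times(tau_m: float, *internal: float) -> float:
    """Harmonic combination; zero if any internal time is zero."""
    if any(t == 0.0 for t in internal):
        return 0.0
    inv = 1.0 / tau_m + sum(1.0 / t for t in internal)
    return 1.0 / inv


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: which parameters float and which are pinned.

    ``tau_m_policy`` is ``"local"`` (tau_m is fitted per residue, counted
    in k) or ``"fixed"`` (tau_m pinned at a configured value, not counted).
    """

    model_id: int
    free_params: tuple[str, ...]
    fixed_values: Mapping[str, float] = field(default_factory=dict)
    tau_m_policy: str = "local"

    def __post_init__(self) -> None:
        if self.tau_m_policy not in ("local", "fixed"):
            raise ValueError("tau_m_policy must be 'local' or 'fixed'")
        if ("tau_m" in self.free_params) != (self.tau_m_policy == "local"):
            raise ValueError("tau_m must be free iff tau_m_policy is 'local'")

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.free_params)


def model_spec(model_id: int, *, local_tau_m: bool = True) -> ModelSpec:
    """Build the canonical ModelSpec for one of models 1-5."""
    fixed = MODEL_FIXED[model_id]
    free = tuple(p for p in PARAM_NAMES[1:] if p not in fixed)
    if local_tau_m:
        free = ("tau_m",) + free
    return ModelSpec(
        model_id=model_id,
        free_params=free,
        fixed_values=dict(fixed),
        tau_m_policy="local" if local_tau_m else "fixed",
    )


def model_param_vector(
    spec: ModelSpec,
    free_values: Sequence[float],
    tau_m_fixed: float | None = None,
) -> ModelFreeParams:
    """Embed an ordered free-parameter vector into the full five-vector."""
    if len(free_values) != spec.k:
        raise ValueError(
            f"model {spec.model_id} expects {spec.k} free values, "
            f"got {len(free_values)}"
        )
    values = dict(zip(spec.free_params, free_values))
    values.update(spec.fixed_values)
    if "tau_m" not in values:
        if tau_m_fixed is None:
            raise ValueError("tau_m_fixed required when tau_m is not free")
        values["tau_m"] = tau_m_fixed
    return ModelFreeParams(**{n: float(values[n]) for n in PARAM_NAMES})


def spectral_density(omega, tau_m, Sf2, Ss2, tau_f, tau_s):
    """Vectorized J(omega); all arguments broadcast.  Times in s, omega rad/s."""
    omega = np.asarray(omega, dtype=float)
    tau_m = np.asarray(tau_m, dtype=float)
    tau_f = np.asarray(tau_f, dtype=float)
    tau_s = np.asarray(tau_s, dtype=float)
    Sf2 = np.asarray(Sf2, dtype=float)
    Ss2 = np.asarray(Ss2, dtype=float)

    tau1 = _combine_arr(tau_m, tau_s)
    tau2 = _combine_arr(tau_m, tau_f)
    tau3 = _combine_arr3(tau_m, tau_s, tau_f)

    J = (
        Sf2 * Ss2 * _lorentz(tau_m, omega)
        + Sf2 * (1.0 - Ss2) * _lorentz(tau1, omega)
        + (1.0 - Sf2) * Ss2 * _lorentz(tau2, omega)
        + (1.0 - Sf2) * (1.0 - Ss2) * _lorentz(tau3, omega)
    )
    return 0.4 * J


def spectral_density_grad(omega, tau_m, Sf2, Ss2, tau_f, tau_s):
    """J(omega) and its gradient wrt (tau_m, Sf2, Ss2, tau_f, tau_s).

    Returns ``(J, dJ)`` with ``dJ`` stacked along a trailing axis of
    length 5.  Derivatives at tau = 0 use the one-sided limits.
    """
    omega = np.asarray(omega, dtype=float)
    tau_m = np.asarray(tau_m, dtype=float)
    tau_f = np.asarray(tau_f, dtype=float)
    tau_s = np.asarray(tau_s, dtype=float)
    Sf2 = np.asarray(Sf2, dtype=float)
    Ss2 = np.asarray(Ss2, dtype=float)

    tau1 = _combine_arr(tau_m, tau_s)
    tau2 = _combine_arr(tau_m, tau_f)
    tau3 = _combine_arr3(tau_m, tau_s, tau_f)

    Lm, L1, L2, L3 = (_lorentz(t, omega) for t in (tau_m, tau1, tau2, tau3))
    Dm, D1, D2, D3 = (_dlorentz(t, omega) for t in (tau_m, tau1, tau2, tau3))

    A = Sf2 * Ss2
    Bc = Sf2 * (1.0 - Ss2)
    C = (1.0 - Sf2) * Ss2
    D = (1.0 - Sf2) * (1.0 - Ss2)

    J = 0.4 * (A * Lm + Bc * L1 + C * L2 + D * L3)

    # d tau_eff / d tau_x = (tau_eff / tau_x)^2; limit 1 as tau_x -> 0+
    # when the combined time tracks tau_x, 0 when another zero pins it.
    r1s = _safe_ratio_sq(tau1, tau_s, limit=1.0)
    r2f = _safe_ratio_sq(tau2, tau_f, limit=1.0)
    r3s = _safe_ratio_sq(tau3, tau_s, limit=np.where(tau_f > 0, 1.0, 0.0))
    r3f = _safe_ratio_sq(tau3, tau_f, limit=np.where(tau_s > 0, 1.0, 0.0))
    r1m = (tau1 / tau_m) ** 2
    r2m = (tau2 / tau_m) ** 2
    r3m = (tau3 / tau_m) ** 2

    d_tau_m = 0.4 * (A * Dm + Bc * D1 * r1m + C * D2 * r2m + D * D3 * r3m)
    d_Sf2 = 0.4 * (Ss2 * Lm + (1.0 - Ss2) * L1 - Ss2 * L2 - (1.0 - Ss2) * L3)
    d_Ss2 = 0.4 * (Sf2 * Lm - Sf2 * L1 + (1.0 - Sf2) * L2 - (1.0 - Sf2) * L3)
    d_tau_f = 0.4 * (C * D2 * r2f + D * D3 * r3f)
    d_tau_s = 0.4 * (Bc * D1 * r1s + D * D3 * r3s)

    dJ = np.stack(
        np.broadcast_arrays(d_tau_m, d_Sf2, d_Ss2, d_tau_f, d_tau_s), axis=-1
    )
    return J, dJ


def evaluate_J(params: ModelFreeParams, omega):
    """J(omega) for a validated parameter set (scalar or array omega)."""
    return spectral_density(
        omega, params.tau_m, params.Sf2, params.Ss2, params.tau_f, params.tau_s
    )


def _lorentz(tau, omega):
    return tau / (1.0 + (omega * tau) ** 2)


def _dlorentz(tau, omega):
    x2 = (omega * tau) ** 2
    return (1.0 - x2) / (1.0 + x2) ** 2


def _combine_arr(tau_m, tau_x):
    safe = np.where(tau_x > 0, tau_x, 1.0)
    with np.errstate(over="ignore"):
        inv = 1.0 / tau_m + 1.0 / safe
        return np.where(tau_x > 0, 1.0 / inv, 0.0)


def _combine_arr3(tau_m, tau_s, tau_f):
    both = (tau_s > 0) & (tau_f > 0)
    safe_s = np.where(tau_s > 0, tau_s, 1.0)
    safe_f = np.where(tau_f > 0, tau_f, 1.0)
    with np.errstate(over="ignore"):
        inv = 1.0 / tau_m + 1.0 / safe_s + 1.0 / safe_f
        return np.where(both, 1.0 / inv, 0.0)


def _safe_ratio_sq(tau_eff, tau_x, limit):
    safe = np.where(tau_x > 0, tau_x, 1.0)
    return np.where(tau_x > 0, (tau_eff / safe) ** 2, limit)
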