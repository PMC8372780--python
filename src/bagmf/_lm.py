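"""Batched bounded Levenberg-Marquardt for many small weighted fits.

The bootstrap ensembles refit the same five-parameter spectral density
model to thousands of 9-point data vectors.  Calling a general-purpose
optimizer once per replicate dominates runtime, so this module solves all
replicates simultaneously: residuals and analytic Jacobians are evaluated
on (B, n) arrays and the damped normal equations are solved with a
batched (B, k, k) linear solve.

Box bounds are handled dogbox-style: coordinates pinned at a bound whose
gradient points outward are frozen out of the linear system, and trial
points are clipped back into the box.  Damping follows Nielsen's
gain-ratio update, which avoids the slow crawl a fixed up/down factor
shows on sloppy five-parameter fits.

This is an internal acceleration path; ``fitting_selection.fit_model``
(scipy least_squares) remains the reference single-fit implementation and
the two are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np

from .modelfree import PARAM_NAMES, ModelSpec, spectral_density, spectral_density_grad


def _assemble_full(X, spec: ModelSpec, tau_m_fixed, B):
    """Map free-parameter matrix X (B, k) onto the five full columns."""
    cols = {}
    for j, name in enumerate(spec.free_params):
        cols[name] = X[:, j]
    for name, value in spec.fixed_values.items():
        cols[name] = np.full(B, float(value))
    if "tau_m" not in cols:
        cols["tau_m"] = np.full(B, float(tau_m_fixed))
    return [cols[n] for n in PARAM_NAMES]


def residual_and_jac(X, Y, ERR, OMEGA, spec: ModelSpec, tau_m_fixed):
    """Weighted residuals (B, n) and Jacobian (B, n, k) for free params."""
    B = X.shape[0]
    full = _assemble_full(X, spec, tau_m_fixed, B)
    J, dJ = spectral_density_grad(OMEGA, *[c[:, None] for c in full])
    r = (J - Y) / ERR
    free_idx = [PARAM_NAMES.index(n) for n in spec.free_params]
    jac = dJ[..., free_idx] / ERR[..., None]
    return r, jac


def chi2_batch(X, Y, ERR, OMEGA, spec: ModelSpec, tau_m_fixed=None):
    B = X.shape[0]
    full = _assemble_full(X, spec, tau_m_fixed, B)
    J = spectral_density(OMEGA, *[c[:, None] for c in full])
    return np.sum(((J - Y) / ERR) ** 2, axis=1)


def lm_fit_batch(
    Y,
    ERR,
    OMEGA,
    spec: ModelSpec,
    x0,
    lb,
    ub,
    tau_m_fixed=None,
    scale=None,
    max_iter=200,
    ftol=1e-14,
    xtol=1e-9,
):
    """Minimize the weighted chi-square for B problems at once.

    Parameters
    ----------
    Y, ERR, OMEGA : (B, n) arrays
        Data values, uncertainties (> 0) and angular frequencies.
    spec : ModelSpec
        Candidate model; its free parameters are optimized.
    x0 : (k,) or (B, k) array
        Start point(s), broadcast over the batch.
    lb, ub : (k,) arrays
        Box bounds on the free parameters.
    scale : (k,) array, optional
        Characteristic parameter magnitudes for conditioning.

    Returns
    -------
    x : (B, k) best parameters
    chi2 : (B,) final chi-square values
    converged : (B,) bool
    """
    Y = np.asarray(Y, dtype=float)
    ERR = np.asarray(ERR, dtype=float)
    OMEGA = np.asarray(OMEGA, dtype=float)
    B = Y.shape[0]
    k = len(lb)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    if scale is None:
        scale = np.array(
            [1e-9 if n.startswith("tau") else 1.0 for n in spec.free_params]
        )
    scale = np.asarray(scale, dtype=float)
    lb_s, ub_s = lb / scale, ub / scale

    X = np.clip(np.broadcast_to(np.asarray(x0, dtype=float), (B, k)).copy(), lb, ub)
    r, jac = residual_and_jac(X, Y, ERR, OMEGA, spec, tau_m_fixed)
    chi2 = np.sum(r**2, axis=1)

    # cached normal-equation pieces, refreshed only for rows that moved
    jac_s = jac * scale
    A = np.einsum("bnj,bnk->bjk", jac_s, jac_s)
    g = np.einsum("bnj,bn->bj", jac_s, r)

    lam = np.full(B, 1e-3)
    nu = np.full(B, 2.0)
    converged = np.zeros(B, dtype=bool)
    eye = np.eye(k)

    for _ in range(max_iter):
        act = ~converged
        if not act.any():
            break
        Xa = X[act]
        Aa = A[act].copy()
        ga = g[act].copy()
        Xs = Xa / scale

        # freeze coordinates pinned at a bound with an outward gradient
        at_lb = (Xs <= lb_s + 1e-12 * (1.0 + np.abs(lb_s))) & (ga > 0)
        at_ub = (Xs >= ub_s - 1e-12 * (1.0 + np.abs(ub_s))) & (ga < 0)
        frozen = at_lb | at_ub
        ga[frozen] = 0.0
        for j in range(k):
            f = frozen[:, j]
            if f.any():
                Aa[f, j, :] = 0.0
                Aa[f, :, j] = 0.0
                Aa[f, j, j] = 1.0

        diagA = np.einsum("bjj->bj", Aa)
        damp = np.maximum(diagA, 1e-14)
        M = Aa + lam[act, None, None] * damp[:, :, None] * eye
        try:
            step = -np.linalg.solve(M, ga[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            M = M + 1e-10 * eye
            step = -np.linalg.solve(M, ga[..., None])[..., 0]

        X_new = np.clip(Xa + step * scale, lb, ub)
        full = _assemble_full(X_new, spec, tau_m_fixed, X_new.shape[0])
        Jm = spectral_density(OMEGA[act], *[c[:, None] for c in full])
        r_new = (Jm - Y[act]) / ERR[act]
        chi2_new = np.sum(r_new**2, axis=1)

        # Nielsen damping via the gain ratio (actual / predicted reduction)
        pred = (
            -np.einsum("bj,bj->b", step, ga)
            - 0.5 * np.einsum("bj,bjk,bk->b", step, Aa, step)
        )
        rho = (chi2[act] - chi2_new) / np.maximum(pred, 1e-300)

        improved = chi2_new <= chi2[act]
        idx = np.flatnonzero(act)
        acc = idx[improved]
        rej = idx[~improved]
        reduction = chi2[acc] - chi2_new[improved]
        step_size = np.abs((X_new[improved] - Xa[improved]) / scale).max(axis=1)
        X[acc] = X_new[improved]
        chi2[acc] = chi2_new[improved]
        rho_acc = rho[improved]
        lam[acc] = lam[acc] * np.maximum(1.0 / 3.0, 1.0 - (2.0 * rho_acc - 1.0) ** 3)
        nu[acc] = 2.0
        lam[rej] = lam[rej] * nu[rej]
        nu[rej] = np.minimum(nu[rej] * 2.0, 64.0)

        done = (reduction <= ftol * (chi2[acc] + 1.0)) | (step_size < xtol)
        converged[acc[done]] = True
        converged[rej[lam[rej] > 1e9]] = True

        upd = acc[~converged[acc]]
        if upd.size:
            r_u, jac_u = residual_and_jac(
                X[upd], Y[upd], ERR[upd], OMEGA[upd], spec, tau_m_fixed
            )
            jac_su = jac_u * scale
            A[upd] = np.einsum("bnj,bnk->bjk", jac_su, jac_su)
            g[upd] = np.einsum("bnj,bn->bj", jac_su, r_u)

    return X, chi2, converged
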