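"""Bootstrap aggregation of model selection and the smoothed estimators.

For every enumerated bootstrap sample the full model selection (all
candidate models, AICc ranking, fast/slow relabelling of the shared
Model 2/3 form) is repeated, and the winning model's parameters are
recorded as a full five-vector with the null conventions Sf2 = 1 /
Ss2 = 1 and tau_f = 0 / tau_s = 0 for parameters the winner pins.  The
smoothed estimate of each parameter is the plain average of that column
over the B replicates.

The smoothed standard deviation uses the plug-in principle: with
Y*_ij the number of times original datum j enters replicate i,

    cov_jk    = (1/B) sum_i (Y*_ij - Ybar*_j) (mu_ik - mubar_k)
    sigma~_k  = sqrt( sum_j cov_jk^2 )

The naive alternative applies the ordinary bootstrap sample standard
deviation to the mixed-model replicate values; the smoothed estimate is
never larger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _lm
from .bootstrap_engine import (
    EnsembleArrays,
    bootstrap_sample_sd,
    build_ensemble,
    enumerate_block_arrangements,
)
from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .fitting_selection import (
    FitOptions,
    FitVector,
    SelectionResult,
    _free_values,
    _param_bounds,
    select_model,
    single_timescale_spec,
)
from .jw_mapping import SpectralDensitySet
from .modelfree import PARAM_NAMES, model_spec

logger = logging.getLogger(__name__)

AGG_COLUMNS = PARAM_NAMES + ("S2",)


@dataclass
class BaggedResult:
    """Smoothed per-residue estimates over the enumerated ensemble."""

    residue: int
    smoothed_params: dict[str, float]
    smoothed_sd: dict[str, float]
    naive_sd: dict[str, float]
    model_fractions: dict[int, float]
    replicate_matrix: np.ndarray  # (B_kept, 5) winner five-vectors
    Y_matrix: np.ndarray  # (B_kept, N) counter vectors
    winning_models: np.ndarray  # (B_kept,) model ids
    B_total: int
    B_kept: int
    #: product of the separately smoothed factors, reported alongside the
    #: default (mean of per-sample Sf2 * Ss2 products)
    S2_product_of_means: float = field(default=np.nan)


def smoothed_sd(
    replicate_matrix: np.ndarray,
    Y_matrix: np.ndarray,
    smoothed_params: np.ndarray | None = None,
    normalization: str = "efron",
) -> np.ndarray:
    """Plug-in smoothed standard deviation per parameter column.

    ``normalization="efron"`` (default) returns sqrt(sum_j cov_jk^2);
    ``"scaled"`` divides the sum by N inside the square root.
    """
    M = np.asarray(replicate_matrix, dtype=float)
    Y = np.asarray(Y_matrix, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    B = M.shape[0]
    if B < 2:
        raise ValueError("need at least two replicates")
    if Y.shape[0] != B:
        raise ValueError("replicate and counter matrices must align")
    center = M.mean(axis=0) if smoothed_params is None else np.asarray(smoothed_params)
    cov = (Y - Y.mean(axis=0)).T @ (M - center) / B  # (N, K)
    ss = np.sum(cov**2, axis=0)
    if normalization == "scaled":
        ss = ss / Y.shape[1]
    elif normalization != "efron":
        raise ValueError(f"unknown normalization: {normalization!r}")
    return np.sqrt(ss)


def naive_sd(replicate_matrix: np.ndarray) -> np.ndarray:
    """Ordinary bootstrap SD applied to the mixed-model replicate values."""
    return bootstrap_sample_sd(np.asarray(replicate_matrix, dtype=float))


def _batched_selection(
    ens: EnsembleArrays,
    options: FitOptions,
    tau_m_fixed: float | None,
    selection: SelectionResult,
):
    """Run full model selection for every replicate in batch form.

    Candidates are fitted with warm starts taken from the original-data
    fits plus generic grid starts; the shared single-timescale form is
    classified per replicate by the fast/slow threshold.
    """
    local = tau_m_fixed is None
    n = ens.Y.shape[1]
    B = ens.B

    candidates = []  # (k, ids_fn, full_params (B,5), chi2 (B,), conv (B,))
    for tag in ("m1", "st", "m4", "m5"):
        if tag == "st":
            spec = single_timescale_spec(local_tau_m=local)
            single = True
        else:
            spec = model_spec(int(tag[1]), local_tau_m=local)
            single = False
        k = spec.k
        if n - k - 1 <= 0:
            continue
        lb, ub = _param_bounds(spec, options, single_timescale=single)
        starts = _replicate_starts(tag, spec, selection, options, lb, ub)
        best_chi2 = np.full(B, np.inf)
        best_X = np.zeros((B, k))
        any_conv = np.zeros(B, dtype=bool)
        for x0 in starts:
            X, c2, conv = _lm.lm_fit_batch(
                ens.Y, ens.ERR, ens.OMEGA, spec, x0, lb, ub,
                tau_m_fixed=tau_m_fixed,
            )
            better = c2 < best_chi2
            best_chi2[better] = c2[better]
            best_X[better] = X[better]
            any_conv |= conv
        full = _embed_batch(best_X, spec, tau_m_fixed, B)
        if tag == "st":
            # relabel per replicate: slow fits move (Sf2, tau_f)->(Ss2, tau_s)
            slow = full[:, 3] >= options.tau_threshold
            relab = full.copy()
            relab[slow, 2] = full[slow, 1]  # Ss2 <- fitted S2
            relab[slow, 1] = 1.0
            relab[slow, 4] = full[slow, 3]  # tau_s <- fitted tau
            relab[slow, 3] = 0.0
            ids = np.where(slow, 3, 2)
            full = relab
        else:
            ids = np.full(B, int(tag[1]))
        aicc_vals = np.where(
            any_conv, best_chi2 + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0),
            np.inf,
        )
        candidates.append((k, ids, full, aicc_vals, any_conv))

    if not candidates:
        raise ValueError("no applicable candidate models")
    # candidates are in ascending-k order, so argmin resolves exact AICc
    # ties toward the more parsimonious model
    aicc_stack = np.stack([c[3] for c in candidates])  # (C, B)
    winner = np.argmin(aicc_stack, axis=0)
    kept = ~np.all(np.isinf(aicc_stack), axis=0)

    replicate_matrix = np.empty((B, 5))
    winning_ids = np.empty(B, dtype=int)
    for ci, (_, ids, full, _, _) in enumerate(candidates):
        sel = winner == ci
        replicate_matrix[sel] = full[sel]
        winning_ids[sel] = ids[sel]
    return replicate_matrix, winning_ids, kept


def _embed_batch(X, spec, tau_m_fixed, B):
    full = np.empty((B, 5))
    for j, name in enumerate(PARAM_NAMES):
        if name in spec.free_params:
            full[:, j] = X[:, spec.free_params.index(name)]
        elif name in spec.fixed_values:
            full[:, j] = spec.fixed_values[name]
        else:
            full[:, j] = tau_m_fixed
    return full


def _replicate_starts(tag, spec, selection: SelectionResult, options, lb, ub):
    """Warm starts: the original-data fit of the matching model plus a
    coarse grid point in the other basin(s)."""
    starts = []
    if tag == "st":
        fit = selection.per_model.get(2) or selection.per_model.get(3)
        if fit is not None:
            p = fit.params
            s2 = p.Sf2 if fit.model_id == 2 else p.Ss2
            tau = p.tau_f if fit.model_id == 2 else p.tau_s
            vals = {"tau_m": p.tau_m, "Sf2": s2, "tau_f": tau}
            starts.append(
                np.array([vals[name] for name in spec.free_params])
            )
        # cover both fast and slow basins explicitly
        for tau0 in (30e-12, 500e-12):
            starts.append(_grid_start(spec, selection, tau0))
    else:
        fit = selection.per_model.get(int(tag[1]))
        if fit is not None:
            starts.append(_free_values(fit, spec))
        starts.append(_grid_start(spec, selection, 100e-12))
    return [np.clip(s, lb, ub) for s in starts]


def _grid_start(spec, selection: SelectionResult, tau0):
    tau_m0 = selection.best_fit.params.tau_m
    defaults = {"tau_m": tau_m0, "Sf2": 0.8, "Ss2": 0.8,
                "tau_f": min(tau0, 50e-12), "tau_s": max(tau0, 300e-12)}
    if "tau_f" in spec.free_params and "tau_s" not in spec.free_params:
        defaults["tau_f"] = tau0  # single-timescale form
    return np.array([defaults[name] for name in spec.free_params])


def bagged_fit(
    sd_set: SpectralDensitySet,
    options: FitOptions = FitOptions(),
    tau_m_fixed: float | None = None,
    const: PhysicalConstants = DEFAULT_CONSTANTS,
    selection: SelectionResult | None = None,
    sd_normalization: str = "efron",
) -> BaggedResult:
    """Bootstrap-aggregate one residue over the full enumerated ensemble."""
    arrangements = enumerate_block_arrangements(sd_set.G)
    ens = build_ensemble(sd_set, arrangements, const)
    if selection is None:
        fv = FitVector.from_sd_set(sd_set, const)
        selection = select_model(fv, options, tau_m_fixed)

    replicate_matrix, winning_ids, kept = _batched_selection(
        ens, options, tau_m_fixed, selection
    )
    B_total = ens.B
    dropped = int(B_total - kept.sum())
    if dropped:
        logger.warning(
            "residue %d: dropped %d/%d bootstrap samples (no converged fit)",
            sd_set.residue, dropped, B_total,
        )
    M = replicate_matrix[kept]
    Y = ens.Y_matrix[kept].astype(float)
    ids = winning_ids[kept]
    B = M.shape[0]

    s2_col = M[:, 1] * M[:, 2]  # per-sample Sf2 * Ss2 before averaging
    M_ext = np.column_stack([M, s2_col])

    mu = M_ext.mean(axis=0)
    sd_smooth = smoothed_sd(M_ext, Y, mu, normalization=sd_normalization)
    sd_naive = naive_sd(M_ext)

    fractions = {
        mid: float(np.sum(ids == mid) / B) for mid in (1, 2, 3, 4, 5)
    }
    return BaggedResult(
        residue=sd_set.residue,
        smoothed_params=dict(zip(AGG_COLUMNS, map(float, mu))),
        smoothed_sd=dict(zip(AGG_COLUMNS, map(float, sd_smooth))),
        naive_sd=dict(zip(AGG_COLUMNS, map(float, sd_naive))),
        model_fractions=fractions,
        replicate_matrix=M,
        Y_matrix=Y,
        winning_models=ids,
        B_total=B_total,
        B_kept=B,
        S2_product_of_means=float(mu[1] * mu[2]),
    )


def bagged_table(results: list[BaggedResult]) -> pd.DataFrame:
    """Per-residue summary CSV layout (times in ns)."""
    rows = []
    for r in results:
        row: dict[str, float] = {"residue": r.residue, "B": r.B_kept}
        for mid in (1, 2, 3, 4, 5):
            row[f"frac_model{mid}"] = r.model_fractions[mid]
        for name in AGG_COLUMNS:
            scale = 1e9 if name.startswith("tau") else 1.0
            suffix = "_ns" if name.startswith("tau") else ""
            row[f"{name}{suffix}"] = r.smoothed_params[name] * scale
            row[f"{name}{suffix}_sd"] = r.smoothed_sd[name] * scale
            row[f"{name}{suffix}_sd_naive"] = r.naive_sd[name] * scale
        row["S2_product_of_means"] = r.S2_product_of_means
        rows.append(row)
    return pd.DataFrame(rows)


def replicate_histogram_table(result: BaggedResult) -> pd.DataFrame:
    """Long-format dump of replicate parameter values for distribution plots."""
    rows = []
    for i in range(result.B_kept):
        for j, name in enumerate(PARAM_NAMES):
            rows.append(
                {
                    "parameter": name,
                    "value": result.replicate_matrix[i, j],
                    "model_id": int(result.winning_models[i]),
                }
            )
    return pd.DataFrame(rows)
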