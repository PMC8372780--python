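"""Enumerated block-constrained bootstrap ensemble.

Spectral density values of the three classes J(0), J(wN) and J(0.87 wH)
must not be interchanged by resampling, so bootstrap samples are drawn
within each class.  Within one class of G field-ordered values an
arrangement is a multiset of size G with no value repeated more than
twice; for G = 4 there are 19 such arrangements and for G = 3 there are
7.  The ensemble enumerates every combination of one arrangement per
class (19^3 = 6859 samples at G = 4) rather than sampling at random; the
first sample is the identity and reproduces the original data.

Sample index i (1-based) decomposes in mixed radix base n_arr, the most
significant digit selecting the J(0) arrangement:

    l = (i - 1) // n_arr**2 + 1
    m = ((i - 1) // n_arr) % n_arr + 1
    n = (i - 1) % n_arr + 1
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .jw_mapping import (
    SpectralDensitySet,
    jackknife_J0_uncertainty,
    weighted_mean_J0,
)
from .constants import DEFAULT_CONSTANTS, PhysicalConstants

logger = logging.getLogger(__name__)

# Published arrangement order for G = 4 (1-based pointer vectors).  The
# canonical generated order is not guaranteed to match this table, so it
# is stored verbatim to honour the documented index arithmetic (sample
# 1260 -> blocks (4, 10, 6)).
_G4_POINTERS: tuple[tuple[int, ...], ...] = (
    (1, 2, 3, 4),
    (1, 1, 3, 4),
    (1, 2, 1, 4),
    (1, 2, 3, 1),
    (2, 2, 3, 4),
    (1, 2, 2, 4),
    (1, 2, 3, 2),
    (3, 2, 3, 4),
    (1, 3, 3, 4),
    (1, 2, 3, 3),
    (4, 2, 3, 4),
    (1, 4, 3, 4),
    (1, 2, 4, 4),
    (1, 1, 2, 2),
    (1, 1, 3, 3),
    (1, 1, 4, 4),
    (2, 2, 3, 3),
    (2, 2, 4, 4),
    (3, 3, 4, 4),
)


@dataclass(frozen=True)
class BlockArrangement:
    """One within-block resampling: 1-based pointer and its counter."""

    pointer: tuple[int, ...]
    counter: tuple[int, ...]

    def __post_init__(self) -> None:
        G = len(self.pointer)
        if counter_from_pointer(self.pointer) != self.counter:
            raise ValueError("counter inconsistent with pointer")
        if sum(self.counter) != G or max(self.counter) > 2:
            raise ValueError("counter must sum to G with multiplicity <= 2")


def counter_from_pointer(pointer: tuple[int, ...]) -> tuple[int, ...]:
    """Multiplicity of each 1-based index in the pointer vector."""
    G = len(pointer)
    return tuple(pointer.count(j + 1) for j in range(G))


def enumerate_block_arrangements(G: int) -> list[BlockArrangement]:
    """All multisets of size G over G items with multiplicity <= 2.

    The identity arrangement comes first.  For G = 4 the published table
    order is used; otherwise the remaining arrangements follow the
    counter vectors in descending lexicographic order.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    if G == 4:
        return [
            BlockArrangement(p, counter_from_pointer(p)) for p in _G4_POINTERS
        ]
    identity = tuple([1] * G)
    counters = sorted(
        (
            c
            for c in itertools.product((0, 1, 2), repeat=G)
            if sum(c) == G and c != identity
        ),
        reverse=True,
    )
    out = [BlockArrangement(tuple(range(1, G + 1)), identity)]
    for c in counters:
        pointer = tuple(
            j + 1 for j, count in enumerate(c) for _ in range(count)
        )
        out.append(BlockArrangement(pointer, c))
    return out


def ensemble_size(G: int) -> int:
    """Total enumerated bootstrap samples: (arrangements per block)^3."""
    return len(enumerate_block_arrangements(G)) ** 3


def index_to_block_indices(i: int, n_arr: int) -> tuple[int, int, int]:
    """Mixed-radix split of sample index i into block indices (l, m, n).

    l selects the J(0) arrangement, m the J(wN) arrangement and n the
    J(0.87 wH) arrangement; all indices are 1-based.
    """
    if not 1 <= i <= n_arr**3:
        raise ValueError(f"sample index {i} outside 1..{n_arr ** 3}")
    q = i - 1
    return (q // n_arr**2 + 1, (q // n_arr) % n_arr + 1, q % n_arr + 1)


@dataclass(frozen=True)
class BootstrapSample:
    """One resampled spectral density vector plus its counter vector."""

    index_i: int
    block_indices: tuple[int, int, int]
    Y_star: np.ndarray  # length N = 3G, concatenated per-block counters
    y_star: np.ndarray  # length N raw resampled values (J0|JwN|JwH order)
    y_fit: np.ndarray  # length 1 + 2G fit vector
    err_fit: np.ndarray
    omega_fit: np.ndarray


def _resample_j0(sd_set: SpectralDensitySet, pointer: tuple[int, ...]):
    idx = np.array(pointer) - 1
    vals = sd_set.J0[idx]
    errs = sd_set.J0_err[idx]
    mean = weighted_mean_J0(vals, errs)
    err = jackknife_J0_uncertainty(vals, errs)
    return vals, mean, err


def build_sample(
    i: int,
    arrangements: list[BlockArrangement],
    sd_set: SpectralDensitySet,
    const: PhysicalConstants = DEFAULT_CONSTANTS,
) -> BootstrapSample:
    """Materialize the i-th enumerated bootstrap sample for one residue.

    The three pointer vectors are applied to the field-ordered J(0),
    J(wN) and J(0.87 wH) lists; the resampled J(0) multiset is collapsed
    to its weighted mean with a fresh jackknife uncertainty, exactly as
    for the original data.
    """
    n_arr = len(arrangements)
    l, m, n = index_to_block_indices(i, n_arr)
    arr_l, arr_m, arr_n = arrangements[l - 1], arrangements[m - 1], arrangements[n - 1]

    j0_vals, j0_mean, j0_err = _resample_j0(sd_set, arr_l.pointer)

    idx_m = np.array(arr_m.pointer) - 1
    idx_n = np.array(arr_n.pointer) - 1
    wN, wH = sd_set.omegas(const)

    y_fit = np.concatenate(([j0_mean], sd_set.JwN[idx_m], sd_set.JwH087[idx_n]))
    err_fit = np.concatenate(
        ([j0_err], sd_set.JwN_err[idx_m], sd_set.JwH087_err[idx_n])
    )
    omega_fit = np.concatenate(([0.0], wN[idx_m], wH[idx_n]))

    Y_star = np.concatenate((arr_l.counter, arr_m.counter, arr_n.counter))
    y_star = np.concatenate(
        (j0_vals, sd_set.JwN[idx_m], sd_set.JwH087[idx_n])
    )
    return BootstrapSample(
        index_i=i,
        block_indices=(l, m, n),
        Y_star=Y_star,
        y_star=y_star,
        y_fit=y_fit,
        err_fit=err_fit,
        omega_fit=omega_fit,
    )


@dataclass(frozen=True)
class EnsembleArrays:
    """The full enumerated ensemble for one residue, in batch form."""

    Y: np.ndarray  # (B, 1 + 2G) fit values
    ERR: np.ndarray  # (B, 1 + 2G)
    OMEGA: np.ndarray  # (B, 1 + 2G)
    Y_matrix: np.ndarray  # (B, 3G) concatenated counter vectors
    indices: np.ndarray  # (B, 3) 1-based block indices

    @property
    def B(self) -> int:
        return self.Y.shape[0]


def build_ensemble(
    sd_set: SpectralDensitySet,
    arrangements: list[BlockArrangement] | None = None,
    const: PhysicalConstants = DEFAULT_CONSTANTS,
) -> EnsembleArrays:
    """Vectorized construction of all B = n_arr^3 bootstrap samples."""
    G = sd_set.G
    if arrangements is None:
        arrangements = enumerate_block_arrangements(G)
    n_arr = len(arrangements)
    B = n_arr**3

    # per-arrangement J(0) means/errors and per-block selections
    j0_mean = np.empty(n_arr)
    j0_err = np.empty(n_arr)
    for a, arr in enumerate(arrangements):
        _, j0_mean[a], j0_err[a] = _resample_j0(sd_set, arr.pointer)

    ptr = np.array([arr.pointer for arr in arrangements]) - 1  # (n_arr, G)
    counters = np.array([arr.counter for arr in arrangements])  # (n_arr, G)
    wN, wH = sd_set.omegas(const)

    q = np.arange(B)
    l = q // n_arr**2
    m = (q // n_arr) % n_arr
    n = q % n_arr

    JwN_sel = sd_set.JwN[ptr]  # (n_arr, G)
    JwN_err_sel = sd_set.JwN_err[ptr]
    wN_sel = wN[ptr]
    JwH_sel = sd_set.JwH087[ptr]
    JwH_err_sel = sd_set.JwH087_err[ptr]
    wH_sel = wH[ptr]

    Y = np.concatenate(
        (j0_mean[l][:, None], JwN_sel[m], JwH_sel[n]), axis=1
    )
    ERR = np.concatenate(
        (j0_err[l][:, None], JwN_err_sel[m], JwH_err_sel[n]), axis=1
    )
    OMEGA = np.concatenate(
        (np.zeros((B, 1)), wN_sel[m], wH_sel[n]), axis=1
    )
    Y_matrix = np.concatenate((counters[l], counters[m], counters[n]), axis=1)
    indices = np.stack((l + 1, m + 1, n + 1), axis=1)
    return EnsembleArrays(Y=Y, ERR=ERR, OMEGA=OMEGA, Y_matrix=Y_matrix, indices=indices)


def ensemble_audit_table(ens: EnsembleArrays) -> pd.DataFrame:
    """Audit dump: sample index, block indices and the counter vector."""
    N = ens.Y_matrix.shape[1]
    data = {
        "i": np.arange(1, ens.B + 1),
        "l": ens.indices[:, 0],
        "m": ens.indices[:, 1],
        "n": ens.indices[:, 2],
    }
    for j in range(N):
        data[f"Y{j + 1}"] = ens.Y_matrix[:, j]
    return pd.DataFrame(data)


def bootstrap_sample_sd(values: np.ndarray) -> np.ndarray:
    """Sample standard deviation over bootstrap replicates (ddof = 1)."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least two replicates")
    return values.std(axis=0, ddof=1)


def conventional_bootstrap_sd(
    sd_set: SpectralDensitySet,
    best_fit,
    options=None,
    tau_m_fixed: float | None = None,
    const: PhysicalConstants = DEFAULT_CONSTANTS,
) -> dict[str, float]:
    """Fixed-model bootstrap standard deviations over the full ensemble.

    The model selected against the original data is refitted (parameters
    only) to every enumerated sample; the per-parameter sample standard
    deviation over the B replicates is returned (0.0 for pinned
    parameters).  Non-converged replicates are dropped and logged.
    """
    from . import _lm
    from .fitting_selection import (
        FitOptions,
        _free_values,
        _param_bounds,
    )
    from .modelfree import PARAM_NAMES, model_spec

    options = options or FitOptions()
    ens = build_ensemble(sd_set, const=const)
    local = tau_m_fixed is None
    spec = model_spec(best_fit.model_id, local_tau_m=local)
    lb, ub = _param_bounds(spec, options)
    x0 = _free_values(best_fit, spec)
    X, _, converged = _lm.lm_fit_batch(
        ens.Y, ens.ERR, ens.OMEGA, spec, x0, lb, ub, tau_m_fixed=tau_m_fixed
    )
    X = X[converged]
    dropped = ens.B - X.shape[0]
    if dropped:
        logger.info(
            "conventional bootstrap: dropped %d/%d replicates", dropped, ens.B
        )
    sds = bootstrap_sample_sd(X)
    out = {name: 0.0 for name in PARAM_NAMES}
    out.update({name: float(s) for name, s in zip(spec.free_params, sds)})
    return out
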