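"""Reduced spectral density mapping of multi-field R1/R2/NOE data.

Each (R1, R2, NOE) triple measured at one static field maps linearly onto
three spectral density values:

    sigma_NH   = (NOE - 1) * R1 * gamma_N / gamma_H
    J(0.87 wH) = 4 * sigma_NH / (5 * d_NH^2)
    J(wN)      = 4 * (R1 - 1.249 * sigma_NH) / (3 d_NH^2 + 4 c_NH^2)
    J(0)       = 6 * (R2 - 0.5 R1 - 0.454 * sigma_NH) / (3 d_NH^2 + 4 c_NH^2)

Uncertainties are propagated to first order (exact here, since the map is
linear in R1, R2 and sigma_NH given independent Gaussian errors).  The G
per-field J(0) values are collapsed to an inverse-variance weighted mean
whose uncertainty comes from delete-one jackknife resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

RATES_COLUMNS = [
    "residue", "field_MHz",
    "R1", "R1_err", "R2", "R2_err", "NOE", "NOE_err",
]


@dataclass(frozen=True)
class RelaxationRecord:
    """One residue x one field measurement triple with uncertainties."""

    residue: int
    field_MHz: float
    R1: float
    R1_err: float
    R2: float
    R2_err: float
    NOE: float
    NOE_err: float

    def __post_init__(self) -> None:
        if self.field_MHz <= 0:
            raise ValueError(f"residue {self.residue}: field_MHz must be > 0")
        if self.R1 <= 0 or self.R2 <= 0:
            raise ValueError(
                f"residue {self.residue}: relaxation rates must be positive"
            )
        if min(self.R1_err, self.R2_err, self.NOE_err) < 0:
            raise ValueError(f"residue {self.residue}: errors must be >= 0")


@dataclass(frozen=True)
class MappedJ:
    """Spectral density triple for one field, with propagated errors."""

    J0: float
    J0_err: float
    JwN: float
    JwN_err: float
    JwH087: float
    JwH087_err: float


def map_record_to_J(
    rec: RelaxationRecord,
    const: PhysicalConstants = DEFAULT_CONSTANTS,
) -> MappedJ:
    """Reduced mapping of one record onto (J(0), J(wN), J(0.87 wH))."""
    d2 = const.d_NH**2
    c2 = const.c_NH(rec.field_MHz) ** 2
    denom = 3.0 * d2 + 4.0 * c2
    g = const.gamma_N / const.gamma_H

    sigma_NH = (rec.NOE - 1.0) * rec.R1 * g
    # partials of sigma_NH
    ds_dR1 = (rec.NOE - 1.0) * g
    ds_dNOE = rec.R1 * g

    JwH = 4.0 * sigma_NH / (5.0 * d2)
    JwH_err = (4.0 / (5.0 * d2)) * math.hypot(
        ds_dR1 * rec.R1_err, ds_dNOE * rec.NOE_err
    )

    JwN = 4.0 * (rec.R1 - 1.249 * sigma_NH) / denom
    JwN_err = (4.0 / denom) * math.hypot(
        (1.0 - 1.249 * ds_dR1) * rec.R1_err, 1.249 * ds_dNOE * rec.NOE_err
    )

    J0 = 6.0 * (rec.R2 - 0.5 * rec.R1 - 0.454 * sigma_NH) / denom
    J0_err = (6.0 / denom) * math.sqrt(
        rec.R2_err**2
        + ((0.5 + 0.454 * ds_dR1) * rec.R1_err) ** 2
        + (0.454 * ds_dNOE * rec.NOE_err) ** 2
    )

    return MappedJ(J0, J0_err, JwN, JwN_err, JwH, JwH_err)


def weighted_mean_J0(values: Sequence[float], errors: Sequence[float]) -> float:
    """Inverse-variance weighted mean; rejects degenerate zero errors."""
    values = np.asarray(values, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if values.shape != errors.shape or values.ndim != 1 or values.size == 0:
        raise ValueError("values and errors must be equal-length 1-D arrays")
    if np.any(errors <= 0):
        raise ValueError("all uncertainties must be > 0 for weighting")
    w = 1.0 / errors**2
    return float(np.sum(w * values) / np.sum(w))


def jackknife_J0_uncertainty(
    values: Sequence[float], errors: Sequence[float]
) -> float:
    """Delete-one jackknife standard error of the weighted-mean J(0).

    With a single field there is nothing to resample: the propagated
    error of the lone value is returned instead.
    """
    values = np.asarray(values, dtype=float)
    errors = np.asarray(errors, dtype=float)
    G = values.size
    if G == 1:
        return float(errors[0])
    loo = np.empty(G)
    for i in range(G):
        keep = np.arange(G) != i
        loo[i] = weighted_mean_J0(values[keep], errors[keep])
    return float(math.sqrt((G - 1) / G * np.sum((loo - loo.mean()) ** 2)))


@dataclass(frozen=True)
class SpectralDensitySet:
    """Per-residue spectral density values at G fields (SI units, s/rad).

    Arrays are ordered by ascending static field.  ``J0_mean`` /
    ``J0_mean_err`` hold the weighted-mean J(0) and its jackknife error.
    """

    residue: int
    fields_MHz: tuple[float, ...]
    J0: np.ndarray
    J0_err: np.ndarray
    JwN: np.ndarray
    JwN_err: np.ndarray
    JwH087: np.ndarray
    JwH087_err: np.ndarray
    J0_mean: float
    J0_mean_err: float

    @property
    def G(self) -> int:
        return len(self.fields_MHz)

    @classmethod
    def from_records(
        cls,
        records: Iterable[RelaxationRecord],
        const: PhysicalConstants = DEFAULT_CONSTANTS,
        j0_error_mode: str = "jackknife",
    ) -> "SpectralDensitySet":
        """Map one residue's records (one per field) and average J(0).

        ``j0_error_mode`` selects the uncertainty attached to the mean
        J(0): ``"jackknife"`` (default) or ``"combined"`` (jackknife and
        propagated weighted-mean error added in quadrature).
        """
        records = sorted(records, key=lambda r: r.field_MHz)
        if not records:
            raise ValueError("no records supplied")
        residues = {r.residue for r in records}
        if len(residues) != 1:
            raise ValueError(f"records span multiple residues: {residues}")
        fields = tuple(r.field_MHz for r in records)
        if len(set(fields)) != len(fields):
            raise ValueError(f"residue {records[0].residue}: duplicate fields")

        mapped = [map_record_to_J(r, const) for r in records]
        J0 = np.array([m.J0 for m in mapped])
        J0_err = np.array([m.J0_err for m in mapped])
        mean = weighted_mean_J0(J0, J0_err)
        jack = jackknife_J0_uncertainty(J0, J0_err)
        if j0_error_mode == "combined":
            propagated = 1.0 / math.sqrt(np.sum(1.0 / J0_err**2))
            mean_err = math.hypot(jack, propagated)
        elif j0_error_mode == "jackknife":
            mean_err = jack
        else:
            raise ValueError(f"unknown j0_error_mode: {j0_error_mode!r}")

        return cls(
            residue=records[0].residue,
            fields_MHz=fields,
            J0=J0,
            J0_err=J0_err,
            JwN=np.array([m.JwN for m in mapped]),
            JwN_err=np.array([m.JwN_err for m in mapped]),
            JwH087=np.array([m.JwH087 for m in mapped]),
            JwH087_err=np.array([m.JwH087_err for m in mapped]),
            J0_mean=mean,
            J0_mean_err=mean_err,
        )

    def omegas(self, const: PhysicalConstants = DEFAULT_CONSTANTS):
        """(omega_N per field, 0.87*omega_H per field), ascending field."""
        wN = np.array([const.omega_N(f) for f in self.fields_MHz])
        wH = np.array([0.87 * const.omega_H(f) for f in self.fields_MHz])
        return wN, wH

    def fit_arrays(self, const: PhysicalConstants = DEFAULT_CONSTANTS):
        """(y, err, omega) of length 1 + 2G for model fitting.

        Layout: mean J(0), then the G J(wN) and G J(0.87 wH) values in
        ascending-frequency order.
        """
        wN, wH = self.omegas(const)
        y = np.concatenate(([self.J0_mean], self.JwN, self.JwH087))
        err = np.concatenate(([self.J0_mean_err], self.JwN_err, self.JwH087_err))
        omega = np.concatenate(([0.0], wN, wH))
        if np.any(np.diff(omega) < 0):
            raise AssertionError("fit-vector frequencies not non-decreasing")
        return y, err, omega

    def raw_vector(self):
        """The N = 3G raw values (J(0) block, J(wN) block, J(0.87 wH) block)."""
        return np.concatenate((self.J0, self.JwN, self.JwH087))


def read_rates_csv(path: str | Path) -> pd.DataFrame:
    """Read a rates table; separator sniffed between comma and tab."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if list(df.columns) != RATES_COLUMNS:
        raise ValueError(
            f"{path}: expected header {RATES_COLUMNS}, got {list(df.columns)}"
        )
    return df


def records_from_frame(df: pd.DataFrame) -> dict[int, list[RelaxationRecord]]:
    """Group a rates table into per-residue record lists, validating rows."""
    by_residue: dict[int, list[RelaxationRecord]] = {}
    for idx, row in df.iterrows():
        try:
            rec = RelaxationRecord(
                residue=int(row["residue"]),
                field_MHz=float(row["field_MHz"]),
                R1=float(row["R1"]),
                R1_err=float(row["R1_err"]),
                R2=float(row["R2"]),
                R2_err=float(row["R2_err"]),
                NOE=float(row["NOE"]),
                NOE_err=float(row["NOE_err"]),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
        by_residue.setdefault(rec.residue, []).append(rec)
    return by_residue


def map_rates_table(
    df: pd.DataFrame,
    const: PhysicalConstants = DEFAULT_CONSTANTS,
    j0_error_mode: str = "jackknife",
) -> list[SpectralDensitySet]:
    """Map a full rates table to per-residue spectral density sets."""
    grouped = records_from_frame(df)
    return [
        SpectralDensitySet.from_records(recs, const, j0_error_mode)
        for _, recs in sorted(grouped.items())
    ]


def jw_table(sets: list[SpectralDensitySet]) -> pd.DataFrame:
    """Presentation table of mapped values in ns/rad, fields ascending."""
    rows = []
    for s in sets:
        row: dict[str, float] = {
            "residue": s.residue,
            "J0_mean_ns": s.J0_mean * 1e9,
            "J0_mean_err_ns": s.J0_mean_err * 1e9,
        }
        for i, f in enumerate(s.fields_MHz):
            tag = f"{f:g}"
            row[f"JwN_{tag}_ns"] = s.JwN[i] * 1e9
            row[f"JwN_{tag}_err_ns"] = s.JwN_err[i] * 1e9
            row[f"JwH087_{tag}_ns"] = s.JwH087[i] * 1e9
            row[f"JwH087_{tag}_err_ns"] = s.JwH087_err[i] * 1e9
        rows.append(row)
    return pd.DataFrame(rows)
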