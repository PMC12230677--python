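"""Conformational-ensemble figures of merit for charge assignment methods.

Given per-(method, conformation, atom) charge tables, this module computes
the statistics used to compare charge assignment methods across an
ensemble of geometric conformations:

* rms charge transfer magnitude: sigma_method, the population rms of the
  conformation-averaged charges about the method's overall mean charge
  (the mean matters because training sets can contain charged molecules);
* conformational sensitivity: the pooled rms deviation of per-conformation
  charges about each atom's conformation average, and its normalization by
  sigma_method (unitless);
* the covariance and Pearson correlation matrices between methods over
  conformation-averaged charges, the summed correlations S_alpha, and the
  count of strong (>= 0.9) off-diagonal correlations.

All denominators are population (1/N) normalized; these statistics are rms
quantities, not sample standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

STRONG_CORRELATION = 0.9


@dataclass
class EnsembleChargeTable:
    """Rectangular charge table: values[method, conformation, atom]."""

    methods: list[str]
    conformations: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("values must have shape (methods, conformations, atoms)")
        if self.values.shape[0] != len(self.methods):
            raise ValidationError("method labels inconsistent with values")
        if self.values.shape[1] != len(self.conformations):
            raise ValidationError("conformation labels inconsistent with values")
        if self.values.shape[1] < 1:
            raise ValidationError("need at least one conformation per method")

    @property
    def n_atoms(self) -> int:
        return self.values.shape[2]

    def method_index(self, method: str) -> int:
        try:
            return self.methods.index(method)
        except ValueError as exc:
            raise ValidationError(f"unknown method {method!r}") from exc

    def to_long(self) -> pd.DataFrame:
        rows = []
        for mi, m in enumerate(self.methods):
            for ci, c in enumerate(self.conformations):
                for a in range(self.n_atoms):
                    rows.append((m, c, a, self.values[mi, ci, a]))
        return pd.DataFrame(rows, columns=["method", "conformation", "atom", "charge"])

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "EnsembleChargeTable":
        """Build from a long-format table (method, conformation, atom, charge)."""
        need = {"method", "conformation", "atom", "charge"}
        if not need.issubset(df.columns):
            raise ValidationError(f"long table must have columns {sorted(need)}")
        pivot = df.pivot_table(
            index=["method", "conformation"], columns="atom", values="charge"
        )
        if pivot.isna().any().any():
            raise ValidationError("charge table is not rectangular over (method, conformation, atom)")
        methods = sorted(df["method"].unique())
        confs = sorted(df["conformation"].unique())
        atoms = sorted(df["atom"].unique())
        values = np.array(
            [[pivot.loc[(m, c), atoms].to_numpy() for c in confs] for m in methods]
        )
        return cls(methods=methods, conformations=[str(c) for c in confs], values=values)


@dataclass
class MeritReport:
    methods: list[str]
    sigma: np.ndarray  # rms charge transfer per method
    mean_charge: np.ndarray
    sensitivity: np.ndarray
    normalized_sensitivity: np.ndarray
    covariance: np.ndarray  # Lambda
    correlation: np.ndarray  # Omega
    summed_correlations: np.ndarray  # S_alpha
    n_strong: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.methods,
                "rms_charge_transfer": self.sigma,
                "mean_charge": self.mean_charge,
                "sensitivity": self.sensitivity,
                "normalized_sensitivity": self.normalized_sensitivity,
                "summed_correlations": self.summed_correlations,
                "n_strong": self.n_strong,
            }
        )


def conformation_average(table: EnsembleChargeTable) -> np.ndarray:
    """Arithmetic mean over conformations: shape (methods, atoms)."""
    return table.values.mean(axis=1)


def rms_charge_transfer(avg_charges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-method sigma and overall mean charge from conformation-averaged
    charges of shape (methods, atoms)."""
    avg_charges = np.atleast_2d(np.asarray(avg_charges, dtype=float))
    if avg_charges.shape[1] < 2:
        raise ValidationError("need at least two atoms")
    qbar = avg_charges.mean(axis=1)
    sigma = np.sqrt(np.mean((avg_charges - qbar[:, None]) ** 2, axis=1))
    return sigma, qbar


def conformational_sensitivity(
    table: EnsembleChargeTable, method: str
) -> tuple[float, float]:
    """(sensitivity, normalized sensitivity) of one method.

    Sensitivity is the rms of (q_Aj - q_A^avg) pooled over all atoms and
    conformations; normalization divides by sigma_method.
    """
    if len(table.conformations) < 2:
        raise ValidationError("need at least two conformations")
    mi = table.method_index(method)
    vals = table.values[mi]  # (conf, atoms)
    dev = vals - vals.mean(axis=0, keepdims=True)
    sens = float(np.sqrt(np.mean(dev**2)))
    sigma, _ = rms_charge_transfer(vals.mean(axis=0)[None, :])
    if sigma[0] == 0.0:
        raise ValidationError(
            f"method {method!r} has zero rms charge transfer; normalized "
            "sensitivity undefined"
        )
    return sens, sens / float(sigma[0])


def method_correlations(avg_charges: np.ndarray, methods: list[str]) -> MeritReport:
    """Covariance and Pearson correlation matrices between methods.

    ``avg_charges`` has shape (methods, atoms).  S_alpha sums each row of
    the correlation matrix (self included); ``n_strong`` counts strong
    correlations Omega >= 0.9 with other methods (self excluded).
    """
    avg = np.atleast_2d(np.asarray(avg_charges, dtype=float))
    if avg.shape[0] < 2:
        raise ValidationError("need at least two methods")
    sigma, qbar = rms_charge_transfer(avg)
    if np.any(sigma == 0.0):
        zero = [methods[i] for i in np.flatnonzero(sigma == 0.0)]
        raise ValidationError(f"zero-variance method(s): {zero}; correlation undefined")
    centered = avg - qbar[:, None]
    cov = centered @ centered.T / avg.shape[1]
    corr = cov / np.outer(sigma, sigma)
    s_alpha = corr.sum(axis=1)
    off = corr - 2.0 * np.eye(len(methods))  # self-correlation pushed below threshold
    n_strong = (off >= STRONG_CORRELATION).sum(axis=1)
    return MeritReport(
        methods=list(methods),
        sigma=sigma,
        mean_charge=qbar,
        sensitivity=np.full(len(methods), np.nan),
        normalized_sensitivity=np.full(len(methods), np.nan),
        covariance=cov,
        correlation=corr,
        summed_correlations=s_alpha,
        n_strong=n_strong.astype(int),
    )


def merit_report(table: EnsembleChargeTable) -> MeritReport:
    """Full figure-of-merit report for an ensemble charge table."""
    avg = conformation_average(table)
    report = method_correlations(avg, table.methods)
    for i, m in enumerate(table.methods):
        if len(table.conformations) >= 2:
            sens, nsens = conformational_sensitivity(table, m)
        else:
            sens, nsens = 0.0, 0.0
        report.sensitivity[i] = sens
        report.normalized_sensitivity[i] = nsens
    return report


def pareto_table(report: MeritReport, rrmse_medians: dict[str, float]) -> pd.DataFrame:
    """Accuracy/sensitivity trade-off table, one row per method, ordered by
    (median RRMSE, sensitivity)."""
    missing = [m for m in report.methods if m not in rrmse_medians]
    if missing:
        raise ValidationError(f"rrmse_medians missing methods: {missing}")
    df = report.to_frame()
    df["median_rrmse"] = [rrmse_medians[m] for m in report.methods]
    df = df[
        [
            "method",
            "median_rrmse",
            "sensitivity",
            "normalized_sensitivity",
            "rms_charge_transfer",
            "summed_correlations",
            "n_strong",
        ]
    ]
    return df.sort_values(["median_rrmse", "sensitivity"], kind="stable").reset_index(
        drop=True
    )
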