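"""Accumulation-ratio inference from residual-metabolite measurements.

A chemostat culture held at a fixed specific growth rate is assumed to
maintain a constant cytosolic concentration c_in of a symported
carboxylate while the extracellular pH is ramped.  If the transporter
operates at thermodynamic equilibrium, the measured residual
concentration obeys

    c_out(pH_out) = c_in * 10**(pH_out - pH_in)

equivalently, on a log scale, a straight line of unit slope in pH_out:

    log10 c_out = (log10 c_in - pH_in) + pH_out

This module provides
  * :class:`ConcentrationSeries` -- replicate residual concentrations
    indexed by extracellular pH, read from tidy CSV;
  * :func:`infer_cytosolic_concentration` -- the back-calculation of c_in
    as the measured c_out at the pH where dpH = 0;
  * :func:`accumulation_ratio_profile` / :class:`ARProfile` -- observed
    vs predicted accumulation ratios across the ramp;
  * :func:`deviation_report` -- flags pH values where the culture departs
    from the equilibrium line;
  * :class:`AccumulationRatioModel` -- a least-squares fit of the
    log-linear equilibrium law, statsmodels-style (fit() returns a
    results object with estimates, standard errors and a summary table).

Only the offset alpha = log10 c_in - pH_in of the unit-slope line is
identifiable from a single series; pH_in and c_in are recovered
conditionally on an anchor for the other (the literature convention,
also used for the study data this emulates, anchors pH_in = 7.0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ExtrapolationError, InsufficientDataError
from .thermo import LACTIC_ACID, PYRUVIC_ACID, WeakAcid

__all__ = [
    "ConcentrationSeries",
    "ARProfile",
    "AccumulationRatioModel",
    "AccumulationRatioResults",
    "infer_cytosolic_concentration",
    "accumulation_ratio_profile",
    "deviation_report",
    "recover_parameters",
]

logger = logging.getLogger(__name__)

#: Known acids for unit conversion on read, keyed by lowercase name.
KNOWN_ACIDS: dict[str, WeakAcid] = {
    "lactate": LACTIC_ACID,
    "pyruvate": PYRUVIC_ACID,
}

_G_PER_L_ALIASES = {"g/l", "g_per_l", "g l-1", "gl-1", "g/L"}


@dataclass
class ConcentrationSeries:
    """Replicate residual-metabolite concentrations indexed by pH_out.

    ``data`` holds columns ``pH_out`` (dimensionless, within [4, 9]),
    ``concentration`` (mM, >= 0) and ``replicate_id``.  Input expressed in
    g/L is converted to mM on construction using the acid's molar mass.
    """

    metabolite: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"pH_out", "concentration", "replicate_id"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"series missing columns {sorted(missing)}")
        df = self.data
        if ((df["pH_out"] < 4.0) | (df["pH_out"] > 9.0)).any():
            raise ValueError("pH_out values must lie within [4, 9]")
        if (df["concentration"] < 0).any():
            raise ValueError("concentrations must be >= 0")
        if df["pH_out"].nunique() < 2:
            raise ValueError("series needs at least 2 distinct pH values")

    @classmethod
    def from_points(
        cls,
        metabolite: str,
        points: Iterable[tuple[float, float] | tuple[float, float, str]],
    ) -> "ConcentrationSeries":
        """Build a series from (pH_out, concentration[, replicate_id]) tuples."""
        rows = []
        for p in points:
            if len(p) == 2:
                rows.append((p[0], p[1], "r1"))
            else:
                rows.append(tuple(p))
        df = pd.DataFrame(rows, columns=["pH_out", "concentration", "replicate_id"])
        return cls(metabolite, df)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, metabolite: str | None = None
    ) -> dict[str, "ConcentrationSeries"] | "ConcentrationSeries":
        """Build series from a tidy frame with optional unit conversion.

        Expected columns: metabolite, pH_out, concentration, unit
        (``mM`` or ``g/L``), replicate_id.  Returns one series per
        metabolite (a dict), or a single series if ``metabolite`` given.
        """
        df = df.copy()
        if "unit" in df.columns:
            conc = df["concentration"].astype(float).to_numpy()
            for unit in df["unit"].unique():
                rows = df["unit"] == unit
                if str(unit).strip().lower() in {"mm"}:
                    continue
                if str(unit).strip().lower() in {a.lower() for a in _G_PER_L_ALIASES}:
                    for met in df.loc[rows, "metabolite"].unique():
                        acid = KNOWN_ACIDS.get(str(met).lower())
                        if acid is None:
                            raise ValueError(
                                f"cannot convert g/L for unknown metabolite {met!r}"
                            )
                        sel = rows & (df["metabolite"] == met)
                        conc[sel.to_numpy()] = (
                            conc[sel.to_numpy()] / acid.molar_mass * 1000.0
                        )
                else:
                    raise ValueError(f"unrecognised unit {unit!r}")
            df["concentration"] = conc
        if "replicate_id" not in df.columns:
            df["replicate_id"] = "r1"
        out = {
            str(met): cls(
                str(met),
                g[["pH_out", "concentration", "replicate_id"]].reset_index(drop=True),
            )
            for met, g in df.groupby("metabolite")
        }
        if metabolite is not None:
            return out[metabolite]
        return out

    @classmethod
    def from_csv(cls, path, metabolite: str | None = None):
        return cls.from_dataframe(pd.read_csv(path), metabolite=metabolite)

    def replicate_mean(self) -> pd.DataFrame:
        """Arithmetic mean concentration across replicates, sorted by pH."""
        return (
            self.data.groupby("pH_out", as_index=False)["concentration"]
            .mean()
            .sort_values("pH_out")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.data)


def infer_cytosolic_concentration(
    series: ConcentrationSeries, pH_in: float, match_tol: float = 0.05
) -> float:
    """Back-calculate the cytosolic concentration from the dpH = 0 point.

    At pH_out == pH_in the equilibrium ratio is 1, so the cytosolic
    concentration equals the measured extracellular one.  The
    replicate-averaged measurement at the pH closest to ``pH_in`` is used
    when one lies within ``match_tol`` pH units; otherwise the value is
    linearly interpolated (in concentration) between the two bracketing
    pH points.  The query must lie inside the measured range --
    extrapolation raises :class:`ExtrapolationError`.
    """
    mean = series.replicate_mean()
    pH = mean["pH_out"].to_numpy(float)
    conc = mean["concentration"].to_numpy(float)
    if not (pH.min() <= pH_in <= pH.max()):
        raise ExtrapolationError(
            f"pH_in={pH_in} outside measured range [{pH.min()}, {pH.max()}]"
        )
    nearest = np.argmin(np.abs(pH - pH_in))
    if abs(pH[nearest] - pH_in) <= match_tol:
        return float(conc[nearest])
    return float(np.interp(pH_in, pH, conc))


@dataclass
class ARProfile:
    """Observed and predicted accumulation ratios along a pH ramp.

    ``table`` columns: pH_out, c_out (replicate mean, mM), observed_ar,
    predicted_ar.  ``per_replicate`` keeps the individual replicate
    ratios for dispersion reporting.
    """

    metabolite: str
    assumed_pH_in: float
    assumed_c_in: float
    table: pd.DataFrame
    per_replicate: pd.DataFrame = field(repr=False, default=None)

    def plot(self, ax=None):
        """Observed vs predicted AR on a log axis (QC figure)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(self.table["pH_out"], self.table["predicted_ar"], "k-",
                    label=f"10^(pH_in - pH_out), pH_in={self.assumed_pH_in}")
        ax.semilogy(self.table["pH_out"], self.table["observed_ar"], "o",
                    label=f"observed ({self.metabolite})")
        ax.set_xlabel("extracellular pH")
        ax.set_ylabel("accumulation ratio (in/out)")
        ax.legend()
        return ax


def accumulation_ratio_profile(
    series: ConcentrationSeries, pH_in: float, c_in: float
) -> ARProfile:
    """Observed (c_in / c_out) and predicted (10**(pH_in - pH_out)) ARs.

    Zero or below-detection concentrations cannot yield a finite ratio
    and are dropped with a logged warning.
    """
    if not c_in > 0:
        raise ValueError("c_in must be > 0")
    data = series.data
    zeros = data["concentration"] <= 0
    if zeros.any():
        logger.warning(
            "dropping %d zero/below-detection measurements from %s",
            int(zeros.sum()),
            series.metabolite,
        )
        data = data[~zeros]
    if data.empty:
        raise InsufficientDataError("no positive concentrations left in series")
    per_rep = data.copy()
    per_rep["observed_ar"] = c_in / per_rep["concentration"]
    per_rep["predicted_ar"] = 10.0 ** (pH_in - per_rep["pH_out"])
    mean = (
        data.groupby("pH_out", as_index=False)["concentration"]
        .mean()
        .sort_values("pH_out")
        .reset_index(drop=True)
        .rename(columns={"concentration": "c_out"})
    )
    mean["observed_ar"] = c_in / mean["c_out"]
    mean["predicted_ar"] = 10.0 ** (pH_in - mean["pH_out"])
    return ARProfile(
        metabolite=series.metabolite,
        assumed_pH_in=pH_in,
        assumed_c_in=c_in,
        table=mean,
        per_replicate=per_rep.reset_index(drop=True),
    )


def deviation_report(profile: ARProfile, rel_tol: float = 0.3) -> pd.DataFrame:
    """Flag departures of the observed AR from the equilibrium prediction.

    Points with observed < predicted * (1 - rel_tol) are flagged
    ``below-equilibrium`` (in the study system: interpreted as elevated
    intracellular demand above the cytosolic pH), observed >
    predicted * (1 + rel_tol) as ``above-equilibrium``, the rest
    ``at-equilibrium``.  Default band 30%, wide enough that a faithful
    ramp measured with 5% noise is never flagged at or below pH_in.
    """
    if not 0.0 < rel_tol < 1.0:
        raise ValueError("rel_tol must lie in (0, 1)")
    t = profile.table.copy()
    flags = np.where(
        t["observed_ar"] < t["predicted_ar"] * (1.0 - rel_tol),
        "below-equilibrium",
        np.where(
            t["observed_ar"] > t["predicted_ar"] * (1.0 + rel_tol),
            "above-equilibrium",
            "at-equilibrium",
        ),
    )
    t["flag"] = flags
    return t[["pH_out", "observed_ar", "predicted_ar", "flag"]]


class AccumulationRatioModel:
    """Least-squares fit of the log-linear symport-equilibrium law.

    The model for measurements below the internalization threshold is

        log10 c_out_i = alpha + pH_out_i + eps_i,   alpha = log10 c_in - pH_in

    with the slope in pH_out fixed at its theoretical value of 1.  A
    free-slope ordinary least squares fit (statsmodels) is run alongside
    as a diagnostic: a fitted slope far from 1 indicates the culture is
    not tracking transport equilibrium.

    Parameters
    ----------
    series
        The measured concentration series (zero values are dropped).
    max_pH
        Upper pH cut; points above it (where the transporter is being
        internalised in the study system) are excluded from the fit.

    Examples
    --------
    >>> model = AccumulationRatioModel(series, max_pH=7.0)
    >>> res = model.fit(assume_c_in=0.62)
    >>> res.pH_in_hat, res.alpha_se
    """

    MIN_POINTS = 5

    def __init__(self, series: ConcentrationSeries, max_pH: float | None = None):
        data = series.data
        data = data[data["concentration"] > 0]
        if max_pH is not None:
            data = data[data["pH_out"] <= max_pH]
        if len(data) < self.MIN_POINTS:
            raise InsufficientDataError(
                f"need >= {self.MIN_POINTS} usable points, got {len(data)}"
            )
        self.series = series
        self.max_pH = max_pH
        self.pH = data["pH_out"].to_numpy(float)
        self.log10_c = np.log10(data["concentration"].to_numpy(float))

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, metabolite: str, max_pH: float | None = None
    ) -> "AccumulationRatioModel":
        series = ConcentrationSeries.from_dataframe(df, metabolite=metabolite)
        return cls(series, max_pH=max_pH)

    def fit(
        self,
        assume_pH_in: float | None = None,
        assume_c_in: float | None = None,
    ) -> "AccumulationRatioResults":
        """Estimate the equilibrium offset and the anchored parameter.

        Exactly one of ``assume_pH_in`` / ``assume_c_in`` should be
        supplied; with neither, pH_in is anchored at 7.0 (the literature
        convention for the cytosolic pH of budding yeast).  Supplying
        both raises.
        """
        import statsmodels.api as sm

        if assume_pH_in is not None and assume_c_in is not None:
            raise ValueError("anchor either pH_in or c_in, not both")
        anchored = "c_in" if assume_c_in is not None else "pH_in"
        if anchored == "pH_in" and assume_pH_in is None:
            assume_pH_in = 7.0

        resid = self.log10_c - self.pH  # alpha estimate per point
        n = resid.size
        alpha = float(resid.mean())
        dof = n - 1
        resid_se = float(np.sqrt(np.sum((resid - alpha) ** 2) / dof))
        alpha_se = resid_se / np.sqrt(n)

        ols = sm.OLS(self.log10_c, sm.add_constant(self.pH)).fit()
        slope = float(ols.params[1])
        slope_se = float(ols.bse[1])

        if anchored == "c_in":
            c_in_hat = float(assume_c_in)
            pH_in_hat = float(np.log10(c_in_hat) - alpha)
            pH_in_se, c_in_se = alpha_se, 0.0
        else:
            pH_in_hat = float(assume_pH_in)
            c_in_hat = float(10.0 ** (alpha + pH_in_hat))
            pH_in_se = 0.0
            c_in_se = float(c_in_hat * np.log(10.0) * alpha_se)

        return AccumulationRatioResults(
            model=self,
            alpha=alpha,
            alpha_se=alpha_se,
            resid_se=resid_se,
            nobs=n,
            anchored=anchored,
            pH_in_hat=pH_in_hat,
            pH_in_se=pH_in_se,
            c_in_hat=c_in_hat,
            c_in_se=c_in_se,
            diag_slope=slope,
            diag_slope_se=slope_se,
        )


@dataclass
class AccumulationRatioResults:
    """Results of :meth:`AccumulationRatioModel.fit`.

    ``alpha`` is the identifiable offset log10 c_in - pH_in of the
    unit-slope equilibrium line; ``pH_in_hat``/``c_in_hat`` are the
    conditional estimates given the anchored parameter (the anchored
    one's standard error is reported as 0).  ``diag_slope`` is the
    free-slope OLS diagnostic, expected ~1 at equilibrium.
    """

    model: AccumulationRatioModel
    alpha: float
    alpha_se: float
    resid_se: float
    nobs: int
    anchored: str
    pH_in_hat: float
    pH_in_se: float
    c_in_hat: float
    c_in_se: float
    diag_slope: float
    diag_slope_se: float

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {"alpha": self.alpha, "pH_in": self.pH_in_hat, "c_in": self.c_in_hat}
        )

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            {"alpha": self.alpha_se, "pH_in": self.pH_in_se, "c_in": self.c_in_se}
        )

    def predict(self, pH_out) -> np.ndarray:
        """Predicted c_out (mM) on the fitted equilibrium line."""
        return 10.0 ** (self.alpha + np.asarray(pH_out, dtype=float))

    def summary(self) -> str:
        lines = [
            "Accumulation-ratio equilibrium fit",
            "==================================",
            f"metabolite:        {self.model.series.metabolite}",
            f"n points (<= pH {self.model.max_pH}): {self.nobs}",
            f"alpha = log10 c_in - pH_in: {self.alpha:.4f} +/- {self.alpha_se:.4f}",
            f"residual SE (log10 mM):     {self.resid_se:.4f}",
            f"anchored parameter:         {self.anchored}",
            f"pH_in:  {self.pH_in_hat:.4f} +/- {self.pH_in_se:.4f}",
            f"c_in:   {self.c_in_hat:.4f} +/- {self.c_in_se:.4f} mM",
            f"diagnostic free slope:      {self.diag_slope:.4f} +/- "
            f"{self.diag_slope_se:.4f} (expect ~1 at equilibrium)",
        ]
        return "\n".join(lines)


def recover_parameters(
    series: ConcentrationSeries,
    max_pH: float | None = None,
    assume_pH_in: float | None = None,
    assume_c_in: float | None = None,
) -> AccumulationRatioResults:
    """Convenience wrapper: fit the equilibrium line and recover (pH_in, c_in).

    Only the combination log10 c_in - pH_in is identifiable from one
    series, so one parameter anchors the other; see
    :class:`AccumulationRatioModel` for details.
    """
    model = AccumulationRatioModel(series, max_pH=max_pH)
    return model.fit(assume_pH_in=assume_pH_in, assume_c_in=assume_c_in)
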