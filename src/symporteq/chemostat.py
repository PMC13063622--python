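"""Chemostat pH-ramp simulator for a mixed lactate/ethanol feed.

Synthetic-data generator emulating aerobic, carbon-limited continuous
cultures of budding yeast fed 33 mM L-lactate + 50 mM ethanol at a
dilution rate of 0.07 1/h while the culture pH is ramped linearly
(0.05 or 0.01 pH units per hour in the emulated study designs).

Model structure
---------------
State: biomass X (g/L) and residual lactate, ethanol and pyruvate (mM).

* Lactate crosses the membrane through a reversible electroneutral
  H+/anion symporter.  In the linear nonequilibrium regime the net
  specific uptake is first-order in the displacement from equilibrium:

      q_lac = k_up * f(pH) * (S_lac - c_in_lac * 10**(pH_out - pH_in))

  where f(pH) is the fraction of transporter still at the cell surface,
  a decreasing logistic that drops at the internalization threshold
  (between pH 7.0 and 7.25 in the emulated system).  With a large rate
  constant k_up the residual lactate tracks the thermodynamic floor
  c_in * 10**(pH_out - pH_in), i.e. transport at equilibrium.
* Pyruvate (absent from the feed) is exported through the same carrier:
  the mirrored reverse flux drives S_pyr toward its equilibrium value
  from below.
* Ethanol uptake is Monod-limited; total growth is capped by a declining
  logistic mu_max(pH) calibrated so growth falls below D just above
  pH 7.2, producing washout (declining biomass, rising residual ethanol)
  as the ramp crosses that point.

The noise-free trace is a deterministic function of the configuration;
measurement noise enters only in :func:`sample_measurements`
(multiplicative lognormal, seeded).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import IntegrationError
from .inference import ConcentrationSeries
from .thermo import LACTIC_ACID

__all__ = [
    "ChemostatConfig",
    "CultureTrace",
    "surface_fraction",
    "mu_max_of_pH",
    "steady_state",
    "simulate",
    "sample_measurements",
]

#: 0.6 g biomass per g substrate expressed per mmol (typical aerobic yields).
_YIELD_LACTATE = 0.6 * LACTIC_ACID.molar_mass / 1000.0   # g/mmol
_YIELD_ETHANOL = 0.6 * 46.07 / 1000.0                    # g/mmol


@dataclass(frozen=True)
class ChemostatConfig:
    """Parameters of the simulated continuous culture.

    Defaults reproduce the emulated study design: D = 0.07 1/h, feed of
    33 mM lactate + 50 mM ethanol, steady state established at pH 6.75
    and then a linear ramp to pH 7.25 at 0.05 pH units per hour, with
    cytosolic pH 7.0 and cytosolic lactate/pyruvate 0.62 / 0.18 mM.
    """

    dilution_rate: float = 0.07          # 1/h
    feed_lactate: float = 33.0           # mM
    feed_ethanol: float = 50.0           # mM
    yield_lactate: float = _YIELD_LACTATE   # g biomass / mmol
    yield_ethanol: float = _YIELD_ETHANOL   # g biomass / mmol
    qmax_ethanol: float = 12.0           # mmol / (g h)
    monod_K_ethanol: float = 0.1         # mM
    mu_ref: float = 0.35                 # 1/h, pH-permissive maximum growth rate
    pH_crit: float = 7.2                 # midpoint of the mu_max decline
    mu_steepness: float = 12.0           # decades per pH unit of the decline
    pH_start: float = 6.75
    pH_end: float = 7.25
    ramp_rate: float = 0.05              # pH units / h
    internalization_pH_half: float = 7.1
    internalization_steepness: float = 8.0
    uptake_rate_constant: float = 800.0  # L / (g h), reversible symport law
    pH_in: float = 7.0
    c_in_lactate: float = 0.62           # mM
    c_in_pyruvate: float = 0.18          # mM
    noise_cv: float = 0.05
    seed: int = 0
    settle_time: float = 24.0            # h at pH_start before the ramp
    hold_time: float = 0.0               # h at pH_end after the ramp

    def __post_init__(self) -> None:
        if not self.dilution_rate > 0:
            raise ValueError("dilution_rate must be > 0")
        if not self.ramp_rate > 0:
            raise ValueError("ramp_rate must be > 0")
        for name in ("feed_lactate", "feed_ethanol", "c_in_lactate",
                     "c_in_pyruvate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    # -- derived timing ------------------------------------------------
    @property
    def ramp_duration(self) -> float:
        return abs(self.pH_end - self.pH_start) / self.ramp_rate

    @property
    def total_time(self) -> float:
        return self.settle_time + self.ramp_duration + self.hold_time

    def pH_at(self, t):
        """Programmed pH profile: settle, exact linear ramp, optional hold."""
        t = np.asarray(t, dtype=float)
        ramped = self.pH_start + np.sign(self.pH_end - self.pH_start) * (
            self.ramp_rate * np.clip(t - self.settle_time, 0.0, None)
        )
        lo, hi = sorted((self.pH_start, self.pH_end))
        return np.clip(ramped, lo, hi)

    # -- serialisation -------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "ChemostatConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ChemostatConfig":
        """Load from a YAML or JSON file mirroring the field names."""
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def surface_fraction(pH, pH_half: float, steepness: float):
    """Fraction of transporter remaining at the plasma membrane.

    Decreasing logistic 1 / (1 + 10**(k * (pH - pH_half))); 0.5 at
    pH_half, -> 1 well below it, -> 0 well above (internalised).
    """
    return 1.0 / (1.0 + 10.0 ** (steepness * (np.asarray(pH, float) - pH_half)))


def mu_max_of_pH(pH, config: ChemostatConfig):
    """pH-dependent growth-rate ceiling (declining logistic).

    Calibrated so the ceiling crosses D = 0.07 1/h just above pH 7.2,
    mirroring the failure of ethanol-grown cultures to sustain the
    dilution rate beyond that pH.
    """
    return config.mu_ref / (
        1.0 + 10.0 ** (config.mu_steepness * (np.asarray(pH, float) - config.pH_crit))
    )


def _rates(config: ChemostatConfig, X, S_lac, S_eth, S_pyr, pH):
    """Specific rates at one state point.

    Returns (mu, q_lac, q_eth, q_pyr, f_surface); q in mmol/(g h),
    positive = uptake (q_pyr positive = export).
    """
    S_lac = max(S_lac, 0.0)
    S_eth = max(S_eth, 0.0)
    S_pyr = max(S_pyr, 0.0)
    f = float(surface_fraction(pH, config.internalization_pH_half,
                               config.internalization_steepness))
    floor_lac = config.c_in_lactate * 10.0 ** (pH - config.pH_in)
    eq_pyr = config.c_in_pyruvate * 10.0 ** (pH - config.pH_in)
    q_lac = config.uptake_rate_constant * f * (S_lac - floor_lac)
    q_pyr = config.uptake_rate_constant * f * (eq_pyr - S_pyr)
    mu_cap = float(mu_max_of_pH(pH, config))
    mu_lac = config.yield_lactate * max(q_lac, 0.0)
    q_eth_monod = config.qmax_ethanol * S_eth / (config.monod_K_ethanol + S_eth)
    q_eth_demand = max(0.0, mu_cap - mu_lac) / config.yield_ethanol
    q_eth = min(q_eth_monod, q_eth_demand)
    mu = min(mu_cap, mu_lac + config.yield_ethanol * q_eth)
    return mu, q_lac, q_eth, q_pyr, f


def _rhs(t, y, config: ChemostatConfig):
    X, S_lac, S_eth, S_pyr = y
    pH = float(config.pH_at(t))
    mu, q_lac, q_eth, q_pyr, _ = _rates(config, X, S_lac, S_eth, S_pyr, pH)
    D = config.dilution_rate
    Xp = max(X, 0.0)
    return [
        (mu - D) * Xp,
        D * (config.feed_lactate - S_lac) - q_lac * Xp,
        D * (config.feed_ethanol - S_eth) - q_eth * Xp,
        -D * S_pyr + q_pyr * Xp,
    ]


def steady_state(config: ChemostatConfig, pH: float) -> dict:
    """Nontrivial chemostat steady state at a fixed pH.

    Solves mu = D together with the three substrate balances.  At mu = D
    the system reduces to one scalar equation in the residual lactate
    concentration: lactate uptake fixes the lactate-derived growth,
    ethanol uptake must supply the remainder (which pins the residual
    ethanol through the Monod law), and the ethanol balance then yields
    the biomass.  Raises if the pH-dependent growth ceiling lies below
    the dilution rate (washout: no steady state with biomass).
    """
    if float(mu_max_of_pH(pH, config)) <= config.dilution_rate:
        raise ValueError(
            f"mu_max({pH:.2f}) <= D: washout, no steady state with biomass"
        )
    D = config.dilution_rate
    f = float(surface_fraction(pH, config.internalization_pH_half,
                               config.internalization_steepness))
    kf = config.uptake_rate_constant * f
    floor_lac = config.c_in_lactate * 10.0 ** (pH - config.pH_in)
    eq_pyr = config.c_in_pyruvate * 10.0 ** (pH - config.pH_in)
    if D / config.yield_ethanol >= config.qmax_ethanol * config.feed_ethanol / (
        config.monod_K_ethanol + config.feed_ethanol
    ) and config.feed_lactate == 0:
        raise ValueError("ethanol supply cannot sustain D: washout")

    def residual(S_lac: float) -> float:
        q_lac = kf * (S_lac - floor_lac)
        mu_lac = config.yield_lactate * max(q_lac, 0.0)
        q_eth = (D - mu_lac) / config.yield_ethanol
        if q_eth <= 1e-12:
            return -1e6  # lactate alone overshoots D: S_lac must be lower
        if q_eth >= config.qmax_ethanol:
            return float("nan")
        S_eth = config.monod_K_ethanol * q_eth / (config.qmax_ethanol - q_eth)
        X = D * (config.feed_ethanol - S_eth) / q_eth
        return D * (config.feed_lactate - S_lac) - q_lac * X

    lo = floor_lac
    hi = max(config.feed_lactate, floor_lac * 1.5 + 1e-6)
    if residual(lo) <= 0:  # no net uptake possible: floor above feed level
        S_lac = floor_lac
    else:
        from scipy.optimize import brentq

        # shrink the bracket until the upper end is negative
        step = (hi - lo) / 64 or 1e-6
        b = lo + step
        while residual(b) > 0:
            b = min(b + step, hi)
            if b >= hi:
                break
        S_lac = brentq(residual, lo, b, xtol=1e-14, rtol=1e-15)
    q_lac = kf * (S_lac - floor_lac)
    mu_lac = config.yield_lactate * max(q_lac, 0.0)
    q_eth = (D - mu_lac) / config.yield_ethanol
    S_eth = config.monod_K_ethanol * q_eth / (config.qmax_ethanol - q_eth)
    X = D * (config.feed_ethanol - S_eth) / q_eth
    S_pyr = kf * X * eq_pyr / (D + kf * X)
    mu, q_lac, q_eth, q_pyr, f = _rates(config, X, S_lac, S_eth, S_pyr, pH)
    return {
        "biomass": float(X),
        "lactate": float(S_lac),
        "ethanol": float(S_eth),
        "pyruvate": float(S_pyr),
        "mu": float(mu),
        "q_lactate": float(q_lac),
        "q_ethanol": float(q_eth),
        "q_pyruvate": float(q_pyr),
        "surface_fraction": float(f),
    }


@dataclass
class CultureTrace:
    """Noise-free time series produced by :func:`simulate`.

    ``data`` columns: time (h), pH_out, biomass (g/L), lactate, ethanol,
    pyruvate (mM), surface_fraction, growth_rate (1/h).
    """

    config: ChemostatConfig
    data: pd.DataFrame

    @property
    def ramp_window(self) -> tuple[float, float]:
        c = self.config
        return c.settle_time, c.settle_time + c.ramp_duration

    def ramp_segment(self) -> pd.DataFrame:
        """Rows within the programmed ramp (pH strictly monotone there)."""
        t0, t1 = self.ramp_window
        d = self.data
        return d[(d["time"] >= t0) & (d["time"] <= t1)].reset_index(drop=True)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format (time, pH_out, variable, value) table for CSV export."""
        return self.data.melt(
            id_vars=["time", "pH_out"], var_name="variable", value_name="value"
        )

    def plot(self, ax=None):
        """Biomass and residual substrates against culture pH (QC figure)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.data
        ax.plot(d["time"], d["biomass"], label="biomass (g/L)")
        ax.plot(d["time"], d["lactate"], label="lactate (mM)")
        ax.plot(d["time"], d["ethanol"], label="ethanol (mM)")
        ax.plot(d["time"], d["pyruvate"], label="pyruvate (mM)")
        ax2 = ax.twinx()
        ax2.plot(d["time"], d["pH_out"], "k--", alpha=0.5, label="pH")
        ax.set_xlabel("time (h)")
        ax.legend(loc="upper left")
        return ax


def simulate(
    config: ChemostatConfig,
    t_end: float | None = None,
    dt_out: float = 0.05,
    start_at_steady_state: bool = True,
) -> CultureTrace:
    """Integrate the culture through settle, ramp and hold phases.

    Uses stiff-safe adaptive integration (LSODA, max step 0.1 h); the
    reversible uptake law makes the substrate balances stiff relative to
    the biomass dynamics.  The trace is bit-for-bit reproducible for a
    given configuration.

    Parameters
    ----------
    t_end
        Simulation horizon (h); defaults to settle + ramp + hold.
    dt_out
        Output grid spacing (h).
    start_at_steady_state
        Initialise at the fixed-pH steady state of the starting pH
        (the emulated experiments establish steady state before the
        ramp).  When False, starts from a crude inoculum guess.
    """
    if t_end is None:
        t_end = config.total_time
    if start_at_steady_state:
        ss = steady_state(config, config.pH_start)
        y0 = [ss["biomass"], ss["lactate"], ss["ethanol"], ss["pyruvate"]]
    else:
        y0 = [0.5, config.feed_lactate, config.feed_ethanol, 0.0]
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_eval = t_eval[t_eval <= t_end]
    sol = solve_ivp(
        _rhs,
        (0.0, float(t_end)),
        y0,
        args=(config,),
        method="LSODA",
        t_eval=t_eval,
        max_step=0.1,
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise IntegrationError(f"chemostat integration failed: {sol.message}")
    pH = config.pH_at(sol.t)
    rates = [
        _rates(config, *y, p) for y, p in zip(sol.y.T, pH)
    ]
    mu = np.array([r[0] for r in rates])
    f = np.array([r[4] for r in rates])
    data = pd.DataFrame(
        {
            "time": sol.t,
            "pH_out": pH,
            "biomass": np.clip(sol.y[0], 0.0, None),
            "lactate": np.clip(sol.y[1], 0.0, None),
            "ethanol": np.clip(sol.y[2], 0.0, None),
            "pyruvate": np.clip(sol.y[3], 0.0, None),
            "surface_fraction": f,
            "growth_rate": mu,
        }
    )
    return CultureTrace(config=config, data=data)


def sample_measurements(
    trace: CultureTrace,
    sampling_pHs: Sequence[float],
    noise_cv: float | None = None,
    seed: int | None = None,
    n_replicates: int = 2,
    metabolites: Sequence[str] = ("lactate", "pyruvate"),
) -> dict[str, ConcentrationSeries]:
    """Sample the trace at given culture pH values, with measurement noise.

    Emulates taking culture samples when the ramping culture reaches
    specific extracellular pH values.  Noise is multiplicative lognormal
    with coefficient of variation ``noise_cv`` (mean-one, so noise-free
    sampling returns the exact trace values), drawn independently per
    replicate from a seeded generator.

    Returns one :class:`ConcentrationSeries` per metabolite, ready for
    the inference layer.
    """
    config = trace.config
    if noise_cv is None:
        noise_cv = config.noise_cv
    if seed is None:
        seed = config.seed
    seg = trace.ramp_segment()
    pH_grid = seg["pH_out"].to_numpy(float)
    order = np.argsort(pH_grid)
    pH_grid = pH_grid[order]
    sampling_pHs = np.asarray(sampling_pHs, dtype=float)
    lo, hi = pH_grid.min(), pH_grid.max()
    if ((sampling_pHs < lo - 1e-9) | (sampling_pHs > hi + 1e-9)).any():
        raise ValueError(
            f"sampling pH outside the ramp range [{lo:.3f}, {hi:.3f}]"
        )
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    out: dict[str, ConcentrationSeries] = {}
    for met in metabolites:
        values = np.interp(sampling_pHs, pH_grid, seg[met].to_numpy(float)[order])
        rows = []
        for rep in range(n_replicates):
            if noise_cv > 0:
                factors = np.exp(rng.normal(-0.5 * sigma**2, sigma,
                                            size=values.size))
            else:
                factors = np.ones_like(values)
            for p, v in zip(sampling_pHs, values * factors):
                rows.append((p, float(v), f"r{rep + 1}"))
        df = pd.DataFrame(rows, columns=["pH_out", "concentration", "replicate_id"])
        out[met] = ConcentrationSeries(met, df)
    return out
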