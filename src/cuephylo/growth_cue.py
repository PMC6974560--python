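"""Carbon use efficiency from OD600 and headspace CO2 time series.

CUE partitions consumed carbon between growth and respiration during the
exponential phase of a batch culture:

    CUE = mu / (mu + R)

where mu is the intrinsic growth rate (OLS slope of ln biomass-C against
time over the exponential window) and R is the mass-specific respiration
rate over the same window.  The exponential window is the contiguous run of
3-10 time points maximising the ln-biomass slope.  Replicates whose growth
or respiration slope does not differ from zero (F test, p > 0.05) are
discarded, and an assay condition is retained only when at least two
replicates survive.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AssayConstants",
    "GrowthCurve",
    "ExponentialFit",
    "find_exponential_window",
    "od_to_biomass_c",
    "co2_to_carbon",
    "fit_exponential_rates",
    "compute_cue",
    "estimate_cue_table",
    "qc_filter",
    "energy_per_carbon",
    "DEFAULT_SUBSTRATES",
]

ATM_PA = 101325.0
GAS_R = 8.314462618
CARBON_UG_PER_UMOL = 12.011

#: Heat of combustion (kJ/mol) and carbon atoms per molecule for the assay
#: substrates.  PDB is an undefined mixture and has no entry.
DEFAULT_SUBSTRATES: dict[str, tuple[float, int]] = {
    "glucose": (2805.0, 6),
    "pyruvate": (1168.0, 3),
    "succinate": (1491.0, 4),
}


@dataclasses.dataclass
class AssayConstants:
    """Assay-wide conversion constants.

    ``biomass_per_od`` is the biomass-carbon conversion factor in
    ug C OD^-1 ml^-1 (the conventional value 130; the unit prefix of the
    printed factor is ambiguous in parts of the literature, so the number is
    configurable — CUE itself only requires biomass and CO2 carbon to share
    a mass unit).
    """

    biomass_per_od: float = 130.0
    culture_ml: float = 10.0
    headspace_ml: float = 25.0
    substrate_table: dict[str, tuple[float, int]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SUBSTRATES)
    )

    def __post_init__(self) -> None:
        if min(self.biomass_per_od, self.culture_ml, self.headspace_ml) <= 0:
            raise ValueError("assay constants must be positive")


@dataclasses.dataclass
class GrowthCurve:
    """One replicate's time series under one assay condition."""

    isolate: str
    substrate: str
    temperature_c: float
    replicate: str
    time_h: np.ndarray
    od600: np.ndarray
    co2_ppm: np.ndarray

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        self.co2_ppm = np.asarray(self.co2_ppm, dtype=float)
        if len(self.time_h) < 3:
            raise ValueError("a growth curve needs >= 3 time points")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time must be strictly increasing")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GrowthCurve":
        frame = frame.sort_values("time_h")
        return cls(
            isolate=str(frame["isolate"].iloc[0]),
            substrate=str(frame["substrate"].iloc[0]),
            temperature_c=float(frame["temperature_c"].iloc[0]),
            replicate=str(frame["replicate"].iloc[0]),
            time_h=frame["time_h"].to_numpy(),
            od600=frame["od600"].to_numpy(),
            co2_ppm=frame["co2_ppm"].to_numpy(),
        )


@dataclasses.dataclass
class ExponentialFit:
    """Rates fitted over the exponential window of one replicate."""

    window: tuple[int, int]  # inclusive index range
    mu: float
    mu_p: float
    r_mass_specific: float
    r_p: float
    cue: float


def find_exponential_window(
    time_h: np.ndarray,
    ln_biomass: np.ndarray,
    min_pts: int = 3,
    max_pts: int = 10,
) -> tuple[int, int]:
    """Contiguous window of ``min_pts``-``max_pts`` points maximising the
    least-squares slope of ln(biomass) vs time.

    Ties are broken in favour of the longer window, then the earlier start,
    so the result is deterministic.  Returns inclusive indices.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(ln_biomass, dtype=float)
    finite = np.isfinite(t) & np.isfinite(y)
    if not np.all(finite):
        raise ValueError("non-finite values in window search")
    n = len(t)
    if n < min_pts:
        raise ValueError(f"need at least {min_pts} points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    best = None  # (slope, length, -start)
    best_win = None
    for length in range(min_pts, min(max_pts, n) + 1):
        for start in range(0, n - length + 1):
            sl = slice(start, start + length)
            tt, yy = t[sl], y[sl]
            tc = tt - tt.mean()
            slope = float(tc @ yy) / float(tc @ tc)
            key = (round(slope, 12), length, -start)
            if best is None or key > best:
                best = key
                best_win = (start, start + length - 1)
    assert best_win is not None
    return best_win


def od_to_biomass_c(od600, constants: AssayConstants):
    """Microbial biomass carbon (ug) in the culture from OD600."""
    od = np.asarray(od600, dtype=float)
    if np.any(od < 0):
        raise ValueError("negative OD600")
    return od * constants.biomass_per_od * constants.culture_ml


def co2_to_carbon(co2_ppm, constants: AssayConstants, temperature_c: float):
    """Cumulative CO2 carbon (ug) in the headspace above the first read.

    The headspace molar content follows the ideal-gas law at 1 atm and the
    assay temperature; ppm above baseline converts linearly to umol CO2 and
    then to ug C.
    """
    ppm = np.asarray(co2_ppm, dtype=float)
    if constants.headspace_ml <= 0:
        raise ValueError("headspace volume must be positive")
    t_k = temperature_c + 273.15
    total_umol = ATM_PA * (constants.headspace_ml * 1e-6) / (GAS_R * t_k) * 1e6
    delta = (ppm - ppm.flat[0]) * 1e-6 * total_umol
    return delta * CARBON_UG_PER_UMOL


def compute_cue(mu: float, r: float) -> float:
    """CUE = mu / (mu + R), the fraction of carbon flux allocated to growth."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if r < 0:
        raise ValueError("R must be non-negative")
    return mu / (mu + r)


def _slope_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and its F-test p (single regressor: F = t^2, n-2 df)."""
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in regressor")
    if np.allclose(y, y[0]):
        return 0.0, 1.0  # flat series: zero slope, clearly non-significant
    res = sps.linregress(x, y)
    return float(res.slope), float(res.pvalue)


def fit_exponential_rates(
    curve: GrowthCurve,
    constants: AssayConstants,
    min_pts: int = 3,
    max_pts: int = 10,
    respiration_method: str = "cumulative",
) -> ExponentialFit:
    """Fit mu and mass-specific R over the exponential window of one curve.

    mu is the slope of ln(biomass C) vs time.  The default respiration
    estimator regresses cumulative CO2-C on biomass C over the window: under
    exponential growth dCO2C/dt = R * B exactly, so that slope equals R/mu
    and R = slope * mu.  The alternative ``interval`` method averages
    per-interval rates Delta(CO2C)/Delta(t) divided by the interval
    geometric-mean biomass.  Both carry the respiration regression's slope
    F-test p-value.
    """
    biomass = od_to_biomass_c(curve.od600, constants)
    if np.any(biomass <= 0):
        raise ValueError("biomass must be positive for the log transform")
    ln_b = np.log(biomass)
    w0, w1 = find_exponential_window(curve.time_h, ln_b, min_pts, max_pts)
    sl = slice(w0, w1 + 1)
    t = curve.time_h[sl]
    b = biomass[sl]
    cum_c = co2_to_carbon(curve.co2_ppm, constants, curve.temperature_c)[sl]
    mu, mu_p = _slope_with_p(t, ln_b[sl])
    slope_cb, r_p = _slope_with_p(b, cum_c)
    if respiration_method == "cumulative":
        r = slope_cb * mu
    elif respiration_method == "interval":
        rates = np.diff(cum_c) / np.diff(t)
        b_gm = np.sqrt(b[:-1] * b[1:])
        r = float(np.mean(rates / b_gm))
    else:
        raise ValueError("respiration_method must be 'cumulative' or 'interval'")
    r_eff = max(r, 0.0)
    cue = compute_cue(mu, r_eff) if mu > 0 else np.nan
    return ExponentialFit(
        window=(w0, w1), mu=mu, mu_p=mu_p, r_mass_specific=r, r_p=r_p, cue=cue
    )


def estimate_cue_table(
    curves: pd.DataFrame | Iterable[GrowthCurve],
    constants: AssayConstants,
    min_pts: int = 3,
    max_pts: int = 10,
    respiration_method: str = "cumulative",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-replicate CUE table from tidy curve data.

    Accepts the tidy frame written by the simulator (or read from CSV) or an
    iterable of :class:`GrowthCurve`.  Adds a ``qc_pass`` flag: both slope
    F-tests significant at ``alpha``.
    """
    if isinstance(curves, pd.DataFrame):
        groups = [
            GrowthCurve.from_frame(g)
            for _, g in curves.groupby(
                ["isolate", "substrate", "temperature_c", "replicate"], sort=True
            )
        ]
    else:
        groups = list(curves)
    rows = []
    for c in groups:
        fit = fit_exponential_rates(c, constants, min_pts, max_pts, respiration_method)
        rows.append(
            {
                "isolate": c.isolate,
                "substrate": c.substrate,
                "temperature_c": c.temperature_c,
                "replicate": c.replicate,
                "cue": fit.cue,
                "mu": fit.mu,
                "r": fit.r_mass_specific,
                "mu_p": fit.mu_p,
                "r_p": fit.r_p,
                "window_start": fit.window[0],
                "window_end": fit.window[1],
                "qc_pass": (fit.mu_p <= alpha) and (fit.r_p <= alpha),
            }
        )
    return pd.DataFrame(rows)


def qc_filter(
    records: pd.DataFrame, min_replicates: int = 2, alpha: float = 0.05
) -> pd.DataFrame:
    """Apply the replicate- and condition-level quality filters.

    Drops replicates whose growth or respiration slope F-test exceeds
    ``alpha``, then drops entire (isolate, substrate, temperature)
    conditions with fewer than ``min_replicates`` survivors.  An empty
    result is allowed.
    """
    ok = records[(records["mu_p"] <= alpha) & (records["r_p"] <= alpha)].copy()
    if ok.empty:
        return ok
    counts = ok.groupby(["isolate", "substrate", "temperature_c"])["replicate"].transform(
        "size"
    )
    return ok[counts >= min_replicates].reset_index(drop=True)


def energy_per_carbon(substrate: str, constants: AssayConstants) -> float:
    """Substrate energy content per mole of carbon (kJ / mol C).

    Heat of combustion divided by the number of carbon atoms per molecule —
    the substrate-quality axis used when relating CUE to the energy density
    of the growth substrate.
    """
    try:
        heat, n_c = constants.substrate_table[substrate]
    except KeyError:
        raise KeyError(f"substrate {substrate!r} not in substrate table") from None
    if n_c <= 0:
        raise ValueError("carbon count must be positive")
    return heat / n_c
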