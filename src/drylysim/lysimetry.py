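"""Gravimetric lysimeter trace processing.

Turns raw load-cell weight series, soil-probe traces and climate records into
whole-plant physiological quantities: plant daily transpiration (PDT, the
predawn-minus-evening container weight difference), daily plant weight gain
(dPW, the day-over-day post-drainage morning weight difference, attributable
to biomass because drainage returns the container to a fixed water level),
cumulative series, biomass water-use efficiency (WUE, the slope of cumulative
gain on cumulative transpiration during the well-watered pretreatment), the
diurnal transpiration rate (first derivative of the smoothed weight) and the
size- and demand-normalized transpiration ETW = rate / plant weight / VPD.

All operations are pure given a config; nothing is cached between plants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import savgol_filter

#: Standard Topp (1980) third-order polynomial coefficients for mineral soils,
#: permittivity -> volumetric water content (m3/m3).  Calibrated sensors
#: override these via config.
TOPP_DEFAULT_COEFFS = (-5.3e-2, 2.92e-2, -5.5e-4, 4.3e-6)


@dataclass(frozen=True)
class WeighTrace:
    """Container-weight time series for one pot on a regular time grid.

    ``data`` is indexed by timestamp and carries ``weight_g`` plus boolean
    ``irrigation`` and ``drainage`` columns; a drainage flag marks the step at
    which free drainage after an irrigation event has finished, so the
    container is back at its controlled water level.
    """

    plant_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("weight_g", "irrigation", "drainage"):
            if col not in self.data.columns:
                raise ValueError(f"weight trace missing column {col!r}")
        idx = self.data.index
        if len(idx) > 2:
            steps = np.diff(idx.view("i8"))
            if not (steps > 0).all() or len(set(steps)) != 1:
                raise ValueError("weight trace grid must be strictly increasing and regular")
        if (self.data["weight_g"] <= 0).any():
            raise ValueError("container weights must be positive")

    @property
    def step_min(self) -> float:
        idx = self.data.index
        return float((idx[1] - idx[0]).total_seconds() / 60.0)


@dataclass(frozen=True)
class SoilProbeTrace:
    """Soil moisture / salinity / temperature probe series for one pot.

    ``data`` is indexed by timestamp with at least one of ``permittivity`` or
    ``swc`` (relative soil water content, 0-1), plus optional ``ec`` and
    ``soil_temp``.
    """

    plant_id: str
    data: pd.DataFrame


@dataclass(frozen=True)
class WueFit:
    wue: float
    intercept: float
    r2: float
    n_days: int


@dataclass
class LysimetryConfig:
    """Windows, smoothing and validity thresholds for trace processing."""

    predawn_window: tuple[str, str] = ("04:30", "05:00")
    evening_window: tuple[str, str] = ("19:30", "20:00")
    smooth_window_min: float = 30.0
    smooth_method: str = "moving_average"  # or "savgol"
    vpd_floor_kpa: float = 0.1
    min_window_fraction: float = 0.9
    initial_plant_weight_g: dict[str, float] = field(default_factory=dict)
    topp_coeffs: tuple[float, float, float, float] = TOPP_DEFAULT_COEFFS


def compute_vpd(air_temp_c, rel_humidity_pct):
    """Vapor pressure deficit (kPa) from air temperature and relative humidity.

    Saturation vapor pressure follows the Tetens formula
    e_sat(T) = 0.6108 * exp(17.27 T / (T + 237.3)); VPD = e_sat * (1 - RH/100).
    """
    t = np.asarray(air_temp_c, dtype=float)
    rh = np.asarray(rel_humidity_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must be within [0, 100]%")
    e_sat = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    vpd = e_sat * (1.0 - rh / 100.0)
    if vpd.ndim == 0:
        return float(vpd)
    return vpd


def topp_vwc(permittivity, coeffs=None):
    """Volumetric water content (m3/m3) from dielectric permittivity.

    Evaluates the third-order Topp polynomial c0 + c1 e + c2 e^2 + c3 e^3 and
    clips to [0, 1].  Returns ``(vwc, clipped)`` where ``clipped`` flags
    values that fell outside the physical range before clipping.
    """
    if coeffs is None:
        coeffs = TOPP_DEFAULT_COEFFS
    if len(coeffs) != 4:
        raise ValueError("Topp calibration requires 4 polynomial coefficients")
    eps = np.asarray(permittivity, dtype=float)
    c0, c1, c2, c3 = coeffs
    raw = c0 + c1 * eps + c2 * eps**2 + c3 * eps**3
    clipped = (raw < 0) | (raw > 1)
    vwc = np.clip(raw, 0.0, 1.0)
    if vwc.ndim == 0:
        return float(vwc), bool(clipped)
    return vwc, clipped


def _smooth(weight: pd.Series, window_steps: int, method: str) -> pd.Series:
    if method == "moving_average":
        return weight.rolling(window_steps, center=True, min_periods=1).mean()
    if method == "savgol":
        wl = window_steps if window_steps % 2 == 1 else window_steps + 1
        wl = min(wl, len(weight) if len(weight) % 2 == 1 else len(weight) - 1)
        return pd.Series(savgol_filter(weight.to_numpy(), wl, 2), index=weight.index)
    raise ValueError(f"unknown smoothing method {method!r}")


def smooth_and_rate(
    trace: WeighTrace,
    window_min: float = 30.0,
    method: str = "moving_average",
    mask_pad_min: float | None = None,
) -> pd.Series:
    """Transpiration rate series (g/min) from the first derivative of smoothed weight.

    The weight series is smoothed (centered moving average by default,
    Savitzky-Golay as an alternative), differentiated, and negated so that
    water loss is positive.  Steps within an irrigation-to-drainage interval,
    padded by half the smoothing window on each side, are masked (NaN): the
    weight jump there is water added, not transpiration.
    """
    step = trace.step_min
    window_steps = max(3, int(round(window_min / step)))
    if window_steps > len(trace.data):
        raise ValueError("smoothing window exceeds trace span")
    smoothed = _smooth(trace.data["weight_g"], window_steps, method)
    rate = pd.Series(
        -np.gradient(smoothed.to_numpy(), step), index=trace.data.index, name="rate_g_min"
    )
    # Mask irrigation/drainage disturbances.
    pad = int(np.ceil((mask_pad_min if mask_pad_min is not None else window_min / 2) / step))
    disturbed = (trace.data["irrigation"] | trace.data["drainage"]).to_numpy()
    # Extend mask from each irrigation step to the following drainage step.
    active = False
    spans = np.zeros(len(disturbed), dtype=bool)
    for i in range(len(disturbed)):
        if trace.data["irrigation"].iat[i]:
            active = True
        if active:
            spans[i] = True
        if trace.data["drainage"].iat[i]:
            active = False
    mask = spans | disturbed
    if pad and mask.any():
        idx = np.flatnonzero(mask)
        for j in idx:
            mask[max(0, j - pad) : j + pad + 1] = True
    rate[mask] = np.nan
    return rate


def _window_mean(
    day_frame: pd.DataFrame, window: tuple[str, str], min_fraction: float, step_min: float
) -> float:
    """Mean weight over a clock-time window of one day; NaN when too sparse
    or when an irrigation event falls inside the window."""
    sub = day_frame.between_time(window[0], window[1])
    t0 = pd.Timestamp(f"2000-01-01 {window[0]}")
    t1 = pd.Timestamp(f"2000-01-01 {window[1]}")
    expected = int((t1 - t0).total_seconds() / 60.0 / step_min) + 1
    if len(sub) < min_fraction * expected:
        return np.nan
    if sub["irrigation"].any():
        return np.nan
    return float(sub["weight_g"].mean())


def daily_transpiration(
    trace: WeighTrace,
    predawn_window: tuple[str, str] = ("04:30", "05:00"),
    evening_window: tuple[str, str] = ("19:30", "20:00"),
    min_window_fraction: float = 0.9,
) -> pd.DataFrame:
    """Plant daily transpiration (PDT) per day.

    PDT_k = mean weight over the predawn window of day k minus the mean over
    the evening window of day k, each a 30-min average by default.  Days with
    a sparse or irrigation-contaminated window are flagged invalid (NaN PDT),
    not dropped.
    """
    step = trace.step_min
    rows = []
    for day, frame in trace.data.groupby(trace.data.index.normalize()):
        wm = _window_mean(frame, predawn_window, min_window_fraction, step)
        we = _window_mean(frame, evening_window, min_window_fraction, step)
        pdt = wm - we
        rows.append({"day": day, "w_morning": wm, "w_evening": we,
                     "pdt_g": pdt, "valid": bool(np.isfinite(pdt))})
    return pd.DataFrame(rows).set_index("day")


def daily_weight_gain(
    trace: WeighTrace,
    predawn_window: tuple[str, str] = ("04:30", "05:00"),
    min_window_fraction: float = 0.9,
) -> pd.DataFrame:
    """Daily plant weight gain dPW_k per day pair.

    dPW_k is the difference between the post-drainage morning container
    weights of days k+1 and k (30-min predawn means).  Because drainage
    returns the container water level to a fixed mark, the difference is the
    plant's biomass gain.  Mornings without a completed-drainage marker since
    the previous evening are skipped with a warning.
    """
    step = trace.step_min
    days = []
    for day, frame in trace.data.groupby(trace.data.index.normalize()):
        w = _window_mean(frame, predawn_window, min_window_fraction, step)
        window_start = day + pd.Timedelta(
            hours=int(predawn_window[0][:2]), minutes=int(predawn_window[0][3:])
        )
        prev_evening = window_start - pd.Timedelta(hours=12)
        drained = bool(
            trace.data.loc[prev_evening:window_start, "drainage"].any()
        )
        days.append({"day": day, "w_morning": w, "drained": drained})
    tab = pd.DataFrame(days).set_index("day")
    rows, skipped = [], []
    for k in range(len(tab) - 1):
        d0 = tab.index[k]
        if not (tab["drained"].iloc[k] and tab["drained"].iloc[k + 1]):
            skipped.append(str(d0.date()))
            continue
        dpw = tab["w_morning"].iloc[k + 1] - tab["w_morning"].iloc[k]
        rows.append({"day": d0, "dpw_g": dpw, "valid": bool(np.isfinite(dpw))})
    if skipped:
        warnings.warn(
            f"{trace.plant_id}: no drainage-complete marker bracketing "
            f"{len(skipped)} day(s) ({skipped[0]}..{skipped[-1]}); skipped",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["day", "dpw_g", "valid"]).set_index("day")


def build_daily(trace: WeighTrace, config: LysimetryConfig | None = None) -> pd.DataFrame:
    """Per-day physiology table: PDT, dPW and their cumulative series."""
    cfg = config or LysimetryConfig()
    pdt = daily_transpiration(
        trace, cfg.predawn_window, cfg.evening_window, cfg.min_window_fraction
    )
    dpw = daily_weight_gain(trace, cfg.predawn_window, cfg.min_window_fraction)
    daily = pdt[["pdt_g"]].join(dpw[["dpw_g"]], how="left")
    daily["cum_transp_g"] = daily["pdt_g"].fillna(0).cumsum()
    daily["cum_gain_g"] = daily["dpw_g"].fillna(0).cumsum()
    daily.insert(0, "plant_id", trace.plant_id)
    return daily


def fit_wue(daily: pd.DataFrame, phase: slice | tuple | None = None) -> WueFit:
    """Biomass water-use efficiency from the pretreatment phase.

    Ordinary least-squares slope of cumulative weight gain on cumulative
    transpiration over the phase days.  Requires at least 3 days and
    non-degenerate transpiration.
    """
    tab = daily
    if phase is not None:
        if isinstance(phase, tuple):
            tab = daily.iloc[phase[0] : phase[1]]
        else:
            tab = daily.iloc[phase]
    tab = tab.dropna(subset=["pdt_g", "dpw_g"])
    if len(tab) < 3:
        raise ValueError(f"WUE fit requires >= 3 valid days, got {len(tab)}")
    x = tab["cum_transp_g"].to_numpy()
    y = tab["cum_gain_g"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("zero variance in cumulative transpiration; WUE undefined")
    res = stats.linregress(x, y)
    return WueFit(
        wue=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_days=len(tab),
    )


def normalize_etw(
    rate: pd.Series,
    plant_weight_by_day: pd.Series,
    vpd: pd.Series,
    vpd_floor_kpa: float = 0.1,
) -> pd.Series:
    """Transpiration normalized to plant weight and VPD.

    ETW(t) = rate(t) / plant_weight(day of t) / VPD(t), in
    g g^-1 kPa^-1 min^-1.  Undefined (NaN) where VPD is below the floor —
    nocturnal values would otherwise blow up dividing by a near-zero demand.
    ``plant_weight_by_day`` is indexed by normalized day (morning weight:
    initial plant weight plus cumulative gain).
    """
    if (plant_weight_by_day <= 0).any():
        raise ValueError("plant weight must be positive for ETW normalization")
    days = rate.index.normalize()
    weights = plant_weight_by_day.reindex(days).to_numpy()
    vpd_aligned = vpd.reindex(rate.index).to_numpy()
    etw = rate.to_numpy() / weights / vpd_aligned
    etw[vpd_aligned < vpd_floor_kpa] = np.nan
    return pd.Series(etw, index=rate.index, name="etw")


def plant_weight_series(
    daily: pd.DataFrame, initial_weight_g: float, wue: float | None = None
) -> pd.Series:
    """Morning plant weight per day: initial weight + cumulative prior gain.

    Days without a measurable dPW (no irrigation/drainage cycle, i.e. the
    drought phase) contribute ``wue x PDT`` to the running gain when a WUE
    estimate is supplied — growth does not stop when irrigation is withheld,
    only its gravimetric measurement does.  Without ``wue`` those days
    contribute zero (the weight estimate freezes at the last drained morning).
    """
    if initial_weight_g <= 0:
        raise ValueError("initial plant weight must be positive")
    inc = daily["dpw_g"]
    if wue is not None:
        inc = inc.fillna(wue * daily["pdt_g"])
    gain = inc.fillna(0).cumsum().shift(1, fill_value=0.0)
    return initial_weight_g + gain
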