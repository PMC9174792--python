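"""Plate-reader growth-curve analysis and between-media comparison.

Growth is called on blank-corrected OD600 series by a simple threshold rule:
an isolate *grew* when the maximum OD minus the first-timepoint OD is at
least 0.05. The maximum specific growth rate is estimated by the steepest
log-linear sliding-window fit, and the lag phase from the intersection of
that tangent with the starting OD level. Media are compared per isolate by a
Welch t-test on replicate maximum ODs with Benjamini-Hochberg correction
across isolates, reported alongside the log2 ratio of mean maximum ODs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GROWTH_THRESHOLD = 0.05  # ΔOD600 at or above which an isolate is called grown

CONTROL_LABEL = "control"


@dataclass
class WellTimeSeries:
    """OD600 readings for one well on a strictly increasing time grid (hours)."""

    time: np.ndarray
    od: np.ndarray
    well: str = ""
    medium: str = ""
    isolate: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.od.shape:
            raise ValueError("time and od must be 1-D arrays of equal length")
        if len(self.time) < 2:
            raise ValueError("a growth series needs at least 2 points")
        if not np.all(np.isfinite(self.od)) or not np.all(np.isfinite(self.time)):
            raise ValueError("time and od must be finite")
        if self.time[0] < 0:
            raise ValueError("time must start at or after 0")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def is_control(self) -> bool:
        return self.isolate == CONTROL_LABEL


@dataclass(frozen=True)
class GrowthSummary:
    """Threshold growth call plus curve metrics for one well."""

    delta_od: float
    grew: bool
    max_od: float
    mu_max: float | None = None  # per hour
    lag: float | None = None  # hours; undefined when not grown

    def __post_init__(self):
        if self.lag is not None and self.lag < 0:
            raise ValueError("lag must be >= 0 when defined")


def blank_correct(
    culture: WellTimeSeries, control: WellTimeSeries, interpolate: bool = False
) -> WellTimeSeries:
    """Subtract an uninoculated-control series pointwise from a culture series.

    With ``interpolate=True`` the control is linearly interpolated onto the
    culture's time grid; otherwise the grids must match exactly.
    """
    if np.array_equal(culture.time, control.time):
        ctrl_od = control.od
    elif interpolate:
        ctrl_od = np.interp(culture.time, control.time, control.od)
    else:
        raise ValueError(
            "culture and control time grids differ; pass interpolate=True to resample"
        )
    return WellTimeSeries(
        time=culture.time.copy(),
        od=culture.od - ctrl_od,
        well=culture.well,
        medium=culture.medium,
        isolate=culture.isolate,
    )


def growth_metrics(
    series: WellTimeSeries,
    threshold: float = GROWTH_THRESHOLD,
    window: int = 5,
    log_floor: float = 1e-4,
    noise_guard: float = 5e-3,
) -> GrowthSummary:
    """Summarize a (blank-corrected) growth curve.

    delta_od is max(od) - od[0] and the growth call is ``delta_od >=
    threshold`` ("0.05 or greater"). mu_max is the steepest slope of a
    degree-1 fit of log OD over a sliding window of ``window`` points; ODs
    are clipped to ``log_floor`` for the log transform only, never for
    delta_od. Windows dipping below ``noise_guard`` are skipped when any
    fully-above window exists, so reader noise around zero cannot masquerade
    as exponential growth. The lag is where the steepest tangent re-crosses
    the starting log-OD level. Series shorter than the window get only
    delta_od/grew.
    """
    od = series.od
    delta = float(od.max() - od[0])
    grew = delta >= threshold
    max_od = float(od.max())
    if len(od) < window or window < 2:
        return GrowthSummary(delta_od=delta, grew=grew, max_od=max_od)

    log_od = np.log(np.maximum(od, log_floor))
    t = series.time
    starts = range(len(od) - window + 1)
    clean = [i for i in starts if od[i : i + window].min() >= noise_guard]
    best_slope, best_intercept = -np.inf, 0.0
    for i in clean or starts:
        slope, intercept = np.polyfit(t[i : i + window], log_od[i : i + window], 1)
        if slope > best_slope:
            best_slope, best_intercept = float(slope), float(intercept)
    mu_max = best_slope if np.isfinite(best_slope) else None
    lag = None
    if grew and mu_max is not None and mu_max > 0:
        lag = max(0.0, (log_od[0] - best_intercept) / mu_max)
    return GrowthSummary(delta_od=delta, grew=grew, max_od=max_od, mu_max=mu_max, lag=lag)


@dataclass(frozen=True)
class MediumComparison:
    """Per-isolate NLDM-vs-reference comparison of replicate max ODs."""

    table: pd.DataFrame = field(repr=False)
    medium_a: str = "NLDM"
    medium_b: str = "R2A"


def compare_media(
    max_ods: pd.DataFrame,
    medium_a: str = "NLDM",
    medium_b: str = "R2A",
    equal_var: bool = False,
) -> MediumComparison:
    """Compare replicate maximum ODs between two media, per isolate.

    ``max_ods`` is long-format with columns ``isolate``, ``medium``,
    ``max_od``. For each isolate with >= 2 replicates in both media a
    two-sample t-test (Welch by default) is run; p-values are BH-adjusted
    across isolates and the log2 ratio of mean max ODs (a/b) is reported.
    Isolates missing a medium or with too few replicates are excluded with a
    warning.
    """
    required = {"isolate", "medium", "max_od"}
    if not required <= set(max_ods.columns):
        raise ValueError(f"max_ods must have columns {sorted(required)}")
    rows = []
    for isolate, sub in max_ods.groupby("isolate", sort=True):
        a = sub.loc[sub["medium"] == medium_a, "max_od"].to_numpy(float)
        b = sub.loc[sub["medium"] == medium_b, "max_od"].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            warnings.warn(
                f"isolate {isolate!r} excluded: needs >= 2 replicates in both media "
                f"({medium_a}: {len(a)}, {medium_b}: {len(b)})",
                stacklevel=2,
            )
            continue
        mean_a, mean_b = float(a.mean()), float(b.mean())
        if np.allclose(a.std(), 0) and np.allclose(b.std(), 0) and math.isclose(mean_a, mean_b):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        if math.isclose(mean_a, mean_b):
            log2_ratio = 0.0
        else:
            log2_ratio = float(np.log2(mean_a / mean_b)) if mean_a > 0 and mean_b > 0 else float("nan")
        rows.append(
            {
                "isolate": isolate,
                f"mean_{medium_a}": mean_a,
                f"mean_{medium_b}": mean_b,
                "log2_ratio": log2_ratio,
                "t": float(t),
                "p": float(p),
            }
        )
    if not rows:
        raise ValueError("no isolate had enough replicates in both media")
    df = pd.DataFrame(rows).set_index("isolate")
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["direction"] = np.where(
        df["log2_ratio"] > 0, f"{medium_a}>{medium_b}",
        np.where(df["log2_ratio"] < 0, f"{medium_b}>{medium_a}", "equal"),
    )
    return MediumComparison(table=df, medium_a=medium_a, medium_b=medium_b)


# ---------------------------------------------------------------------------
# plate-level IO and orchestration

def read_growth_csv(path) -> pd.DataFrame:
    """Long-format plate reader CSV with columns well,time_h,od600."""
    df = pd.read_csv(path)
    missing = {"well", "time_h", "od600"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_plate_map(path) -> pd.DataFrame:
    """Plate map TSV with columns well,isolate,medium,role (culture/control)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"well", "isolate", "medium", "role"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["role"]) - {"culture", "control"}
    if bad:
        raise ValueError(f"{path}: unknown roles {sorted(bad)}")
    return df


def _series_from_frame(sub: pd.DataFrame, well: str, medium: str, isolate: str) -> WellTimeSeries:
    sub = sub.sort_values("time_h")
    return WellTimeSeries(
        time=sub["time_h"].to_numpy(float),
        od=sub["od600"].to_numpy(float),
        well=well,
        medium=medium,
        isolate=isolate,
    )


def analyze_plate(
    plate: pd.DataFrame,
    plate_map: pd.DataFrame,
    threshold: float = GROWTH_THRESHOLD,
    window: int = 5,
) -> pd.DataFrame:
    """Blank-correct every culture well and summarize its growth.

    The blank for each medium is the mean OD trace over that medium's
    uninoculated control wells (interpolated onto each culture grid when
    needed). Returns one row per culture well with the plate-map metadata
    and the :class:`GrowthSummary` fields.
    """
    info = plate_map.set_index("well")
    series: dict[str, WellTimeSeries] = {}
    for well, sub in plate.groupby("well"):
        if well not in info.index:
            raise ValueError(f"well {well!r} present in plate data but absent from plate map")
        meta = info.loc[well]
        series[well] = _series_from_frame(sub, well, meta["medium"], meta["isolate"])

    controls: dict[str, WellTimeSeries] = {}
    for medium in info["medium"].unique():
        wells = info.index[(info["medium"] == medium) & (info["role"] == "control")]
        ctrl = [series[w] for w in wells if w in series]
        if not ctrl:
            continue
        grid = ctrl[0].time
        ods = np.vstack([np.interp(grid, s.time, s.od) for s in ctrl])
        controls[medium] = WellTimeSeries(
            time=grid, od=ods.mean(axis=0), well="<mean control>", medium=medium,
            isolate=CONTROL_LABEL,
        )

    rows = []
    for well, s in series.items():
        if info.loc[well, "role"] != "culture":
            continue
        if s.medium in controls:
            s = blank_correct(s, controls[s.medium], interpolate=True)
        else:
            warnings.warn(f"no control wells for medium {s.medium!r}; skipping blank correction")
        gs = growth_metrics(s, threshold=threshold, window=window)
        rows.append(
            {
                "well": well, "isolate": s.isolate, "medium": s.medium,
                "delta_od": gs.delta_od, "grew": gs.grew, "max_od": gs.max_od,
                "mu_max": gs.mu_max, "lag": gs.lag,
            }
        )
    return pd.DataFrame(rows)
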