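"""Electrochemical DNA-biosensor signal analytics.

Covers the numeric pipeline of a methylene-blue DPV hybridisation assay:

* baseline-corrected peak extraction from a differential-pulse
  voltammogram (the hybridisation signal is the methylene-blue reduction
  peak height, proportional to the amount of hybridised duplex);
* replicate statistics (mean, SD, relative standard deviation
  RSD = sigma * 100 / mu);
* log-linear calibration (peak current vs log10 concentration), contiguous
  linear-range detection, and limit of detection from blank noise;
* effective electroactive surface area from the Randles–Ševčík relation
  Ip = 2.69e5 * n^(3/2) * A * D^(1/2) * C * v^(1/2) (reversible couple,
  25 °C; Ip in A, D in cm²/s, C in mol/cm³, v in V/s, A in cm²);
* a selectivity summary organising measured peak currents of target vs
  mismatch / noncomplementary / nontarget oligos.

Units convention throughout: potentials in volts, currents in
microamperes, concentrations in molar — except inside the Randles–Ševčík
formula, where the stated CGS-style contract applies (handled internally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Randles–Ševčík prefactor for a reversible diffusion-controlled couple at 25 °C.
RANDLES_SEVCIK_CONST = 2.69e5


class VoltammetryError(ValueError):
    """Raised for malformed traces/series or invalid analysis parameters."""


# ---------------------------------------------------------------------------
# Voltammogram + peak extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Voltammogram:
    """A potential sweep: potentials in V (strictly monotone), currents in μA."""

    potentials: np.ndarray
    currents: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.potentials, dtype=float)
        c = np.asarray(self.currents, dtype=float)
        object.__setattr__(self, "potentials", p)
        object.__setattr__(self, "currents", c)
        if p.ndim != 1 or c.ndim != 1 or len(p) != len(c):
            raise VoltammetryError("potentials and currents must be equal-length 1-D")
        if len(p) < 10:
            raise VoltammetryError(f"voltammogram needs >= 10 points, got {len(p)}")
        d = np.diff(p)
        if np.all(d > 0):
            direction = "ascending"
        elif np.all(d < 0):
            direction = "descending"
        else:
            raise VoltammetryError(
                "potential sweep must be strictly monotone (duplicate or "
                "non-monotone potential values found)"
            )
        object.__setattr__(self, "metadata", {**self.metadata, "direction": direction})

    def __len__(self) -> int:
        return len(self.potentials)


def read_voltammogram(path: str | Path) -> Voltammogram:
    """Read a two-column potential/current table (CSV or TSV, optional header).

    Units are taken from a ``potential_V,current_uA``-style header when
    present; otherwise V and μA are assumed (logged).
    """
    df = _read_numeric_table(path, 2, ["potential_V", "current_uA"])
    return Voltammogram(
        df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), {"source": str(path)}
    )


def _read_numeric_table(
    path: str | Path, ncols: int, default_names: list[str]
) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    first = path.read_text().lstrip().splitlines()
    if not first:
        raise VoltammetryError(f"{path} is empty")
    def _numeric(line: str) -> bool:
        try:
            [float(x) for x in line.split(sep)]
            return True
        except ValueError:
            return False
    header = 0 if not _numeric(first[0]) else None
    if header is None:
        logger.info("%s: no header; assuming columns %s", path, default_names)
    df = pd.read_csv(path, sep=sep, header=header)
    if df.shape[1] < ncols:
        raise VoltammetryError(f"{path}: expected {ncols} columns, got {df.shape[1]}")
    df = df.iloc[:, :ncols]
    if not all(np.issubdtype(d, np.number) for d in df.dtypes):
        raise VoltammetryError(f"{path}: non-numeric rows present")
    return df


@dataclass(frozen=True)
class PeakResult:
    """Baseline-corrected peak height Ip (μA) at potential Ep (V)."""

    ip: float
    ep: float
    no_peak: bool = False
    baseline_mode: str = "chord"


def peak_current(
    v: Voltammogram,
    window: tuple[float, float],
    baseline: Literal["chord", "flat"] = "chord",
) -> PeakResult:
    """Extract the baseline-corrected peak from *v* inside *window* (volts).

    ``chord``: the baseline is the straight line joining the trace values
    at the window edges; Ip is the maximum of (current − baseline) over
    the window.  Adding any linear function of potential to the trace
    leaves a chord-mode Ip unchanged.  ``flat``: the baseline is the
    median of the 10% of window points nearest the two edges.

    A non-positive Ip is returned with ``no_peak=True``, not raised.
    """
    lo, hi = min(window), max(window)
    p, c = v.potentials, v.currents
    if lo < p.min() - 1e-12 or hi > p.max() + 1e-12:
        raise VoltammetryError(
            f"window ({lo}, {hi}) V outside sweep ({p.min()}, {p.max()}) V"
        )
    mask = (p >= lo) & (p <= hi)
    if mask.sum() < 5:
        raise VoltammetryError(f"only {int(mask.sum())} points inside window; need >= 5")
    pw, cw = p[mask], c[mask]
    order = np.argsort(pw)
    pw, cw = pw[order], cw[order]
    if baseline == "chord":
        base = np.interp(pw, [pw[0], pw[-1]], [cw[0], cw[-1]])
    elif baseline == "flat":
        n_edge = max(1, int(round(0.05 * len(pw))))
        base = np.full_like(cw, float(np.median(np.r_[cw[:n_edge], cw[-n_edge:]])))
    else:
        raise VoltammetryError(f"unknown baseline mode {baseline!r}")
    corrected = cw - base
    i = int(np.argmax(corrected))
    ip = float(corrected[i])
    return PeakResult(ip=ip, ep=float(pw[i]), no_peak=ip <= 0, baseline_mode=baseline)


# ---------------------------------------------------------------------------
# Replicate statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicateStats:
    """Mean μ, standard deviation σ and RSD = σ·100/μ of replicate peak currents."""

    values: tuple[float, ...]
    mean: float
    sd: float
    rsd: float
    ddof: int

    def rounded(self, sig: int = 3) -> tuple[float, float, float]:
        """(μ, σ, RSD) at *sig* significant figures, the reporting convention."""
        def r(x: float) -> float:
            if x == 0:
                return 0.0
            from math import floor, log10
            return round(x, -int(floor(log10(abs(x)))) + sig - 1)
        return r(self.mean), r(self.sd), r(self.rsd)


def replicate_stats(values: Sequence[float], ddof: int = 1) -> ReplicateStats:
    """Replicate precision statistics.

    σ uses the declared ``ddof`` (1 = sample SD, the default; 0 =
    population SD); RSD = σ × 100 / μ.  Requires at least two values and a
    positive mean.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise VoltammetryError(f"need >= 2 replicate values, got {len(vals)}")
    if ddof not in (0, 1):
        raise VoltammetryError(f"ddof must be 0 or 1, got {ddof}")
    mu = float(np.mean(vals))
    if mu <= 0:
        raise VoltammetryError(f"RSD undefined for nonpositive mean ({mu})")
    sigma = float(np.std(vals, ddof=ddof))
    return ReplicateStats(tuple(map(float, vals)), mu, sigma, sigma * 100.0 / mu, ddof)


def rsd_from_summary(mean: float, sd: float) -> float:
    """RSD = σ·100/μ from already-summarised μ and σ."""
    if mean <= 0:
        raise VoltammetryError(f"RSD undefined for nonpositive mean ({mean})")
    return sd * 100.0 / mean


# ---------------------------------------------------------------------------
# Calibration, linear range, LOD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationSeries:
    """(concentration [M], peak current [μA]) points, optionally with blank noise."""

    concentrations: np.ndarray
    peak_currents: np.ndarray
    blank_sigma: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        i = np.asarray(self.peak_currents, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "peak_currents", i)
        if len(c) != len(i):
            raise VoltammetryError("concentration/current length mismatch")
        if np.any(c <= 0):
            raise VoltammetryError("concentrations must be positive")
        if len(np.unique(c)) != len(c):
            raise VoltammetryError("concentrations must be distinct")

    def sorted(self) -> "CalibrationSeries":
        order = np.argsort(self.concentrations)
        return CalibrationSeries(
            self.concentrations[order], self.peak_currents[order], self.blank_sigma
        )

    def __len__(self) -> int:
        return len(self.concentrations)


def read_calibration(path: str | Path) -> CalibrationSeries:
    """Read a (concentration_M, peak_current_uA) CSV/TSV."""
    df = _read_numeric_table(path, 2, ["concentration_M", "peak_current_uA"])
    return CalibrationSeries(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


@dataclass(frozen=True)
class CalibrationFit:
    """OLS of peak current on log10(concentration)."""

    slope: float       # μA per log10(M)
    intercept: float   # μA
    r_squared: float
    n: int


def fit_calibration(series: CalibrationSeries) -> CalibrationFit:
    """Ordinary least squares of peak current on log10(concentration).

    R² is the squared Pearson correlation of fitted vs observed values.
    """
    if len(series) < 3:
        raise VoltammetryError(f"calibration fit needs >= 3 points, got {len(series)}")
    x = np.log10(series.concentrations)
    if np.ptp(x) == 0:
        raise VoltammetryError("zero variance in log10(concentration)")
    res = stats.linregress(x, series.peak_currents)
    return CalibrationFit(float(res.slope), float(res.intercept),
                          float(res.rvalue) ** 2, len(series))


@dataclass(frozen=True)
class LinearRange:
    """The longest contiguous concentration run with an acceptable linear fit."""

    found: bool
    low: float | None = None
    high: float | None = None
    indices: tuple[int, ...] = ()   # into the concentration-sorted series
    fit: CalibrationFit | None = None


def linear_range(
    series: CalibrationSeries,
    r2_min: float = 0.99,
    min_points: int = 4,
) -> LinearRange:
    """Find the linear span of a calibration series.

    Enumerates contiguous runs of the concentration-sorted points (no
    subset search — calibration ranges are reported as contiguous spans)
    and returns the longest run of at least *min_points* whose OLS fit of
    current on log10(C) reaches R² ≥ *r2_min*; length ties break by higher
    R².  Returns ``LinearRange(found=False)`` when no run qualifies.
    """
    s = series.sorted()
    n = len(s)
    if n < min_points:
        raise VoltammetryError(f"need >= {min_points} points, got {n}")
    best: tuple[int, float] | None = None  # (length, r2)
    best_run: tuple[int, int] | None = None
    for i in range(n):
        for j in range(i + min_points, n + 1):
            sub = CalibrationSeries(s.concentrations[i:j], s.peak_currents[i:j])
            fit = fit_calibration(sub)
            if fit.r_squared >= r2_min:
                key = (j - i, fit.r_squared)
                if best is None or key > best:
                    best = key
                    best_run = (i, j)
    if best_run is None:
        return LinearRange(found=False)
    i, j = best_run
    sub = CalibrationSeries(s.concentrations[i:j], s.peak_currents[i:j])
    return LinearRange(
        found=True,
        low=float(s.concentrations[i]),
        high=float(s.concentrations[j - 1]),
        indices=tuple(range(i, j)),
        fit=fit_calibration(sub),
    )


LOD_K = {"three_sigma": 3.0, "three_point_three_sigma": 3.3}


def limit_of_detection(
    slope: float,
    blank_sigma: float,
    rule: Literal["three_sigma", "three_point_three_sigma"] = "three_point_three_sigma",
    reference_concentration: float | None = None,
    intercept: float | None = None,
    blank_mean: float = 0.0,
) -> float:
    """Concentration whose fitted signal exceeds the blank mean by k·σ_blank.

    With calibration line I = intercept + slope·log10(C), the signal
    threshold is blank_mean + k·σ (k = 3 or 3.3 per *rule*) and

        LOD = C_ref · 10^(k·σ / |slope|),

    where C_ref is the concentration whose fitted signal equals the blank
    mean.  Pass C_ref directly via *reference_concentration*, or pass
    *intercept* (and optionally *blank_mean*) to derive
    log10(C_ref) = (blank_mean − intercept) / slope.  This inversion
    convention is what run manifests record.
    """
    if slope == 0:
        raise VoltammetryError("zero calibration slope")
    if blank_sigma <= 0:
        raise VoltammetryError(f"blank sigma must be positive, got {blank_sigma}")
    try:
        k = LOD_K[rule]
    except KeyError:
        raise VoltammetryError(f"unknown LOD rule {rule!r}") from None
    if reference_concentration is None:
        if intercept is None:
            raise VoltammetryError(
                "need reference_concentration or intercept to anchor the LOD"
            )
        log_cref = (blank_mean - intercept) / slope
    else:
        if reference_concentration <= 0:
            raise VoltammetryError("reference concentration must be positive")
        log_cref = np.log10(reference_concentration)
    return float(10.0 ** (log_cref + k * blank_sigma / abs(slope)))


# ---------------------------------------------------------------------------
# Randles–Ševčík surface area
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RedoxConstants:
    """n: electrons transferred; D: diffusion coefficient [cm²/s]; C: bulk
    concentration [mol/cm³] of the redox indicator."""

    n: float
    D: float
    C: float

    def __post_init__(self) -> None:
        if self.n <= 0 or self.D <= 0 or self.C <= 0:
            raise VoltammetryError("redox constants must be positive")


@dataclass(frozen=True)
class ScanRateSeries:
    """(scan rate [V/s], peak current [μA]) points with the redox constants."""

    scan_rates: np.ndarray
    peak_currents: np.ndarray
    constants: RedoxConstants

    def __post_init__(self) -> None:
        v = np.asarray(self.scan_rates, dtype=float)
        i = np.asarray(self.peak_currents, dtype=float)
        object.__setattr__(self, "scan_rates", v)
        object.__setattr__(self, "peak_currents", i)
        if len(v) != len(i):
            raise VoltammetryError("scan-rate/current length mismatch")
        if len(v) < 3:
            raise VoltammetryError(f"need >= 3 scan rates, got {len(v)}")
        if np.any(v <= 0):
            raise VoltammetryError("scan rates must be positive")


def read_scan_rate_series(
    path: str | Path, constants: RedoxConstants
) -> ScanRateSeries:
    """Read a (scan_rate_V_per_s, peak_current_uA) CSV/TSV."""
    df = _read_numeric_table(path, 2, ["scan_rate_V_per_s", "peak_current_uA"])
    return ScanRateSeries(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), constants)


def effective_surface_area(series: ScanRateSeries) -> float:
    """Electroactive surface area A [cm²] from the Ip-vs-√v slope.

    Fits Ip (converted to amperes) on √v by OLS; for a reversible
    diffusion-controlled couple at 25 °C,
    A = slope / (2.69e5 · n^{3/2} · D^{1/2} · C).
    A non-positive slope means the response is not diffusion-controlled
    and is an error.
    """
    x = np.sqrt(series.scan_rates)
    y = series.peak_currents * 1e-6  # μA -> A
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise VoltammetryError(
            "non-diffusive response: Ip does not increase with sqrt(scan rate)"
        )
    k = series.constants
    return float(res.slope / (RANDLES_SEVCIK_CONST * k.n**1.5 * np.sqrt(k.D) * k.C))


def randles_sevcik_current(
    area_cm2: float, constants: RedoxConstants, scan_rate: float | np.ndarray
) -> np.ndarray:
    """Forward Randles–Ševčík peak current in μA for given area and scan rate."""
    k = constants
    ip_amp = RANDLES_SEVCIK_CONST * k.n**1.5 * area_cm2 * np.sqrt(k.D) * k.C * np.sqrt(
        np.asarray(scan_rate, dtype=float)
    )
    return ip_amp * 1e6


# ---------------------------------------------------------------------------
# Selectivity summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectivitySummary:
    """Measured peak currents organised relative to the target oligo.

    ``discriminates`` is True when the target peak current exceeds every
    nontarget peak current.  The input currents are data, not computed.
    """

    table: pd.DataFrame
    target_label: str
    discriminates: bool
    max_nontarget: float


def selectivity_summary(
    labelled: Sequence[tuple[str, float]], target_label: str
) -> SelectivitySummary:
    """Tabulate (label, Ip) pairs with ratios to the target current."""
    labels = [lab for lab, _ in labelled]
    if target_label not in labels:
        raise VoltammetryError(f"target label {target_label!r} not in panel")
    if len(labelled) < 2:
        raise VoltammetryError("need the target plus >= 1 nontarget")
    ip_target = dict(labelled)[target_label]
    rows = [
        {
            "label": lab,
            "peak_current_uA": ip,
            "ratio_to_target": ip / ip_target,
            "role": "target" if lab == target_label else "nontarget",
        }
        for lab, ip in labelled
    ]
    table = pd.DataFrame(rows)
    max_nt = float(table.loc[table["role"] == "nontarget", "peak_current_uA"].max())
    return SelectivitySummary(
        table=table,
        target_label=target_label,
        discriminates=bool(ip_target > max_nt),
        max_nontarget=max_nt,
    )
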