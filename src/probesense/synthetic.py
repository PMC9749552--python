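"""Seeded generators with planted ground truth.

Two families of simulated data give every analytic operation an oracle
without external downloads:

* MSAs with a planted probe window — a conserved target row, nontarget
  rows carrying an exact, intended number of mismatches inside the window
  (mirroring the 6–14-base / 19–45% divergence of a real cytb barcode
  panel) and low background divergence elsewhere;
* DPV traces, calibration series and scan-rate series built from a
  Gaussian peak on a linear baseline whose amplitude follows a
  floor / log-linear / saturation response in concentration — the shape of
  a methylene-blue hybridisation signal, where accumulated dye is
  proportional to hybridised duplex — plus i.i.d. Gaussian noise.

Every generator is a pure function of its spec and seed, so outputs are
bit-reproducible.  Gaps are never planted inside the probe window by
default, keeping the planted mismatch counts exact; a stress flag plants
them to exercise the invalid-window path.

What these simulations do not emulate: phylogenetic correlation between
species (substitutions are i.i.d. uniform over the three alternative
bases), electrode drift, non-Gaussian electrochemical noise, and peak
shape changes with concentration.  Passing tests therefore establish the
correctness of the analytic code, not instrument-level realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .probe_design import GAP, AlignedSet
from .voltammetry import (
    CalibrationSeries,
    RedoxConstants,
    ScanRateSeries,
    Voltammogram,
    peak_current,
    randles_sevcik_current,
)

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# MSA generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MsaSpec:
    """Design of a planted-window alignment.

    per_species_window_mismatches maps each nontarget species id to the
    exact number of mismatching positions it gets inside the planted
    window.  background_divergence is the per-site substitution
    probability outside the window; indel_rate the per-site gap
    probability (nontargets only, outside the window unless
    ``stress_gaps_in_window``).
    """

    alignment_length: int = 200
    window_start: int = 60
    window_length: int = 31
    per_species_window_mismatches: Mapping[str, int] = field(
        default_factory=lambda: {"sp2": 6, "sp3": 14}
    )
    background_divergence: float = 0.05
    indel_rate: float = 0.0
    target_id: str = "target"
    seed: int = 0
    stress_gaps_in_window: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.window_start <= self.alignment_length - self.window_length:
            raise ValueError("planted window does not fit in the alignment")
        for sid, k in self.per_species_window_mismatches.items():
            if not 0 <= k <= self.window_length:
                raise ValueError(f"{sid}: intended count {k} exceeds window length")
        for p in (self.background_divergence, self.indel_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not self.per_species_window_mismatches:
            raise ValueError("need at least one nontarget species")

    @property
    def n_species(self) -> int:
        return 1 + len(self.per_species_window_mismatches)


@dataclass(frozen=True)
class MsaGroundTruth:
    """What was planted: window coordinates and exact per-species counts."""

    window_start: int
    window_length: int
    per_species_counts: dict[str, int]
    target_sequence: str


def generate_msa(spec: MsaSpec) -> tuple[AlignedSet, MsaGroundTruth]:
    """Build an alignment whose best probe window is known by construction.

    The target row is a uniform-random root sequence.  Each nontarget row
    mutates exactly its intended number of window positions (chosen
    without replacement, substitution to a uniformly chosen different
    base) and each outside-window site independently with
    ``background_divergence``; with ``indel_rate > 0`` outside-window
    sites additionally become gaps.

    Planted mismatch positions are anchored: the first and last window
    columns are always among each species' mutated sites (one of them for
    a single-mismatch species).  Any shifted window therefore drops at
    least one planted mismatch from every species, making the planted
    window the strictly best probe window in the zero-background limit —
    the ground truth the recovery oracle relies on.
    """
    rng = np.random.default_rng(spec.seed)
    L, w0, wlen = spec.alignment_length, spec.window_start, spec.window_length
    root = rng.choice(BASES, size=L)
    window_cols = set(range(w0, w0 + wlen))

    records: list[tuple[str, str]] = [(spec.target_id, "".join(root))]
    counts: dict[str, int] = {}
    for sid, k in spec.per_species_window_mismatches.items():
        row = root.copy()
        anchors = [w0, w0 + wlen - 1][:k]
        interior = np.arange(w0 + 1, w0 + wlen - 1)
        extra = rng.choice(interior, size=max(0, k - len(anchors)), replace=False)
        pos = np.concatenate([np.array(anchors, dtype=int), extra.astype(int)])
        for p in pos:
            row[p] = rng.choice([b for b in BASES if b != root[p]])
        for col in range(L):
            if col in window_cols and not spec.stress_gaps_in_window:
                continue
            if col in pos:
                continue
            if spec.indel_rate and rng.random() < spec.indel_rate:
                row[col] = GAP
            elif rng.random() < spec.background_divergence:
                row[col] = rng.choice([b for b in BASES if b != root[col]])
        records.append((sid, "".join(row)))
        counts[sid] = int(k)
    msa = AlignedSet(tuple(records), spec.target_id)
    truth = MsaGroundTruth(w0, wlen, counts, "".join(root))
    return msa, truth


def write_alignment_fasta(msa: AlignedSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in msa.records:
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# DPV generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmplitudeModel:
    """Piecewise peak-amplitude response A(C) in μA.

    floor below ``linear_low``; a + b·log10(C) inside
    [linear_low, linear_high]; ``saturation`` above — the qualitative
    floor / log-linear / plateau shape of a hybridisation calibration.

    The default plateau (44 μA) sits ~4 μA below the log-linear limb's
    value at ``linear_high`` (48.2 μA): a high-dose rolloff, as saturating
    hybridisation calibrations show once probe sites fill.  A plateau at
    or above the extrapolated line would make the end of the linear range
    statistically invisible to an R²-based range search.
    """

    a: float = 80.0           # μA at C = 1 M (intercept of the log-linear limb)
    b: float = 6.0            # μA per decade
    linear_low: float = 1e-11
    linear_high: float = 5e-6
    floor: float = 1.0        # μA
    saturation: float = 44.0  # μA

    def __post_init__(self) -> None:
        if self.linear_low >= self.linear_high:
            raise ValueError("linear_low must be below linear_high")

    def amplitude(self, concentration: float) -> float:
        if concentration < self.linear_low:
            return self.floor
        if concentration > self.linear_high:
            return self.saturation
        return self.a + self.b * np.log10(concentration)


@dataclass(frozen=True)
class DpvSpec:
    """Design of a synthetic DPV trace.

    Defaults emulate a methylene-blue reduction peak inside a −0.5–0 V
    sweep: peak near −0.25 V, width 40 mV, gentle linear baseline, and a
    log-linear amplitude of ~6 μA per decade spanning the
    1e-11 – 5e-6 M linear window.
    """

    peak_center: float = -0.25        # V
    peak_width: float = 0.04          # V (Gaussian sigma)
    baseline_intercept: float = 2.0   # μA
    baseline_slope: float = -4.0      # μA per V
    amplitude_model: AmplitudeModel = field(default_factory=AmplitudeModel)
    noise_sigma: float = 0.05         # μA
    potential_range: tuple[float, float] = (-0.5, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_width <= 0:
            raise ValueError("peak width must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")

    @property
    def analysis_window(self) -> tuple[float, float]:
        """A peak window for chord extraction: ±4σ around the peak, clipped."""
        lo, hi = self.potential_range
        return (max(lo, self.peak_center - 4 * self.peak_width),
                min(hi, self.peak_center + 4 * self.peak_width))


def generate_dpv(
    spec: DpvSpec,
    concentration: float,
    n_points: int = 200,
    rng: np.random.Generator | None = None,
) -> Voltammogram:
    """One DPV trace at the given target concentration.

    current(E) = baseline(E) + A(C)·exp(−(E−Ep)²/2σ²) + N(0, noise_sigma),
    with A(C) from the spec's piecewise amplitude model.  With no *rng*
    given, a fresh generator seeded from ``spec.seed`` is used, so two
    identical calls return identical traces.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    E = np.linspace(*spec.potential_range, n_points)
    amp = spec.amplitude_model.amplitude(concentration)
    current = (
        spec.baseline_intercept
        + spec.baseline_slope * E
        + amp * np.exp(-0.5 * ((E - spec.peak_center) / spec.peak_width) ** 2)
    )
    if spec.noise_sigma > 0:
        current = current + rng.normal(0.0, spec.noise_sigma, size=n_points)
    return Voltammogram(E, current, {"concentration_M": concentration})


@dataclass(frozen=True)
class CalibrationTruth:
    """Planted calibration parameters attached to a generated series."""

    slope: float
    intercept: float
    linear_low: float
    linear_high: float


def generate_calibration(
    spec: DpvSpec,
    concentrations: Sequence[float],
    replicates: int = 1,
    n_points: int = 200,
    n_blanks: int = 10,
) -> tuple[CalibrationSeries, CalibrationTruth]:
    """Simulate a full calibration sweep end to end.

    For each concentration, *replicates* DPV traces are generated and
    chord-extracted; the replicate-mean peak current becomes the series
    point.  blank_sigma is the SD of peak currents from *n_blanks*
    floor-level traces (concentration three decades below the linear
    window).  The planted slope/intercept/linear-range are returned as
    ground truth.
    """
    if len(concentrations) < 3:
        raise ValueError("need >= 3 concentrations")
    rng = np.random.default_rng(spec.seed)
    window = spec.analysis_window
    points = []
    for c in sorted(concentrations):
        ips = [
            peak_current(generate_dpv(spec, c, n_points, rng=rng), window).ip
            for _ in range(replicates)
        ]
        points.append((c, float(np.mean(ips))))
    blank_c = spec.amplitude_model.linear_low * 1e-3
    blank_ips = [
        peak_current(generate_dpv(spec, blank_c, n_points, rng=rng), window).ip
        for _ in range(n_blanks)
    ]
    blank_sigma = float(np.std(blank_ips, ddof=1)) if spec.noise_sigma > 0 else None
    series = CalibrationSeries(
        np.array([c for c, _ in points]),
        np.array([i for _, i in points]),
        blank_sigma=blank_sigma,
    )
    am = spec.amplitude_model
    return series, CalibrationTruth(am.b, am.a, am.linear_low, am.linear_high)


def generate_scan_rate_series(
    area_cm2: float,
    constants: RedoxConstants,
    scan_rates: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> ScanRateSeries:
    """Ip drawn from the forward Randles–Ševčík relation plus Gaussian noise (μA)."""
    if area_cm2 <= 0:
        raise ValueError("area must be positive")
    rng = np.random.default_rng(seed)
    v = np.asarray(scan_rates, dtype=float)
    ip = randles_sevcik_current(area_cm2, constants, v)
    if noise_sigma > 0:
        ip = ip + rng.normal(0.0, noise_sigma, size=len(v))
    return ScanRateSeries(v, ip, constants)


# ---------------------------------------------------------------------------
# YAML spec loading (CLI `simulate` subcommand)
# ---------------------------------------------------------------------------

def msa_spec_from_yaml(path: str | Path, seed: int | None = None) -> MsaSpec:
    """Load an MsaSpec from a YAML mapping; *seed* overrides the file's seed."""
    data = _load_yaml(path)
    if seed is not None:
        data["seed"] = seed
    return MsaSpec(**data)


def dpv_spec_from_yaml(path: str | Path, seed: int | None = None) -> DpvSpec:
    """Load a DpvSpec from YAML; an ``amplitude_model`` sub-mapping is allowed."""
    data = _load_yaml(path)
    if seed is not None:
        data["seed"] = seed
    if "amplitude_model" in data:
        data["amplitude_model"] = AmplitudeModel(**data["amplitude_model"])
    if "potential_range" in data:
        data["potential_range"] = tuple(data["potential_range"])
    return DpvSpec(**data)


def _load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return data
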