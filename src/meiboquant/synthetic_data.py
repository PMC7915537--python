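"""Synthetic inputs for every pipeline stage.

Generates centroided LC-MS chromatograms with genotype-specific meibum
compositions, equimolar standard-mix runs with embedded per-species
ionization responses, two-transition melting curves with Gaussian
noise, and ellipse-axis fixtures.  Everything is deterministic under a
seed, and every generated dataset carries a known ground truth so the
quantitation and fitting stages can be tested by parameter recovery.

The genotype presets encode the headline composition statistics of
mouse meibum: in the wild type, free cholesterol is 7% of the sterol
pool (Chl + CE) and CE chain lengths follow a smooth unimodal
distribution over C10-C34 dominated by monounsaturated species;
heterozygous Soat1+/- meibum is indistinguishable from wild type;
Soat1-null meibum has no CE with fatty acids longer than C20, only
trace short-chain CE far below quantitation limits, free cholesterol
as the dominant lipid (>30% of the total), and a roughly doubled
apparent TAG share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chromatogram_io import ScanSet
from .eic_quant import interpolate_by_ecl
from .lipid_registry import LipidRegistry, ce_id
from .melting import HillParams, MeltingCurve, hill_model
from .morphometry import EyeAxes

__all__ = [
    "SpeciesSignal",
    "CompositionSpec",
    "SimConfig",
    "MeltSimSpec",
    "STANDARD_STEROL_RESPONSES",
    "make_preset",
    "simulate_chromatogram",
    "simulate_melting_curve",
    "make_ellipse_fixture",
    "default_melt_grid",
]

#: Relative sterol-channel (m/z 369.35) responses of the calibration
#: standards: free cholesterol 1.00, cholesteryl oleate 2.21,
#: cholesteryl nervonate 2.41 — the generator's ionization ground truth.
STANDARD_STEROL_RESPONSES: dict[str, float] = {
    "Chl": 1.00,
    ce_id(18, 1): 2.21,
    ce_id(24, 1): 2.41,
}

_CE_RESPONSE_ANCHORS = [(16.0, 2.21), (22.0, 2.41)]  # (ECL, response)


@dataclass(frozen=True)
class SpeciesSignal:
    """Generative ionization model for one species.

    ``response`` is total ion signal per mole (relative scale);
    ``fragment_yield`` is the fraction of that signal appearing on the
    shared m/z 369.35 sterol channel, the remainder on the proton
    adduct.
    """

    amount: float
    response: float = 1.0
    fragment_yield: float = 0.0

    def __post_init__(self):
        if self.amount < 0:
            raise ValueError("amounts must be non-negative")
        if self.response <= 0:
            raise ValueError("response factors must be positive")
        if not 0.0 <= self.fragment_yield <= 1.0:
            raise ValueError("fragment yield must be in [0, 1]")

    @property
    def sterol_signal_per_mole(self) -> float:
        return self.response * self.fragment_yield

    @property
    def adduct_signal_per_mole(self) -> float:
        return self.response * (1.0 - self.fragment_yield)


@dataclass
class CompositionSpec:
    """Molar composition plus per-species ionization model."""

    species: dict[str, SpeciesSignal] = field(default_factory=dict)

    def scaled(self, factor: float) -> "CompositionSpec":
        return CompositionSpec(
            {sid: SpeciesSignal(s.amount * factor, s.response, s.fragment_yield)
             for sid, s in self.species.items()}
        )


def _ce_signal(amount: float, ecl: float) -> SpeciesSignal:
    """CE ionization: unit molar response on the proton adduct plus the
    chain-length-interpolated response on the sterol fragment channel."""
    sterol = interpolate_by_ecl(_CE_RESPONSE_ANCHORS, ecl)
    total = 1.0 + sterol
    return SpeciesSignal(amount, response=total, fragment_yield=sterol / total)


_PRESETS = ("wild_type", "het", "soat1_null", "standard_mix")

#: Wild-type lipid-class molar split (percent of total).  Chosen so the
#: sterol pool has exactly 7% free cholesterol; the WE/CE/TAG split
#: approximates the apparent class balance of normal mouse meibum.
_WT_CLASS_AMOUNTS = {"Chl": 7.0 / 3.0, "CE": 31.0, "WE": 58.0, "TAG": 26.0 / 3.0}

#: Soat1-null class split: cholesterol dominant (>30% of total lipid),
#: CE reduced to sub-LLOQ traces, apparent TAG share roughly doubled.
_NULL_CLASS_AMOUNTS = {"Chl": 33.0, "WE": 50.0, "TAG": 17.0}

#: Per-species trace amount for residual short-chain (C16-C20) CE in
#: the null preset — orders of magnitude below the LLOQ.
_NULL_TRACE_CE_AMOUNT = 1e-6

_WE_WEIGHTS = {"WE 42:1": 0.30, "WE 43:1": 0.12, "WE 44:1": 0.18,
               "WE 46:1": 0.20, "WE 48:2": 0.12, "WE 50:2": 0.08}


def _wt_ce_weights() -> dict[str, float]:
    """Smooth unimodal CE chain profile over C10-C34, 80% monounsaturated."""
    weights: dict[str, float] = {}
    for n in range(10, 35):
        for x in (0, 1):
            ecl = n - 2 * x
            w = np.exp(-((ecl - 23.0) ** 2) / (2 * 5.0**2))
            weights[ce_id(n, x)] = w * (0.8 if x == 1 else 0.2)
    total = sum(weights.values())
    return {sid: w / total for sid, w in weights.items()}


def make_preset(name: str) -> CompositionSpec:
    """A named composition: wild_type, het, soat1_null or standard_mix."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {_PRESETS}")
    if name == "standard_mix":
        spec = CompositionSpec()
        spec.species["Chl"] = SpeciesSignal(1.0, response=1.0, fragment_yield=1.0)
        spec.species[ce_id(18, 1)] = _ce_signal(1.0, 16.0)
        spec.species[ce_id(24, 1)] = _ce_signal(1.0, 22.0)
        spec.species["TAG 54:3"] = SpeciesSignal(1.0)  # triolein
        spec.species["WE 42:1"] = SpeciesSignal(1.0)   # lignoceryl oleate
        return spec
    if name in ("wild_type", "het"):
        spec = CompositionSpec()
        spec.species["Chl"] = SpeciesSignal(_WT_CLASS_AMOUNTS["Chl"],
                                            response=1.0, fragment_yield=1.0)
        for sid, w in _wt_ce_weights().items():
            n, x = map(int, sid.split()[1].split(":"))
            spec.species[sid] = _ce_signal(_WT_CLASS_AMOUNTS["CE"] * w, n - 2 * x)
        for sid, w in _WE_WEIGHTS.items():
            spec.species[sid] = SpeciesSignal(_WT_CLASS_AMOUNTS["WE"] * w)
        spec.species["TAG 52:3"] = SpeciesSignal(_WT_CLASS_AMOUNTS["TAG"])
        return spec
    # soat1_null
    spec = CompositionSpec()
    spec.species["Chl"] = SpeciesSignal(_NULL_CLASS_AMOUNTS["Chl"],
                                        response=1.0, fragment_yield=1.0)
    for n in range(16, 21):
        for x in (0, 1):
            spec.species[ce_id(n, x)] = _ce_signal(_NULL_TRACE_CE_AMOUNT, n - 2 * x)
    for sid, w in _WE_WEIGHTS.items():
        spec.species[sid] = SpeciesSignal(_NULL_CLASS_AMOUNTS["WE"] * w)
    spec.species["TAG 52:3"] = SpeciesSignal(_NULL_CLASS_AMOUNTS["TAG"])
    return spec


@dataclass
class SimConfig:
    """Acquisition and noise settings for chromatogram simulation."""

    rt_start_min: float = 0.0
    rt_end_min: float = 46.0
    rt_step_min: float = 0.02
    peak_width_sigma_min: float = 0.1
    mz_jitter_sd_mda: float = 3.0
    intensity_noise_cv: float = 0.02
    baseline_level: float = 50.0
    signal_scale: float = 1e4  # counts x min per molar unit at unit response
    seed: int = 0

    def __post_init__(self):
        if self.rt_step_min <= 0 or self.rt_end_min <= self.rt_start_min:
            raise ValueError("invalid retention-time grid")
        if self.peak_width_sigma_min <= 0:
            raise ValueError("peak width must be positive")
        if self.intensity_noise_cv < 0 or self.mz_jitter_sd_mda < 0:
            raise ValueError("noise settings must be non-negative")

    def rt_grid(self) -> np.ndarray:
        n = int(round((self.rt_end_min - self.rt_start_min) / self.rt_step_min)) + 1
        return self.rt_start_min + self.rt_step_min * np.arange(n)


def _is_fragment_channel(adduct: str) -> bool:
    return adduct in ("M-H2O+H", "M-FA+H")


def simulate_chromatogram(comp: CompositionSpec, cfg: SimConfig,
                          registry: LipidRegistry) -> ScanSet:
    """Centroided scans with Gaussian elution peaks plus baseline.

    Each species elutes as a Gaussian at its registry retention time
    with integrated area = amount x channel response x signal_scale,
    split between the sterol-fragment channel and the proton adduct by
    the species' fragment yield.  Every registry channel receives a
    flat chemical baseline.  Centroid m/z values are jittered with
    Gaussian error; intensities carry multiplicative Gaussian noise.
    """
    rts = cfg.rt_grid()
    n_scans = rts.size
    # unique centroid positions across all registry channels
    targets = sorted({round(ch.target_mz, 6) for ch in registry.channels})
    target_index = {t: i for i, t in enumerate(targets)}
    intensity = np.full((n_scans, len(targets)), float(cfg.baseline_level))

    norm = cfg.peak_width_sigma_min * np.sqrt(2 * np.pi)
    for sid, sig in comp.species.items():
        if sig.amount == 0:
            continue
        if sid not in registry.species:
            raise ValueError(f"species {sid!r} not in registry")
        sp = registry.get(sid)
        if sp.nominal_rt_min is None:
            raise ValueError(f"species {sid!r} has no nominal retention time")
        profile = np.exp(-((rts - sp.nominal_rt_min) ** 2)
                         / (2 * cfg.peak_width_sigma_min**2)) / norm
        for ch in registry.channels_for(sid):
            per_mole = (sig.sterol_signal_per_mole if _is_fragment_channel(ch.adduct)
                        else sig.adduct_signal_per_mole)
            if per_mole <= 0:
                continue
            area = sig.amount * per_mole * cfg.signal_scale
            intensity[:, target_index[round(ch.target_mz, 6)]] += area * profile

    rng = np.random.default_rng(cfg.seed)
    mz = np.tile(np.array(targets), (n_scans, 1))
    if cfg.mz_jitter_sd_mda > 0:
        mz = mz + rng.normal(0.0, cfg.mz_jitter_sd_mda / 1000.0, size=mz.shape)
    if cfg.intensity_noise_cv > 0:
        intensity = intensity * (1.0 + cfg.intensity_noise_cv
                                 * rng.standard_normal(size=intensity.shape))
        intensity = np.clip(intensity, 0.0, None)
    mz_arrays = list(mz)
    intensity_arrays = list(intensity)
    return ScanSet(rts, mz_arrays, intensity_arrays,
                   metadata={"polarity": "positive", "mz_range": "100-2000"})


# ---------------------------------------------------------------------------
# Melting curves


def default_melt_grid(n_points: int = 150) -> np.ndarray:
    """Evenly spaced temperatures over -25..+125 degC, in Kelvin."""
    return np.linspace(248.15, 398.15, n_points)


@dataclass
class MeltSimSpec:
    """Settings for simulating a noisy melting curve."""

    params: HillParams
    temp_grid_k: np.ndarray = field(default_factory=default_melt_grid)
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        self.temp_grid_k = np.asarray(self.temp_grid_k, dtype=float)
        if not np.all(np.diff(self.temp_grid_k) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


def simulate_melting_curve(spec: MeltSimSpec) -> MeltingCurve:
    """Two-transition model evaluated on the grid plus Gaussian noise."""
    values = hill_model(spec.temp_grid_k, spec.params)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    return MeltingCurve(spec.temp_grid_k.copy(), values)


def make_ellipse_fixture(ratio: float) -> EyeAxes:
    """Unit-semi-major-axis ellipse with the given short/long ratio."""
    if not 0 < ratio <= 1:
        raise ValueError("axis ratio must be in (0, 1]")
    return EyeAxes(a=1.0, b=ratio)
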