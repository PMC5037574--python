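"""Synthetic two-group 1H-NMR cohorts with known ground truth.

Emulates 600 MHz 1D NOESY-presat spectra of cellular aqueous extracts:
each metabolite is a list of Lorentzian lines with fixed relative areas,
scaled by a per-sample concentration. Group B applies multiplicative fold
changes to a designated subset of metabolites, so every downstream stage
(binning, OPLS-DA, biomarker calling) can be tested against a planted
truth without any real data.

The lineshape is a pure Lorentzian (no Gaussian convolution, no J-coupling
simulation); multiplets are represented as explicit peak lists. Chemical
shift axes are stored in ascending ppm; renderers may flip to the NMR
display convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "MetaboliteSpec",
    "CohortScenario",
    "Spectrum",
    "GroundTruth",
    "simulate_spectrum",
    "simulate_cohort",
    "default_library",
    "default_cohort_scenario",
    "default_assignments",
    "scenario_from_dict",
    "scenario_to_dict",
]


class ScenarioError(ValueError):
    """Raised when a cohort scenario is internally inconsistent."""


@dataclass(frozen=True)
class MetaboliteSpec:
    """One metabolite: named Lorentzian peaks plus a baseline concentration.

    Parameters
    ----------
    name : str
    peaks : tuple of (center_ppm, relative_area, width_hz)
        ``relative_area`` values are dimensionless weights (their sum need
        not be 1); ``width_hz`` is the full width at half maximum in Hz.
    base_level : float
        Group-A mean concentration in arbitrary units, >= 0.
    """

    name: str
    peaks: tuple[tuple[float, float, float], ...]
    base_level: float

    def validate(self, axis_range: tuple[float, float]) -> None:
        if not self.peaks:
            raise ScenarioError(f"metabolite {self.name!r} has no peaks")
        if self.base_level < 0:
            raise ScenarioError(f"metabolite {self.name!r} has negative base level")
        total = sum(a for _, a, _ in self.peaks)
        if total <= 0:
            raise ScenarioError(
                f"metabolite {self.name!r}: relative areas must sum to a positive value"
            )
        lo, hi = axis_range
        for center, area, width in self.peaks:
            if area < 0 or width <= 0:
                raise ScenarioError(
                    f"metabolite {self.name!r}: peak at {center} ppm has invalid "
                    f"area/width ({area}, {width})"
                )
            if not (lo <= center <= hi):
                raise ScenarioError(
                    f"metabolite {self.name!r}: peak centre {center} ppm outside "
                    f"axis range {lo}-{hi} ppm"
                )


@dataclass(frozen=True)
class Spectrum:
    """A 1D NMR trace: ascending ppm axis, intensities, spectrometer frequency."""

    ppm: np.ndarray
    intensity: np.ndarray
    frequency_mhz: float


@dataclass
class CohortScenario:
    """Design of a two-group cohort (group A = sensitive-analogue, B = resistant-analogue).

    ``fold_changes`` maps metabolite names to the multiplicative factor applied
    to the group-B mean level. ``within_group_cv`` is the coefficient of
    variation of biological-replicate levels; ``shift_jitter_sd`` (ppm) is the
    s.d. of one whole-multiplet shift offset drawn per metabolite per sample
    (truncated at +/-3 s.d., mimicking pH-driven movement).
    """

    library: tuple[MetaboliteSpec, ...]
    n_per_group: int = 10
    spectrometer_frequency: float = 600.0
    axis_range: tuple[float, float] = (0.5, 9.5)
    n_points: int = 16384
    fold_changes: dict[str, float] = field(default_factory=dict)
    within_group_cv: float = 0.03
    noise_sd: float = 1.0
    shift_jitter_sd: float = 0.0002
    seed: int = 0
    group_names: tuple[str, str] = ("ES", "ER")

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ScenarioError("n_per_group must be >= 2")
        if self.n_points < 2:
            raise ScenarioError("n_points must be >= 2")
        lo, hi = self.axis_range
        if not lo < hi:
            raise ScenarioError("axis_range low must be < high")
        if self.within_group_cv < 0 or self.noise_sd < 0 or self.shift_jitter_sd < 0:
            raise ScenarioError("cv, noise and jitter must be non-negative")
        if not self.library:
            raise ScenarioError("library is empty")
        names = [m.name for m in self.library]
        if len(set(names)) != len(names):
            raise ScenarioError("duplicate metabolite names in library")
        for m in self.library:
            m.validate(self.axis_range)
        for name, fold in self.fold_changes.items():
            if name not in names:
                raise ScenarioError(f"fold_changes references unknown metabolite {name!r}")
            if fold <= 0:
                raise ScenarioError(f"fold factor for {name!r} must be > 0")

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.axis_range[0], self.axis_range[1], self.n_points)


@dataclass
class GroundTruth:
    """Realized per-sample metabolite levels and the planted perturbation set."""

    metabolite_names: list[str]
    levels: np.ndarray  # samples x metabolites
    perturbed_set: list[tuple[str, str]]  # (name, "increase"|"decrease")


def _lorentzian(x: np.ndarray, center: float, area: float, hwhm_ppm: float) -> np.ndarray:
    return (area / np.pi) * hwhm_ppm / ((x - center) ** 2 + hwhm_ppm**2)


def simulate_spectrum(
    scenario: CohortScenario,
    levels: dict[str, float],
    sample_seed: int,
) -> Spectrum:
    """Render one spectrum from per-metabolite concentrations.

    Intensity at each axis point is the sum over peaks of a Lorentzian with
    area proportional to level x relative_area, the whole multiplet displaced
    by a per-metabolite jitter draw, plus white Gaussian noise of s.d.
    ``noise_sd``. Identical (scenario, levels, sample_seed) gives bit-identical
    output.
    """
    scenario.validate()
    for name, level in levels.items():
        if level < 0:
            raise ScenarioError(f"negative level for {name!r}")
    x = scenario.axis
    y = np.zeros_like(x)
    rng = np.random.default_rng(sample_seed)
    for met in scenario.library:
        level = levels.get(met.name, 0.0)
        if scenario.shift_jitter_sd > 0:
            jitter = stats.truncnorm.rvs(
                -3.0, 3.0, scale=scenario.shift_jitter_sd, random_state=rng
            )
        else:
            jitter = 0.0
        if level == 0.0:
            continue
        for center, rel_area, width_hz in met.peaks:
            hwhm_ppm = (width_hz / 2.0) / scenario.spectrometer_frequency
            y += _lorentzian(x, center + jitter, level * rel_area, hwhm_ppm)
    if scenario.noise_sd > 0:
        y += rng.normal(0.0, scenario.noise_sd, size=x.shape)
    return Spectrum(ppm=x, intensity=y, frequency_mhz=scenario.spectrometer_frequency)


def simulate_cohort(
    scenario: CohortScenario,
) -> tuple[list[Spectrum], list[str], GroundTruth]:
    """Simulate 2 x n_per_group spectra (group A first, then group B).

    Group-B mean level of metabolite m is the group-A mean times
    ``fold_changes[m]``; within-group levels are Gaussian with coefficient of
    variation ``within_group_cv`` (clipped at zero). Returns the spectra, the
    class labels and the realized ground truth.
    """
    scenario.validate()
    names = [m.name for m in scenario.library]
    base = np.array([m.base_level for m in scenario.library])
    folds = np.array([scenario.fold_changes.get(n, 1.0) for n in names])

    root = np.random.SeedSequence(scenario.seed)
    level_seed, *sample_seeds = root.spawn(1 + 2 * scenario.n_per_group)
    level_rng = np.random.default_rng(level_seed)

    n = scenario.n_per_group
    means = np.vstack([np.tile(base, (n, 1)), np.tile(base * folds, (n, 1))])
    sds = scenario.within_group_cv * means
    levels = np.clip(level_rng.normal(means, sds), 0.0, None)

    spectra: list[Spectrum] = []
    for i in range(2 * n):
        seed_i = int(sample_seeds[i].generate_state(1)[0] % (2**31))
        spectra.append(simulate_spectrum(scenario, dict(zip(names, levels[i])), seed_i))

    ga, gb = scenario.group_names
    labels = [ga] * n + [gb] * n
    perturbed = [
        (name, "increase" if fold > 1 else "decrease")
        for name, fold in scenario.fold_changes.items()
        if fold != 1.0
    ]
    truth = GroundTruth(metabolite_names=names, levels=levels, perturbed_set=perturbed)
    return spectra, labels, truth


# ---------------------------------------------------------------------------
# Default default cohort: 36 metabolites typical of cellular aqueous
# extracts, 14 of them perturbed in the resistant-analogue group (GSH down).
# Positions and intensities are configuration for the simulator, not measured
# assignments; peaks of perturbed metabolites are kept clear of other peaks.
# ---------------------------------------------------------------------------

_W = 1.2  # default linewidth, Hz


def _met(name, peaks, base):
    return MetaboliteSpec(name=name, peaks=tuple((c, a, _W) for c, a in peaks), base_level=base)


def default_library() -> tuple[MetaboliteSpec, ...]:
    """36-metabolite library loosely following common cell-extract assignments."""
    return (
        # --- perturbed in the resistant-analogue group (14) ---
        _met("lactate", [(1.33, 0.75), (4.12, 0.25)], 8.0),
        _met("alanine", [(1.48, 1.0)], 6.0),
        _met("glutamate", [(2.06, 0.4), (2.35, 0.6)], 8.0),
        _met("glutamine", [(2.14, 0.45), (2.46, 0.55)], 10.0),
        _met("succinate", [(2.41, 1.0)], 3.0),
        _met("GSH", [(2.55, 0.3), (2.95, 0.4), (4.56, 0.3)], 11.0),
        _met("creatine", [(3.04, 0.6), (3.93, 0.4)], 8.0),
        _met("choline", [(3.20, 1.0)], 3.0),
        _met("phosphocholine", [(3.22, 1.0)], 6.0),
        _met("taurine", [(3.26, 0.5), (3.42, 0.5)], 20.0),
        _met("glycine", [(3.56, 1.0)], 10.0),
        _met("myo-inositol", [(3.62, 0.6), (4.06, 0.4)], 14.0),
        _met("AMP", [(6.14, 0.3), (8.26, 0.35), (8.61, 0.35)], 5.0),
        _met("formate", [(8.46, 1.0)], 8.0),
        # --- unperturbed background (22) ---
        _met("isoleucine", [(0.94, 0.7), (1.26, 0.3)], 4.0),
        _met("leucine", [(0.96, 1.0)], 4.0),
        _met("valine", [(1.00, 0.6), (2.28, 0.4)], 4.0),
        _met("ethanol", [(1.12, 1.0)], 2.0),
        _met("threonine", [(1.18, 0.5), (4.26, 0.5)], 4.0),
        _met("arginine", [(1.68, 0.5), (3.77, 0.5)], 4.0),
        _met("lysine", [(1.72, 0.6), (1.90, 0.4)], 5.0),
        _met("acetate", [(1.92, 1.0)], 3.0),
        _met("citrate", [(2.62, 0.5), (2.70, 0.5)], 5.0),
        _met("methionine", [(2.64, 1.0)], 3.0),
        _met("aspartate", [(2.80, 0.6), (3.85, 0.4)], 4.0),
        _met("asparagine", [(2.86, 1.0)], 3.0),
        _met("glucose", [(3.48, 0.5), (5.23, 0.5)], 6.0),
        _met("uracil", [(5.80, 0.5), (7.52, 0.5)], 2.0),
        _met("uridine", [(5.90, 0.5), (7.87, 0.5)], 3.0),
        _met("inosine", [(6.05, 0.5), (8.34, 0.5)], 3.0),
        _met("fumarate", [(6.52, 1.0)], 2.0),
        _met("tyrosine", [(6.90, 0.5), (7.19, 0.5)], 3.0),
        _met("histidine", [(7.06, 0.5), (7.78, 0.5)], 3.0),
        _met("phenylalanine", [(7.33, 0.6), (7.42, 0.4)], 3.0),
        _met("tryptophan", [(7.54, 0.5), (7.73, 0.5)], 2.0),
        _met("NAD+", [(8.17, 0.4), (9.33, 0.6)], 2.0),
    )


#: Fold changes applied to the resistant-analogue group in the default cohort.
#: Base levels above are chosen so the expected total spectral area stays
#: near-balanced between groups, as total-area normalization presumes.
DEFAULT_FOLD_CHANGES: dict[str, float] = {
    "lactate": 1.5,
    "alanine": 1.5,
    "glutamate": 1.5,
    "glutamine": 0.67,
    "succinate": 2.0,
    "GSH": 0.6,
    "creatine": 1.5,
    "choline": 2.0,
    "phosphocholine": 1.5,
    "taurine": 0.5,
    "glycine": 0.67,
    "myo-inositol": 0.67,
    "AMP": 1.5,
    "formate": 0.5,
}


def default_cohort_scenario(seed: int = 1, **overrides) -> CohortScenario:
    """The default two-group cohort: n=10/group, 14/36 metabolites perturbed."""
    scenario = CohortScenario(
        library=default_library(),
        fold_changes=dict(DEFAULT_FOLD_CHANGES),
        seed=seed,
    )
    return replace(scenario, **overrides) if overrides else scenario


def default_assignments(
    library: tuple[MetaboliteSpec, ...] | None = None,
    half_width: float = 0.015,
) -> dict[str, list[tuple[float, float]]]:
    """Metabolite -> ppm windows (one per peak, center +/- half_width)."""
    if library is None:
        library = default_library()
    return {
        m.name: [(c - half_width, c + half_width) for c, _, _ in m.peaks]
        for m in library
    }


# -- scenario (de)serialization for YAML/JSON config files -------------------


def scenario_to_dict(s: CohortScenario) -> dict:
    return {
        "n_per_group": s.n_per_group,
        "spectrometer_frequency": s.spectrometer_frequency,
        "axis_range": list(s.axis_range),
        "n_points": s.n_points,
        "library": [
            {"name": m.name, "base_level": m.base_level,
             "peaks": [list(p) for p in m.peaks]}
            for m in s.library
        ],
        "fold_changes": dict(s.fold_changes),
        "within_group_cv": s.within_group_cv,
        "noise_sd": s.noise_sd,
        "shift_jitter_sd": s.shift_jitter_sd,
        "seed": s.seed,
        "group_names": list(s.group_names),
    }


def scenario_from_dict(d: dict) -> CohortScenario:
    d = dict(d)
    library = tuple(
        MetaboliteSpec(
            name=m["name"],
            peaks=tuple(tuple(p) for p in m["peaks"]),
            base_level=float(m["base_level"]),
        )
        for m in d.pop("library")
    )
    if "axis_range" in d:
        d["axis_range"] = tuple(d["axis_range"])
    if "group_names" in d:
        d["group_names"] = tuple(d["group_names"])
    scenario = CohortScenario(library=library, **d)
    scenario.validate()
    return scenario
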