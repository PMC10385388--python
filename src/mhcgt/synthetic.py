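"""Synthetic multi-temporal grassland reflectance generator.

Field spectra of the seven forage species are emulated with a low-parameter
shape model carrying the canonical features of green-vegetation reflectance:

* a flat visible continuum,
* Gaussian chlorophyll absorption wells near 490 nm (blue) and 670 nm (red),
* a Gaussian green reflectance peak near 550 nm,
* a logistic red-edge transition to the near-infrared plateau.

Each species is one :class:`SpeciesArchetype`; the four acquisition phases
(June = growth, August = maturity, of 2020 and 2021) modulate well depth,
red-edge position and plateau level, mimicking phenology-driven pigment and
canopy changes. Maturity shallows the chlorophyll wells, blue-shifts the red
edge and slightly lowers the NIR plateau. A ``class_overlap`` knob shrinks
every archetype toward the across-species mean, controlling how separable
the classes are; i.i.d. Gaussian band noise is added afterwards and spectra
are clipped to the physical [0, 1] range.

This is a qualitative emulation (no radiative-transfer realism); it exists
so that the classifier, training and evaluation stages can be exercised and
tested end to end on data with the right structure and cardinalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import PHASES, SPECIES, SpectralDataset, WavelengthGrid, phase_key

__all__ = [
    "PhaseModifier",
    "SpeciesArchetype",
    "GeneratorConfig",
    "default_archetypes",
    "noise_free_spectrum",
    "simulate_spectrum",
    "generate_dataset",
    "blend_archetypes",
]

#: Default per-band Gaussian noise scale (reflectance units).
DEFAULT_NOISE_SIGMA = 0.045

#: Default inter-archetype similarity; shrink factor is overlap/(1+overlap).
DEFAULT_CLASS_OVERLAP = 0.25


@dataclass(frozen=True)
class PhaseModifier:
    """Phenological adjustment of one archetype for one (year, month) phase.

    depth_scale multiplies absorption-well depths and the green-peak height,
    edge_shift_nm shifts the red-edge inflection, plateau_scale multiplies
    the NIR plateau level.
    """

    depth_scale: float = 1.0
    edge_shift_nm: float = 0.0
    plateau_scale: float = 1.0


@dataclass(frozen=True)
class SpeciesArchetype:
    """Parametric reflectance shape of one species plus its phase modifiers."""

    species_name: str
    baseline_continuum: float
    absorption_features: tuple[tuple[float, float, float], ...]  # (center, width, depth)
    green_peak: tuple[float, float, float]  # (center nm, width nm, height)
    red_edge: tuple[float, float]  # (inflection nm, steepness nm)
    nir_plateau: float
    phase_modifiers: dict[str, PhaseModifier] = field(default_factory=dict)
    noise_sigma: float = DEFAULT_NOISE_SIGMA

    def __post_init__(self):
        if not 0.0 <= self.baseline_continuum <= 1.0:
            raise ValueError("baseline_continuum must lie in [0, 1]")
        if not 0.0 <= self.nir_plateau <= 1.0:
            raise ValueError("nir_plateau must lie in [0, 1]")
        for center, width, depth in self.absorption_features:
            if width <= 0:
                raise ValueError("absorption-well widths must be positive")
            if not 0.0 <= depth <= 1.0:
                raise ValueError("absorption-well depths must lie in [0, 1]")
        if self.green_peak[1] <= 0:
            raise ValueError("green-peak width must be positive")
        if not 0.0 <= self.green_peak[2] <= 1.0:
            raise ValueError("green-peak height must lie in [0, 1]")
        if self.red_edge[1] <= 0:
            raise ValueError("red-edge steepness must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        expected = {phase_key(p) for p in PHASES}
        if self.phase_modifiers and set(self.phase_modifiers) != expected:
            raise ValueError(
                f"phase_modifiers must cover exactly {sorted(expected)}"
            )

    def modifier(self, phase: tuple[int, str]) -> PhaseModifier:
        key = phase_key(phase)
        if key not in self.phase_modifiers:
            raise ValueError(
                f"unknown phase {phase!r}; configured phases: "
                f"{sorted(self.phase_modifiers)}"
            )
        return self.phase_modifiers[key]


def _default_phase_modifiers() -> dict[str, PhaseModifier]:
    """Growth (June) is the reference; maturity (August) shallows pigment
    wells, blue-shifts the red edge and lowers the plateau; 2021 amplitudes
    differ slightly from 2020 (between-year environmental variation). The
    modulation is kept gentle enough that a species' phase cloud does not
    cross its spectral neighbours' levels."""
    return {
        "2020-June": PhaseModifier(1.00, 0.0, 1.000),
        "2020-August": PhaseModifier(0.88, -3.0, 0.965),
        "2021-June": PhaseModifier(1.05, 1.5, 1.020),
        "2021-August": PhaseModifier(0.92, -2.0, 0.980),
    }


# Hand-set, deterministic archetype parameters: legumes (Medicago spp.,
# Onobrychis) get deeper chlorophyll wells, taller green peaks and higher
# NIR plateaus than the grasses (Elymus, Hordeum, Bromus), with per-species
# offsets in continuum, red-edge position and green-peak height so every
# pair is distinguishable. The between-species signal is deliberately
# distributed over many bands while the per-band noise (DEFAULT_NOISE_SIGMA)
# is of comparable scale to single-band gaps.
_ARCHETYPE_TABLE = [
    # name,                 cont,  blue(c,w,d),        red(c,w,d),          green(c,w,h),      edge(c,s), plateau
    ("Medicago sativa", 0.045, (488, 26, 0.060), (668, 30, 0.085), (550, 21, 0.130), (724, 10.0), 0.750),
    ("Medicago ruthenica", 0.060, (490, 24, 0.050), (670, 28, 0.062), (552, 20, 0.095), (714, 9.0), 0.620),
    ("Elymus canadensis", 0.080, (492, 27, 0.034), (672, 33, 0.044), (548, 23, 0.065), (703, 13.5), 0.500),
    ("Hordeum brevisubulatum", 0.095, (486, 25, 0.024), (666, 31, 0.030), (546, 25, 0.045), (694, 15.5), 0.330),
    ("Medicago varia", 0.050, (489, 25, 0.055), (669, 29, 0.075), (551, 21, 0.115), (731, 11.0), 0.820),
    ("Onobrychis viciaefolia", 0.038, (491, 23, 0.042), (671, 27, 0.054), (554, 18, 0.080), (719, 8.5), 0.680),
    ("Bromus ciliatus", 0.070, (487, 26, 0.028), (667, 32, 0.038), (549, 22, 0.055), (708, 12.0), 0.420),
]


def default_archetypes() -> list[SpeciesArchetype]:
    """Deterministic archetypes for the seven species (no randomness)."""
    out = []
    for name, cont, blue, red, green, edge, plateau in _ARCHETYPE_TABLE:
        out.append(
            SpeciesArchetype(
                species_name=name,
                baseline_continuum=cont,
                absorption_features=(blue, red),
                green_peak=green,
                red_edge=edge,
                nir_plateau=plateau,
                phase_modifiers=_default_phase_modifiers(),
            )
        )
    assert [a.species_name for a in out] == list(SPECIES)
    return out


def noise_free_spectrum(
    archetype: SpeciesArchetype,
    phase: tuple[int, str],
    grid: WavelengthGrid | None = None,
) -> np.ndarray:
    """Closed-form archetype reflectance curve for one phase (no noise)."""
    grid = grid or WavelengthGrid()
    mod = archetype.modifier(phase) if archetype.phase_modifiers else PhaseModifier()
    lam = grid.band_centers
    r = np.full_like(lam, archetype.baseline_continuum)
    for center, width, depth in archetype.absorption_features:
        r -= mod.depth_scale * depth * np.exp(-0.5 * ((lam - center) / width) ** 2)
    gc, gw, gh = archetype.green_peak
    r += mod.depth_scale * gh * np.exp(-0.5 * ((lam - gc) / gw) ** 2)
    edge_c, edge_s = archetype.red_edge
    rise = (mod.plateau_scale * archetype.nir_plateau) - archetype.baseline_continuum
    r += rise / (1.0 + np.exp(-(lam - (edge_c + mod.edge_shift_nm)) / edge_s))
    return np.clip(r, 0.0, 1.0)


def simulate_spectrum(
    archetype: SpeciesArchetype,
    phase: tuple[int, str],
    grid: WavelengthGrid | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One 125-band reflectance spectrum: archetype curve + band noise.

    Deterministic given the state of ``rng``; with ``noise_sigma == 0`` the
    result is the noise-free closed-form curve.
    """
    grid = grid or WavelengthGrid()
    r = noise_free_spectrum(archetype, phase, grid)
    if archetype.noise_sigma > 0:
        if rng is None:
            raise ValueError("an rng is required when noise_sigma > 0")
        r = r + rng.normal(0.0, archetype.noise_sigma, size=r.shape)
    return np.clip(r, 0.0, 1.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic dataset.

    ``class_overlap`` >= 0 shrinks every archetype toward the mean archetype
    by overlap/(1+overlap); 0 leaves the archetypes untouched and larger
    values make the species progressively harder to separate.
    """

    archetypes: tuple[SpeciesArchetype, ...] = field(
        default_factory=lambda: tuple(default_archetypes())
    )
    samples_per_class_phase: int = 600
    seed: int = 0
    class_overlap: float = DEFAULT_CLASS_OVERLAP

    def __post_init__(self):
        if len(self.archetypes) != 7:
            raise ValueError("exactly 7 archetypes are required")
        if self.samples_per_class_phase < 1:
            raise ValueError("samples_per_class_phase must be >= 1")
        if self.class_overlap < 0:
            raise ValueError("class_overlap must be >= 0")


def blend_archetypes(
    archetypes: tuple[SpeciesArchetype, ...], class_overlap: float
) -> list[SpeciesArchetype]:
    """Shrink every archetype's shape parameters toward the across-species
    mean by t = overlap/(1+overlap); phase modifiers and noise are kept."""
    t = class_overlap / (1.0 + class_overlap)
    if t == 0.0:
        return list(archetypes)

    def mix(own: float, mean: float) -> float:
        return (1.0 - t) * own + t * mean

    n_wells = len(archetypes[0].absorption_features)
    mean_cont = np.mean([a.baseline_continuum for a in archetypes])
    mean_wells = np.mean(
        [[list(w) for w in a.absorption_features] for a in archetypes], axis=0
    )
    mean_green = np.mean([list(a.green_peak) for a in archetypes], axis=0)
    mean_edge = np.mean([list(a.red_edge) for a in archetypes], axis=0)
    mean_plateau = np.mean([a.nir_plateau for a in archetypes])
    out = []
    for a in archetypes:
        if len(a.absorption_features) != n_wells:
            raise ValueError("archetypes must share the absorption-well count to blend")
        wells = tuple(
            tuple(mix(v, m) for v, m in zip(w, mw))
            for w, mw in zip(a.absorption_features, mean_wells)
        )
        out.append(
            replace(
                a,
                baseline_continuum=mix(a.baseline_continuum, mean_cont),
                absorption_features=wells,
                green_peak=tuple(mix(v, m) for v, m in zip(a.green_peak, mean_green)),
                red_edge=tuple(mix(v, m) for v, m in zip(a.red_edge, mean_edge)),
                nir_plateau=mix(a.nir_plateau, mean_plateau),
            )
        )
    return out


def generate_dataset(config: GeneratorConfig | None = None) -> SpectralDataset:
    """Generate the full balanced dataset: 7 species × 4 phases ×
    ``samples_per_class_phase`` records, reproducible from ``config.seed``."""
    config = config or GeneratorConfig()
    grid = WavelengthGrid()
    rng = np.random.default_rng(config.seed)
    blended = blend_archetypes(config.archetypes, config.class_overlap)

    per_cell = config.samples_per_class_phase
    blocks, labels, years, months, ids = [], [], [], [], []
    for s_idx, arch in enumerate(blended):
        for year, month in PHASES:
            base = noise_free_spectrum(arch, (year, month), grid)
            noise = (
                rng.normal(0.0, arch.noise_sigma, size=(per_cell, len(grid)))
                if arch.noise_sigma > 0
                else np.zeros((per_cell, len(grid)))
            )
            blocks.append(np.clip(base[None, :] + noise, 0.0, 1.0))
            labels.extend([s_idx + 1] * per_cell)
            years.extend([year] * per_cell)
            months.extend([month] * per_cell)
            tag = arch.species_name.replace(" ", "-")
            ids.extend(f"{tag}_{year}{month}_{k:04d}" for k in range(per_cell))

    data = np.concatenate(blocks, axis=0)[:, :, None]
    return SpectralDataset(
        data=data,
        labels=np.array(labels),
        years=np.array(years),
        months=np.array(months, dtype=object),
        ids=np.array(ids, dtype=object),
        grid=grid,
        class_names=tuple(a.species_name for a in config.archetypes),
    )
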