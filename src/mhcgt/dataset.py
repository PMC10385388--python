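"""Core data containers: wavelength grid and the (N, S, M) spectral dataset.

A record is one mean reflectance spectrum of a grassland sample: 125 bands
covering 400–1000 nm, a species label (1–7), and the acquisition phase
(year 2020/2021 × month June/August). The tensor layout (N samples,
S=125 sequence steps, M=1 variable per step) is the exchange format every
downstream stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_BANDS = 125
WAVELENGTH_MIN_NM = 400.0
WAVELENGTH_MAX_NM = 1000.0

#: The seven grassland species, in canonical label order (labels 1–7).
SPECIES = (
    "Medicago sativa",
    "Medicago ruthenica",
    "Elymus canadensis",
    "Hordeum brevisubulatum",
    "Medicago varia",
    "Onobrychis viciaefolia",
    "Bromus ciliatus",
)

#: The four acquisition phases: (year, month).
PHASES = ((2020, "June"), (2020, "August"), (2021, "June"), (2021, "August"))


def phase_key(phase: tuple[int, str]) -> str:
    return f"{phase[0]}-{phase[1]}"


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform 125-point band-center grid on [400, 1000] nm (~4.84 nm step)."""

    band_centers: np.ndarray = field(
        default_factory=lambda: np.linspace(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, N_BANDS)
    )

    def __post_init__(self):
        c = np.asarray(self.band_centers, dtype=float)
        object.__setattr__(self, "band_centers", c)
        if c.shape != (N_BANDS,):
            raise ValueError(f"grid must have exactly {N_BANDS} bands, got {c.shape}")
        if not np.all(np.diff(c) > 0):
            raise ValueError("band centers must be strictly increasing")
        if not (c[0] == WAVELENGTH_MIN_NM and c[-1] == WAVELENGTH_MAX_NM):
            raise ValueError("grid must span 400–1000 nm inclusive")
        if not np.allclose(np.diff(c), np.diff(c)[0]):
            raise ValueError("band centers must be uniformly spaced")

    def __len__(self):
        return N_BANDS

    def band_name(self, i: int) -> str:
        return f"b{self.band_centers[i]:.1f}"

    def band_names(self) -> list[str]:
        return [self.band_name(i) for i in range(N_BANDS)]

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.band_centers - wavelength_nm)))


@dataclass
class SpectralDataset:
    """Reflectance sequences with species labels and phase metadata.

    data: (N, S, M) reflectance in [0, 1]; labels: species index 1..K;
    years/months: acquisition phase per sample; ids: sample identifiers.
    """

    data: np.ndarray
    labels: np.ndarray
    years: np.ndarray
    months: np.ndarray
    ids: np.ndarray
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    class_names: tuple[str, ...] = SPECIES

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.years = np.asarray(self.years, dtype=np.int64)
        self.months = np.asarray(self.months, dtype=object)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be (N, S, M)")
        n = self.data.shape[0]
        for name, arr in (
            ("labels", self.labels),
            ("years", self.years),
            ("months", self.months),
            ("ids", self.ids),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length N={n}, got {arr.shape}")
        if n and (self.labels.min() < 1 or self.labels.max() > len(self.class_names)):
            raise ValueError("labels must lie in 1..num_classes")
        if n and (self.data.min() < 0.0 or self.data.max() > 1.0):
            raise ValueError("reflectance values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def seq_len(self) -> int:
        return self.data.shape[1]

    @property
    def n_vars(self) -> int:
        return self.data.shape[2]

    @property
    def phases(self) -> list[tuple[int, str]]:
        return [(int(y), str(m)) for y, m in zip(self.years, self.months)]

    def subset(self, indices) -> "SpectralDataset":
        indices = np.asarray(indices)
        return SpectralDataset(
            data=self.data[indices],
            labels=self.labels[indices],
            years=self.years[indices],
            months=self.months[indices],
            ids=self.ids[indices],
            grid=self.grid,
            class_names=self.class_names,
        )

    def replace_data(self, data: np.ndarray) -> "SpectralDataset":
        return SpectralDataset(
            data=data,
            labels=self.labels.copy(),
            years=self.years.copy(),
            months=self.months.copy(),
            ids=self.ids.copy(),
            grid=self.grid,
            class_names=self.class_names,
        )
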