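"""Synthetic MALDI-TOF panels with species/specimen/spot variance structure.

Each species is a template of Gaussian peaks; specimens modulate peak
heights, spots add calibration drift, baseline and detector noise.  The
generator is fully deterministic under its seed and produces the variance
hierarchy the matching method assumes: technical replicates are more
similar than same-species specimens, which are more similar than spectra
of different species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from maldicci.spectra_io import RawSpectrum, SpectrumMeta


@dataclass(frozen=True)
class SpeciesTemplate:
    """A species fingerprint: peak positions, heights and widths."""

    species_label: str
    peak_masses: np.ndarray
    peak_heights: np.ndarray
    peak_widths: np.ndarray

    def __post_init__(self) -> None:
        masses = np.asarray(self.peak_masses, dtype=float)
        heights = np.asarray(self.peak_heights, dtype=float)
        widths = np.asarray(self.peak_widths, dtype=float)
        if not (masses.size == heights.size == widths.size):
            raise ValueError("peak arrays must have equal length")
        if masses.size < 1:
            raise ValueError("a template needs at least one peak")
        if np.unique(masses).size != masses.size:
            raise ValueError("peak masses must be unique")
        if np.any(heights <= 0) or np.any(widths <= 0):
            raise ValueError("peak heights and widths must be positive")
        object.__setattr__(self, "peak_masses", masses)
        object.__setattr__(self, "peak_heights", heights)
        object.__setattr__(self, "peak_widths", widths)


@dataclass(frozen=True)
class GeneratorConfig:
    """Panel-generation parameters (all noise scales may be zero)."""

    n_species: int = 10
    specimens_per_species: int = 2
    spots_per_specimen: int = 10
    test_specimens_per_species: int = 3
    specimen_jitter: float = 0.15
    spot_noise: float = 0.01
    mass_drift: float = 2.0
    baseline_amplitude: float = 0.5
    fraction_unreferenced: float = 0.0
    sibling_pair: bool = False
    similarity_ceiling: float = 0.5
    mass_min: float = 2000.0
    mass_max: float = 20000.0
    raw_step: float = 0.5
    peaks_per_species_min: int = 25
    peaks_per_species_max: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if min(self.specimens_per_species, self.spots_per_specimen) < 1:
            raise ValueError("specimens_per_species and spots_per_specimen must be >= 1")
        for name in ("specimen_jitter", "spot_noise", "mass_drift", "baseline_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.fraction_unreferenced <= 1.0:
            raise ValueError("fraction_unreferenced must be in [0, 1]")


def _template_profile(template: SpeciesTemplate, grid: np.ndarray) -> np.ndarray:
    """Sum-of-Gaussians profile of a template on a mass grid."""
    profile = np.zeros_like(grid)
    step = grid[1] - grid[0]
    for mass, height, width in zip(
        template.peak_masses, template.peak_heights, template.peak_widths
    ):
        lo = int(max(0, math.floor((mass - 6 * width - grid[0]) / step)))
        hi = int(min(grid.size, math.ceil((mass + 6 * width - grid[0]) / step) + 1))
        if lo >= hi:
            continue
        window = grid[lo:hi]
        profile[lo:hi] += height * np.exp(-0.5 * ((window - mass) / width) ** 2)
    return profile


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def make_species_templates(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[SpeciesTemplate]:
    """Draw reproducible species templates with bounded pairwise similarity.

    Each template places one informative peak in every 500 Da window of the
    scored 3000-12000 Da range plus extra random peaks, so every interval
    carries signal.  Pairwise cosine similarity between template profiles
    must stay below config.similarity_ceiling (bounded retries).  With
    ``sibling_pair`` the first two species share most peaks, emulating a
    sibling-species complex.
    """
    rng = rng or np.random.default_rng(config.seed)
    coarse = np.arange(config.mass_min, config.mass_max, 4.0)

    templates: list[SpeciesTemplate] = []
    profiles: list[np.ndarray] = []
    for idx in range(config.n_species):
        label = f"species{idx + 1:02d}"
        if config.sibling_pair and idx == 1:
            base = templates[0]
            masses = base.peak_masses + rng.uniform(-3.0, 3.0, base.peak_masses.size)
            heights = base.peak_heights * rng.lognormal(0.0, 0.2, base.peak_heights.size)
            n_new = max(2, base.peak_masses.size // 10)
            masses = np.concatenate([masses, rng.uniform(3000.0, 12000.0, n_new)])
            heights = np.concatenate([heights, rng.lognormal(0.0, 0.5, n_new) * 0.5])
            widths = np.full(masses.size, float(rng.uniform(2.0, 5.0)))
            masses, keep = np.unique(np.round(masses, 3), return_index=True)
            template = SpeciesTemplate(label, masses, heights[keep], widths[keep])
            templates.append(template)
            profiles.append(_template_profile(template, coarse))
            continue
        for _attempt in range(50):
            # one anchor peak per scored 500 Da window + extra peaks anywhere
            anchor = rng.uniform(3000.0 + 30.0, 3500.0 - 30.0 + 1e-9, 18) + 500.0 * np.arange(18)
            n_extra = int(
                rng.integers(
                    max(0, config.peaks_per_species_min - 18),
                    max(1, config.peaks_per_species_max - 18 + 1),
                )
            )
            extra = rng.uniform(config.mass_min + 100.0, config.mass_max - 100.0, n_extra)
            masses = np.concatenate([anchor, extra])
            heights = rng.lognormal(0.0, 0.6, masses.size)
            widths = np.full(masses.size, float(rng.uniform(2.0, 5.0)))
            masses, keep = np.unique(np.round(masses, 3), return_index=True)
            template = SpeciesTemplate(label, masses, heights[keep], widths[keep])
            profile = _template_profile(template, coarse)
            comparable = profiles[1:] if (config.sibling_pair and len(profiles) > 1) else profiles
            if all(_cosine(profile, p) < config.similarity_ceiling for p in comparable):
                templates.append(template)
                profiles.append(profile)
                break
        else:
            raise RuntimeError(
                f"could not draw a template for {label} below similarity ceiling "
                f"{config.similarity_ceiling}"
            )
    return templates


def generate_spectrum(
    template: SpeciesTemplate,
    specimen_jitter: np.ndarray | None,
    spot_drift: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
    spectrum_id: str,
) -> RawSpectrum:
    """One raw spectrum: jittered template peaks + drift + baseline + noise.

    specimen_jitter is a per-peak height multiplier (None = all ones); the
    spot's mass drift rigidly shifts every peak.  Baseline is a smooth
    decreasing quadratic, noise is truncated-Gaussian (non-negative).
    """
    grid = np.arange(config.mass_min, config.mass_max + config.raw_step / 2, config.raw_step)
    jitter = np.ones(template.peak_masses.size) if specimen_jitter is None else specimen_jitter
    shifted = SpeciesTemplate(
        species_label=template.species_label,
        peak_masses=template.peak_masses + spot_drift,
        peak_heights=template.peak_heights * jitter,
        peak_widths=template.peak_widths,
    )
    intensity = _template_profile(shifted, grid)
    if config.baseline_amplitude > 0:
        rel = (grid - config.mass_min) / (config.mass_max - config.mass_min)
        intensity += config.baseline_amplitude * (1.0 - rel) ** 2
    if config.spot_noise > 0:
        intensity += np.abs(rng.normal(0.0, config.spot_noise, grid.size))
    return RawSpectrum(mz=grid, intensity=intensity, spectrum_id=spectrum_id)


def _specimen_spectra(
    template: SpeciesTemplate,
    specimen_id: str,
    panel: str,
    config: GeneratorConfig,
    seed_seq: np.random.SeedSequence,
) -> tuple[list[RawSpectrum], list[SpectrumMeta]]:
    rng = np.random.default_rng(seed_seq)
    jitter = rng.lognormal(0.0, config.specimen_jitter, template.peak_masses.size)
    spectra, meta = [], []
    for spot in range(1, config.spots_per_specimen + 1):
        drift = float(rng.normal(0.0, config.mass_drift)) if config.mass_drift > 0 else 0.0
        # id matches what read_mzxml derives for a per-specimen file: stem + scan number
        sid = f"{specimen_id}.{spot}"
        spectra.append(
            generate_spectrum(template, jitter, drift, config, rng, spectrum_id=sid)
        )
        meta.append(
            SpectrumMeta(
                spectrum_id=sid,
                specimen_id=specimen_id,
                spot_index=spot,
                species_label=template.species_label,
                panel=panel,
            )
        )
    return spectra, meta


def generate_panels(
    config: GeneratorConfig,
) -> tuple[list[RawSpectrum], list[SpectrumMeta], list[RawSpectrum], list[SpectrumMeta]]:
    """Generate disjoint reference and test panels.

    Returns (reference spectra, reference meta, test spectra, test meta).
    A leading fraction_unreferenced share of species is excluded from the
    reference panel (their test specimens are queries of unreferenced
    species); metadata species labels always carry the truth.
    """
    templates = make_species_templates(config)
    n_unref = int(round(config.fraction_unreferenced * config.n_species))
    unreferenced = {t.species_label for t in templates[:n_unref]}

    ref_spectra: list[RawSpectrum] = []
    ref_meta: list[SpectrumMeta] = []
    test_spectra: list[RawSpectrum] = []
    test_meta: list[SpectrumMeta] = []

    for s_idx, template in enumerate(templates):
        if template.species_label not in unreferenced:
            for r_idx in range(config.specimens_per_species):
                specimen_id = f"{template.species_label}.ref{r_idx + 1:02d}"
                seq = np.random.SeedSequence(
                    entropy=config.seed, spawn_key=(1, s_idx, r_idx)
                )
                spectra, meta = _specimen_spectra(
                    template, specimen_id, "reference", config, seq
                )
                ref_spectra.extend(spectra)
                ref_meta.extend(meta)
        for t_idx in range(config.test_specimens_per_species):
            specimen_id = f"{template.species_label}.test{t_idx + 1:02d}"
            seq = np.random.SeedSequence(entropy=config.seed, spawn_key=(2, s_idx, t_idx))
            spectra, meta = _specimen_spectra(template, specimen_id, "test", config, seq)
            test_spectra.extend(spectra)
            test_meta.extend(meta)

    return ref_spectra, ref_meta, test_spectra, test_meta


__all__ = [
    "SpeciesTemplate",
    "GeneratorConfig",
    "make_species_templates",
    "generate_spectrum",
    "generate_panels",
]
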