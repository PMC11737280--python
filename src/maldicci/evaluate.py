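"""Simulation-based estimation of identification performance.

The experiment mirrors the querying protocol: per repeat, a fixed number
of spots is drawn at random (without replacement) for every test specimen,
the specimen is identified by the highest CCI over the drawn spots against
the whole reference database, classified against its true species label,
and panel-level metrics are computed.  Medians and equal-tailed 95%
credible intervals are taken across repeats.

In "unreferenced" mode every same-species reference spectrum is ineligible
for each query, forcing each result to be a false positive or a true
negative; this indirectly estimates specificity for queries of species
absent from the database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from maldicci.cci import CCIConfig, cci_matrix
from maldicci.identify import DEFAULT_THRESHOLD, FN, FP, TN, TP
from maldicci.preprocess import ProcessedSpectrum
from maldicci.refdb import ReferenceDatabase
from maldicci.spectra_io import SpectrumMeta

logger = logging.getLogger(__name__)

METRICS = ("sensitivity", "specificity", "ppv", "npv", "accuracy")
MODES = ("standard", "unreferenced")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the performance-simulation experiment."""

    n_spots: int = 1
    threshold: float = DEFAULT_THRESHOLD
    n_repeats: int = 1000
    seed: int = 0
    mode: str = "standard"

    def __post_init__(self) -> None:
        if self.n_spots < 1:
            raise ValueError("n_spots must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass(frozen=True)
class PerformanceEstimate:
    """A metric summarized across simulation repeats."""

    metric: str
    median: float
    cri_low: float
    cri_high: float
    n_repeats: int
    n_dropped: int = 0  # repeats where the metric was undefined


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, Optional[float]]:
    """Sensitivity, specificity, PPV, NPV and accuracy from confusion counts.

    Ratios with a zero denominator are returned as None (undefined).
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("at least one evaluated query is required")

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "accuracy": (tp + tn) / total,
    }


def credible_interval(
    samples: Sequence[float], level: float = 0.95
) -> tuple[float, float, float]:
    """Equal-tailed empirical percentile interval (low, median, high)."""
    values = np.asarray(samples, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("need at least one finite sample")
    alpha = 100.0 * (1.0 - level) / 2.0
    low, med, high = np.percentile(values, [alpha, 50.0, 100.0 - alpha])
    return float(low), float(med), float(high)


# ---------------------------------------------------------------------------
# simulation engine
# ---------------------------------------------------------------------------


@dataclass
class _PanelTables:
    """Per-spectrum best scores precomputed once per (test panel, database)."""

    specimen_ids: list[str]             # evaluated specimens, sorted
    true_species: list[str]
    spot_indices: list[np.ndarray]      # spectrum row indices per specimen
    best_all_val: np.ndarray            # per spectrum: max log10cci over all refs
    best_all_species: np.ndarray        # species of that argmax reference
    best_unref_val: np.ndarray          # max over refs of a different species
    unref_eligible: np.ndarray          # specimen-level: any eligible reference
    db_species: set[str]


def prepare_tables(
    test_spectra: Sequence[ProcessedSpectrum],
    test_meta: Sequence[SpectrumMeta],
    db: ReferenceDatabase,
    config: CCIConfig | None = None,
) -> _PanelTables:
    """Precompute the test x reference CCI table and per-spot best matches."""
    config = config or CCIConfig()
    meta_map = {m.spectrum_id: m for m in test_meta}
    spectra = sorted(
        (s for s in test_spectra if s.spectrum_id in meta_map),
        key=lambda s: s.spectrum_id,
    )
    if not spectra:
        raise ValueError("no test spectra with metadata")
    matrix = cci_matrix(spectra, db.spectra, config)  # (n_test, n_ref)
    ref_species = np.array([db.species_of(i) for i in db.spectrum_ids])

    best_all_val = matrix.max(axis=1)
    best_all_species = ref_species[np.argmax(matrix, axis=1)]

    n = len(spectra)
    best_unref_val = np.full(n, -np.inf)
    for j, s in enumerate(spectra):
        own = meta_map[s.spectrum_id].species_label
        eligible = ref_species != own
        if eligible.any():
            best_unref_val[j] = matrix[j, eligible].max()

    specimens: dict[str, list[int]] = {}
    species_of_specimen: dict[str, str] = {}
    for j, s in enumerate(spectra):
        m = meta_map[s.spectrum_id]
        specimens.setdefault(m.specimen_id, []).append(j)
        species_of_specimen[m.specimen_id] = m.species_label

    specimen_ids = sorted(specimens)
    unref_eligible = np.array(
        [(ref_species != species_of_specimen[sid]).any() for sid in specimen_ids]
    )
    dropped = [sid for sid, ok in zip(specimen_ids, unref_eligible) if not ok]
    if dropped:
        logger.warning(
            "specimens with no eligible cross-species reference (excluded in "
            "unreferenced mode): %s", dropped,
        )
    return _PanelTables(
        specimen_ids=specimen_ids,
        true_species=[species_of_specimen[sid] for sid in specimen_ids],
        spot_indices=[np.array(specimens[sid]) for sid in specimen_ids],
        best_all_val=best_all_val,
        best_all_species=best_all_species,
        best_unref_val=best_unref_val,
        unref_eligible=unref_eligible,
        db_species=db.species_set,
    )


def _spot_selection(
    seed: int, repeat: int, specimen_index: int, spots: np.ndarray, n_spots: int
) -> np.ndarray:
    """First n_spots of a seeded per-(repeat, specimen) permutation.

    Using a permutation prefix makes selections nested across spot counts:
    the spots drawn for n and the same (seed, repeat) are a subset of those
    drawn for n+1, so max-monotonicity holds per repeat.
    """
    seq = np.random.SeedSequence(entropy=seed, spawn_key=(repeat, specimen_index))
    rng = np.random.default_rng(seq)
    order = rng.permutation(spots.size)
    return spots[order[: min(n_spots, spots.size)]]


def run_simulation(
    tables: _PanelTables,
    thresholds: Sequence[float],
    n_spots: int,
    n_repeats: int,
    seed: int,
    mode: str = "standard",
) -> dict[float, dict[str, np.ndarray]]:
    """Per-repeat metric samples for each threshold (one pass over repeats).

    Spot selections depend only on (seed, repeat, specimen), never on the
    threshold or the mode, so per-repeat results are paired across
    thresholds and across the two modes.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    thresholds = list(thresholds)
    samples = {
        t: {metric: np.full(n_repeats, np.nan) for metric in METRICS} for t in thresholds
    }
    active = [
        i for i in range(len(tables.specimen_ids))
        if mode == "standard" or tables.unref_eligible[i]
    ]
    if not active:
        logger.warning("no eligible specimens under mode %r; all metrics undefined", mode)
        return samples
    for repeat in range(n_repeats):
        best_vals = np.empty(len(active))
        species_ok = np.empty(len(active), dtype=bool)
        referenced = np.empty(len(active), dtype=bool)
        for k, i in enumerate(active):
            chosen = _spot_selection(seed, repeat, i, tables.spot_indices[i], n_spots)
            if mode == "standard":
                vals = tables.best_all_val[chosen]
                j = chosen[int(np.argmax(vals))]
                best_vals[k] = tables.best_all_val[j]
                species_ok[k] = tables.best_all_species[j] == tables.true_species[i]
                referenced[k] = tables.true_species[i] in tables.db_species
            else:
                best_vals[k] = tables.best_unref_val[chosen].max()
                species_ok[k] = False   # any identification is a false positive
                referenced[k] = False   # queries emulate unreferenced species
        for threshold in thresholds:
            identified = best_vals >= threshold
            tp = int(np.sum(identified & species_ok))
            fp = int(np.sum(identified & ~species_ok))
            tn = int(np.sum(~identified & ~referenced))
            fn = int(np.sum(~identified & referenced))
            metrics = compute_metrics(tp, tn, fp, fn)
            for metric in METRICS:
                value = metrics[metric]
                if value is not None:
                    samples[threshold][metric][repeat] = value
    return samples


def _summaries(
    metric_samples: dict[str, np.ndarray], n_repeats: int
) -> dict[str, PerformanceEstimate]:
    out = {}
    for metric, values in metric_samples.items():
        finite = values[np.isfinite(values)]
        dropped = n_repeats - finite.size
        if finite.size == 0:
            out[metric] = PerformanceEstimate(metric, float("nan"), float("nan"),
                                              float("nan"), n_repeats, dropped)
        else:
            low, med, high = credible_interval(finite)
            out[metric] = PerformanceEstimate(metric, med, low, high, n_repeats, dropped)
    return out


def simulate_performance(
    test_spectra: Sequence[ProcessedSpectrum],
    test_meta: Sequence[SpectrumMeta],
    db: ReferenceDatabase,
    config: SimulationConfig,
    cci_config: CCIConfig | None = None,
    tables: _PanelTables | None = None,
) -> dict[str, PerformanceEstimate]:
    """Median and 95% CrI for each metric under one simulation configuration."""
    if tables is None:
        tables = prepare_tables(test_spectra, test_meta, db, cci_config)
    samples = run_simulation(
        tables, [config.threshold], config.n_spots, config.n_repeats,
        config.seed, config.mode,
    )
    return _summaries(samples[config.threshold], config.n_repeats)


def simulate_unreferenced_specificity(
    test_spectra: Sequence[ProcessedSpectrum],
    test_meta: Sequence[SpectrumMeta],
    db: ReferenceDatabase,
    config: SimulationConfig,
    cci_config: CCIConfig | None = None,
    tables: _PanelTables | None = None,
) -> PerformanceEstimate:
    """Specificity with all same-species references disabled (forced FP/TN)."""
    config = SimulationConfig(
        n_spots=config.n_spots, threshold=config.threshold,
        n_repeats=config.n_repeats, seed=config.seed, mode="unreferenced",
    )
    estimates = simulate_performance(
        test_spectra, test_meta, db, config, cci_config, tables
    )
    return estimates["specificity"]


def threshold_sweep(
    test_spectra: Sequence[ProcessedSpectrum],
    test_meta: Sequence[SpectrumMeta],
    db: ReferenceDatabase,
    thresholds: Sequence[float],
    n_spots: int = 1,
    n_repeats: int = 1000,
    seed: int = 0,
    cci_config: CCIConfig | None = None,
    tables: _PanelTables | None = None,
) -> pd.DataFrame:
    """ROC table: per threshold, standard-mode sensitivity and
    unreferenced-mode specificity with medians and 95% CrIs."""
    if tables is None:
        tables = prepare_tables(test_spectra, test_meta, db, cci_config)
    std = run_simulation(tables, thresholds, n_spots, n_repeats, seed, "standard")
    unref = run_simulation(tables, thresholds, n_spots, n_repeats, seed, "unreferenced")
    rows = []
    for threshold in thresholds:
        sens = _summaries(std[threshold], n_repeats)["sensitivity"]
        spec = _summaries(unref[threshold], n_repeats)["specificity"]
        rows.append(
            {
                "threshold": threshold,
                "n_spots": n_spots,
                "sensitivity_median": sens.median,
                "sensitivity_cri_low": sens.cri_low,
                "sensitivity_cri_high": sens.cri_high,
                "specificity_median": spec.median,
                "specificity_cri_low": spec.cri_low,
                "specificity_cri_high": spec.cri_high,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "METRICS",
    "MODES",
    "SimulationConfig",
    "PerformanceEstimate",
    "compute_metrics",
    "credible_interval",
    "prepare_tables",
    "run_simulation",
    "simulate_performance",
    "simulate_unreferenced_specificity",
    "threshold_sweep",
]
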