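"""Reference mass-spectra database: build, self-compare, summarize, QC, merge.

A database is a labelled collection of processed spectra indexed by
specimen and species.  Pairwise CCI tables over the database (or between a
query panel and the database) underpin repeatability/reproducibility
summaries, specimen-level median matrices, bank-to-bank best-match
concordance and QC filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from maldicci.cci import CCIConfig, cci_matrix
from maldicci.preprocess import ProcessedSpectrum
from maldicci.spectra_io import SpectrumMeta, read_metadata, write_metadata

logger = logging.getLogger(__name__)

#: pair categories partitioning all distinct unordered spectrum pairs
REPLICATE = "replicate"
SAME_SPECIES = "same_species"
DIFFERENT_SPECIES = "different_species"
PAIR_CATEGORIES = (REPLICATE, SAME_SPECIES, DIFFERENT_SPECIES)


class DatabaseError(ValueError):
    """Raised for inconsistent database contents."""


@dataclass(frozen=True)
class SimilaritySummary:
    """Median and IQR of log10(CCI) within one pair category."""

    category: str
    median_log10cci: float
    iqr_low: float
    iqr_high: float
    n_pairs: int


@dataclass
class ReferenceDatabase:
    """Processed spectra with per-spectrum metadata, ordered by spectrum id."""

    spectra: list[ProcessedSpectrum]
    meta: dict[str, SpectrumMeta]

    def __post_init__(self) -> None:
        if len(self.spectra) != len(self.meta):
            raise DatabaseError("every spectrum needs exactly one metadata record")
        for s in self.spectra:
            if s.spectrum_id not in self.meta:
                raise DatabaseError(f"no metadata for spectrum {s.spectrum_id}")
        # deterministic ordering: lexicographic by spectrum_id
        self.spectra = sorted(self.spectra, key=lambda s: s.spectrum_id)
        specimen_species: dict[str, str] = {}
        for m in self.meta.values():
            prior = specimen_species.setdefault(m.specimen_id, m.species_label)
            if prior != m.species_label:
                raise DatabaseError(
                    f"specimen {m.specimen_id} has conflicting species labels "
                    f"({prior!r} vs {m.species_label!r})"
                )

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def spectrum_ids(self) -> list[str]:
        return [s.spectrum_id for s in self.spectra]

    @property
    def species_set(self) -> set[str]:
        return {m.species_label for m in self.meta.values()}

    @property
    def specimen_ids(self) -> list[str]:
        return sorted({m.specimen_id for m in self.meta.values()})

    def species_of(self, spectrum_id: str) -> str:
        return self.meta[spectrum_id].species_label

    def specimen_of(self, spectrum_id: str) -> str:
        return self.meta[spectrum_id].specimen_id

    def summary(self) -> dict:
        per_species: dict[str, set[str]] = {}
        for m in self.meta.values():
            per_species.setdefault(m.species_label, set()).add(m.specimen_id)
        return {
            "n_spectra": len(self),
            "n_specimens": len(self.specimen_ids),
            "n_species": len(self.species_set),
            "specimens_per_species": {k: len(v) for k, v in sorted(per_species.items())},
        }


def build_database(
    spectra: Sequence[ProcessedSpectrum], meta: Iterable[SpectrumMeta]
) -> ReferenceDatabase:
    """Index processed spectra by their metadata into a ReferenceDatabase."""
    meta_map = {m.spectrum_id: m for m in meta}
    kept = []
    for s in spectra:
        if s.spectrum_id in meta_map:
            kept.append(s)
        else:
            logger.warning("spectrum %s has no metadata record; excluded", s.spectrum_id)
    db = ReferenceDatabase(spectra=kept, meta={m: meta_map[m] for m in
                                               (s.spectrum_id for s in kept)})
    info = db.summary()
    logger.info(
        "built database: %d spectra, %d specimens, %d species",
        info["n_spectra"], info["n_specimens"], info["n_species"],
    )
    return db


def pair_category(meta_a: SpectrumMeta, meta_b: SpectrumMeta) -> str:
    if meta_a.specimen_id == meta_b.specimen_id:
        return REPLICATE
    if meta_a.species_label == meta_b.species_label:
        return SAME_SPECIES
    return DIFFERENT_SPECIES


def enumerate_pairs(
    metas: Sequence[SpectrumMeta],
) -> Iterator[tuple[SpectrumMeta, SpectrumMeta, str]]:
    """All distinct unordered metadata pairs with their category (n*(n-1)/2 rows)."""
    for a, b in combinations(metas, 2):
        yield a, b, pair_category(a, b)


def enumerate_cross_pairs(
    queries: Sequence[SpectrumMeta], refs: Sequence[SpectrumMeta]
) -> Iterator[tuple[SpectrumMeta, SpectrumMeta]]:
    """The full query x reference cross product (|q| * |r| rows)."""
    for q in queries:
        for r in refs:
            yield q, r


def all_pairs_cci(
    db: ReferenceDatabase,
    config: CCIConfig | None = None,
    block_size: int = 64,
) -> pd.DataFrame:
    """log10(CCI) for every distinct unordered spectrum pair in the database.

    Returns a long table (id_a, id_b, specimen_a, specimen_b, species_a,
    species_b, category, log10cci) with exactly n*(n-1)/2 rows, computed in
    row blocks so the full matrix never has to be materialized at once.
    """
    if len(db) == 0:
        raise DatabaseError("database is empty")
    config = config or CCIConfig()
    n = len(db)
    ids = db.spectrum_ids
    rows = []
    for start in range(0, n, block_size):
        block = db.spectra[start : start + block_size]
        m = cci_matrix(block, db.spectra[start:], config)
        for i, spectrum in enumerate(block):
            gi = start + i
            for gj in range(gi + 1, n):
                ma, mb = db.meta[ids[gi]], db.meta[ids[gj]]
                rows.append(
                    (
                        ids[gi],
                        ids[gj],
                        ma.specimen_id,
                        mb.specimen_id,
                        ma.species_label,
                        mb.species_label,
                        pair_category(ma, mb),
                        m[i, gj - start],
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "id_a", "id_b", "specimen_a", "specimen_b",
            "species_a", "species_b", "category", "log10cci",
        ],
    )


def cross_panel_cci(
    queries: Sequence[ProcessedSpectrum],
    query_meta: Sequence[SpectrumMeta],
    db: ReferenceDatabase,
    config: CCIConfig | None = None,
    block_size: int = 64,
) -> pd.DataFrame:
    """log10(CCI) for every query x reference pair (|q| * |r| rows)."""
    config = config or CCIConfig()
    qmeta = {m.spectrum_id: m for m in query_meta}
    ids_r = db.spectrum_ids
    rows = []
    queries = sorted(queries, key=lambda s: s.spectrum_id)
    for start in range(0, len(queries), block_size):
        block = queries[start : start + block_size]
        m = cci_matrix(block, db.spectra, config)
        for i, q in enumerate(block):
            mq = qmeta[q.spectrum_id]
            for j, rid in enumerate(ids_r):
                mr = db.meta[rid]
                rows.append(
                    (
                        q.spectrum_id, rid,
                        mq.specimen_id, mr.specimen_id,
                        mq.species_label, mr.species_label,
                        m[i, j],
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "id_query", "id_ref", "specimen_query", "specimen_ref",
            "species_query", "species_ref", "log10cci",
        ],
    )


def percentile_with_neginf(values: np.ndarray, qs: Sequence[float]) -> np.ndarray:
    """Linear-interpolation percentiles where -inf sorts below all finite values.

    np.percentile turns interpolation between two -inf order statistics into
    NaN; here any interpolation touching a -inf lower neighbour yields -inf
    (unless the weight sits entirely on the upper neighbour).
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("need at least one value")
    out = np.empty(len(qs))
    for k, q in enumerate(qs):
        pos = (q / 100.0) * (v.size - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        t = pos - lo
        a, b = v[lo], v[hi]
        if a == b or t == 0.0:
            out[k] = a
        elif np.isneginf(a):
            out[k] = b if t == 1.0 else -np.inf
        else:
            out[k] = a + (b - a) * t
    return out


def median_with_neginf(values: np.ndarray) -> float:
    return float(percentile_with_neginf(values, [50.0])[0])


def summarize_similarity(pair_table: pd.DataFrame) -> list[SimilaritySummary]:
    """Median and IQR of log10(CCI) per pair category (-inf sorts lowest)."""
    summaries = []
    for category in PAIR_CATEGORIES:
        values = pair_table.loc[pair_table["category"] == category, "log10cci"].to_numpy()
        if values.size == 0:
            summaries.append(
                SimilaritySummary(category, float("nan"), float("nan"), float("nan"), 0)
            )
            continue
        low, med, high = percentile_with_neginf(values, [25.0, 50.0, 75.0])
        summaries.append(SimilaritySummary(category, float(med), float(low), float(high),
                                           int(values.size)))
    return summaries


def specimen_median_matrix(
    db: ReferenceDatabase, pair_table: pd.DataFrame | None = None,
    config: CCIConfig | None = None,
) -> pd.DataFrame:
    """Square matrix of median log10(CCI) collated by specimen pair.

    The diagonal holds within-specimen (technical replicate) medians; the
    matrix is symmetric by construction.
    """
    specimens = db.specimen_ids
    if len(specimens) < 1:
        raise DatabaseError("need at least one specimen")
    if pair_table is None:
        pair_table = all_pairs_cci(db, config)
    groups: dict[tuple[str, str], list[float]] = {}
    for spec_a, spec_b, value in zip(
        pair_table["specimen_a"], pair_table["specimen_b"], pair_table["log10cci"]
    ):
        key = (spec_a, spec_b) if spec_a <= spec_b else (spec_b, spec_a)
        groups.setdefault(key, []).append(value)
    matrix = pd.DataFrame(np.nan, index=specimens, columns=specimens)
    for (a, b), values in groups.items():
        med = median_with_neginf(np.asarray(values))
        matrix.loc[a, b] = med
        matrix.loc[b, a] = med
    return matrix


def bank_to_bank_best_match(
    db: ReferenceDatabase,
    disable_self: bool = True,
    disable_same_specimen: bool = False,
    disable_same_species: bool = False,
    config: CCIConfig | None = None,
    block_size: int = 64,
) -> pd.DataFrame:
    """Best-matching counterpart for every spectrum under eligibility flags.

    For each spectrum, the eligible spectrum with the highest CCI (ties
    broken by lexicographic spectrum id, i.e. first in database order).
    Records concordance of the matched species and whether the spectrum's
    species is represented by a single specimen in the database.
    """
    if len(db) < 2:
        raise DatabaseError("bank-to-bank comparison needs at least 2 spectra")
    config = config or CCIConfig()
    ids = db.spectrum_ids
    specimens = np.array([db.specimen_of(i) for i in ids])
    species = np.array([db.species_of(i) for i in ids])
    specimen_counts = (
        pd.DataFrame({"specimen": specimens, "species": species})
        .drop_duplicates()["species"].value_counts()
    )

    rows = []
    for start in range(0, len(ids), block_size):
        block = db.spectra[start : start + block_size]
        m = cci_matrix(block, db.spectra, config)
        for i, spectrum in enumerate(block):
            gi = start + i
            eligible = np.ones(len(ids), dtype=bool)
            if disable_self:
                eligible[gi] = False
            if disable_same_specimen:
                eligible &= specimens != specimens[gi]
            if disable_same_species:
                eligible &= species != species[gi]
            record = {
                "spectrum_id": ids[gi],
                "specimen_id": specimens[gi],
                "species": species[gi],
                "single_specimen_species": bool(specimen_counts[species[gi]] == 1),
            }
            if not eligible.any():
                record.update(
                    best_match_id=None, best_match_species=None,
                    best_log10cci=np.nan, concordant=None, eligible=False,
                )
            else:
                scores = np.where(eligible, m[i], -np.inf)
                best = int(np.argmax(scores))  # first (lexicographically smallest) on ties
                record.update(
                    best_match_id=ids[best],
                    best_match_species=species[best],
                    best_log10cci=float(scores[best]),
                    concordant=bool(species[best] == species[gi]),
                    eligible=True,
                )
            rows.append(record)
    return pd.DataFrame(rows)


def qc_filter(
    db: ReferenceDatabase,
    replicate_median_cutoff: float,
    config: CCIConfig | None = None,
    pair_table: pd.DataFrame | None = None,
) -> tuple[ReferenceDatabase, pd.DataFrame]:
    """Drop spectra whose median replicate log10(CCI) falls below the cutoff.

    Returns the filtered database and an exclusion report.  Warns when a
    species loses all of its spectra.
    """
    if pair_table is None:
        pair_table = all_pairs_cci(db, config)
    replicate_pairs = pair_table[pair_table["category"] == REPLICATE]
    medians: dict[str, float] = {}
    for sid in db.spectrum_ids:
        mask = (replicate_pairs["id_a"] == sid) | (replicate_pairs["id_b"] == sid)
        values = replicate_pairs.loc[mask, "log10cci"].to_numpy()
        medians[sid] = median_with_neginf(values) if values.size else -np.inf
    removed = {sid for sid, med in medians.items() if med < replicate_median_cutoff}
    report = pd.DataFrame(
        {
            "spectrum_id": db.spectrum_ids,
            "median_replicate_log10cci": [medians[s] for s in db.spectrum_ids],
            "removed": [s in removed for s in db.spectrum_ids],
        }
    )
    kept = [s for s in db.spectra if s.spectrum_id not in removed]
    kept_meta = {s.spectrum_id: db.meta[s.spectrum_id] for s in kept}
    filtered = ReferenceDatabase(spectra=kept, meta=kept_meta)
    lost = db.species_set - filtered.species_set if kept else db.species_set
    if lost:
        logger.warning("QC cutoff %.3g removed all spectra of species: %s",
                       replicate_median_cutoff, sorted(lost))
    return filtered, report


def merge_databases(db_a: ReferenceDatabase, db_b: ReferenceDatabase) -> ReferenceDatabase:
    """Union of two databases with disjoint spectrum ids."""
    collisions = set(db_a.meta) & set(db_b.meta)
    if collisions:
        raise DatabaseError(f"spectrum id collision on merge: {sorted(collisions)[:5]}")
    return ReferenceDatabase(
        spectra=list(db_a.spectra) + list(db_b.spectra),
        meta={**db_a.meta, **db_b.meta},
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_database(db: ReferenceDatabase, directory: str | Path) -> None:
    """Persist a database as a directory (spectra matrix + metadata TSV)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = db.spectrum_ids
    intensities = np.stack([s.intensity for s in db.spectra])
    np.savez_compressed(
        directory / "spectra.npz",
        grid_mz=db.spectra[0].grid_mz,
        intensities=intensities,
        spectrum_ids=np.array(ids),
    )
    write_metadata([db.meta[i] for i in ids], directory / "metadata.tsv")


def load_database(directory: str | Path) -> ReferenceDatabase:
    directory = Path(directory)
    payload = np.load(directory / "spectra.npz", allow_pickle=False)
    grid = payload["grid_mz"]
    spectra = [
        ProcessedSpectrum(grid_mz=grid, intensity=row, spectrum_id=str(sid),
                          provenance=("loaded",))
        for sid, row in zip(payload["spectrum_ids"], payload["intensities"])
    ]
    meta = {m.spectrum_id: m for m in read_metadata(directory / "metadata.tsv")}
    return ReferenceDatabase(spectra=spectra, meta=meta)


__all__ = [
    "REPLICATE",
    "SAME_SPECIES",
    "DIFFERENT_SPECIES",
    "PAIR_CATEGORIES",
    "DatabaseError",
    "SimilaritySummary",
    "ReferenceDatabase",
    "build_database",
    "pair_category",
    "enumerate_pairs",
    "enumerate_cross_pairs",
    "all_pairs_cci",
    "cross_panel_cci",
    "summarize_similarity",
    "specimen_median_matrix",
    "bank_to_bank_best_match",
    "qc_filter",
    "merge_databases",
    "save_database",
    "load_database",
]
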