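"""Domain types, validation and file I/O for banded spotlight-survey data.

The canonical data layout is a long-format table with one row per
(transect, year, distance band) holding a non-negative count.  Perpendicular
distances are recorded in bands (by default 0-5, 5-10, 10-20, 20-40, 40-60
and 60-100 m), not as exact distances, and animals are counted on both sides
of the road.  A (transect, year) pair that appears nowhere in the
observation table is treated as *not surveyed*, not as zero.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_BAND_EDGES",
    "DistanceBands",
    "TransectRecord",
    "ObservationRecord",
    "SurveyDataset",
    "HabitatAreas",
    "RunConfig",
    "read_survey",
    "write_survey",
    "read_areas",
    "write_areas",
    "load_config",
    "save_config",
]

#: Default perpendicular-distance band edges in metres.
DEFAULT_BAND_EDGES = (0.0, 5.0, 10.0, 20.0, 40.0, 60.0, 100.0)

_PROP_TOL = 1e-6


class SurveyDataError(ValueError):
    """Raised when a survey file or dataset fails validation."""


@dataclass(frozen=True)
class DistanceBands:
    """Ordered perpendicular-distance band edges in metres.

    Bands are half-open intervals ``[lower, upper)``; an observation at
    exactly a boundary distance belongs to the upper band.
    """

    edges: tuple[float, ...] = DEFAULT_BAND_EDGES

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        if len(edges) < 2:
            raise SurveyDataError("need at least two band edges")
        if edges[0] != 0.0:
            raise SurveyDataError("first band edge must be 0")
        diffs = np.diff(edges)
        if np.any(diffs <= 0) or np.any(np.asarray(edges) < 0):
            raise SurveyDataError("band edges must be non-negative and strictly increasing")

    @property
    def n_bands(self) -> int:
        return len(self.edges) - 1

    @property
    def lower(self) -> np.ndarray:
        return np.asarray(self.edges[:-1], dtype=float)

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.edges[1:], dtype=float)

    @property
    def widths(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def half_width(self) -> float:
        """Maximum survey distance (strip half-width), metres."""
        return self.edges[-1]


@dataclass(frozen=True)
class TransectRecord:
    """One surveyed road section.

    ``length_km`` is the transect length l_j in kilometres; ``habitat_props``
    holds the proportion of the transect buffer classified as each vegetation
    group (p_{i,j}), in ``habitat_names`` order, or ``None`` for datasets
    without habitat information (Flinders-style).
    """

    transect_id: str
    length_km: float
    region_id: str | None = None
    habitat_props: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.length_km <= 0:
            raise SurveyDataError(
                f"transect {self.transect_id!r}: length must be > 0, got {self.length_km}"
            )
        if self.habitat_props is not None:
            props = np.asarray(self.habitat_props, dtype=float)
            if np.any(props < 0):
                raise SurveyDataError(
                    f"transect {self.transect_id!r}: negative habitat proportion"
                )
            total = props.sum()
            if abs(total - 1.0) > _PROP_TOL:
                raise SurveyDataError(
                    f"transect {self.transect_id!r}: habitat proportions sum to "
                    f"{total:.8f}, not 1"
                )
            object.__setattr__(self, "habitat_props", tuple(props / total))

    @property
    def length_m(self) -> float:
        return self.length_km * 1000.0


@dataclass(frozen=True)
class ObservationRecord:
    """Count of animals in one distance band on one transect-year."""

    transect_id: str
    year: int
    band_index: int
    count: int

    def __post_init__(self) -> None:
        if self.band_index < 0:
            raise SurveyDataError(f"band_index must be >= 0, got {self.band_index}")
        if self.count < 0:
            raise SurveyDataError(
                f"transect {self.transect_id!r}, year {self.year}: negative count"
            )


@dataclass
class SurveyDataset:
    """A validated survey panel: bands, transects and banded counts.

    The panel may be unbalanced: (transect, year) pairs absent from
    ``observations`` were not surveyed.  Within a surveyed pair, bands with
    no record are taken as zero counts when the likelihood is assembled.
    ``years`` may list the intended survey years of a design that has no
    counts yet; otherwise years are inferred from the observations.
    """

    bands: DistanceBands
    transects: list[TransectRecord]
    observations: list[ObservationRecord]
    reference_year: int = 2020
    habitat_names: tuple[str, ...] = ()
    region_names: tuple[str, ...] = ()
    years: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [t.transect_id for t in self.transects]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise SurveyDataError(f"duplicate transect ids: {sorted(dupes)}")
        known = set(ids)
        seen: set[tuple[str, int, int]] = set()
        for obs in self.observations:
            if obs.transect_id not in known:
                raise SurveyDataError(
                    f"observation references unknown transect {obs.transect_id!r}"
                )
            if obs.band_index >= self.bands.n_bands:
                raise SurveyDataError(
                    f"transect {obs.transect_id!r}, year {obs.year}: band_index "
                    f"{obs.band_index} out of range (have {self.bands.n_bands} bands)"
                )
            key = (obs.transect_id, obs.year, obs.band_index)
            if key in seen:
                raise SurveyDataError(f"duplicate observation record for {key}")
            seen.add(key)
        for t in self.transects:
            if t.habitat_props is not None and len(t.habitat_props) != len(self.habitat_names):
                raise SurveyDataError(
                    f"transect {t.transect_id!r}: {len(t.habitat_props)} habitat "
                    f"proportions but {len(self.habitat_names)} habitat names"
                )
            if t.region_id is not None and self.region_names and t.region_id not in self.region_names:
                raise SurveyDataError(
                    f"transect {t.transect_id!r}: unknown region {t.region_id!r}"
                )

    # -- derived indexing -------------------------------------------------

    @property
    def transect_ids(self) -> list[str]:
        return [t.transect_id for t in self.transects]

    @property
    def year_list(self) -> list[int]:
        if self.years is not None:
            return sorted(self.years)
        return sorted({o.year for o in self.observations})

    def transect(self, transect_id: str) -> TransectRecord:
        for t in self.transects:
            if t.transect_id == transect_id:
                return t
        raise KeyError(transect_id)

    def panel(self) -> dict[str, np.ndarray]:
        """Dense likelihood panel over surveyed (transect, year) pairs.

        Returns index arrays of length n_pairs * n_bands with zero counts
        filled in for bands missing from a surveyed pair.
        """
        t_index = {tid: k for k, tid in enumerate(self.transect_ids)}
        years = self.year_list
        y_index = {y: k for k, y in enumerate(years)}
        pairs = sorted({(o.transect_id, o.year) for o in self.observations})
        nb = self.bands.n_bands
        counts = np.zeros((len(pairs), nb), dtype=np.int64)
        pair_index = {p: k for k, p in enumerate(pairs)}
        for o in self.observations:
            counts[pair_index[(o.transect_id, o.year)], o.band_index] = o.count
        tr_idx = np.repeat([t_index[p[0]] for p in pairs], nb)
        yr_idx = np.repeat([y_index[p[1]] for p in pairs], nb)
        band_idx = np.tile(np.arange(nb), len(pairs))
        return {
            "count": counts.ravel(),
            "transect_idx": np.asarray(tr_idx, dtype=np.int64),
            "year_idx": np.asarray(yr_idx, dtype=np.int64),
            "band_idx": band_idx,
            "years": np.asarray(years, dtype=float),
            "n_pairs": np.int64(len(pairs)),
        }

    def fingerprint(self) -> str:
        """Short content hash identifying the dataset."""
        h = hashlib.sha256()
        h.update(repr(self.bands.edges).encode())
        for t in sorted(self.transects, key=lambda t: t.transect_id):
            h.update(repr((t.transect_id, t.length_km, t.region_id, t.habitat_props)).encode())
        for o in sorted(self.observations, key=lambda o: (o.transect_id, o.year, o.band_index)):
            h.update(repr((o.transect_id, o.year, o.band_index, o.count)).encode())
        h.update(repr((self.reference_year, self.habitat_names, self.region_names)).encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class HabitatAreas:
    """Total land area (hectares) of each vegetation group."""

    areas: dict[str, float]

    def __post_init__(self) -> None:
        for name, a in self.areas.items():
            if a < 0:
                raise SurveyDataError(f"habitat {name!r}: negative area {a}")

    @property
    def labels(self) -> list[str]:
        return list(self.areas)

    @property
    def total(self) -> float:
        return float(sum(self.areas.values()))

    def subset(self, labels: Sequence[str]) -> "HabitatAreas":
        unknown = [l for l in labels if l not in self.areas]
        if unknown:
            raise KeyError(f"unknown habitat labels: {unknown}")
        return HabitatAreas({l: self.areas[l] for l in labels})


# ---------------------------------------------------------------------------
# file I/O


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SurveyDataError(f"{path}: missing columns {missing}")


def read_survey(
    counts_path: str | Path,
    transects_path: str | Path,
    bands: DistanceBands | Sequence[float] | None = None,
    reference_year: int = 2020,
) -> SurveyDataset:
    """Read a survey dataset from a counts CSV and a transect CSV.

    The counts file has columns ``transect_id, year, band_index, count``.  A
    per-sighting file (same columns minus ``count``, one row per animal) is
    also accepted and aggregated to banded counts.  Habitat-proportion
    columns in the transect file form a ``prop_<name>`` block; proportions
    within 1e-6 of summing to 1 are renormalised, anything further off is
    rejected.
    """
    if bands is None:
        bands = DistanceBands()
    elif not isinstance(bands, DistanceBands):
        bands = DistanceBands(tuple(bands))

    tdf = pd.read_csv(transects_path, dtype={"transect_id": str})
    _require_columns(tdf, ["transect_id", "length_km"], transects_path)
    prop_cols = [c for c in tdf.columns if c.startswith("prop_")]
    habitat_names = tuple(c[len("prop_"):] for c in prop_cols)
    has_region = "region_id" in tdf.columns

    transects = []
    for row_no, d in enumerate(tdf.to_dict("records"), start=2):
        props = None
        if prop_cols:
            props = tuple(float(d[c]) for c in prop_cols)
            s = sum(props)
            if abs(s - 1.0) > _PROP_TOL:
                raise SurveyDataError(
                    f"{transects_path} row {row_no}: habitat proportions sum to {s:.8f}"
                )
        try:
            transects.append(
                TransectRecord(
                    transect_id=str(d["transect_id"]),
                    length_km=float(d["length_km"]),
                    region_id=str(d["region_id"]) if has_region and not pd.isna(d["region_id"]) else None,
                    habitat_props=props,
                )
            )
        except SurveyDataError as e:
            raise SurveyDataError(f"{transects_path} row {row_no}: {e}") from e

    known = {t.transect_id for t in transects}
    cdf = pd.read_csv(counts_path, dtype={"transect_id": str})
    _require_columns(cdf, ["transect_id", "year", "band_index"], counts_path)
    per_sighting = "count" not in cdf.columns
    if per_sighting:
        cdf = cdf.assign(count=1)

    for row_no, (tid, b_idx, cnt) in enumerate(
        zip(cdf["transect_id"], cdf["band_index"], cdf["count"]), start=2
    ):
        if tid not in known:
            raise SurveyDataError(f"{counts_path} row {row_no}: unknown transect {tid!r}")
        if not (0 <= b_idx < bands.n_bands):
            raise SurveyDataError(
                f"{counts_path} row {row_no}: band_index {b_idx} out of range"
            )
        if cnt < 0:
            raise SurveyDataError(f"{counts_path} row {row_no}: negative count {cnt}")

    if per_sighting:
        cdf = (
            cdf.groupby(["transect_id", "year", "band_index"], as_index=False)["count"].sum()
        )
    else:
        dupes = cdf.duplicated(["transect_id", "year", "band_index"])
        if dupes.any():
            row_no = int(dupes.idxmax()) + 2
            raise SurveyDataError(
                f"{counts_path} row {row_no}: duplicate (transect, year, band) record"
            )

    observations = [
        ObservationRecord(str(t), int(y), int(b), int(c))
        for t, y, b, c in zip(
            cdf["transect_id"], cdf["year"], cdf["band_index"], cdf["count"]
        )
    ]
    region_names = tuple(sorted({t.region_id for t in transects if t.region_id is not None}))
    return SurveyDataset(
        bands=bands,
        transects=transects,
        observations=observations,
        reference_year=reference_year,
        habitat_names=habitat_names,
        region_names=region_names,
    )


def write_survey(
    dataset: SurveyDataset,
    counts_path: str | Path,
    transects_path: str | Path,
) -> None:
    """Write a dataset to the two-CSV layout read by :func:`read_survey`.

    Habitat proportions are written with 17 significant digits so the
    sum-to-one invariant survives a round trip.
    """
    cdf = pd.DataFrame(
        [
            (o.transect_id, o.year, o.band_index, o.count)
            for o in dataset.observations
        ],
        columns=["transect_id", "year", "band_index", "count"],
    )
    cdf.to_csv(counts_path, index=False)

    rows = []
    for t in dataset.transects:
        row: dict[str, object] = {
            "transect_id": t.transect_id,
            "length_km": repr(t.length_km),
        }
        if t.region_id is not None:
            row["region_id"] = t.region_id
        if t.habitat_props is not None:
            for name, p in zip(dataset.habitat_names, t.habitat_props):
                row[f"prop_{name}"] = f"{p:.17g}"
        rows.append(row)
    cols = ["transect_id", "length_km"]
    if any(t.region_id is not None for t in dataset.transects):
        cols.append("region_id")
    cols.extend(f"prop_{n}" for n in dataset.habitat_names)
    pd.DataFrame(rows, columns=cols).to_csv(transects_path, index=False)


def read_areas(path: str | Path) -> HabitatAreas:
    """Read a two-column habitat/area CSV (``habitat, area_ha``)."""
    df = pd.read_csv(path)
    _require_columns(df, ["habitat", "area_ha"], path)
    areas: dict[str, float] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        name = str(row.habitat)
        if name in areas:
            raise SurveyDataError(f"{path} row {row_no}: duplicate habitat {name!r}")
        a = float(row.area_ha)
        if a < 0:
            raise SurveyDataError(f"{path} row {row_no}: negative area {a} for {name!r}")
        areas[name] = a
    return HabitatAreas(areas)


def write_areas(areas: HabitatAreas, path: str | Path) -> None:
    pd.DataFrame(
        {"habitat": areas.labels, "area_ha": [areas.areas[l] for l in areas.labels]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Key-value run configuration (YAML on disk)."""

    variant: str = "flinders"
    reference_year: int = 2020
    chains: int = 2
    iterations: int = 400
    warmup: int = 200
    seed: int = 0
    prior_scales: dict[str, float] = field(default_factory=dict)
    excluded_habitats: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.variant not in ("flinders", "mainland"):
            raise SurveyDataError(f"unknown model variant {self.variant!r}")
        if self.warmup >= self.iterations:
            raise SurveyDataError("warmup must be smaller than iterations")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise SurveyDataError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
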