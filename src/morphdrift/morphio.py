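"""Landmark configuration I/O and template validation.

File conventions
----------------
* TPS files use ``LM3=<p>`` blocks followed by ``p`` whitespace-separated
  ``x y z`` lines and an ``ID=<specimen_id>`` line.  Missing landmarks are
  written as the ``9999 9999 9999`` sentinel.  Landmark order follows the
  template (1-based in files by TPS convention, 0-based internally).
* Long CSV files carry one row per landmark with columns
  ``specimen_id, replicate, landmark, x, y, z``; a blank coordinate triple
  marks a missing landmark.
* Specimen metadata lives in a separate CSV (``specimen_id, year, period,
  sex``) joined at read time.
* Templates serialize to YAML or JSON.

Coordinates are kept in mm exactly as digitized; no unit conversion happens
anywhere before superimposition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DistanceDefinition",
    "LandmarkTemplate",
    "SpecimenRecord",
    "ShapeDataset",
    "TemplateError",
    "LandmarkParseError",
    "MetadataError",
    "read_landmarks",
    "write_landmarks",
    "read_metadata",
]

#: sentinel coordinate value marking a missing landmark in TPS files
MISSING_SENTINEL = 9999.0

#: collection-year ranges defining each time period
PERIOD_YEARS: dict[str, tuple[int, int]] = {"1890s": (1889, 1895), "2010s": (2014, 2016)}

VALID_SEXES = ("F", "M")
VALID_VIEWS = ("dorsal", "ventral", "common", "mandible")


class TemplateError(ValueError):
    """A landmark template violates one of its structural invariants."""


class LandmarkParseError(ValueError):
    """A landmark file could not be parsed against the template."""


class MetadataError(ValueError):
    """Specimen metadata is missing or carries unknown codes."""


@dataclass(frozen=True)
class DistanceDefinition:
    """An interlandmark distance trait.

    ``mirror_of`` names the contralateral distance this one is averaged
    with when building bilateral traits.
    """

    name: str
    endpoints: tuple[str, str]
    mirror_of: str | None = None

    def __post_init__(self) -> None:
        if self.endpoints[0] == self.endpoints[1]:
            raise TemplateError(f"distance {self.name!r}: endpoints must be distinct")


@dataclass
class LandmarkTemplate:
    """Declares landmark identity, bilateral structure, view membership and
    the interlandmark-distance trait set for one skeletal element."""

    landmark_names: list[str]
    dim: int = 3
    paired: list[tuple[str, str]] = field(default_factory=list)
    midline: list[str] = field(default_factory=list)
    views: dict[str, str] = field(default_factory=dict)
    distance_defs: list[DistanceDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.paired = [tuple(p) for p in self.paired]
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_names)

    def index(self, name: str) -> int:
        """0-based row index of a landmark id."""
        try:
            return self._index[name]
        except (AttributeError, KeyError):
            self._index = {n: i for i, n in enumerate(self.landmark_names)}
            return self._index[name]

    def view_landmarks(self, view: str) -> list[str]:
        """Landmark ids labelled with ``view`` (common landmarks belong to
        both dorsal and ventral digitizing orientations)."""
        if view in ("dorsal", "ventral"):
            return [n for n in self.landmark_names if self.views.get(n) in (view, "common")]
        return [n for n in self.landmark_names if self.views.get(n) == view]

    def validate(self) -> None:
        names = self.landmark_names
        if len(set(names)) != len(names):
            raise TemplateError("duplicate landmark names")
        known = set(names)
        flat_pairs = [n for pair in self.paired for n in pair]
        for n in flat_pairs:
            if n not in known:
                raise TemplateError(f"paired landmark {n!r} not in landmark_names")
        if len(set(flat_pairs)) != len(flat_pairs):
            raise TemplateError("a landmark appears in more than one bilateral pair")
        for n in self.midline:
            if n not in known:
                raise TemplateError(f"midline landmark {n!r} not in landmark_names")
        if set(self.midline) & set(flat_pairs):
            raise TemplateError("paired and midline landmark sets must be disjoint")
        for n, v in self.views.items():
            if n not in known:
                raise TemplateError(f"view entry for unknown landmark {n!r}")
            if v not in VALID_VIEWS:
                raise TemplateError(f"unknown view {v!r} for landmark {n!r}")
        by_name = {d.name: d for d in self.distance_defs}
        if len(by_name) != len(self.distance_defs):
            raise TemplateError("duplicate distance definition names")
        for d in self.distance_defs:
            for e in d.endpoints:
                if e not in known:
                    raise TemplateError(f"distance {d.name!r} references unknown landmark {e!r}")
            if d.mirror_of is not None:
                partner = by_name.get(d.mirror_of)
                if partner is None:
                    raise TemplateError(f"distance {d.name!r}: mirror_of {d.mirror_of!r} undefined")
                if partner.mirror_of != d.name:
                    raise TemplateError(f"mirror relation {d.name!r}<->{d.mirror_of!r} not reciprocal")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "landmark_names": list(self.landmark_names),
            "dim": self.dim,
            "paired": [list(p) for p in self.paired],
            "midline": list(self.midline),
            "views": dict(self.views),
            "distance_defs": [
                {"name": d.name, "endpoints": list(d.endpoints), "mirror_of": d.mirror_of}
                for d in self.distance_defs
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "LandmarkTemplate":
        return cls(
            landmark_names=list(data["landmark_names"]),
            dim=int(data.get("dim", 3)),
            paired=[tuple(p) for p in data.get("paired", [])],
            midline=list(data.get("midline", [])),
            views=dict(data.get("views", {})),
            distance_defs=[
                DistanceDefinition(d["name"], tuple(d["endpoints"]), d.get("mirror_of"))
                for d in data.get("distance_defs", [])
            ],
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix.lower() == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "LandmarkTemplate":
        path = Path(path)
        raw = path.read_text()
        data = json.loads(raw) if path.suffix.lower() == ".json" else yaml.safe_load(raw)
        return cls.from_dict(data)


@dataclass
class SpecimenRecord:
    """One digitization of one specimen: a p x 3 coordinate block (mm) plus
    museum metadata.  ``replicate`` 0 is the primary measurement."""

    specimen_id: str
    coords: np.ndarray
    missing_mask: np.ndarray | None = None
    year: int | None = None
    period: str | None = None
    sex: str | None = None
    replicate: int = 0
    imputed_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"{self.specimen_id}: coords must be p x 3")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.coords).all(axis=1)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (self.coords.shape[0],):
            raise ValueError(f"{self.specimen_id}: missing_mask length mismatch")
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros(self.coords.shape[0], dtype=bool)

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def validate(self, template: LandmarkTemplate | None = None) -> None:
        if template is not None and self.n_landmarks != template.n_landmarks:
            raise LandmarkParseError(
                f"specimen {self.specimen_id!r}: {self.n_landmarks} landmarks, "
                f"template declares {template.n_landmarks}"
            )
        observed = self.coords[~self.missing_mask]
        if not np.isfinite(observed).all():
            raise ValueError(f"specimen {self.specimen_id!r}: non-finite observed coordinates")
        if self.sex is not None and self.sex not in VALID_SEXES:
            raise MetadataError(f"specimen {self.specimen_id!r}: unknown sex code {self.sex!r}")
        if self.period is not None:
            if self.period not in PERIOD_YEARS:
                raise MetadataError(
                    f"specimen {self.specimen_id!r}: unknown period code {self.period!r}"
                )
            if self.year is not None:
                lo, hi = PERIOD_YEARS[self.period]
                if not lo <= self.year <= hi:
                    raise MetadataError(
                        f"specimen {self.specimen_id!r}: year {self.year} outside "
                        f"{self.period} range {lo}-{hi}"
                    )


@dataclass
class ShapeDataset:
    """A template plus the specimens digitized against it."""

    template: LandmarkTemplate
    specimens: list[SpecimenRecord]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, int]] = set()
        for s in self.specimens:
            key = (s.specimen_id, s.replicate)
            if key in seen:
                raise ValueError(f"duplicate specimen_id x replicate: {key}")
            seen.add(key)
            s.validate(self.template)

    def __len__(self) -> int:
        return len(self.specimens)

    def primary(self) -> "ShapeDataset":
        """Subset to replicate-0 measurements."""
        return ShapeDataset(self.template, [s for s in self.specimens if s.replicate == 0])

    def subset(self, keep: Iterable[SpecimenRecord]) -> "ShapeDataset":
        return ShapeDataset(self.template, list(keep))

    def coords_array(self) -> np.ndarray:
        """n x p x 3 stack of all specimen coordinates."""
        return np.stack([s.coords for s in self.specimens])

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "specimen_id": [s.specimen_id for s in self.specimens],
                "replicate": [s.replicate for s in self.specimens],
                "year": [s.year for s in self.specimens],
                "period": [s.period for s in self.specimens],
                "sex": [s.sex for s in self.specimens],
            }
        )


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the specimen metadata CSV (specimen_id, year, period, sex)."""
    meta = pd.read_csv(path, dtype={"specimen_id": str})
    required = {"specimen_id", "year", "period", "sex"}
    missing = required - set(meta.columns)
    if missing:
        raise MetadataError(f"metadata file {path} lacks columns: {sorted(missing)}")
    if meta["specimen_id"].duplicated().any():
        dup = meta.loc[meta["specimen_id"].duplicated(), "specimen_id"].iloc[0]
        raise MetadataError(f"duplicate specimen_id {dup!r} in metadata")
    return meta.set_index("specimen_id")


def _apply_metadata(record: SpecimenRecord, meta: pd.DataFrame | None) -> SpecimenRecord:
    if meta is None or record.specimen_id not in meta.index:
        return record
    row = meta.loc[record.specimen_id]
    return replace(
        record,
        year=int(row["year"]) if pd.notna(row["year"]) else None,
        period=str(row["period"]) if pd.notna(row["period"]) else None,
        sex=str(row["sex"]) if pd.notna(row["sex"]) else None,
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_landmarks(
    path: str | Path,
    format: str | None = None,
    template: LandmarkTemplate | None = None,
    metadata: str | Path | pd.DataFrame | None = None,
) -> ShapeDataset:
    """Read a TPS or long-CSV landmark file into a :class:`ShapeDataset`.

    ``format`` defaults from the file extension.  ``metadata`` may be a path
    to a metadata CSV or an already-loaded frame; metadata columns are joined
    by ``specimen_id``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "tps" if path.suffix.lower() == ".tps" else "csv"
    if format not in ("tps", "csv"):
        raise ValueError(f"unknown landmark format {format!r}")
    if isinstance(metadata, (str, Path)):
        metadata = read_metadata(metadata)

    if format == "tps":
        records = _parse_tps(path)
    else:
        records = _parse_long_csv(path)

    records = [_apply_metadata(r, metadata) for r in records]
    if template is None:
        p = records[0].n_landmarks if records else 0
        template = LandmarkTemplate([f"lm{i + 1:02d}" for i in range(p)])
    dataset = ShapeDataset(template, records)
    return dataset


def _parse_tps(path: Path) -> list[SpecimenRecord]:
    lines = path.read_text().splitlines()
    records: list[SpecimenRecord] = []
    seen_ids: dict[str, int] = {}
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM"):
            raise LandmarkParseError(f"{path}:{i + 1}: expected LM3= block, got {line!r}")
        try:
            p = int(line.split("=", 1)[1])
        except (IndexError, ValueError) as exc:
            raise LandmarkParseError(f"{path}:{i + 1}: bad LM line {line!r}") from exc
        coords = np.full((p, 3), np.nan)
        i += 1
        for j in range(p):
            if i >= len(lines):
                raise LandmarkParseError(f"{path}: truncated coordinate block")
            parts = lines[i].split()
            if len(parts) != 3:
                raise LandmarkParseError(
                    f"{path}:{i + 1}: expected 3 coordinates, got {len(parts)}"
                )
            coords[j] = [float(v) for v in parts]
            i += 1
        specimen_id = None
        while i < len(lines) and not lines[i].strip().upper().startswith("LM"):
            tag = lines[i].strip()
            if tag.upper().startswith("ID="):
                specimen_id = tag.split("=", 1)[1].strip()
            i += 1
        if specimen_id is None:
            specimen_id = f"specimen{len(records) + 1}"
        # repeat digitizations of one specimen get successive replicate ids
        replicate = seen_ids.get(specimen_id, 0)
        seen_ids[specimen_id] = replicate + 1
        missing = np.all(coords == MISSING_SENTINEL, axis=1) | ~np.isfinite(coords).all(axis=1)
        coords[missing] = np.nan
        records.append(
            SpecimenRecord(specimen_id, coords, missing_mask=missing, replicate=replicate)
        )
    return records


def _parse_long_csv(path: Path) -> list[SpecimenRecord]:
    df = pd.read_csv(path, dtype={"specimen_id": str})
    required = {"specimen_id", "replicate", "landmark", "x", "y", "z"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise LandmarkParseError(f"{path}: missing columns {sorted(missing_cols)}")
    records = []
    for (sid, rep), grp in df.groupby(["specimen_id", "replicate"], sort=False):
        coords = grp[["x", "y", "z"]].to_numpy(dtype=float)
        missing = ~np.isfinite(coords).all(axis=1)
        coords = coords.copy()
        coords[missing] = np.nan
        records.append(
            SpecimenRecord(str(sid), coords, missing_mask=missing, replicate=int(rep))
        )
    return records


def write_landmarks(dataset: ShapeDataset, path: str | Path, format: str | None = None) -> Path:
    """Write a dataset to TPS or long CSV; lossless round-trip at 6 decimals.

    Missing landmarks are emitted as the format's sentinel (``9999`` triple
    for TPS, blank coordinates for CSV).
    """
    path = Path(path)
    if format is None:
        format = "tps" if path.suffix.lower() == ".tps" else "csv"
    if format == "tps":
        blocks = []
        for s in dataset.specimens:
            out = np.where(
                s.missing_mask[:, None], MISSING_SENTINEL, np.nan_to_num(s.coords, nan=MISSING_SENTINEL)
            )
            rows = "\n".join(" ".join(f"{v:.6f}" for v in row) for row in out)
            block = f"LM3={s.n_landmarks}\n{rows}\nID={s.specimen_id}" if s.n_landmarks else f"LM3=0\nID={s.specimen_id}"
            blocks.append(block)
        path.write_text("\n".join(blocks) + "\n" if blocks else "")
    elif format == "csv":
        names = dataset.template.landmark_names
        rows = []
        for s in dataset.specimens:
            for j in range(s.n_landmarks):
                lm = names[j] if j < len(names) else f"lm{j + 1:02d}"
                if s.missing_mask[j]:
                    rows.append((s.specimen_id, s.replicate, lm, "", "", ""))
                else:
                    rows.append(
                        (s.specimen_id, s.replicate, lm)
                        + tuple(f"{v:.6f}" for v in s.coords[j])
                    )
        pd.DataFrame(
            rows, columns=["specimen_id", "replicate", "landmark", "x", "y", "z"]
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown landmark format {format!r}")
    return path
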