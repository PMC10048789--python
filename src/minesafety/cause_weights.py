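"""Accident-cause taxonomy, weight estimation, and synthetic cause records.

The model's parameters are weight vectors over the element hierarchy of the
24Model accident-causation taxonomy: organizational layers (safety culture,
safety management system) and individual layers (safety ability, unsafe acts).
Weights are the observed proportions of each cause element among the causes
tallied from coal-and-gas-outburst accident investigations.  Because no such
tally is distributed with this package, a synthetic generator draws accident
records as independent Poisson counts per (accident, group) allocated
multinomially by a set of true proportions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CauseTaxonomy",
    "CauseRecord",
    "WeightTable",
    "DEFAULT_TAXONOMY",
    "normalize_weights",
    "estimate_weights",
    "generate_accident_records",
    "default_weight_table",
    "records_to_frame",
    "records_from_frame",
    "read_records_csv",
    "write_records_csv",
]

#: group_id -> (layer name, ordered element codes)
_DEFAULT_GROUPS: dict[str, tuple[str, tuple[str, ...]]] = {
    "a": ("safety culture element categories", ("SC1", "SC2", "SC3", "SC4")),
    "b": ("safety management organizational structure sub-elements",
          ("SM21", "SM22", "SM23")),
    "c": ("safety management procedure sub-elements",
          ("SM31", "SM32", "SM33", "SM34", "SM35", "SM36", "SM37")),
    "d": ("safety management sub-systems", ("SM1", "SM2", "SM3")),
    "e": ("safety knowledge sub-elements",
          ("SA11", "SA12", "SA13", "SA14", "SA15", "SA16", "SA17")),
    "f": ("safety awareness sub-elements", ("SA21", "SA22", "SA23")),
    "g": ("safety psychology sub-elements", ("SA41", "SA42", "SA43", "SA44")),
    "h": ("safety ability components", ("SA1", "SA2", "SA3", "SA4")),
}

_GROUP_SIZES = {"a": 4, "b": 3, "c": 7, "d": 3, "e": 7, "f": 3, "g": 4, "h": 4}


class InvalidRatioError(ValueError):
    """Raised when a ratio vector cannot be normalized to proportions."""


class WeightEstimationError(ValueError):
    """Raised when cause records cannot support weight estimation."""


class SchemaError(ValueError):
    """Raised for records or tables that violate the taxonomy schema."""


@dataclass(frozen=True)
class CauseTaxonomy:
    """Element hierarchy of the accident-cause taxonomy.

    ``groups`` maps a group id (``a`` .. ``h``) to its ordered element codes;
    ``layer_names`` carries a human-readable name per group.  Group sizes are
    fixed at (a:4, b:3, c:7, d:3, e:7, f:3, g:4, h:4).
    """

    groups: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {g: v[1] for g, v in _DEFAULT_GROUPS.items()}
    )
    layer_names: Mapping[str, str] = field(
        default_factory=lambda: {g: v[0] for g, v in _DEFAULT_GROUPS.items()}
    )

    def __post_init__(self) -> None:
        if set(self.groups) != set(_GROUP_SIZES):
            raise SchemaError(
                f"taxonomy must define exactly groups {sorted(_GROUP_SIZES)}, "
                f"got {sorted(self.groups)}"
            )
        for gid, codes in self.groups.items():
            if len(codes) != _GROUP_SIZES[gid]:
                raise SchemaError(
                    f"group {gid!r} must have {_GROUP_SIZES[gid]} elements, "
                    f"got {len(codes)}"
                )
            if len(set(codes)) != len(codes):
                raise SchemaError(f"duplicate element codes in group {gid!r}")

    def group_size(self, group_id: str) -> int:
        return len(self.groups[group_id])

    def element_index(self, group_id: str, element_code: str) -> int:
        try:
            return self.groups[group_id].index(element_code)
        except (KeyError, ValueError) as exc:
            raise SchemaError(
                f"element {element_code!r} not in group {group_id!r}"
            ) from exc


DEFAULT_TAXONOMY = CauseTaxonomy()


@dataclass(frozen=True)
class CauseRecord:
    """Count of one cause element observed in one accident investigation."""

    accident_id: str
    group_id: str
    element_code: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise SchemaError(f"count must be >= 0, got {self.count}")


class WeightTable:
    """One proportion vector per weight group, each summing to 1.

    Vectors are validated against the taxonomy group sizes and must sum to 1
    within 1e-3 (printed two- to four-decimal vectors round-trip).
    """

    _SUM_TOL = 1e-3

    def __init__(self, vectors: Mapping[str, Sequence[float]],
                 taxonomy: CauseTaxonomy = DEFAULT_TAXONOMY) -> None:
        self.taxonomy = taxonomy
        self._vectors: dict[str, np.ndarray] = {}
        for gid in sorted(_GROUP_SIZES):
            if gid not in vectors:
                raise SchemaError(f"missing weight vector for group {gid!r}")
            v = np.asarray(vectors[gid], dtype=float)
            if v.shape != (taxonomy.group_size(gid),):
                raise SchemaError(
                    f"group {gid!r} expects {taxonomy.group_size(gid)} "
                    f"weights, got shape {v.shape}"
                )
            if np.any(v < 0) or np.any(v > 1):
                raise SchemaError(f"group {gid!r} weights must lie in [0,1]")
            if abs(v.sum() - 1.0) > self._SUM_TOL:
                raise SchemaError(
                    f"group {gid!r} weights sum to {v.sum():.6f}, not 1"
                )
            self._vectors[gid] = v

    def __getitem__(self, group_id: str) -> np.ndarray:
        return self._vectors[group_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightTable):
            return NotImplemented
        return all(np.array_equal(self[g], other[g]) for g in _GROUP_SIZES)

    def items(self):
        return self._vectors.items()

    def weight(self, group_id: str, element_code: str) -> float:
        return float(self[group_id][self.taxonomy.element_index(group_id, element_code)])

    def to_dict(self) -> dict[str, list[float]]:
        return {g: [float(x) for x in v] for g, v in self._vectors.items()}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path, taxonomy: CauseTaxonomy = DEFAULT_TAXONOMY) -> "WeightTable":
        with open(path, encoding="utf-8") as fh:
            return cls(json.load(fh), taxonomy)

    def __repr__(self) -> str:
        return f"WeightTable({self.to_dict()})"


def normalize_weights(ratios: Sequence[float]) -> np.ndarray:
    """Normalize a nonnegative ratio vector to proportions summing to 1.

    Scale-invariant: ``normalize_weights(k * r) == normalize_weights(r)`` for
    any k > 0.  Raises :class:`InvalidRatioError` on negative entries or an
    all-zero vector.
    """
    r = np.asarray(ratios, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise InvalidRatioError("ratios must be a nonempty 1-d vector")
    if np.any(r < 0):
        raise InvalidRatioError("ratios must be nonnegative")
    total = r.sum()
    if total <= 0:
        raise InvalidRatioError("at least one ratio must be positive")
    return r / total


# published parameterisation: groups given as raw ratios are normalized
# exactly; groups given only as decimals use the printed decimals verbatim.
_RATIO_GROUPS = {"a": (2, 6, 7, 7), "b": (21, 77, 44)}
_DECIMAL_GROUPS = {
    "c": (0.08, 0.08, 0.21, 0.17, 0.12, 0.17, 0.17),
    "d": (0.2, 0.5, 0.3),
    "e": (0.7896, 0.0861, 0.0615, 0.0232, 0.0137, 0.0178, 0.0082),
    "f": (0.6066, 0.2049, 0.1885),
    "g": (0.4085, 0.2022, 0.2336, 0.1557),
    "h": (0.5, 0.1, 0.2, 0.2),
}


def default_weight_table(taxonomy: CauseTaxonomy = DEFAULT_TAXONOMY) -> WeightTable:
    """Weight vectors estimated from the 84 coal-and-gas-outburst accidents."""
    vectors: dict[str, Sequence[float]] = {
        g: normalize_weights(r) for g, r in _RATIO_GROUPS.items()
    }
    vectors.update(_DECIMAL_GROUPS)
    return WeightTable(vectors, taxonomy)


def estimate_weights(records: Iterable[CauseRecord],
                     taxonomy: CauseTaxonomy = DEFAULT_TAXONOMY) -> WeightTable:
    """Estimate group weight vectors as element-count proportions.

    For each group, ``weight[element] = sum(count of element) / sum(count of
    group)``.  A group with zero total count cannot be estimated and raises
    :class:`WeightEstimationError`; an element code outside its group raises
    :class:`SchemaError`.
    """
    totals = {g: np.zeros(taxonomy.group_size(g)) for g in taxonomy.groups}
    for rec in records:
        if rec.group_id not in totals:
            raise SchemaError(f"unknown group {rec.group_id!r}")
        idx = taxonomy.element_index(rec.group_id, rec.element_code)
        totals[rec.group_id][idx] += rec.count
    vectors = {}
    for gid, counts in totals.items():
        if counts.sum() <= 0:
            raise WeightEstimationError(
                f"group {gid!r} has zero total count; cannot estimate weights"
            )
        vectors[gid] = counts / counts.sum()
    return WeightTable(vectors, taxonomy)


def generate_accident_records(
    taxonomy: CauseTaxonomy,
    true_weights: WeightTable,
    n_accidents: int,
    mean_causes_per_accident_per_group: float = 3.0,
    seed: int | None = None,
) -> list[CauseRecord]:
    """Draw synthetic accident-cause records.

    Per accident and group the number of cause occurrences is
    Poisson(``mean_causes_per_accident_per_group``) and the occurrences are
    allocated multinomially by ``true_weights``.  Identical inputs and seed
    give identical records.  ``n_accidents`` of zero yields an empty list;
    negative values raise ``ValueError``.
    """
    if n_accidents < 0:
        raise ValueError(f"n_accidents must be >= 0, got {n_accidents}")
    if mean_causes_per_accident_per_group <= 0:
        raise ValueError("mean_causes_per_accident_per_group must be > 0")
    rng = np.random.default_rng(seed)
    records: list[CauseRecord] = []
    for i in range(n_accidents):
        aid = f"ACC{i:05d}"
        for gid in sorted(taxonomy.groups):
            codes = taxonomy.groups[gid]
            n_causes = int(rng.poisson(mean_causes_per_accident_per_group))
            if n_causes == 0:
                continue
            alloc = rng.multinomial(n_causes, true_weights[gid])
            for code, cnt in zip(codes, alloc):
                if cnt > 0:
                    records.append(CauseRecord(aid, gid, code, int(cnt)))
    return records


_CSV_COLUMNS = ["accident_id", "group_id", "element_code", "count"]


def records_to_frame(records: Iterable[CauseRecord]) -> pd.DataFrame:
    rows = [(r.accident_id, r.group_id, r.element_code, r.count) for r in records]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def records_from_frame(frame: pd.DataFrame,
                       taxonomy: CauseTaxonomy = DEFAULT_TAXONOMY) -> list[CauseRecord]:
    missing = set(_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"cause-record table missing columns {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        rec = CauseRecord(str(row.accident_id), str(row.group_id),
                          str(row.element_code), int(row.count))
        taxonomy.element_index(rec.group_id, rec.element_code)  # schema check
        records.append(rec)
    return records


def write_records_csv(records: Iterable[CauseRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path, taxonomy: CauseTaxonomy = DEFAULT_TAXONOMY) -> list[CauseRecord]:
    return records_from_frame(pd.read_csv(path), taxonomy)
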