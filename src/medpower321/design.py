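"""Design specifications and grids for 3-2-1 multilevel mediation power analysis.

A *design* is one configuration of a cluster-randomized 3-2-1 mediation study:
standardized effect sizes for the level-3 paths (``a3``: X->M, ``b3``: M->Y,
``c3p``: the direct effect X->Y), the standardized level-2 path ``b2``,
intraclass correlation coefficients of the mediator (level 3) and the outcome
(levels 2 and 3), and the per-level sample sizes ``n3`` (clusters), ``n2``
(units per cluster) and ``n1`` (observations per unit).

A *grid* is a fully crossed set of candidate values per field.  The default
grid covers small/medium/large effects (0.14/0.39/0.59), small/medium direct
effects, ICCs in {0.05, 0.10, 0.20} and sample sizes typical of implementation
trials, giving 17,496 designs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, asdict
from typing import Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "DesignSpec",
    "GridDefinition",
    "enumerate_grid",
    "total_sample",
    "count_by_total",
    "grid_to_frame",
]

#: Field order used everywhere (enumeration, CSV columns, hashing).
SPEC_FIELDS = (
    "a3", "b3", "c3p", "b2",
    "icc_m3", "icc_y2", "icc_y3",
    "n3", "n2", "n1",
)


class DesignError(ValueError):
    """Raised when a design specification or grid violates an invariant."""


@dataclass(frozen=True)
class DesignSpec:
    """One cell of the design grid.

    Standardization convention: ``a3``, ``b3`` and ``c3p`` are between-level
    (level-3) standardized coefficients; ``b2`` is standardized at level 2.
    ICCs give the proportion of total (unit) variance of M and Y residing at
    the named level.
    """

    a3: float
    b3: float
    c3p: float
    b2: float
    icc_m3: float
    icc_y2: float
    icc_y3: float
    n3: int
    n2: int
    n1: int

    def __post_init__(self) -> None:
        if not 0.0 < self.icc_m3 < 1.0:
            raise DesignError(f"icc_m3 must be in (0, 1), got {self.icc_m3}")
        for name in ("icc_y2", "icc_y3"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise DesignError(f"{name} must be in (0, 1), got {v}")
        if self.icc_y2 + self.icc_y3 >= 1.0:
            raise DesignError(
                f"icc_y2 + icc_y3 must be < 1, got {self.icc_y2 + self.icc_y3}"
            )
        if abs(self.a3) >= 1.0:
            raise DesignError(f"|a3| must be < 1, got {self.a3}")
        if abs(self.b2) >= 1.0:
            raise DesignError(f"|b2| must be < 1, got {self.b2}")
        r2b = self.b3 ** 2 + self.c3p ** 2 + 2 * self.a3 * self.b3 * self.c3p
        if r2b >= 1.0:
            raise DesignError(
                "between-level R^2 for Y must be < 1: "
                f"b3^2 + c3p^2 + 2*a3*b3*c3p = {r2b:.6f}"
            )
        if self.n3 < 2 or self.n3 % 2:
            raise DesignError(f"n3 must be even and >= 2, got {self.n3}")
        if self.n2 < 2:
            raise DesignError(f"n2 must be >= 2, got {self.n2}")
        if self.n1 < 1:
            raise DesignError(f"n1 must be >= 1, got {self.n1}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return (self.n3, self.n2, self.n1)

    def to_dict(self) -> dict:
        return asdict(self)

    def canonical_json(self) -> str:
        """JSON with fields in canonical order; stable across runs."""
        d = self.to_dict()
        return json.dumps({k: d[k] for k in SPEC_FIELDS}, separators=(",", ":"))

    def key(self) -> int:
        """Stable 63-bit integer identifier derived from the canonical JSON."""
        digest = hashlib.sha256(self.canonical_json().encode()).digest()
        return int.from_bytes(digest[:8], "big") & ((1 << 63) - 1)


#: The published default grid: 3^7 * 4 * 2 = 17,496 designs.
PAPER_GRID = {
    "a3": (0.14, 0.39, 0.59),
    "b3": (0.14, 0.39, 0.59),
    "c3p": (0.14, 0.39),
    "b2": (0.39,),
    "icc_m3": (0.05, 0.10, 0.20),
    "icc_y2": (0.05, 0.10, 0.20),
    "icc_y3": (0.05, 0.10, 0.20),
    "n3": (10, 20, 40, 60),
    "n2": (5, 10, 20),
    "n1": (3, 6, 12),
}


@dataclass(frozen=True)
class GridDefinition:
    """Value lists for each DesignSpec field; defaults reproduce the published grid."""

    a3: tuple = PAPER_GRID["a3"]
    b3: tuple = PAPER_GRID["b3"]
    c3p: tuple = PAPER_GRID["c3p"]
    b2: tuple = PAPER_GRID["b2"]
    icc_m3: tuple = PAPER_GRID["icc_m3"]
    icc_y2: tuple = PAPER_GRID["icc_y2"]
    icc_y3: tuple = PAPER_GRID["icc_y3"]
    n3: tuple = PAPER_GRID["n3"]
    n2: tuple = PAPER_GRID["n2"]
    n1: tuple = PAPER_GRID["n1"]

    def __post_init__(self) -> None:
        for name in SPEC_FIELDS:
            vals = getattr(self, name)
            if not isinstance(vals, tuple):
                object.__setattr__(self, name, tuple(vals))
                vals = getattr(self, name)
            if len(vals) == 0:
                raise DesignError(f"grid field {name!r} has no values")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence]) -> "GridDefinition":
        unknown = set(mapping) - set(SPEC_FIELDS)
        if unknown:
            raise DesignError(f"unknown grid fields: {sorted(unknown)}")
        return cls(**{k: tuple(v) for k, v in mapping.items()})

    def size(self) -> int:
        n = 1
        for name in SPEC_FIELDS:
            n *= len(getattr(self, name))
        return n


def enumerate_grid(grid: GridDefinition | None = None) -> Iterator[DesignSpec]:
    """Yield every design of the fully crossed grid.

    Order is lexicographic over the fields in declaration order
    (a3, b3, c3p, b2, icc_m3, icc_y2, icc_y3, n3, n2, n1), each field
    iterating in its listed value order; stable across runs.

    Every yielded spec is validated; an invalid grid value raises
    :class:`DesignError` naming the offending field.
    """
    if grid is None:
        grid = GridDefinition()
    value_lists = [getattr(grid, name) for name in SPEC_FIELDS]
    for combo in itertools.product(*value_lists):
        try:
            yield DesignSpec(**dict(zip(SPEC_FIELDS, combo)))
        except DesignError as err:
            raise DesignError(
                f"invalid grid combination {dict(zip(SPEC_FIELDS, combo))}: {err}"
            ) from err


def total_sample(spec: DesignSpec) -> int:
    """Total number of level-1 observations, n3 * n2 * n1."""
    return spec.n3 * spec.n2 * spec.n1


def count_by_total(grid: GridDefinition | None = None) -> dict[int, int]:
    """Map each achievable total sample size to its number of grid designs.

    Counts sum to the grid size; each total's count equals the number of
    (n3, n2, n1) triples with that product times the product of the
    non-sample-size axis lengths.
    """
    if grid is None:
        grid = GridDefinition()
    other = 1
    for name in SPEC_FIELDS[:-3]:
        other *= len(getattr(grid, name))
    counts: dict[int, int] = {}
    for n3, n2, n1 in itertools.product(grid.n3, grid.n2, grid.n1):
        t = n3 * n2 * n1
        counts[t] = counts.get(t, 0) + other
    return dict(sorted(counts.items()))


def grid_to_frame(grid: GridDefinition | None = None) -> pd.DataFrame:
    """Enumerate a grid into a DataFrame, one row per design, canonical columns."""
    rows = [s.to_dict() for s in enumerate_grid(grid)]
    df = pd.DataFrame(rows, columns=list(SPEC_FIELDS))
    df["total_sample"] = df.n3 * df.n2 * df.n1
    return df
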