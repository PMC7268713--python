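"""Forced-distribution grid for Q-sorting.

A Q-grid fixes how many statements a participant may place at each rank
(e.g. one statement at +5, two at +4, ...).  Every sort in a study must
obey the same grid, which gives all sorts identical mean and variance and
makes the by-person correlation matrix well defined.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path


class GridError(ValueError):
    """Raised for structurally invalid grid definitions."""


@dataclass(frozen=True)
class GridSpec:
    """Rank → capacity map over a contiguous integer rank range.

    Parameters
    ----------
    capacity
        Mapping from rank (int) to the number of statements that must be
        placed at that rank.  Ranks must form a contiguous range with
        step 1 and all capacities must be positive.
    """

    capacity: Mapping[int, int]
    _ranks: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        cap = {int(r): int(c) for r, c in self.capacity.items()}
        if not cap:
            raise GridError("grid has no ranks")
        ranks = tuple(sorted(cap))
        if ranks != tuple(range(ranks[0], ranks[-1] + 1)):
            raise GridError(f"rank range {ranks} is not contiguous")
        for r, c in cap.items():
            if c <= 0:
                raise GridError(f"capacity at rank {r} must be positive, got {c}")
        object.__setattr__(self, "capacity", cap)
        object.__setattr__(self, "_ranks", ranks)

    # -- basic geometry -------------------------------------------------

    @property
    def ranks(self) -> tuple[int, ...]:
        """All ranks, ascending."""
        return self._ranks

    @property
    def r_min(self) -> int:
        return self._ranks[0]

    @property
    def r_max(self) -> int:
        return self._ranks[-1]

    @property
    def n_statements(self) -> int:
        """Total number of statements a conforming sort must place."""
        return sum(self.capacity.values())

    @property
    def is_symmetric(self) -> bool:
        """True when capacity(r) == capacity(-r) for every rank."""
        return all(
            -r in self.capacity and self.capacity[r] == self.capacity[-r]
            for r in self._ranks
        )

    @property
    def mean(self) -> float:
        return sum(r * c for r, c in self.capacity.items()) / self.n_statements

    @property
    def variance(self) -> float:
        """Population variance of the rank values every sort shares."""
        m = self.mean
        return sum(c * (r - m) ** 2 for r, c in self.capacity.items()) / self.n_statements

    def rank_values(self) -> list[int]:
        """The full multiset of rank values, ascending (length n_statements)."""
        out: list[int] = []
        for r in self._ranks:
            out.extend([r] * self.capacity[r])
        return out

    # -- serialization --------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"ranks": {str(r): self.capacity[r] for r in self._ranks}}, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GridSpec":
        """Read a grid from a JSON file path or JSON text (``{"ranks": {...}}``)."""
        if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("{")):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = source
        obj = json.loads(text)
        if "ranks" not in obj:
            raise GridError('grid JSON must contain a "ranks" object')
        return cls({int(r): int(c) for r, c in obj["ranks"].items()})


def derive_grid(ranks: Iterable[int]) -> GridSpec:
    """Infer the grid from one complete sort's rank column.

    The capacity of each rank is its frequency in the column; the rank
    range is the observed min..max.  A gap in the range (a rank between
    min and max that never occurs) is rejected as non-contiguous.
    """
    values = [int(r) for r in ranks]
    if not values:
        raise GridError("empty rank column")
    cap: dict[int, int] = {}
    for v in values:
        cap[v] = cap.get(v, 0) + 1
    lo, hi = min(cap), max(cap)
    missing = [r for r in range(lo, hi + 1) if r not in cap]
    if missing:
        raise GridError(f"rank range {lo}..{hi} has gaps at {missing}: not a contiguous grid")
    return GridSpec(cap)
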