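"""Q-sort panel data model and validation.

The analysis input is a statements × participants matrix of integer
ranks, every column of which must be a complete sort conforming to the
study grid.  Validation never raises on bad data — violations are
returned as records so a whole panel can be audited in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .grid import GridSpec


@dataclass(frozen=True)
class Statement:
    """One Q-sample item."""

    id: int
    text: str
    short_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.id < 1:
            raise ValueError(f"statement ids are 1-based, got {self.id}")
        if not str(self.text).strip():
            raise ValueError(f"statement {self.id} has empty text")


def default_statements(n: int) -> list[Statement]:
    """Placeholder statements 1..n for panels supplied without wording."""
    return [Statement(i, f"Statement {i}") for i in range(1, n + 1)]


@dataclass(frozen=True)
class QSort:
    """One participant's complete assignment of statements to ranks."""

    participant_id: str
    ranks: dict[int, int]  # statement id -> rank


@dataclass
class ParticipantMeta:
    """Demographics attached to one participant (all fields optional).

    ``eq5d_profile`` is the five-character EQ-5D descriptive-system
    profile ("11111" = no problems on any dimension); ``vas`` is the
    0-100 self-rated health score.
    """

    participant_id: str
    gender: Optional[str] = None
    age: Optional[float] = None
    education: Optional[str] = None
    eq5d_profile: Optional[str] = None
    vas: Optional[float] = None
    residence: Optional[str] = None
    region: Optional[str] = None

    def __post_init__(self) -> None:
        if self.eq5d_profile is not None:
            p = str(self.eq5d_profile)
            if len(p) != 5 or any(ch not in "12345" for ch in p):
                raise ValueError(
                    f"participant {self.participant_id}: EQ-5D profile must be five digits 1-5, got {p!r}"
                )
            self.eq5d_profile = p
        if self.vas is not None and not (0 <= self.vas <= 100):
            raise ValueError(f"participant {self.participant_id}: VAS {self.vas} outside [0, 100]")


@dataclass(frozen=True)
class Violation:
    """One validation finding for one participant column."""

    participant_id: str
    kind: str  # "capacity" | "missing_statement" | "duplicate_statement" | "unknown_statement"
    rank: Optional[int] = None
    expected_count: Optional[int] = None
    observed_count: Optional[int] = None
    statement_id: Optional[int] = None

    def describe(self) -> str:
        if self.kind == "capacity":
            return (
                f"{self.participant_id}: rank {self.rank:+d} holds {self.observed_count} "
                f"statements, grid allows {self.expected_count}"
            )
        return f"{self.participant_id}: {self.kind.replace('_', ' ')} {self.statement_id}"


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...]

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "violations": [
                {k: v for k, v in vars(viol).items() if v is not None}
                for viol in self.violations
            ],
        }


class QSortPanel:
    """Statements × participants rank matrix plus its grid.

    Parameters
    ----------
    sorts
        DataFrame indexed by statement id with one integer column per
        participant.
    grid
        The forced distribution every column must obey.
    statements
        Optional statement wordings; defaults to placeholders.
    """

    def __init__(
        self,
        sorts: pd.DataFrame,
        grid: GridSpec,
        statements: Optional[list[Statement]] = None,
    ) -> None:
        sorts = sorts.copy()
        sorts.index = sorts.index.astype(int)
        if statements is None:
            statements = default_statements(len(sorts))
        ids = [s.id for s in statements]
        if sorted(ids) != list(range(1, len(ids) + 1)):
            raise ValueError("statement ids must be unique and contiguous from 1")
        if len(ids) != len(sorts):
            raise ValueError(
                f"{len(statements)} statements but {len(sorts)} panel rows"
            )
        if set(sorts.index) != set(ids):
            raise ValueError("panel row index does not match statement ids")
        if len(sorts.columns) != len(set(sorts.columns)):
            raise ValueError("duplicate participant ids")
        self.sorts = sorts.astype(int)
        self.grid = grid
        self.statements = sorted(statements, key=lambda s: s.id)

    # -- views ----------------------------------------------------------

    @property
    def n_statements(self) -> int:
        return len(self.sorts)

    @property
    def n_participants(self) -> int:
        return self.sorts.shape[1]

    @property
    def participant_ids(self) -> list[str]:
        return [str(c) for c in self.sorts.columns]

    @property
    def values(self) -> np.ndarray:
        """Rank matrix as (n_statements, n_participants) int array, id-ordered."""
        return self.sorts.sort_index().to_numpy()

    def column(self, participant_id: str) -> pd.Series:
        return self.sorts[participant_id]

    def qsort(self, participant_id: str) -> QSort:
        col = self.sorts[participant_id]
        return QSort(str(participant_id), {int(i): int(v) for i, v in col.items()})

    def statement_text(self, statement_id: int) -> str:
        return self.statements[statement_id - 1].text


def validate_sort(ranks: dict[int, int], grid: GridSpec, n_statements: int, participant_id: str) -> list[Violation]:
    """Check one sort against coverage and capacity; returns violation records."""
    out: list[Violation] = []
    seen: set[int] = set()
    for sid in ranks:
        if sid < 1 or sid > n_statements:
            out.append(Violation(participant_id, "unknown_statement", statement_id=sid))
        elif sid in seen:
            out.append(Violation(participant_id, "duplicate_statement", statement_id=sid))
        seen.add(sid)
    for sid in range(1, n_statements + 1):
        if sid not in ranks:
            out.append(Violation(participant_id, "missing_statement", statement_id=sid))
    counts: dict[int, int] = {}
    for sid, r in ranks.items():
        if 1 <= sid <= n_statements:
            counts[r] = counts.get(r, 0) + 1
    for r in sorted(set(grid.ranks) | set(counts)):
        expected = grid.capacity.get(r, 0)
        observed = counts.get(r, 0)
        if expected != observed:
            out.append(
                Violation(participant_id, "capacity", rank=r, expected_count=expected, observed_count=observed)
            )
    return out


def validate_panel(panel: QSortPanel) -> ValidationReport:
    """Validate every column of a panel against its grid.

    The outcome is invariant under column permutation: each participant
    is checked independently.
    """
    violations: list[Violation] = []
    n = panel.n_statements
    for pid in panel.participant_ids:
        ranks = {int(i): int(v) for i, v in panel.sorts[pid].items()}
        violations.extend(validate_sort(ranks, panel.grid, n, str(pid)))
    return ValidationReport(tuple(violations))
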