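"""The packaged health-perceptions Q-study instrument and results.

Bundled with the package: the 42-statement Q-sample on what matters
when judging a person's health, the −5..+5 forced grid (capacities
1,2,3,5,6,8,6,5,3,2,1), the five published factor arrays, and the
sample/exemplar demographic counts (110 participants; factor exemplar
counts 19/25/16/6/4).  The grid capacities are derived by counting rank
frequencies in the published factor arrays, which agree across all five
factors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .grid import GridSpec, derive_grid
from .panel import ParticipantMeta, Statement

CONDITION_OF_INSTRUCTION = (
    "When judging a person's health, how important is it to know about their ___?"
)


def _data_path(name: str):
    return resources.files("qmethod.data").joinpath(name)


@dataclass
class StudyFixture:
    """Instrument plus published summary tables, validated on load."""

    statements: list[Statement]
    grid: GridSpec
    factor_arrays: pd.DataFrame          # 42 × 5 integer ranks
    sample_counts: dict                  # whole-sample demographics
    exemplar_counts: dict                # per-factor exemplar demographics

    @property
    def n_statements(self) -> int:
        return len(self.statements)

    @property
    def n_factors(self) -> int:
        return self.factor_arrays.shape[1]

    @property
    def factor_n(self) -> list[int]:
        return list(self.exemplar_counts["factor_n"])


def load_fixture() -> StudyFixture:
    """Load and cross-validate the packaged study data.

    Checks: 42 uniquely numbered statements; each factor-array column
    independently re-derives the same grid; demographic blocks sum to
    the participant total (less recorded non-responses) and, per
    factor, to that factor's exemplar count.
    """
    stmts_df = pd.read_csv(_data_path("statements.csv"))
    statements = [Statement(int(r.id), str(r.text)) for r in stmts_df.itertuples()]

    arrays = pd.read_csv(_data_path("factor_arrays.csv"), index_col="statement_id").astype(int)
    grid = GridSpec.from_json(_data_path("grid.json").read_text(encoding="utf-8"))

    for col in arrays.columns:
        if derive_grid(arrays[col]).capacity != grid.capacity:
            raise AssertionError(f"fixture column {col} does not conform to the packaged grid")
    if len(statements) != grid.n_statements or list(arrays.index) != [s.id for s in statements]:
        raise AssertionError("fixture statements, grid and arrays are inconsistent")

    sample = json.loads(_data_path("table1_counts.json").read_text(encoding="utf-8"))
    total = sample["total"]
    for block, counts in sample["blocks"].items():
        s = sum(counts.values())
        if s not in (total, total - 1):
            raise AssertionError(f"sample block {block!r} sums to {s}, expected {total} or {total - 1}")

    exemplars = json.loads(_data_path("table3_counts.json").read_text(encoding="utf-8"))
    factor_n = exemplars["factor_n"]
    for block, counts in exemplars["blocks"].items():
        for j, n in enumerate(factor_n):
            s = sum(v[j] for v in counts.values())
            if s not in (n, n - 1):
                raise AssertionError(
                    f"exemplar block {block!r} factor {j + 1} sums to {s}, expected {n} or {n - 1}"
                )
    return StudyFixture(statements, grid, arrays, sample, exemplars)


# ---------------------------------------------------------------------------
# sample summaries
# ---------------------------------------------------------------------------

def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (52% not 51%)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_counts(counts: dict[str, int], total: int) -> dict[str, tuple[int, int]]:
    """category → (count, integer percent of ``total``)."""
    return {cat: (n, round_half_away(100.0 * n / total)) for cat, n in counts.items()}


# Category bands used in the published sample table.  Band edges follow
# the table's labels: 40-60 is [40, 60), 60-80 is [60, 80).
AGE_BANDS = [("< 40", 0, 40), ("40-60", 40, 60), ("60+", 60, math.inf)]
VAS_BANDS = [("80-100", 80, 101), ("60-80", 60, 80), ("< 60", 0, 60)]
EQ5D_NAMED = ("11111", "11112", "11121", "11122")


def _band(value: float, bands) -> str:
    for label, lo, hi in bands:
        if lo <= value < hi:
            return label
    return "Other"


def summarize_sample(
    meta: list[ParticipantMeta],
    known: dict[str, list[str]] | None = None,
) -> dict[str, dict[str, tuple[int, int]]]:
    """Tabulate a metadata list into count-and-percent blocks.

    Percentages use the full participant count as denominator, rounding
    half away from zero; missing values are kept out of every block but
    still count toward the denominator.  Category values outside the
    expected set are collected under "Other".
    """
    if not meta:
        raise ValueError("metadata list is empty")
    total = len(meta)
    known = known or {}

    def collect(values: list[str | None], expected: list[str] | None) -> dict[str, int]:
        counts: dict[str, int] = {}
        for v in values:
            if v is None:
                continue
            cat = v if (expected is None or v in expected) else "Other"
            counts[cat] = counts.get(cat, 0) + 1
        return counts

    blocks: dict[str, dict[str, int]] = {
        "gender": collect([m.gender for m in meta], known.get("gender")),
        "age": collect(
            [None if m.age is None else _band(m.age, AGE_BANDS) for m in meta], None
        ),
        "education": collect([m.education for m in meta], known.get("education")),
        "eq5d_profile": collect(
            [
                None if m.eq5d_profile is None
                else (m.eq5d_profile if m.eq5d_profile in EQ5D_NAMED else "Other")
                for m in meta
            ],
            None,
        ),
        "vas": collect([None if m.vas is None else _band(m.vas, VAS_BANDS) for m in meta], None),
        "residence": collect([m.residence for m in meta], known.get("residence")),
        "region": collect([m.region for m in meta], known.get("region")),
    }
    return {name: summarize_counts(c, total) for name, c in blocks.items() if c}


def sample_metadata_from_counts(fixture: StudyFixture | None = None) -> list[ParticipantMeta]:
    """Synthesize a participant list whose marginals reproduce the sample table.

    Each demographic block is expanded independently into a column of
    category labels (padded with None for recorded non-responses) and
    the columns are zipped positionally, so joint distributions are
    arbitrary but every marginal matches the published counts.  Ages
    and VAS scores are placed at band interiors.
    """
    fx = fixture or load_fixture()
    blocks = fx.sample_counts["blocks"]
    total = fx.sample_counts["total"]

    def expand(counts: dict[str, int], mapper=lambda c: c) -> list:
        col: list = []
        for cat, n in counts.items():
            col.extend([mapper(cat)] * n)
        col.extend([None] * (total - len(col)))
        return col

    age_mid = {"< 40": 30.0, "40-60": 50.0, "60+": 70.0}
    vas_mid = {"80-100": 90.0, "60-80": 70.0, "< 60": 50.0}
    eq5d_other = "21111"  # any non-ceiling profile stands in for "Other"

    cols = {
        "gender": expand(blocks["gender"]),
        "age": expand(blocks["age"], lambda c: age_mid[c]),
        "education": expand(blocks["education"]),
        "eq5d_profile": expand(
            blocks["eq5d_profile"], lambda c: c if c in EQ5D_NAMED else eq5d_other
        ),
        "vas": expand(blocks["vas"], lambda c: vas_mid[c]),
        "residence": expand(blocks["residence"]),
        "region": expand(blocks["region"]),
    }
    return [
        ParticipantMeta(
            participant_id=f"p{i + 1:03d}",
            gender=cols["gender"][i],
            age=cols["age"][i],
            education=cols["education"][i],
            eq5d_profile=cols["eq5d_profile"][i],
            vas=cols["vas"][i],
            residence=cols["residence"][i],
            region=cols["region"][i],
        )
        for i in range(total)
    ]
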