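"""Markdown report rendering in the layouts of published Q-study tables."""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .factor import FactorSolution
from .panel import ParticipantMeta
from .study import AGE_BANDS, EQ5D_NAMED, VAS_BANDS, _band


def _md_table(df: pd.DataFrame, index_label: str = "") -> str:
    header = [index_label] + [str(c) for c in df.columns]
    lines = ["| " + " | ".join(header) + " |",
             "| " + " | ".join("---" for _ in header) + " |"]
    for idx, row in df.iterrows():
        cells = [str(idx)] + [
            f"{v:.3f}" if isinstance(v, float) else str(v) for v in row
        ]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def exemplar_crosstab(
    meta: list[ParticipantMeta], solution: FactorSolution
) -> pd.DataFrame:
    """Per-factor demographic counts for flagged exemplars.

    Mirrors the published exemplar-demographics layout: one column per
    factor, one row per category, counting only flagged participants.
    """
    by_pid = {m.participant_id: m for m in meta}
    k = solution.k
    cols = [f"F{j + 1}" for j in range(k)]
    members: dict[int, list[ParticipantMeta]] = {j: [] for j in range(k)}
    for f in solution.flags.flags:
        if f.factor is not None and f.participant_id in by_pid:
            members[f.factor].append(by_pid[f.participant_id])

    def block(label: str, getter) -> list[tuple[str, list[int]]]:
        cats: dict[str, list[int]] = {}
        for j in range(k):
            for m in members[j]:
                v = getter(m)
                if v is None:
                    continue
                cats.setdefault(str(v), [0] * k)[j] += 1
        return [(f"{label}: {c}", counts) for c, counts in sorted(cats.items())]

    rows: list[tuple[str, list[int]]] = [("n", [len(members[j]) for j in range(k)])]
    rows += block("Gender", lambda m: m.gender)
    rows += block("Age", lambda m: None if m.age is None else _band(m.age, AGE_BANDS))
    rows += block("Education", lambda m: m.education)
    rows += block(
        "EQ-5D",
        lambda m: None if m.eq5d_profile is None
        else (m.eq5d_profile if m.eq5d_profile in EQ5D_NAMED else "Other"),
    )
    rows += block("VAS", lambda m: None if m.vas is None else _band(m.vas, VAS_BANDS))
    rows += block("Residence", lambda m: m.residence)
    rows += block("Region", lambda m: m.region)
    return pd.DataFrame(
        {label: counts for label, counts in rows}, index=cols
    ).T


def render_report(
    solution: FactorSolution,
    meta: Optional[list[ParticipantMeta]] = None,
    condition_of_instruction: Optional[str] = None,
) -> str:
    """Human-readable markdown report of a full analysis."""
    parts: list[str] = ["# Q-methodology analysis report", ""]
    if condition_of_instruction:
        parts += [f"**Condition of instruction:** {condition_of_instruction}", ""]
    parts += [
        f"Panel: {solution.panel.n_statements} statements × "
        f"{solution.panel.n_participants} participants; "
        f"{solution.k} factor(s) retained ({solution.retention.mode}).",
        "",
        f"Loading threshold: |f| ≥ {solution.threshold:.4f} "
        f"(α = {solution.config.alpha}; rounds to {round(solution.threshold, 1)}).",
        "",
        "## Eigenvalues and explained variance",
        "",
        _md_table(
            solution.scree().head(max(solution.k + 3, 8)).set_index("factor").round(3),
            "factor",
        ),
        "",
        "## Retention decisions",
        "",
    ]
    parts += [f"- {line}" for line in solution.retention.rationale]
    parts += [
        "",
        "## Rotated loadings and flags",
        "",
        _md_table(
            solution.rotated.loadings.round(3).join(
                solution.flags.to_frame()[["factor", "status"]]
                .rename(columns={"factor": "flagged"})
                .fillna("")
            ),
            "participant",
        ),
        "",
        "## Factor arrays",
        "",
    ]
    arrays = solution.arrays.copy()
    arrays.insert(0, "statement", [
        solution.panel.statement_text(int(i)) for i in arrays.index
    ])
    parts += [_md_table(arrays, "id"), ""]
    if len(solution.distinguishing.columns):
        parts += [
            "## Distinguishing and consensus statements",
            "",
            "`**` distinguishes at α = 0.01, `*` at α = 0.05; consensus = ",
            "distinguishes no factor at α = 0.05.",
            "",
            _md_table(solution.distinguishing, "id"),
            "",
        ]
    if meta:
        parts += [
            "## Exemplar demographics by factor",
            "",
            _md_table(exemplar_crosstab(meta, solution), "category"),
            "",
        ]
    return "\n".join(parts)
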