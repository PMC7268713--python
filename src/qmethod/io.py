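"""CSV/JSON readers and writers for panels, metadata and solutions.

All files are UTF-8 comma-separated with a header row.  Typographic
minus signs and dashes (as printed in journal tables) are normalized to
ASCII ``-`` on read; ranks must parse as integers.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional

import pandas as pd

from .grid import GridSpec
from .panel import ParticipantMeta, QSortPanel, Statement, validate_panel

_MINUS = re.compile(r"[−‐‑–—]")  # −, ‐, ‑, –, —


class ParseError(ValueError):
    """Malformed input file: names the offending row/cell."""


class PanelValidationError(ValueError):
    """Structurally parseable panel that violates the grid."""

    def __init__(self, report) -> None:
        lines = [v.describe() for v in report.violations]
        super().__init__("panel fails validation:\n  " + "\n  ".join(lines))
        self.report = report


def _to_int(raw, where: str) -> int:
    s = _MINUS.sub("-", str(raw)).strip()
    try:
        return int(s)
    except (TypeError, ValueError):
        raise ParseError(f"non-integer rank {raw!r} at {where}") from None


def read_panel(
    path: str | Path,
    grid: GridSpec,
    layout: str = "wide",
    statements: Optional[list[Statement]] = None,
    validate: bool = True,
) -> QSortPanel:
    """Read a Q-sort panel from CSV.

    ``wide`` layout: first column ``statement_id``, one further column
    per participant.  ``long`` layout: columns ``participant_id,
    statement_id, rank``.  Column/row order is preserved as read.  With
    ``validate`` (default) the panel must pass grid validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)

    if layout == "wide":
        if df.shape[1] < 2:
            raise ParseError(f"{path.name}: wide panel needs a statement column plus participants")
        sid_col = df.columns[0]
        sids = [_to_int(v, f"{path.name} row {i + 2}, column {sid_col!r}") for i, v in enumerate(df[sid_col])]
        if len(set(sids)) != len(sids):
            dupes = sorted({s for s in sids if sids.count(s) > 1})
            raise ParseError(f"{path.name}: duplicate statement id(s) {dupes}")
        data = {}
        for col in df.columns[1:]:
            vals = []
            for i, v in enumerate(df[col]):
                if str(v).strip() == "":
                    raise ParseError(f"{path.name}: missing cell at row {i + 2}, participant {col!r}")
                vals.append(_to_int(v, f"{path.name} row {i + 2}, participant {col!r}"))
            data[str(col)] = vals
        sorts = pd.DataFrame(data, index=pd.Index(sids, name="statement_id"))
    else:
        needed = {"participant_id", "statement_id", "rank"}
        if not needed.issubset(df.columns):
            raise ParseError(f"{path.name}: long panel needs columns {sorted(needed)}")
        seen: set[tuple[str, int]] = set()
        records: dict[str, dict[int, int]] = {}
        order: list[str] = []
        for i, row in df.iterrows():
            where = f"{path.name} row {i + 2}"
            pid = str(row["participant_id"]).strip()
            if not pid:
                raise ParseError(f"{where}: empty participant_id")
            sid = _to_int(row["statement_id"], where)
            if (pid, sid) in seen:
                raise ParseError(f"{where}: duplicate entry for participant {pid!r}, statement {sid}")
            seen.add((pid, sid))
            if str(row["rank"]).strip() == "":
                raise ParseError(f"{where}: missing rank")
            if pid not in records:
                records[pid] = {}
                order.append(pid)
            records[pid][sid] = _to_int(row["rank"], where)
        all_sids = sorted({s for r in records.values() for s in r})
        for pid, r in records.items():
            missing = [s for s in all_sids if s not in r]
            if missing:
                raise ParseError(f"{path.name}: participant {pid!r} missing statement(s) {missing}")
        sorts = pd.DataFrame(
            {pid: [records[pid][s] for s in all_sids] for pid in order},
            index=pd.Index(all_sids, name="statement_id"),
        )

    panel = QSortPanel(sorts, grid, statements)
    if validate:
        report = validate_panel(panel)
        if not report.ok:
            raise PanelValidationError(report)
    return panel


def write_panel(panel: QSortPanel, path: str | Path) -> Path:
    """Write a panel in wide layout."""
    path = Path(path)
    out = panel.sorts.sort_index()
    out.index.name = "statement_id"
    out.to_csv(path)
    return path


def read_metadata(path: str | Path) -> list[ParticipantMeta]:
    """Read a participant-metadata CSV (missing cells allowed)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "participant_id" not in df.columns:
        raise ParseError(f"{Path(path).name}: metadata needs a participant_id column")

    def _opt(row, col):
        v = str(row.get(col, "")).strip()
        return v or None

    out = []
    for _, row in df.iterrows():
        age = _opt(row, "age")
        vas = _opt(row, "vas")
        out.append(
            ParticipantMeta(
                participant_id=str(row["participant_id"]),
                gender=_opt(row, "gender"),
                age=float(_MINUS.sub("-", age)) if age is not None else None,
                education=_opt(row, "education"),
                eq5d_profile=_opt(row, "eq5d_profile"),
                vas=float(vas) if vas is not None else None,
                residence=_opt(row, "residence"),
                region=_opt(row, "region"),
            )
        )
    return out


def read_arrays(path: str | Path) -> pd.DataFrame:
    """Read a factor-array CSV (statement_id index, one column per factor)."""
    df = pd.read_csv(path, index_col="statement_id")
    return df.astype(int)


def write_solution(solution, out_dir: str | Path) -> dict[str, Path]:
    """Write a FactorSolution to loadings.csv, arrays.csv, eigen.csv, solution.json.

    arrays.csv round-trips bit-exactly through :func:`read_arrays`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    loadings = solution.rotated.loadings.copy()
    flag_frame = solution.flags.to_frame()
    loadings["flagged_factor"] = [
        "" if pd.isna(f) else f"F{int(f)}{'-' if s < 0 else ''}"
        for f, s in zip(flag_frame["factor"], flag_frame["sign"])
    ]
    loadings["status"] = flag_frame["status"]
    loadings.index.name = "participant_id"
    paths["loadings"] = out / "loadings.csv"
    loadings.to_csv(paths["loadings"], float_format="%.6f")

    paths["arrays"] = out / "arrays.csv"
    solution.arrays.to_csv(paths["arrays"])

    paths["eigen"] = out / "eigen.csv"
    solution.scree().to_csv(paths["eigen"], index=False, float_format="%.6f")

    zs = solution.scores.zscores.copy()
    zs.index.name = "statement_id"
    paths["zscores"] = out / "zscores.csv"
    zs.to_csv(paths["zscores"], float_format="%.6f")

    if len(solution.distinguishing.columns):
        paths["distinguishing"] = out / "distinguishing.csv"
        solution.distinguishing.to_csv(paths["distinguishing"])

    meta = {
        "config": solution.config.to_dict(),
        "k_retained": solution.k,
        "retention_mode": solution.retention.mode,
        "retention_rationale": solution.retention.rationale,
        "loading_threshold": solution.threshold,
        "exemplar_counts": solution.scores.exemplar_counts,
        "rotation": {
            "converged": solution.rotated.converged,
            "n_sweeps": solution.rotated.n_sweeps,
            "criterion": solution.rotated.criterion,
            "kaiser_normalized": solution.rotated.kaiser_normalized,
        },
        "grid": {str(r): c for r, c in solution.panel.grid.capacity.items()},
        "n_participants": solution.panel.n_participants,
        "n_statements": solution.panel.n_statements,
    }
    paths["solution"] = out / "solution.json"
    paths["solution"].write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")
    return paths
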