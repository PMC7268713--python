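"""By-person factor analysis of Q-sort panels.

The pipeline follows standard Q-methodology practice: correlate the
sorts person-by-person, extract principal components of the by-person
correlation matrix, retain factors by the eigenvalue-greater-than-one
and two-exemplar rules, rotate with Varimax, flag pure significant
loaders, estimate weighted factor z-scores from the flagged exemplars,
and quantize the z-scores back onto the forced grid to obtain one
"ideal" sort (factor array) per factor.  Distinguishing and consensus
statements are classified with the standard-error-of-differences test.

Notation: P participants, S statements, k retained factors.  Loadings
are P×k; a participant's communality h² is the row sum of squared
loadings and is invariant under orthogonal rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .grid import GridSpec
from .panel import QSortPanel

# Conventional two-tailed normal deviates used throughout Q methodology.
Z_CRIT = {0.05: 1.96, 0.01: 2.58}

# Assumed reliability of a single Q-sort, used in composite reliability.
SORT_RELIABILITY = 0.80

# |loading| is clamped below 1 before weighting to keep w = f/(1-f²) finite.
LOADING_CLAMP = 0.999


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot produce a valid result."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def correlate(panel: QSortPanel, method: str = "pearson") -> pd.DataFrame:
    """By-person correlation matrix of the panel's sorts.

    Under a shared forced grid all sorts have identical mean and
    variance, so Pearson correlation reduces to a scaled inner product
    of the rank vectors; Spearman is offered for consistency with
    non-parametric reporting.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if panel.n_participants < 2:
        raise PipelineError("correlate", "need at least two sorts to correlate")
    X = panel.values.astype(float)
    if np.any(X.std(axis=0) == 0):
        raise PipelineError("correlate", "zero-variance sort (degenerate one-rank grid)")
    if method == "pearson":
        R = np.corrcoef(X, rowvar=False)
    else:
        rho = spearmanr(X).statistic
        if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
            R = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        else:
            R = np.asarray(rho)
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    ids = panel.participant_ids
    out = pd.DataFrame(R, index=ids, columns=ids)
    out.attrs["method"] = method
    return out


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

@dataclass
class Extraction:
    """Principal-component extraction of a by-person correlation matrix.

    ``eigenvalues`` holds the full spectrum (length P, descending); the
    loading matrix keeps only the first ``m`` columns, scaled so column
    j has squared norm equal to eigenvalue j.
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # P × m
    n_participants: int

    @property
    def pct_variance(self) -> np.ndarray:
        """Per-factor explained variance, percent of total (= 100·λ/P)."""
        return 100.0 * self.eigenvalues / self.n_participants


def _fix_column_signs(L: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    Makes solutions reproducible across linear-algebra backends, where
    eigenvector signs are otherwise arbitrary.
    """
    L = L.copy()
    for j in range(L.shape[1]):
        col = L[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            L[:, j] = -col
    return L


def pca_extract(corr: pd.DataFrame, m: Optional[int] = None, tol: float = 1e-8) -> Extraction:
    """Eigendecomposition of the correlation matrix, top-``m`` loadings.

    Column j of the loadings is eigenvector j scaled by sqrt(λ_j), with
    the sign convention of :func:`_fix_column_signs`.  The full spectrum
    is retained so trace conservation (Σλ = P) can always be checked.
    """
    R = np.asarray(corr, dtype=float)
    P = R.shape[0]
    if R.shape != (P, P) or not np.allclose(R, R.T, atol=1e-6):
        raise PipelineError("pca_extract", "correlation matrix is not symmetric")
    if m is None:
        m = min(8, P - 1) if P > 1 else 1
    if not 1 <= m <= P:
        raise ValueError(f"m must be in 1..{P}, got {m}")
    eigval, eigvec = np.linalg.eigh((R + R.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval[-1] < -1e-6:
        raise PipelineError("pca_extract", f"matrix is not PSD (min eigenvalue {eigval[-1]:.3g})")
    eigval = np.clip(eigval, 0.0, None)
    L = _fix_column_signs(eigvec[:, :m] * np.sqrt(eigval[:m]))
    ids = list(corr.index) if isinstance(corr, pd.DataFrame) else list(range(P))
    cols = [f"F{j + 1}" for j in range(m)]
    return Extraction(eigval, pd.DataFrame(L, index=ids, columns=cols), P)


def eigenvalue_from_pct(pct: float, n_sorts: int) -> float:
    """Eigenvalue implied by a percent-of-variance figure: λ = pct·P/100."""
    if not 0 <= pct <= 100:
        raise ValueError(f"percentage {pct} outside [0, 100]")
    if n_sorts < 1:
        raise ValueError("n_sorts must be >= 1")
    return pct * n_sorts / 100.0


def pct_from_eigenvalue(eigenvalue: float, n_sorts: int) -> float:
    """Exact inverse of :func:`eigenvalue_from_pct`."""
    if n_sorts < 1:
        raise ValueError("n_sorts must be >= 1")
    return eigenvalue * 100.0 / n_sorts


def scree_table(eigenvalues: Sequence[float], n_sorts: Optional[int] = None) -> pd.DataFrame:
    """Advisory scree table: eigenvalue, percent variance, cumulative percent.

    No automatic elbow detection is attempted; retention uses the
    explicit rules in :func:`retain_factors`.
    """
    ev = np.asarray(list(eigenvalues), dtype=float)
    if np.any(np.diff(ev) > 1e-12):
        raise ValueError("eigenvalues must be descending")
    P = n_sorts if n_sorts is not None else len(ev)
    pct = 100.0 * ev / P
    return pd.DataFrame(
        {
            "factor": np.arange(1, len(ev) + 1),
            "eigenvalue": ev,
            "pct_variance": pct,
            "cumulative_pct": np.cumsum(pct),
        }
    )


# ---------------------------------------------------------------------------
# rotation
# ---------------------------------------------------------------------------

def varimax_criterion(L: np.ndarray) -> float:
    """Raw varimax objective: Σ_j var over rows of squared loadings."""
    sq = np.asarray(L, dtype=float) ** 2
    return float(np.sum(sq.var(axis=0)))


@dataclass
class RotatedLoadings:
    loadings: pd.DataFrame              # P × k
    rotation: np.ndarray                # k × k orthonormal
    kaiser_normalized: bool
    converged: bool
    n_sweeps: int
    criterion: float

    @property
    def communalities(self) -> pd.Series:
        sq = self.loadings.to_numpy() ** 2
        return pd.Series(sq.sum(axis=1), index=self.loadings.index, name="h2")


def _pairwise_sweep(L: np.ndarray, p: int, q: int) -> float:
    """Rotate columns (p, q) in place by the closed-form optimal angle.

    The per-pair angle maximizing the varimax criterion has the classic
    closed form tan(4φ) = (D − 2AB/n)/(C − (A² − B²)/n) with
    u = x² − y², v = 2xy (Kaiser's planar solution).  Returns φ.
    """
    x, y = L[:, p], L[:, q]
    u = x**2 - y**2
    v = 2.0 * x * y
    n = L.shape[0]
    A, B = u.sum(), v.sum()
    C, D = (u**2 - v**2).sum(), (2.0 * u * v).sum()
    num = D - 2.0 * A * B / n
    den = C - (A**2 - B**2) / n
    phi = 0.25 * np.arctan2(num, den)
    c, s = np.cos(phi), np.sin(phi)
    L[:, p], L[:, q] = c * x + s * y, -s * x + c * y
    return float(phi)


def varimax(
    loadings: pd.DataFrame | np.ndarray,
    kaiser: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> RotatedLoadings:
    """Varimax rotation by cyclic pairwise sweeps.

    Kaiser normalization (default on, matching common factor-analysis
    software) divides each row by its communality sqrt before rotation
    and restores the scale afterwards; rows with zero communality pass
    through unscaled.  Sweeps continue until the criterion improves by
    less than ``tol``; non-convergence within ``max_iter`` sweeps is
    recorded (and warned about), not fatal.

    After convergence columns are reordered by explained variance
    (descending) and signed so each column's largest-magnitude entry is
    positive; the returned rotation matrix includes that permutation,
    so ``rotated = unrotated @ rotation`` always holds.
    """
    if isinstance(loadings, pd.DataFrame):
        index, columns = loadings.index, list(loadings.columns)
        L0 = loadings.to_numpy(dtype=float)
    else:
        L0 = np.asarray(loadings, dtype=float)
        index = pd.RangeIndex(L0.shape[0])
        columns = [f"F{j + 1}" for j in range(L0.shape[1])]
    P, k = L0.shape
    if k == 1:
        return RotatedLoadings(
            pd.DataFrame(L0.copy(), index=index, columns=columns),
            np.eye(1), kaiser, True, 0, varimax_criterion(L0),
        )

    h = np.sqrt((L0**2).sum(axis=1))
    scale = np.where(h > 0, h, 1.0) if kaiser else np.ones(P)
    W = L0 / scale[:, None]

    R = np.eye(k)
    crit = varimax_criterion(W)
    converged = False
    sweeps = 0
    for sweeps in range(1, max_iter + 1):
        for p in range(k - 1):
            for q in range(p + 1, k):
                phi = _pairwise_sweep(W, p, q)
                c, s = np.cos(phi), np.sin(phi)
                rp, rq = R[:, p].copy(), R[:, q].copy()
                R[:, p], R[:, q] = c * rp + s * rq, -s * rp + c * rq
        new_crit = varimax_criterion(W)
        gain = new_crit - crit
        crit = new_crit
        if gain < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"varimax did not converge in {max_iter} sweeps", RuntimeWarning)

    L = W * scale[:, None]
    # Order columns by explained variance, fix signs; fold both into R.
    ss = (L**2).sum(axis=0)
    order = np.argsort(-ss, kind="stable")
    L, R = L[:, order], R[:, order]
    signs = np.ones(k)
    for j in range(k):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            signs[j] = -1.0
    L, R = L * signs, R * signs
    return RotatedLoadings(
        pd.DataFrame(L, index=index, columns=[f"F{j + 1}" for j in range(k)]),
        R, kaiser, converged, sweeps, varimax_criterion(L),
    )


# ---------------------------------------------------------------------------
# flagging
# ---------------------------------------------------------------------------

def loading_threshold(n_statements: int, alpha: float = 0.01) -> float:
    """Significance threshold for a loading: z_α / sqrt(S).

    The standard error of a zero loading is taken as 1/sqrt(S) (the
    Q-methodology convention), so with 42 statements and α = 0.01 the
    threshold is 2.58/√42 ≈ 0.398 — the value usually quoted as 0.4.
    The raw (unrounded) value is returned.
    """
    if n_statements < 2:
        raise ValueError("need at least two statements")
    if alpha not in Z_CRIT:
        raise ValueError(f"alpha must be one of {sorted(Z_CRIT)}, got {alpha}")
    return Z_CRIT[alpha] / np.sqrt(n_statements)


@dataclass(frozen=True)
class Flag:
    participant_id: str
    factor: Optional[int]    # 0-based factor index, None if unflagged
    sign: int                # +1 / -1 (0 when unflagged)
    loading: float           # loading on the flagged factor (0.0 when unflagged)
    status: str              # "flagged" | "confounded" | "non-significant"


@dataclass
class FlagSet:
    flags: list[Flag]
    threshold: float
    rule: str  # "pure" | "pqmethod"

    def flagged(self, factor: int, sign: Optional[int] = None) -> list[Flag]:
        out = [f for f in self.flags if f.factor == factor]
        if sign is not None:
            out = [f for f in out if f.sign == sign]
        return out

    def counts(self, k: int) -> list[int]:
        return [len(self.flagged(j)) for j in range(k)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [f.participant_id for f in self.flags],
                "factor": [None if f.factor is None else f.factor + 1 for f in self.flags],
                "sign": [f.sign for f in self.flags],
                "loading": [f.loading for f in self.flags],
                "status": [f.status for f in self.flags],
            }
        ).set_index("participant_id")


def flag_exemplars(rotated: RotatedLoadings, threshold: float, rule: str = "pure") -> FlagSet:
    """Identify exemplars: sorts that define exactly one factor.

    ``rule="pure"`` flags a participant on factor j iff |loading_j| ≥
    threshold while every other |loading| stays below it.  Participants
    significant on two or more factors are confounded; significant on
    none, non-significant — neither is flagged, and neither contributes
    to factor scores.  ``rule="pqmethod"`` additionally requires the
    squared loading to exceed half the communality (a² > h²/2), the
    auto-flagging heuristic of the PQMethod program.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if rule not in ("pure", "pqmethod"):
        raise ValueError(f"unknown flagging rule {rule!r}")
    L = rotated.loadings
    flags: list[Flag] = []
    for pid, row in zip(L.index, L.to_numpy()):
        above = np.abs(row) >= threshold
        n_above = int(above.sum())
        if n_above == 1:
            j = int(np.argmax(above))
            ok = True
            if rule == "pqmethod":
                ok = row[j] ** 2 > (row**2).sum() / 2.0
            if ok:
                flags.append(Flag(str(pid), j, int(np.sign(row[j])), float(row[j]), "flagged"))
                continue
            flags.append(Flag(str(pid), None, 0, 0.0, "non-significant"))
        elif n_above > 1:
            flags.append(Flag(str(pid), None, 0, 0.0, "confounded"))
        else:
            flags.append(Flag(str(pid), None, 0, 0.0, "non-significant"))
    return FlagSet(flags, threshold, rule)


# ---------------------------------------------------------------------------
# retention
# ---------------------------------------------------------------------------

@dataclass
class Retention:
    k: int
    rationale: list[str]
    mode: str  # "auto" | "fixed"


def retain_factors(
    extraction: Extraction,
    threshold: float,
    max_k: Optional[int] = None,
    kaiser: bool = True,
    flag_rule: str = "pure",
) -> Retention:
    """Choose how many leading factors to retain.

    A candidate count k is admissible when, after Varimax-rotating the
    k leading components, every one of them has eigenvalue > 1.00 and
    at least two significantly loading exemplars.  The largest
    admissible k wins; the rationale records which rule rejected each
    larger candidate.
    """
    ev = extraction.eigenvalues
    m = extraction.loadings.shape[1]
    if max_k is None:
        max_k = m
    max_k = min(max_k, m)
    rationale: list[str] = []

    n_eig = int(np.sum(ev[:max_k] > 1.0))
    if n_eig < max_k:
        rationale.append(
            f"eigenvalue rule: only the {n_eig} leading eigenvalues exceed 1.00 "
            f"(candidate {n_eig + 1} has {ev[n_eig]:.3f})"
        )
    for k in range(min(n_eig, max_k), 0, -1):
        rot = varimax(extraction.loadings.iloc[:, :k], kaiser=kaiser)
        counts = flag_exemplars(rot, threshold, rule=flag_rule).counts(k)
        weak = [j + 1 for j, c in enumerate(counts) if c < 2]
        if not weak:
            rationale.append(
                f"retained k={k}: eigenvalues all > 1.00 and exemplar counts {counts} all >= 2"
            )
            return Retention(k, rationale, "auto")
        rationale.append(
            f"rejected k={k}: factor(s) {weak} have fewer than two pure significant loaders "
            f"(counts {counts})"
        )
    raise PipelineError(
        "retain_factors",
        "no factor satisfies both retention rules (eigenvalue > 1.00 and two exemplars); "
        "inspect the scree table and loadings manually. " + " / ".join(rationale),
    )


# ---------------------------------------------------------------------------
# factor scores and arrays
# ---------------------------------------------------------------------------

def factor_weights(loading: float | np.ndarray) -> np.ndarray | float:
    """Exemplar weight w = f/(1 − f²) (Spearman weighting).

    Higher-loading sorts count more toward the factor estimate; the
    weight's sign follows the loading's.  |f| is clamped to 0.999 so
    the weight stays finite for (near-)perfect loadings.
    """
    f = np.clip(np.asarray(loading, dtype=float), -LOADING_CLAMP, LOADING_CLAMP)
    w = f / (1.0 - f**2)
    return float(w) if np.isscalar(loading) or np.ndim(loading) == 0 else w


@dataclass
class FactorScores:
    """Per-factor statement z-scores estimated from flagged exemplars."""

    zscores: pd.DataFrame        # S × k, each column mean 0 sd 1
    exemplar_counts: list[int]   # sorts merged into each factor (p_f)
    weights: list[dict[str, float]]  # per factor: participant -> weight


def factor_zscores(panel: QSortPanel, flags: FlagSet, k: int, bipolar: str = "exclude") -> FactorScores:
    """Weighted-exemplar estimate of each factor's statement scores.

    For factor j the raw score of statement s is Σ_i w_i · rank_{s,i}
    over the flagged sorts i, with w = f/(1−f²); z-scores standardize
    the raw scores across the S statements.  Negative loaders are
    excluded by default; with ``bipolar="include"`` their sorts enter
    rank-negated (the mirrored viewpoint expressed on a symmetric grid).
    """
    if bipolar not in ("exclude", "include"):
        raise ValueError(f"bipolar must be 'exclude' or 'include', got {bipolar!r}")
    S = panel.n_statements
    ids = [s.id for s in panel.statements]
    Z = np.empty((S, k))
    counts: list[int] = []
    weights: list[dict[str, float]] = []
    X = panel.sorts.sort_index()
    for j in range(k):
        members = flags.flagged(j)
        used: list[tuple[str, float, int]] = []
        for f in members:
            if f.sign < 0 and bipolar == "exclude":
                continue
            used.append((f.participant_id, abs(float(factor_weights(f.loading))), f.sign))
        if not used:
            raise PipelineError(
                "factor_zscores",
                f"factor {j + 1} has no included exemplars "
                f"({len(members)} flagged, negative loaders excluded)",
            )
        raw = np.zeros(S)
        wmap: dict[str, float] = {}
        for pid, w, sign in used:
            col = X[pid].to_numpy(dtype=float)
            raw += w * (sign * col if bipolar == "include" else col)
            wmap[pid] = sign * w
        sd = raw.std()
        if sd == 0:
            raise PipelineError("factor_zscores", f"factor {j + 1} raw scores are constant")
        Z[:, j] = (raw - raw.mean()) / sd
        counts.append(len(used))
        weights.append(wmap)
    zf = pd.DataFrame(Z, index=pd.Index(ids, name="statement_id"),
                      columns=[f"F{j + 1}" for j in range(k)])
    return FactorScores(zf, counts, weights)


def quantize_to_array(zscores: pd.Series | np.ndarray, grid: GridSpec) -> pd.Series:
    """Fill z-ordered statements onto the grid to form a factor array.

    Statements are sorted by z descending and assigned ranks from r_max
    downward, each rank taking exactly its capacity.  Exact z ties are
    broken by ascending statement id: the lower id receives the higher
    rank.  The result always conforms to the grid.
    """
    if isinstance(zscores, pd.Series):
        ids = [int(i) for i in zscores.index]
        z = zscores.to_numpy(dtype=float)
    else:
        z = np.asarray(zscores, dtype=float)
        ids = list(range(1, len(z) + 1))
    if len(z) != grid.n_statements:
        raise ValueError(f"{len(z)} z-scores for a grid of {grid.n_statements} statements")
    order = sorted(range(len(z)), key=lambda i: (-z[i], ids[i]))
    ranks = {}
    pos = 0
    for r in reversed(grid.ranks):
        for _ in range(grid.capacity[r]):
            ranks[ids[order[pos]]] = r
            pos += 1
    out = pd.Series({i: ranks[i] for i in ids}, name="rank")
    out.index.name = "statement_id"
    return out.astype(int)


# ---------------------------------------------------------------------------
# distinguishing / consensus statements
# ---------------------------------------------------------------------------

def composite_reliability(p: int, r0: float = SORT_RELIABILITY) -> float:
    """Spearman-Brown composite reliability of a p-exemplar factor."""
    if p < 1:
        raise ValueError("factor must have at least one exemplar")
    return r0 * p / (1.0 + (p - 1) * r0)


def factor_se(p: int, r0: float = SORT_RELIABILITY) -> float:
    """Standard error of a factor's z-scores: sqrt(1 − reliability)."""
    return float(np.sqrt(1.0 - composite_reliability(p, r0)))


def distinguish_statements(scores: FactorScores, alpha: float = 0.05) -> pd.DataFrame:
    """Classify statements as distinguishing or consensus across factors.

    For factors f, g the standard error of the difference is
    SED = sqrt(SE_f² + SE_g²) with SE = sqrt(1 − composite reliability).
    A statement distinguishes factor f at level α when |z_f − z_g| >
    z_α · SED for every other factor g.  A consensus statement
    distinguishes no factor at α = 0.05.
    """
    Z = scores.zscores.to_numpy()
    S, k = Z.shape
    if k < 2:
        raise ValueError("distinguishing statements require at least two factors")
    se = np.array([factor_se(p) for p in scores.exemplar_counts])
    sed = np.sqrt(se[:, None] ** 2 + se[None, :] ** 2)
    out: dict[str, list] = {"statement_id": list(scores.zscores.index)}
    dist_at = {}
    for a, zc in Z_CRIT.items():
        dmat = np.zeros((S, k), dtype=bool)
        for f in range(k):
            others = [g for g in range(k) if g != f]
            diffs = np.abs(Z[:, [f]] - Z[:, others])
            dmat[:, f] = np.all(diffs > zc * sed[f, others], axis=1)
        dist_at[a] = dmat
    for f in range(k):
        col = np.full(S, "", dtype=object)
        col[dist_at[0.05][:, f]] = "*"
        col[dist_at[0.01][:, f]] = "**"
        out[f"distinguishes_F{f + 1}"] = list(col)
    out["consensus"] = list(~dist_at[0.05].any(axis=1))
    return pd.DataFrame(out).set_index("statement_id")


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every knob of the analysis, echoed verbatim into outputs."""

    corr_method: str = "pearson"
    n_extract: Optional[int] = None       # default min(8, P-1)
    alpha: float = 0.01                   # flagging significance level
    retention: str | int = "auto"         # "auto" or a fixed k
    kaiser: bool = True
    bipolar: str = "exclude"              # negative exemplars: exclude | include
    flag_rule: str = "pure"               # pure | pqmethod
    distinguish_alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "corr_method": self.corr_method,
            "n_extract": self.n_extract,
            "alpha": self.alpha,
            "retention": self.retention,
            "kaiser": self.kaiser,
            "bipolar": self.bipolar,
            "flag_rule": self.flag_rule,
            "distinguish_alpha": self.distinguish_alpha,
        }


@dataclass
class FactorSolution:
    """Complete record of one analysis run."""

    panel: QSortPanel
    config: PipelineConfig
    correlation: pd.DataFrame
    extraction: Extraction
    retention: Retention
    rotated: RotatedLoadings
    flags: FlagSet
    scores: FactorScores
    arrays: pd.DataFrame              # S × k integer ranks
    distinguishing: pd.DataFrame
    threshold: float

    @property
    def k(self) -> int:
        return self.retention.k

    def scree(self) -> pd.DataFrame:
        return scree_table(self.extraction.eigenvalues, self.extraction.n_participants)


def run_pipeline(panel: QSortPanel, config: Optional[PipelineConfig] = None) -> FactorSolution:
    """Correlate → extract → retain → rotate → flag → score → quantize → compare."""
    cfg = config or PipelineConfig()
    corr = correlate(panel, cfg.corr_method)
    extraction = pca_extract(corr, cfg.n_extract)
    threshold = loading_threshold(panel.n_statements, cfg.alpha)

    if cfg.retention == "auto":
        retention = retain_factors(
            extraction, threshold, kaiser=cfg.kaiser, flag_rule=cfg.flag_rule
        )
    else:
        k = int(cfg.retention)
        if not 1 <= k <= extraction.loadings.shape[1]:
            raise PipelineError("retain_factors", f"fixed k={k} outside 1..{extraction.loadings.shape[1]}")
        retention = Retention(k, [f"fixed by configuration: k={k}"], "fixed")
    k = retention.k

    rotated = varimax(extraction.loadings.iloc[:, :k], kaiser=cfg.kaiser)
    flags = flag_exemplars(rotated, threshold, rule=cfg.flag_rule)
    if retention.mode == "fixed":
        empty = [j + 1 for j in range(k) if not any(
            f.sign > 0 or cfg.bipolar == "include" for f in flags.flagged(j)
        )]
        if empty:
            raise PipelineError(
                "flag_exemplars",
                f"fixed k={k} requested but factor(s) {empty} have no usable exemplars",
            )
    scores = factor_zscores(panel, flags, k, bipolar=cfg.bipolar)
    arrays = pd.DataFrame(
        {f"F{j + 1}": quantize_to_array(scores.zscores.iloc[:, j], panel.grid) for j in range(k)}
    )
    arrays.index.name = "statement_id"
    distinguishing = distinguish_statements(scores) if k >= 2 else pd.DataFrame(
        index=scores.zscores.index
    )
    return FactorSolution(
        panel, cfg, corr, extraction, retention, rotated, flags, scores,
        arrays, distinguishing, threshold,
    )
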