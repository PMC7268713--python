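"""Synthetic Q-sort panels with known latent structure.

The generator emulates the statistical shape of a Q study: K latent
viewpoints, each a grid-conforming prototype array; participants are
noisy realizations of one prototype (pure loaders), 50/50 mixtures of
two prototypes (confounded), or rank-negations (negative loaders).
Noise is added on the standardized rank scale and the perturbed scores
are re-quantized onto the grid, so every simulated sort is valid by
construction and ``noise_sd`` has one interpretable unit (fractions of
a sort's own standard deviation).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .factor import quantize_to_array
from .grid import GridSpec
from .panel import QSortPanel, Statement

REJECTION_BUDGET = 10_000


@dataclass
class SimConfig:
    """Panel-generation settings; the single seed drives all randomness."""

    grid: GridSpec
    K: int = 4
    n_per_factor: list[int] = field(default_factory=lambda: [15, 15, 15, 15])
    noise_sd: float = 1.0
    confounded_frac: float = 0.0
    negative_frac: float = 0.0
    max_pairwise_corr: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if len(self.n_per_factor) != self.K:
            raise ValueError(f"n_per_factor has {len(self.n_per_factor)} entries for K={self.K}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("confounded_frac", "negative_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class Assignment:
    """Ground truth for one participant."""

    participant_id: str
    kind: str                      # "pure" | "confounded" | "negative"
    factor: Optional[int]          # 0-based; None for confounded
    sign: int
    mixture: Optional[tuple[int, int]] = None  # the two mixed factors


@dataclass
class SimTruth:
    prototypes: pd.DataFrame       # S × K integer ranks
    assignments: list[Assignment]

    def pure_map(self) -> dict[str, int]:
        return {a.participant_id: a.factor for a in self.assignments if a.kind == "pure"}

    def to_json(self, path: str | Path) -> Path:
        obj = {
            "prototypes": {c: self.prototypes[c].tolist() for c in self.prototypes.columns},
            "statement_ids": [int(i) for i in self.prototypes.index],
            "assignments": [
                {
                    "participant_id": a.participant_id,
                    "kind": a.kind,
                    "factor": a.factor,
                    "sign": a.sign,
                    "mixture": list(a.mixture) if a.mixture else None,
                }
                for a in self.assignments
            ],
        }
        path = Path(path)
        path.write_text(json.dumps(obj, indent=2) + "\n", encoding="utf-8")
        return path


def _standardize(ranks: np.ndarray) -> np.ndarray:
    r = np.asarray(ranks, dtype=float)
    return (r - r.mean()) / r.std()


def make_prototypes(
    grid: GridSpec,
    K: int,
    rng: np.random.Generator,
    max_pairwise_corr: float = 0.3,
) -> pd.DataFrame:
    """Draw K well-separated grid-conforming prototype arrays.

    Candidate arrays are random permutations of the grid's rank
    multiset; a candidate is accepted only if its Spearman correlation
    with every already-accepted prototype stays within
    ``max_pairwise_corr`` in absolute value.  Deterministic given the
    generator state; raises after 10,000 rejected draws.
    """
    values = np.array(grid.rank_values())
    S = grid.n_statements
    accepted: list[np.ndarray] = []
    draws = 0
    while len(accepted) < K:
        if draws >= REJECTION_BUDGET:
            raise RuntimeError(
                f"could not draw {K} prototypes with pairwise |rho| <= {max_pairwise_corr} "
                f"in {REJECTION_BUDGET} draws; loosen the bound"
            )
        draws += 1
        cand = rng.permutation(values)
        ok = all(
            abs(float(spearmanr(cand, p).statistic)) <= max_pairwise_corr for p in accepted
        )
        if ok:
            accepted.append(cand)
    ids = pd.Index(range(1, S + 1), name="statement_id")
    return pd.DataFrame(
        {f"P{j + 1}": accepted[j] for j in range(K)}, index=ids, dtype=int
    )


def simulate_panel(
    config: SimConfig,
    prototypes: Optional[pd.DataFrame] = None,
    statements: Optional[list[Statement]] = None,
) -> tuple[QSortPanel, SimTruth]:
    """Generate a panel of forced-distribution sorts with ground truth.

    Pure participants: standardized prototype ranks + iid N(0, noise_sd)
    noise, re-quantized onto the grid with the same descending-z,
    ascending-id tie-break the analysis uses.  Confounded participants
    mix two distinct prototypes 50/50 before noise; negative
    participants start from the rank-negated prototype (the mirror
    viewpoint, valid on a symmetric grid).  Counts: ``n_per_factor``
    pure sorts per factor, plus ``round(confounded_frac * n_pure)``
    mixture sorts; each pure sort is negative with probability
    ``negative_frac``.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    if prototypes is None:
        prototypes = make_prototypes(grid, config.K, rng, config.max_pairwise_corr)
    Z = np.column_stack([_standardize(prototypes[c].to_numpy()) for c in prototypes.columns])

    assignments: list[Assignment] = []
    latents: list[np.ndarray] = []
    for j, n in enumerate(config.n_per_factor):
        for _ in range(n):
            negative = rng.random() < config.negative_frac
            sign = -1 if negative else 1
            latents.append(sign * Z[:, j])
            assignments.append(
                Assignment("", "negative" if negative else "pure", j, sign)
            )
    n_pure = len(latents)
    n_conf = int(round(config.confounded_frac * n_pure))
    for _ in range(n_conf):
        a, b = rng.choice(config.K, size=2, replace=False)
        mix = 0.5 * Z[:, a] + 0.5 * Z[:, b]
        latents.append(mix)
        assignments.append(Assignment("", "confounded", None, 1, (int(a), int(b))))

    width = max(3, len(str(len(latents))))
    sorts = {}
    for i, (latent, a) in enumerate(zip(latents, assignments)):
        pid = f"p{i + 1:0{width}d}"
        a.participant_id = pid
        noisy = latent + rng.normal(0.0, config.noise_sd, size=len(latent))
        sorts[pid] = quantize_to_array(
            pd.Series(noisy, index=prototypes.index), grid
        ).to_numpy()
    panel = QSortPanel(
        pd.DataFrame(sorts, index=prototypes.index), grid, statements
    )
    return panel, SimTruth(prototypes, assignments)


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------

@dataclass
class FactorMatch:
    mapping: list[tuple[int, int]]       # (estimated col, prototype col), 0-based
    correlations: list[float]            # |Spearman| per matched pair
    signs: list[int]

    @property
    def mean_abs_corr(self) -> float:
        return float(np.mean(self.correlations))


def match_factors(estimated: pd.DataFrame, prototypes: pd.DataFrame) -> FactorMatch:
    """Best injective matching of estimated arrays to prototypes.

    Exhaustive search over assignments (supported up to K = 7, i.e. K!
    candidates) maximizing the summed |Spearman| correlation.  When the
    counts differ, the smaller side is matched injectively into the
    larger.
    """
    k, K = estimated.shape[1], prototypes.shape[1]
    if max(k, K) > 7:
        raise ValueError("factor matching supports at most 7 factors per side")
    E = estimated.to_numpy(dtype=float)
    P = prototypes.to_numpy(dtype=float)
    C = np.zeros((k, K))
    for i in range(k):
        for j in range(K):
            C[i, j] = float(spearmanr(E[:, i], P[:, j]).statistic)
    small, large = (k, K) if k <= K else (K, k)
    best, best_score = None, -np.inf
    for perm in itertools.permutations(range(large), small):
        pairs = (
            [(i, perm[i]) for i in range(small)] if k <= K
            else [(perm[i], i) for i in range(small)]
        )
        score = sum(abs(C[i, j]) for i, j in pairs)
        if score > best_score:
            best, best_score = pairs, score
    corrs = [abs(C[i, j]) for i, j in best]
    signs = [1 if C[i, j] >= 0 else -1 for i, j in best]
    return FactorMatch(best, corrs, signs)


def recovery_report(solution, truth: SimTruth) -> dict:
    """Compare a pipeline solution against simulation ground truth.

    Reports the retained k vs the true K, the mean matched |Spearman|
    between estimated arrays and prototypes (over matched pairs only
    when counts differ), and flag accuracy: the fraction of pure
    participants flagged on their true factor (via the matching).
    """
    match = match_factors(solution.arrays, truth.prototypes)
    est_to_proto = dict(match.mapping)
    pure = truth.pure_map()
    hits = 0
    for f in solution.flags.flags:
        pid = f.participant_id
        if pid in pure and f.factor is not None and est_to_proto.get(f.factor) == pure[pid]:
            hits += 1
    return {
        "k_true": truth.prototypes.shape[1],
        "k_est": solution.k,
        "n_matched": len(match.mapping),
        "mean_matched_abs_spearman": match.mean_abs_corr,
        "matched_correlations": match.correlations,
        "flag_accuracy": hits / len(pure) if pure else float("nan"),
        "exact_recovery": bool(
            len(match.mapping) == truth.prototypes.shape[1]
            and solution.k == truth.prototypes.shape[1]
            and all(
                (solution.arrays.iloc[:, i].to_numpy() == truth.prototypes.iloc[:, j].to_numpy()).all()
                for i, j in match.mapping
            )
        ),
    }
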