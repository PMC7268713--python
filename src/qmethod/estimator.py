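"""Scikit-learn estimator facade over the Q-methodology pipeline.

``QFactorAnalysis`` is a decomposition-style estimator for by-person
factor analysis: the observations (rows of X) are statements and the
features (columns) are participants, so the correlation being
decomposed is between persons, not items.  It composes with sklearn
tooling (``get_params``/``set_params``, cloning, pipelines), while the
underlying stages remain available as functions in
:mod:`qmethod.factor`.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .factor import PipelineConfig, factor_weights, run_pipeline
from .grid import GridSpec, derive_grid
from .panel import QSortPanel


class QFactorAnalysis(TransformerMixin, BaseEstimator):
    """By-person factor analysis of forced-distribution Q-sorts.

    Parameters
    ----------
    n_factors : "auto" or int, default "auto"
        "auto" retains the largest leading set of factors that all have
        eigenvalue > 1.00 and at least two significantly loading
        exemplars; an integer fixes k.
    corr_method : {"pearson", "spearman"}
        By-person correlation used for extraction.
    alpha : {0.01, 0.05}
        Significance level of the loading threshold z_alpha/sqrt(S).
    n_extract : int or None
        Components extracted before retention; default min(8, P-1).
    kaiser : bool
        Kaiser-normalize rows during Varimax rotation.
    bipolar : {"exclude", "include"}
        Whether negatively loading exemplars enter factor-score
        estimation (rank-negated) or are left out.
    flag_rule : {"pure", "pqmethod"}
        Exemplar flagging rule: pure loaders only, or additionally
        requiring a² > h²/2.
    grid : GridSpec or None
        Forced distribution; derived from the first column when None.

    Attributes
    ----------
    solution_ : FactorSolution
        Full record of the fitted pipeline.
    eigenvalues_ : ndarray, full spectrum of the by-person correlation.
    loadings_ : DataFrame (P × k), Varimax-rotated, flags in flags_.
    zscores_ : DataFrame (S × k) statement z-scores per factor.
    arrays_ : DataFrame (S × k) integer factor arrays on the grid.
    n_factors_ : int, retained factor count.
    threshold_ : float, loading significance threshold used.

    Examples
    --------
    >>> from qmethod.simulate import SimConfig, simulate_panel
    >>> from qmethod.study import load_fixture
    >>> cfg = SimConfig(grid=load_fixture().grid, K=3,
    ...                 n_per_factor=[10, 10, 10], noise_sd=0.5, seed=7)
    >>> panel, truth = simulate_panel(cfg)
    >>> qfa = QFactorAnalysis().fit(panel)
    >>> qfa.n_factors_
    3
    """

    def __init__(
        self,
        n_factors: str | int = "auto",
        corr_method: str = "pearson",
        alpha: float = 0.01,
        n_extract: Optional[int] = None,
        kaiser: bool = True,
        bipolar: str = "exclude",
        flag_rule: str = "pure",
        grid: Optional[GridSpec] = None,
    ) -> None:
        self.n_factors = n_factors
        self.corr_method = corr_method
        self.alpha = alpha
        self.n_extract = n_extract
        self.kaiser = kaiser
        self.bipolar = bipolar
        self.flag_rule = flag_rule
        self.grid = grid

    # -- plumbing -------------------------------------------------------

    def _as_panel(self, X) -> QSortPanel:
        if isinstance(X, QSortPanel):
            return X
        if isinstance(X, pd.DataFrame):
            sorts = X.astype(int)
            if sorts.index.dtype.kind not in "iu":
                sorts = sorts.set_axis(range(1, len(sorts) + 1), axis=0)
        else:
            A = np.asarray(X)
            if A.ndim != 2:
                raise ValueError(f"X must be 2-D (statements × participants), got shape {A.shape}")
            if not np.all(A == np.round(A)):
                raise ValueError("Q-sort ranks must be integers")
            sorts = pd.DataFrame(
                A.astype(int),
                index=range(1, A.shape[0] + 1),
                columns=[f"p{j + 1:03d}" for j in range(A.shape[1])],
            )
        grid = self.grid if self.grid is not None else derive_grid(sorts.iloc[:, 0])
        return QSortPanel(sorts, grid)

    def _config(self) -> PipelineConfig:
        retention = "auto" if self.n_factors == "auto" else int(self.n_factors)
        return PipelineConfig(
            corr_method=self.corr_method,
            n_extract=self.n_extract,
            alpha=self.alpha,
            retention=retention,
            kaiser=self.kaiser,
            bipolar=self.bipolar,
            flag_rule=self.flag_rule,
        )

    # -- estimator API --------------------------------------------------

    def fit(self, X, y=None) -> "QFactorAnalysis":
        """Run the full pipeline on a panel.

        X may be a QSortPanel, a DataFrame or an integer array of shape
        (n_statements, n_participants); every column must conform to
        the grid.
        """
        panel = self._as_panel(X)
        solution = run_pipeline(panel, self._config())
        self.solution_ = solution
        self.panel_ = panel
        self.eigenvalues_ = solution.extraction.eigenvalues
        self.loadings_ = solution.rotated.loadings
        self.flags_ = solution.flags
        self.zscores_ = solution.scores.zscores
        self.arrays_ = solution.arrays
        self.n_factors_ = solution.k
        self.threshold_ = solution.threshold
        self.n_features_in_ = panel.n_participants
        return self

    def transform(self, X) -> np.ndarray:
        """Project statement rank rows onto the fitted factors.

        Rows of X are statements scored by the same participants the
        model was fitted on; each row is reduced to its weighted
        exemplar score per factor (standardized across the given rows
        when there are at least two).  ``fit_transform`` on the
        training panel therefore reproduces ``zscores_``.
        """
        check_is_fitted(self, "solution_")
        if isinstance(X, QSortPanel):
            A = X.values.astype(float)
            cols = X.participant_ids
        elif isinstance(X, pd.DataFrame):
            A = X.to_numpy(dtype=float)
            cols = [str(c) for c in X.columns]
        else:
            A = np.asarray(X, dtype=float)
            cols = self.panel_.participant_ids
        if A.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {A.shape[1]} participants, model was fitted with {self.n_features_in_}"
            )
        pos = {pid: i for i, pid in enumerate(cols)}
        k = self.n_factors_
        raw = np.zeros((A.shape[0], k))
        for j, wmap in enumerate(self.solution_.scores.weights):
            for pid, w in wmap.items():
                raw[:, j] += w * A[:, pos[pid]]
        if raw.shape[0] > 1:
            sd = raw.std(axis=0)
            sd[sd == 0] = 1.0
            raw = (raw - raw.mean(axis=0)) / sd
        return raw

    def score(self, X=None, y=None) -> float:
        """Total explained variance fraction of the retained factors."""
        check_is_fitted(self, "solution_")
        ev = self.eigenvalues_
        return float(ev[: self.n_factors_].sum() / ev.sum())
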