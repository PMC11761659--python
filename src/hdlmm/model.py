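"""Model/Results front end for penalized high-dimensional mixed models.

``HighDimLMM`` holds the data and the modelling choices (penalty family,
random-effect covariance structure, unpenalized set); ``fit`` runs the
coordinate-descent solver at a single regularization strength and returns a
``HighDimLMMResults``; ``fit_path`` fits a grid of strengths and returns a
``PathResults`` whose ``best`` attribute is the BIC-selected model.

Example
-------
>>> from hdlmm import HighDimLMM
>>> from hdlmm.simulate import gene_expression_setting, simulate
>>> sim = simulate(gene_expression_setting(1, seed=1))
>>> model = HighDimLMM.from_clustered_data(sim.data, penalty="scad")
>>> res = model.fit(lam=25.0)
>>> res.fe_params[:5]  # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import ClusteredData
from .likelihood import ModelParams
from .penalties import PenaltySpec
from .selection import PathResult, bic, fit_path, lambda_grid, selection_metrics
from .solver import FitResult, SolverControl, fit_once

__all__ = ["HighDimLMM", "HighDimLMMResults", "PathResults"]


class HighDimLMM:
    """Penalized linear mixed-effects model.

    Parameters
    ----------
    y, X, Z, groups : arrays
        Response, fixed-effect design, random-effect design and cluster
        labels. If ``Z`` is None, ``z_columns`` selects columns of X.
    nonpen : iterable of int
        0-based indices of unpenalized X columns. By convention this holds
        the intercept and every column that also appears in Z.
    penalty : {"lasso", "scad"}
    a : SCAD shape parameter (> 2), default 3.7.
    cov_structure : {"scalar", "diagonal", "unstructured"}
    standardize : bool
        If True, penalized columns are scaled to unit standard deviation
        for the solve and estimates are transformed back.
    """

    def __init__(
        self,
        y,
        X,
        Z=None,
        groups=None,
        nonpen=(0,),
        z_columns=None,
        penalty: str = "scad",
        a: float = 3.7,
        cov_structure: str = "scalar",
        standardize: bool = False,
        names=None,
    ):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if Z is None:
            if z_columns is None:
                raise ValueError("supply Z or z_columns")
            Z = X[:, list(z_columns)]
        if groups is None:
            raise ValueError("groups is required")
        self.data = ClusteredData(
            X=X, Z=np.asarray(Z, float), y=y, groups=groups,
            nonpen=frozenset(nonpen),
        )
        self.penalty = penalty
        self.a = a
        self.cov_structure = cov_structure
        self.standardize = bool(standardize)
        self.names = (
            list(names) if names is not None
            else [f"x{j + 1}" for j in range(self.data.n_fixed)]
        )
        if self.standardize:
            sd = self.data.X.std(axis=0, ddof=0)
            mask = self.data.penalized_mask() & (sd > 0)
            scale = np.ones(self.data.n_fixed)
            scale[mask] = sd[mask]
            self._scale = scale
            Xs = self.data.X / scale
            self._work = ClusteredData(
                X=Xs, Z=self.data.Z, y=self.data.y,
                groups=self.data.groups, nonpen=self.data.nonpen,
            )
        else:
            self._scale = np.ones(self.data.n_fixed)
            self._work = self.data

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_clustered_data(cls, data: ClusteredData, **kwargs) -> "HighDimLMM":
        return cls(
            y=data.y, X=data.X, Z=data.Z, groups=data.group_labels[data.groups],
            nonpen=data.nonpen, **kwargs,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        response: str,
        groups: str,
        features=None,
        z_columns=(),
        intercept: bool = True,
        nonpen_extra=(),
        **kwargs,
    ) -> "HighDimLMM":
        """Build from a tidy DataFrame.

        ``z_columns`` names the feature columns that carry random slopes;
        with ``intercept=True`` a constant column is prepended and receives
        a random intercept. Named Z columns and the intercept are
        unpenalized.
        """
        if features is None:
            features = [c for c in df.columns if c not in (response, groups)]
        unknown = [c for c in z_columns if c not in features]
        if unknown:
            raise KeyError(f"z_columns not among features: {unknown}")
        # order: intercept, random-slope columns, everything else
        rest = [c for c in features if c not in z_columns]
        ordered = list(z_columns) + rest
        X = df[ordered].to_numpy(dtype=float)
        names = list(ordered)
        if intercept:
            X = np.hstack([np.ones((len(df), 1)), X])
            names = ["intercept"] + names
        q = len(z_columns) + int(intercept)
        if q == 0:
            raise ValueError("need an intercept or at least one z column")
        nonpen = set(range(q)) | {names.index(c) for c in nonpen_extra}
        return cls(
            y=df[response].to_numpy(dtype=float), X=X, Z=X[:, :q],
            groups=df[groups].to_numpy(), nonpen=frozenset(nonpen),
            names=names, **kwargs,
        )

    # -- fitting ----------------------------------------------------------
    def _spec(self, lam: float) -> PenaltySpec:
        return PenaltySpec(family=self.penalty, lam=float(lam), a=self.a)

    def _wrap(self, fit: FitResult) -> "HighDimLMMResults":
        if self.standardize:
            import dataclasses

            beta = fit.params.beta / self._scale
            fit = dataclasses.replace(
                fit, params=ModelParams(beta=beta, var=fit.params.var)
            )
        return HighDimLMMResults(self, fit)

    def fit(
        self,
        lam: float,
        control: SolverControl | None = None,
        init: ModelParams | None = None,
    ) -> "HighDimLMMResults":
        """Coordinate descent at a single regularization strength."""
        fit = fit_once(
            self._work, self._spec(lam), self.cov_structure,
            init=init, control=control,
        )
        return self._wrap(fit)

    def fit_path(
        self,
        lams=None,
        n_points: int = 10,
        bounds=None,
        control: SolverControl | None = None,
        spacing: str = "log",
    ) -> "PathResults":
        """Fit a grid of lams and select the BIC-minimizing model."""
        if lams is None:
            lams = lambda_grid(
                self._work, self._spec(1.0), n_points=n_points, bounds=bounds,
                cov_structure=self.cov_structure, control=control,
                spacing=spacing,
            )
        path = fit_path(
            self._work, self._spec(1.0), lams, self.cov_structure, control
        )
        return PathResults(self, path)


class HighDimLMMResults:
    """Estimates, diagnostics and summary for one fitted model."""

    def __init__(self, model: HighDimLMM, fit: FitResult):
        self.model = model
        self._fit = fit

    # -- estimates --------------------------------------------------------
    @property
    def fe_params(self) -> np.ndarray:
        """Fixed-effect estimates beta_hat."""
        return self._fit.params.beta

    @property
    def cov_re(self) -> np.ndarray:
        """Estimated random-effect covariance Psi_hat."""
        return self._fit.params.var.psi()

    @property
    def sigma2(self) -> float:
        """Estimated error variance."""
        return self._fit.params.var.sigma2

    @property
    def llf(self) -> float:
        return self._fit.loglik

    @property
    def objective(self) -> float:
        return self._fit.objective

    @property
    def lam(self) -> float:
        return self._fit.lam

    @property
    def bic(self) -> float:
        return bic(self._fit, self.model._work)

    @property
    def df(self) -> int:
        return self._fit.n_nonzero + self._fit.params.var.n_params

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def diverged_interpolating(self) -> bool:
        return self._fit.diverged_interpolating

    @property
    def n_iter(self) -> int:
        return self._fit.n_iter

    @property
    def active_history(self):
        return self._fit.active_history

    @property
    def fitresult(self) -> FitResult:
        """The underlying solver result."""
        return self._fit

    def coefficients(self, nonzero_only: bool = False) -> pd.DataFrame:
        """Coefficient table with 1-based indices and penalization flags."""
        pen = self.model.data.penalized_mask()
        df = pd.DataFrame(
            {
                "index": np.arange(1, self.model.data.n_fixed + 1),
                "name": self.model.names,
                "estimate": self.fe_params,
                "penalized": pen,
            }
        )
        if nonzero_only:
            df = df[df["estimate"] != 0.0].reset_index(drop=True)
        return df

    def selection_report(self, beta_true):
        """Support-recovery metrics against a known generating beta."""
        return selection_metrics(self.fe_params, beta_true)

    def predict(self, X=None) -> np.ndarray:
        """Population-level (fixed-effect) prediction X beta_hat."""
        X = self.model.data.X if X is None else np.asarray(X, float)
        return X @ self.fe_params

    def resid(self) -> np.ndarray:
        return self.model.data.y - self.predict()

    def summary(self) -> str:
        d = self.model.data
        status = (
            "diverged (interpolating)" if self.diverged_interpolating
            else ("converged" if self.converged else "max-iter")
        )
        lines = [
            "Penalized Linear Mixed Model Results",
            "=" * 54,
            f"Penalty:        {self.model.penalty.upper()} (lam={self.lam:g})",
            f"Cov structure:  {self.model.cov_structure}",
            f"N obs:          {d.n_obs}    clusters: {d.n_groups}",
            f"p fixed:        {d.n_fixed}    q random: {d.n_random}",
            f"Status:         {status} in {self.n_iter} iterations",
            f"log-likelihood: {self.llf:.4f}",
            f"BIC:            {self.bic:.4f}   df: {self.df}",
            f"sigma2:         {self.sigma2:.4f}",
            "Psi (random-effect covariance):",
        ]
        for row in np.atleast_2d(self.cov_re):
            lines.append("    " + "  ".join(f"{v: .4f}" for v in row))
        lines.append("-" * 54)
        lines.append("Nonzero coefficients:")
        tab = self.coefficients(nonzero_only=True)
        for _, r in tab.iterrows():
            flag = "penalized" if r["penalized"] else "unpenalized"
            lines.append(
                f"  beta_{int(r['index']):<4d} {r['name']:<12s} "
                f"{r['estimate']: .4f}  ({flag})"
            )
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<HighDimLMMResults lam={self.lam:g} "
            f"nnz={self._fit.n_nonzero} bic={self.bic:.2f}>"
        )


class PathResults:
    """Results over a lam grid with BIC selection."""

    def __init__(self, model: HighDimLMM, path: PathResult):
        self.model = model
        self._path = path
        self.lams = path.lams
        self.bic_values = path.bic_values
        self.best_index = path.best_index

    @property
    def best(self) -> HighDimLMMResults:
        """The BIC-selected model."""
        return self.model._wrap(self._path.best)

    def results(self, i: int) -> HighDimLMMResults:
        return self.model._wrap(self._path.fits[i])

    def to_frame(self) -> pd.DataFrame:
        return self._path.to_frame()

    def plot(self, ax=None):
        """BIC against lam with the selected model marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        finite = np.isfinite(self.bic_values)
        ax.plot(self.lams[finite], self.bic_values[finite], "o-")
        ax.axvline(self.lams[self.best_index], color="red", ls="--")
        ax.set_xlabel("lam")
        ax.set_ylabel("BIC")
        ax.set_xscale("log")
        return ax

    def __repr__(self):
        return (
            f"<PathResults {len(self.lams)} lams, "
            f"best lam={self.lams[self.best_index]:g}>"
        )
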