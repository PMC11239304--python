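"""Posterior expected outcome gains per condition.

Decision-making in the posterior-expected-value framework needs, for every
alternative intervention t, the model-implied expected outcome gain Ŷ_t —
for the full sample and separately within each advantage group.  The working
model is a parsimonious linear regression on the factor codes: intercept, all
main effects, and all interactions up to ``interaction_order`` (two-way by
default; ``interaction_order = k`` is the saturated cell-means model).

Two inference backends share the same estimand (the posterior mean of the
model-implied cell mean):

``closed_form``
    The flat-prior conjugate posterior, whose mean coincides exactly with
    ordinary least squares.  Reported uncertainty is the classical standard
    error of the fitted cell mean.
``sampling``
    Monte-Carlo draws from the flat-prior normal–inverse-gamma posterior
    (σ² from a scaled inverse-χ², β | σ² multivariate normal around the OLS
    solution).  Agrees with the closed form up to Monte-Carlo error; useful
    when downstream summaries of posterior draws are wanted.

Predictions are invariant to the factor-coding convention (effect ±1 versus
dummy 0/1) for a fixed term set; effect coding is the default as is
conventional for factorial optimization trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import FactorialDesign, InterventionCode
from .simulate import GROUP_COLUMN, ORCTDataset, OUTCOME_COLUMN

__all__ = [
    "FitError",
    "ModelSpec",
    "PosteriorSummary",
    "fit_expected_outcomes",
    "fit_by_group",
    "group_gain_table",
    "predict_cell_mean",
]

Scope = Literal["full"] | int


class FitError(ValueError):
    """Raised when the outcome model cannot be fitted (e.g. rank deficiency)."""


@dataclass(frozen=True)
class ModelSpec:
    """What to include in the outcome regression and how to fit it."""

    interaction_order: int = 2
    coding: Literal["effect", "dummy"] = "effect"
    backend: Literal["closed_form", "sampling"] = "closed_form"
    draws: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interaction_order < 1:
            raise ValueError("interaction_order must be >= 1 (main effects)")
        if self.coding not in ("effect", "dummy"):
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.backend not in ("closed_form", "sampling"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.draws < 2:
            raise ValueError("draws must be >= 2")

    def terms(self, design: FactorialDesign) -> list[tuple[str, ...]]:
        """Model terms as tuples of component names; ``()`` is the intercept.

        The term set is closed under marginality by construction: every
        interaction's lower-order relatives are present.
        """
        order = min(self.interaction_order, design.k)
        names = design.component_names
        out: list[tuple[str, ...]] = [()]
        for r in range(1, order + 1):
            out.extend(combinations(names, r))
        return out


def _term_label(term: tuple[str, ...]) -> str:
    return ":".join(term) if term else "Intercept"


def _model_matrix(
    onoff: np.ndarray, names: list[str], terms: list[tuple[str, ...]], coding: str
) -> np.ndarray:
    """Model matrix for rows of 0/1 factor indicators."""
    base = 2.0 * onoff - 1.0 if coding == "effect" else onoff.astype(float)
    idx = {name: j for j, name in enumerate(names)}
    cols = []
    for term in terms:
        if not term:
            cols.append(np.ones(len(onoff)))
        else:
            col = np.ones(len(onoff))
            for name in term:
                col = col * base[:, idx[name]]
            cols.append(col)
    return np.column_stack(cols)


def _check_rank(x: np.ndarray, terms: list[tuple[str, ...]]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank == x.shape[1]:
        return
    # identify columns whose removal does not reduce rank: those are inestimable
    offending = [
        _term_label(term)
        for j, term in enumerate(terms)
        if np.linalg.matrix_rank(np.delete(x, j, axis=1)) == rank
    ]
    raise FitError(
        "rank-deficient model matrix; inestimable term(s): "
        + ", ".join(offending or ["<unidentified>"])
    )


@dataclass
class PosteriorSummary:
    """Expected gains Ŷ_t with uncertainty, for one scope (full sample or group).

    ``expected`` and ``sd`` are Series indexed by condition label in design
    enumeration order.  ``draws`` (conditions as columns) is populated by the
    sampling backend only.
    """

    scope: Scope
    backend: str
    expected: pd.Series
    sd: pd.Series
    n_obs: int
    spec: ModelSpec
    draws: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def gains(self) -> Mapping[str, float]:
        return self.expected.to_dict()

    def predict(self, code: InterventionCode | str) -> tuple[float, float]:
        return predict_cell_mean(self, code)

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "backend": self.backend,
            "n_obs": self.n_obs,
            "seed": self.spec.seed if self.backend == "sampling" else None,
            "conditions": [
                {"condition": t, "expected_gain": float(m), "sd": float(s)}
                for t, m, s in zip(self.expected.index, self.expected, self.sd)
            ],
        }


def fit_expected_outcomes(
    dataset: ORCTDataset, spec: ModelSpec | None = None, scope: Scope = "full"
) -> PosteriorSummary:
    """Fit the outcome regression and return Ŷ_t for every condition.

    ``scope="full"`` uses all records; an integer scope g restricts the fit
    to the records of advantage group g (a separate, unpooled per-group fit).
    """
    spec = spec or ModelSpec()
    data = dataset.data
    if scope != "full":
        data = data[data[GROUP_COLUMN] == int(scope)]
        if data.empty:
            raise FitError(f"no records for advantage group {scope}")
    names = dataset.design.component_names
    terms = spec.terms(dataset.design)
    x = _model_matrix(data[names].to_numpy(dtype=float), names, terms, spec.coding)
    if x.shape[0] < x.shape[1]:
        raise FitError(
            f"{x.shape[0]} records cannot identify {x.shape[1]} model terms"
        )
    _check_rank(x, terms)
    y = data[OUTCOME_COLUMN].to_numpy(dtype=float)
    res = sm.OLS(y, x).fit()

    conditions = dataset.design.conditions()
    onoff_c = np.array(
        [[int(n in code.on_set) for n in names] for code in conditions], dtype=float
    )
    xc = _model_matrix(onoff_c, names, terms, spec.coding)
    labels = [code.label for code in conditions]

    mean = xc @ res.params
    cov = np.asarray(res.cov_params())
    sd = np.sqrt(np.einsum("ij,jk,ik->i", xc, cov, xc))
    draws_frame = None

    if spec.backend == "sampling":
        rng = np.random.default_rng(np.random.SeedSequence((int(spec.seed),)))
        df_resid = int(res.df_resid)
        if df_resid < 1:
            raise FitError("sampling backend needs positive residual degrees of freedom")
        xtx_inv = np.linalg.inv(x.T @ x)
        chol = np.linalg.cholesky(xtx_inv)
        sigma2 = res.ssr / rng.chisquare(df_resid, size=spec.draws)
        z = rng.standard_normal((spec.draws, len(res.params)))
        betas = res.params + (z * np.sqrt(sigma2)[:, None]) @ chol.T
        cell_draws = betas @ xc.T
        mean = cell_draws.mean(axis=0)
        sd = cell_draws.std(axis=0, ddof=1)
        draws_frame = pd.DataFrame(cell_draws, columns=labels)

    return PosteriorSummary(
        scope=scope,
        backend=spec.backend,
        expected=pd.Series(mean, index=labels, name="expected_gain"),
        sd=pd.Series(sd, index=labels, name="sd"),
        n_obs=len(data),
        spec=spec,
        draws=draws_frame,
    )


def predict_cell_mean(
    summary: PosteriorSummary, code: InterventionCode | str
) -> tuple[float, float]:
    """Expected gain and posterior SD for one condition of a fitted model."""
    label = code.label if isinstance(code, InterventionCode) else str(code)
    if label not in summary.expected.index:
        raise FitError(f"condition {label!r} is outside the fitted design")
    return float(summary.expected[label]), float(summary.sd[label])


def fit_by_group(
    dataset: ORCTDataset, spec: ModelSpec | None = None
) -> dict[int, PosteriorSummary]:
    """Separate fits for each advantage group, keyed by 1-based group label."""
    groups = sorted(dataset.data[GROUP_COLUMN].unique())
    return {int(g): fit_expected_outcomes(dataset, spec, int(g)) for g in groups}


def group_gain_table(summaries: Mapping[int, PosteriorSummary]) -> pd.DataFrame:
    """Condition × group table of expected gains Ŷ_{t,g}.

    Rows are condition labels (design order), columns are group labels
    ordered by increasing advantage — the input shape the equity metrics
    expect.
    """
    if not summaries:
        raise ValueError("no group summaries supplied")
    cols = {g: s.expected for g, s in sorted(summaries.items())}
    return pd.DataFrame(cols)
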