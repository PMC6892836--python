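"""Stepwise multiple linear regression on wavelengths or index groups.

The selector is the classic forward-with-backward-elimination procedure: at
each step the candidate with the smallest partial-F p-value enters if it
beats ``alpha_enter``, then any entered term whose p-value has drifted above
``alpha_remove`` leaves.  Ties are broken by the lower p-value and then the
lower column position, so a selection trace is fully deterministic for a
given design.  Entered models are always refit by ordinary least squares so
the reported coefficients, R2, and RMSE are exactly reproducible from the
data.

Two front-ends mirror the two modelling styles used with canopy spectra:
``wavelengths_from_intervals`` runs the selector over every wavelength
inside PLSR-derived sensitive band intervals (capped with uniform thinning
to keep the candidate set tractable), and ``group_model`` fits an index
group either with every member index (``all_terms``) or stepwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .plsr import BandInterval, EvaluationMetrics, evaluate_predictions
from .spectra import SpectraSet


@dataclass
class StepRecord:
    action: str  # "enter" | "remove"
    term: str
    p_value: float


@dataclass
class SMLRModel:
    trait: str
    scope: str
    predictors: list[str]
    intercept: float
    coefficients: np.ndarray
    r2: float
    rmse: float
    trace: list[StepRecord] = field(default_factory=list)

    def equation(self, lhs: str | None = None, digits: int = 4) -> str:
        """Human-readable model equation, e.g. ``DW = 1.09 - 5.56 (R733)``."""
        lhs = lhs or self.trait or "y"
        parts = [f"{lhs} = {self.intercept:.{digits}g}"]
        for name, b in zip(self.predictors, self.coefficients):
            sign = "-" if b < 0 else "+"
            parts.append(f"{sign} {abs(b):.{digits}g} ({name})")
        return " ".join(parts)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        missing = [p for p in self.predictors if p not in data.columns]
        if missing:
            raise KeyError(f"missing predictors: {missing}")
        X = data[self.predictors].to_numpy(dtype=float)
        return self.intercept + X @ self.coefficients


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """(coefs incl. intercept, SSE, R2) for a design with intercept column."""
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    return beta, sse, r2


def _partial_f_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Partial-F p-value for each column of X in the full model."""
    n, k = X.shape
    beta, sse_full, _ = _ols(X, y)
    df_resid = n - k - 1
    if df_resid <= 0 or sse_full <= 0:
        return np.zeros(k)
    pvals = np.empty(k)
    for j in range(k):
        reduced = np.delete(X, j, axis=1)
        _, sse_red, _ = _ols(reduced, y)
        f = (sse_red - sse_full) / (sse_full / df_resid)
        f = max(f, 0.0)
        pvals[j] = stats.f.sf(f, 1, df_resid)
    return pvals


def stepwise_select(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    max_terms: int | None = None,
    trait: str = "",
    scope: str = "",
) -> SMLRModel:
    """Forward-with-backward stepwise selection over named candidates."""
    y = np.asarray(y, dtype=float).ravel()
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    n = len(y)
    if max_terms is None:
        max_terms = min(len(names), n - 2)
    selected: list[int] = []
    trace: list[StepRecord] = []

    while True:
        changed = False
        # --- forward step: exact partial-F for every candidate at once via
        # QR-orthogonalization against the current model
        if len(selected) < max_terms:
            A = np.column_stack([np.ones(n), Xm[:, selected]])
            Q, _ = np.linalg.qr(A)
            r = y - Q @ (Q.T @ y)
            rss = float(r @ r)
            df = n - len(selected) - 2
            best_j, best_p = None, np.inf
            if rss > 0 and df > 0:
                cand_idx = [j for j in range(len(names)) if j not in selected]
                C = Xm[:, cand_idx]
                C_res = C - Q @ (Q.T @ C)
                ss = np.einsum("ij,ij->j", C_res, C_res)
                xy = C_res.T @ r
                col_scale = np.einsum("ij,ij->j", C, C) + 1.0
                with np.errstate(divide="ignore", invalid="ignore"):
                    r2_part = np.where(ss > 1e-12 * col_scale, xy**2 / (ss * rss), 0.0)
                r2_part = np.clip(r2_part, 0.0, 1.0)
                with np.errstate(divide="ignore"):
                    fstat = np.where(r2_part < 1.0, r2_part * df / (1.0 - r2_part), np.inf)
                pvals = stats.f.sf(fstat, 1, df)
                pvals[ss <= 1e-12 * col_scale] = np.inf  # collinear: skip
                order = np.lexsort((cand_idx, pvals))
                j = int(order[0])
                best_j, best_p = cand_idx[j], float(pvals[j])
            if best_j is not None and best_p < alpha_enter:
                selected.append(best_j)
                trace.append(StepRecord("enter", names[best_j], best_p))
                changed = True
        # --- backward step
        while len(selected) > 1:
            pvals = _partial_f_pvalues(Xm[:, selected], y)
            worst = int(np.argmax(pvals))
            if pvals[worst] > alpha_remove:
                term = selected.pop(worst)
                trace.append(StepRecord("remove", names[term], float(pvals[worst])))
                changed = True
            else:
                break
        if not changed:
            break

    if selected:
        beta, sse, r2 = _ols(Xm[:, selected], y)
        rmse = float(np.sqrt(sse / n))
        model = SMLRModel(
            trait=trait,
            scope=scope,
            predictors=[names[j] for j in selected],
            intercept=float(beta[0]),
            coefficients=beta[1:],
            r2=r2,
            rmse=rmse,
            trace=trace,
        )
    else:
        model = SMLRModel(
            trait=trait,
            scope=scope,
            predictors=[],
            intercept=float(y.mean()),
            coefficients=np.array([]),
            r2=0.0,
            rmse=float(y.std()),
            trace=trace,
        )
    return model


def wavelengths_from_intervals(
    spectra: SpectraSet,
    intervals: list[BandInterval],
    traits: pd.DataFrame,
    trait: str,
    scope: str = "",
    max_candidates: int = 300,
    max_terms: int | None = 4,
    **stepwise_kwargs,
) -> SMLRModel:
    """Stepwise selection over every wavelength inside the band intervals.

    Candidates beyond ``max_candidates`` are thinned uniformly; predictor
    names follow the R-lambda convention (``R733`` = reflectance at 733 nm).
    With hundreds of strongly collinear reflectance candidates an uncapped
    stepwise run keeps absorbing noise terms, so the model size defaults to
    at most 4 terms — the parsimony regime these wavelength equations are
    meant for.
    """
    if not intervals:
        raise ValueError("no band intervals supplied")
    wl: list[int] = []
    for iv in intervals:
        wl.extend(range(iv.start, iv.end + 1))
    wl = sorted(set(wl))
    if len(wl) > max_candidates:
        pick = np.linspace(0, len(wl) - 1, max_candidates).round().astype(int)
        wl = [wl[i] for i in np.unique(pick)]
    X = pd.DataFrame(
        {f"R{w}": spectra.band(w) for w in wl},
        index=pd.Index(spectra.plot_ids, name="plot_id"),
    )
    if "plot_id" in traits.columns:
        traits = traits.set_index("plot_id")
    y = traits.loc[X.index, trait].to_numpy(dtype=float)
    return stepwise_select(
        X, y, trait=trait, scope=scope, max_terms=max_terms, **stepwise_kwargs
    )


def group_model(
    sri_table: pd.DataFrame,
    registry,
    group: str,
    traits: pd.DataFrame,
    trait: str,
    scope: str = "",
    mode: str = "all_terms",
    **stepwise_kwargs,
) -> SMLRModel:
    """Linear model of a trait on one wavelength-region index group.

    ``all_terms`` (default) fits OLS on every index in the group, dropping
    collinear columns with a warning; ``stepwise`` applies the selector.
    """
    members = [d.name for d in registry if d.group == group]
    if not members:
        raise ValueError(f"no indices in group {group!r}")
    X = sri_table[members]
    if "plot_id" in traits.columns:
        traits = traits.set_index("plot_id")
    y = traits.loc[X.index, trait].to_numpy(dtype=float)
    if mode == "stepwise":
        return stepwise_select(X, y, trait=trait, scope=scope, **stepwise_kwargs)
    if mode != "all_terms":
        raise ValueError(f"unknown mode {mode!r}")
    Xm = X.to_numpy(dtype=float)
    names = list(X.columns)
    # drop collinear columns (greedy, keep earliest) before the full fit
    keep: list[int] = []
    for j in range(Xm.shape[1]):
        trial = keep + [j]
        A = np.column_stack([np.ones(len(y)), Xm[:, trial]])
        if np.linalg.matrix_rank(A) == len(trial) + 1:
            keep.append(j)
    if len(keep) < Xm.shape[1]:
        import warnings

        warnings.warn(
            f"dropped {Xm.shape[1] - len(keep)} collinear index column(s) from {group}",
            stacklevel=2,
        )
    beta, sse, r2 = _ols(Xm[:, keep], y)
    return SMLRModel(
        trait=trait,
        scope=scope,
        predictors=[names[j] for j in keep],
        intercept=float(beta[0]),
        coefficients=beta[1:],
        r2=r2,
        rmse=float(np.sqrt(sse / len(y))),
    )


def evaluate_equation(
    model: SMLRModel, data: pd.DataFrame, observed: np.ndarray | None = None
) -> tuple[np.ndarray, EvaluationMetrics | None]:
    """Apply a fitted equation to new data; score it if observations given."""
    predictions = model.predict(data)
    metrics = None
    if observed is not None:
        metrics = evaluate_predictions(np.asarray(observed, dtype=float), predictions)
    return predictions, metrics
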