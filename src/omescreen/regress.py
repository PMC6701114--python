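"""Per-pair nested linear models with cohort x readout interaction.

For one microbe (response ``y``, relative abundance) and one immune readout
(predictor ``x``), the full model is

    y ~ Cohort + x + Cohort:x

under treatment (reference-cell) coding, and the reduced model is

    y ~ Cohort.

A partial F-test between the two asks whether the immune readout has any
explanatory value, allowing the slope to differ by cohort.  With K cohorts
the full model has 2K parameters (intercept, K-1 cohort offsets, a slope,
K-1 interaction offsets) and the reduced has K, so the numerator degrees of
freedom are K.

Per-pair diagnostics:

* two-sided t-tests for each non-reference cohort's interaction coefficient
  (does that cohort's slope differ from the reference's?);
* DFFITS influence, the standardized change in the i-th fitted value when
  observation i is deleted, computed from leverages and residuals in closed
  form; ``max_influence`` is max |DFFITS|;
* per-cohort fitted line segments spanning each cohort's own observed x
  range, plus glyph-normalized endpoints mapped into the unit square for
  sparkline-sized microplots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ContractError, DegenerateFitError, InsufficientDataError

# rank tolerance for the QR diagonal, relative to the largest diagonal entry
_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class CohortLine:
    """Fitted regression segment for one cohort."""

    cohort: str
    intercept: float
    slope: float
    x_min: float
    x_max: float

    @property
    def y_at_xmin(self) -> float:
        return self.intercept + self.slope * self.x_min

    @property
    def y_at_xmax(self) -> float:
        return self.intercept + self.slope * self.x_max


@dataclass
class PairFit:
    """All regression artifacts for one microbe x immune pair."""

    microbe: str
    immune: str
    n: int
    cohort_labels: list[str]  # reference first
    beta: np.ndarray  # [b0, cohort offsets..., slope, interaction offsets...]
    rss_full: float
    rss_reduced: float
    df_full: int
    df_reduced: int
    F: float
    p: float
    interaction_p: dict[str, float]
    dffits: np.ndarray | None
    max_influence: float | None
    cohort_lines: list[CohortLine]
    degenerate_perfect: bool = False
    # sample-level detail, kept for export and diagnostics
    x: np.ndarray = field(default_factory=lambda: np.empty(0))
    y: np.ndarray = field(default_factory=lambda: np.empty(0))
    cohorts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    # full-model internals (design-aligned), private to this module's helpers
    _cov_unscaled: np.ndarray | None = None
    _leverage: np.ndarray | None = None
    _residuals: np.ndarray | None = None

    @property
    def n_cohorts(self) -> int:
        return len(self.cohort_labels)

    @property
    def reference(self) -> str:
        return self.cohort_labels[0]

    def coefficient(self, term: str) -> float:
        """Coefficient by semantic name: 'intercept', 'slope', 'cohort:<c>',
        'interaction:<c>'."""
        K = self.n_cohorts
        if term == "intercept":
            return float(self.beta[0])
        if term == "slope":
            return float(self.beta[K])
        kind, _, cohort = term.partition(":")
        idx = self.cohort_labels.index(cohort)  # raises for unknown cohort
        if idx == 0:
            raise ContractError(f"{kind} term undefined for reference cohort")
        if kind == "cohort":
            return float(self.beta[idx])
        if kind == "interaction":
            return float(self.beta[K + idx])
        raise KeyError(term)


def _ordered_labels(cohorts: np.ndarray, reference: str) -> list[str]:
    labels = [reference]
    for c in cohorts:
        c = str(c)
        if c not in labels:
            labels.append(c)
    return labels


def _design(x: np.ndarray, cohorts: np.ndarray, labels: list[str]) -> np.ndarray:
    """Full-model design: intercept, cohort indicators, x, cohort:x columns."""
    n, K = len(x), len(labels)
    X = np.zeros((n, 2 * K))
    X[:, 0] = 1.0
    for j, lab in enumerate(labels[1:], start=1):
        X[:, j] = cohorts == lab
    X[:, K] = x
    for j, lab in enumerate(labels[1:], start=1):
        X[:, K + j] = x * (cohorts == lab)
    return X


def _qr_ols(X: np.ndarray, y: np.ndarray):
    """Least squares via thin QR; returns beta, rss, leverage, cov_unscaled.

    Raises DegenerateFitError when the design is rank-deficient.
    """
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() <= _RANK_RTOL * max(diag.max(), 1.0):
        raise DegenerateFitError("singular design matrix", reason="singular_design")
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    leverage = np.einsum("ij,ij->i", Q, Q)
    Rinv = np.linalg.inv(R)
    cov_unscaled = Rinv @ Rinv.T
    return beta, rss, resid, leverage, cov_unscaled


def fit_pair(y, x, cohorts, reference: str, *, microbe: str = "y",
             immune: str = "x") -> PairFit:
    """Fit the full and reduced models for one pair and compute all statistics.

    Samples with NaN in either variable must already be removed (see
    :func:`omescreen.tables.pairwise_complete`).

    Raises
    ------
    InsufficientDataError
        if any cohort has fewer than 2 samples, or n is too small for the
        full model to have at least one residual degree of freedom.
    DegenerateFitError
        if the design is singular (e.g. x constant within every cohort) or
        the response is constant.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    cohorts = np.asarray([str(c) for c in cohorts], dtype=object)
    if not (len(y) == len(x) == len(cohorts)):
        raise ContractError("y, x and cohorts must have equal length")
    if str(reference) not in set(cohorts):
        raise ContractError(f"reference cohort {reference!r} absent from data")

    labels = _ordered_labels(cohorts, str(reference))
    K = len(labels)
    n = len(y)
    for lab in labels:
        if int((cohorts == lab).sum()) < 2:
            raise InsufficientDataError(
                f"pair ({microbe}, {immune}): cohort {lab!r} has < 2 samples"
            )
    p_full = 2 * K
    if n < p_full + 1:
        raise InsufficientDataError(
            f"pair ({microbe}, {immune}): n={n} < {p_full + 1} required "
            f"for the full model with {K} cohorts"
        )
    if np.ptp(y) == 0.0:
        raise DegenerateFitError(
            f"pair ({microbe}, {immune}): constant response",
            reason="constant_response",
        )

    X_full = _design(x, cohorts, labels)
    beta, rss_full, resid, leverage, cov_unscaled = _qr_ols(X_full, y)

    X_red = X_full[:, :K]
    _, rss_reduced, _, _, _ = _qr_ols(X_red, y)
    # floating-point guard: nesting guarantees rss_reduced >= rss_full
    rss_reduced = max(rss_reduced, rss_full)

    df_full = n - p_full
    df_reduced = n - K
    df_num = df_reduced - df_full  # == K

    # Noise floor: residual sums of squares at the level of accumulated
    # rounding error are treated as exact zeros, so exact-arithmetic
    # contracts (F = 0 when the models coincide; degenerate when the full
    # model interpolates) survive floating point.
    floor = (1e-12 * max(np.abs(y).max(), 1.0)) ** 2 * n
    degenerate_perfect = False
    if rss_reduced <= floor:
        # reduced model already numerically perfect: nested models coincide
        F_stat, p_val = 0.0, 1.0
    elif rss_full <= floor:
        # full model interpolates a non-trivial response: no residual scale
        F_stat, p_val = float("inf"), 0.0
        degenerate_perfect = True
    else:
        F_stat = ((rss_reduced - rss_full) / df_num) / (rss_full / df_full)
        p_val = float(stats.f.sf(F_stat, df_num, df_full))

    fit = PairFit(
        microbe=microbe, immune=immune, n=n, cohort_labels=labels,
        beta=beta, rss_full=rss_full, rss_reduced=rss_reduced,
        df_full=df_full, df_reduced=df_reduced,
        F=float(F_stat), p=p_val, interaction_p={},
        dffits=None, max_influence=None, cohort_lines=[],
        degenerate_perfect=degenerate_perfect,
        x=x, y=y, cohorts=cohorts,
        _cov_unscaled=cov_unscaled, _leverage=leverage, _residuals=resid,
    )
    if not degenerate_perfect:
        fit.interaction_p = interaction_pvalues(fit)
        d, m = dffits(fit)
        fit.dffits, fit.max_influence = d, m
    fit.cohort_lines = cohort_lines(fit)
    return fit


def interaction_pvalues(fit: PairFit) -> dict[str, float]:
    """Two-sided t-test p-value of each non-reference interaction coefficient.

    Tests whether cohort c's slope differs from the reference cohort's, with
    residual degrees of freedom df_full and standard errors from the diagonal
    of the unscaled covariance times rss_full/df_full.
    """
    if fit.degenerate_perfect or fit._cov_unscaled is None:
        raise ContractError("interaction p-values undefined for a degenerate fit")
    K = fit.n_cohorts
    sigma2 = fit.rss_full / fit.df_full
    out: dict[str, float] = {}
    for j, cohort in enumerate(fit.cohort_labels[1:], start=1):
        se = float(np.sqrt(sigma2 * fit._cov_unscaled[K + j, K + j]))
        t = fit.beta[K + j] / se if se > 0 else np.inf * np.sign(fit.beta[K + j])
        out[cohort] = float(2.0 * stats.t.sf(abs(t), fit.df_full))
    return out


def interaction_pvalue(fit: PairFit, cohort: str) -> float:
    """Interaction p-value for one cohort; the reference has no such term."""
    if cohort == fit.reference:
        raise ContractError(
            f"no interaction term for the reference cohort {cohort!r}"
        )
    if cohort not in fit.cohort_labels:
        raise ContractError(f"unknown cohort {cohort!r}")
    return interaction_pvalues(fit)[cohort]


def dffits(fit: PairFit) -> tuple[np.ndarray | None, float | None]:
    """Per-observation DFFITS and the maximum absolute influence.

    DFFITS_i = e_i * sqrt(h_i / (1 - h_i)) / (s_(i) * sqrt(1 - h_i)), the
    standardized change in prediction i when observation i is left out,
    computed in closed form from the full-model leverages h and residuals e;
    s_(i)^2 = (rss - e_i^2/(1-h_i)) / (df_full - 1).  Observations with zero
    residual get DFFITS = 0 by convention.

    Returns (None, None) with a warning when the deletion fit is undefined
    (df_full <= 1).
    """
    if fit.degenerate_perfect or fit._leverage is None:
        raise ContractError("DFFITS undefined for a degenerate fit")
    if fit.df_full <= 1:
        warnings.warn(
            f"pair ({fit.microbe}, {fit.immune}): too few residual df "
            f"({fit.df_full}) for leave-one-out diagnostics; skipped",
            stacklevel=2,
        )
        return None, None
    h = fit._leverage
    e = fit._residuals
    out = np.zeros_like(e)
    one_minus_h = np.clip(1.0 - h, 1e-12, None)
    s2_del = (fit.rss_full - e**2 / one_minus_h) / (fit.df_full - 1)
    s2_del = np.clip(s2_del, 0.0, None)
    nz = (e != 0.0) & (s2_del > 0.0)
    out[nz] = (
        e[nz] / np.sqrt(s2_del[nz] * one_minus_h[nz])
        * np.sqrt(h[nz] / one_minus_h[nz])
    )
    return out, float(np.max(np.abs(out)))


@dataclass(frozen=True)
class GlyphSegment:
    """A cohort line mapped into the unit square for microplot rendering."""

    cohort: str
    x0: float
    y0: float
    x1: float
    y1: float


def cohort_lines(fit: PairFit) -> list[CohortLine]:
    """Per-cohort (intercept, slope, x_min, x_max) fitted segments.

    Under treatment coding the reference cohort's line is (b0, b_x) and a
    non-reference cohort c's line is (b0 + b_c, b_x + b_cx).  Each segment
    spans only its own cohort's observed x range, so cohorts with different
    dynamic ranges draw segments of different lengths.
    """
    K = fit.n_cohorts
    out = []
    for j, cohort in enumerate(fit.cohort_labels):
        intercept = float(fit.beta[0] + (fit.beta[j] if j > 0 else 0.0))
        slope = float(fit.beta[K] + (fit.beta[K + j] if j > 0 else 0.0))
        xs = fit.x[fit.cohorts == cohort]
        out.append(CohortLine(cohort, intercept, slope,
                              float(xs.min()), float(xs.max())))
    return out


def glyph_segments(lines: list[CohortLine]) -> list[GlyphSegment]:
    """Map cohort segments into the unit square with a shared affine transform.

    The shared x range is the union of cohort x ranges and the shared y range
    the union of fitted values at segment endpoints, so the pooled extreme
    endpoints land on the unit-square boundary.  A degenerate (zero-width)
    range maps to the midline 0.5.
    """
    xs = [v for ln in lines for v in (ln.x_min, ln.x_max)]
    ys = [v for ln in lines for v in (ln.y_at_xmin, ln.y_at_xmax)]
    x_lo, x_hi = min(xs), max(xs)
    y_lo, y_hi = min(ys), max(ys)

    def nx(v: float) -> float:
        return (v - x_lo) / (x_hi - x_lo) if x_hi > x_lo else 0.5

    def ny(v: float) -> float:
        return (v - y_lo) / (y_hi - y_lo) if y_hi > y_lo else 0.5

    return [
        GlyphSegment(ln.cohort, nx(ln.x_min), ny(ln.y_at_xmin),
                     nx(ln.x_max), ny(ln.y_at_xmax))
        for ln in lines
    ]
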