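"""Partial least squares regression on field blocks, with leave-one-out
cross-validation and the internal statistics used to judge 3D-QSAR models.

The fit is single-response NIPALS with deflation on X, deterministic (no
random initialization).  Reported statistics follow the conventions
field-based QSAR packages print:

* r² = 1 − SSE/SST on the training data (non-cross-validated),
* SEE = √(SSE/(n − onc − 1)),
* F = (r²/onc) / ((1 − r²)/(n − onc − 1)),
* q² = 1 − PRESS/SST with each prediction from a model refit without that
  compound (column centering and channel scaling recomputed per fold),
* field contributions per channel: the share of Σ_j |b_j|·s_j with s_j the
  training standard deviation of column j (this package's convention; the
  field reports contributions without ever defining the formula).

A model is conventionally trusted when q² > 0.5, r² > 0.6 and SEE ≪ 1;
:func:`quality_gate` exposes that rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import DegenerateInputError, DomainError
from .field_engine import FieldBlock

_TOL = 1e-12


def _as_design(x, rows=None):
    """(design matrix, channel label per column) from a FieldBlock or ndarray."""
    if isinstance(x, FieldBlock):
        labels = x.column_channels()[x.column_mask]
        return x.design_matrix(rows), labels
    m = np.asarray(x, float)
    if rows is not None:
        m = m[rows]
    return m, np.array(["X"] * m.shape[1], object)


@dataclass
class PLSModelSummary:
    """Fitted PLS model with its internal validation statistics."""

    onc: int
    q2: float | None
    r2: float
    see: float
    f_stat: float
    contributions: dict[str, float]
    coefficients: np.ndarray     # per retained (scaled) column
    intercept: float
    x_mean: np.ndarray = dc_field(repr=False, default=None)
    y_mean: float = 0.0

    def predict(self, x, rows=None) -> np.ndarray:
        m, _ = _as_design(x, rows)
        return self.y_mean + (m - self.x_mean) @ self.coefficients


def _nipals(xc: np.ndarray, yc: np.ndarray, k: int):
    """NIPALS PLS1: returns (coefficients, components actually extracted)."""
    x = xc.copy()
    y = yc.copy()
    ws, ps, qs = [], [], []
    for _ in range(k):
        w = x.T @ y
        nw = np.linalg.norm(w)
        if nw < _TOL:
            break
        w /= nw
        t = x @ w
        tt = float(t @ t)
        if tt < _TOL:
            break
        p = x.T @ t / tt
        q = float(y @ t / tt)
        x -= np.outer(t, p)
        y = y - t * q
        ws.append(w)
        ps.append(p)
        qs.append(q)
    if not ws:
        return np.zeros(xc.shape[1]), 0
    W = np.column_stack(ws)
    P = np.column_stack(ps)
    b = W @ np.linalg.solve(P.T @ W, np.asarray(qs))
    return b, len(ws)


def fit_pls(x, y, n_components: int) -> PLSModelSummary:
    """Fit NIPALS PLS on centered (and block-scaled) data.

    ``x`` may be a :class:`FieldBlock` (its mask and channel scales apply)
    or a plain matrix.  Deflation may exhaust the rank of X before
    ``n_components``; the effective count is reported as ``onc``.
    """
    m, labels = _as_design(x)
    y = np.asarray(y, float).ravel()
    n, p = m.shape
    if n != y.size:
        raise DomainError(f"{n} rows of X vs {y.size} activities")
    if n_components < 1 or n_components > min(n - 1, p):
        raise DomainError(
            f"n_components must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    if np.std(y) < _TOL:
        raise DegenerateInputError("zero-variance activities")
    x_mean = m.mean(axis=0)
    y_mean = float(y.mean())
    b, onc = _nipals(m - x_mean, y - y_mean, n_components)
    resid = y - (y_mean + (m - x_mean) @ b)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y_mean) ** 2))
    r2 = 1.0 - sse / sst
    dof = max(n - onc - 1, 1)
    see = float(np.sqrt(sse / dof))
    f_stat = (r2 / onc) / ((1.0 - r2) / dof) if r2 < 1.0 else np.inf
    sd = m.std(axis=0, ddof=0)
    weight = np.abs(b) * sd
    total = weight.sum()
    contributions = {}
    for c in dict.fromkeys(labels):
        share = float(weight[labels == c].sum())
        contributions[str(c)] = share / total if total > 0 else 0.0
    return PLSModelSummary(onc=onc, q2=None, r2=r2, see=see, f_stat=f_stat,
                           contributions=contributions, coefficients=b,
                           intercept=y_mean - float(x_mean @ b),
                           x_mean=x_mean, y_mean=y_mean)


def loo_q2(x, y, n_components: int) -> float:
    """Leave-one-out q² = 1 − PRESS/SST.

    Every fold refits from scratch: when ``x`` is a :class:`FieldBlock`
    the channel variance scaling is recomputed on the n−1 training rows
    (the column mask stays fixed so dimensions are stable), and centering
    is always per-fold.
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    if n < 3:
        raise DomainError("leave-one-out needs n >= 3")
    if np.std(y) < _TOL:
        raise DegenerateInputError("zero-variance activities")
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        if isinstance(x, FieldBlock):
            from .field_engine import filter_and_scale
            fold = filter_and_scale(x, min_sd=0.0, train_rows=keep)
            fold.column_mask = x.column_mask
            m_train = fold.design_matrix(keep)
            m_test = fold.design_matrix([i])
        else:
            m = np.asarray(x, float)
            m_train, m_test = m[keep], m[[i]]
        k = min(n_components, m_train.shape[0] - 1, m_train.shape[1])
        x_mean = m_train.mean(axis=0)
        y_mean = float(y[keep].mean())
        b, _ = _nipals(m_train - x_mean, y[keep] - y_mean, k)
        pred = y_mean + float((m_test[0] - x_mean) @ b)
        press += (pred - y[i]) ** 2
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / sst


def select_onc(x, y, max_components: int = 15) -> tuple[int, list[float]]:
    """Optimal number of components: argmax of the LOO q² profile over
    1..max_components, ties broken toward fewer components."""
    if max_components < 1:
        raise DomainError("max_components must be >= 1")
    m, _ = _as_design(x)
    cap = min(max_components, m.shape[0] - 2, m.shape[1])
    profile = [loo_q2(x, y, k) for k in range(1, cap + 1)]
    onc = int(np.argmax(profile)) + 1
    for k, q in enumerate(profile, start=1):   # exact-tie rule: smallest index
        if q == profile[onc - 1]:
            onc = k
            break
    return onc, profile


def quality_gate(summary: PLSModelSummary, q2: float | None = None,
                 q2_min: float = 0.5, r2_min: float = 0.6,
                 see_max: float = 1.0) -> tuple[bool, list[str]]:
    """Internal-validation gate: q² > 0.5, r² > 0.6 and SEE well below 1."""
    q2 = summary.q2 if q2 is None else q2
    reasons = []
    if q2 is None or not q2 > q2_min:
        reasons.append(f"q2 {q2} fails > {q2_min}")
    if not summary.r2 > r2_min:
        reasons.append(f"r2 {summary.r2:.3f} fails > {r2_min}")
    if not summary.see < see_max:
        reasons.append(f"SEE {summary.see:.3f} fails < {see_max}")
    return (not reasons), reasons
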