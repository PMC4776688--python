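"""Transfer entropy between activity and heart rate, Darbellay-Vajda estimated.

Transfer entropy from a source X to a target Y with history lengths
k = l = 1, prediction lag t and source lag tau is

    TE(X -> Y) = sum p(y_{i+t}, y_i, x_{i+t-tau})
                 * log2[ p(y_{i+t} | y_i, x_{i+t-tau}) / p(y_{i+t} | y_i) ]

It measures, in bits, the reduction in uncertainty about the target's next
sample provided by the source's past beyond the target's own past.  Joint
probabilities are estimated by plug-in counts on a Darbellay-Vajda adaptive
partition of the rank-transformed sample space: each hyperrectangular cell
is recursively split at its marginal midpoints into 2^d subcells while a
chi-squared test rejects within-cell uniformity, and the marginal
probabilities a cell contributes are counted by projecting its edges onto
the corresponding coordinate subspaces.

Per subject the pipeline computes TE at tau = 1..5 on the synchronized
10-min grid in both directions and summarizes each five-point curve by
descending-degree cubic-fit coefficients, mirroring the MSE features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocessing import ParameterError, RegularSeries

DEFAULT_TAUS = (1, 2, 3, 4, 5)
MIN_TRIPLES = 500


@dataclass
class Cell:
    lo: np.ndarray
    hi: np.ndarray
    count: int


def rank_transform(x: np.ndarray) -> np.ndarray:
    """Map values to (0, 1) by average ranks; removes marginal-scale effects."""
    ranks = stats.rankdata(x, method="average")
    return (ranks - 0.5) / len(x)


def _in_range(x: np.ndarray, lo: float, hi: float, top: bool) -> np.ndarray:
    upper = x <= hi if top else x < hi
    return (x >= lo) & upper


def dv_partition(
    points: np.ndarray,
    alpha: float = 0.05,
    min_expected: float = 5.0,
) -> list[Cell]:
    """Adaptive partition of points in the unit box into locally uniform cells.

    A cell splits at its marginal midpoints into ``2^d`` subcells when the
    chi-squared statistic of the subcell counts exceeds the ``1 - alpha``
    quantile at ``2^d - 1`` degrees of freedom, provided the expected count
    per subcell (n_cell / 2^d) is at least ``min_expected``.  Leaves tile
    the box without overlap and their counts sum to n.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] not in (2, 3):
        raise ParameterError("dv_partition expects an (n, d) array with d in {2, 3}")
    n, d = pts.shape
    n_sub = 2 ** d
    crit = stats.chi2.ppf(1.0 - alpha, df=n_sub - 1)
    leaves: list[Cell] = []

    def recurse(idx: np.ndarray, lo: np.ndarray, hi: np.ndarray, depth: int) -> None:
        m = len(idx)
        expected = m / n_sub
        sub = pts[idx]
        # a cell of identical points (tied ranks) can never become uniform
        degenerate = m > 0 and np.all(sub.max(axis=0) == sub.min(axis=0))
        if expected < min_expected or degenerate or depth > 60:
            leaves.append(Cell(lo, hi, m))
            return
        mid = (lo + hi) / 2.0
        codes = np.zeros(m, dtype=int)
        for j in range(d):
            codes |= (sub[:, j] >= mid[j]).astype(int) << j
        counts = np.bincount(codes, minlength=n_sub)
        chi2_stat = np.sum((counts - expected) ** 2) / expected
        if chi2_stat <= crit:
            leaves.append(Cell(lo, hi, m))
            return
        for code in range(n_sub):
            clo, chi = lo.copy(), hi.copy()
            for j in range(d):
                if code >> j & 1:
                    clo[j] = mid[j]
                else:
                    chi[j] = mid[j]
            members = idx[codes == code]
            if len(members) == 0:
                leaves.append(Cell(clo, chi, 0))
            else:
                recurse(members, clo, chi, depth + 1)

    recurse(np.arange(n), np.zeros(d), np.ones(d), 0)
    return leaves


@dataclass
class TEParams:
    """Transfer-entropy estimator settings (k = l = 1 history blocks)."""

    t: int = 1
    tau: int = 1
    alpha: float = 0.05
    min_expected: float = 5.0
    min_triples: int = MIN_TRIPLES

    def __post_init__(self) -> None:
        if self.t < 1 or self.tau < 1:
            raise ParameterError("lags t and tau must be >= 1")


def transfer_entropy(
    source: np.ndarray, target: np.ndarray, params: TEParams | None = None
) -> float:
    """TE(source -> target) in bits on synchronized equally sampled arrays.

    Triples ``(y_{i+t}, y_i, x_{i+t-tau})`` with any missing member are
    dropped; returns NaN when fewer than ``min_triples`` remain.
    """
    params = params or TEParams()
    x = np.asarray(source, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("source and target must be equally long")
    t, tau = params.t, params.tau
    i0 = max(0, tau - t)
    i1 = len(y) - t
    if i1 <= i0:
        return np.nan
    i = np.arange(i0, i1)
    yf, yp, xp = y[i + t], y[i], x[i + t - tau]
    ok = ~(np.isnan(yf) | np.isnan(yp) | np.isnan(xp))
    yf, yp, xp = yf[ok], yp[ok], xp[ok]
    n = len(yf)
    if n < params.min_triples:
        return np.nan

    pts = np.column_stack([rank_transform(yf), rank_transform(yp), rank_transform(xp)])
    leaves = dv_partition(pts, alpha=params.alpha, min_expected=params.min_expected)

    te = 0.0
    for cell in leaves:
        if cell.count == 0:
            continue
        top = cell.hi >= 1.0  # include the closed upper face of the unit box
        in_yf = _in_range(pts[:, 0], cell.lo[0], cell.hi[0], top[0])
        in_yp = _in_range(pts[:, 1], cell.lo[1], cell.hi[1], top[1])
        in_xp = _in_range(pts[:, 2], cell.lo[2], cell.hi[2], top[2])
        n_yp = int(in_yp.sum())
        n_ypxp = int((in_yp & in_xp).sum())
        n_yfyp = int((in_yf & in_yp).sum())
        te += (cell.count / n) * np.log2(cell.count * n_yp / (n_ypxp * n_yfyp))
    return float(te)


@dataclass
class CouplingProfile:
    """TE values at tau = 1..5 for one direction plus the cubic-fit coefficients."""

    direction: str  # "act->hr" or "hr->act"
    taus: np.ndarray
    te: np.ndarray
    coeffs: np.ndarray
    available: bool = True


def te_profile(
    source: RegularSeries | np.ndarray,
    target: RegularSeries | np.ndarray,
    direction: str,
    taus: tuple[int, ...] = DEFAULT_TAUS,
    t: int = 1,
    alpha: float = 0.05,
    min_expected: float = 5.0,
    min_triples: int = MIN_TRIPLES,
) -> CouplingProfile:
    from .complexity import fit_cubic

    x = source.values if isinstance(source, RegularSeries) else np.asarray(source, float)
    y = target.values if isinstance(target, RegularSeries) else np.asarray(target, float)
    te = np.array([
        transfer_entropy(x, y, TEParams(t=t, tau=tau, alpha=alpha,
                                        min_expected=min_expected,
                                        min_triples=min_triples))
        for tau in taus
    ])
    taus_arr = np.asarray(taus)
    if np.isnan(te).any():
        return CouplingProfile(direction, taus_arr, te, np.full(4, np.nan),
                               available=False)
    return CouplingProfile(direction, taus_arr, te, fit_cubic(taus_arr, te))
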