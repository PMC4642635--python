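"""Haplotype-sharing relatedness measures and marker-based comparators.

Given the N×|E| haplomarker design matrix ``X`` (multiplicities
``x_is ∈ {0,1,2}`` of segment ``s`` in genome ``i``, with ``2p`` segments
per genome), two similarity measures are defined:

* the intersect measure  ``b_ij = Σ_s min(x_is, x_js) / 2p`` — the fraction
  of genome the two individuals share; ``b_ii = 1`` and ``0 ≤ b_ij ≤ 1``;
* the product measure    ``c_ij = Σ_s x_is x_js / 2p = (X Xᵀ / 2p)_ij`` —
  twice the identity-by-state coefficient of coancestry off the diagonal
  and ``1 + f_i`` on it, where ``f_i`` is the IBS inbreeding
  (homozygosity) of individual ``i``.

For multiplicities in {0,1,2}, ``xy = 2 min(x,y) − I(x = y = 1)``, giving
the link ``C = 2B − κ`` where ``κ_ij`` counts intervals heterozygous for
the same segment pair in both genomes (shared heterozygosity). All
numerators are accumulated in integer arithmetic and divided once, so these
identities hold exactly.

The module also provides vanRaden's marker-based G, off-diagonal matrix
comparison statistics (mean squared deviation and adjusted R² with and
without intercept), and a ``−log b`` distance with classical principal
coordinates for visualising relatedness structure.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import DimensionError, NumericalError
from .genomes import HaplomarkerMatrix

__all__ = [
    "RelationshipMatrix",
    "intersect_measure",
    "product_measure",
    "shared_heterozygosity",
    "homozygosity",
    "vanraden_g",
    "compare_matrices",
    "b_to_distance",
    "principal_coordinates",
]

SYMMETRY_TOL = 1e-12
WEIGHT_SUM_TOL = 1e-9


class RelationshipMatrix:
    """Labelled symmetric N×N relationship matrix.

    ``kind`` tags the construction: "A" (pedigree numerator), "B"
    (intersect), "C" (product), "G" (vanRaden), "R" (hybrid),
    "kappa" or "conditioned".
    """

    def __init__(self, values: np.ndarray, ids: Sequence[str], kind: str = ""):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise DimensionError(f"relationship matrix must be square, got {values.shape}")
        if values.shape[0] != len(ids):
            raise DimensionError(
                f"{len(ids)} ids for a {values.shape[0]}×{values.shape[1]} matrix"
            )
        asym = np.max(np.abs(values - values.T), initial=0.0)
        if asym > SYMMETRY_TOL:
            raise DimensionError(f"matrix is asymmetric (max |M - Mᵀ| = {asym:g})")
        self.values = values
        self.ids = list(ids)
        self.kind = kind

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def loc(self, id1: str, id2: str) -> float:
        return float(self.values[self.ids.index(id1), self.ids.index(id2)])

    def restrict(self, subset: Sequence[str]) -> "RelationshipMatrix":
        """Submatrix over ``subset``, in the given order."""
        pos = {v: i for i, v in enumerate(self.ids)}
        try:
            idx = np.array([pos[s] for s in subset], dtype=int)
        except KeyError as exc:
            raise DimensionError(f"id {exc.args[0]!r} not in matrix") from None
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], list(subset), self.kind)

    def offdiagonals(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries (i < j), row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def __repr__(self) -> str:
        return f"RelationshipMatrix(kind={self.kind!r}, n={self.n})"


def _check_weights(weights, p: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (p,):
        raise DimensionError(f"expected {p} interval weights, got shape {w.shape}")
    if np.any(w < 0):
        raise DimensionError("interval weights must be non-negative")
    if abs(w.sum() - 1.0) > WEIGHT_SUM_TOL:
        raise DimensionError(f"interval weights sum to {w.sum()!r}, not 1")
    return w


def _grams(X: HaplomarkerMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Integer Gram matrices: XXᵀ and HHᵀ with H = I(X == 1)."""
    V = X.values
    H = (V == 1).astype(np.int64)
    return V @ V.T, H @ H.T


def intersect_measure(
    X: HaplomarkerMatrix, weights: Sequence[float] | None = None
) -> RelationshipMatrix:
    """Intersect measure B: fraction of shared genome.

    Unweighted: ``b_ij = Σ_s min(x_is, x_js) / 2p``. With interval weights
    ``w`` (non-negative, summing to one): ``b_ij = Σ_s w_{l(s)}
    min(x_is, x_js) / 2``; uniform weights ``w_k = 1/p`` reproduce the
    unweighted measure (computed through the same integer path, scaled by
    ``p·w``, so the agreement is exact).
    """
    p = X.p
    w = None if weights is None else _check_weights(weights, p)
    if w is None or np.all(w == w[0]):
        gx, gh = _grams(X)
        B = (gx + gh) / (4 * p)
        if w is not None:
            B = B * float(w[0] * p)
    else:
        V, lev = X.values, X.levels
        H = (V == 1).astype(np.int64)
        wc = w[lev]
        B = ((V * wc) @ V.T + (H * wc) @ H.T) / 4.0
        B = (B + B.T) / 2.0
    return RelationshipMatrix(B, X.ids, kind="B")


def product_measure(
    X: HaplomarkerMatrix, weights: Sequence[float] | None = None
) -> RelationshipMatrix:
    """Product measure C = XXᵀ/2p; diagonal is ``1 + f_i``.

    Weighted form: ``c_ij = Σ_s w_{l(s)} x_is x_js / 2``; uniform weights
    reduce exactly to the unweighted measure.
    """
    p = X.p
    w = None if weights is None else _check_weights(weights, p)
    if w is None or np.all(w == w[0]):
        C = (X.values @ X.values.T) / (2 * p)
        if w is not None:
            C = C * float(w[0] * p)
    else:
        C = (X.values * w[X.levels]) @ X.values.T / 2.0
        C = (C + C.T) / 2.0
    return RelationshipMatrix(C, X.ids, kind="C")


def shared_heterozygosity(X: HaplomarkerMatrix) -> RelationshipMatrix:
    """κ_ij = #{s : x_is = x_js = 1} / 2p, linking the measures: C = 2B − κ."""
    _, gh = _grams(X)
    return RelationshipMatrix(gh / (2 * X.p), X.ids, kind="kappa")


def homozygosity(X: HaplomarkerMatrix) -> pd.Series:
    """f_i = #{s : x_is = 2} / p — the IBS-sense inbreeding coefficient."""
    f = (X.values == 2).sum(axis=1) / X.p
    return pd.Series(f, index=X.ids, name="f")


def vanraden_g(
    M: np.ndarray,
    ids: Sequence[str] | None = None,
    denominator: str = "allele-frequency",
    drop_monomorphic: bool = False,
) -> RelationshipMatrix:
    """vanRaden's genomic relationship matrix from unphased genotypes.

    ``M`` is N×p with genotype codes in {0, 1, 2}. Rows are centered by the
    column means ``m̄_k`` (sample frequencies) and the cross-products scaled
    by a single denominator:

    * ``denominator="allele-frequency"`` (default): ``Σ_k 2 p̂_k (1 − p̂_k)``
      with ``p̂_k = m̄_k / 2`` — the standard method-1 scaling;
    * ``denominator="genotype-mean"``: ``Σ_k 2 m̄_k (1 − m̄_k)`` using the
      mean genotype directly (may be negative when ``m̄_k > 1``; exposed for
      comparison only).

    Markers with no variation are an error unless ``drop_monomorphic``.
    Sample-mean centering forces every row of G to sum to zero.
    """
    M = np.asarray(M)
    if M.ndim != 2:
        raise DimensionError(f"genotype matrix must be 2-D, got shape {M.shape}")
    n, p = M.shape
    if n < 2:
        raise DimensionError("vanRaden G requires at least two individuals")
    if not np.isin(M, (0, 1, 2)).all():
        raise DimensionError("genotypes must take values in {0, 1, 2}")
    if ids is None:
        ids = [str(i) for i in range(n)]

    constant = (M == M[0]).all(axis=0)
    if constant.any():
        which = np.flatnonzero(constant)
        if not drop_monomorphic:
            raise DimensionError(
                f"monomorphic marker(s) at column(s) {which.tolist()}; "
                "re-run with drop_monomorphic=True to exclude them"
            )
        M = M[:, ~constant]
        if M.shape[1] == 0:
            raise DimensionError("all markers are monomorphic")

    mbar = M.mean(axis=0)
    if denominator == "allele-frequency":
        phat = mbar / 2.0
        denom = float(np.sum(2.0 * phat * (1.0 - phat)))
    elif denominator == "genotype-mean":
        denom = float(np.sum(2.0 * mbar * (1.0 - mbar)))
    else:
        raise ValueError(
            f"denominator must be 'allele-frequency' or 'genotype-mean', got {denominator!r}"
        )
    if denom == 0.0:
        raise NumericalError("vanRaden denominator is zero")
    centered = M - mbar
    G = (centered @ centered.T) / denom
    G = (G + G.T) / 2.0  # exact symmetry against rounding
    return RelationshipMatrix(G, ids, kind="G")


def compare_matrices(x1: RelationshipMatrix, x2: RelationshipMatrix) -> dict:
    """Off-diagonal agreement between two relationship matrices.

    Returns the mean squared deviation over the distinct off-diagonal pairs
    and adjusted R² statistics from simple linear regressions of the
    off-diagonals of ``x1`` (the reference measure) on those of ``x2``,
    with and without an intercept.
    """
    if x1.ids != x2.ids:
        raise DimensionError("matrices must share the same ids in the same order")
    y = x1.offdiagonals()
    x = x2.offdiagonals()
    n = y.size
    if n < 3:
        raise DimensionError("need at least three individuals to compare off-diagonals")
    msd = float(np.mean((y - x) ** 2))

    # no intercept: y = βx
    sxx = float(x @ x)
    slope0 = float(x @ y) / sxx if sxx > 0 else 0.0
    ss_res0 = float(np.sum((y - slope0 * x) ** 2))
    ss_tot0 = float(y @ y)
    r2_0 = 1.0 - ss_res0 / ss_tot0 if ss_tot0 > 0 else float("nan")
    adj0 = 1.0 - (1.0 - r2_0) * n / (n - 1)

    # with intercept: y = α + βx
    xc, yc = x - x.mean(), y - y.mean()
    sxx_c = float(xc @ xc)
    slope1 = float(xc @ yc) / sxx_c if sxx_c > 0 else 0.0
    alpha = float(y.mean() - slope1 * x.mean())
    ss_res1 = float(np.sum((y - alpha - slope1 * x) ** 2))
    ss_tot1 = float(yc @ yc)
    r2_1 = 1.0 - ss_res1 / ss_tot1 if ss_tot1 > 0 else float("nan")
    adj1 = 1.0 - (1.0 - r2_1) * (n - 1) / (n - 2)

    return {
        "msd": msd,
        "adj_r2_no_intercept": adj0,
        "adj_r2_with_intercept": adj1,
        "slope_no_intercept": slope0,
        "slope_with_intercept": slope1,
        "intercept": alpha,
        "n_pairs": n,
    }


def b_to_distance(B: RelationshipMatrix) -> np.ndarray:
    """−log(b) distance matrix; ``b = 0`` pairs map to ``inf``, diagonal 0."""
    with np.errstate(divide="ignore"):
        D = -np.log(B.values)
    np.fill_diagonal(D, 0.0)
    return D


def principal_coordinates(D: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Classical scaling of a distance matrix.

    Double-centers ``−D²/2`` and eigen-decomposes; returns the N×k
    coordinate matrix (columns ordered by decreasing eigenvalue, scaled by
    the square roots of the positive eigenvalues; non-positive axes are
    zero) together with the first ``k`` eigenvalues. Non-finite distances
    are refused.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DimensionError(f"distance matrix must be square, got {D.shape}")
    if not np.isfinite(D).all():
        raise NumericalError(
            "distance matrix contains non-finite entries (pairs with b = 0); "
            "principal coordinates require finite distances"
        )
    n = D.shape[0]
    if not 1 <= k <= n - 1:
        raise DimensionError(f"number of axes k={k} must be in 1..{n - 1}")
    D2 = D * D
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    Bmat = -0.5 * J @ D2 @ J
    Bmat = (Bmat + Bmat.T) / 2.0
    eigval, eigvec = scipy.linalg.eigh(Bmat)
    order = np.argsort(eigval)[::-1][:k]
    lam = eigval[order]
    coords = eigvec[:, order] * np.sqrt(np.clip(lam, 0.0, None))
    return coords, lam
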