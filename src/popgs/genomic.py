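"""Marker QC, panel construction and genomic relationship matrices.

The additive genomic relationship matrix follows VanRaden's cross-product
form with trace normalisation,

    G = (M - P1) W (M - P1)' / (trace[(M - P1) W (M - P1)'] / n),

where ``M`` is the n x m dosage matrix, ``P1`` the matrix of ``2 p_j``
(observed allele frequencies), and ``W`` an optional diagonal of per-marker
weights.  The genomic dominance matrix uses the heterozygosity indicator
coding centred by ``2 p_j q_j``.  Both have ``trace(K)/n = 1`` exactly by
construction.

Marker panels are built from an imputation-quality table: hard filters on
Props (proportion of alleles correctly imputed), cProps (its chance-corrected
counterpart) and MAF, followed by window thinning that keeps the
best-supported marker per fixed-width genomic window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, InvalidParameterError, RelationshipMatrix

__all__ = [
    "filter_markers", "thin_markers", "make_weights",
    "g_matrix", "d_matrix_genomic", "regularize",
]

_QC_COLUMNS = ("marker", "chrom", "pos_bp", "props", "cprops", "maf")


def _check_qc(qc: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _QC_COLUMNS if c not in qc.columns]
    if missing:
        raise InvalidParameterError(f"QC table lacks columns {missing}")
    return qc


def filter_markers(qc: pd.DataFrame, props_min: float = 0.90,
                   cprops_min: float = 0.60, maf_min: float = 0.05) -> pd.DataFrame:
    """Markers passing all three strict thresholds, original order preserved.

    The boundary convention is strict (a marker with Props exactly at the
    threshold is excluded).
    """
    qc = _check_qc(qc)
    for name, val in (("props_min", props_min), ("cprops_min", cprops_min),
                      ("maf_min", maf_min)):
        if not 0.0 <= val <= 1.0:
            raise InvalidParameterError(f"{name}={val} outside [0, 1]")
    keep = ((qc["props"] > props_min) & (qc["cprops"] > cprops_min)
            & (qc["maf"] > maf_min))
    return qc.loc[keep]


def thin_markers(qc: pd.DataFrame, window_bp: int) -> pd.DataFrame:
    """Keep at most one marker per non-overlapping window per chromosome.

    Windows are anchored at position 1 (1-based, half-open).  Within a
    window the marker with the highest Props wins, ties broken by highest
    cProps, remaining ties by lowest position.  Output keeps genomic order.
    """
    qc = _check_qc(qc)
    if window_bp <= 0:
        raise InvalidParameterError("window_bp must be positive")
    df = qc.copy()
    df["_win"] = (df["pos_bp"].astype(np.int64) - 1) // int(window_bp)
    df["_ord"] = np.arange(len(df))
    best = (df.sort_values(["chrom", "_win", "props", "cprops", "pos_bp"],
                           ascending=[True, True, False, False, True],
                           kind="stable")
              .groupby(["chrom", "_win"], sort=False).head(1)
              .sort_values("_ord"))
    return best.drop(columns=["_win", "_ord"])


def make_weights(values: np.ndarray) -> np.ndarray:
    """Validate and rescale per-marker weights to mean 1."""
    w = np.asarray(values, dtype=float)
    if (w < 0).any() or not np.isfinite(w).all():
        raise InvalidParameterError("weights must be finite and non-negative")
    mean = w.mean()
    if mean <= 0:
        raise InvalidParameterError("weights sum to zero")
    return w / mean


def _trace_normalized(Zc: np.ndarray, weights: np.ndarray | None,
                      ids, kind: str) -> RelationshipMatrix:
    n = Zc.shape[0]
    if weights is not None:
        w = make_weights(weights)
        if w.shape[0] != Zc.shape[1]:
            raise InvalidParameterError(
                f"{w.shape[0]} weights for {Zc.shape[1]} markers")
        ZW = Zc * w
    else:
        ZW = Zc
    K = ZW @ Zc.T
    c = np.trace(K) / n
    if c <= 0:
        raise InvalidParameterError(
            "zero trace: no polymorphic markers contribute to the matrix")
    return RelationshipMatrix(ids=list(ids), values=K / c, kind=kind, scale=c)


def g_matrix(genotypes: GenotypeMatrix, weights: np.ndarray | None = None,
             allele_freq: np.ndarray | None = None) -> RelationshipMatrix:
    """VanRaden additive genomic relationship matrix with trace scaling.

    By default the centring frequencies are the observed frequencies of the
    genotyped set; pass ``allele_freq`` to centre on a declared base
    population (e.g. founder frequencies), which makes the expectations of
    the entries match the pedigree coefficients.  Missing dosages must be
    imputed beforehand (``GenotypeMatrix.impute_mean``).  Monomorphic
    markers contribute zero columns after centring and are harmless; an
    all-monomorphic panel raises an error.
    """
    M = np.asarray(genotypes.dosages, dtype=float)
    if np.isnan(M).any():
        raise InvalidParameterError(
            "missing genotypes; impute to marker means first")
    p = (M.mean(axis=0) / 2.0 if allele_freq is None
         else np.asarray(allele_freq, dtype=float))
    Mc = M - 2.0 * p
    kind = "G" if weights is None else "Gw"
    return _trace_normalized(Mc, weights, genotypes.ids, kind)


def d_matrix_genomic(genotypes: GenotypeMatrix,
                     weights: np.ndarray | None = None,
                     allele_freq: np.ndarray | None = None
                     ) -> RelationshipMatrix:
    """Genomic dominance relationship matrix (heterozygosity coding).

    The indicator of heterozygosity is centred by ``2 p_j q_j`` and the
    cross-product is trace-normalised exactly as for the additive matrix.
    A panel with no heterozygous genotype at all carries no dominance
    information and raises an error.
    """
    M = np.asarray(genotypes.dosages, dtype=float)
    if np.isnan(M).any():
        raise InvalidParameterError(
            "missing genotypes; impute to marker means first")
    X = (M == 1).astype(float)
    if not X.any():
        raise InvalidParameterError(
            "fully homozygous genotypes: dominance matrix is degenerate")
    p = (M.mean(axis=0) / 2.0 if allele_freq is None
         else np.asarray(allele_freq, dtype=float))
    Xc = X - 2.0 * p * (1.0 - p)
    kind = "D_gen" if weights is None else "Dw"
    return _trace_normalized(Xc, weights, genotypes.ids, kind)


def regularize(K: RelationshipMatrix, epsilon: float) -> RelationshipMatrix:
    """Shrink toward the identity: ``K' = (1 - eps) K + eps I``.

    For ``epsilon > 0`` the result is positive definite whenever ``K`` is
    positive semi-definite, making it safe to invert in the mixed-model
    equations.
    """
    if epsilon < 0:
        raise InvalidParameterError("epsilon must be >= 0")
    if epsilon == 0:
        return K
    V = (1.0 - epsilon) * K.values + epsilon * np.eye(K.n)
    return RelationshipMatrix(ids=K.ids, values=V, kind=K.kind, scale=K.scale)
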