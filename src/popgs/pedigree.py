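"""Pedigree-based relationship matrices, marker-based pedigree correction,
and effective population size.

The numerator relationship matrix ``A`` is built by the tabular method with
founders assumed unrelated and non-inbred.  The pedigree dominance matrix
follows the classical parental-pair identity
``D(X,Y) = 0.25 (A(a,c) A(b,d) + A(a,d) A(b,c))``.

Pedigree correction uses opposing-homozygote exclusion: a parent sharing no
recent ancestry with an offspring accumulates marker loci at which the two
carry opposite homozygous genotypes, whereas a true parent shows none (up to
genotyping error).  Misassigned parents are reassigned to the declared
candidate with the smallest opposing-homozygote count, or set unknown when no
candidate is compatible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (UNKNOWN, GenotypeMatrix, InvalidParameterError, Pedigree,
                   PedigreeError, RelationshipMatrix, read_pedigree)  # noqa: F401

__all__ = [
    "read_pedigree", "a_matrix", "d_matrix_pedigree", "opposing_homozygotes",
    "correct_pedigree", "effective_size",
]


def a_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator (additive) relationship matrix by the tabular method.

    Founders are treated as unrelated and non-inbred; the diagonal is
    ``1 + F`` with ``F`` the inbreeding coefficient.
    """
    n = len(pedigree)
    si, di = pedigree.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = si[i], di[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(ids=pedigree.ids, values=A, kind="A")


def d_matrix_pedigree(pedigree: Pedigree,
                      A: RelationshipMatrix | None = None) -> RelationshipMatrix:
    """Pedigree dominance relationship matrix.

    For X with parents (a, b) and Y with parents (c, d),
    ``D(X,Y) = 0.25 (A(a,c) A(b,d) + A(a,d) A(b,c))``; entries involving an
    unknown parent are zero and the diagonal is 1 (non-inbred convention).
    """
    if A is None:
        A = a_matrix(pedigree)
    if [str(i) for i in A.ids] != pedigree.ids:
        A = A.submatrix(pedigree.ids)
    n = len(pedigree)
    si, di = pedigree.parent_indices()
    Av = A.values
    # pad with a zero row/column standing in for unknown parents
    Ap = np.zeros((n + 1, n + 1))
    Ap[:n, :n] = Av
    s = np.where(si >= 0, si, n)
    d = np.where(di >= 0, di, n)
    D = 0.25 * (Ap[np.ix_(s, s)] * Ap[np.ix_(d, d)]
                + Ap[np.ix_(s, d)] * Ap[np.ix_(d, s)])
    np.fill_diagonal(D, 1.0)
    return RelationshipMatrix(ids=pedigree.ids, values=D, kind="D_ped")


def opposing_homozygotes(genotypes: GenotypeMatrix, offspring: str,
                         candidate: str) -> int:
    """Count markers at which one individual is dosage 0 and the other 2."""
    a = np.asarray(genotypes.row(offspring), dtype=float)
    b = np.asarray(genotypes.row(candidate), dtype=float)
    shared = ~(np.isnan(a) | np.isnan(b))
    if not shared.any():
        raise InvalidParameterError(
            f"no shared non-missing markers between {offspring!r} and {candidate!r}")
    a, b = a[shared], b[shared]
    return int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))


def _oh_counts(geno_a: np.ndarray, geno_b: np.ndarray) -> np.ndarray:
    """Pairwise opposing-homozygote counts between rows of two dosage blocks."""
    a0 = (geno_a == 0).astype(np.float64)
    a2 = (geno_a == 2).astype(np.float64)
    b0 = (geno_b == 0).astype(np.float64)
    b2 = (geno_b == 2).astype(np.float64)
    return (a0 @ b2.T + a2 @ b0.T)


def correct_pedigree(pedigree: Pedigree, genotypes: GenotypeMatrix,
                     oh_threshold_fraction: float = 0.01
                     ) -> tuple[Pedigree, pd.DataFrame]:
    """Reassign misattributed parents using opposing-homozygote exclusion.

    For each offspring, a declared parent whose opposing-homozygote fraction
    exceeds ``oh_threshold_fraction`` is replaced by the declared candidate
    (of the same parental role) with the smallest count, provided that count
    falls below the threshold; otherwise the parent is set unknown.  Returns
    the corrected pedigree and a change log.
    """
    m = genotypes.n_markers
    thresh = oh_threshold_fraction * m
    log_rows = []
    new_records = []
    offspring = pedigree.offspring()
    off_geno = genotypes.subset(ids=offspring).dosages
    # candidate parents: ids declared in the role, plus genotyped founders
    # whose role is unknown (e.g. a parent whose every offspring was
    # mislabelled no longer appears as sire or dam)
    sires, dams = pedigree.sires(), pedigree.dams()
    roleless = [f for f in pedigree.founders()
                if f not in set(sires) | set(dams)
                and f in set(genotypes.ids)]
    candidates = {"sire": sires + roleless, "dam": dams + roleless}
    cand_geno = {r: genotypes.subset(ids=c).dosages for r, c in candidates.items()}
    oh = {r: _oh_counts(off_geno, g) for r, g in cand_geno.items()}
    off_index = {o: k for k, o in enumerate(offspring)}

    for iid, sire, dam in pedigree.records:
        if sire == UNKNOWN and dam == UNKNOWN:
            new_records.append((iid, sire, dam))
            continue
        k = off_index[iid]
        new_parents = []
        for role, declared in (("sire", sire), ("dam", dam)):
            cands = candidates[role]
            counts = oh[role][k]
            if declared == UNKNOWN:
                new_parents.append(declared)
                continue
            declared_count = counts[cands.index(declared)]
            if declared_count <= thresh:
                new_parents.append(declared)
                continue
            # exclude the offspring itself from candidacy
            order = np.argsort(counts, kind="stable")
            best = next((j for j in order if cands[j] != iid), None)
            if best is not None and counts[best] <= thresh:
                new_parent = cands[best]
            else:
                new_parent = UNKNOWN
            new_parents.append(new_parent)
            log_rows.append({
                "id": iid, "role": role, "old": declared, "new": new_parent,
                "oh_old": int(declared_count),
                "oh_new": (int(counts[best]) if new_parent != UNKNOWN else np.nan),
            })
        new_records.append((iid, new_parents[0], new_parents[1]))

    log = pd.DataFrame(log_rows,
                       columns=["id", "role", "old", "new", "oh_old", "oh_new"])
    return Pedigree(new_records), log


def effective_size(K: RelationshipMatrix, group: list[str] | None = None) -> float:
    """Effective population size (status number) from mean group coancestry.

    ``Ns = 1 / (2 fbar)`` with ``fbar`` the mean of the coancestry matrix
    ``C = K / 2`` over all ordered pairs (including self pairs) of ``group``.
    """
    if group is None:
        group = K.ids
    idx = K.indices(group)
    C = K.values[np.ix_(idx, idx)] / 2.0
    fbar = float(C.mean())
    if fbar <= 0:
        raise InvalidParameterError("mean coancestry is zero; Ns undefined")
    return 1.0 / (2.0 * fbar)
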