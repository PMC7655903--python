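"""Shared containers and text-format I/O.

The pipeline moves three kinds of objects between stages: a :class:`Pedigree`
(topologically ordered id/sire/dam triplets), a :class:`GenotypeMatrix`
(individuals x markers allele dosages, optionally phased, with a marker map),
and a :class:`RelationshipMatrix` (symmetric relationship coefficients keyed
by individual ids).  All on-disk formats are plain text (CSV/TSV/VCF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: reserved id for an unknown parent in pedigree files
UNKNOWN = "0"


class PopgsError(ValueError):
    """Base class for errors raised by this package."""


class InvalidParameterError(PopgsError):
    pass


class PedigreeError(PopgsError):
    pass


class ConvergenceError(PopgsError):
    """REML did not converge; carries the last iterate in ``.model``."""

    def __init__(self, message, model=None):
        super().__init__(message)
        self.model = model


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

class Pedigree:
    """Ordered (id, sire, dam) records with parents before offspring.

    Construction validates uniqueness of ids and absence of cycles, and
    topologically sorts records so that every parent precedes its offspring.
    Parents that are used but never declared as individuals are added
    implicitly as founders.  Unknown parents are coded ``"0"``.
    """

    def __init__(self, records: Iterable[tuple[str, str, str]]):
        records = [(str(i), str(s), str(d)) for i, s, d in records]
        ids = [r[0] for r in records]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise PedigreeError(
                f"duplicate individual ids: {list(dup[dup > 1].index)[:5]}"
            )
        if UNKNOWN in set(ids):
            raise PedigreeError(f"{UNKNOWN!r} is reserved for unknown parents")
        declared = set(ids)
        implicit = []
        for _, s, d in records:
            for p in (s, d):
                if p != UNKNOWN and p not in declared:
                    declared.add(p)
                    implicit.append((p, UNKNOWN, UNKNOWN))
        records = implicit + records
        self._records = self._toposort(records)
        self._index = {r[0]: k for k, r in enumerate(self._records)}

    @staticmethod
    def _toposort(records):
        by_id = {r[0]: r for r in records}
        order: list[tuple[str, str, str]] = []
        state: dict[str, int] = {}  # 0 in progress, 1 done

        for start, _, _ in records:
            if state.get(start) == 1:
                continue
            stack = [start]
            while stack:
                node = stack[-1]
                if state.get(node) == 1:
                    stack.pop()
                    continue
                state[node] = 0
                pending = []
                for p in by_id[node][1:]:
                    if p == UNKNOWN or state.get(p) == 1:
                        continue
                    if state.get(p) == 0:
                        raise PedigreeError(
                            f"pedigree cycle involving {node!r} and {p!r}"
                        )
                    pending.append(p)
                if pending:
                    stack.extend(pending)
                else:
                    state[node] = 1
                    order.append(by_id[node])
                    stack.pop()
        return order

    # -- accessors ---------------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self._records]

    @property
    def records(self) -> list[tuple[str, str, str]]:
        return list(self._records)

    def __len__(self):
        return len(self._records)

    def __contains__(self, item):
        return item in self._index

    def parents_of(self, iid: str) -> tuple[str, str]:
        return self._records[self._index[iid]][1:]

    def founders(self) -> list[str]:
        return [i for i, s, d in self._records if s == UNKNOWN and d == UNKNOWN]

    def offspring(self) -> list[str]:
        return [i for i, s, d in self._records if s != UNKNOWN or d != UNKNOWN]

    def sires(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, s, _ in self._records:
            if s != UNKNOWN:
                seen.setdefault(s)
        return list(seen)

    def dams(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, _, d in self._records:
            if d != UNKNOWN:
                seen.setdefault(d)
        return list(seen)

    def families(self) -> dict[tuple[str, str], list[str]]:
        """Full-sib families: (sire, dam) -> offspring, both parents known."""
        fams: dict[tuple[str, str], list[str]] = {}
        for i, s, d in self._records:
            if s != UNKNOWN and d != UNKNOWN:
                fams.setdefault((s, d), []).append(i)
        return fams

    def family_map(self) -> dict[str, str]:
        """Map offspring id -> family label 'sire x dam'."""
        out = {}
        for (s, d), members in self.families().items():
            for m in members:
                out[m] = f"{s}x{d}"
        return out

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire/dam row indices in pedigree order; -1 for unknown."""
        si = np.full(len(self), -1, dtype=np.int64)
        di = np.full(len(self), -1, dtype=np.int64)
        for k, (_, s, d) in enumerate(self._records):
            if s != UNKNOWN:
                si[k] = self._index[s]
            if d != UNKNOWN:
                di[k] = self._index[d]
        return si, di

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._records, columns=["id", "sire", "dam"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __eq__(self, other):
        return isinstance(other, Pedigree) and self._records == other._records


def read_pedigree(path) -> Pedigree:
    """Read and validate a 3-column pedigree file (id, sire, dam).

    Accepts comma or whitespace separation, with or without a header line.
    Children listed before their parents are reordered; cycles and duplicate
    ids raise :class:`PedigreeError`.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     header=None, comment="#", skip_blank_lines=True)
    if df.shape[1] < 3:
        raise PedigreeError(f"expected 3 columns in {path}, got {df.shape[1]}")
    first = [str(x).lower() for x in df.iloc[0, :3]]
    if first[0] in ("id", "individual", "indiv") or first[1] in ("sire", "father"):
        df = df.iloc[1:]
    df = df.iloc[:, :3].fillna(UNKNOWN)
    return Pedigree(df.itertuples(index=False, name=None))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x markers allele dosages (0/1/2) with a marker map.

    ``markers`` has columns ``marker``, ``chrom``, ``pos_bp``.  When
    ``haplotypes`` is present it is an (n, m, 2) array of per-gamete allele
    counts whose sum over the last axis equals ``dosages``; it is carried by
    the simulator so that gene dropping stays phase-aware.
    """

    ids: list[str]
    dosages: np.ndarray
    markers: pd.DataFrame
    haplotypes: np.ndarray | None = None

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.ids), len(self.markers)):
            raise InvalidParameterError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} ids x {len(self.markers)} markers"
            )
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def row(self, iid: str) -> np.ndarray:
        return self.dosages[self._index[str(iid)]]

    def subset(self, ids: Sequence[str] | None = None,
               marker_mask: np.ndarray | None = None) -> "GenotypeMatrix":
        rows = (np.arange(self.n_individuals) if ids is None
                else np.array([self._index[str(i)] for i in ids]))
        cols = (np.arange(self.n_markers) if marker_mask is None
                else np.flatnonzero(np.asarray(marker_mask))
                if np.asarray(marker_mask).dtype == bool
                else np.asarray(marker_mask))
        hap = None if self.haplotypes is None else self.haplotypes[np.ix_(rows, cols)]
        return GenotypeMatrix(
            ids=[self.ids[r] for r in rows],
            dosages=self.dosages[np.ix_(rows, cols)],
            markers=self.markers.iloc[cols].reset_index(drop=True),
            haplotypes=hap,
        )

    def allele_freq(self) -> np.ndarray:
        """Observed alternate-allele frequency per marker (mean dosage / 2)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def impute_mean(self) -> "GenotypeMatrix":
        """Replace missing dosages (NaN) by the marker mean dosage."""
        d = np.asarray(self.dosages, dtype=float).copy()
        if np.isnan(d).any():
            col_mean = np.nanmean(d, axis=0)
            nan_r, nan_c = np.nonzero(np.isnan(d))
            d[nan_r, nan_c] = col_mean[nan_c]
        return GenotypeMatrix(self.ids, d, self.markers, self.haplotypes)

    # -- I/O ---------------------------------------------------------------
    def write_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosages, index=self.ids,
                          columns=self.markers["marker"])
        df.index.name = "id"
        df.to_csv(path, sep="\t")

    def write_marker_map(self, path) -> None:
        self.markers[["marker", "chrom", "pos_bp"]].to_csv(path, sep="\t",
                                                           index=False)

    def write_vcf(self, path) -> None:
        """Write genotypes as an uncompressed VCF (GT field only)."""
        dos = np.asarray(self.dosages)
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in pd.unique(self.markers["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.ids) + "\n")
            for j, rec in enumerate(self.markers.itertuples(index=False)):
                col = dos[:, j]
                gts = "\t".join(
                    "./." if np.isnan(float(g)) else gt_codes[int(round(float(g)))]
                    for g in col
                )
                fh.write(f"{rec.chrom}\t{int(rec.pos_bp)}\t{rec.marker}\tA\tC"
                         f"\t.\t.\t.\tGT\t{gts}\n")


def read_genotypes_tsv(path, marker_map_path=None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if marker_map_path is not None:
        markers = pd.read_csv(marker_map_path, sep="\t",
                              dtype={"marker": str, "chrom": str})
        markers = markers.set_index("marker").loc[df.columns].reset_index()
    else:
        markers = pd.DataFrame({"marker": df.columns.astype(str),
                                "chrom": "0", "pos_bp": 0})
    return GenotypeMatrix(ids=list(df.index.astype(str)),
                          dosages=df.to_numpy(dtype=float), markers=markers)


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read biallelic genotypes from a VCF into dosages (GT -> 0/1/2)."""
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    vcf = VCF(str(path))
    ids = [str(s) for s in vcf.samples]
    rows, names, chroms, pos = [], [], [], []
    for var in vcf:
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
        names.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(str(var.CHROM))
        pos.append(int(var.POS))
    markers = pd.DataFrame({"marker": names, "chrom": chroms, "pos_bp": pos})
    return GenotypeMatrix(ids=ids, dosages=np.column_stack(rows) if rows
                          else np.empty((len(ids), 0)), markers=markers)


# ---------------------------------------------------------------------------
# Relationship matrices
# ---------------------------------------------------------------------------

@dataclass
class RelationshipMatrix:
    """Symmetric matrix of relationship coefficients keyed by individual ids.

    ``kind`` tags the construction (A, Acor, D_ped, G, D_gen, Gw...);
    ``scale`` stores the trace-normalisation constant of genomic matrices
    (``trace[(M-P)W(M-P)']/n``) so that marker effects can be back-solved on
    the same scale the matrix was built on.
    """

    ids: list[str]
    values: np.ndarray
    kind: str = "K"
    scale: float | None = None

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InvalidParameterError(
                f"matrix shape {self.values.shape} does not match {n} ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise InvalidParameterError("relationship matrix is not symmetric")
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def indices(self, ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._index[str(i)] for i in ids])
        except KeyError as exc:
            raise InvalidParameterError(f"id {exc.args[0]!r} not in matrix") from exc

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        idx = self.indices(ids)
        return RelationshipMatrix(ids=[self.ids[k] for k in idx],
                                  values=self.values[np.ix_(idx, idx)],
                                  kind=self.kind, scale=self.scale)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self._index[str(a)], self._index[str(b)]])

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh((self.values + self.values.T) / 2)[0])

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.index.name = "id"
        df.to_csv(path, sep="\t")


def read_relationship_tsv(path, kind: str = "K") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(ids=list(df.index.astype(str)),
                              values=df.to_numpy(dtype=float), kind=kind)
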