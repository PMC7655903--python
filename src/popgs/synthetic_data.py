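"""Simulation of a clonally replicated forest-tree breeding population.

The generator emulates the statistical structure of a poplar-style breeding
cohort: a couple of dozen founders crossed in a partial factorial plus
pair matings, ~1,000 full-sib offspring in 35 families, linked biallelic
markers dropped through the pedigree with recombination, a finite-QTL
genetic architecture for several correlated traits with optional dominance,
and clonally replicated field observations in complete blocks with a smooth
spatially autocorrelated micro-environment.  Every operation is
deterministic given its seed.

The default :func:`study_population_design` embeds the corrected cross
layout of the reference breeding population (35 crosses, 1,011 offspring,
family sizes 10-118); trait-architecture defaults are conventions chosen to
give moderate-to-high clonal-mean heritabilities (mean ~0.73), not estimates
of any real trait.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (UNKNOWN, GenotypeMatrix, InvalidParameterError, Pedigree,
                   PedigreeError)

__all__ = [
    "MatingDesign", "TraitArchitecture", "TruthRecord",
    "study_population_design", "simulate_founders", "simulate_pedigree",
    "drop_genes", "simulate_traits", "simulate_field_trial",
    "corrupt_pedigree", "export_dataset",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MatingDesign:
    """Founders partitioned into sires and dams plus a list of crosses."""

    sires: list[str]
    dams: list[str]
    crosses: list[tuple[str, str, int]]  # (sire, dam, n_offspring)
    design_kind: str = "mixed"           # factorial | pair | mixed

    def __post_init__(self):
        self.sires = [str(s) for s in self.sires]
        self.dams = [str(d) for d in self.dams]
        if set(self.sires) & set(self.dams):
            raise InvalidParameterError("an id cannot be both sire and dam")
        declared = set(self.sires) | set(self.dams)
        for s, d, n in self.crosses:
            if str(s) not in set(self.sires) or str(d) not in set(self.dams):
                raise InvalidParameterError(
                    f"cross ({s}, {d}) references undeclared founders")
            if n < 1:
                raise InvalidParameterError("n_offspring must be >= 1")
        if self.design_kind not in ("factorial", "pair", "mixed"):
            raise InvalidParameterError(f"unknown design kind {self.design_kind!r}")
        if self.design_kind == "factorial":
            want = {(s, d) for s in self.sires for d in self.dams}
            got = {(str(s), str(d)) for s, d, _ in self.crosses}
            if got != want:
                raise InvalidParameterError(
                    "factorial design must use every sire x dam combination")

    @property
    def founders(self) -> list[str]:
        return self.sires + self.dams

    @property
    def n_offspring(self) -> int:
        return sum(n for _, _, n in self.crosses)

    @classmethod
    def factorial(cls, sires, dams, n_per_cross: int) -> "MatingDesign":
        crosses = [(s, d, n_per_cross) for s in sires for d in dams]
        return cls(sires=list(sires), dams=list(dams), crosses=crosses,
                   design_kind="factorial")


#: corrected cross table of the reference population: 12 sires x 11 dams,
#: 35 full-sib families, 1,011 offspring, family sizes 10..118
_STUDY_SIRES = ["SRZ", "BDG", "71077-308", "92510-1", "72145-007",
                "72131-017", "73182-009", "73193-056", "72131-036",
                "3824-3", "71034-2-406", "72146-11"]
_STUDY_DAMS = ["VGN", "71041-3-402", "71072-501", "SSC", "71040",
               "662200037", "73193-089", "662200216", "71069-914",
               "73193-091", "H480"]
_STUDY_CELLS = {
    "VGN": {"SRZ": 55, "BDG": 57, "71077-308": 54, "92510-1": 32,
            "72131-017": 34, "73182-009": 14, "73193-056": 30},
    "71041-3-402": {"BDG": 28, "71077-308": 11, "92510-1": 17,
                    "72145-007": 30, "73182-009": 25},
    "71072-501": {"SRZ": 25, "BDG": 28, "71077-308": 29},
    "SSC": {"SRZ": 15, "BDG": 20, "71077-308": 20, "92510-1": 22},
    "71040": {"72145-007": 24, "72131-017": 20},
    "662200037": {"72145-007": 25, "72131-017": 32, "73182-009": 118,
                  "73193-056": 31},
    "73193-089": {"72131-017": 22, "73182-009": 20, "73193-056": 18},
    "662200216": {"73182-009": 31, "72131-036": 19},
    "71069-914": {"3824-3": 22},
    "73193-091": {"3824-3": 21, "72146-11": 30},
    "H480": {"3824-3": 13, "72146-11": 19},
}


def study_population_design() -> MatingDesign:
    """The reference breeding population's corrected mating design.

    A partial 4x4 factorial block (dams VGN, 71041-3-402, 71072-501, SSC by
    sires SRZ, BDG, 71077-308, 92510-1) plus pair/multi-pair matings; 35
    crosses totalling 1,011 offspring with family sizes from 10 to 118.
    """
    crosses = [(sire, dam, n)
               for dam in _STUDY_DAMS
               for sire, n in _STUDY_CELLS[dam].items()]
    return MatingDesign(sires=list(_STUDY_SIRES), dams=list(_STUDY_DAMS),
                        crosses=crosses, design_kind="mixed")


@dataclass
class TraitArchitecture:
    """Finite-QTL architecture for a battery of correlated traits.

    ``dominance_ratio`` is the ratio of dominance-deviation variance to
    additive variance at the QTL; ``target_h2`` the broad-sense heritability
    of clonal means the field trial is calibrated to; ``spatial_range`` the
    correlation length of the micro-environmental surface in plot units and
    ``spatial_variance_fraction`` its share of the plot-level phenotypic
    variance.
    """

    n_traits: int = 7
    n_qtl: int = 100
    additive_effect_scale: float = 1.0
    dominance_ratio: float = 0.0
    genetic_correlation: np.ndarray | None = None
    target_h2: np.ndarray | None = None
    n_blocks: int = 6
    spatial_range: float = 10.0
    spatial_variance_fraction: float = 0.15
    surface_model: str = "bspline"   # or "gp" for a Gaussian-process draw

    def __post_init__(self):
        if self.n_traits < 1 or self.n_qtl < 1 or self.n_blocks < 1:
            raise InvalidParameterError("counts must be positive")
        if not 0.0 <= self.dominance_ratio <= 1.0:
            raise InvalidParameterError("dominance_ratio must be in [0, 1]")
        if not 0.0 <= self.spatial_variance_fraction < 1.0:
            raise InvalidParameterError(
                "spatial_variance_fraction must be in [0, 1)")
        if self.genetic_correlation is None:
            C = np.full((self.n_traits, self.n_traits), 0.3)
            np.fill_diagonal(C, 1.0)
            self.genetic_correlation = C
        self.genetic_correlation = np.asarray(self.genetic_correlation, float)
        C = self.genetic_correlation
        if C.shape != (self.n_traits, self.n_traits):
            raise InvalidParameterError("genetic_correlation has wrong shape")
        if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise InvalidParameterError(
                "genetic_correlation must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(C)[0] <= 1e-10:
            raise InvalidParameterError(
                "genetic_correlation must be positive definite")
        if self.target_h2 is None:
            base = np.array([0.85, 0.80, 0.75, 0.75, 0.70, 0.65, 0.60])
            self.target_h2 = np.resize(base, self.n_traits)
        self.target_h2 = np.atleast_1d(np.asarray(self.target_h2, float))
        if self.target_h2.size == 1:
            self.target_h2 = np.repeat(self.target_h2, self.n_traits)
        if not ((self.target_h2 > 0) & (self.target_h2 <= 1)).all():
            raise InvalidParameterError("target_h2 must lie in (0, 1]")

    @property
    def trait_names(self) -> list[str]:
        return [f"trait{k + 1}" for k in range(self.n_traits)]


@dataclass
class TruthRecord:
    """Ground truth per individual and trait: TBV, TDV and their sum."""

    ids: list[str]
    traits: list[str]
    tbv: np.ndarray   # (n, t) true breeding values, centred
    tdv: np.ndarray   # (n, t) true dominance deviations, centred
    qtl_markers: list[str] = dc_field(default_factory=list)

    @property
    def genotypic_value(self) -> np.ndarray:
        return self.tbv + self.tdv

    def frame(self) -> pd.DataFrame:
        rows = []
        for j, tr in enumerate(self.traits):
            rows.append(pd.DataFrame({
                "genotype": self.ids, "trait": tr,
                "tbv": self.tbv[:, j], "tdv": self.tdv[:, j],
                "genotypic_value": self.tbv[:, j] + self.tdv[:, j]}))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _marker_map(n_markers, n_chromosomes, chrom_length_bp, rng):
    per = np.full(n_chromosomes, n_markers // n_chromosomes)
    per[: n_markers % n_chromosomes] += 1
    rows = []
    for c in range(n_chromosomes):
        pos = np.sort(rng.choice(np.arange(1, chrom_length_bp + 1),
                                 size=per[c], replace=False))
        rows.append(pd.DataFrame({
            "marker": [f"chr{c + 1}_m{k + 1}" for k in range(per[c])],
            "chrom": f"chr{c + 1}", "pos_bp": pos}))
    return pd.concat(rows, ignore_index=True)


def simulate_founders(n_sires: int, n_dams: int, n_markers: int,
                      maf_range: tuple[float, float] = (0.05, 0.5),
                      n_chromosomes: int = 19, seed: int = 0,
                      chrom_length_bp: int = 50_000_000,
                      sire_ids=None, dam_ids=None
                      ) -> GenotypeMatrix:
    """Founder genotypes in Hardy-Weinberg and linkage equilibrium.

    Allele frequencies are uniform on ``maf_range``; haplotypes are carried
    so the founders can be gene-dropped.  Marker positions are strictly
    increasing within each chromosome.
    """
    if n_sires < 1 or n_dams < 1 or n_markers < 1 or n_chromosomes < 1:
        raise InvalidParameterError("counts must be positive")
    if n_markers < n_chromosomes:
        raise InvalidParameterError("need at least one marker per chromosome")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise InvalidParameterError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    markers = _marker_map(n_markers, n_chromosomes, chrom_length_bp, rng)
    p = rng.uniform(lo, hi, size=n_markers)
    markers["true_freq"] = p  # simulation truth, used by expectation tests
    ids = list(sire_ids) if sire_ids is not None else \
        [f"sire{k + 1}" for k in range(n_sires)]
    ids += list(dam_ids) if dam_ids is not None else \
        [f"dam{k + 1}" for k in range(n_dams)]
    if len(ids) != n_sires + n_dams:
        raise InvalidParameterError("id lists do not match founder counts")
    hap = (rng.uniform(size=(len(ids), n_markers, 2)) < p[None, :, None]
           ).astype(np.int8)
    return GenotypeMatrix(ids=ids, dosages=hap.sum(axis=2), markers=markers,
                          haplotypes=hap)


def simulate_pedigree(design: MatingDesign, seed: int = 0) -> Pedigree:
    """Expand a mating design into a pedigree (founders first)."""
    records = [(f, UNKNOWN, UNKNOWN) for f in design.founders]
    for k, (s, d, n) in enumerate(design.crosses):
        for j in range(n):
            records.append((f"F{k + 1:02d}_{j + 1:03d}", str(s), str(d)))
    return Pedigree(records)


def _gamete(hap, chrom_codes, pos_mb, rate_per_mb, chrom_starts,
            chrom_lengths, rng):
    """Recombine one parent's two haplotypes into a gamete."""
    m = hap.shape[0]
    choose = np.empty(m, dtype=np.int8)
    for c, (a, b) in enumerate(chrom_starts):
        length = chrom_lengths[c]
        n_x = rng.poisson(rate_per_mb * length)
        start = rng.integers(0, 2)
        if n_x == 0:
            choose[a:b] = start
            continue
        xpos = np.sort(rng.uniform(0.0, length, size=n_x))
        seg = np.searchsorted(xpos, pos_mb[a:b] - pos_mb[a:b].min())
        choose[a:b] = (start + seg) % 2
    return hap[np.arange(m), choose]


def drop_genes(pedigree: Pedigree, founder_genotypes: GenotypeMatrix,
               marker_map: pd.DataFrame | None = None,
               recomb_rate_per_mb: float = 0.01, seed: int = 0
               ) -> GenotypeMatrix:
    """Drop founder haplotypes through the pedigree with recombination.

    Each offspring receives one recombined gamete per parent; crossover
    counts are Poisson with rate ``recomb_rate_per_mb x chromosome length``
    and no interference (0.01/Mb corresponds to the conventional 1 cM/Mb).
    Mendelian consistency holds at every marker by construction.
    """
    if founder_genotypes.haplotypes is None:
        raise InvalidParameterError("founder genotypes must carry haplotypes")
    markers = marker_map if marker_map is not None else founder_genotypes.markers
    rng = np.random.default_rng(seed)
    chroms = list(pd.unique(markers["chrom"]))
    pos_mb = markers["pos_bp"].to_numpy(dtype=float) / 1e6
    chrom_starts, chrom_lengths = [], []
    cvals = markers["chrom"].to_numpy()
    for c in chroms:
        idx = np.flatnonzero(cvals == c)
        a, b = idx[0], idx[-1] + 1
        if not (np.diff(markers["pos_bp"].to_numpy()[a:b]) > 0).all():
            raise InvalidParameterError(
                f"positions not strictly increasing on {c}")
        chrom_starts.append((a, b))
        chrom_lengths.append(pos_mb[a:b].max() - pos_mb[a:b].min())

    m = founder_genotypes.n_markers
    hap = {f: founder_genotypes.haplotypes[k]
           for k, f in enumerate(founder_genotypes.ids)}
    founder_set = set(pedigree.founders())
    for iid, sire, dam in pedigree.records:
        if iid in founder_set:
            if iid not in hap:
                raise InvalidParameterError(f"founder {iid!r} not genotyped")
            continue
        if sire == UNKNOWN or dam == UNKNOWN:
            raise PedigreeError(
                f"{iid!r} has an unknown parent; cannot gene-drop")
        h = np.empty((m, 2), dtype=np.int8)
        h[:, 0] = _gamete(hap[sire], cvals, pos_mb, recomb_rate_per_mb,
                          chrom_starts, chrom_lengths, rng)
        h[:, 1] = _gamete(hap[dam], cvals, pos_mb, recomb_rate_per_mb,
                          chrom_starts, chrom_lengths, rng)
        hap[iid] = h
    ids = pedigree.ids
    H = np.stack([hap[i] for i in ids])
    return GenotypeMatrix(ids=ids, dosages=H.sum(axis=2),
                          markers=markers.reset_index(drop=True), haplotypes=H)


def simulate_traits(genotypes: GenotypeMatrix, architecture: TraitArchitecture,
                    seed: int = 0) -> TruthRecord:
    """Draw QTL effects and compute true breeding/dominance values.

    One shared QTL panel is sampled for all traits; per-QTL additive effects
    are multivariate normal across traits with the architecture's genetic
    correlation (pleiotropy generates the trait correlations).  Realised TBV
    are centred and rescaled so the additive standard deviation equals
    ``additive_effect_scale`` exactly; dominance deviations are scaled to
    ``dominance_ratio`` times the additive variance.
    """
    arch = architecture
    if arch.n_qtl > genotypes.n_markers:
        raise InvalidParameterError("n_qtl exceeds the number of markers")
    rng = np.random.default_rng(seed)
    qtl = np.sort(rng.choice(genotypes.n_markers, size=arch.n_qtl,
                             replace=False))
    M = np.asarray(genotypes.dosages, float)[:, qtl]
    Mc = M - M.mean(axis=0)
    Lc = np.linalg.cholesky(arch.genetic_correlation)
    a = rng.normal(size=(arch.n_qtl, arch.n_traits)) @ Lc.T
    tbv = Mc @ a
    sd = tbv.std(axis=0)
    if (sd == 0).any():
        raise InvalidParameterError(
            "no additive variance realised; QTL are monomorphic")
    tbv = tbv / sd * arch.additive_effect_scale

    t = arch.n_traits
    if arch.dominance_ratio > 0:
        X = (M == 1).astype(float)
        Xc = X - X.mean(axis=0)
        dd = rng.normal(size=(arch.n_qtl, t))
        tdv = Xc @ dd
        sdd = tdv.std(axis=0)
        sdd[sdd == 0] = 1.0
        tdv = tdv / sdd * (np.sqrt(arch.dominance_ratio)
                           * arch.additive_effect_scale)
    else:
        tdv = np.zeros_like(tbv)
    names = list(genotypes.markers["marker"].iloc[qtl])
    return TruthRecord(ids=list(genotypes.ids), traits=arch.trait_names,
                       tbv=tbv, tdv=tdv, qtl_markers=names)


def _bspline_draw(rows, cols, spatial_range, rng):
    """Smooth random surface from a tensor B-spline basis."""
    from .field_adjustment import bspline_surface_design

    kr = max(2, int(round((rows.max() - rows.min()) / spatial_range)) + 1)
    kc = max(2, int(round((cols.max() - cols.min()) / spatial_range)) + 1)
    B = bspline_surface_design(rows, cols, kr, kc)
    return B @ rng.normal(size=B.shape[1])


def _gp_draw(rows, cols, spatial_range, rng):
    """Gaussian-process surface with a squared-exponential kernel."""
    pts = np.column_stack([rows, cols]).astype(float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    C = np.exp(-0.5 * d2 / spatial_range ** 2) + 1e-8 * np.eye(len(pts))
    return np.linalg.cholesky(C) @ rng.normal(size=len(pts))


def simulate_field_trial(truth: TruthRecord, layout: tuple[int, int],
                         n_blocks: int | None = None,
                         architecture: TraitArchitecture | None = None,
                         seed: int = 0, trial: str = "trial1"
                         ) -> pd.DataFrame:
    """Clonally replicated field observations in complete blocks.

    Each block is a horizontal band of the layout holding one ramet of every
    genotype at a randomised plot.  Observation = trait mean + genotypic
    value + smooth spatial surface + iid residual; the residual variance is
    calibrated so the broad-sense heritability of clonal means equals the
    architecture's ``target_h2`` and the surface variance matches
    ``spatial_variance_fraction`` of the plot-level variance.
    """
    arch = architecture if architecture is not None else TraitArchitecture(
        n_traits=len(truth.traits))
    nb = n_blocks if n_blocks is not None else arch.n_blocks
    n_rows, n_cols = layout
    n_geno = len(truth.ids)
    rows_per_block = n_rows // nb
    if rows_per_block * n_cols < n_geno:
        raise InvalidParameterError(
            f"layout {layout} cannot hold {nb} blocks of {n_geno} genotypes")
    rng = np.random.default_rng(seed)

    rec_block, rec_row, rec_col, rec_geno = [], [], [], []
    for b in range(nb):
        perm = rng.permutation(n_geno)
        r0 = b * rows_per_block
        plots = [(r0 + k // n_cols + 1, k % n_cols + 1)
                 for k in range(n_geno)]
        for g, (r, c) in zip(perm, plots):
            rec_block.append(b + 1)
            rec_row.append(r)
            rec_col.append(c)
            rec_geno.append(truth.ids[g])
    rec_block = np.array(rec_block)
    rec_row = np.array(rec_row)
    rec_col = np.array(rec_col)
    geno_idx = np.array([truth.ids.index(g) for g in rec_geno])

    frames = []
    G = truth.genotypic_value
    for j, tr in enumerate(truth.traits):
        gv = G[:, j]
        var_g = float(gv.var())
        h2 = float(arch.target_h2[min(j, len(arch.target_h2) - 1)])
        var_e = nb * var_g * (1.0 - h2) / h2
        f = arch.spatial_variance_fraction
        var_s = f / (1.0 - f) * (var_g + var_e)
        if var_s > 0:
            draw = (_gp_draw if arch.surface_model == "gp" else _bspline_draw)(
                rec_row, rec_col, arch.spatial_range, rng)
            draw = draw - draw.mean()
            sd = draw.std()
            surface = draw / (sd if sd > 0 else 1.0) * np.sqrt(var_s)
        else:
            surface = np.zeros(len(rec_row))
        resid = (rng.normal(size=len(rec_row)) * np.sqrt(var_e)
                 if var_e > 0 else np.zeros(len(rec_row)))
        value = 10.0 * (j + 1) + gv[geno_idx] + surface + resid
        frames.append(pd.DataFrame({
            "trial": trial, "block": rec_block, "row": rec_row,
            "col": rec_col, "genotype": rec_geno, "trait": tr,
            "value": value, "true_surface": surface}))
    return pd.concat(frames, ignore_index=True)


def corrupt_pedigree(pedigree: Pedigree, error_rate: float, seed: int = 0
                     ) -> tuple[Pedigree, pd.DataFrame]:
    """Introduce wrong-paternity errors in whole or partial family blocks.

    A fraction ``error_rate`` of the offspring (chosen as contiguous runs
    within randomly ordered full-sib families, mimicking mislabelled
    complete or partial crosses) has its sire replaced by a different
    declared sire.  Returns the corrupted pedigree and a change log.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise InvalidParameterError("error_rate must be in [0, 1]")
    sires = pedigree.sires()
    if error_rate > 0 and len(sires) < 2:
        raise InvalidParameterError(
            "cannot corrupt paternity with a single declared sire")
    offspring = [r for r in pedigree.records if r[1] != UNKNOWN]
    n_target = int(round(error_rate * len(offspring)))
    rng = np.random.default_rng(seed)
    fams = pedigree.families()
    fam_keys = list(fams.keys())
    rng.shuffle(fam_keys)
    chosen: dict[str, str] = {}
    remaining = n_target
    for key in fam_keys:
        if remaining <= 0:
            break
        members = fams[key]
        take = min(len(members), remaining)
        start = (0 if take == len(members)
                 else int(rng.integers(0, len(members) - take + 1)))
        true_sire = key[0]
        alt = [s for s in sires if s != true_sire]
        new_sire = alt[int(rng.integers(0, len(alt)))]
        for iid in members[start:start + take]:
            chosen[iid] = new_sire
        remaining -= take
    new_records, log_rows = [], []
    for iid, s, d in pedigree.records:
        if iid in chosen:
            new_records.append((iid, chosen[iid], d))
            log_rows.append({"id": iid, "old_sire": s,
                             "new_sire": chosen[iid], "dam": d})
        else:
            new_records.append((iid, s, d))
    log = pd.DataFrame(log_rows, columns=["id", "old_sire", "new_sire", "dam"])
    return Pedigree(new_records), log


# ---------------------------------------------------------------------------
# Dataset export
# ---------------------------------------------------------------------------

def export_dataset(out_dir, pedigree: Pedigree, genotypes: GenotypeMatrix,
                   observations: pd.DataFrame, truth: TruthRecord,
                   params: dict | None = None) -> None:
    """Write a simulated dataset as plain-text files plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pedigree.write_csv(out / "pedigree.csv")
    genotypes.write_tsv(out / "genotypes.tsv")
    genotypes.write_marker_map(out / "marker_map.tsv")
    genotypes.write_vcf(out / "genotypes.vcf")
    observations.drop(columns=["true_surface"], errors="ignore").to_csv(
        out / "observations.csv", index=False)
    truth.frame().to_csv(out / "truth.csv", index=False)
    with open(out / "params.json", "w") as fh:
        json.dump(params or {}, fh, indent=2, default=str)
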