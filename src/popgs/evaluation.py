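"""Training-set design, prediction-quality metrics and scenario grids.

Cross-validation follows the breeding-program question being asked:
*individual* sampling splits within family cohorts (training and validation
share families — the easy, operational case), while *family* sampling holds
out whole full-sib families (predicting unobserved crosses — the hard
case).  An optional TestSet of later-generation candidates is excluded from
every training set.  Prediction quality is scored by predictive ability
(Pearson r between GEBV and adjusted clonal means), accuracy (predictive
ability divided by the square root of a reference heritability), Spearman
and Pearson correlations within top-tier slices of the candidate ranking,
the bias regression of phenotype on prediction, and within-family gain of
genomic over pedigree prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (ConvergenceError, InvalidParameterError,
                   RelationshipMatrix)
from .mixed_model import fit_reml, heritability

__all__ = [
    "PartitionScheme", "make_partitions", "predictive_ability", "accuracy",
    "rank_metrics", "bias_regression", "within_family_gain", "run_scenario",
    "ScenarioConfig",
]


# ---------------------------------------------------------------------------
# Partition design
# ---------------------------------------------------------------------------

@dataclass
class PartitionScheme:
    """How to split candidates into training and validation sets."""

    composition: str = "individual"      # "individual" | "family"
    fraction: float = 0.5                # fraction used for TRAINING
    n_repetitions: int = 10
    seed: int = 0
    test_set_ids: tuple = ()
    disjoint_folds: bool = False         # classical folds instead of resamples

    def __post_init__(self):
        if self.composition not in ("individual", "family"):
            raise InvalidParameterError(
                f"unknown composition {self.composition!r}")
        if not 0.0 < self.fraction < 1.0:
            raise InvalidParameterError("fraction must be in (0, 1)")
        if self.n_repetitions < 1:
            raise InvalidParameterError("n_repetitions must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.composition}-T{int(round(self.fraction * 100))}"


def make_partitions(individuals, family_map: dict, scheme: PartitionScheme
                    ) -> list[tuple[list[str], list[str]]]:
    """Independent training/validation splits under a partition scheme.

    ``individual`` composition samples the training fraction of individuals
    regardless of family; ``family`` composition samples whole full-sib
    families so no family straddles the two sides.  TestSet ids are removed
    from the pool before splitting.  Per-repetition seeds are
    ``scheme.seed + repetition``.
    """
    pool = [str(i) for i in individuals
            if str(i) not in set(map(str, scheme.test_set_ids))]
    missing = [i for i in pool if i not in family_map]
    if missing:
        raise InvalidParameterError(
            f"family_map does not cover {missing[:5]}")
    if scheme.disjoint_folds:
        return _disjoint_folds(pool, family_map, scheme)
    out = []
    for rep in range(scheme.n_repetitions):
        rng = np.random.default_rng(scheme.seed + rep)
        if scheme.composition == "individual":
            n_train = int(round(scheme.fraction * len(pool)))
            if n_train == 0 or n_train == len(pool):
                raise InvalidParameterError(
                    "fraction leaves an empty training or validation side")
            perm = rng.permutation(len(pool))
            train = [pool[k] for k in perm[:n_train]]
            valid = [pool[k] for k in perm[n_train:]]
        else:
            fams: dict[str, list[str]] = {}
            for i in pool:
                fams.setdefault(str(family_map[i]), []).append(i)
            keys = sorted(fams)
            n_fam = int(round(scheme.fraction * len(keys)))
            n_fam = min(max(n_fam, 1), len(keys) - 1)
            if len(keys) < 2:
                raise InvalidParameterError(
                    "family composition needs >= 2 families")
            perm = rng.permutation(len(keys))
            chosen = {keys[k] for k in perm[:n_fam]}
            train = [i for i in pool if str(family_map[i]) in chosen]
            valid = [i for i in pool if str(family_map[i]) not in chosen]
        out.append((train, valid))
    return out


def _disjoint_folds(pool, family_map, scheme):
    """Classical k-fold variant: validation sets partition the pool."""
    rng = np.random.default_rng(scheme.seed)
    k = scheme.n_repetitions
    out = []
    if scheme.composition == "individual":
        perm = rng.permutation(len(pool))
        folds = np.array_split(perm, k)
        for f in folds:
            valid = [pool[j] for j in f]
            train = [pool[j] for j in perm if pool[j] not in set(valid)]
            out.append((train, valid))
    else:
        fams = sorted({str(family_map[i]) for i in pool})
        perm = rng.permutation(len(fams))
        folds = np.array_split(perm, k)
        for f in folds:
            held = {fams[j] for j in f}
            valid = [i for i in pool if str(family_map[i]) in held]
            train = [i for i in pool if str(family_map[i]) not in held]
            out.append((train, valid))
    return out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _aligned(predicted, observed):
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise InvalidParameterError("prediction/observation length mismatch")
    return p, o


def predictive_ability(predicted, observed) -> float:
    """Pearson correlation between predictions and observed values."""
    p, o = _aligned(predicted, observed)
    if len(p) < 3:
        raise InvalidParameterError("need at least 3 paired values")
    if p.std() == 0 or o.std() == 0:
        raise InvalidParameterError("zero variance in predictions or observations")
    return float(np.corrcoef(p, o)[0, 1])


def accuracy(pa: float, h2_ref: float) -> float:
    """Predictive ability scaled by the reference model's heritability.

    ``pa / sqrt(h2_ref)``; values above 1 are legitimate when the reference
    heritability is lower than the share of variance the model captures.
    """
    if not 0.0 < h2_ref <= 1.0:
        raise InvalidParameterError("h2_ref must be in (0, 1]")
    return float(pa) / float(np.sqrt(h2_ref))


DEFAULT_TIERS = ((0.0, 0.05), (0.05, 0.10), (0.10, 0.50), (0.0, 1.0))


def rank_metrics(predicted, observed, tiers=DEFAULT_TIERS,
                 best: str = "high") -> pd.DataFrame:
    """Spearman and Pearson correlations within observed-value tiers.

    Tiers are quantile slices of the observed values ordered best-first
    (``best="high"`` for traits where large is good, ``"low"`` otherwise,
    e.g. disease scores).  The default tiers are the elite 5%, the 5-10%
    and 10-50% slices, and the full set.  A tier with fewer than 3 members
    yields NaN correlations rather than being dropped.
    """
    p, o = _aligned(predicted, observed)
    n = len(p)
    if best not in ("high", "low"):
        raise InvalidParameterError("best must be 'high' or 'low'")
    order = np.argsort(-o if best == "high" else o, kind="stable")
    frac = np.empty(n)
    frac[order] = np.arange(n) / n
    rows = []
    for lo, hi in tiers:
        sel = (frac >= lo) & (frac < hi) if hi < 1.0 else (frac >= lo)
        ns = int(sel.sum())
        if ns < 3 or p[sel].std() == 0 or o[sel].std() == 0:
            pe = sp = np.nan
        else:
            pe = float(np.corrcoef(p[sel], o[sel])[0, 1])
            sp = float(stats.spearmanr(p[sel], o[sel]).statistic)
        rows.append({"tier": f"{lo:g}-{hi:g}", "n": ns,
                     "pearson": pe, "spearman": sp})
    return pd.DataFrame(rows)


def bias_regression(observed, predicted) -> tuple[float, float]:
    """Least-squares regression of observed on predicted: (intercept, slope).

    Slope 1 and intercept 0 indicate unbiased predictions; slopes above 1
    mean the spread of predictions understates the spread of phenotypes.
    """
    p, o = _aligned(predicted, observed)
    if len(p) < 3:
        raise InvalidParameterError("need at least 3 pairs")
    if p.std() == 0:
        raise InvalidParameterError("zero variance in predictions")
    res = stats.linregress(p, o)
    return float(res.intercept), float(res.slope)


def within_family_gain(predicted_g, predicted_p, observed, family_map,
                       min_size: int = 3) -> tuple[pd.DataFrame, float]:
    """Within-family predictive-ability gain of genomic over pedigree.

    Per full-sib family with at least ``min_size`` evaluated members:
    ``Pearson(pred_genomic, obs) - Pearson(pred_pedigree, obs)``.  A
    prediction that is constant within a family (the pedigree parent
    average) carries no within-family ranking information and scores 0 by
    convention.  The summary is the family-size-weighted mean difference.
    """
    pg = pd.Series(predicted_g).astype(float)
    pp = pd.Series(predicted_p).astype(float)
    ob = pd.Series(observed).astype(float)
    if not (pg.index.equals(pp.index) and pg.index.equals(ob.index)):
        raise InvalidParameterError("prediction vectors are not aligned")

    def _corr0(x, y):
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    rows, skipped = [], []
    fams: dict[str, list] = {}
    for i in pg.index:
        fams.setdefault(str(family_map[str(i)]), []).append(i)
    for fam, members in sorted(fams.items()):
        if len(members) < min_size:
            skipped.append(fam)
            continue
        x_g = pg.loc[members].to_numpy()
        x_p = pp.loc[members].to_numpy()
        y = ob.loc[members].to_numpy()
        if y.std() == 0:
            skipped.append(fam)
            continue
        rows.append({"family": fam, "n": len(members),
                     "pa_genomic": _corr0(x_g, y),
                     "pa_pedigree": _corr0(x_p, y)})
    if skipped:
        warnings.warn(f"skipped {len(skipped)} families below the size/variance "
                      "threshold", stacklevel=2)
    if not rows:
        raise InvalidParameterError("no family large enough to evaluate")
    table = pd.DataFrame(rows)
    table["gain"] = table["pa_genomic"] - table["pa_pedigree"]
    wmean = float(np.average(table["gain"], weights=table["n"]))
    return table, wmean


# ---------------------------------------------------------------------------
# Scenario orchestration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Factorial comparison grid: traits x matrices x schemes."""

    phenotypes: pd.DataFrame                 # individuals x traits, id index
    matrices: dict[str, RelationshipMatrix]  # label -> matrix
    family_map: dict                         # id -> family label
    schemes: list[PartitionScheme] = dc_field(default_factory=list)
    traits: list[str] | None = None
    reference_matrix: str | None = None      # h2 reference (A model); default: first
    test_set_ids: tuple = ()
    trait_direction: dict = dc_field(default_factory=dict)  # trait -> high|low
    fit_kwargs: dict = dc_field(default_factory=dict)


def _reference_h2(config: ScenarioConfig) -> dict[str, float]:
    ref = config.reference_matrix or next(iter(config.matrices))
    K = config.matrices[ref]
    out = {}
    for trait in config.traits:
        y = config.phenotypes[trait].dropna()
        fit = fit_reml(y, [("additive", K)], raise_on_nonconvergence=False,
                       **config.fit_kwargs)
        out[trait] = max(heritability(fit.vc), 1e-6)
    return out


def run_scenario(config: ScenarioConfig) -> tuple[pd.DataFrame, dict]:
    """Execute the full grid; returns (long-format results, provenance).

    One model fit per (trait, matrix, scheme, repetition); metrics for the
    validation set and, when TestSet ids are configured, for the TestSet.
    Failures are recorded per cell (fail-soft) and flagged in the
    provenance record under ``"failures"``.
    """
    if config.traits is None:
        config.traits = [str(c) for c in config.phenotypes.columns]
    h2_ref = _reference_h2(config)
    test_ids = [str(i) for i in config.test_set_ids]
    results, failures = [], []

    for trait in config.traits:
        y_all = config.phenotypes[trait].dropna()
        y_all.index = y_all.index.astype(str)
        direction = config.trait_direction.get(trait, "high")
        for mat_label, K in config.matrices.items():
            for scheme in config.schemes:
                scheme_ts = PartitionScheme(
                    composition=scheme.composition, fraction=scheme.fraction,
                    n_repetitions=scheme.n_repetitions, seed=scheme.seed,
                    test_set_ids=tuple(test_ids) + tuple(scheme.test_set_ids),
                    disjoint_folds=scheme.disjoint_folds)
                parts = make_partitions(list(y_all.index), config.family_map,
                                        scheme_ts)
                for rep, (train, valid) in enumerate(parts):
                    # no-leakage guard: validation and TestSet phenotypes
                    # must never reach the training data
                    assert not (set(train) & set(valid))
                    assert not (set(train) & set(test_ids))
                    cell = {"trait": trait, "matrix": mat_label,
                            "scheme": scheme.composition,
                            "fraction": scheme.fraction, "repetition": rep}
                    try:
                        fit = fit_reml(y_all.loc[train], [("additive", K)],
                                       **config.fit_kwargs)
                        for pop, ids in (("VS", valid), ("TestSet", test_ids)):
                            ids = [i for i in ids if i in y_all.index]
                            if not ids:
                                continue
                            pred = fit.gebv.loc[ids]
                            obs = y_all.loc[ids]
                            pa = predictive_ability(pred, obs)
                            acc = accuracy(pa, h2_ref[trait])
                            inter, slope = bias_regression(obs, pred)
                            metrics = {"predictive_ability": pa,
                                       "accuracy": acc,
                                       "bias_intercept": inter,
                                       "bias_slope": slope}
                            tiers = rank_metrics(pred.to_numpy(),
                                                 obs.to_numpy(),
                                                 best=direction)
                            for _, row in tiers.iterrows():
                                metrics[f"spearman_{row['tier']}"] = row["spearman"]
                                metrics[f"pearson_{row['tier']}"] = row["pearson"]
                            for name, value in metrics.items():
                                results.append({**cell, "population": pop,
                                                "metric": name,
                                                "value": value})
                    except (InvalidParameterError, ConvergenceError,
                            np.linalg.LinAlgError) as exc:
                        failures.append({**cell, "error": str(exc)})

    table = pd.DataFrame(results, columns=["trait", "matrix", "scheme",
                                           "fraction", "repetition",
                                           "population", "metric", "value"])
    provenance = {
        "traits": config.traits,
        "matrices": list(config.matrices),
        "schemes": [s.label for s in config.schemes],
        "h2_reference": h2_ref,
        "n_test_set": len(test_ids),
        "failures": failures,
        "status": "ok" if not failures else "partial-failure",
    }
    return table, provenance
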