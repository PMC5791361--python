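"""Five-fold cross-validated genomic prediction within one population.

Folds are stratified by sire so that every paternal half-sib group of
size ≥ k contributes to every fold — the within-population design used
for family-structured aquaculture data, where a purely random split
could leave whole families out of the training set.  Per fold, REML and
gBLUP are fitted on the training individuals only; allele frequencies
for centering, the normalisation constant φ and the allele substitution
effects all derive from the training rows, so no validation phenotype
or genotype frequency information leaks into its own prediction.
Validation phenotypes are predicted as ŷ = Xβ̂ + Wα̂ and compared with
the observed values by correlation and by the regression of actual on
predicted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .data_model import GenotypeMatrix, PhenotypeTable
from .kinship import _vanraden
from .marker_stats import allele_frequencies
from .mixed_model import (
    ModelSpec,
    VarianceComponents,
    _design_matrix,
    backsolve_ase,
    gblup_solve,
    predictive_ability,
    reml_kernel,
)

__all__ = ["FoldAssignment", "CVResult", "make_folds", "run_cv"]


@dataclass
class FoldAssignment:
    """Per-individual fold labels (1..k), stratified by sire."""

    ids: list[str]
    fold: np.ndarray  # int, 1-based
    k: int
    seed: int | None
    strata: np.ndarray

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold == fold)

    def sizes(self) -> list[int]:
        return [int(np.sum(self.fold == f)) for f in range(1, self.k + 1)]


@dataclass
class CVResult:
    per_fold: pd.DataFrame  # fold, r, accuracy, r2, slope, intercept, n, h2
    predictions: pd.DataFrame  # id, fold, y_actual, y_pred
    pooled: dict  # r, accuracy, r2, slope, intercept, n
    best_fold: int
    pseudo_h2: float


def make_folds(ids, strata, k: int = 5, seed: int | None = None) -> FoldAssignment:
    """Balanced, stratum-covering k-fold assignment.

    Within each stratum (sire), members are shuffled and dealt to folds
    in increasing order of current fold load (ties broken at random),
    so every stratum spreads as evenly as possible over folds and
    overall fold sizes differ by at most one.
    """
    ids = [str(i) for i in ids]
    strata = np.asarray([str(s) for s in strata])
    n = len(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if strata.size != n:
        raise ValueError("strata length must match ids")
    rng = np.random.default_rng(seed)
    fold = np.zeros(n, dtype=int)
    load = np.zeros(k, dtype=int)
    for s in sorted(set(strata.tolist())):
        members = np.flatnonzero(strata == s)
        rng.shuffle(members)
        # folds sorted by load, random among equals
        order = np.lexsort((rng.random(k), load))
        for j, m in enumerate(members):
            f = order[j % k]
            fold[m] = f + 1
            load[f] += 1
            if (j + 1) % k == 0:
                order = np.lexsort((rng.random(k), load))
    return FoldAssignment(ids=ids, fold=fold, k=k, seed=seed, strata=strata)


def run_cv(
    phenotypes: PhenotypeTable,
    spec: ModelSpec,
    genotypes: GenotypeMatrix,
    folds: FoldAssignment,
    refit_varcomp: bool = True,
    h2_denominator: float | None = None,
) -> CVResult:
    """k-fold cross-validated gBLUP for one trait.

    Variance components are re-estimated inside each training fold when
    ``refit_varcomp`` (default); otherwise estimated once on the full
    data and reused.  The accuracy denominator is the model's own
    pseudo-heritability unless ``h2_denominator`` overrides it (e.g.
    with a pedigree estimate).
    """
    df = phenotypes.data.set_index("id")
    ids = folds.ids
    if set(ids) - set(genotypes.individual_ids):
        raise ValueError("fold ids missing from genotype matrix")
    gpos = {v: i for i, v in enumerate(genotypes.individual_ids)}
    rows = np.array([gpos[i] for i in ids])
    Xall = genotypes.to_float()[rows]
    y = df.loc[ids, spec.response].to_numpy(dtype=float)
    table = df.loc[ids].reset_index()

    full_vc: VarianceComponents | None = None
    if not refit_varcomp:
        p_full = allele_frequencies(Xall)
        Gf, _, _, _ = _vanraden(Xall, freqs=p_full)
        Xf_full, _, _ = _design_matrix(table, spec.fixed_effects)
        full_vc, _ = reml_kernel(y, Xf_full, Gf)

    fold_rows = []
    preds = np.full(len(ids), np.nan)
    h2s = []
    for f in range(1, folds.k + 1):
        val = folds.indices(f)
        trn = np.flatnonzero(folds.fold != f)
        y_trn = y[trn]
        if np.std(y_trn) == 0:
            import warnings

            warnings.warn(f"fold {f}: zero training variance, skipped", stacklevel=2)
            continue
        # training-derived frequencies; any missing calls are completed
        # with training means before centering
        p_trn = allele_frequencies(Xall[trn])
        G_trn, phi, poly, W_trn = _vanraden(Xall[trn], freqs=p_trn)
        X_design, _, levels = _design_matrix(table.iloc[trn], spec.fixed_effects)
        if refit_varcomp:
            vc, _ = reml_kernel(y_trn, X_design, G_trn)
        else:
            vc = full_vc
        beta, g_hat = gblup_solve(y_trn, X_design, G_trn, vc.sigma2_g, vc.sigma2_e)
        ase = backsolve_ase(g_hat, W_trn, phi, G=G_trn)
        # validation rows centered with TRAINING frequencies
        Xv = Xall[np.ix_(val, np.flatnonzero(poly))]
        pv = p_trn[poly]
        Xv = np.where(np.isnan(Xv), 2.0 * pv, Xv)
        W_val = Xv - 2.0 * pv
        Xv_design, _, _ = _design_matrix(
            table.iloc[val], spec.fixed_effects, levels=levels
        )
        y_hat = Xv_design @ beta + W_val @ ase
        preds[val] = y_hat
        h2s.append(vc.h2)
        m = predictive_ability(y[val], y_hat, h2=1.0)
        fold_rows.append(
            {
                "fold": f,
                "n": len(val),
                "h2": vc.h2,
                "r": m["r"],
                "r2": m["r2"],
                "slope": m["slope"],
                "intercept": m["intercept"],
            }
        )

    per_fold = pd.DataFrame(fold_rows)
    pseudo_h2 = float(np.mean(h2s)) if h2s else np.nan
    denom = h2_denominator if h2_denominator is not None else pseudo_h2
    denom = min(max(denom, 1e-6), 1.0)
    pooled = predictive_ability(y[~np.isnan(preds)], preds[~np.isnan(preds)], h2=denom)
    best_fold = (
        int(per_fold.loc[per_fold["r2"].idxmax(), "fold"]) if len(per_fold) else -1
    )
    predictions = pd.DataFrame(
        {"id": ids, "fold": folds.fold, "y_actual": y, "y_pred": preds}
    )
    return CVResult(
        per_fold=per_fold,
        predictions=predictions,
        pooled=pooled,
        best_fold=best_fold,
        pseudo_h2=pseudo_h2,
    )
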