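"""Per-marker statistics, QC filtering, LD pruning, subsampling, imputation.

The working representation for the estimator/transformer layer is a
NaN-coded float dosage array (individuals × markers); the
``GenotypeMatrix``-level functions at the bottom are thin wrappers that
round-trip through that representation.

Allele-frequency conventions: ``p`` is the frequency of the counted
allele estimated as ``mean(dosage)/2`` over non-missing calls; minor
allele frequency is ``min(p, 1-p)``.  Expected heterozygosity is
``2p(1-p)`` and the codominant (Botstein) polymorphic information
content for a biallelic locus is ``1 - (p² + q²) - 2p²q²``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data_model import GenotypeMatrix, Pedigree

__all__ = [
    "MarkerStats",
    "MarkerQC",
    "LDPruner",
    "MarkerSubsampler",
    "GenotypeImputer",
    "compute_marker_stats",
    "filter_markers",
    "ld_prune",
    "subsample_markers",
    "impute_genotypes",
    "allele_frequencies",
]


def _check_dosage(X, allow_nan=True) -> np.ndarray:
    return check_array(
        X, dtype=float, ensure_all_finite="allow-nan" if allow_nan else True
    )


def allele_frequencies(X: np.ndarray) -> np.ndarray:
    """Counted-allele frequency per marker from non-missing dosages.

    Markers with no observed calls get NaN.
    """
    X = np.asarray(X, dtype=float)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns -> NaN
        return np.nanmean(X, axis=0) / 2.0


@dataclass
class MarkerStats:
    """Per-marker summary statistics (frame indexed by marker id).

    Columns: ``p`` (counted-allele frequency), ``maf``, ``call_rate``,
    ``het_expected``, ``pic_codominant`` and optionally
    ``pic_additive``.  Markers without a single observed call are
    flagged ``defined=False`` with NaN statistics rather than dropped.
    """

    table: pd.DataFrame

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]

    @property
    def maf(self) -> np.ndarray:
        return self.table["maf"].to_numpy()

    @property
    def call_rate(self) -> np.ndarray:
        return self.table["call_rate"].to_numpy()


def _stats_from_array(
    X: np.ndarray, marker_ids, additive_pic: bool = False
) -> MarkerStats:
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    n_obs = np.sum(~np.isnan(X), axis=0)
    call_rate = n_obs / n
    p = allele_frequencies(X)
    q = 1.0 - p
    maf = np.minimum(p, q)
    het = 2.0 * p * q
    pic_co = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2
    cols = {
        "p": p,
        "maf": maf,
        "call_rate": call_rate,
        "het_expected": het,
        "pic_codominant": pic_co,
        "defined": n_obs > 0,
    }
    if additive_pic:
        # 2pq(1-2pq): an additive-coding informativeness index; the
        # genotyping provider's own "additive PIC" definition is not
        # public, so no equivalence is claimed.
        cols["pic_additive"] = het * (1.0 - het)
    df = pd.DataFrame(cols, index=list(marker_ids))
    df.loc[~df["defined"], ["p", "maf", "het_expected", "pic_codominant"]] = np.nan
    return MarkerStats(df)


# ---------------------------------------------------------------------------
# Transformers
# ---------------------------------------------------------------------------


class MarkerQC(TransformerMixin, BaseEstimator):
    """Filter markers on missingness and minor allele frequency.

    Retains markers with ``missing fraction < max_missing`` AND
    ``maf > min_maf`` — both strict, mirroring the usual "<10% missing,
    MAF > 0.05" phrasing of QC protocols.  Markers at the boundary are
    removed.

    Attributes
    ----------
    support_ : bool array (n_markers,)
        Retained-marker mask.
    stats_ : MarkerStats
        Statistics computed on the fit data.
    """

    def __init__(self, max_missing: float = 0.10, min_maf: float = 0.05):
        self.max_missing = max_missing
        self.min_maf = min_maf

    def fit(self, X, y=None):
        if not (0 <= self.max_missing <= 1 and 0 <= self.min_maf <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
        X = _check_dosage(X)
        self.stats_ = _stats_from_array(X, range(X.shape[1]))
        missing_frac = np.isnan(X).mean(axis=0)  # exact, unlike 1 - call_rate
        maf = np.where(np.isnan(self.stats_.maf), -1.0, self.stats_.maf)
        self.support_ = (missing_frac < self.max_missing) & (maf > self.min_maf)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = _check_dosage(X)
        return X[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_


class LDPruner(TransformerMixin, BaseEstimator):
    """Greedy sliding-window LD pruning on squared dosage correlation.

    Within each window (left to right, advancing by ``step``), the later
    marker of any retained pair with r² > ``r2_max`` is dropped; earlier
    markers win, so the result is deterministic given marker order.
    Missing dosages are mean-imputed for the correlation computation
    only.
    """

    def __init__(self, r2_max: float = 0.95, window: int = 50, step: int = 25):
        self.r2_max = r2_max
        self.window = window
        self.step = step

    def fit(self, X, y=None):
        if not (0 < self.r2_max <= 1):
            raise ValueError("r2_max must lie in (0, 1]")
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        X = _check_dosage(X)
        m = X.shape[1]
        p = allele_frequencies(X)
        Xi = np.where(np.isnan(X), 2.0 * p, X)
        keep = np.ones(m, dtype=bool)
        sd = Xi.std(axis=0)
        for start in range(0, max(m - 1, 1), self.step):
            idx = np.arange(start, min(start + self.window, m))
            idx = idx[keep[idx]]
            if idx.size < 2:
                continue
            sub = Xi[:, idx]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.corrcoef(sub, rowvar=False)
            r2 = np.nan_to_num(r) ** 2
            for a in range(len(idx)):
                if not keep[idx[a]]:
                    continue
                for b in range(a + 1, len(idx)):
                    if keep[idx[b]] and r2[a, b] > self.r2_max:
                        keep[idx[b]] = False
        # zero-variance (monomorphic/fully missing) markers carry no LD
        # information and are left untouched here; QC handles them.
        self.support_ = keep
        self.n_features_in_ = m
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = _check_dosage(X)
        return X[:, self.support_]


class MarkerSubsampler(TransformerMixin, BaseEstimator):
    """Uniform random subsample of round(fraction·n_markers) markers.

    Column order of retained markers is preserved; bit-reproducible for
    a given ``random_state``.
    """

    def __init__(self, fraction: float = 1.0, random_state: int | None = None):
        self.fraction = fraction
        self.random_state = random_state

    def fit(self, X, y=None):
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must lie in (0, 1]")
        X = _check_dosage(X)
        m = X.shape[1]
        size = int(round(self.fraction * m))
        if size < 1:
            raise ValueError("fraction·n_markers must be >= 1")
        rng = np.random.default_rng(self.random_state)
        chosen = np.sort(rng.choice(m, size=size, replace=False))
        self.support_ = np.zeros(m, dtype=bool)
        self.support_[chosen] = True
        self.n_features_in_ = m
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = _check_dosage(X)
        return X[:, self.support_]


class GenotypeImputer(TransformerMixin, BaseEstimator):
    """Fill missing dosages with 2p or the full-sib family mean.

    ``strategy="mean_dosage"`` fills each marker with its observed mean
    dosage (= 2p̂).  ``strategy="family_mean"`` fills with the mean of
    the individual's full-sib family at that marker, falling back to 2p̂
    when the whole family is missing; family labels are passed to
    ``fit``/``transform``.  Output dosages are real-valued.
    """

    def __init__(self, strategy: str = "mean_dosage"):
        self.strategy = strategy

    def fit(self, X, y=None, families=None):
        if self.strategy not in ("mean_dosage", "family_mean"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "family_mean" and families is None:
            raise ValueError("family_mean imputation requires family labels")
        X = _check_dosage(X)
        # observed mean dosage = 2p̂; fully missing columns fall back to 0
        self.column_means_ = np.nan_to_num(2.0 * allele_frequencies(X), nan=0.0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, families=None):
        check_is_fitted(self, "column_means_")
        X = _check_dosage(X).copy()
        if self.strategy == "family_mean":
            if families is None:
                raise ValueError("family_mean imputation requires family labels")
            families = np.asarray(families)
            for fam in pd.unique(families):
                rows = families == fam
                sub = X[rows]
                with np.errstate(invalid="ignore"):
                    fam_mean = np.nanmean(sub, axis=0)
                fam_mean = np.where(np.isnan(fam_mean), self.column_means_, fam_mean)
                sub_miss = np.isnan(sub)
                sub[sub_miss] = np.broadcast_to(fam_mean, sub.shape)[sub_miss]
                X[rows] = sub
        miss = np.isnan(X)
        X[miss] = np.broadcast_to(self.column_means_, X.shape)[miss]
        return X

    # keep a plain signature for sklearn pipelines
    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(
            X, families=fit_params.get("families")
        )


# ---------------------------------------------------------------------------
# GenotypeMatrix-level wrappers
# ---------------------------------------------------------------------------


def compute_marker_stats(g: GenotypeMatrix, additive_pic: bool = False) -> MarkerStats:
    """Per-marker MAF, call rate, expected heterozygosity and PIC."""
    return _stats_from_array(g.to_float(), g.marker_ids, additive_pic=additive_pic)


def filter_markers(
    g: GenotypeMatrix, max_missing: float = 0.10, min_maf: float = 0.05
) -> GenotypeMatrix:
    """QC filter: keep markers with missing < max_missing and maf > min_maf."""
    qc = MarkerQC(max_missing=max_missing, min_maf=min_maf).fit(g.to_float())
    kept = np.flatnonzero(qc.support_)
    if kept.size == 0:
        import warnings

        warnings.warn("no markers survive QC filter", stacklevel=2)
    return g.select_markers(kept)


def ld_prune(
    g: GenotypeMatrix, r2_max: float = 0.95, window: int = 50, step: int = 25
) -> GenotypeMatrix:
    """Remove later markers of pairs with squared correlation > r2_max."""
    pruner = LDPruner(r2_max=r2_max, window=window, step=step).fit(g.to_float())
    return g.select_markers(np.flatnonzero(pruner.support_))


def subsample_markers(g: GenotypeMatrix, fraction: float, seed: int) -> GenotypeMatrix:
    """Random marker subset of round(fraction·n_markers), reproducible by seed."""
    sub = MarkerSubsampler(fraction=fraction, random_state=seed).fit(g.to_float())
    return g.select_markers(np.flatnonzero(sub.support_))


def impute_genotypes(
    g: GenotypeMatrix,
    method: str = "mean_dosage",
    pedigree: Pedigree | None = None,
) -> GenotypeMatrix:
    """Return a complete (no-missing) real-valued genotype matrix."""
    families = None
    if method == "family_mean":
        if pedigree is None:
            raise ValueError("family_mean imputation requires a pedigree")
        fam = pedigree.families()
        families = np.array([fam.get(i, "unpedigreed") for i in g.individual_ids])
    imp = GenotypeImputer(strategy=method)
    X = imp.fit(g.to_float(), families=families).transform(
        g.to_float(), families=families
    )
    return GenotypeMatrix(
        g.individual_ids, g.marker_ids, X, np.zeros_like(X, dtype=bool), real_valued=True
    )
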