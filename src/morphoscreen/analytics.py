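"""Plate-level statistics for morphology screens.

Implements the screen's analytical chain: per-feature z-scoring, Pearson
correlation, PCA with loadings (eigenvector * sqrt(eigenvalue)),
cytotoxic (dead) well exclusion, per-plate fold change against DMSO
controls, B-scores via Tukey two-way median polish, dual top-5% gating on
fold change and B-score for both gating metrics, and hit calling with a
compound-level rollup.

The B-score of well (i, j) on a plate is the median-polish residual
divided by 1.4826 * median(|residuals|); it is invariant to additive
row/column positional artifacts, which per-plate fold change is not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .layout import ROLES, normalize_well, parse_well

logger = logging.getLogger(__name__)

#: Identity / annotation columns of a feature table; everything else numeric
#: is treated as a morphology feature.
ID_COLUMNS = ("plate_id", "well", "row", "col", "role", "compound_id", "concentration_um")

GATING_FEATURES = ("median_colony_area", "pct_colonies_with_lumens")

MAD_SCALE = 1.4826  # consistency factor: MAD -> SD under normality


class FeatureMatrix:
    """Wells x features table with plate/well/role annotations.

    Wraps a :class:`pandas.DataFrame` whose rows are wells. Required
    columns: ``plate_id``, ``well``, ``role``; any numeric non-identity
    column is a feature. Well names are normalized ("B7" -> "B07") and
    ``row``/``col`` are derived when absent.
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy().reset_index(drop=True)
        for col in ("plate_id", "well", "role"):
            if col not in df.columns:
                raise ValueError(f"feature table missing required column: {col}")
        df["well"] = df["well"].map(normalize_well)
        if "row" not in df.columns:
            df["row"] = df["well"].str[0]
        if "col" not in df.columns:
            df["col"] = [parse_well(w)[1] for w in df["well"]]
        bad_roles = set(df["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")
        dup = df.duplicated(subset=["plate_id", "well"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["plate_id", "well"]].tolist()
            raise ValueError(f"duplicate (plate, well) key: {tuple(key)}")
        self.data = df

    @property
    def features(self) -> List[str]:
        return [
            c
            for c in self.data.columns
            if c not in ID_COLUMNS and pd.api.types.is_numeric_dtype(self.data[c])
        ]

    @property
    def feature_values(self) -> pd.DataFrame:
        return self.data[self.features]

    def with_features(self, values: pd.DataFrame) -> "FeatureMatrix":
        """New matrix with identity columns kept and features replaced."""
        ids = self.data[[c for c in self.data.columns if c in ID_COLUMNS]]
        return FeatureMatrix(pd.concat([ids, values], axis=1))

    def well_keys(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.data[["plate_id", "well"]])

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _as_frame(fm: Union[FeatureMatrix, pd.DataFrame]) -> FeatureMatrix:
    return fm if isinstance(fm, FeatureMatrix) else FeatureMatrix(fm)


# ---------------------------------------------------------------------------
# standardization / correlation / PCA


def zscore_features(
    fm: Union[FeatureMatrix, pd.DataFrame], features: Optional[Sequence[str]] = None
) -> FeatureMatrix:
    """Standardize each feature to mean 0, SD 1 (population SD).

    Constant (zero-variance) columns are dropped with a warning; an error
    is raised if nothing remains.
    """
    fm = _as_frame(fm)
    features = list(features or fm.features)
    X = fm.data[features].astype(float)
    sd = X.std(ddof=0)
    constant = [c for c in features if not sd[c] > 0]
    if constant:
        logger.warning("dropping constant feature columns: %s", constant)
        features = [c for c in features if c not in constant]
    if not features:
        raise ValueError("all feature columns are constant")
    Z = (X[features] - X[features].mean()) / sd[features]
    return fm.with_features(Z)


def pearson_matrix(fm: Union[FeatureMatrix, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise Pearson correlation between features (features x features)."""
    fm = _as_frame(fm)
    X = fm.feature_values.astype(float)
    if len(X) < 2:
        raise ValueError("need at least two wells")
    sd = X.std(ddof=0)
    zero = [c for c in X.columns if not sd[c] > 0]
    if zero:
        raise ValueError(f"zero-variance feature columns: {zero}")
    return X.corr(method="pearson")


@dataclass
class PCAResult:
    """PCA of the z-scored feature matrix.

    ``loadings`` are eigenvector * sqrt(eigenvalue) (feature-component
    correlations, for standardized input); ``explained_variance_ratio``
    is each eigenvalue over the total variance of all components.
    """

    scores: pd.DataFrame  # wells x PCk, indexed by (plate_id, well)
    loadings: pd.DataFrame  # features x PCk
    explained_variance_ratio: np.ndarray
    eigenvalues: np.ndarray
    n_samples: int


def pca_morphospace(
    fm: Union[FeatureMatrix, pd.DataFrame], n_components: Optional[int] = None
) -> PCAResult:
    """PCA on z-scored features; wells with missing features are dropped.

    Components are ordered by descending eigenvalue with a deterministic
    sign convention: the feature with the largest |loading| on each
    component has a positive loading.
    """
    fm = _as_frame(fm)
    z = zscore_features(fm)
    X = z.feature_values.astype(float)
    complete = X.notna().all(axis=1)
    if not complete.all():
        logger.warning("dropping %d wells with incomplete features", int((~complete).sum()))
    X = X[complete]
    keys = z.data.loc[complete, ["plate_id", "well"]]
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs >=2 wells and >=2 features")
    max_comp = min(n - 1, p)
    k = max_comp if n_components is None else int(n_components)
    if k < 1 or k > max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}]")

    Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
    cov = Xc.T @ Xc / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: dominant feature of each component loads positively
    for j in range(eigvecs.shape[1]):
        i = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] *= -1.0

    total = eigvals.sum()
    evr = eigvals / total if total > 0 else np.zeros_like(eigvals)
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(
        Xc @ eigvecs[:, :k], columns=comps, index=pd.MultiIndex.from_frame(keys)
    )
    loadings = pd.DataFrame(
        eigvecs[:, :k] * np.sqrt(eigvals[:k]), columns=comps, index=X.columns
    )
    return PCAResult(scores, loadings, evr[:k], eigvals[:k], n)


def cumulative_variance(p: PCAResult, k: int) -> float:
    """Fraction of total variance explained by the first k components."""
    if k < 1 or k > len(p.explained_variance_ratio):
        raise ValueError(f"k must be in [1, {len(p.explained_variance_ratio)}]")
    return float(p.explained_variance_ratio[:k].sum())


# ---------------------------------------------------------------------------
# plate normalization


def filter_dead_wells(
    fm: Union[FeatureMatrix, pd.DataFrame], min_fraction_of_dmso: float = 0.5
) -> Tuple[FeatureMatrix, pd.DataFrame]:
    """Exclude cytotoxic compound wells by depressed colony count.

    A compound well is excluded iff its colony count is strictly below
    ``min_fraction_of_dmso`` x the median DMSO colony count of its own
    plate (ties retained); control wells are never excluded. Returns the
    filtered matrix and the excluded rows.
    """
    fm = _as_frame(fm)
    df = fm.data
    if "colony_count" not in df.columns:
        raise ValueError("colony_count column required for dead-well filtering")
    excluded = np.zeros(len(df), bool)
    for plate, sub in df.groupby("plate_id"):
        dmso = sub.loc[sub["role"] == "dmso", "colony_count"]
        if dmso.empty:
            raise ValueError(f"plate {plate} has no DMSO wells")
        cutoff = min_fraction_of_dmso * float(dmso.median())
        mask = (sub["role"] == "compound") & (sub["colony_count"] < cutoff)
        excluded[sub.index[mask]] = True
    kept = FeatureMatrix(df[~excluded])
    return kept, df[excluded].copy()


def fold_change(fm: Union[FeatureMatrix, pd.DataFrame], feature: str) -> pd.Series:
    """Per-well value divided by the same-plate DMSO mean of ``feature``.

    Computed for every well, controls included; a plate's DMSO fold
    changes therefore average to exactly 1.
    """
    fm = _as_frame(fm)
    df = fm.data
    if feature not in df.columns:
        raise ValueError(f"unknown feature: {feature}")
    out = pd.Series(np.nan, index=df.index, name=f"fold_change_{feature}")
    for plate, sub in df.groupby("plate_id"):
        dmso = sub.loc[sub["role"] == "dmso", feature].astype(float)
        if dmso.empty:
            raise ValueError(f"plate {plate} has no DMSO wells")
        denom = float(dmso.mean())
        if not denom > 0:
            raise ValueError(f"plate {plate}: non-positive DMSO mean for {feature}")
        out[sub.index] = sub[feature].astype(float) / denom
    return out


@dataclass
class PlateEffects:
    """Two-way median-polish decomposition of one plate.

    value[i, j] = overall + row_effects[i] + col_effects[j] +
    residuals[i, j] holds exactly for every observed cell; missing cells
    have NaN residuals.
    """

    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    n_iterations: int
    converged: bool

    def reconstruct(self) -> np.ndarray:
        return (
            self.overall
            + self.row_effects[:, None]
            + self.col_effects[None, :]
            + self.residuals
        )


def median_polish(
    matrix: np.ndarray, tol: float = 1e-6, max_iter: int = 20
) -> PlateEffects:
    """Two-way median polish with missing values (NaN) allowed.

    The decomposition is initialized with the least-squares two-way fit
    (row/column mean sweeps) and then refined by alternating row- and
    column-median sweeps, folding effect medians into the overall term,
    until the largest sweep adjustment is below ``tol`` or ``max_iter``
    passes. The mean initialization pins down which of the (generally
    non-unique) median-polish fixed points is reached, making the
    residuals of a complete plate exactly invariant to additive
    row/column perturbations; the median sweeps keep the fit robust to
    outlying wells.
    """
    X = np.asarray(matrix, float)
    if X.ndim != 2:
        raise ValueError("expected a 2D plate matrix")
    obs = ~np.isnan(X)
    if not obs.any():
        raise ValueError("all-missing matrix")
    if (obs.any(axis=1).sum() < 2) or (obs.any(axis=0).sum() < 2):
        raise ValueError("need data in at least 2 rows and 2 columns")

    res = X.copy()
    nr, nc = X.shape
    row_eff = np.zeros(nr)
    col_eff = np.zeros(nc)
    overall = 0.0
    converged = False
    it = 0

    def _nanmedian0(a: np.ndarray, axis: int) -> np.ndarray:
        # all-NaN rows/columns contribute a zero adjustment
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmedian(a, axis=axis)
        return np.where(np.isnan(m), 0.0, m)

    def _nanmean0(a: np.ndarray, axis: int) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(a, axis=axis)
        return np.where(np.isnan(m), 0.0, m)

    # least-squares initialization (see docstring)
    rm = _nanmean0(res, axis=1)
    row_eff += rm
    res -= rm[:, None]
    cm = _nanmean0(res, axis=0)
    col_eff += cm
    res -= cm[None, :]

    for it in range(1, max_iter + 1):
        delta = 0.0
        rm = _nanmedian0(res, axis=1)
        row_eff += rm
        res -= rm[:, None]
        delta = max(delta, float(np.abs(rm).max()))
        d = float(np.median(col_eff))
        overall += d
        col_eff -= d
        cm = _nanmedian0(res, axis=0)
        col_eff += cm
        res -= cm[None, :]
        delta = max(delta, float(np.abs(cm).max()))
        d = float(np.median(row_eff))
        overall += d
        row_eff -= d
        if delta < tol:
            converged = True
            break
    res[~obs] = np.nan
    return PlateEffects(overall, row_eff, col_eff, res, it, converged)


def score_residuals(residuals: np.ndarray) -> np.ndarray:
    """B-scores from polish residuals: r / (1.4826 * median|r|).

    If the median absolute residual is zero, cells with zero residual
    score 0 and nonzero residuals are unscorable (NaN, with a warning).
    """
    res = np.asarray(residuals, float)
    if np.isnan(res).all():
        return res.copy()
    absres = np.abs(res)
    mad = float(np.nanmedian(absres))
    tiny = 1e-9 * max(float(np.nanmax(absres)), 1.0)
    if mad <= tiny:
        zeroish = absres <= tiny
        out = np.where(zeroish, 0.0, np.nan)
        out[np.isnan(res)] = np.nan
        if np.any(~np.isnan(res) & ~zeroish):
            logger.warning("zero MAD: nonzero residuals are unscorable")
        return out
    return res / (MAD_SCALE * mad)


def b_score(
    matrix: np.ndarray, tol: float = 1e-6, max_iter: int = 20
) -> Tuple[np.ndarray, PlateEffects]:
    """B-scores of one plate: median polish then MAD-scaled residuals."""
    effects = median_polish(matrix, tol=tol, max_iter=max_iter)
    return score_residuals(effects.residuals), effects


def plate_grid(
    df: pd.DataFrame, feature: str, n_rows: int = 16, n_cols: int = 24
) -> np.ndarray:
    """Arrange one plate's per-well values on the physical row x col grid."""
    grid = np.full((n_rows, n_cols), np.nan)
    for well, value in zip(df["well"], df[feature].astype(float)):
        r, c = parse_well(well)
        grid[r, c - 1] = value
    return grid


def b_score_wells(
    fm: Union[FeatureMatrix, pd.DataFrame],
    feature: str,
    population_roles: Tuple[str, ...] = ("compound",),
    exclude_keys: Optional[Set[Tuple[str, str]]] = None,
    n_rows: int = 16,
    n_cols: int = 24,
) -> pd.Series:
    """Per-well B-scores of ``feature``, plate by plate.

    Only wells whose role is in ``population_roles`` (and not in
    ``exclude_keys``) enter the polish; other positions are treated as
    missing and receive NaN scores, mirroring screens where B-scores are
    computed for drug-treated wells only.
    """
    fm = _as_frame(fm)
    df = fm.data
    exclude_keys = exclude_keys or set()
    out = pd.Series(np.nan, index=df.index, name=f"bscore_{feature}")
    for plate, sub in df.groupby("plate_id"):
        eligible = sub["role"].isin(population_roles) & ~sub.apply(
            lambda r: (r["plate_id"], r["well"]) in exclude_keys, axis=1
        )
        masked = sub.copy()
        masked.loc[~eligible, feature] = np.nan
        grid = plate_grid(masked, feature, n_rows, n_cols)
        if np.isnan(grid).all():
            continue
        try:
            scores, _ = b_score(grid)
        except ValueError as exc:
            logger.warning("plate %s: B-scores not computable (%s)", plate, exc)
            continue
        for idx, well in zip(sub.index, sub["well"]):
            r, c = parse_well(well)
            out[idx] = scores[r, c - 1]
    return out


def z_score_wells(
    fm: Union[FeatureMatrix, pd.DataFrame],
    feature: str,
    population_roles: Tuple[str, ...] = ("compound",),
) -> pd.Series:
    """Naive per-plate z-scores of ``feature`` (no positional correction).

    The mean and SD are taken over the plate's population wells; unlike
    the B-score this does not remove row/column artifacts, so wells in
    drifted plate regions score high. Provided as the baseline the
    B-score improves on.
    """
    fm = _as_frame(fm)
    df = fm.data
    out = pd.Series(np.nan, index=df.index, name=f"zscore_{feature}")
    for plate, sub in df.groupby("plate_id"):
        pop = sub.loc[sub["role"].isin(population_roles), feature].astype(float).dropna()
        if len(pop) < 2 or not pop.std(ddof=0) > 0:
            continue
        mu, sd = pop.mean(), pop.std(ddof=0)
        idx = sub.index[sub["role"].isin(population_roles)]
        out[idx] = (sub.loc[idx, feature].astype(float) - mu) / sd
    return out


# ---------------------------------------------------------------------------
# gating and hit calling


def top_percent_gate(
    values: pd.Series, percent: float = 5.0, population: Optional[pd.Series] = None
) -> Tuple[pd.Series, float]:
    """Flag values in the top ``percent`` of the population.

    The threshold is the (100 - percent)th linear-interpolation percentile
    of the population's values; every well (population member or not) with
    a value >= threshold is flagged. NaNs are never flagged.
    """
    if not 0 < percent < 100:
        raise ValueError("percent must be in (0, 100)")
    pop = values if population is None else values[population]
    pop = pop.dropna()
    if pop.empty:
        raise ValueError("empty gating population")
    threshold = float(np.percentile(pop.to_numpy(), 100.0 - percent))
    if float(pop.min()) == float(pop.max()):
        logger.warning("degenerate gate: all population values equal; all flagged")
    flags = values >= threshold
    flags[values.isna()] = False
    return flags, threshold


@dataclass
class HitTable:
    """Dual-gating result: per-well scores, gate flags and hit calls.

    ``table`` has one row per well with fold changes and B-scores for
    both gating metrics, the four gate flags, ``excluded_dead`` and
    ``is_hit``; ``compound_rollup`` aggregates hit wells per compound
    (a compound is a hit if >=1 of its wells is).
    """

    table: pd.DataFrame
    thresholds: Dict[str, float]
    compound_rollup: pd.DataFrame
    params: Dict[str, object] = field(default_factory=dict)

    @property
    def hit_wells(self) -> pd.DataFrame:
        return self.table[self.table["is_hit"]]


def call_hits(
    fm: Union[FeatureMatrix, pd.DataFrame],
    percent: float = 5.0,
    metrics: Tuple[str, str] = GATING_FEATURES,
    dead_fraction: Optional[float] = None,
    n_rows: int = 16,
    n_cols: int = 24,
) -> HitTable:
    """Dual top-percent hit calling on fold change and B-score.

    For each gating metric the per-well fold change (vs same-plate DMSO
    mean) and B-score are computed; a well is a hit iff it lies in the top
    ``percent`` of the compound-well population on all four scores. If
    ``dead_fraction`` is given, cytotoxic wells are excluded first (and
    reported via ``excluded_dead``); otherwise the input is assumed
    pre-filtered.
    """
    fm = _as_frame(fm)
    exclude: Set[Tuple[str, str]] = set()
    if dead_fraction is not None:
        _, dropped = filter_dead_wells(fm, dead_fraction)
        exclude = set(zip(dropped["plate_id"], dropped["well"]))

    df = fm.data.copy()
    keys = list(zip(df["plate_id"], df["well"]))
    df["excluded_dead"] = [k in exclude for k in keys]
    population = (df["role"] == "compound") & ~df["excluded_dead"]

    thresholds: Dict[str, float] = {}
    gate_cols: List[str] = []
    short = {metrics[0]: "area", metrics[1]: "lumens"}
    for metric in metrics:
        if metric not in df.columns:
            raise ValueError(f"gating feature missing: {metric}")
        tag = short[metric]
        fc = fold_change(fm, metric)
        bs = b_score_wells(fm, metric, exclude_keys=exclude, n_rows=n_rows, n_cols=n_cols)
        df[f"fold_change_{tag}"] = fc.to_numpy()
        df[f"bscore_{tag}"] = bs.to_numpy()
        for kind in ("fold_change", "bscore"):
            col = f"{kind}_{tag}"
            flags, thr = top_percent_gate(df[col], percent, population)
            df[f"gate_{col}"] = flags
            thresholds[col] = thr
            gate_cols.append(f"gate_{col}")

    df["is_hit"] = df[gate_cols].all(axis=1) & population
    hit_rows = df[df["is_hit"]]
    rollup = (
        hit_rows.groupby("compound_id")
        .agg(
            n_hit_wells=("well", "size"),
            concentrations=("concentration_um", lambda s: sorted(s.tolist())),
            plates=("plate_id", lambda s: sorted(set(s))),
        )
        .reset_index()
    )
    params = {
        "percent": percent,
        "metrics": list(metrics),
        "quantile_definition": "linear interpolation between order statistics; flag by >= threshold",
        "population": "compound wells screen-wide, controls and dead-excluded wells removed",
        "dead_fraction": dead_fraction,
    }
    return HitTable(df, thresholds, rollup, params)


# ---------------------------------------------------------------------------
# QC and small utilities


@dataclass
class ControlSeparation:
    """DMSO vs positive-control QC on the gating metrics."""

    metrics: Dict[str, Dict[str, float]]  # metric -> medians/IQRs/p-value
    passed: bool


def control_separation(
    fm: Union[FeatureMatrix, pd.DataFrame],
    metrics: Tuple[str, ...] = GATING_FEATURES,
    alpha: float = 0.05,
) -> ControlSeparation:
    """Wilcoxon rank-sum separation of positive controls from DMSO.

    QC passes when, for every metric, the positive-control median exceeds
    the DMSO median with a two-sided rank-sum p-value below ``alpha``.
    """
    fm = _as_frame(fm)
    df = fm.data
    out: Dict[str, Dict[str, float]] = {}
    passed = True
    for role in ("dmso", "positive"):
        if not (df["role"] == role).any():
            raise ValueError(f"control role absent: {role}")
    for metric in metrics:
        dmso = df.loc[df["role"] == "dmso", metric].dropna().astype(float)
        pos = df.loc[df["role"] == "positive", metric].dropna().astype(float)
        stat, p = stats.ranksums(pos, dmso)
        q1d, q3d = np.percentile(dmso, [25, 75])
        q1p, q3p = np.percentile(pos, [25, 75])
        out[metric] = {
            "dmso_median": float(dmso.median()),
            "dmso_iqr": float(q3d - q1d),
            "positive_median": float(pos.median()),
            "positive_iqr": float(q3p - q1p),
            "statistic": float(stat),
            "p_value": float(p),
            "n_dmso": int(len(dmso)),
            "n_positive": int(len(pos)),
        }
        if not (p < alpha and out[metric]["positive_median"] > out[metric]["dmso_median"]):
            passed = False
    return ControlSeparation(out, passed)


def normalize_colony_counts(
    treated: Sequence[float], control: Sequence[float]
) -> Dict[str, float]:
    """Treated replicate counts over the control mean; mean +/- SEM."""
    treated = np.asarray(treated, float)
    control = np.asarray(control, float)
    cmean = float(control.mean())
    if not cmean > 0:
        raise ValueError("control mean must be positive")
    norm = treated / cmean
    sem = float(stats.sem(norm, ddof=1)) if norm.size > 1 else float("nan")
    return {
        "normalized": norm,
        "mean": float(norm.mean()),
        "sem": sem,
        "n": int(norm.size),
    }
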