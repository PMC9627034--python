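"""Inferential layer: feature x naturalness model, FDR-corrected contrasts,
voxel-wise age correlation with cluster-based permutation inference, ROI
regressions and within-subject error bars.

The repeated-measures model treats per-subject intercepts as fixed
constants, which for the balanced crossed design (every subject contributes
all feature x condition cells) coincides with the random-intercept fit for
the fixed-effect estimates and their F tests.

Cluster inference follows the nonparametric permutation recipe for
correlation maps: voxels whose Pearson-r-derived t statistic exceeds the
two-sided parametric threshold at ``cluster_alpha`` are grouped into
sign-homogeneous spatially connected clusters; the cluster mass is the sum
of member t values; the null distribution is built by shuffling ages across
participants and recording the maximum absolute cluster mass per
permutation, so the resulting p values are familywise-corrected over the
whole grid and both signs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .errors import InvalidParameterError
from .types import (
    CONDITIONS,
    FEATURES,
    Cluster,
    ClusterResult,
    RoiFit,
    StatMap,
)

__all__ = [
    "fit_feature_naturalness_model",
    "pairwise_contrasts",
    "benjamini_hochberg",
    "corr_t_map",
    "cluster_permutation",
    "roi_regression",
    "lowest_t_voxel",
    "within_subject_se",
    "ModelFit",
]


# ---------------------------------------------------------------------------
# feature x naturalness model
# ---------------------------------------------------------------------------

class ModelFit:
    """Fixed-effects fit of coherence ~ feature + naturalness + subject.

    Exposes per-effect F statistics with their degrees of freedom, the
    residual variance, fitted cell means, and counts needed by the contrast
    machinery.
    """

    def __init__(
        self,
        cell_means: pd.DataFrame,
        feature_means: pd.Series,
        condition_means: pd.Series,
        f_tests: dict[str, tuple[float, int, int, float]],
        sigma2: float,
        n_subjects: int,
    ) -> None:
        self.cell_means = cell_means
        self.feature_means = feature_means
        self.condition_means = condition_means
        self.f_tests = f_tests  # effect -> (F, df_num, df_den, p)
        self.sigma2 = sigma2
        self.n_subjects = n_subjects


def _check_balanced(tbl: pd.DataFrame) -> None:
    counts = tbl.groupby(["subject_id", "feature", "condition"]).size()
    if (counts != 1).any():
        raise InvalidParameterError(
            "unbalanced table: every subject must contribute exactly one value "
            "per feature x condition cell (balanced designs only)"
        )
    per_subject = tbl.groupby("subject_id").size()
    expected = len(FEATURES) * len(CONDITIONS)
    if (per_subject != expected).any():
        raise InvalidParameterError(
            f"every subject must contribute all {expected} feature x condition cells"
        )


def fit_feature_naturalness_model(tbl: pd.DataFrame) -> ModelFit:
    """Fit value ~ C(feature) + C(condition) + C(subject) by OLS and report
    F tests for the two fixed effects.

    ``tbl`` needs columns subject_id, feature, condition, value.  With the
    balanced design the factors are orthogonal, so sequential, Type-II and
    Type-III sums of squares coincide.
    """
    required = {"subject_id", "feature", "condition", "value"}
    missing = required - set(tbl.columns)
    if missing:
        raise InvalidParameterError(f"table is missing columns {sorted(missing)}")
    if tbl["subject_id"].nunique() < 2:
        raise InvalidParameterError("need at least two subjects")
    _check_balanced(tbl)

    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    fit = smf.ols("value ~ C(feature) + C(condition) + C(subject_id)", data=tbl).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-residual fits emit divide warnings
        table = anova_lm(fit, typ=2)

    sigma2 = float(fit.mse_resid) if fit.df_resid > 0 else 0.0
    # a residual variance at rounding level means an exact cell-mean fit
    exact = sigma2 <= 1e-12 * max(float(np.var(tbl["value"])), 1e-300)
    f_tests: dict[str, tuple[float, int, int, float]] = {}
    for effect, row_name in (("feature", "C(feature)"), ("naturalness", "C(condition)")):
        f_val = float(table.loc[row_name, "F"])
        p_val = float(table.loc[row_name, "PR(>F)"])
        if exact or not np.isfinite(f_val):  # report a capped F
            f_val, p_val = np.inf, 0.0
        f_tests[effect] = (
            f_val,
            int(table.loc[row_name, "df"]),
            int(fit.df_resid),
            p_val,
        )

    cell_means = (
        tbl.groupby(["feature", "condition"])["value"].mean().rename("mean").reset_index()
    )
    return ModelFit(
        cell_means=cell_means,
        feature_means=tbl.groupby("feature")["value"].mean(),
        condition_means=tbl.groupby("condition")["value"].mean(),
        f_tests=f_tests,
        sigma2=sigma2,
        n_subjects=tbl["subject_id"].nunique(),
    )


def pairwise_contrasts(fit: ModelFit, family: str = "features") -> pd.DataFrame:
    """Pairwise contrasts with normal (z) reference and BH-adjusted p values.

    ``family='features'``: the 6 pairwise differences between feature-level
    marginal means.  ``family='naturalness-within-feature'``: natural minus
    reversed within each of the 4 features.
    """
    s = fit.n_subjects
    rows = []
    if family == "features":
        levels = list(fit.feature_means.index)
        m = s * len(CONDITIONS)  # observations per feature level
        se = np.sqrt(2 * fit.sigma2 / m)
        for i, a in enumerate(levels):
            for b in levels[i + 1 :]:
                rows.append((f"{a} - {b}", fit.feature_means[a] - fit.feature_means[b], se))
    elif family == "naturalness-within-feature":
        se = np.sqrt(2 * fit.sigma2 / s)
        cm = fit.cell_means.set_index(["feature", "condition"])["mean"]
        for f in sorted(set(fit.cell_means["feature"])):
            est = cm[(f, "natural")] - cm[(f, "reversed")]
            rows.append((f"{f}: natural - reversed", est, se))
    else:
        raise InvalidParameterError(
            "family must be 'features' or 'naturalness-within-feature'"
        )
    out = pd.DataFrame(rows, columns=["contrast", "estimate", "se"])
    with np.errstate(divide="ignore", invalid="ignore"):
        out["z"] = np.where(out["se"] > 0, out["estimate"] / out["se"], np.inf * np.sign(out["estimate"]))
    out["p"] = 2 * sps.norm.sf(np.abs(out["z"]))
    out["p_fdr"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjusted p values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise InvalidParameterError("p values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# age-correlation maps and cluster permutation
# ---------------------------------------------------------------------------

def _pearson_maps(index_stack: np.ndarray, ages_centered: np.ndarray) -> np.ndarray:
    """Pearson r between ages and every voxel column; zero-variance voxels
    get r = 0.  ``ages_centered`` must be centered and may be 1- or 2-D
    (permutations x subjects)."""
    xc = index_stack - index_stack.mean(axis=0)
    x_norm = np.sqrt((xc**2).sum(axis=0))
    a_norm = np.sqrt((ages_centered**2).sum(axis=-1))
    num = ages_centered @ xc
    denom = np.atleast_1d(a_norm)[..., None] * x_norm[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, num / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def corr_t_map(index_stack: np.ndarray, ages: np.ndarray) -> StatMap:
    """Voxel-wise Pearson correlation with age and its t statistic
    t = r sqrt((n-2)/(1-r^2)); |r| = 1 maps to a signed infinity."""
    index_stack = np.asarray(index_stack, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if index_stack.ndim != 2 or index_stack.shape[0] != ages.size:
        raise InvalidParameterError("index stack must be (n_subjects, n_voxels)")
    n = ages.size
    if n < 4:
        raise InvalidParameterError("need at least 4 subjects")
    xc = index_stack - index_stack.mean(axis=0)
    if np.any((xc**2).sum(axis=0) == 0):
        warnings.warn("zero-variance voxel(s); correlation set to 0 there", stacklevel=2)
    r = _pearson_maps(index_stack, ages - ages.mean())[0]
    exact = np.abs(r) >= 1.0 - 1e-12  # collinear up to rounding
    r = np.where(exact, np.sign(r), r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    t = np.where(exact, np.sign(r) * np.inf, t)
    return StatMap(r=r, t=t, n_subjects=n)


_STRUCTURES = {6: 1, 18: 2, 26: 3}


def _clusters_from_tmap(
    t_map: np.ndarray, grid_shape: tuple[int, int, int], t_thresh: float, structure: np.ndarray
) -> list[tuple[np.ndarray, int, float]]:
    vol = t_map.reshape(grid_shape)
    out: list[tuple[np.ndarray, int, float]] = []
    for sign in (1, -1):
        mask = (sign * vol) > t_thresh
        if not mask.any():
            continue
        labels, n = ndimage.label(mask, structure=structure)
        flat_labels = labels.ravel()
        for lab in range(1, n + 1):
            voxels = np.flatnonzero(flat_labels == lab)
            out.append((voxels, sign, float(t_map[voxels].sum())))
    return out


def _max_cluster_mass(
    t_map: np.ndarray, grid_shape: tuple[int, int, int], t_thresh: float, structure: np.ndarray
) -> float:
    masses = [abs(m) for _, _, m in _clusters_from_tmap(t_map, grid_shape, t_thresh, structure)]
    return max(masses, default=0.0)


def cluster_permutation(
    index_stack: np.ndarray,
    ages: np.ndarray,
    grid_shape: tuple[int, int, int],
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 18,
) -> ClusterResult:
    """Cluster-based permutation test of the voxel-wise age correlation.

    The permutation stream is a single ``numpy.random.default_rng(seed)``
    from which ``n_perm`` age reorderings are drawn in sequence, so any two
    procedures sharing the seed see identical shuffles.  Cluster p values
    are (1 + #{perm max |mass| >= observed |mass|}) / (n_perm + 1); they can
    never reach 0 and have resolution 1/(n_perm + 1).
    """
    index_stack = np.asarray(index_stack, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if n_perm < 100:
        raise InvalidParameterError("n_perm must be >= 100")
    if np.ptp(ages) == 0:
        raise InvalidParameterError("ages are constant; correlation is undefined")
    if int(np.prod(grid_shape)) != index_stack.shape[1]:
        raise InvalidParameterError("grid shape does not cover the voxel dimension")
    if connectivity not in _STRUCTURES:
        raise InvalidParameterError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])

    stat_map = corr_t_map(index_stack, ages)
    n = ages.size
    t_thresh = sps.t.ppf(1 - cluster_alpha / 2, df=n - 2)
    observed = _clusters_from_tmap(stat_map.t, grid_shape, t_thresh, structure)

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(ages) for _ in range(n_perm)])
    perms -= perms.mean(axis=1, keepdims=True)
    r_null = _pearson_maps(index_stack, perms)  # (n_perm, n_voxels)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = r_null * np.sqrt((n - 2) / (1 - r_null**2))
    t_null = np.where(np.abs(r_null) >= 1.0, np.sign(r_null) * np.inf, t_null)

    null_max = np.array(
        [_max_cluster_mass(t_null[i], grid_shape, t_thresh, structure) for i in range(n_perm)]
    )

    clusters = []
    for voxels, sign, mass in observed:
        p = (1 + int(np.sum(null_max >= abs(mass)))) / (n_perm + 1)
        clusters.append(Cluster(voxels=voxels, sign=sign, mass=mass, p_value=p))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(
        clusters=clusters,
        stat_map=stat_map,
        n_permutations=n_perm,
        cluster_alpha=cluster_alpha,
        seed=seed,
        null_max_mass=null_max,
    )


# ---------------------------------------------------------------------------
# ROI regressions and plotting helpers
# ---------------------------------------------------------------------------

def roi_regression(
    index_stack: np.ndarray, ages: np.ndarray, roi_mask: np.ndarray, roi_label: str = "roi"
) -> RoiFit:
    """OLS of the per-subject ROI-mean index on age.

    Reports slope, F(1, n-2), p, R-squared and eta-squared; with a single
    predictor eta-squared equals R-squared (SS_age / SS_total).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise InvalidParameterError("ROI mask is empty")
    index_stack = np.asarray(index_stack, dtype=float)
    ages = np.asarray(ages, dtype=float)
    y = index_stack[:, roi_mask].mean(axis=1)
    n = ages.size
    res = sps.linregress(ages, y)
    r2 = res.rvalue**2
    df_den = n - 2
    with np.errstate(divide="ignore"):
        f_stat = r2 / (1 - r2) * df_den if r2 < 1 else np.inf
    return RoiFit(
        roi=roi_label,
        slope=float(res.slope),
        intercept=float(res.intercept),
        f_stat=float(f_stat),
        p_value=float(res.pvalue),
        r_squared=float(r2),
        eta_squared=float(r2),
        df_den=df_den,
        subject_means=y,
    )


def lowest_t_voxel(stat_map: StatMap, within: np.ndarray | None = None) -> int:
    """Index of the voxel with the most negative t (ties -> lowest index)."""
    t = stat_map.t.copy()
    if within is not None:
        within = np.asarray(within, dtype=bool)
        t = np.where(within, t, np.nan)
    if np.all(np.isnan(t)):
        raise InvalidParameterError("no finite t value to minimize")
    return int(np.nanargmin(t))


def within_subject_se(cell_matrix: np.ndarray) -> np.ndarray:
    """Per-condition standard errors for within-subject designs.

    Cousineau normalization (subtract each subject's mean, add back the grand
    mean) followed by Morey's bias correction sqrt(C / (C - 1)) on the
    per-condition SD/sqrt(n).
    """
    y = np.asarray(cell_matrix, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2:
        raise InvalidParameterError("need a (subjects x conditions) matrix with >= 2 subjects")
    n_sub, n_cond = y.shape
    if n_cond < 2:
        raise InvalidParameterError("need at least two conditions")
    adj = y - y.mean(axis=1, keepdims=True) + y.mean()
    se = adj.std(axis=0, ddof=1) / np.sqrt(n_sub)
    return se * np.sqrt(n_cond / (n_cond - 1))
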