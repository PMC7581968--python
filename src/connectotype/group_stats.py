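"""Control-referenced white-matter loss scoring and group contrasts.

A subject's summed connection strength in a class is normalised against the
control distribution, ``z = (strength - control mean) / control SD``, and
transformed to a bounded loss score ``loss = tanh(-z)`` so that higher
values mean greater connection loss and the score lives in (-1, 1).

Group contrasts fit, per connection class, an ordinary least-squares model
``strength ~ group + age + sex`` and control the false discovery rate over
all classes with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .connectome import Connectome
from .parcellation import Parcellation

__all__ = [
    "WMLossScores",
    "wm_loss",
    "regional_loss_map",
    "contrast_classes",
    "composite_loss",
    "spearman",
    "summary_t_test",
    "chi2_2x2",
    "bh_fdr",
    "normality_screen",
]


@dataclass
class WMLossScores:
    """Per-subject, per-class z-scores and tanh loss scores."""

    z: pd.DataFrame
    loss: pd.DataFrame
    excluded: list

    def __post_init__(self) -> None:
        assert self.z.shape == self.loss.shape


def wm_loss(
    strengths: pd.DataFrame,
    meta: pd.DataFrame,
    *,
    control_group: str = "control",
) -> WMLossScores:
    """Control-normalised WM-loss scores for every subject and class.

    ``strengths`` is subjects x class-labels; ``meta`` must carry a
    ``group`` column on the same index. Classes with zero control variance
    are excluded with a warning. Controls are scored too (against their own
    mean, so their average loss is near zero).
    """
    controls = meta.index[meta["group"] == control_group]
    if len(controls) < 3:
        raise ValueError("need at least 3 control subjects")
    mu = strengths.loc[controls].mean(axis=0)
    sd = strengths.loc[controls].std(axis=0, ddof=1)
    degenerate = sd.index[(sd == 0) | sd.isna()].tolist()
    if degenerate:
        warnings.warn(
            f"excluding {len(degenerate)} zero-variance classes: {degenerate[:5]}"
        )
    keep = [c for c in strengths.columns if c not in set(degenerate)]
    z = (strengths[keep] - mu[keep]) / sd[keep]
    return WMLossScores(z=z, loss=np.tanh(-z), excluded=degenerate)


def regional_loss_map(
    connectomes: list[Connectome],
    parcellation: Parcellation,
    class_kind: str,
    *,
    hemisphere: str = "left",
    target_group: str = "pd_low",
    control_group: str = "control",
) -> pd.Series:
    """Per-region WM-loss score for one connection type.

    For every cortical region of ``hemisphere``, the regional strength is
    the sum of its weights to the type's partner set: the ipsilateral
    subcortical block (``subcortical_cortical``), all contralateral cortical
    regions (``interhemispheric``), or the other cortical regions of its own
    hemisphere (``intrahemispheric``). Strengths are z-scored against
    controls per region, tanh(-z)-transformed, and averaged over the target
    group, yielding one loss score per region — the response map for the
    imaging-transcriptomics regression.
    """
    regions = parcellation.cortical_ids_of(hemisphere)
    other = "right" if hemisphere == "left" else "left"
    if class_kind == "subcortical_cortical":
        partners = parcellation.subcortical_block(hemisphere)
        exclude_self = False
    elif class_kind == "interhemispheric":
        partners = parcellation.cortical_ids_of(other)
        exclude_self = False
    elif class_kind == "intrahemispheric":
        partners = regions
        exclude_self = True
    else:
        raise ValueError(f"no regional score defined for kind {class_kind!r}")

    rows = {}
    for c in connectomes:
        sub = c.weights[np.ix_(regions, partners)]
        s = sub.sum(axis=1)
        if exclude_self:
            s = s - np.diag(c.weights[np.ix_(regions, regions)]).copy()  # diag is 0 anyway
        rows[c.subject_id] = s
    table = pd.DataFrame(rows, index=regions).T
    groups = pd.Series({c.subject_id: c.group for c in connectomes})
    mu = table.loc[groups == control_group].mean(axis=0)
    sd = table.loc[groups == control_group].std(axis=0, ddof=1)
    z = (table - mu) / sd
    loss = np.tanh(-z)
    out = loss.loc[groups == target_group].mean(axis=0)
    out.name = f"wm_loss[{class_kind}]"
    return out


def _kind_of(label: str) -> str:
    return label.split(":", 1)[0]


def contrast_classes(
    strengths: pd.DataFrame,
    meta: pd.DataFrame,
    *,
    groups: tuple[str, str] = ("pd_high", "pd_low"),
    covariates: tuple[str, ...] = ("age", "sex"),
    alpha: float = 0.05,
    mixed: bool = False,
) -> pd.DataFrame:
    """Per-class group contrast with covariate adjustment and BH-FDR.

    Fits, for each connection class, ``strength ~ group + covariates`` over
    the subjects of the two groups and reports the group coefficient (coded
    0 for ``groups[0]``, 1 for ``groups[1]``), its t statistic and two-sided
    p value, and the BH-FDR q value across all classes. ``mixed=True``
    switches to one mixed model per connection kind (within-class
    standardised strengths, subject random intercept) and reads per-class
    group effects off the class-by-group interaction.
    """
    mask = meta["group"].isin(groups)
    meta = meta.loc[mask]
    strengths = strengths.loc[meta.index]
    if (meta["group"] == groups[0]).sum() < 2 or (meta["group"] == groups[1]).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    design = pd.DataFrame(index=meta.index)
    design["group"] = (meta["group"] == groups[1]).astype(float)
    for cov in covariates:
        col = meta[cov]
        if col.isna().any():
            raise ValueError(f"covariate {cov!r} has missing values")
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.notna().all():
            design[cov] = numeric.astype(float)
        else:  # categorical covariate (e.g. sex) -> reference-coded dummy
            design[cov] = pd.get_dummies(col, drop_first=True).iloc[:, 0].astype(float)
    X = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy(float)) < X.shape[1]:
        raise ValueError(f"rank-deficient design; columns: {list(X.columns)}")

    if mixed:
        rows = _contrast_mixed(strengths, design, meta)
    else:
        rows = []
        for label in strengths.columns:
            fit = sm.OLS(strengths[label].astype(float), X).fit()
            rows.append({
                "class": label, "kind": _kind_of(label),
                "beta": fit.params["group"], "t": fit.tvalues["group"],
                "p": fit.pvalues["group"],
            })
    res = pd.DataFrame(rows)
    res["q"] = bh_fdr(res["p"].to_numpy())
    res["significant"] = res["q"] < alpha
    return res.set_index("class")


def _contrast_mixed(strengths, design, meta):
    """Mixed-model variant: per kind, subject random intercept."""
    rows = []
    for kind in sorted({_kind_of(c) for c in strengths.columns}):
        cols = [c for c in strengths.columns if _kind_of(c) == kind]
        std = (strengths[cols] - strengths[cols].mean()) / strengths[cols].std(ddof=1)
        long = std.stack().rename("strength").reset_index()
        long.columns = ["subject_id", "cls", "strength"]
        long = long.merge(design.reset_index().rename(columns={"index": "subject_id",
                                                               design.index.name or "index": "subject_id"}),
                          on="subject_id")
        formula = "strength ~ 0 + C(cls) + C(cls):group"
        for cov in design.columns:
            if cov != "group":
                formula += f" + {cov}"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, long, groups=long["subject_id"]).fit()
        for c in cols:
            term = f"C(cls)[{c}]:group"
            rows.append({
                "class": c, "kind": kind, "beta": fit.params[term],
                "t": fit.tvalues[term], "p": fit.pvalues[term],
            })
    return rows


def composite_loss(loss: pd.DataFrame, class_kind: str) -> pd.Series:
    """Sum of a subject's loss scores over all classes of one kind."""
    cols = [c for c in loss.columns if _kind_of(c) == class_kind]
    if not cols:
        raise ValueError(f"no classes of kind {class_kind!r}")
    out = loss[cols].sum(axis=1)
    out.name = f"composite_{class_kind}"
    return out


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with t-approximation p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need equal-length vectors with at least 5 points")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def summary_t_test(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float]:
    """Pooled-variance two-sample t test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean2 - mean1) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def chi2_2x2(a: int, b: int, c: int, d: int, *, yates: bool = True) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, optional Yates correction."""
    table = np.array([[a, b], [c, d]])
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("cells must be nonnegative integers")
    res = stats.chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values)."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


def normality_screen(strengths: pd.DataFrame) -> pd.Series:
    """Shapiro-Wilk p value per class — a reported diagnostic, not a gate."""
    return strengths.apply(lambda col: stats.shapiro(col.astype(float)).pvalue)
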