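"""Permutational and mixed-model statistics for distance-based community data.

* :func:`permanova` — sequential (Type-I) sum-of-squares partitioning of a
  Gower-centered distance matrix with permutation pseudo-F tests (the
  ``adonis``-style table: term, df, SS, F, R², p).
* :func:`mantel_kendall` — Kendall tau-b between two square matrices with a
  node-label permutation (Mantel-scheme) two-sided test.
* :func:`indicator_analysis` — IndVal statistic sqrt(specificity * fidelity)
  per taxon between two groups, with a permutation test.
* :func:`dyad_mixed_model` — Gaussian linear mixed model on dyadic distances
  with crossed random intercepts (focal individual, band), likelihood-ratio
  chi-square for the category effect, optional adjusted pairwise contrasts.
* :func:`band_jsd_anova` — one-way ANOVA with Tukey HSD over within/between
  band dyad groups.

Monte-Carlo permutation p-values use (1 + #exceedances) / (1 + n_perm);
exhaustive enumeration reports the plain proportion including the identity.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    """adonis-style table: one row per term plus Residual and Total."""

    table: pd.DataFrame  # index term; columns df, SS, F, R2, p
    n_permutations: int
    seed: int | None

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.4f}")


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def _hat(x: np.ndarray) -> tuple:
    """Projection matrix onto the column space of x, and its rank."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    keep = diag > diag.max() * 1e-10 if diag.size else np.array([], bool)
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


def _design_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    col = metadata[term]
    if col.nunique() < 2:
        raise ValueError(f"term {term!r} has a single level")
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(float).reshape(-1, 1)
    return pd.get_dummies(col, drop_first=True).to_numpy(float)


def permanova(
    dist,
    metadata: pd.DataFrame,
    terms: list,
    n_perm: int = 999,
    seed: int | None = 0,
    permutations: str = "monte_carlo",
) -> PermanovaResult:
    """Sequential PERMANOVA of a distance matrix on metadata terms.

    ``permutations="exhaustive"`` enumerates every relabelling (n <= 8) and
    reports p as the proportion of permutations, identity included, whose
    pseudo-F reaches the observed value.
    """
    ids = dist.ids
    md = metadata.loc[ids]
    n = len(ids)
    if n < 3:
        raise ValueError("PERMANOVA needs at least 3 samples")
    g = _gower_center(dist.values)
    ss_total = float(np.trace(g))

    x = np.ones((n, 1))
    hats, ranks = [], []
    for term in terms:
        x = np.hstack([x, _design_columns(md, term)])
        h, r = _hat(x)
        hats.append(h)
        ranks.append(r)
        if len(ranks) >= 2 and ranks[-1] == ranks[-2]:
            logger.warning("term %r adds no rank (collinear); SS will be ~0", term)
    dfs = np.diff([1] + ranks)
    if (dfs < 0).any():
        raise ValueError("rank-deficient design")
    df_resid = n - ranks[-1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    def term_f_stats(gmat):
        ss_model = np.array([np.sum(h * gmat) for h in hats])  # tr(H G), H symmetric
        ss_terms = np.diff(np.concatenate([[0.0], ss_model]))
        ss_resid = np.trace(gmat) - ss_model[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_terms / dfs) / (ss_resid / df_resid)
        return ss_terms, ss_resid, f

    ss_terms, ss_resid, f_obs = term_f_stats(g)
    # permutations reproducing the observed grouping tie with f_obs up to
    # floating-point jitter; ties must count as exceedances for a valid test
    f_floor = f_obs - 1e-9 * np.maximum(1.0, np.abs(f_obs))

    if permutations == "exhaustive":
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        exceed = np.zeros(len(terms))
        total = 0
        for perm in itertools.permutations(range(n)):
            gp = g[np.ix_(perm, perm)]
            _, _, f_p = term_f_stats(gp)
            exceed += f_p >= f_floor
            total += 1
        pvals = exceed / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(terms))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            gp = g[np.ix_(perm, perm)]
            _, _, f_p = term_f_stats(gp)
            exceed += f_p >= f_floor
        pvals = (1.0 + exceed) / (1.0 + n_perm)
        n_used = n_perm

    rows = []
    for t, df_t, ss_t, f_t, p_t in zip(terms, dfs, ss_terms, f_obs, pvals):
        rows.append(
            {"term": t, "df": int(df_t), "SS": ss_t, "F": f_t,
             "R2": ss_t / ss_total, "p": p_t}
        )
    rows.append({"term": "Residual", "df": int(df_resid), "SS": ss_resid,
                 "F": np.nan, "R2": ss_resid / ss_total, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total,
                 "F": np.nan, "R2": 1.0, "p": np.nan})
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table, n_used, seed)


# ---------------------------------------------------------------------------
# Mantel-style Kendall correlation


@dataclass
class MatrixCorrelationResult:
    tau: float
    p_perm: float
    n_perm: int
    seed: int | None


def _lower_triangle(values: np.ndarray) -> np.ndarray:
    return values[np.tril_indices(values.shape[0], k=-1)]


def mantel_kendall(assoc, dist, n_perm: int = 999, seed: int | None = 0) -> MatrixCorrelationResult:
    """Kendall tau-b between two square matrices, node-permutation p (two-sided)."""
    if list(assoc.ids) != list(dist.ids):
        raise ValueError("matrices must share ids in the same order")
    n = len(dist.ids)
    if n < 4:
        raise ValueError("need at least 4 nodes")
    x = _lower_triangle(np.asarray(assoc.values, float))
    y = _lower_triangle(dist.values)
    tau = sps.kendalltau(x, y).statistic
    rng = np.random.default_rng(seed)
    a = np.asarray(assoc.values, float)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = _lower_triangle(a[np.ix_(perm, perm)])
        tau_p = sps.kendalltau(xp, y).statistic
        if abs(tau_p) >= abs(tau) - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return MatrixCorrelationResult(float(tau), p, n_perm, seed)


# ---------------------------------------------------------------------------
# Indicator (IndVal) analysis


@dataclass
class IndicatorResult:
    """Per-taxon indicator values between two groups."""

    table: pd.DataFrame  # index taxon; columns A, B, stat, group, p
    n_perm: int
    seed: int | None

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p"] < alpha]


def _indval_components(x: np.ndarray, labels: np.ndarray, groups: list):
    means = np.stack([x[labels == gr].mean(axis=0) for gr in groups])
    occur = np.stack([(x[labels == gr] > 0).mean(axis=0) for gr in groups])
    denom = means.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(denom > 0, means / denom, np.nan)
    stat = np.sqrt(a * occur)
    return a, occur, stat


def indicator_analysis(
    rel: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int | None = 0,
    permutations: str = "monte_carlo",
) -> IndicatorResult:
    """IndVal = sqrt(A * B) per taxon for a two-group design.

    A (specificity) is a group's share of the summed group mean abundances;
    B (fidelity) the occurrence fraction within the group.  Each taxon is
    associated with its arg-max group; p is a permutation test on the max
    statistic.  Taxa absent everywhere are excluded with a warning.
    """
    labels = groups.loc[rel.index].to_numpy()
    uniq = sorted(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    for gr in uniq:
        if (labels == gr).sum() < 2:
            raise ValueError(f"group {gr!r} has fewer than 2 samples")
    present = rel.columns[(rel > 0).any(axis=0)]
    dropped = set(rel.columns) - set(present)
    if dropped:
        logger.warning("%d taxa absent everywhere excluded", len(dropped))
    x = rel[present].to_numpy(float)
    a, b, stat = _indval_components(x, labels, uniq)
    best = stat.argmax(axis=0)
    cols = np.arange(x.shape[1])
    stat_obs = stat[best, cols]

    if permutations == "exhaustive":
        exceed = np.zeros(x.shape[1])
        total = 0
        for perm in itertools.permutations(range(len(labels))):
            _, _, s_p = _indval_components(x, labels[list(perm)], uniq)
            exceed += s_p.max(axis=0) >= stat_obs - 1e-12
            total += 1
        pvals = exceed / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(x.shape[1])
        for _ in range(n_perm):
            _, _, s_p = _indval_components(x, rng.permutation(labels), uniq)
            exceed += s_p.max(axis=0) >= stat_obs - 1e-12
        pvals = (1.0 + exceed) / (1.0 + n_perm)
        n_used = n_perm

    table = pd.DataFrame(
        {
            "A": a[best, cols],
            "B": b[best, cols],
            "stat": stat_obs,
            "group": [uniq[k] for k in best],
            "p": pvals,
        },
        index=pd.Index(present, name="taxon"),
    )
    return IndicatorResult(table, n_used, seed)


# ---------------------------------------------------------------------------
# Dyadic mixed model and band ANOVA


@dataclass
class GroupComparisonResult:
    """Group means +/- SE of dyadic distances with an overall test."""

    family: str
    means: pd.Series
    ses: pd.Series
    statistic: float
    statistic_name: str  # "chi2" (LRT) or "F"
    df: object  # int for LRT, (df1, df2) for ANOVA
    p: float
    pairwise: pd.DataFrame | None = None
    singular: bool = False
    notes: list = field(default_factory=list)


def _means_ses(df: pd.DataFrame, by: str) -> tuple:
    grp = df.groupby(by)["distance"]
    means = grp.mean()
    ses = grp.sem().fillna(0.0)
    return means, ses


def dyad_mixed_model(
    dyads, pairwise: bool = False, family_label: str | None = None
) -> GroupComparisonResult:
    """Gaussian LMM on dyadic distances with crossed random intercepts.

    distance ~ category + (1|focal) + (1|other) + (1|band), ML fit, where
    ``focal`` and ``other`` are the two individuals behind each dyad — both
    enter as variance components because every individual recurs across many
    dyads (a multi-membership structure; modelling only one member leaves
    the test anticonservative).  The category effect is tested by
    likelihood-ratio chi-square against the intercept-only model with the
    same random effects.  With ``pairwise`` (the three-category maternal
    family) Bonferroni-adjusted Wald z contrasts between all category pairs
    are added.  Singular fits are refit without the band random term and
    flagged.
    """
    import statsmodels.formula.api as smf

    data = dyads.pairs.copy()
    family = family_label or dyads.family
    cats = sorted(data["category"].unique())
    if len(cats) < 2:
        raise ValueError("need at least 2 categories")
    means, ses = _means_ses(data, "category")
    if np.isclose(data["distance"].var(ddof=0), 0.0):
        return GroupComparisonResult(
            family, means, ses, 0.0, "chi2", len(cats) - 1, 1.0,
            notes=["degenerate input: zero response variance"],
        )
    data["_one"] = 1
    if "other" not in data.columns:
        data["other"] = np.where(
            data["focal"] == data["id_a"], data["id_b"], data["id_a"]
        )
    vc = {"focal": "0 + C(focal)"}
    if not (data["other"] == data["focal"]).all() and data["other"].nunique() > 1:
        vc["other"] = "0 + C(other)"
    singular = False
    if data["band"].nunique() > 1:
        vc["band"] = "0 + C(band)"
    else:
        singular = True

    def fit(formula, vcf):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data, groups="_one", vc_formula=vcf)
            return model.fit(reml=False, method="lbfgs", maxiter=200)

    notes = []
    try:
        full = fit("distance ~ C(category)", vc)
        null = fit("distance ~ 1", vc)
    except (np.linalg.LinAlgError, ValueError):
        vc.pop("band", None)
        singular = True
        notes.append("band random term dropped (singular fit)")
        full = fit("distance ~ C(category)", vc)
        null = fit("distance ~ 1", vc)
    chi2 = max(0.0, 2.0 * (full.llf - null.llf))
    df = len(cats) - 1
    p = float(sps.chi2.sf(chi2, df))

    pw = None
    if pairwise:
        # Wald z contrasts between categories from the treatment-coded fit,
        # Bonferroni-adjusted over all category pairs
        params, cov = full.fe_params, full.cov_params()
        names = {c: f"C(category)[T.{c}]" for c in cats[1:]}
        n_pairs = len(cats) * (len(cats) - 1) // 2
        rows = []
        for c1, c2 in itertools.combinations(cats, 2):
            vec = pd.Series(0.0, index=params.index)
            if c1 in names:
                vec[names[c1]] -= 1.0
            if c2 in names:
                vec[names[c2]] += 1.0
            est = float(vec @ params)
            se = float(np.sqrt(vec @ cov.loc[params.index, params.index] @ vec))
            z = est / se if se > 0 else 0.0
            p_raw = 2 * sps.norm.sf(abs(z))
            rows.append(
                {"cat_a": c1, "cat_b": c2, "estimate": est, "z": z,
                 "p_adjusted": min(1.0, p_raw * n_pairs)}
            )
        pw = pd.DataFrame(rows)
    return GroupComparisonResult(
        family, means, ses, float(chi2), "chi2", df, p, pw, singular, notes
    )


def band_jsd_anova(band_dyads) -> GroupComparisonResult:
    """One-way ANOVA + Tukey HSD over within/between-band dyad groups."""
    data = band_dyads.pairs
    groups = sorted(data["group"].unique())
    samples = [data.loc[data["group"] == gr, "distance"].to_numpy() for gr in groups]
    small = [gr for gr, s in zip(groups, samples) if s.size < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 dyads: {small}")
    f, p = sps.f_oneway(*samples)
    tukey = sps.tukey_hsd(*samples)
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        rows.append(
            {"group_a": groups[i], "group_b": groups[j],
             "diff": samples[i].mean() - samples[j].mean(),
             "p_adjusted": float(tukey.pvalue[i, j])}
        )
    means, ses = _means_ses(data, "group")
    n_total = sum(s.size for s in samples)
    return GroupComparisonResult(
        band_dyads.family, means, ses, float(f), "F",
        (len(groups) - 1, n_total - len(groups)), float(p), pd.DataFrame(rows),
    )
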