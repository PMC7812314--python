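"""Differential statistics for the shotgun (LC-MS) side.

Implements the statistical chain applied to a MaxQuant-style peptide
evidence table from a two-condition experiment with few replicates:

* missing-value imputation by per-column down-shifted normal draws
  (missing low-abundance values are simulated below the detection limit);
* an empirical-Bayes moderated t-test: per-peptide sample variances are
  shrunk toward a pooled prior estimated by moment matching on the
  log-variances, giving the familiar posterior variance
  ``s2_post = (d0*s0^2 + d*s2) / (d0 + d)`` and a t statistic on
  ``d0 + d`` degrees of freedom;
* fold-change classification: ``log2FC = log2(mu_case / mu_control)`` of
  linear-scale group means; peptides with positive log2FC belong to the
  case condition, negative to the control, zero stay unclassified;
* the protein-level presence (unique peptide observed in >= m of n
  replicates) and enrichment (> 4-fold in >= m of n animals) filters;
* hypergeometric over-representation analysis with Benjamini-Hochberg
  adjustment, over user-supplied term sets.

Statistics are computed on log2 intensities; the fold-change means are
taken on the linear scale after back-transforming imputed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

P_FLOOR = 1e-300  # keeps the MLP ratio finite


# ---------------------------------------------------------------------------
# Peptide table container

@dataclass
class PeptideTable:
    """Peptide evidence with log2 intensities and observation flags.

    ``log2`` holds log2-transformed intensities with NaN marking missing
    values until imputation; ``observed`` records which cells were measured
    (imputation never changes it).  ``groups`` maps each condition name to
    its intensity column names.  ``stats`` collects per-peptide results
    (group means, log2fc, t_mod, p, group label) as they are computed.
    """

    meta: pd.DataFrame  # Sequence, Mass, Protein, Unique
    log2: pd.DataFrame
    observed: pd.DataFrame
    groups: dict[str, list[str]]
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def group_names(self) -> tuple[str, str]:
        names = list(self.groups)
        if len(names) != 2:
            raise ValueError(f"expected exactly two groups, got {names}")
        return names[0], names[1]

    def copy(self) -> "PeptideTable":
        return replace(
            self,
            meta=self.meta.copy(),
            log2=self.log2.copy(),
            observed=self.observed.copy(),
            stats=self.stats.copy(),
        )


def read_peptides_table(source, group_names: tuple[str, str] | None = None) -> PeptideTable:
    """Load a MaxQuant ``peptides.txt``-style TSV (or DataFrame).

    Intensity columns are those named ``Intensity <group>_<replicate>``;
    zeros are treated as missing (the MaxQuant convention).
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    int_cols = [c for c in df.columns if c.startswith("Intensity ")]
    if not int_cols:
        raise ValueError("no 'Intensity <group>_<rep>' columns found")
    groups: dict[str, list[str]] = {}
    for c in int_cols:
        name = c[len("Intensity "):]
        g = name.rsplit("_", 1)[0]
        groups.setdefault(g, []).append(c)
    if group_names is not None:
        missing = [g for g in group_names if g not in groups]
        if missing:
            raise ValueError(f"groups {missing} not present in table columns")
        groups = {g: groups[g] for g in group_names}
    meta = pd.DataFrame(
        {
            "Sequence": df["Sequence"],
            "Mass": df["Mass"].astype(float),
            "Protein": df.get("Leading razor protein", df.get("Proteins")),
            "Unique": df["Unique"].astype(str).str.lower().isin(["yes", "true", "1"])
            if "Unique" in df
            else True,
        }
    )
    linear = df[[c for cols in groups.values() for c in cols]].astype(float)
    observed = (linear > 0) & linear.notna()
    log2 = pd.DataFrame(
        np.where(observed, np.log2(linear.where(observed)), np.nan),
        columns=linear.columns,
        index=linear.index,
    )
    return PeptideTable(meta=meta, log2=log2, observed=observed, groups=groups)


# ---------------------------------------------------------------------------
# Imputation

class DownshiftImputer(TransformerMixin, BaseEstimator):
    """Impute missing log-intensities from a down-shifted normal distribution.

    For each column (sample), missing cells are drawn from
    ``Normal(mean - downshift * sd, (width * sd)^2)`` where mean and sd are
    computed over the column's observed values — the conventional proteomics
    model for values below the instrument's detection limit.

    Parameters follow the standard choice: ``downshift=1.8``, ``width=0.3``
    (in units of the column SD).
    """

    def __init__(self, downshift: float = 1.8, width: float = 0.3, random_state: int = 0):
        self.downshift = downshift
        self.width = width
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n_obs = (~np.isnan(X)).sum(axis=0)
        if np.any(n_obs < 3):
            bad = int(np.flatnonzero(n_obs < 3)[0])
            raise ValueError(f"column {bad} has fewer than 3 observed values")
        self.col_mean_ = np.nanmean(X, axis=0)
        self.col_sd_ = np.nanstd(X, axis=0, ddof=1)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float).copy()
        rng = np.random.default_rng(self.random_state)
        for j in range(X.shape[1]):
            miss = np.isnan(X[:, j])
            if miss.any():
                X[miss, j] = rng.normal(
                    self.col_mean_[j] - self.downshift * self.col_sd_[j],
                    self.width * self.col_sd_[j],
                    miss.sum(),
                )
        return X


def impute_missing(
    table: PeptideTable, downshift: float = 1.8, width: float = 0.3, seed: int = 0
) -> PeptideTable:
    """Fill missing log2 intensities; observed cells and flags are untouched.

    Raises a ValueError naming the offending column if any sample has fewer
    than 3 observed values.
    """
    out = table.copy()
    if not out.log2.isna().any().any():
        return out
    n_obs = out.observed.sum(axis=0)
    low = n_obs[n_obs < 3]
    if len(low):
        raise ValueError(f"column {low.index[0]!r} has only {int(low.iloc[0])} observed values")
    imp = DownshiftImputer(downshift=downshift, width=width, random_state=seed)
    filled = imp.fit_transform(out.log2.to_numpy())
    out.log2 = pd.DataFrame(filled, columns=out.log2.columns, index=out.log2.index)
    return out


# ---------------------------------------------------------------------------
# Moderated t-test

@dataclass
class ModeratedTestParams:
    prior_df: float  # d0; np.inf means complete shrinkage to the prior
    prior_var: float  # s0^2


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0."""
    if y <= 0:
        return np.inf
    return brentq(lambda x: special.polygamma(1, x) - y, 1e-9, 1e9, xtol=1e-12, rtol=1e-14)


def _estimate_prior(s2: np.ndarray, d: float) -> ModeratedTestParams:
    """Moment-match a scaled inverse-chi-square prior to observed variances.

    Uses the log-variance representation: if s2 ~ s0^2 * chi2_d / d scaled
    by the prior, then e = log(s2) - digamma(d/2) + log(d/2) has mean
    ``log(s0^2) + digamma(d0/2) - log(d0/2)`` and variance
    ``trigamma(d/2) + trigamma(d0/2)``; d0 is recovered by inverting the
    trigamma function.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return ModeratedTestParams(prior_df=np.inf, prior_var=float(np.mean(s2[ok])) if ok.any() else 1.0)
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    mean_e = float(np.mean(e))
    var_e = float(np.var(e, ddof=1))
    target = var_e - float(special.polygamma(1, d / 2.0))
    if target <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(mean_e))
    else:
        x = _trigamma_inverse(target)
        d0 = 2.0 * x
        s0_sq = float(np.exp(mean_e + special.digamma(x) - np.log(x)))
    return ModeratedTestParams(prior_df=d0, prior_var=s0_sq)


class ModeratedTTest(BaseEstimator):
    """Empirical-Bayes moderated two-sample t-test, scikit-learn style.

    ``fit(X, y)`` expects ``X`` of shape (n_samples, n_features) — samples
    in rows, peptides in columns, log2 scale — and ``y`` the two-level
    group label per sample.  Per feature, the pooled within-group variance
    ``s2`` (d = n1 + n2 - 2 df) is shrunk toward a prior ``s0^2`` with d0
    prior df estimated from all features, and

        t = (mean_2 - mean_1) / (s_post * sqrt(1/n1 + 1/n2)),
        p from a t distribution with d0 + d degrees of freedom.

    Setting ``prior_df=0`` disables shrinkage and reproduces the ordinary
    pooled-variance t-test exactly.

    Attributes (after fit): ``d0_``, ``s0_sq_``, ``t_``, ``p_``, ``df_``,
    ``mean_diff_``.
    """

    def __init__(self, prior_df: float | None = None):
        self.prior_df = prior_df

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        levels = pd.unique(y)
        if len(levels) != 2:
            raise ValueError(f"y must have exactly two levels, got {levels}")
        g1, g2 = X[y == levels[0]], X[y == levels[1]]
        n1, n2 = len(g1), len(g2)
        if n1 < 2 or n2 < 2:
            raise ValueError("both groups need >= 2 replicates")
        m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
        ss = ((g1 - m1) ** 2).sum(axis=0) + ((g2 - m2) ** 2).sum(axis=0)
        d = n1 + n2 - 2
        s2 = ss / d
        if self.prior_df is None:
            params = _estimate_prior(s2, d)
        elif self.prior_df == 0:
            params = ModeratedTestParams(prior_df=0.0, prior_var=0.0)
        else:
            params = ModeratedTestParams(
                prior_df=float(self.prior_df), prior_var=float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0
            )
        d0 = params.prior_df
        if np.isinf(d0):
            s2_post = np.full_like(s2, params.prior_var)
            df_total = np.inf
        else:
            s2_post = (d0 * params.prior_var + d * s2) / (d0 + d)
            df_total = d0 + d
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        diff = m2 - m1
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        self.levels_ = (levels[0], levels[1])
        self.n_ = (n1, n2)
        self.d0_ = d0
        self.s0_sq_ = params.prior_var
        self.s2_ = s2
        self.s2_post_ = s2_post
        self.df_ = df_total
        self.mean_diff_ = diff
        self.t_ = t
        self.p_ = np.clip(np.nan_to_num(p, nan=1.0), P_FLOOR, 1.0)
        return self


def moderated_ttest(
    table: PeptideTable, prior_df: float | None = None
) -> tuple[PeptideTable, ModeratedTestParams]:
    """Attach t_mod and p to the table; contrast is case minus control.

    Requires imputation to have been applied (or no missing values).
    """
    g0, g1 = table.group_names
    if table.log2.isna().any().any():
        raise ValueError("missing values present; impute before testing")
    cols = table.groups[g0] + table.groups[g1]
    X = table.log2[cols].to_numpy().T
    y = np.array([g0] * len(table.groups[g0]) + [g1] * len(table.groups[g1]))
    est = ModeratedTTest(prior_df=prior_df).fit(X, y)
    out = table.copy()
    out.stats = out.stats.reindex(out.meta.index)
    out.stats["t_mod"] = est.t_
    out.stats["p"] = est.p_
    out.stats["p_adj"] = multipletests(est.p_, method="fdr_bh")[1]
    return out, ModeratedTestParams(prior_df=est.d0_, prior_var=est.s0_sq_)


# ---------------------------------------------------------------------------
# Fold change and classification

def fold_change_classify(table: PeptideTable) -> PeptideTable:
    """Compute linear-scale group means, log2FC, and condition labels.

    ``log2FC = log2(mu_case / mu_control)``; peptides with log2FC > 0 are
    labelled with the case condition, < 0 with the control condition, and
    exactly 0 (or non-positive means) stay ``unclassified``.
    """
    g0, g1 = table.group_names  # (control, case)
    out = table.copy()
    linear = np.exp2(out.log2)
    mu0 = linear[out.groups[g0]].mean(axis=1)
    mu1 = linear[out.groups[g1]].mean(axis=1)
    valid = (mu0 > 0) & (mu1 > 0)
    log2fc = pd.Series(np.nan, index=out.meta.index)
    log2fc[valid] = np.log2(mu1[valid] / mu0[valid])
    label = pd.Series("unclassified", index=out.meta.index)
    label[log2fc > 0] = g1
    label[log2fc < 0] = g0
    out.stats = out.stats.reindex(out.meta.index)
    out.stats[f"mu_{g0}"] = mu0
    out.stats[f"mu_{g1}"] = mu1
    out.stats["log2fc"] = log2fc
    out.stats["group"] = label
    return out


# ---------------------------------------------------------------------------
# Protein-level filters

def validate_proteins(table: PeptideTable, min_replicates: int = 2) -> pd.DataFrame:
    """Presence calls: a protein is present in a condition iff >= 1 unique
    peptide has *observed* (not imputed) intensity in >= ``min_replicates``
    replicates of that condition.

    Returns a DataFrame indexed by protein with one boolean column per
    condition plus a ``status`` column ('shared', 'exclusive:<cond>', or
    'absent') — the Venn partition of the two proteomes.
    """
    uniq = table.meta["Unique"].to_numpy()
    calls = {}
    for g, cols in table.groups.items():
        n_obs = table.observed[cols].sum(axis=1).to_numpy()
        pep_ok = uniq & (n_obs >= min_replicates)
        calls[g] = pd.Series(pep_ok, index=table.meta["Protein"]).groupby(level=0).any()
    out = pd.DataFrame(calls)
    g0, g1 = table.group_names
    status = np.where(
        out[g0] & out[g1],
        "shared",
        np.where(out[g0], f"exclusive:{g0}", np.where(out[g1], f"exclusive:{g1}", "absent")),
    )
    out["status"] = status
    return out


def enriched_proteins(
    intensities: pd.DataFrame,
    groups: dict[str, list[str]],
    fold: float = 4.0,
    min_animals: int = 2,
    paired: bool = False,
    pvals: pd.Series | None = None,
    alpha: float | None = None,
) -> dict[str, pd.Index]:
    """Per-condition enrichment: ratio > ``fold`` in >= ``min_animals`` animals.

    ``intensities`` is a protein x sample table of linear intensities.  In
    the unpaired default each animal of one condition is compared with the
    *mean* of the other condition (the animals are distinct individuals);
    with ``paired=True`` animals are paired by replicate index.  If
    ``pvals``/``alpha`` are given the result is intersected with moderated
    test significance.  The inequality is strict: a ratio exactly equal to
    ``fold`` does not count.
    """
    names = list(groups)
    if len(names) != 2:
        raise ValueError("exactly two conditions required")
    out: dict[str, pd.Index] = {}
    eps = 1e-12
    for me, other in ((names[0], names[1]), (names[1], names[0])):
        mine = intensities[groups[me]].to_numpy(dtype=float)
        theirs = intensities[groups[other]].to_numpy(dtype=float)
        if paired:
            if mine.shape[1] != theirs.shape[1]:
                raise ValueError("paired mode requires equal replicate counts")
            ratios = mine / np.maximum(theirs, eps)
        else:
            ratios = mine / np.maximum(theirs.mean(axis=1, keepdims=True), eps)
        hit = (ratios > fold).sum(axis=1) >= min_animals
        idx = intensities.index[hit]
        if pvals is not None and alpha is not None:
            idx = idx.intersection(pvals.index[pvals < alpha])
        out[me] = idx
    return out


# ---------------------------------------------------------------------------
# Over-representation analysis

def ora_hypergeometric(
    selected: set[str], terms: dict[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per term.

    For a term with K members (within the universe of size N) and a
    selection of size n overlapping it in k genes,
    ``p = P(X >= k)`` with ``X ~ Hypergeom(N, K, n)``; Benjamini-Hochberg
    adjustment across terms.  Term member sets are intersected with the
    universe first.
    """
    universe = set(universe)
    selected = set(selected)
    if not universe:
        raise ValueError("empty universe")
    if not selected:
        raise ValueError("empty selection")
    if not selected <= universe:
        raise ValueError("selected set must be a subset of the universe")
    N, n = len(universe), len(selected)
    rows = []
    for term, members in terms.items():
        m = set(members) & universe
        K = len(m)
        k = len(m & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(term=term, k=k, K=K, n=n, N=N, p=min(max(p, P_FLOOR), 1.0)))
    res = pd.DataFrame(rows)
    if len(res):
        res["p_adj"] = multipletests(res["p"], method="fdr_bh")[1]
        res = res.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    return res


def protein_intensity_table(table: PeptideTable) -> pd.DataFrame:
    """Sum linear peptide intensities per protein and sample (simple rollup)."""
    linear = np.exp2(table.log2)
    linear = linear.where(table.observed, 0.0)
    linear.index = table.meta["Protein"]
    return linear.groupby(level=0).sum()
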