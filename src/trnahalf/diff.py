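"""Per-locus counting, CPM filtering, and NB-GLM differential abundance.

The model is the standard count-based one for small replicated designs:
per-locus counts y_gj ~ NB(mu_gj, phi_g) with log mu_gj = beta_{g,group(j)}
+ log(effective library size_j).  The common dispersion maximizes the
summed Cox-Reid adjusted profile likelihood (APL); per-locus (tagwise)
dispersions are shrunk toward the common value by weighted likelihood with
a prior-degrees-of-freedom weight.  Group contrasts are tested with the GLM
likelihood-ratio test: twice the log-likelihood gap between the full
three-group fit and a fit merging the contrasted groups, referred to
chi-square with 1 df.

Fold changes follow the signed-ratio convention used in the reporting
tables: the ratio of group means if >= 1, else minus its reciprocal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .simulate import GROUPS

_PHI_FLOOR = 1e-8


class CountError(ValueError):
    pass


@dataclass
class CountMatrix:
    counts: pd.DataFrame  # loci x samples, non-negative integers
    groups: pd.Series  # sample -> group label
    lib_sizes: pd.Series  # total mapped reads per sample
    norm_factors: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise CountError("negative counts")
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            raise CountError("every sample column needs a group label")
        self.lib_sizes = self.lib_sizes.reindex(self.counts.columns).astype(float)
        if (self.lib_sizes <= 0).any():
            raise CountError("library sizes must be positive")
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=self.counts.columns)

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.norm_factors

    def group_columns(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.groups.items():
            out.setdefault(g, []).append(s)
        return out


def count_loci(
    annotations_by_sample: dict[str, pd.DataFrame],
    groups: dict[str, str],
    classes: tuple[str, ...] = ("tRNA_5p",),
    lib_sizes: dict[str, int] | None = None,
) -> CountMatrix:
    """Per-locus read counts from best-one-reported annotations.

    Each read contributes to exactly one locus.  The default library size
    is the sample's total annotated (mapped) read count.
    """
    cols = {}
    libs = {}
    for sample, df in annotations_by_sample.items():
        if df["read_id"].duplicated().any():
            raise CountError(f"duplicate read ids in sample {sample}")
        sel = df[df["feature_class"].isin(classes)]
        cols[sample] = sel.groupby("locus_id").size()
        libs[sample] = len(df) if lib_sizes is None else lib_sizes[sample]
    counts = pd.DataFrame(cols).fillna(0).astype(int)
    counts = counts.sort_index()
    return CountMatrix(
        counts, pd.Series(groups), pd.Series(libs, dtype=float)
    )


# ---------------------------------------------------------------------------
# normalization and filtering


def tmm_norm_factors(
    cm: CountMatrix, logratio_trim: float = 0.3, abs_trim: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M normalization factors (geometric mean centered at 1).

    The reference is the sample with the median library size.
    """
    counts = cm.counts.astype(float)
    libs = cm.lib_sizes
    ref = (libs - libs.median()).abs().idxmin()
    yr = counts[ref].values
    nr = libs[ref]
    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        y = counts[s].values
        n = libs[s]
        ok = (y > 0) & (yr > 0)
        if ok.sum() < 3:
            factors[s] = 1.0
            continue
        p, pr = y[ok] / n, yr[ok] / nr
        m = np.log2(p / pr)
        a = 0.5 * np.log2(p * pr)
        w = 1.0 / ((n - y[ok]) / (n * y[ok]) + (nr - yr[ok]) / (nr * yr[ok]))
        k = len(m)
        lo_m, hi_m = np.floor(k * logratio_trim), np.ceil(k * (1 - logratio_trim))
        lo_a, hi_a = np.floor(k * abs_trim), np.ceil(k * (1 - abs_trim))
        rank_m = m.argsort().argsort()
        rank_a = a.argsort().argsort()
        keep = (rank_m >= lo_m) & (rank_m < hi_m) & (rank_a >= lo_a) & (rank_a < hi_a)
        if not keep.any():
            factors[s] = 1.0
            continue
        factors[s] = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    f = pd.Series(factors).reindex(counts.columns)
    return f / np.exp(np.log(f).mean())


def cpm(cm: CountMatrix, use_norm: bool = False) -> pd.DataFrame:
    """Counts per million of (optionally effective) library size."""
    libs = cm.effective_lib_sizes if use_norm else cm.lib_sizes
    if (libs == 0).any():
        raise CountError("zero library size")
    return cm.counts / libs * 1e6


def filter_low(
    cm: CountMatrix, min_cpm: float = 500.0, stat: str = "group_mean"
) -> CountMatrix:
    """Keep loci reaching ``min_cpm`` in at least one experimental group.

    ``stat`` chooses the within-group summary: the group-mean CPM (default)
    or the per-sample maximum.
    """
    x = cpm(cm)
    keep = pd.Series(False, index=cm.counts.index)
    for g, cols in cm.group_columns().items():
        val = x[cols].mean(axis=1) if stat == "group_mean" else x[cols].max(axis=1)
        keep |= val >= min_cpm
    return CountMatrix(
        cm.counts.loc[keep], cm.groups, cm.lib_sizes, cm.norm_factors
    )


# ---------------------------------------------------------------------------
# NB log-likelihood and vectorized one-way GLM fits


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row sums of NB log-likelihood; phi broadcastable to y's shape."""
    mu = np.maximum(mu, 1e-12)
    phi = np.maximum(phi, 0.0)
    pois = y * np.log(mu) - mu - gammaln(y + 1)
    if np.all(phi < _PHI_FLOOR):
        return pois.sum(axis=1)
    phi_s = np.maximum(phi, _PHI_FLOOR)
    r = 1.0 / phi_s
    nb = (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + y * np.log(phi_s * mu / (1 + phi_s * mu))
        - r * np.log1p(phi_s * mu)
    )
    ll = np.where(phi < _PHI_FLOOR, pois, nb)
    return ll.sum(axis=1)


def _fit_oneway(
    y: np.ndarray,
    offsets: np.ndarray,
    param_cols: list[np.ndarray],
    phi: np.ndarray | float,
    n_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Newton fit of per-group log-means with offsets.

    ``param_cols`` gives the column indices belonging to each coefficient.
    Returns (beta: loci x params, mu: loci x samples, converged: loci).
    """
    G, S = y.shape
    phi = np.broadcast_to(np.asarray(phi, dtype=float).reshape(-1, 1), (G, 1)).copy()
    beta = np.empty((G, len(param_cols)))
    mu = np.empty_like(y, dtype=float)
    converged = np.ones(G, dtype=bool)
    e_off = np.exp(offsets)
    for k, cols in enumerate(param_cols):
        yk = y[:, cols]
        ek = e_off[cols]
        tot = yk.sum(axis=1)
        b = np.where(tot > 0, np.log(np.maximum(tot, 0.5) / ek.sum()), -30.0)
        conv = np.zeros(G, dtype=bool)
        for _ in range(n_iter):
            m = np.exp(np.clip(b[:, None] + offsets[cols][None, :], -40, 40))
            denom = 1 + phi * m
            score = ((yk - m) / denom).sum(axis=1)
            info = (m * (1 + phi * yk) / denom**2).sum(axis=1)
            step = score / np.maximum(info, 1e-12)
            step = np.clip(step, -5, 5)
            b = np.clip(b + step, -30.0, 30.0)
            conv = np.abs(score) < tol * (1 + np.abs(yk).sum(axis=1))
            if conv.all():
                break
        converged &= conv | (tot == 0)
        beta[:, k] = b
        mu[:, cols] = np.exp(np.clip(b[:, None] + offsets[cols][None, :], -40, 40))
    return beta, mu, converged


def _apl(
    y: np.ndarray,
    offsets: np.ndarray,
    param_cols: list[np.ndarray],
    phi: float,
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per locus at a common phi."""
    _, mu, _ = _fit_oneway(y, offsets, param_cols, phi)
    ll = _nb_loglik(y, mu, np.full((y.shape[0], 1), phi))
    adj = np.zeros(y.shape[0])
    for cols in param_cols:
        info = (mu[:, cols] / (1 + phi * mu[:, cols])).sum(axis=1)
        adj += 0.5 * np.log(np.maximum(info, 1e-12))
    return ll - adj


def _quad_argmax(x: np.ndarray, f: np.ndarray) -> float:
    """Refine a grid argmax by quadratic interpolation in x (log-phi)."""
    i = int(np.argmax(f))
    if i == 0 or i == len(x) - 1:
        return x[i]
    d1 = (f[i + 1] - f[i - 1]) / 2
    d2 = f[i + 1] - 2 * f[i] + f[i - 1]
    if d2 >= 0:
        return x[i]
    return float(np.clip(x[i] - d1 / d2 * (x[i + 1] - x[i]), x[0], x[-1]))


@dataclass
class DispersionEstimate:
    common: float
    tagwise: pd.Series  # per locus


def estimate_dispersion(
    cm: CountMatrix,
    prior_df: float = 10.0,
    grid: np.ndarray | None = None,
) -> DispersionEstimate:
    """Common + tagwise NB dispersions by Cox-Reid APL maximization.

    The common value maximizes the APL summed over loci; tagwise values
    maximize each locus's APL plus ``prior_df / residual_df`` times the
    locus-averaged APL (weighted-likelihood shrinkage toward common).
    All-zero loci are excluded and inherit the common value.
    """
    param_cols = _param_cols(cm, None)
    S = cm.counts.shape[1]
    df_resid = S - len(param_cols)
    if df_resid <= 0:
        raise CountError(
            "no residual degrees of freedom (one sample per group); "
            "supply a fixed dispersion instead of estimating one"
        )
    nonzero = cm.counts.sum(axis=1) > 0
    y = cm.counts.loc[nonzero].values.astype(float)
    if y.shape[0] == 0:
        raise CountError("all loci have zero counts")
    offsets = np.log(cm.effective_lib_sizes.values)
    if grid is None:
        grid = np.logspace(-4, 1, 25)
    logg = np.log(grid)
    apl = np.column_stack([_apl(y, offsets, param_cols, p) for p in grid])
    common = float(np.exp(_quad_argmax(logg, apl.sum(axis=0))))
    prior_n = prior_df / df_resid
    score = apl + prior_n * apl.mean(axis=0)[None, :]
    tag = np.empty(y.shape[0])
    for i in range(y.shape[0]):
        tag[i] = np.exp(_quad_argmax(logg, score[i]))
    tagwise = pd.Series(common, index=cm.counts.index, dtype=float)
    tagwise.loc[nonzero] = tag
    return DispersionEstimate(common, tagwise)


# ---------------------------------------------------------------------------
# likelihood-ratio testing and fold-change conventions


def signed_fold_change(mean_ref: float, mean_alt: float) -> float:
    """Ratio of means reported as r if r >= 1 else -1/r (sign = direction)."""
    if mean_ref == 0 and mean_alt == 0:
        return float("nan")
    if mean_ref == 0:
        return float("inf")
    if mean_alt == 0:
        return float("-inf")
    r = mean_alt / mean_ref
    return r if r >= 1 else -1.0 / r


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaNs propagate)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _group_order(cm: CountMatrix) -> list[str]:
    """Design groups in canonical young/old/old-CR order where applicable."""
    present = list(dict.fromkeys(cm.groups))
    return [g for g in GROUPS if g in present] + [g for g in present if g not in GROUPS]


def _param_cols(cm: CountMatrix, merge: tuple[str, str] | None) -> list[np.ndarray]:
    """Column-index groups for the one-way design, optionally merging two
    groups (the reduced model of a contrast)."""
    cols = {g: [] for g in _group_order(cm)}
    for j, s in enumerate(cm.counts.columns):
        cols[cm.groups[s]].append(j)
    if merge is not None:
        a, b = merge
        cols[a] = cols[a] + cols.pop(b)
    return [np.asarray(v) for v in cols.values()]


DEFAULT_CONTRASTS = (
    ("age", "old_control", "young_control"),
    ("cr", "old_CR", "old_control"),
)


def fit_and_test(
    cm: CountMatrix,
    dispersion: DispersionEstimate | float,
    contrasts: tuple[tuple[str, str, str], ...] = DEFAULT_CONTRASTS,
) -> pd.DataFrame:
    """Per-locus NB GLM likelihood-ratio tests for the requested contrasts.

    Each contrast (name, alt, ref) compares the full per-group-mean model
    against a reduced model merging alt and ref (1 df).  The output carries
    raw group mean counts, the signed mean-ratio fold change, the signed
    model-based fold change (from fitted coefficients), LRT p-values, and
    BH q-values per contrast.
    """
    if isinstance(dispersion, DispersionEstimate):
        phi = dispersion.tagwise.reindex(cm.counts.index).values
    else:
        phi = np.full(cm.counts.shape[0], float(dispersion))
    y = cm.counts.values.astype(float)
    offsets = np.log(cm.effective_lib_sizes.values)
    group_names = _group_order(cm)
    full_cols = _param_cols(cm, None)
    beta_full, mu_full, conv_full = _fit_oneway(y, offsets, full_cols, phi)
    ll_full = _nb_loglik(y, mu_full, phi[:, None])

    out = pd.DataFrame(index=cm.counts.index)
    for g, cols in zip(group_names, full_cols):
        out[f"mean_{g}"] = y[:, cols].mean(axis=1)
    gidx = {g: i for i, g in enumerate(group_names)}

    for name, alt, ref in contrasts:
        for g in (alt, ref):
            if g not in gidx:
                raise CountError(f"contrast group {g!r} not in design")
        red_cols = _param_cols(cm, (alt, ref))
        _, mu_red, conv_red = _fit_oneway(y, offsets, red_cols, phi)
        ll_red = _nb_loglik(y, mu_red, phi[:, None])
        lrt = np.maximum(2.0 * (ll_full - ll_red), 0.0)
        p = chi2.sf(lrt, df=1)
        p[~(conv_full & conv_red)] = np.nan
        ratio_fc = np.array(
            [
                signed_fold_change(r, a)
                for r, a in zip(out[f"mean_{ref}"], out[f"mean_{alt}"])
            ]
        )
        log_model = beta_full[:, gidx[alt]] - beta_full[:, gidx[ref]]
        model_r = np.exp(log_model)
        model_fc = np.where(model_r >= 1, model_r, -1.0 / np.maximum(model_r, 1e-300))
        out[f"{name}_fc"] = ratio_fc
        out[f"{name}_model_fc"] = model_fc
        out[f"{name}_lrt"] = lrt
        out[f"{name}_p"] = p
    for name, _, _ in contrasts:
        out[f"{name}_q"] = bh_adjust(out[f"{name}_p"])
    out.index.name = "locus"
    return out.sort_values(f"{contrasts[0][0]}_p")


def write_diff_table(result: pd.DataFrame, path) -> None:
    result.round(6).to_csv(path, sep="\t", lineterminator="\n")
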