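"""Differential enrichment statistics on the rounded count matrix.

Implements, from the published formulas rather than by delegating to a
stats package: trimmed-mean-of-M-values (TMM) scaling with supplied
library sizes, log2 counts-per-million, a common negative-binomial
dispersion by Cox–Reid adjusted profile likelihood, per-feature NB
log-linear fits with group-means parameterization and likelihood-ratio
contrasts, and Storey q-values with fixed λ.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy
from scipy.stats import chi2, rankdata

__all__ = [
    "NormalizationResult",
    "ContrastResult",
    "tmm_factors",
    "log2_cpm",
    "group_mean_log2_cpm",
    "estimate_dispersion",
    "fit_and_test",
    "qvalues",
    "run_contrasts",
    "plot_enrichment_scatter",
]

TMM_LOGRATIO_TRIM = 0.30
TMM_ABUNDANCE_TRIM = 0.05
DEFAULT_PRIOR_COUNT = 0.5
STOREY_LAMBDA = 0.5
NEWTON_TOL = 1e-8
NEWTON_MAX_ITER = 100
_NEG_INF_BETA = -745.0  # exp() underflows to 0 below this


@dataclass
class NormalizationResult:
    """Per-sample TMM scaling factors (geometric mean 1) and effective
    library sizes (library size × factor)."""

    samples: list[str]
    factors: np.ndarray
    library_sizes: np.ndarray

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.library_sizes * self.factors

    def factor_of(self, sample: str) -> float:
        return float(self.factors[self.samples.index(sample)])


@dataclass
class ContrastResult:
    """One subfamily's result for one pairwise group contrast."""

    subfamily: str
    contrast: str
    log2_fold_change: float
    group_mean_cpm: dict[str, float]
    p_value: float
    q_value: float
    converged: bool


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    abundance_trim: float,
) -> float:
    """log2 TMM factor of `obs` against `ref` (the published recipe)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
    keep = np.isfinite(m) & np.isfinite(a)
    m, a = m[keep], a[keep]
    obs_k, ref_k = obs[keep], ref[keep]
    n = m.size
    if n == 0:
        return 0.0
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not sel.any():
        return 0.0
    # inverse asymptotic (binomial) variance of M as precision weight
    var = (
        (lib_obs - obs_k[sel]) / (lib_obs * obs_k[sel])
        + (lib_ref - ref_k[sel]) / (lib_ref * ref_k[sel])
    )
    w = 1.0 / var
    f = float(np.sum(w * m[sel]) / np.sum(w))
    return 0.0 if not np.isfinite(f) else f


def tmm_factors(
    counts: pd.DataFrame,
    library_sizes: Mapping[str, int] | Sequence[int],
    logratio_trim: float = TMM_LOGRATIO_TRIM,
    abundance_trim: float = TMM_ABUNDANCE_TRIM,
) -> NormalizationResult:
    """TMM scaling factors for a feature × sample count table.

    The reference sample is the one whose upper-quartile count
    proportion is closest to the mean upper quartile.  Per sample, M and
    A statistics over features nonzero in both sample and reference are
    double-trimmed (30% on M, 5% on A, two-sided) and the factor is
    2^(precision-weighted mean M), with precision the inverse asymptotic
    binomial variance.  Factors are centered to geometric mean 1.
    """
    samples = list(counts.columns)
    if len(samples) < 2:
        raise ValueError("TMM needs ≥2 samples")
    if isinstance(library_sizes, Mapping):
        libs = np.array([float(library_sizes[s]) for s in samples])
    else:
        libs = np.asarray(library_sizes, dtype=float)
    mat = counts.to_numpy(dtype=float)
    zero = np.flatnonzero(mat.sum(axis=0) == 0)
    if zero.size:
        raise ValueError(
            f"sample(s) with all-zero counts: {[samples[i] for i in zero]}"
        )
    if np.any(libs <= 0):
        bad = [samples[i] for i in np.flatnonzero(libs <= 0)]
        raise ValueError(f"sample(s) with nonpositive library size: {bad}")
    uq = np.array(
        [np.quantile(mat[:, j], 0.75) / libs[j] for j in range(len(samples))]
    )
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    log_f = np.array(
        [
            _tmm_pair(
                mat[:, j], mat[:, ref_idx], libs[j], libs[ref_idx],
                logratio_trim, abundance_trim,
            )
            for j in range(len(samples))
        ]
    )
    factors = 2.0 ** log_f
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationResult(samples, factors, libs)


# ---------------------------------------------------------------------------
# CPM
# ---------------------------------------------------------------------------

def log2_cpm(
    counts: pd.DataFrame,
    effective_library_sizes: Mapping[str, float] | Sequence[float],
    prior_count: float = DEFAULT_PRIOR_COUNT,
) -> pd.DataFrame:
    """log2((count + prior) / (effective library size + 2·prior) × 1e6)."""
    samples = list(counts.columns)
    if isinstance(effective_library_sizes, Mapping):
        libs = np.array([float(effective_library_sizes[s]) for s in samples])
    else:
        libs = np.asarray(effective_library_sizes, dtype=float)
    if np.any(libs <= 0):
        raise ValueError("effective library sizes must be positive")
    mat = counts.to_numpy(dtype=float)
    vals = np.log2((mat + prior_count) / (libs + 2 * prior_count) * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=samples)


def group_mean_log2_cpm(
    cpm: pd.DataFrame, design: Mapping[str, str]
) -> pd.DataFrame:
    """Arithmetic mean of per-sample log2 CPM within each design group."""
    groups: dict[str, list[str]] = {}
    for sample in cpm.columns:
        try:
            groups.setdefault(design[sample], []).append(sample)
        except KeyError:
            raise ValueError(f"sample {sample!r} missing from design") from None
    return pd.DataFrame(
        {g: cpm[cols].mean(axis=1) for g, cols in sorted(groups.items())}
    )


# ---------------------------------------------------------------------------
# NB GLM machinery (group-means parameterization, log link, offsets)
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Elementwise NB (or Poisson when dispersion=0) log-likelihood."""
    mu = np.maximum(mu, 1e-300)
    if dispersion <= 0:
        return xlogy(y, mu) - mu - gammaln(y + 1)
    r = 1.0 / dispersion
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + xlogy(y, mu / (r + mu))
    )


def _fit_nb_mean(
    y: np.ndarray, log_offsets: np.ndarray, dispersion: float
) -> tuple[np.ndarray, np.ndarray]:
    """MLE intercept per row of ``y`` (rows = features, cols = samples of
    one group), with fixed per-sample offsets and dispersion.

    Returns (beta, converged).  Newton iteration on the score
    Σ (y−μ)/(1+φμ) = 0; for φ=0 the Poisson solution is closed-form.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    e = np.exp(log_offsets)
    rowsum = y.sum(axis=1)
    with np.errstate(divide="ignore"):
        beta = np.log(rowsum / e.sum())
    beta = np.where(rowsum > 0, beta, _NEG_INF_BETA)
    converged = np.ones(y.shape[0], dtype=bool)
    if dispersion <= 0:
        return beta, converged
    active = rowsum > 0
    for _ in range(NEWTON_MAX_ITER):
        if not active.any():
            break
        b = beta[active]
        mu = np.exp(b[:, None] + log_offsets[None, :])
        denom = 1.0 + dispersion * mu
        score = ((y[active] - mu) / denom).sum(axis=1)
        info = (mu * (1.0 + dispersion * y[active]) / denom**2).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -10.0, 10.0)
        beta[active] = b + step
        done = np.abs(step) < NEWTON_TOL
        idx = np.flatnonzero(active)
        active[idx[done]] = False
    converged[np.flatnonzero(active)] = False
    return beta, converged


def _group_indices(
    samples: Sequence[str], design: Mapping[str, str]
) -> dict[str, np.ndarray]:
    groups: dict[str, list[int]] = {}
    for j, s in enumerate(samples):
        if s not in design:
            raise ValueError(f"sample {s!r} missing from design")
        groups.setdefault(design[s], []).append(j)
    return {g: np.array(idx) for g, idx in groups.items()}


def estimate_dispersion(
    counts: pd.DataFrame,
    design: Mapping[str, str],
    effective_library_sizes: Mapping[str, float] | Sequence[float],
    grid: tuple[float, float, int] = (1e-4, 4.0, 15),
) -> float:
    """Common NB dispersion by Cox–Reid adjusted profile likelihood.

    Maximizes Σ_features [ loglik(β̂; φ) − ½ log det(Xᵀ W X) ] over a
    log-spaced grid with golden-section refinement; the group-means
    design makes the Cox–Reid term ½ Σ_groups log Σ_j μ_j/(1+φμ_j).
    Returns 0 when the optimum sits at the Poisson boundary.
    """
    samples = list(counts.columns)
    groups = _group_indices(samples, design)
    if all(idx.size < 2 for idx in groups.values()):
        raise ValueError("no group has ≥2 replicates; dispersion inestimable")
    if isinstance(effective_library_sizes, Mapping):
        libs = np.array([float(effective_library_sizes[s]) for s in samples])
    else:
        libs = np.asarray(effective_library_sizes, dtype=float)
    log_off = np.log(libs)
    y = counts.to_numpy(dtype=float)

    def apl(phi: float) -> float:
        total = 0.0
        for idx in groups.values():
            yg = y[:, idx]
            beta, _ = _fit_nb_mean(yg, log_off[idx], phi)
            mu = np.exp(beta[:, None] + log_off[idx][None, :])
            ll = _nb_loglik(yg, mu, phi).sum()
            w = mu / (1.0 + phi * mu)
            cr = 0.5 * np.log(np.maximum(w.sum(axis=1), 1e-300)).sum()
            total += ll - cr
        return total

    lo, hi, n = grid
    phis = np.geomspace(lo, hi, n)
    vals = np.array([apl(p) for p in phis])
    best = int(np.argmax(vals))
    if best == 0:
        return 0.0
    # golden-section refinement on log φ in the bracket around the best point
    a = np.log(phis[max(best - 1, 0)])
    b = np.log(phis[min(best + 1, n - 1)])
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = apl(np.exp(c)), apl(np.exp(d))
    for _ in range(40):
        if b - a < 1e-4:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = apl(np.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = apl(np.exp(d))
    return float(np.exp((a + b) / 2.0))


def fit_and_test(
    counts: pd.DataFrame,
    design: Mapping[str, str],
    dispersion: float,
    contrast: tuple[str, str],
    effective_library_sizes: Mapping[str, float] | Sequence[float],
) -> pd.DataFrame:
    """Per-feature NB log-linear fit and likelihood-ratio contrast test.

    Fits group-mean coefficients with log effective library sizes as
    offsets; tests H0: β_a = β_b by LRT against the merged-group fit,
    p from χ²(1).  Returns a frame with log2_fold_change, p_value and a
    converged flag (non-converged rows get p = NaN).
    """
    group_a, group_b = contrast
    samples = list(counts.columns)
    groups = _group_indices(samples, design)
    for g in contrast:
        if g not in groups:
            raise ValueError(f"contrast group {g!r} absent from design")
    if isinstance(effective_library_sizes, Mapping):
        libs = np.array([float(effective_library_sizes[s]) for s in samples])
    else:
        libs = np.asarray(effective_library_sizes, dtype=float)
    log_off = np.log(libs)
    y = counts.to_numpy(dtype=float)

    idx_a, idx_b = groups[group_a], groups[group_b]
    beta_a, conv_a = _fit_nb_mean(y[:, idx_a], log_off[idx_a], dispersion)
    beta_b, conv_b = _fit_nb_mean(y[:, idx_b], log_off[idx_b], dispersion)
    idx_ab = np.concatenate([idx_a, idx_b])
    beta_ab, conv_ab = _fit_nb_mean(y[:, idx_ab], log_off[idx_ab], dispersion)

    mu_a = np.exp(beta_a[:, None] + log_off[idx_a][None, :])
    mu_b = np.exp(beta_b[:, None] + log_off[idx_b][None, :])
    mu_ab = np.exp(beta_ab[:, None] + log_off[idx_ab][None, :])
    ll_full = (
        _nb_loglik(y[:, idx_a], mu_a, dispersion).sum(axis=1)
        + _nb_loglik(y[:, idx_b], mu_b, dispersion).sum(axis=1)
    )
    ll_null = _nb_loglik(y[:, idx_ab], mu_ab, dispersion).sum(axis=1)
    stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    converged = conv_a & conv_b & conv_ab
    p = np.where(converged, chi2.sf(stat, df=1), np.nan)
    log2fc = (beta_a - beta_b) / np.log(2.0)
    return pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "lrt_statistic": stat,
            "p_value": p,
            "converged": converged,
        },
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def qvalues(p: Sequence[float], lam: float = STOREY_LAMBDA) -> np.ndarray:
    """Storey q-values with a fixed λ (NaN p-values stay NaN).

    π₀ = min(1, #{p > λ} / (m(1−λ)));
    q(i) = min_{j ≥ i} π₀·m·p(j)/j for p sorted ascending.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values outside [0, 1]")
    pi0 = min(1.0, np.sum(pv > lam) / (m * (1.0 - lam)))
    order = np.argsort(pv, kind="stable")
    ranks = np.arange(1, m + 1)
    raw = pi0 * m * pv[order] / ranks
    qs = np.minimum.accumulate(raw[::-1])[::-1]
    qs = np.minimum(qs, 1.0)
    out = np.empty(m)
    out[order] = qs
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# Orchestration helpers
# ---------------------------------------------------------------------------

def run_contrasts(
    counts: pd.DataFrame,
    library_sizes: Mapping[str, int],
    design: Mapping[str, str],
    contrasts: Sequence[tuple[str, str]],
    prior_count: float = DEFAULT_PRIOR_COUNT,
    lam: float = STOREY_LAMBDA,
    dispersion: float | None = None,
) -> dict[str, pd.DataFrame]:
    """TMM → CPM → dispersion → per-contrast NB LRT → q-values.

    Returns one result frame per contrast, keyed "A_vs_B", with log2FC,
    per-group mean log2 CPM, p, q, and the convergence flag.
    """
    norm = tmm_factors(counts, library_sizes)
    eff = dict(zip(norm.samples, norm.effective_library_sizes))
    cpm = log2_cpm(counts, eff, prior_count)
    group_cpm = group_mean_log2_cpm(cpm, design)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, design, eff)
    results: dict[str, pd.DataFrame] = {}
    for group_a, group_b in contrasts:
        res = fit_and_test(counts, design, dispersion, (group_a, group_b), eff)
        res["q_value"] = qvalues(res["p_value"].to_numpy(), lam)
        res.insert(0, f"mean_log2_cpm_{group_b}", group_cpm[group_b])
        res.insert(0, f"mean_log2_cpm_{group_a}", group_cpm[group_a])
        res.attrs["dispersion"] = dispersion
        results[f"{group_a}_vs_{group_b}"] = res
    return results


def plot_enrichment_scatter(
    group_cpm_x: pd.Series,
    group_cpm_y: pd.Series,
    q: Sequence[float],
    path: str | Path,
    label_x: str = "group X mean log2 CPM",
    label_y: str = "group Y mean log2 CPM",
    fdr_bins: Sequence[float] = (0.05, 0.01, 0.001),
) -> None:
    """Scatter of per-subfamily group-mean log2 CPM, point size by FDR bin
    (smaller q → larger point), with the identity diagonal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    q = np.asarray(q, dtype=float)
    edges = sorted(fdr_bins, reverse=True)  # e.g. 0.05, 0.01, 0.001
    sizes = np.full(q.shape, 12.0)
    for i, edge in enumerate(edges):
        sizes[q < edge] = 12.0 + 18.0 * (i + 1)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(group_cpm_x, group_cpm_y, s=sizes, alpha=0.7, edgecolor="none")
    lims = [
        min(group_cpm_x.min(), group_cpm_y.min()) - 0.5,
        max(group_cpm_x.max(), group_cpm_y.max()) + 0.5,
    ]
    ax.plot(lims, lims, lw=0.8, color="grey")
    ax.set_xlim(lims)
    ax.set_ylim(lims)
    ax.set_xlabel(label_x)
    ax.set_ylabel(label_y)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
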