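"""Per-feature linear models for differential enrichment and expression.

Two designs are supported, both fitted per feature (gene or window) on
log2-cpm values with optional mean–variance precision weights and
empirical-Bayes variance moderation:

* **condition model** ``Y = clones + clones:condition`` — the reported
  effect is the mean over clones of the DOX-vs-noDOX coefficient (an
  ordinary log fold change);
* **induction model** ``Y ~ 0 + clones + clones:induction`` — each clone
  gets an intercept and a slope on the per-sample fraction of induced
  cells. The reported effect is the mean of the per-clone slopes: the
  log fold change that *would* be observed if 100 % of cells were induced
  (the induction-corrected logFC). In a cell mixture where a fraction f of
  cells multiplies expression by 2**beta, the bulk signal ratio is
  ``f*2**beta + (1-f)``, so an uncorrected logFC underestimates |beta|
  whenever f < 1; the regression on f removes the first-order part of
  that attenuation and equals beta exactly at f = 1.

The surface follows the statsmodels convention: :class:`DifferentialModel`
is built from a count matrix plus sample metadata, and ``fit()`` returns a
:class:`DifferentialResults` carrying the per-feature estimates, moderated
statistics, BH q-values and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .chipquant import CountMatrix, SampleInfo

__all__ = [
    "DifferentialModel",
    "DifferentialResults",
    "log2_cpm",
    "build_design",
    "voom_weights",
    "fit_weighted_linear_model",
    "estimate_moderation",
    "moderate_and_test",
    "benjamini_hochberg",
    "tpm_from_counts",
    "filter_expressed_genes",
    "cluster_samples",
    "mixture_log2_ratio",
]


def mixture_log2_ratio(f: float | np.ndarray, beta: float | np.ndarray) -> np.ndarray:
    """log2 of the bulk DOX/noDOX ratio when a fraction f of cells applies 2**beta."""
    f = np.asarray(f, dtype=float)
    return np.log2(f * 2.0 ** np.asarray(beta, dtype=float) + (1.0 - f))


def log2_cpm(
    counts: np.ndarray | CountMatrix,
    library_sizes: Sequence[float] | None = None,
    factors: Sequence[float] | None = None,
) -> np.ndarray:
    """log2 counts per million with the canonical (+0.5, +1) offsets.

    value = log2((count + 0.5) / (library_size*factor + 1) * 1e6).
    """
    if isinstance(counts, CountMatrix):
        if library_sizes is None:
            library_sizes = counts.library_sizes
        counts = counts.counts
    counts = np.asarray(counts, dtype=float)
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    lib = np.asarray(library_sizes, dtype=float)
    if factors is not None:
        lib = lib * np.asarray(factors, dtype=float)
    if (lib <= 0).any():
        raise ValueError("effective library sizes must be positive")
    return np.log2((counts + 0.5) / (lib + 1.0) * 1e6)


def build_design(
    samples: Sequence[SampleInfo], model: str
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Design matrix and effect contrast for one of the two models.

    Returns (X, column_names, contrast). ``model`` is "condition" or
    "induction". Clones are taken from the sample metadata; the contrast
    averages the per-clone condition (or induction-slope) coefficients.
    """
    clones = sorted({s.clone for s in samples})
    n = len(samples)
    if model == "condition":
        # intercept + clone offsets + per-clone DOX indicator
        cols = ["intercept"] + [f"clone[{c}]" for c in clones[1:]]
        cols += [f"clone[{c}]:DOX" for c in clones]
        X = np.zeros((n, len(cols)))
        X[:, 0] = 1.0
        for i, s in enumerate(samples):
            ci = clones.index(s.clone)
            if ci > 0:
                X[i, ci] = 1.0
            if s.condition == "DOX":
                X[i, len(clones) + clones.index(s.clone)] = 1.0
        contrast = np.zeros(len(cols))
        contrast[len(clones):] = 1.0 / len(clones)
    elif model == "induction":
        cols = [f"clone[{c}]" for c in clones]
        cols += [f"clone[{c}]:induction" for c in clones]
        X = np.zeros((n, len(cols)))
        for i, s in enumerate(samples):
            ci = clones.index(s.clone)
            X[i, ci] = 1.0
            X[i, len(clones) + ci] = s.induction_fraction
        contrast = np.zeros(len(cols))
        contrast[len(clones):] = 1.0 / len(clones)
    else:
        raise ValueError(f"unknown model {model!r}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix rank-deficient (rank {rank} < {X.shape[1]} columns); "
            "check that every clone has both conditions"
        )
    return X, cols, contrast


def fit_weighted_linear_model(
    y: np.ndarray,
    design: np.ndarray,
    weights: np.ndarray | None = None,
    contrast: np.ndarray | None = None,
) -> pd.DataFrame:
    """Weighted least squares per feature.

    ``y`` is features x samples; ``weights`` (same shape) are precision
    weights. Returns a DataFrame with the contrast effect, its unscaled
    standard error factor, residual variance s2 and residual df. With
    residual df = 0 (saturated design) the coefficients are exact
    interpolants and s2 is NaN.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n_feat, n_samp = y.shape
    p = design.shape[1]
    if design.shape[0] != n_samp:
        raise ValueError("design rows must match number of samples")
    if weights is None:
        weights = np.ones_like(y)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != y.shape:
        raise ValueError("weights shape must match y")
    if (weights <= 0).any() or not np.isfinite(weights).all():
        raise ValueError("weights must be positive and finite")
    if contrast is None:
        contrast = np.zeros(p)
        contrast[-1] = 1.0
    df_resid = n_samp - p

    effect = np.empty(n_feat)
    se_unscaled = np.empty(n_feat)
    s2 = np.full(n_feat, np.nan)
    fitted = np.empty_like(y)
    coefs = np.empty((n_feat, p))
    for i in range(n_feat):
        w = weights[i]
        Xw = design * np.sqrt(w)[:, None]
        yw = y[i] * np.sqrt(w)
        xtx = Xw.T @ Xw
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError as exc:
            raise ValueError("design matrix singular under the given weights") from exc
        beta = xtx_inv @ (Xw.T @ yw)
        coefs[i] = beta
        fitted[i] = design @ beta
        effect[i] = contrast @ beta
        se_unscaled[i] = np.sqrt(contrast @ xtx_inv @ contrast)
        if df_resid > 0:
            resid = y[i] - fitted[i]
            s2[i] = np.sum(w * resid**2) / df_resid

    out = pd.DataFrame(
        {
            "effect": effect,
            "se_unscaled": se_unscaled,
            "s2": s2,
            "df_resid": float(df_resid),
        }
    )
    out.attrs["fitted"] = fitted
    out.attrs["coefficients"] = coefs
    return out


def voom_weights(
    log2cpm: np.ndarray,
    design: np.ndarray,
    lowess_frac: float = 0.5,
    min_features: int = 10,
) -> np.ndarray:
    """Mean-variance precision weights for count-derived log2-cpm values.

    An unweighted fit per feature gives residual SDs; a lowess trend of
    sqrt(SD) against the feature's mean log2-count is interpolated at every
    observation's fitted value, and the weight is trend**-4, clipped to
    [1e-6, 1e6]. With too few features for trend estimation, unit weights
    are returned with a warning.
    """
    log2cpm = np.atleast_2d(np.asarray(log2cpm, dtype=float))
    n_feat = log2cpm.shape[0]
    if n_feat < min_features:
        warnings.warn(
            f"only {n_feat} features; falling back to unit precision weights",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.ones_like(log2cpm)
    base = fit_weighted_linear_model(log2cpm, design)
    fitted = base.attrs["fitted"]
    if base["df_resid"].iloc[0] < 1:
        warnings.warn(
            "saturated design: residual SD unavailable, using unit weights",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.ones_like(log2cpm)
    sx = log2cpm.mean(axis=1)
    sy = np.sqrt(np.sqrt(base["s2"].to_numpy()))  # sqrt of residual SD
    from statsmodels.nonparametric.smoothers_lowess import lowess

    smoothed = lowess(sy, sx, frac=lowess_frac, return_sorted=True)
    xs, ys = smoothed[:, 0], smoothed[:, 1]
    trend = np.interp(np.clip(fitted, xs[0], xs[-1]), xs, ys)
    weights = np.clip(trend, 1e-12, None) ** -4
    return np.clip(weights, 1e-6, 1e6)


def estimate_moderation(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior on residual variances.

    Returns (d0, s0_2): prior df and prior variance. Works on z = log(s2):
    E[z] and Var[z] under the hierarchical model are expressed via digamma /
    trigamma; the excess of Var[z] over trigamma(df/2) is inverted through
    the trigamma function to get d0. Non-positive excess means the
    variances are less dispersed than chi-square sampling alone allows:
    d0 = inf (complete shrinkage to the common value).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        return 0.0, float(np.median(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df_resid / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_2


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / max(x, 1e-12) < tol:
            break
    return float(x)


def moderate_and_test(
    fits: pd.DataFrame,
    d0: float | None = None,
    s0_2: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-tests with BH correction.

    Posterior variance = (d0*s0_2 + df*s2)/(d0 + df); the moderated t uses
    the posterior SD in place of s and has d0 + df degrees of freedom.
    d0 = 0 leaves the per-feature variances untouched; d0 = inf replaces
    them all with s0_2. If (d0, s0_2) are not supplied they are estimated
    from the fitted variances by :func:`estimate_moderation`.
    """
    df_resid = float(fits["df_resid"].iloc[0])
    if df_resid < 1:
        raise ValueError("moderated testing requires residual df >= 1")
    if d0 is None or s0_2 is None:
        d0_est, s0_2_est = estimate_moderation(fits["s2"].to_numpy(), df_resid)
        d0 = d0_est if d0 is None else d0
        s0_2 = s0_2_est if s0_2 is None else s0_2
    s2 = fits["s2"].to_numpy()
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = fits["se_unscaled"].to_numpy() * np.sqrt(s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits["effect"].to_numpy() / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = fits.copy()
    out["s2_post"] = s2_post
    out["se"] = se
    out["t"] = t
    out["p"] = p
    out["q"] = benjamini_hochberg(p)
    out.attrs["d0"] = float(d0)
    out.attrs["s0_2"] = float(s0_2)
    return out


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def tpm_from_counts(
    counts: np.ndarray | CountMatrix, exonic_lengths_bp: Sequence[float]
) -> np.ndarray:
    """Transcripts per million from exon-length-summed gene counts."""
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    counts = np.asarray(counts, dtype=float)
    lens = np.asarray(exonic_lengths_bp, dtype=float)
    if (lens <= 0).any():
        raise ValueError("exonic lengths must be positive")
    rate = counts / (lens[:, None] / 1000.0)
    denom = rate.sum(axis=0)
    denom[denom == 0] = 1.0
    return rate / denom * 1e6


def filter_expressed_genes(
    tpm: pd.DataFrame, min_tpm: float = 1.0, min_samples: int = 6
) -> list:
    """Genes with TPM strictly above ``min_tpm`` in at least ``min_samples``."""
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    ok = (tpm > min_tpm).sum(axis=1) >= min_samples
    return list(tpm.index[ok])


def cluster_samples(expr: pd.DataFrame) -> dict:
    """Hierarchical sample clustering with Ward linkage on 1 − Pearson r.

    Implements the classic Ward update (Lance–Williams on the distances as
    given, the "Ward.D" flavour) with deterministic tie-breaking by sample
    order. Returns a dict with a scipy-style linkage matrix ``Z``, the
    sample order, and a ``labels(k)`` callable for flat cluster labels.
    """
    x = expr.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least two samples")
    sds = x.std(axis=0)
    flat = [expr.columns[j] for j in range(x.shape[1]) if sds[j] == 0]
    if flat:
        raise ValueError(f"constant expression profile for sample(s): {flat}")
    corr = np.corrcoef(x.T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]

    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                key = (min(i, j), max(i, j))
                val = dist[key]
                if best is None or val < best[0] - 1e-15:
                    best = (val, i, j)
        val, i, j = best
        Z[step] = [i, j, val, sizes[i] + sizes[j]]
        # Ward (Lance-Williams) update on the given distances
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dij = dist[(min(i, j), max(i, j))]
            ni, nj, nk = sizes[i], sizes[j], sizes[k]
            dist[(min(new, k), max(new, k))] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * dij
            ) / (ni + nj + nk)
        sizes[new] = sizes[i] + sizes[j]
        active = [k for k in active if k not in (i, j)] + [new]
    # heights may be non-monotone in pathological ties; clip for dendrogram use
    result = {
        "Z": Z,
        "samples": list(expr.columns),
    }

    def labels(k: int) -> np.ndarray:
        from scipy.cluster.hierarchy import fcluster

        Zm = Z.copy()
        for r in range(1, len(Zm)):
            Zm[r, 2] = max(Zm[r, 2], Zm[r - 1, 2])
        return fcluster(Zm, t=k, criterion="maxclust")

    result["labels"] = labels
    return result


@dataclass
class DifferentialResults:
    """Fit results for a per-feature differential model.

    ``table`` holds one row per feature: effect (logFC or corrected logFC),
    se, s2, df_resid, moderated t, p and BH q. ``params`` carries the
    moderation hyperparameters actually used.
    """

    table: pd.DataFrame
    model: str
    design_columns: list[str]
    contrast: np.ndarray
    d0: float | None = None
    s0_2: float | None = None

    @property
    def effect(self) -> pd.Series:
        return self.table["effect"]

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        if "q" not in self.table:
            raise ValueError("no moderated tests available (saturated design?)")
        return self.table[self.table["q"] < alpha]

    def summary(self, top: int = 10) -> str:
        lines = [
            "Differential model results",
            "==========================",
            f"model:      {self.model}",
            f"features:   {len(self.table)}",
            f"design:     {', '.join(self.design_columns)}",
        ]
        if self.d0 is not None:
            lines.append(f"prior df:   {self.d0:.4g}  prior var: {self.s0_2:.4g}")
        if "q" in self.table:
            nsig = int((self.table["q"] < 0.05).sum())
            lines.append(f"q<0.05:     {nsig}")
        lines.append("")
        cols = [c for c in ("effect", "se", "t", "p", "q") if c in self.table]
        head = self.table.sort_values("p" if "p" in self.table else "effect")
        lines.append(head[cols].head(top).to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


class DifferentialModel:
    """Per-feature condition or induction model on log2-cpm values.

    Parameters
    ----------
    counts
        CountMatrix of features x samples.
    samples
        SampleInfo per column, in column order.
    model
        "condition" (plain DOX-vs-noDOX logFC) or "induction"
        (induction-fraction-corrected logFC).
    factors
        Optional TMM normalization factors (per sample).
    use_voom
        Estimate mean-variance precision weights before the WLS fit.
    """

    def __init__(
        self,
        counts: CountMatrix,
        samples: Sequence[SampleInfo],
        model: str = "induction",
        factors: Sequence[float] | None = None,
        use_voom: bool = True,
    ) -> None:
        if len(samples) != len(counts.sample_ids):
            raise ValueError("need one SampleInfo per count column")
        by_id = {s.sample_id: s for s in samples}
        mismatched = [sid for sid in counts.sample_ids if sid not in by_id]
        if mismatched:
            raise ValueError(f"sample sheet missing count columns: {mismatched}")
        self.counts = counts
        self.samples = [by_id[sid] for sid in counts.sample_ids]
        self.model = model
        self.factors = None if factors is None else np.asarray(factors, dtype=float)
        self.use_voom = use_voom
        self.design, self.design_columns, self.contrast = build_design(
            self.samples, model
        )
        self.log2cpm = log2_cpm(counts, factors=self.factors)

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        samples: Sequence[SampleInfo],
        **kwargs,
    ) -> "DifferentialModel":
        cm = CountMatrix(list(counts.index), list(counts.columns), counts.to_numpy())
        return cls(cm, samples, **kwargs)

    def fit(self, moderate: bool | None = None) -> DifferentialResults:
        """Fit the model; moderate unless the design is saturated."""
        weights = (
            voom_weights(self.log2cpm, self.design)
            if self.use_voom
            else np.ones_like(self.log2cpm)
        )
        fits = fit_weighted_linear_model(
            self.log2cpm, self.design, weights, self.contrast
        )
        fits.index = pd.Index(self.counts.region_ids, name="feature")
        df_resid = float(fits["df_resid"].iloc[0])
        if moderate is None:
            moderate = df_resid >= 1
        d0 = s0 = None
        if moderate:
            fits = moderate_and_test(fits)
            d0, s0 = fits.attrs["d0"], fits.attrs["s0_2"]
        elif df_resid < 1:
            warnings.warn(
                "saturated design (residual df = 0): effects are exact "
                "interpolants; no significance tests",
                RuntimeWarning,
                stacklevel=2,
            )
        return DifferentialResults(
            table=fits,
            model=self.model,
            design_columns=self.design_columns,
            contrast=self.contrast,
            d0=d0,
            s0_2=s0,
        )
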