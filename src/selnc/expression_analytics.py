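"""Subtype assignment, supervised LDA, moderated differential screening
with FDR control, and small RT-qPCR computations (relative expression,
decay half-life).

The differential test is an empirical-Bayes moderated two-sample t: the
prior degrees of freedom d0 and prior variance s0^2 are fitted by moment
matching on the distribution of log sample variances; the posterior
variance s~^2 = (d0*s0^2 + d*s^2) / (d0 + d) replaces the pooled
variance and the statistic is referred to a t distribution with d0 + d
degrees of freedom.  With moderation off the statistic reduces exactly
to the ordinary pooled two-sample t.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import digamma, polygamma

from selnc.formats_io import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Nearest-centroid subtype assignment
# ---------------------------------------------------------------------------

@dataclass
class SubtypeCentroids:
    gene_ids: list[str]
    subtype_labels: list[str]
    values: np.ndarray  # gene x subtype
    min_corr: float = 0.1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.subtype_labels) < 2:
            raise ValueError("need >= 2 subtypes")
        if len(self.gene_ids) < 2:
            raise ValueError("need >= 2 genes")
        if not (-1.0 <= self.min_corr <= 1.0):
            raise ValueError("min_corr must lie in [-1, 1]")
        if self.values.shape != (len(self.gene_ids), len(self.subtype_labels)):
            raise ValueError("centroid table shape mismatch")

    @classmethod
    def from_tsv(cls, path, min_corr: float = 0.1) -> "SubtypeCentroids":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float), min_corr)


def classify_subtype(
    sample_values: dict[str, float] | pd.Series,
    centroids: SubtypeCentroids,
    method: str = "spearman",
) -> tuple[str, float]:
    """Assign a sample to the centroid with the highest rank correlation.

    Returns (label, correlation); label is "Unknown" when the best
    correlation falls below ``centroids.min_corr``.  Genes missing from
    the sample are dropped pairwise; the sample must cover at least half
    of the centroid genes.  Exact ties go to the lexicographically first
    label.
    """
    if isinstance(sample_values, dict):
        sample_values = pd.Series(sample_values)
    shared = [g for g in centroids.gene_ids if g in sample_values.index]
    if len(shared) < 2:
        raise ValueError("fewer than 2 genes shared with the centroid table")
    if len(shared) < 0.5 * len(centroids.gene_ids):
        raise ValueError(
            f"sample covers only {len(shared)}/{len(centroids.gene_ids)} centroid genes"
        )
    idx = [centroids.gene_ids.index(g) for g in shared]
    x = sample_values.loc[shared].to_numpy(dtype=float)
    corr_fn = stats.spearmanr if method == "spearman" else stats.pearsonr
    corrs = []
    for j, label in enumerate(centroids.subtype_labels):
        r = corr_fn(x, centroids.values[idx, j])[0]
        corrs.append((label, float(r) if np.isfinite(r) else -np.inf))
    best_r = max(r for _, r in corrs)
    best_label = min(label for label, r in corrs if r == best_r)
    if best_r < centroids.min_corr:
        return "Unknown", best_r
    return best_label, best_r


# ---------------------------------------------------------------------------
# Supervised LDA (ridge-regularized Fisher discriminant)
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    classes: list[str]
    class_means: np.ndarray      # class x feature
    axes: np.ndarray             # feature x n_axes
    eigenvalues: np.ndarray      # scatter ratios per axis
    priors: np.ndarray
    ridge: float


def lda_fit(X: np.ndarray, labels, ridge: float = 1e-6) -> LDAModel:
    """Fit Fisher LDA with a ridge term on the within-class scatter."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    n, p = X.shape
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    if p >= n and ridge == 0:
        raise ValueError("ridge must be > 0 when features >= samples")

    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    means, priors = [], []
    for cls in classes:
        Xc = X[labels == cls]
        if len(Xc) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        mu = Xc.mean(axis=0)
        means.append(mu)
        priors.append(len(Xc) / n)
        centered = Xc - mu
        Sw += centered.T @ centered
        d = (mu - grand)[:, None]
        Sb += len(Xc) * (d @ d.T)
    Sw_reg = Sw + ridge * np.eye(p)
    if ridge == 0 and np.linalg.matrix_rank(Sw) < p:
        raise ValueError("within-class scatter is singular; set ridge > 0")
    evals, evecs = linalg.eigh(Sb, Sw_reg)
    order = np.argsort(evals)[::-1][: len(classes) - 1]
    return LDAModel(
        classes=[str(c) for c in classes],
        class_means=np.array(means),
        axes=evecs[:, order],
        eigenvalues=evals[order],
        priors=np.array(priors),
        ridge=ridge,
    )


def lda_transform(model: LDAModel, X: np.ndarray) -> np.ndarray:
    return np.asarray(X, dtype=float) @ model.axes


def lda_classify(model: LDAModel, X: np.ndarray) -> list[str]:
    """Nearest class mean in the projected space."""
    proj = lda_transform(model, X)
    mean_proj = model.class_means @ model.axes
    dists = ((proj[:, None, :] - mean_proj[None, :, :]) ** 2).sum(axis=2)
    return [model.classes[i] for i in dists.argmin(axis=1)]


# ---------------------------------------------------------------------------
# Moderated t / FDR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DifferentialResult:
    feature_id: str
    log2fc: float
    t_mod: float
    p: float
    q: float = np.nan


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to observed sample variances.

    Returns (d0, s0_squared); d0 = inf when the variances are no more
    dispersed than chi-square sampling alone explains.
    """
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all features have zero variance; prior moments undefined")
    z = np.log(s2[ok])
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    n = len(e)
    evar = float(((e - emean) ** 2).sum() / (n - 1)) if n > 1 else 0.0
    evar = evar - polygamma(1, d / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def moderated_ttest(
    matrix: ExpressionMatrix | np.ndarray,
    group_mask: np.ndarray,
    moderation: bool = True,
    feature_ids: list[str] | None = None,
) -> list[DifferentialResult]:
    """Two-sample (group vs rest) differential test per feature.

    ``group_mask`` selects the target group's samples.  With
    ``moderation=True`` the pooled variance is shrunk toward an
    empirical-Bayes prior; otherwise the ordinary pooled t is returned.
    q-values are BH-adjusted across features.
    """
    if isinstance(matrix, ExpressionMatrix):
        values = matrix.values
        feature_ids = feature_ids or matrix.feature_ids
    else:
        values = np.asarray(matrix, dtype=float)
        feature_ids = feature_ids or [f"f{i}" for i in range(values.shape[0])]
    group_mask = np.asarray(group_mask, dtype=bool)
    n1, n2 = int(group_mask.sum()), int((~group_mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 samples")

    x1, x2 = values[:, group_mask], values[:, ~group_mask]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    log2fc = m1 - m2
    d = n1 + n2 - 2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / d
    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)

    if moderation:
        d0, s0_sq = _fit_f_dist(s2, d)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
            df_total = d0 + d
    else:
        s2_post = s2
        df_total = d

    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / (np.sqrt(s2_post) * se_factor)
    t = np.where(np.isfinite(t), t, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where((log2fc == 0) & (t == 0), 1.0, p)
    q = bh_fdr(p)
    return [
        DifferentialResult(feature_ids[i], float(log2fc[i]), float(t[i]),
                           float(p[i]), float(q[i]))
        for i in range(len(feature_ids))
    ]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def subtype_de_summary(
    matrix: ExpressionMatrix,
    subtype_labels,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    moderation: bool = True,
) -> dict:
    """One-vs-rest differential screen per subtype with exact intersections.

    Returns a dict with per-subtype :class:`DifferentialResult` lists,
    per-subtype DE feature sets (q < alpha and |log2fc| >= lfc_min),
    all pairwise intersections and the overall intersection.
    """
    labels = np.asarray(list(subtype_labels))
    subtypes = sorted(set(labels.tolist()))
    if len(subtypes) < 2:
        raise ValueError("need >= 2 subtypes")
    results: dict[str, list[DifferentialResult]] = {}
    de_sets: dict[str, set[str]] = {}
    for s in subtypes:
        res = moderated_ttest(matrix, labels == s, moderation=moderation)
        results[s] = res
        de_sets[s] = {
            r.feature_id for r in res if r.q < alpha and abs(r.log2fc) >= lfc_min
        }
    pairwise = {
        (a, b): de_sets[a] & de_sets[b]
        for i, a in enumerate(subtypes) for b in subtypes[i + 1:]
    }
    overall = set.intersection(*de_sets.values()) if de_sets else set()
    return {"results": results, "de_sets": de_sets,
            "pairwise": pairwise, "overall": overall}


# ---------------------------------------------------------------------------
# RT-qPCR helpers
# ---------------------------------------------------------------------------

def ddct(ct_target_trt: float, ct_ref_trt: float,
         ct_target_ctl: float, ct_ref_ctl: float) -> float:
    """Relative expression by the 2^-ddCt method."""
    cts = (ct_target_trt, ct_ref_trt, ct_target_ctl, ct_ref_ctl)
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    delta_delta = (ct_target_trt - ct_ref_trt) - (ct_target_ctl - ct_ref_ctl)
    return float(2.0 ** (-delta_delta))


def estimate_half_life(times_h, rel_expression) -> float:
    """Half-life from a transcription-blocked decay time course.

    Least-squares fit of ln(expression) against time; t1/2 = ln2/|slope|.
    A non-negative slope (no decay) returns +inf with a warning.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(rel_expression, dtype=float)
    if len(t) < 3:
        raise ValueError("need >= 3 timepoints")
    if (y <= 0).any():
        raise ValueError("expression values must be positive")
    slope, _ = np.polyfit(t, np.log(y), 1)
    if slope >= 0:
        warnings.warn("no decay detected; returning +inf half-life")
        return float("inf")
    return float(np.log(2.0) / abs(slope))
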