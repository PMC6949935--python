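"""Alpha diversity, rarefaction, Bray-Curtis and NMDS ordination.

Alpha diversity runs on raw (unfiltered) integer counts, separately from the
network's prevalence-filtered table.  Shannon uses the natural log; the
Simpson index is reported as dominance D = sum p_i^2 (small D = even
community), with 1 - D available alongside.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from skbio.diversity import alpha as _alpha

from .io_model import OtuTable, ValidationError


def _check_counts(counts: np.ndarray) -> np.ndarray:
    c = np.asarray(counts)
    if np.any(c < 0):
        raise ValidationError("counts must be non-negative")
    if not np.allclose(c, np.round(c)):
        raise ValidationError(
            "richness estimators require integer counts; pass raw counts, "
            "not relative abundances")
    return np.round(c).astype(int)


def chao1(counts: np.ndarray) -> float:
    """Chao1 richness: S_obs + F1^2 / (2 F2), from singletons/doubletons.

    With no doubletons the bias-corrected variant S_obs + F1(F1-1)/2 is
    used so the estimator stays finite.
    """
    c = _check_counts(counts)
    c = c[c > 0]
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 ** 2 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def ace(counts: np.ndarray, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator (classical formula).

    Rare taxa (abundance <= ``rare_cutoff``) drive the coverage estimate
    C_ace = 1 - F1 / N_rare and the rare-class coefficient of variation.
    When every rare taxon is a singleton (C_ace = 0) the estimator is
    undefined and Chao1 is returned with a warning.
    """
    c = _check_counts(counts)
    c = c[c > 0]
    rare = c[c <= rare_cutoff]
    if rare.size == 0:
        return float(c.size)
    f1 = int((rare == 1).sum())
    if f1 == rare.size:
        warnings.warn("all rare taxa are singletons; ACE undefined, "
                      "falling back to Chao1", stacklevel=2)
        return chao1(counts)
    return float(_alpha.ace(c, rare_threshold=rare_cutoff))


def shannon(counts: np.ndarray) -> float:
    """Shannon H = -sum p ln p (natural log)."""
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValidationError("total count must be positive")
    return float(_alpha.shannon(c, base=np.e))


def simpson(counts: np.ndarray) -> float:
    """Simpson dominance D = sum p_i^2 (1 - D is the complement form)."""
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValidationError("total count must be positive")
    return float(_alpha.dominance(c))


def rarefaction_curve(counts: np.ndarray, depths: list[int],
                      n_resamples: int = 50, seed: int = 0) -> pd.DataFrame:
    """Mean/sd observed richness under subsampling without replacement.

    Depths above the total count are skipped with a warning.  Sampling is
    multivariate hypergeometric, seeded.
    """
    c = _check_counts(counts)
    c = c[c > 0]
    total = int(c.sum())
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        if depth > total:
            warnings.warn(f"depth {depth} exceeds total count {total}; "
                          "skipped", stacklevel=2)
            continue
        richness = np.empty(n_resamples)
        for i in range(n_resamples):
            sub = rng.multivariate_hypergeometric(c, depth)
            richness[i] = int((sub > 0).sum())
        rows.append((depth, float(richness.mean()), float(richness.std(ddof=1))
                     if n_resamples > 1 else 0.0))
    return pd.DataFrame(rows, columns=["depth", "mean_richness", "sd_richness"])


def expected_rarefaction(counts: np.ndarray, depth: int) -> float:
    """Closed-form hypergeometric expectation of richness at ``depth``.

    E[S_d] = sum_i (1 - C(N - n_i, d) / C(N, d)); the analytic benchmark
    for the resampled curve.
    """
    c = _check_counts(counts)
    c = c[c > 0]
    total = int(c.sum())
    # log-space binomial ratio to stay stable for large counts
    def log_choose(n, k):
        return stats.binom.logpmf(k, n, 0.5) + n * np.log(2) if k <= n else -np.inf
    out = 0.0
    for n_i in c:
        if total - n_i < depth:
            out += 1.0
        else:
            log_ratio = (log_choose(total - n_i, depth)
                         - log_choose(total, depth))
            out += 1.0 - np.exp(log_ratio)
    return float(out)


def bray_curtis(table: OtuTable) -> np.ndarray:
    """Sample x sample Bray-Curtis distance on relative abundances."""
    x = table.abundance.T  # samples x OTUs
    totals = x.sum(axis=1)
    if np.any(totals <= 0):
        bad = [table.sample_ids[i] for i in np.where(totals <= 0)[0]]
        raise ValidationError(f"all-zero sample(s), Bray-Curtis undefined: {bad}")
    rel = x / totals[:, None]
    d = squareform(pdist(rel, metric="braycurtis"))
    return d


# ---------------------------------------------------------------------------
# non-metric multidimensional scaling
# ---------------------------------------------------------------------------

def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson double-centering initialisation."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(vals)


def _stress1(d_config: np.ndarray, disparities: np.ndarray) -> float:
    num = ((d_config - disparities) ** 2).sum()
    den = (d_config ** 2).sum()
    return float(np.sqrt(num / den)) if den > 0 else 0.0


def nmds(dist: np.ndarray, k: int = 2, seed: int = 0, n_restarts: int = 4,
         max_iter: int = 300, tol: float = 1e-7,
         ) -> tuple[np.ndarray, float, list[float]]:
    """Non-metric MDS minimising Kruskal stress-1.

    Classical-scaling initialisation plus seeded random restarts; each
    iteration alternates isotonic regression of configuration distances on
    the input dissimilarities (the disparities) with a Guttman-transform
    configuration update, so the recorded stress trajectory of the best
    start is non-increasing.  Returns (coordinates, stress, trajectory).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("nmds needs a square symmetric distance matrix")
    iu = np.triu_indices(n, k=1)
    diss = d[iu]
    order = np.argsort(diss, kind="stable")
    iso = IsotonicRegression(increasing=True)

    def run(x0: np.ndarray) -> tuple[np.ndarray, float, list[float]]:
        x = x0.copy()
        trajectory: list[float] = []
        prev = np.inf
        for _ in range(max_iter):
            dc = squareform(pdist(x))
            dvec = dc[iu]
            fitted = np.empty_like(dvec)
            fitted[order] = iso.fit_transform(np.arange(order.size),
                                              dvec[order])
            stress = _stress1(dvec, fitted)
            trajectory.append(stress)
            if prev - stress < tol:
                break
            prev = stress
            # Guttman transform with disparities as target distances
            dhat = np.zeros_like(dc)
            dhat[iu] = fitted
            dhat += dhat.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dc > 0, dhat / dc, 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x = (b @ x) / n
        return x, trajectory[-1], trajectory

    rng = np.random.default_rng(seed)
    starts = [_classical_scaling(d, k)]
    scale = diss.max() if diss.size else 1.0
    for _ in range(n_restarts - 1):
        starts.append(rng.standard_normal((n, k)) * scale)
    best = None
    for x0 in starts:
        result = run(x0)
        if best is None or result[1] < best[1]:
            best = result
    coords, stress, trajectory = best
    return coords, stress, trajectory


def alpha_diversity_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample Chao1, ACE, Shannon, Simpson dominance and 1 - D."""
    rows = []
    for j, s in enumerate(table.sample_ids):
        c = table.abundance[:, j]
        d = simpson(c)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append((s, chao1(c), ace(c), shannon(c), d, 1.0 - d))
    return pd.DataFrame(rows, columns=["sample", "chao1", "ace", "shannon",
                                       "simpson_dominance", "simpson_1mD"])
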