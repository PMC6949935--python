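"""Random-matrix-theory threshold selection (Step II).

The similarity matrix is truncated at a candidate cutoff and the eigenvalue
spectrum of the surviving submatrix is examined.  After *unfolding* (mapping
eigenvalues through a smoothed cumulative spectral function so the mean
level spacing is 1), the nearest-neighbour spacing distribution (NNSD)
discriminates two universal regimes:

* Poisson, ``P(s) = exp(-s)`` — uncorrelated eigenvalues, the signature of a
  modular system of independent blocks;
* Gaussian orthogonal ensemble (GOE), whose NNSD is well approximated by the
  Wigner surmise ``P(s) = (pi/2) s exp(-pi s^2 / 4)`` — correlated,
  noise-dominated spectra.

Scanning the cutoff downward from the top, the selected threshold is the
lowest cutoff whose NNSD still fits Poisson: below it, noise correlations
couple the spectrum and the Poisson fit breaks.  A fixed threshold (0.81 by
default, for cross-group comparability) bypasses the scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_model import SimilarityMatrix, ValidationError, logger

#: minimum number of eigenvalues for a statistically meaningful NNSD
MIN_EIGENVALUES = 20


@dataclass
class TruncationResult:
    """Similarity submatrix surviving a cutoff; empty when nothing does."""

    otu_ids: list[str]
    matrix: np.ndarray  # entries below the cutoff zeroed, diagonal 1

    @property
    def is_empty(self) -> bool:
        return len(self.otu_ids) == 0


@dataclass
class SpacingAnalysis:
    """NNSD goodness-of-fit summary at one threshold."""

    threshold: float
    n_active_nodes: int
    eigenvalues: np.ndarray
    unfolded_spacings: np.ndarray
    chi2_poisson: float
    p_poisson: float
    chi2_goe: float
    p_goe: float


@dataclass
class ThresholdScan:
    """Downward threshold scan with the selected cutoff (if any)."""

    analyses: list[SpacingAnalysis] = field(default_factory=list)
    selected_threshold: float | None = None
    mode: str = "rmt_scan"


def truncate_similarity(sim: SimilarityMatrix,
                        threshold: float) -> TruncationResult:
    """Restrict the matrix to OTUs with >= 1 off-diagonal entry >= threshold.

    Surviving entries keep their value, sub-threshold entries are zeroed,
    and the diagonal is set to 1.  An empty result is returned (not raised)
    when no pair reaches the cutoff.
    """
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie strictly in (0, 1)")
    values = sim.values.copy()
    np.fill_diagonal(values, 0.0)
    active = np.where((values >= threshold).any(axis=1))[0]
    if active.size == 0:
        return TruncationResult([], np.empty((0, 0)))
    sub = values[np.ix_(active, active)]
    sub[sub < threshold] = 0.0
    np.fill_diagonal(sub, 1.0)
    return TruncationResult([sim.otu_ids[i] for i in active], sub)


def unfold_eigenvalues(eigenvalues: np.ndarray,
                       smoothing_degree: int = 5) -> np.ndarray:
    """Unfold a spectrum and return nearest-neighbour spacings (mean ~ 1).

    A polynomial of ``smoothing_degree`` is fit to the empirical cumulative
    spectral function F(lambda); eigenvalues map to e_i = N * F_hat(lambda_i)
    and spacings are consecutive differences.  If the fitted F_hat is not
    monotone over the data range the degree is lowered until it is; failing
    at degree 1 is an error.  Exactly degenerate eigenvalues are split by a
    deterministic jitter <= 1e-10 so the spectrum is simple.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    n = lam.size
    if np.unique(lam).size < MIN_EIGENVALUES:
        raise ValidationError(
            f"need >= {MIN_EIGENVALUES} distinct eigenvalues for NNSD, got "
            f"{np.unique(lam).size}")
    # break exact degeneracies with a tiny increasing ramp
    dup = np.concatenate([[False], np.diff(lam) == 0])
    if dup.any():
        ramp = np.cumsum(dup) * 1e-12
        lam = lam + np.where(dup, ramp, 0.0)
        lam = np.sort(lam)

    ecdf = (np.arange(1, n + 1) - 0.5) / n
    for degree in range(smoothing_degree, 0, -1):
        poly = np.polynomial.Polynomial.fit(lam, ecdf, degree)
        deriv = poly.deriv()
        # monotonicity checked on a fine grid across the data range
        grid = np.linspace(lam[0], lam[-1], 4 * n)
        if np.all(deriv(grid) > 0):
            break
        if degree == 1:
            raise ValidationError(
                "could not fit a monotone cumulative spectral function "
                "even at degree 1")
    # affine rectification: pin the fitted cumulative function to the data
    # range so the mean spacing is exactly 1 (unfolding only needs the
    # *local* scale; the global affine factor is a normalisation choice)
    f = poly(lam)
    unfolded = (n - 1) * (f - f[0]) / (f[-1] - f[0])
    spacings = np.diff(unfolded)
    return spacings


def _merge_bins(observed: np.ndarray, expected: np.ndarray,
                min_expected: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent bins until every expected count >= min_expected."""
    obs = list(observed.astype(float))
    exp = list(expected.astype(float))
    i = 0
    while i < len(exp):
        if exp[i] < min_expected and len(exp) > 1:
            j = i + 1 if i + 1 < len(exp) else i - 1
            exp[j] += exp[i]
            obs[j] += obs[i]
            del exp[i], obs[i]
            i = 0  # restart; merged bins can still be small
        else:
            i += 1
    return np.array(obs), np.array(exp)


def _chi2_gof(spacings: np.ndarray, cdf_inv, n_bins: int) -> tuple[float, float]:
    """Chi-square GOF with equal-probability bins under the candidate law."""
    n = spacings.size
    qs = np.arange(1, n_bins) / n_bins
    edges = np.concatenate([[0.0], cdf_inv(qs), [np.inf]])
    observed, _ = np.histogram(spacings, bins=edges)
    expected = np.full(n_bins, n / n_bins)
    observed, expected = _merge_bins(observed, expected)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = len(expected) - 1
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return chi2, p


def nnsd_gof(spacings: np.ndarray,
             n_bins: int = 20) -> tuple[float, float, float, float]:
    """Chi-square fits of the NNSD against Poisson and the Wigner surmise.

    Bins are equal-probability under each null; bins with expected count
    below 1 are merged and the degrees of freedom adjusted.  Returns
    (chi2_poisson, p_poisson, chi2_goe, p_goe).
    """
    s = np.asarray(spacings, dtype=float)
    if s.size < n_bins:
        n_bins = max(2, s.size // 2)
    # Poisson: CDF 1 - exp(-s)  =>  inverse -ln(1-q)
    chi2_p, p_p = _chi2_gof(s, lambda q: -np.log1p(-q), n_bins)
    # Wigner surmise: CDF 1 - exp(-pi s^2/4)  =>  inverse sqrt(-4 ln(1-q)/pi)
    chi2_g, p_g = _chi2_gof(
        s, lambda q: np.sqrt(-4.0 * np.log1p(-q) / np.pi), n_bins)
    return chi2_p, p_p, chi2_g, p_g


def analyze_threshold(sim: SimilarityMatrix, threshold: float,
                      smoothing_degree: int = 5,
                      n_bins: int = 20) -> SpacingAnalysis | None:
    """Truncate at ``threshold`` and run the NNSD analysis, or None if the
    surviving submatrix is empty/too small for spacing statistics."""
    trunc = truncate_similarity(sim, threshold)
    if trunc.is_empty or trunc.matrix.shape[0] < MIN_EIGENVALUES:
        return None
    eigenvalues = np.linalg.eigvalsh(trunc.matrix)
    try:
        spacings = unfold_eigenvalues(eigenvalues, smoothing_degree)
    except ValidationError:
        return None
    chi2_p, p_p, chi2_g, p_g = nnsd_gof(spacings, n_bins)
    return SpacingAnalysis(threshold, trunc.matrix.shape[0], eigenvalues,
                           spacings, chi2_p, p_p, chi2_g, p_g)


def scan_threshold(sim: SimilarityMatrix, scan_from: float = 0.99,
                   scan_to: float = 0.30, step: float = 0.01,
                   alpha: float = 0.05, smoothing_degree: int = 5,
                   mode: str = "rmt_scan",
                   fixed_threshold: float | None = None) -> ThresholdScan:
    """Scan cutoffs downward and keep the lowest still Poisson-consistent.

    At each cutoff (from ``scan_from`` down to ``scan_to`` in ``step``
    decrements) the NNSD of the truncated matrix is tested against Poisson.
    The scan walks down while the Poisson fit holds (p > alpha) and stops at
    the first rejection; the selected threshold is the last cutoff that
    fitted.  ``mode="fixed"`` records ``fixed_threshold`` without scanning.
    """
    if mode == "fixed":
        if fixed_threshold is None:
            raise ValidationError("fixed mode requires fixed_threshold")
        return ThresholdScan([], float(fixed_threshold), "fixed")
    if scan_from <= scan_to:
        raise ValidationError("scan_from must exceed scan_to")
    if step <= 0:
        raise ValidationError("step must be positive")

    scan = ThresholdScan(mode="rmt_scan")
    thresholds = np.arange(scan_from, scan_to - 1e-9, -step)
    last_fit: float | None = None
    for thr in thresholds:
        analysis = analyze_threshold(sim, float(thr), smoothing_degree)
        if analysis is None:
            continue  # too few active nodes yet; keep walking down
        scan.analyses.append(analysis)
        if analysis.p_poisson > alpha:
            last_fit = analysis.threshold
        else:
            break  # spectrum has turned GOE-like; the transition is here
    scan.selected_threshold = last_fit
    if last_fit is None:
        warnings.warn("no scanned threshold fits the Poisson NNSD; "
                      "selected_threshold left unset", stacklevel=2)
        logger.warning("threshold scan found no Poisson-consistent cutoff")
    return scan
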