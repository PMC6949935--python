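"""Synthetic two-group OTU communities with planted correlation modules.

The generator emulates the study design the pipeline targets: two soil
groups of 15 samples each, a few hundred OTUs, block-structured inter-OTU
correlations (planted modules), and environmental variables driven by
specific modules.  Abundances are log-normal counts: correlated Gaussian
latents on the log10 scale are exponentiated and rounded, so the planted
correlation lives on exactly the scale the downstream Pearson step sees.
Structural zeros come from thresholding the smallest latent values, which
makes the 0.01 blank-fill step downstream meet realistic zeros.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_model import OtuTable, SampleMetadata, ValidationError

#: default group labels for the two-soil-condition design
DEFAULT_GROUPS = ("G1", "G2")


@dataclass
class SynthSpec:
    """Parameters of the planted-module community generator.

    Defaults follow the emulated study design: 15 samples per group, four
    planted modules of 25 OTUs within a 200-OTU community, strong (0.9)
    within-module correlation on the log scale, independent modules, mild
    zero inflation.
    """

    n_samples_per_group: int = 15
    n_otus: int = 200
    n_modules: int = 4
    module_sizes: list[int] = field(default_factory=lambda: [25, 25, 25, 25])
    within_module_correlation: float = 0.9
    between_module_correlation: float = 0.0
    env_drivers: dict[int, tuple[str, float]] = field(default_factory=dict)
    zero_inflation: float = 0.1
    dispersion: float = 0.5          # sd of log10 abundance
    mean_log10_abundance: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.module_sizes) != self.n_modules:
            raise ValidationError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_otus:
            raise ValidationError("module sizes must sum to <= n_otus")
        if not 0 < self.within_module_correlation < 1:
            raise ValidationError("within_module_correlation must lie in (0, 1)")
        if not 0 <= self.zero_inflation < 1:
            raise ValidationError("zero_inflation must lie in [0, 1)")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")

    def planted_partition(self) -> dict[str, int]:
        """True module label per OTU id; background OTUs get module 0."""
        labels: dict[str, int] = {}
        k = 0
        for m, size in enumerate(self.module_sizes, start=1):
            for _ in range(size):
                labels[f"OTU{k + 1}"] = m
                k += 1
        for k in range(k, self.n_otus):
            labels[f"OTU{k + 1}"] = 0
        return labels


def _block_correlation(spec: SynthSpec) -> np.ndarray:
    """Build (and PSD-check) the planted block correlation matrix."""
    n = spec.n_otus
    corr = np.full((n, n), spec.between_module_correlation)
    start = 0
    offenders = []
    for m, size in enumerate(spec.module_sizes, start=1):
        block = slice(start, start + size)
        corr[block, block] = spec.within_module_correlation
        start += size
    # background OTUs are independent of everything
    for i in range(start, n):
        corr[i, :] = 0.0
        corr[:, i] = 0.0
    np.fill_diagonal(corr, 1.0)
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin < -1e-8:
        # diagnose which blocks clash: with uniform off-block rho the usual
        # culprit is between > within or a negative between too large
        offenders = [m for m in range(1, spec.n_modules + 1)]
        raise ValidationError(
            "requested block correlation structure is not positive "
            f"semi-definite (min eigenvalue {eigmin:.3g}); offending blocks: "
            f"{offenders}")
    return corr


def _latent_to_counts(latent: np.ndarray, spec: SynthSpec) -> np.ndarray:
    """Exponentiate latents to log-normal counts and plant structural zeros."""
    log10_abund = spec.mean_log10_abundance + spec.dispersion * latent
    counts = np.round(10.0 ** log10_abund)
    if spec.zero_inflation > 0:
        cutoff = np.quantile(latent, spec.zero_inflation)
        counts[latent <= cutoff] = 0.0
    return counts


def generate_community(spec: SynthSpec,
                       group_labels: tuple[str, str] = DEFAULT_GROUPS,
                       ) -> tuple[OtuTable, SampleMetadata]:
    """Draw a two-group community with planted modules and env drivers.

    Each group receives its own independent latent draw from the same block
    correlation structure.  Environmental driver variables are built as
    (module latent mean) x strength + sqrt(1 - strength^2) x noise, so
    ``strength`` is the target correlation with the module signal.  All
    randomness flows from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    corr = _block_correlation(spec)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(spec.n_otus))

    n_per = spec.n_samples_per_group
    n_total = 2 * n_per
    z = rng.standard_normal((spec.n_otus, n_total))
    latent = chol @ z

    counts = _latent_to_counts(latent, spec)

    otu_ids = [f"OTU{i + 1}" for i in range(spec.n_otus)]
    sample_ids = ([f"{group_labels[0]}{i + 1}" for i in range(n_per)]
                  + [f"{group_labels[1]}{i + 1}" for i in range(n_per)])
    group = {s: group_labels[0] if i < n_per else group_labels[1]
             for i, s in enumerate(sample_ids)}
    table = OtuTable(otu_ids, sample_ids, counts, group=group)

    # environmental variables: one per declared driver, plus pure-noise
    # variables so the metadata table is never empty
    variables: dict[str, np.ndarray] = {}
    bounds = np.cumsum([0] + list(spec.module_sizes))
    for module_id, (var_name, strength) in spec.env_drivers.items():
        if not 1 <= module_id <= spec.n_modules:
            raise ValidationError(f"env driver targets unknown module {module_id}")
        if not 0 <= strength <= 1:
            raise ValidationError("driver strength must lie in [0, 1]")
        block = slice(bounds[module_id - 1], bounds[module_id])
        signal = latent[block, :].mean(axis=0)
        signal = (signal - signal.mean()) / signal.std()
        noise = rng.standard_normal(n_total)
        variables[var_name] = strength * signal + np.sqrt(1 - strength ** 2) * noise
    if not variables:
        variables["env_noise"] = rng.standard_normal(n_total)

    meta = SampleMetadata(list(sample_ids), variables, group=dict(group))
    return table, meta


def generate_null_community(n_otus: int, n_samples: int, seed: int,
                            dispersion: float = 0.5,
                            mean_log10_abundance: float = 2.0) -> OtuTable:
    """Independent-OTU log-normal community (diagonal latent covariance).

    The null control for false-positive and spacing-statistics tests: no
    planted correlation, no zeros, so any detected structure is noise.
    """
    if n_samples < 3:
        raise ValidationError(
            "need at least 3 samples for meaningful correlations")
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n_otus, n_samples))
    counts = np.round(10.0 ** (mean_log10_abundance + dispersion * latent))
    counts = np.maximum(counts, 1.0)  # keep strictly positive: null has no zeros
    otu_ids = [f"OTU{i + 1}" for i in range(n_otus)]
    sample_ids = [f"S{j + 1}" for j in range(n_samples)]
    return OtuTable(otu_ids, sample_ids, counts)


def write_truth_sidecar(spec: SynthSpec, path: str | Path) -> None:
    """JSON record of the planted truth for test harnesses."""
    payload = {
        "seed": spec.seed,
        "partition": spec.planted_partition(),
        "env_drivers": {str(m): list(v) for m, v in spec.env_drivers.items()},
        "n_samples_per_group": spec.n_samples_per_group,
        "within_module_correlation": spec.within_module_correlation,
        "between_module_correlation": spec.between_module_correlation,
        "zero_inflation": spec.zero_inflation,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
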