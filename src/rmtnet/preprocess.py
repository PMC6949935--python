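"""Step I of the pipeline: filter, fill, log-transform, correlate.

OTUs seen in too few samples are removed, remaining zeros are filled with a
small positive constant (0.01 by default) so the table is log10-able, and
the similarity matrix is the absolute pairwise Pearson correlation of the
log10 profiles, with the correlation sign kept alongside.
"""

from __future__ import annotations

import numpy as np

from .io_model import OtuTable, SimilarityMatrix, ValidationError


def resolve_min_present(rule: int | float | str, n_samples: int) -> int:
    """Turn a prevalence rule into an integer sample count.

    ``"majority"`` -> floor(n/2)+1 (the 8-of-15 parameterisation); a float in
    (0,1) -> ceil(fraction * n); an int is taken as-is.
    """
    if rule == "majority":
        return n_samples // 2 + 1
    if isinstance(rule, float):
        if not 0 < rule < 1:
            raise ValidationError("fractional prevalence rule must lie in (0,1)")
        return int(np.ceil(rule * n_samples))
    if isinstance(rule, (int, np.integer)):
        if not 1 <= rule <= n_samples:
            raise ValidationError(
                f"prevalence count {rule} outside 1..{n_samples}")
        return int(rule)
    raise ValidationError(f"unrecognised prevalence rule {rule!r}")


def prevalence_filter(table: OtuTable,
                      min_present: int | float | str) -> OtuTable:
    """Keep OTUs with nonzero abundance in at least ``min_present`` samples.

    Sample set and OTU order are preserved.  Removing every OTU is an error
    (the cutoff is too strict for the data at hand).
    """
    k = resolve_min_present(min_present, table.n_samples)
    present = (table.abundance > 0).sum(axis=1)
    keep = [o for o, c in zip(table.otu_ids, present) if c >= k]
    if not keep:
        raise ValidationError(
            f"prevalence filter (>= {k} of {table.n_samples} samples) removed "
            "every OTU; lower the cutoff")
    return table.subset_otus(keep)


def fill_blanks(table: OtuTable, fill_value: float = 0.01) -> OtuTable:
    """Replace every zero cell with ``fill_value``; nonzero cells untouched."""
    if fill_value <= 0:
        raise ValidationError("fill_value must be positive (log10 follows)")
    values = table.abundance.copy()
    values[values == 0] = fill_value
    return table.with_abundance(values)


def log10_transform(table: OtuTable) -> OtuTable:
    """Elementwise log10; requires strictly positive cells (fill first)."""
    if np.any(table.abundance <= 0):
        i, j = np.argwhere(table.abundance <= 0)[0]
        raise ValidationError(
            f"non-positive cell at OTU {table.otu_ids[i]!r}, sample "
            f"{table.sample_ids[j]!r}: run fill_blanks before log10_transform")
    return table.with_abundance(np.log10(table.abundance), is_log_scale=True)


def _pairwise_complete_corr(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Pearson correlation per pair over jointly valid samples only.

    Vectorised through mask algebra: for OTUs i, j all sums run over the
    samples where both are valid.  Pairs with fewer than 3 joint samples or
    degenerate variance get correlation 0.
    """
    m = valid.astype(float)
    xm = x * m
    n_joint = m @ m.T                    # joint sample counts
    s_x = xm @ m.T                       # sum of x_i over joint samples
    s_xx = (x * xm) @ m.T                # sum of x_i^2 over joint samples
    s_xy = xm @ xm.T
    cov = n_joint * s_xy - s_x * s_x.T
    var_i = n_joint * s_xx - s_x ** 2
    var_j = var_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(var_i * var_j)
    r[(n_joint < 3) | (var_i <= 0) | (var_j <= 0)] = 0.0
    return np.nan_to_num(r, nan=0.0)


def pearson_similarity(table: OtuTable,
                       valid_mask: np.ndarray | None = None,
                       ) -> SimilarityMatrix:
    """Absolute Pearson correlation across samples, sign kept separately.

    Requires >= 3 samples and nonzero variance in every OTU profile (a
    constant row has no defined correlation).  When ``valid_mask`` is given
    (True = originally observed cell), each pairwise correlation uses only
    the samples where *both* OTUs were observed, so filled blanks never
    enter a correlation; pairs with fewer than 3 jointly observed samples
    or degenerate variance get similarity 0.
    """
    if table.n_samples < 3:
        raise ValidationError("need >= 3 samples for Pearson correlation")
    x = table.abundance
    flat = np.where(x.std(axis=1) == 0)[0]
    if flat.size:
        names = [table.otu_ids[i] for i in flat[:5]]
        raise ValidationError(
            f"zero-variance OTU profile(s), cannot correlate: {names}")
    if valid_mask is None:
        r = np.corrcoef(x)
    else:
        if valid_mask.shape != x.shape:
            raise ValidationError("valid_mask shape must match the table")
        r = _pairwise_complete_corr(x, valid_mask)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)  # enforce exact symmetry
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix(list(table.otu_ids), np.abs(r), np.sign(r).astype(int))


def preprocess_table(table: OtuTable, min_present: int | float | str = "majority",
               fill_value: float = 0.01,
               pairwise_valid: bool = True) -> tuple[OtuTable, SimilarityMatrix]:
    """Full Step-I chain: filter -> fill -> log10 -> |Pearson| similarity.

    With ``pairwise_valid`` (default) the correlation for each OTU pair is
    computed over the samples where both OTUs were originally observed;
    the 0.01-filled blanks keep the table log-transformable but do not leak
    into the similarity values, where they would act as shared extreme
    outliers and manufacture spurious links.
    """
    filtered = prevalence_filter(table, min_present)
    mask = filtered.abundance > 0 if pairwise_valid else None
    logged = log10_transform(fill_blanks(filtered, fill_value))
    return logged, pearson_similarity(logged, mask)
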