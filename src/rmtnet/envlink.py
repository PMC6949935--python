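"""Module eigengenes and environment linkage (Step IV).

Each sufficiently large module is summarised by its *eigengene* — the
leading left singular direction of the standardized member-OTU x sample
matrix, i.e. a one-vector, sample-length summary of how the module behaves
across samples.  Eigengenes are correlated with environmental variables
(Pearson, t-based p), clustered into a hierarchy (average linkage on
1 - r), and the community as a whole is related to each variable with a
permutation Mantel test on Bray-Curtis vs single-variable Euclidean
distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average as _average_linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .io_model import OtuTable, SampleMetadata, ValidationError
from .topology import ModulePartition
from .diversity import bray_curtis

#: modules at or below this size are skipped for eigengene analysis
MIN_MODULE_SIZE = 5


@dataclass
class ModuleEigengene:
    """Unit-norm sample-length profile summarising one module."""

    module: int
    eigengene: np.ndarray
    variance_explained: float
    sample_ids: list[str]


@dataclass
class MantelResult:
    variable: str
    mantel_r: float
    p: float
    n_permutations: int
    seed: int


# ---------------------------------------------------------------------------
# eigengenes
# ---------------------------------------------------------------------------

def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValidationError("constant OTU profile inside a module")
    return (x - mean) / sd


def module_eigengene(table: OtuTable, partition: ModulePartition,
                     module: int) -> ModuleEigengene | None:
    """First singular direction of a module's standardized abundance block.

    Member profiles are standardized across samples; the eigengene is the
    leading left singular vector of the samples x members matrix, with its
    sign fixed so the correlation with the module's mean profile is >= 0.
    Modules with <= 5 members are skipped (returns None with a warning).
    """
    members = [o for o, m in partition.assignment.items()
               if m == module and o in table.otu_ids]
    if len(members) <= MIN_MODULE_SIZE:
        warnings.warn(f"module {module} has {len(members)} members "
                      f"(<= {MIN_MODULE_SIZE}); eigengene skipped",
                      stacklevel=2)
        return None
    block = table.subset_otus(members).abundance      # members x samples
    z = _standardize_rows(block)
    u, s, _ = np.linalg.svd(z.T, full_matrices=False)  # samples x members
    eig = u[:, 0]
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return ModuleEigengene(module, eig, var_explained, list(table.sample_ids))


def module_eigengenes(table: OtuTable,
                      partition: ModulePartition) -> list[ModuleEigengene]:
    """Eigengenes of every module with more than MIN_MODULE_SIZE members."""
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for module in sorted(partition.sizes):
            eig = module_eigengene(table, partition, module)
            if eig is not None:
                out.append(eig)
    return out


def module_env_heatmap(eigengenes: list[ModuleEigengene],
                       metadata: SampleMetadata) -> pd.DataFrame:
    """Pearson r and two-tailed p for every module x variable pair.

    Missing metadata values are dropped pairwise; constant variables give
    NaN.  ``significant`` flags p < 0.05 (the starred cells of the heatmap).
    """
    rows = []
    for eig in eigengenes:
        if eig.sample_ids != metadata.sample_ids:
            idx = [eig.sample_ids.index(s) for s in metadata.sample_ids]
            profile = eig.eigengene[idx]
        else:
            profile = eig.eigengene
        for var, vec in metadata.variables.items():
            ok = np.isfinite(vec)
            x, y = profile[ok], vec[ok]
            if x.size < 3 or np.std(y) == 0 or np.std(x) == 0:
                rows.append((eig.module, var, np.nan, np.nan, False))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append((eig.module, var, float(r), float(p), p < 0.05))
    return pd.DataFrame(rows, columns=["module", "variable", "r", "p",
                                       "significant"])


def eigengene_hierarchy(eigengenes: list[ModuleEigengene]) -> tuple[str, np.ndarray]:
    """Average-linkage hierarchy of eigengenes on distance 1 - r.

    Returns (newick string with one leaf per module, scipy linkage matrix).
    """
    if len(eigengenes) < 2:
        raise ValidationError("need >= 2 eigengenes for a hierarchy")
    profiles = np.array([e.eigengene for e in eigengenes])
    r = np.corrcoef(profiles)
    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2, 0.0)
    linkage = _average_linkage(squareform(dist, checks=False))
    labels = [f"M{e.module}" for e in eigengenes]
    tree = TreeNode.from_linkage_matrix(linkage, labels)
    newick = str(tree).strip()
    return newick, linkage


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _lower_triangle(d: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(d.shape[0], k=-1)
    return d[i, j]


def mantel_test(table: OtuTable, variable: np.ndarray, variable_name: str = "",
                n_permutations: int = 999, seed: int = 0) -> MantelResult:
    """One-tailed permutation Mantel test of community vs one variable.

    Community distance is Bray-Curtis on relative abundances at the OTU
    level; variable distance is Euclidean on the standardized variable.
    The statistic is the Pearson correlation of the two lower triangles;
    sample labels of the variable matrix are permuted jointly and
    p = (#{r_perm >= r_obs} + 1) / (n_permutations + 1).
    """
    variable = np.asarray(variable, dtype=float)
    if table.n_samples < 4:
        raise ValidationError("Mantel test needs >= 4 samples")
    ok = np.isfinite(variable)
    if not ok.all():
        table = table.subset_samples(
            [s for s, keep in zip(table.sample_ids, ok) if keep])
        variable = variable[ok]
    sd = variable.std()
    if sd == 0:
        raise ValidationError(
            f"variable {variable_name!r} is constant; Mantel undefined")
    v = (variable - variable.mean()) / sd

    comm = bray_curtis(table)
    x = _lower_triangle(comm)
    x_c = x - x.mean()
    x_norm = np.sqrt((x_c ** 2).sum())

    def lower_r(vec: np.ndarray) -> float:
        d = np.abs(vec[:, None] - vec[None, :])
        y = _lower_triangle(d)
        y_c = y - y.mean()
        denom = x_norm * np.sqrt((y_c ** 2).sum())
        return float((x_c * y_c).sum() / denom)

    r_obs = lower_r(v)
    rng = np.random.default_rng(seed)
    n = v.size
    i_idx, j_idx = np.tril_indices(n, k=-1)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    vp = v[perms]                                    # (P, n)
    y = np.abs(vp[:, i_idx] - vp[:, j_idx])          # (P, m)
    y_c = y - y.mean(axis=1, keepdims=True)
    denom = x_norm * np.sqrt((y_c ** 2).sum(axis=1))
    r_perm = (y_c @ x_c) / denom
    p = (np.count_nonzero(r_perm >= r_obs) + 1) / (n_permutations + 1)
    return MantelResult(variable_name, r_obs, float(p), n_permutations, seed)


def mantel_table(table: OtuTable, metadata: SampleMetadata,
                 n_permutations: int = 999, seed: int = 0) -> pd.DataFrame:
    """One Mantel row per environmental variable."""
    rows = []
    for k, var in enumerate(metadata.variable_names()):
        res = mantel_test(table, metadata.variables[var], var,
                          n_permutations, seed + k)
        rows.append((var, res.mantel_r, res.p, res.n_permutations))
    return pd.DataFrame(rows, columns=["variable", "mantel_r", "p",
                                       "n_permutations"])


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_ttests(metadata: SampleMetadata, group: dict[str, str] | None = None,
                 welch: bool = False) -> pd.DataFrame:
    """Two-sample t-test per variable between exactly two groups.

    Student's pooled-variance t by default (``welch=True`` for unequal
    variances); two-tailed p with the usual 0.05/0.01/0.001 star tiers.
    """
    group = group or metadata.group
    if not group:
        raise ValidationError("no group labels available")
    labels = sorted(set(group.values()))
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {labels}")
    masks = {lab: np.array([group.get(s) == lab for s in metadata.sample_ids])
             for lab in labels}
    rows = []
    for var, vec in metadata.variables.items():
        a = vec[masks[labels[0]] & np.isfinite(vec)]
        b = vec[masks[labels[1]] & np.isfinite(vec)]
        if a.size < 2 or b.size < 2:
            raise ValidationError(
                f"variable {var!r}: each group needs >= 2 values")
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append((var,
                     f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                     f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
                     float(t), float(p), _stars(p)))
    return pd.DataFrame(rows, columns=["variable", labels[0], labels[1],
                                       "t", "p", "stars"])


def summary_ttest(mean1: float, sd1: float, n1: int,
                  mean2: float, sd2: float, n2: int,
                  welch: bool = False) -> tuple[float, float]:
    """Two-sample t-test from printed summary statistics (mean, sd, n)."""
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=not welch)
    return float(t), float(p)
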