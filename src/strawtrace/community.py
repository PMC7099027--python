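"""Community-to-carbon-flux linkage statistics.

Links genus-level community composition to the straw-derived C time series:
relative abundance, Bray-Curtis dissimilarity matrices, a permutation Mantel
test between distance matrices, and a genus × SOC-fraction Spearman
correlation table with significance stars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Sample labels of the two inputs do not match."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative dissimilarity matrix with sample labels."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries, row-major (scipy condensed order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass(frozen=True)
class MantelResult:
    """Mantel statistic, one-sided permutation p-value and bookkeeping."""

    r: float
    p: float
    n_perm: int
    method: str
    n: int


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Column-normalise a taxa × samples count table to proportions.

    Samples with zero total count are dropped with a log entry; taxa order
    is preserved.  Idempotent.
    """
    if (table.values < 0).any():
        raise ValueError("abundance table has negative entries")
    sums = table.sum(axis=0)
    zero = sums[sums == 0].index.tolist()
    if zero:
        logger.warning("dropping zero-sum samples: %s", zero)
        table = table.drop(columns=zero)
        sums = sums.drop(zero)
    return table.div(sums, axis=1)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 − 2·Σmin(xᵢ,yᵢ)/Σ(xᵢ+yᵢ)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("Bray-Curtis requires non-negative vectors")
    total = float(np.sum(x + y))
    if total == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return 1.0 - 2.0 * float(np.minimum(x, y).sum()) / total


def bray_curtis_matrix(samples: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis distance matrix for a samples × features table."""
    m = samples.to_numpy(dtype=float)
    if np.any(m < 0):
        raise ValueError("Bray-Curtis requires non-negative entries")
    if np.any(m.sum(axis=1) == 0):
        raise ValueError("all-zero sample rows make Bray-Curtis undefined")
    d = squareform(pdist(m, metric="braycurtis"))
    return DistanceMatrix(tuple(samples.index), d)


def euclidean_matrix(samples: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance matrix for a samples × features table."""
    d = squareform(pdist(samples.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(tuple(samples.index), d)


def _rank_square(d: DistanceMatrix) -> np.ndarray:
    """Square matrix of average ranks of the condensed entries.

    Jointly permuting rows and columns permutes the condensed vector, so the
    rank of every entry is invariant under permutation; ranking once and
    indexing the square rank matrix per permutation is exact.
    """
    ranks = stats.rankdata(d.condensed())
    return squareform(ranks)


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, *, n_perm: int = 999,
           method: str = "spearman", alternative: str = "greater",
           seed=None) -> MantelResult:
    """Permutation Mantel test between two distance matrices.

    The statistic is the Spearman (default) or Pearson correlation of the
    n(n−1)/2 upper-triangle entries.  The null distribution is built by
    jointly permuting the rows and columns of ``d2``; the p-value uses the
    add-one rule p = (1 + #{r* ≥ r}) / (1 + n_perm), one-sided greater by
    default, with ties in the permuted statistics counted as ≥.
    """
    if d1.labels != d2.labels:
        raise AlignmentError(
            f"sample labels differ: {d1.labels[:4]}... vs {d2.labels[:4]}..."
        )
    n = d1.n
    if n < 4:
        raise ValueError(f"Mantel test needs at least 4 samples, got {n}")
    if n_perm < 99:
        raise ValueError(f"n_perm must be at least 99, got {n_perm}")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"alternative must be 'greater' or 'two-sided'")

    if method == "spearman":
        sq1, sq2 = _rank_square(d1), _rank_square(d2)
    else:
        sq1, sq2 = d1.values, d2.values
    iu = np.triu_indices(n, k=1)
    x = sq1[iu]
    y = sq2[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    xz = (x - x.mean()) / x.std()
    # the permuted condensed vector is a rearrangement of y, so its mean and
    # std are permutation-invariant and can be fixed once
    y_mean, y_std = y.mean(), y.std()
    m = x.size
    r_obs = float(xz @ ((y - y_mean) / y_std)) / m

    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for i in range(n_perm):
        p = rng.permutation(n)
        yp = sq2[np.ix_(p, p)][iu]
        r_perm[i] = float(xz @ ((yp - y_mean) / y_std)) / m

    eps = 1e-12
    if alternative == "greater":
        count = int(np.sum(r_perm >= r_obs - eps))
    else:
        count = int(np.sum(np.abs(r_perm) >= abs(r_obs) - eps))
    p_val = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p=p_val, n_perm=n_perm, method=method, n=n)


@dataclass(frozen=True)
class CorrelationTable:
    """Genus × fraction Spearman table: ρ, raw p and significance stars."""

    rho: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    q: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per genus, 'rho (stars)' style columns."""
        out = pd.DataFrame(index=self.rho.index)
        for col in self.rho.columns:
            out[col] = [
                "" if np.isnan(r) else f"{r:.3f}{s}"
                for r, s in zip(self.rho[col], self.stars[col])
            ]
        out.index.name = "genus"
        return out


def significance_stars(p) -> np.ndarray:
    """Map p-values to the conventional codes: * <0.05, ** <0.01, *** <0.001."""
    p = np.asarray(p, dtype=float)
    return np.select([p < 0.001, p < 0.01, p < 0.05], ["***", "**", "*"],
                     default="").astype(object)


def spearman_table(genus_abund: pd.DataFrame, fractions: pd.DataFrame, *,
                   bh_correct: bool = False) -> CorrelationTable:
    """Spearman correlation of each genus with each straw-derived fraction.

    ``genus_abund`` is genera × samples; ``fractions`` is samples ×
    fraction labels (straw-derived C values per sample).  ρ uses average
    ranks; p is the standard t-approximation.  A genus or fraction that is
    constant across samples yields a missing cell (NaN, no star).  Raw
    p-values are reported by default; ``bh_correct=True`` adds
    Benjamini-Hochberg adjusted values in ``q`` (stars stay on raw p).
    """
    samples = list(genus_abund.columns)
    if list(fractions.index) != samples:
        if set(fractions.index) == set(samples):
            fractions = fractions.loc[samples]
        else:
            raise AlignmentError(
                "genus table samples and fraction table samples differ"
            )
    if len(samples) < 4:
        raise ValueError(f"need at least 4 paired samples, got {len(samples)}")

    genera = list(genus_abund.index)
    cols = list(fractions.columns)
    rho = pd.DataFrame(np.nan, index=genera, columns=cols)
    pval = pd.DataFrame(np.nan, index=genera, columns=cols)
    for g in genera:
        x = genus_abund.loc[g].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("genus %s constant across samples: cells missing", g)
            continue
        for c in cols:
            y = fractions[c].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                continue
            r, p = stats.spearmanr(x, y)
            rho.loc[g, c] = r
            pval.loc[g, c] = p
    stars = pval.copy().astype(object)
    stars[:] = significance_stars(pval.to_numpy())
    stars[pval.isna()] = ""
    q = None
    if bh_correct:
        flat = pval.to_numpy().ravel()
        mask = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        if mask.any():
            adj[mask] = stats.false_discovery_control(flat[mask], method="bh")
        q = pd.DataFrame(adj.reshape(pval.shape), index=genera, columns=cols)
    return CorrelationTable(rho=rho, p=pval, stars=stars, q=q)
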