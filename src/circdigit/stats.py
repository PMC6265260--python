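"""Cross-platform concordance and expression-profile clustering.

Concordance between two quantification platforms (e.g. digital counts vs
RNA-seq RPM) is assessed two ways: ordinary least-squares regression on the
paired continuous values (reporting R^2 = squared Pearson correlation and a
two-tailed slope p-value), and dichotomization at pre-defined
expressed/not-expressed cutoffs followed by a two-tailed Fisher's exact test
on the resulting 2x2 table. Expression profiles are clustered by z-scoring
each target across samples and running agglomerative UPGMA (unweighted
average linkage) on the Pearson correlation distance d = 1 - r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def fit_simple_regression(x, y) -> RegressionFit:
    """OLS fit of y on x; R^2 is the squared Pearson correlation and the
    p-value is the two-tailed t test of slope = 0 with n - 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = sps.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=int(x.size),
    )


@dataclass
class Contingency2x2:
    """Detected/not-detected cross-tabulation of two platforms.

    Layout: rows = platform A expressed/not, columns = platform B
    expressed/not; ``a`` counts targets expressed on both.
    """

    a: int
    b: int
    c: int
    d: int
    p_two_tailed: float = 1.0

    @property
    def table(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def fisher_exact_2x2(table) -> float:
    """Two-tailed Fisher's exact p for a 2x2 table of nonnegative integers."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
            raise ValueError("cells must be nonnegative integers")
        arr = arr.astype(int)
    if arr.sum() == 0:
        raise ValueError("table is empty (all zeros)")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def dichotomize_and_crosstab(
    values_a,
    cutoff_a: float,
    values_b,
    cutoff_b: float,
    labels: list[str] | None = None,
) -> tuple[Contingency2x2, list[str], list[str]]:
    """Cross-tabulate expressed/not-expressed calls from two platforms.

    A target is "expressed" on a platform when its value >= the platform's
    cutoff. Returns the contingency table (with its two-tailed Fisher p) and
    the platform-specific detection lists (A-only, B-only).
    """
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("paired vectors must have equal length")
    if labels is None:
        labels = [str(i) for i in range(va.size)]
    ea = va >= cutoff_a
    eb = vb >= cutoff_b
    tab = Contingency2x2(
        a=int((ea & eb).sum()),
        b=int((ea & ~eb).sum()),
        c=int((~ea & eb).sum()),
        d=int((~ea & ~eb).sum()),
    )
    tab.p_two_tailed = fisher_exact_2x2(tab.table)
    a_only = [labels[i] for i in np.nonzero(ea & ~eb)[0]]
    b_only = [labels[i] for i in np.nonzero(~ea & eb)[0]]
    return tab, a_only, b_only


# ---- clustering ------------------------------------------------------------


def zscore_rows(matrix: pd.DataFrame, ddof: int = 0) -> tuple[pd.DataFrame, list[str]]:
    """Center each row to mean 0 and scale to SD 1 (population SD by default).

    Constant rows are set to all-zero and returned in the flag list.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples to z-score")
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=ddof)
    constant = list(matrix.index[sds == 0])
    safe_sds = sds.replace(0, 1.0)
    z = matrix.sub(means, axis=0).div(safe_sds, axis=0)
    z.loc[constant] = 0.0
    return z, constant


@dataclass
class Dendrogram:
    """UPGMA tree: leaves plus ordered (node, node, height) merges.

    Leaf i is node i; the merge at position k creates node n_leaves + k.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]
    dropped: list[str] = field(default_factory=list)

    @property
    def linkage_matrix(self) -> np.ndarray:
        n = len(self.leaves)
        sizes = {}
        rows = []
        for k, (i, j, h) in enumerate(self.merges):
            size = sizes.get(i, 1) + sizes.get(j, 1)
            sizes[n + k] = size
            rows.append([i, j, h, size])
        return np.asarray(rows, dtype=float)

    def cut(self, k: int) -> dict[str, int]:
        """Cut into k flat clusters; returns leaf label -> cluster id."""
        assignments = hierarchy.fcluster(self.linkage_matrix, k, criterion="maxclust")
        return dict(zip(self.leaves, (int(c) for c in assignments)))

    def to_newick(self) -> str:
        from io import StringIO

        from skbio import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.leaves)
        buf = StringIO()
        tree.write(buf, format="newick")
        return buf.getvalue().strip()


def pearson_distance_matrix(vectors: pd.DataFrame) -> pd.DataFrame:
    """d = 1 - Pearson r between the columns of ``vectors``."""
    corr = np.corrcoef(vectors.values, rowvar=False)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=vectors.columns, columns=vectors.columns)


def pearson_average_linkage(matrix: pd.DataFrame, axis: str = "samples") -> Dendrogram:
    """Cluster samples (columns) or targets (rows) by UPGMA on 1 - Pearson r.

    Constant vectors (undefined correlation) are dropped and recorded on the
    result; labels are sorted lexicographically before clustering so ties
    break deterministically by label order.
    """
    if axis not in ("samples", "targets"):
        raise ValueError("axis must be 'samples' or 'targets'")
    data = matrix if axis == "samples" else matrix.T
    # columns are the items to cluster
    sds = data.std(axis=0, ddof=0)
    dropped = [str(c) for c in data.columns[sds == 0]]
    data = data.loc[:, sds > 0]
    if data.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant items to cluster")
    data = data[sorted(data.columns, key=str)]
    dist = pearson_distance_matrix(data)
    condensed = squareform(dist.values, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    merges = [
        (int(row[0]), int(row[1]), float(row[2])) for row in linkage
    ]
    return Dendrogram(
        leaves=[str(c) for c in data.columns], merges=merges, dropped=dropped
    )
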