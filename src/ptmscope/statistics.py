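"""Feature assembly, normalization, PCA, k-means and PTM correlations.

Rows are systems (PTM variants); columns are the nine general descriptors
followed by one binary indicator per modifiable site. The classification
chain — pairwise normalization, PCA on the correlation matrix, k-means on
the leading component scores — separates variants whose interfaces detach
from those that stay compact, and the Pearson correlation of each site
indicator with each descriptor attributes the effect to individual sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .descriptors import DESCRIPTOR_NAMES, DescriptorVector
from .model_io import PTMPattern

__all__ = [
    "FeatureMatrix",
    "PCAResult",
    "ClusterAssignment",
    "CorrelationMatrix",
    "assemble_features",
    "aggregate_hexamer",
    "pairwise_normalize",
    "run_pca",
    "kmeans_on_pcs",
    "correlate_ptm",
]


@dataclass
class FeatureMatrix:
    """Systems x (descriptors + site indicators) table."""

    data: pd.DataFrame
    indicator_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in self.indicator_columns:
            if c not in self.data.columns:
                raise ValueError(f"indicator column {c!r} missing")
            vals = set(np.unique(self.data[c].to_numpy()))
            if not vals <= {0, 1, 0.0, 1.0}:
                raise ValueError(f"indicator column {c!r} must be binary")

    @property
    def descriptor_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.indicator_columns]

    @property
    def n_systems(self) -> int:
        return len(self.data)

    def descriptors_only(self) -> "FeatureMatrix":
        """The matrix restricted to the general descriptor columns.

        The wild-type/modified validation analysis classifies on the nine
        general parameters alone; indicator columns would leak the answer.
        """
        return FeatureMatrix(data=self.data[self.descriptor_columns].copy())


def assemble_features(
    descriptors: list[DescriptorVector],
    patterns: list[PTMPattern],
    names: list[str] | None = None,
) -> FeatureMatrix:
    """One row per system: nine general parameters then site indicators.

    All patterns must share the same ordered site list; row labels default
    to each pattern's name.
    """
    if len(descriptors) != len(patterns):
        raise ValueError("descriptor and pattern lists differ in length")
    if not patterns:
        raise ValueError("no systems")
    site_labels = patterns[0].labels
    for p in patterns:
        if p.labels != site_labels:
            raise ValueError("inconsistent site lists across patterns")
    rows = []
    for d, p in zip(descriptors, patterns):
        row = d.as_row()
        row.update(dict(zip(site_labels, (float(s) for s in p.state))))
        rows.append(row)
    index = names if names is not None else [p.name for p in patterns]
    df = pd.DataFrame(rows, index=index, columns=list(DESCRIPTOR_NAMES) + site_labels)
    return FeatureMatrix(data=df, indicator_columns=site_labels)


def aggregate_hexamer(members: list[DescriptorVector]) -> DescriptorVector:
    """Element-wise mean descriptor vector over assembly members.

    Higher oligomers built from several copies of the dimeric unit are
    represented by the average of the member descriptors.
    """
    if not members:
        raise ValueError("aggregate_hexamer requires at least one member")
    rows = [m.as_row() for m in members]
    mean = {k: float(np.mean([r[k] for r in rows])) for k in rows[0]}
    return DescriptorVector.from_row(mean)


def pairwise_normalize(
    m: FeatureMatrix, pairs: list[tuple[str, str]]
) -> FeatureMatrix:
    """Normalize each descriptor within (wild-type, modified) row pairs.

    Each variable's two values are divided by their pair mean, so every
    normalized pair sums to 2 and the within-pair ratio is preserved.
    Indicator columns are left untouched. A zero pair mean maps both
    entries to 1 with a warning.
    """
    seen: set[str] = set()
    for a, b in pairs:
        for r in (a, b):
            if r not in m.data.index:
                raise KeyError(f"row {r!r} not in feature matrix")
            if r in seen:
                raise ValueError(f"row {r!r} appears in more than one pair")
            seen.add(r)
    out = m.data.copy()
    for a, b in pairs:
        for col in m.descriptor_columns:
            va, vb = float(out.at[a, col]), float(out.at[b, col])
            mean = (va + vb) / 2.0
            if mean == 0.0:
                warnings.warn(f"pair ({a}, {b}) has zero mean in {col!r}; set to 1")
                out.at[a, col] = out.at[b, col] = 1.0
            else:
                out.at[a, col] = va / mean
                out.at[b, col] = vb / mean
    return FeatureMatrix(data=out, indicator_columns=list(m.indicator_columns))


@dataclass
class PCAResult:
    """Loadings, variance shares and scores of a feature-matrix PCA."""

    loadings: pd.DataFrame  # variables x PCs, unit-norm columns
    explained_variance: np.ndarray  # fraction per PC
    sdev: np.ndarray  # standard deviation per PC
    scores: pd.DataFrame  # systems x PCs
    scaled: bool = True

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.explained_variance)

    def retained(self, sdev_threshold: float = 1.0) -> int:
        """Number of components with standard deviation above threshold."""
        return int(np.sum(self.sdev > sdev_threshold))


def run_pca(m: FeatureMatrix, scale: bool = True) -> PCAResult:
    """Principal component analysis of the feature matrix.

    Columns are centered and, when ``scale`` is true (the default —
    descriptors mix Å², kJ/mol, counts and probabilities), divided by
    their standard deviation, which makes this a correlation-matrix PCA.
    Constant columns are dropped with a warning under scaling. Loadings
    are the unit-norm eigenvectors, signed so each column's
    largest-magnitude entry is positive.
    """
    if m.n_systems < 2:
        raise ValueError("PCA needs at least 2 systems")
    df = m.data.astype(float)
    if df.isna().to_numpy().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        warnings.warn(f"dropping rows with missing descriptors: {bad}")
        df = df.dropna(axis=0)
    x = df.to_numpy()
    mu = x.mean(axis=0)
    xc = x - mu
    cols = list(df.columns)
    if scale:
        sd = xc.std(axis=0, ddof=1)
        keep = sd > 1e-12
        if not keep.all():
            dropped = [c for c, k in zip(cols, keep) if not k]
            warnings.warn(f"dropping constant columns under scaling: {dropped}")
            xc = xc[:, keep]
            cols = [c for c, k in zip(cols, keep) if k]
            sd = sd[keep]
        xc = xc / sd
    n = xc.shape[0]
    u, svals, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = svals**2 / (n - 1)
    loadings = vt.T
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
    scores = xc @ loadings
    pcs = [f"PC{k + 1}" for k in range(loadings.shape[1])]
    total_var = eigvals.sum()
    explained = eigvals / total_var if total_var > 0 else eigvals
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=cols, columns=pcs),
        explained_variance=explained,
        sdev=np.sqrt(eigvals),
        scores=pd.DataFrame(scores, index=df.index, columns=pcs),
        scaled=scale,
    )


@dataclass
class ClusterAssignment:
    """k-means partition of the systems in PC-score space."""

    k: int
    labels: pd.Series
    centroids: np.ndarray
    inertia: float
    metadata: dict = field(default_factory=dict)


def kmeans_on_pcs(
    p: PCAResult,
    n_pcs: int = 3,
    k: int = 2,
    restarts: int = 50,
    seed: int = 0,
) -> ClusterAssignment:
    """k-means on the first ``n_pcs`` component scores.

    Lloyd's algorithm with k-means++ initialization, best of ``restarts``
    runs by inertia; fully deterministic given ``seed``.
    """
    if n_pcs > p.scores.shape[1]:
        raise ValueError("n_pcs exceeds available components")
    x = p.scores.iloc[:, :n_pcs].to_numpy()
    if k > len(x):
        raise ValueError("k exceeds the number of systems")
    km = KMeans(
        n_clusters=k,
        n_init=restarts,
        random_state=seed,
        algorithm="lloyd",
        init="k-means++",
    ).fit(x)
    return ClusterAssignment(
        k=k,
        labels=pd.Series(km.labels_, index=p.scores.index, name="cluster"),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        metadata={
            "algorithm": "lloyd",
            "init": "k-means++",
            "restarts": restarts,
            "seed": seed,
            "n_pcs": n_pcs,
        },
    )


@dataclass
class CorrelationMatrix:
    """Pearson r of each site indicator against each descriptor."""

    r: pd.DataFrame  # sites x descriptors
    significant: pd.DataFrame  # boolean, |r| > threshold
    threshold: float = 0.30


def correlate_ptm(m: FeatureMatrix, threshold: float = 0.30) -> CorrelationMatrix:
    """Correlate every site indicator with every descriptor column.

    Pearson r; entries with |r| above ``threshold`` are flagged
    significant. A zero-variance column yields r = 0 (not significant)
    with a warning.
    """
    if m.n_systems < 3:
        raise ValueError("correlation needs at least 3 systems")
    if not m.indicator_columns:
        raise ValueError("no indicator columns present")
    sites = m.indicator_columns
    descs = m.descriptor_columns
    r = pd.DataFrame(0.0, index=sites, columns=descs)
    for s in sites:
        xs = m.data[s].to_numpy(dtype=float)
        for d in descs:
            xd = m.data[d].to_numpy(dtype=float)
            if xs.std() < 1e-12 or xd.std() < 1e-12:
                warnings.warn(f"zero variance in {s!r} or {d!r}; r set to 0")
                r.at[s, d] = 0.0
            else:
                r.at[s, d] = float(np.corrcoef(xs, xd)[0, 1])
    return CorrelationMatrix(
        r=r, significant=r.abs() > threshold, threshold=threshold
    )
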