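"""Linear baselines: PCA explained variance and the feature correlation matrix.

These quantify what a *linear* dimensionality analysis says about the same
data: the number of principal components needed to explain 90% of the
variance (k90) and the pairwise Pearson correlations.  A gap between k90 and
the box-counting estimate indicates non-linear correspondence between
features.

PCA operates on mean-centered but not re-standardized features — every
feature is already scaled to [0, 1], so covariance-PCA keeps eigenvalues on
a comparable scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass(frozen=True)
class PCABaselineResult:
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # rows = components, columns = features
    cumulative_inertia: np.ndarray
    k90: int
    feature_names: tuple[str, ...]
    dominant_features: tuple[str, ...]

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.eigenvectors.T,
            index=self.feature_names,
            columns=[f"PC{i + 1}" for i in range(len(self.eigenvalues))],
        )


def _as_frame(dataset) -> pd.DataFrame:
    if hasattr(dataset, "records"):
        from .preprocess import FEATURES

        return dataset.records[FEATURES]
    if isinstance(dataset, pd.DataFrame):
        return dataset
    arr = np.asarray(dataset, dtype=float)
    return pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])


def pca_baseline(dataset) -> PCABaselineResult:
    """Covariance-PCA of the feature table.

    Reports per-component variances (eigenvalues), unit-length loadings with
    the sign fixed so the largest-magnitude loading is positive, the running
    fraction of explained variance, the most significant feature of each
    component, and k90 — the smallest component count reaching 90%.
    """
    df = _as_frame(dataset)
    X = df.to_numpy(dtype=float)
    n, d = X.shape
    if n <= d:
        raise ValueError(f"need more records than features (n={n}, d={d})")
    pca = PCA(n_components=d)
    pca.fit(X)
    vecs = pca.components_.copy()
    for i in range(d):
        j = int(np.argmax(np.abs(vecs[i])))
        if vecs[i, j] < 0:
            vecs[i] = -vecs[i]
    cum = np.cumsum(pca.explained_variance_ratio_)
    k90 = int(np.searchsorted(cum, 0.9) + 1)
    dominant = tuple(df.columns[int(np.argmax(np.abs(v)))] for v in vecs)
    return PCABaselineResult(
        eigenvalues=pca.explained_variance_,
        eigenvectors=vecs,
        cumulative_inertia=cum,
        k90=k90,
        feature_names=tuple(df.columns),
        dominant_features=dominant,
    )


def correlation_matrix(dataset) -> pd.DataFrame:
    """Pairwise Pearson correlations between the features.

    Symmetric with unit diagonal; entries involving a zero-variance feature
    are undefined and reported as missing (NaN), never as 0.
    """
    df = _as_frame(dataset)
    if len(df) < 2:
        raise ValueError("need at least 2 records")
    return df.corr(method="pearson")
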