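"""Feature screening by two-sample t-tests and PCA reduction.

Each feature column is compared between two groups with an independent
two-sample Student's t-test (pooled variance); columns with two-tailed
p below the significance level (0.01 by default) are selected.  No
multiple-testing correction is applied by design — the false-positive
burden (about one column in a hundred at the default level) is instead
absorbed by projecting the selected columns onto a small number of
principal components before classification.  A Bonferroni flag exists but
defaults off.

PCA is fitted on z-scored training rows only and both training and test
rows are projected onto the top-k components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "count_feature_grid",
    "expected_false_positives",
    "SelectionResult",
    "ttest_screen",
    "PCAProjection",
    "pca_fit_transform",
]


def count_feature_grid(
    channels: int,
    bands: int,
    single_features: int,
    cross_features: int,
    conditions: int,
) -> int:
    """Number of candidate feature columns for a given analysis grid.

    Single-channel features contribute one column per
    (channel, band, feature, condition) cell; cross-channel features have
    no channel axis.  The default grid (15 channels, 6 bands including the
    raw signal, 11 single-channel features, 1 cross-channel feature, 6
    conditions) yields 5976 columns.
    """
    for v in (channels, bands, single_features, cross_features, conditions):
        if v < 0:
            raise ValueError("grid counts must be non-negative")
    return channels * bands * single_features * conditions + bands * cross_features * conditions


def expected_false_positives(m: int, alpha: float) -> int:
    """Expected number of null columns passing the screen, ``round(m * alpha)``."""
    if m < 0:
        raise ValueError("m must be non-negative")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    return int(round(m * alpha))


@dataclass
class SelectionResult:
    """Per-column t statistics, p-values and the selected mask."""

    columns: list
    t: np.ndarray
    p: np.ndarray
    selected: np.ndarray
    alpha: float
    group_pair: tuple

    @property
    def selected_columns(self) -> list:
        return [c for c, keep in zip(self.columns, self.selected) if keep]

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"column": self.columns, "t": self.t, "p": self.p, "selected": self.selected}
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def ttest_screen(
    features: pd.DataFrame,
    group_a: str,
    group_b: str,
    alpha: float = 0.01,
    equal_var: bool = True,
    bonferroni: bool = False,
) -> SelectionResult:
    """Screen every feature column for a group difference.

    ``features`` is a feature matrix with a ``group`` column.  Columns whose
    pooled within-group variance is zero are assigned t = 0, p = 1 (they
    carry no usable signal for this test).  With ``bonferroni=True`` the
    threshold becomes ``alpha / m``.
    """
    cols = [c for c in features.columns if c != "group"]
    a = features.loc[features["group"] == group_a, cols].to_numpy(dtype=float)
    b = features.loc[features["group"] == group_b, cols].to_numpy(dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least two subjects")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant columns trigger a precision-loss warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    degenerate = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    level = alpha / len(cols) if bonferroni else alpha
    # alpha >= 1 is the "keep everything" boundary; strict p < level would
    # still exclude the degenerate p = 1 columns
    selected = np.ones(len(cols), dtype=bool) if level >= 1.0 else p < level
    return SelectionResult(
        columns=cols,
        t=t,
        p=p,
        selected=selected,
        alpha=alpha,
        group_pair=(group_a, group_b),
    )


@dataclass
class PCAProjection:
    """Fitted projection parameters (training rows only)."""

    components: np.ndarray  # (k, d) orthonormal rows
    magnitudes: np.ndarray  # explained variances, non-increasing
    mean: np.ndarray
    sd: np.ndarray | None
    kept_columns: np.ndarray
    k: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = np.asarray(X, dtype=float)[:, self.kept_columns] - self.mean
        if self.sd is not None:
            Z = Z / self.sd
        return Z @ self.components.T

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "components": self.components.tolist(),
            "magnitudes": self.magnitudes.tolist(),
            "mean": self.mean.tolist(),
            "sd": None if self.sd is None else self.sd.tolist(),
            "kept_columns": self.kept_columns.tolist(),
        }


def pca_fit_transform(
    train: np.ndarray,
    test: np.ndarray | None,
    k: int,
    scale: bool = True,
) -> tuple[np.ndarray, np.ndarray | None, PCAProjection]:
    """Fit PCA on (optionally z-scored) training rows; project both sets.

    Normalisation statistics come from the training rows alone, so held-out
    rows never leak into the fit.  Zero-variance training columns are
    dropped with a warning.  ``k`` must not exceed ``min(n_train - 1, d)``.
    """
    train = np.asarray(train, dtype=float)
    n, d = train.shape
    var = train.var(axis=0)
    kept = np.flatnonzero(var > 0)
    if kept.size < d:
        warnings.warn(
            f"dropping {d - kept.size} zero-variance column(s) before PCA",
            stacklevel=2,
        )
    if k > min(n - 1, kept.size):
        raise ValueError(
            f"k={k} exceeds min(n_train-1, d)={min(n - 1, kept.size)}"
        )
    Xt = train[:, kept]
    mean = Xt.mean(axis=0)
    sd = Xt.std(axis=0, ddof=1) if scale else None
    Z = (Xt - mean) / sd if scale else Xt - mean

    pca = PCA(n_components=k, svd_solver="full")
    Ztr = pca.fit_transform(Z)
    proj = PCAProjection(
        components=pca.components_,
        magnitudes=pca.explained_variance_,
        mean=mean,
        sd=sd,
        kept_columns=kept,
        k=k,
    )
    Zte = proj.transform(np.asarray(test, dtype=float)) if test is not None else None
    return Ztr, Zte, proj
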