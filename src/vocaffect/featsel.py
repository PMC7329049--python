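"""Dimensionality screening of the acoustic parameters.

Varimax-rotated PCA on the correlation matrix of the 15 acoustic
parameters, variance-inflation-factor (VIF) collinearity diagnostics, and
selection of the six modelling features (SCoG, duration, f0 mean, f0 s.d.,
HNR mean, HNR max).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The six features carried into every downstream model.
DEFAULT_SELECTED = ("scog", "duration", "f0_mean", "f0_sd", "hnr_mean", "hnr_max")


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # feature x retained component, varimax-rotated
    variance_explained: np.ndarray  # fraction per retained component (pre-rotation order)
    retained: list[int]
    all_variance: np.ndarray        # fraction for every component
    n_rows_used: int


@dataclass
class VIFReport:
    vif: pd.Series

    def __getitem__(self, feature: str) -> float:
        return float(self.vif[feature])


@dataclass
class SelectedFeatureSet:
    features: tuple[str, ...]

    def __iter__(self):
        return iter(self.features)


def _complete_rows(table: pd.DataFrame) -> pd.DataFrame:
    clean = table.dropna()
    dropped = len(table) - len(clean)
    if dropped:
        warnings.warn(f"dropped {dropped} incomplete rows before decomposition",
                      stacklevel=3)
    return clean


def varimax(loadings: np.ndarray, *, kaiser: bool = True,
            tol: float = 1e-6, max_iter: int = 100) -> np.ndarray:
    """Orthogonal varimax rotation of a loading matrix.

    Standard SVD-sweep algorithm; with Kaiser normalization each row is
    scaled to unit communality before rotation and scaled back after.
    Rotation is a right-multiplication by an orthogonal matrix, so row
    communalities and total explained variance are preserved.
    """
    L = np.array(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L
    comm = np.sqrt((L ** 2).sum(axis=1))
    if kaiser:
        safe = np.where(comm > 0, comm, 1.0)
        L = L / safe[:, None]
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        d_old = d
        B = L @ R
        U, s, Vt = np.linalg.svd(
            L.T @ (B ** 3 - B @ np.diag((B ** 2).sum(axis=0)) / p))
        R = U @ Vt
        d = s.sum()
        if d_old != 0 and (d - d_old) / d < tol:
            break
    L = L @ R
    if kaiser:
        L = L * safe[:, None]
    return L


def pca_varimax(feature_table: pd.DataFrame, *,
                variance_rule: float = 0.10,
                min_components: int = 2) -> PCAResult:
    """PCA of the feature correlation matrix with varimax on retained loadings.

    Components explaining more than ``variance_rule`` of the total variance
    are retained; if fewer than ``min_components`` qualify (near-spherical
    data) the top ``min_components`` are kept with a warning. Features are
    standardized internally, so the decomposition is invariant to affine
    rescaling of any column and to row order.
    """
    clean = _complete_rows(feature_table)
    if len(clean) < 2:
        raise ValueError("need at least 2 complete rows")
    X = clean.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    const = np.flatnonzero(sd == 0)
    if const.size:
        raise ValueError(
            f"constant column(s): {', '.join(clean.columns[const])}")
    Xs = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Xs, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    frac = eigval / eigval.sum()
    retained = [i for i, f in enumerate(frac) if f > variance_rule]
    if len(retained) < min_components:
        warnings.warn(
            f"only {len(retained)} components exceed the {variance_rule:.0%} "
            f"variance rule; retaining the top {min_components}", stacklevel=2)
        retained = list(range(min_components))
    raw = eigvec[:, retained] * np.sqrt(eigval[retained])
    rotated = varimax(raw)
    loadings = pd.DataFrame(
        rotated, index=clean.columns,
        columns=[f"PC{i + 1}" for i in retained])
    return PCAResult(loadings=loadings, variance_explained=frac[retained],
                     retained=retained, all_variance=frac,
                     n_rows_used=len(clean))


def vif(feature_table: pd.DataFrame, subset=None) -> VIFReport:
    """Variance inflation factors: VIF_j = 1 / (1 - R²_j).

    R²_j comes from an ordinary least-squares regression of feature j on
    the remaining features of ``subset`` (plus an intercept). An exactly
    collinear subset yields infinite VIF rather than an exception.
    """
    cols = list(subset) if subset is not None else list(feature_table.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 features")
    clean = _complete_rows(feature_table[cols])
    if len(clean) <= len(cols):
        raise ValueError("need more rows than features")
    X = clean.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(cols):
        y = X[:, j]
        others = np.column_stack(
            [np.ones(len(X))] + [X[:, m] for m in range(len(cols)) if m != j])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
        out[name] = np.inf if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return VIFReport(vif=pd.Series(out))


def select_features(pca: PCAResult, vif_report: VIFReport | None = None,
                    *, feature_table: pd.DataFrame | None = None,
                    policy: str = "replicate",
                    vif_threshold: float = 5.0,
                    n_per_component: int = 1) -> SelectedFeatureSet:
    """Choose modelling features from the rotated loadings.

    ``policy='replicate'`` returns the canonical six-feature set. The
    generic policy walks the retained components and keeps, per component,
    the highest-loading features whose running within-set VIF stays below
    ``vif_threshold`` (checked against ``feature_table``).
    """
    if policy == "replicate":
        missing = [f for f in DEFAULT_SELECTED if f not in pca.loadings.index]
        if missing:
            raise ValueError(f"feature table lacks {missing}")
        return SelectedFeatureSet(DEFAULT_SELECTED)
    if feature_table is None:
        raise ValueError("generic policy needs the feature table for VIF checks")
    chosen: list[str] = []
    for comp in pca.loadings.columns:
        ranked = pca.loadings[comp].abs().sort_values(ascending=False).index
        added = 0
        for feat in ranked:
            if feat in chosen or added >= n_per_component:
                continue
            trial = chosen + [feat]
            if len(trial) >= 2:
                rep = vif(feature_table, trial)
                if not np.all(rep.vif < vif_threshold):
                    continue
            chosen.append(feat)
            added += 1
    if not chosen:
        raise ValueError(
            f"no feature satisfies VIF < {vif_threshold}; relax the threshold")
    return SelectedFeatureSet(tuple(chosen))
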