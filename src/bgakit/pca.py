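"""PCA-based ancestry assignment.

Reference individuals (genotypes coded as 0/1/2 copies of the designated
allele) are normalised column-wise — centred by twice the sample allele
frequency and scaled by ``sqrt(p(1-p))`` — and projected onto the top two
principal components.  Each labelled ancestry cluster gets a 2D centroid
and covariance; an unknown profile is projected into the same plane and
assigned to a cluster when its squared Mahalanobis distance falls inside
the chi-square(2 df) quantile ellipse (95% by default).  Landing inside no
cluster, inside more than one, or inside a cluster designated as admixed
reference makes the estimation inconclusive.

A second mode runs PCA directly on a populations x loci allele-frequency
matrix for structure plots of the reference panel itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .decision import Decision, INCONCLUSIVE, PREDICTED
from .panel import ReferencePanel
from .qc import GenotypeProfile
from .zscore import genotype_codes

__all__ = [
    "PcaModel",
    "PcaResult",
    "fit_reference_pca",
    "project_and_assign",
    "population_frequency_pca",
]


@dataclass
class PcaModel:
    """Fitted 2D PCA with per-cluster Gaussian summaries.

    ``loadings`` has shape (2, L) on the normalised scale; clusters map
    label -> (centroid (2,), covariance (2, 2)).  ``admixed_labels`` are
    reference-only clusters that never yield a prediction.
    """

    loci: list[str]
    center: np.ndarray          # 2 * p_hat per locus
    scale: np.ndarray           # sqrt(p_hat (1 - p_hat)) per locus
    loadings: np.ndarray        # (2, L)
    clusters: dict[str, tuple[np.ndarray, np.ndarray]]
    admixed_labels: frozenset[str] = frozenset()
    explained_variance_ratio: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def transform(self, codes: np.ndarray) -> np.ndarray:
        """Project genotype-code rows (NaN mean-imputed) into the PC1/PC2 plane."""
        X = np.atleast_2d(np.asarray(codes, dtype=float)).copy()
        nan = np.isnan(X)
        if nan.any():
            X[nan] = np.broadcast_to(self.center, X.shape)[nan]
        Z = (X - self.center) / self.scale
        return Z @ self.loadings.T


@dataclass
class PcaResult:
    """Projection coordinates, per-cluster distances and the assignment."""

    sample_id: str
    coords: tuple[float, float]
    mahalanobis_sq: pd.Series
    decision: Decision


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude loading positive per PC."""
    out = components.copy()
    for i in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[i])))
        if out[i, j] < 0:
            out[i] = -out[i]
    return out


def fit_reference_pca(
    genotype_matrix: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    loci: Optional[Sequence[str]] = None,
    admixed_labels: Sequence[str] = (),
    ridge: float = 1e-9,
) -> PcaModel:
    """Fit the 2D reference PCA and per-cluster ellipses.

    ``genotype_matrix`` is individuals x loci coded 0/1/2 (NaN allowed,
    mean-imputed); ``labels`` assigns each individual to an ancestry
    cluster.  Requires >= 2 clusters with >= 3 individuals each.  Loci
    monomorphic across all individuals are dropped.  A cluster whose 2D
    covariance is singular gets a diagonal ridge and a warning.
    """
    if isinstance(genotype_matrix, pd.DataFrame):
        loci = list(genotype_matrix.columns)
        X = genotype_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(genotype_matrix, dtype=float)
        loci = list(loci) if loci is not None else [f"locus{i}" for i in range(X.shape[1])]
    labels = list(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("labels must align with genotype_matrix rows")
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2 or (counts < 3).any():
        raise ValueError("need >= 2 clusters with >= 3 individuals each")

    p_hat = np.nanmean(X, axis=0) / 2.0
    keep = (p_hat > 0) & (p_hat < 1)
    if not keep.any():
        raise ValueError("all loci monomorphic in the reference individuals")
    X = X[:, keep]
    loci = [l for l, k in zip(loci, keep) if k]
    p_hat = p_hat[keep]
    center = 2.0 * p_hat
    scale = np.sqrt(p_hat * (1.0 - p_hat))

    Ximp = X.copy()
    nan = np.isnan(Ximp)
    if nan.any():
        Ximp[nan] = np.broadcast_to(center, Ximp.shape)[nan]
    Z = (Ximp - center) / scale

    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(Z)
    loadings = _fix_signs(pca.components_)

    proj = Z @ loadings.T
    clusters: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for lab in sorted(set(labels)):
        pts = proj[np.array(labels) == lab]
        centroid = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) <= 0:
            warnings.warn(f"cluster {lab!r}: singular covariance, adding ridge", stacklevel=2)
            cov = cov + np.eye(2) * max(ridge, 1e-6 * np.trace(cov))
        clusters[lab] = (centroid, cov)

    return PcaModel(
        loci=loci,
        center=center,
        scale=scale,
        loadings=loadings,
        clusters=clusters,
        admixed_labels=frozenset(admixed_labels),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def project_and_assign(
    model: PcaModel,
    genotypes: GenotypeProfile | np.ndarray,
    panel: Optional[ReferencePanel] = None,
    chi2_quantile: float = 0.95,
    sample_id: str = "",
) -> PcaResult:
    """Project an unknown profile and assign it to an ancestry cluster.

    ``genotypes`` may be a called profile (``panel`` then supplies the
    designated-allele coding) or a precoded 0/1/2 vector over
    ``model.loci``.  Missing loci are mean-imputed.  The sample is
    predicted to a cluster iff it lies inside exactly one non-admixed
    cluster's chi-square(2 df) ellipse; otherwise inconclusive.
    """
    if isinstance(genotypes, GenotypeProfile):
        if panel is None:
            raise ValueError("panel required to code a GenotypeProfile")
        codes = genotype_codes(genotypes, panel, model.loci)
        sample_id = sample_id or genotypes.sample_id
    else:
        codes = np.asarray(genotypes, dtype=float)
        if codes.shape[-1] != len(model.loci):
            raise ValueError("code vector length does not match model loci")
    if np.isnan(codes).all():
        raise ValueError("all loci missing: nothing to project")

    xy = model.transform(codes)[0]
    threshold = float(stats.chi2.ppf(chi2_quantile, df=2))
    d2 = {}
    for lab, (centroid, cov) in model.clusters.items():
        delta = xy - centroid
        d2[lab] = float(delta @ np.linalg.solve(cov, delta))
    d2_ser = pd.Series(d2, name="mahalanobis_sq").sort_values(kind="stable")
    inside = [lab for lab, v in d2.items() if v <= threshold]
    inside_assignable = [lab for lab in inside if lab not in model.admixed_labels]
    if len(inside) == 1 and len(inside_assignable) == 1:
        decision = Decision(PREDICTED, label=inside_assignable[0], candidates=tuple(inside))
    else:
        decision = Decision(INCONCLUSIVE, candidates=tuple(sorted(inside)))
    return PcaResult(
        sample_id=sample_id,
        coords=(float(xy[0]), float(xy[1])),
        mahalanobis_sq=d2_ser,
        decision=decision,
    )


def population_frequency_pca(
    freq: pd.DataFrame | np.ndarray,
    scale: bool = False,
) -> pd.DataFrame:
    """2D PCA of a populations x loci allele-frequency matrix.

    Used for structure plots of the reference panel itself (which
    populations separate on PC1/PC2).  Columns are centred; ``scale=True``
    additionally divides by the column standard deviation.  The sign
    convention (largest-magnitude loading positive) makes output
    deterministic.  Requires >= 3 populations.
    """
    if isinstance(freq, pd.DataFrame):
        index = list(freq.index)
        X = freq.to_numpy(dtype=float)
    else:
        X = np.asarray(freq, dtype=float)
        index = [f"pop{i}" for i in range(X.shape[0])]
    if X.shape[0] < 3:
        raise ValueError("population-frequency PCA requires >= 3 populations")
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        nan = np.isnan(X)
        X = X.copy()
        X[nan] = np.broadcast_to(col_mean, X.shape)[nan]
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(Xc)
    components = _fix_signs(pca.components_)
    # re-project with the sign-fixed loadings so coordinates follow the convention
    coords = Xc @ components.T
    return pd.DataFrame(coords, index=index, columns=["PC1", "PC2"]).rename_axis("population")
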