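"""Hand-crafted 2-D radiomics: 21 features per modality (7 shape, 8
intensity, 6 GLCM texture), PCA reduction, and the radiomics-to-Cox arm.

Shape features quantify geometric regularity and symmetry of the ROI mask;
intensity features are first-order statistics of the ROI pixels; texture
features derive from a symmetric gray-level co-occurrence matrix restricted
to pixel pairs inside the ROI, quantized to ``levels`` bins over the ROI
intensity range and averaged over the four distance-1 offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import binary_erosion
from skimage.measure import label, perimeter as _sk_perimeter
from skimage.morphology import convex_hull_image
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

SHAPE_NAMES = (
    "area_regularity",
    "perimeter_convexity",
    "radial_cv",
    "symmetry_horizontal",
    "symmetry_vertical",
    "symmetry_diag_main",
    "symmetry_diag_anti",
)
INTENSITY_NAMES = (
    "size_px", "mean", "std", "median", "min", "max", "kurtosis", "skewness",
)
TEXTURE_NAMES = (
    "glcm_contrast", "glcm_energy", "glcm_correlation",
    "glcm_homogeneity", "glcm_entropy", "glcm_norm_entropy",
)
FEATURE_NAMES = SHAPE_NAMES + INTENSITY_NAMES + TEXTURE_NAMES  # 21 per modality

GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))

__all__ = [
    "SHAPE_NAMES", "INTENSITY_NAMES", "TEXTURE_NAMES", "FEATURE_NAMES",
    "shape_features", "intensity_features", "texture_features",
    "feature_vector", "feature_names_42",
    "PCAModel", "fit_pca", "handcrafted_pipeline",
]


def _largest_component(mask):
    lab = label(mask, connectivity=2)
    if lab.max() <= 1:
        return mask
    sizes = np.bincount(lab.ravel())[1:]
    return lab == (int(np.argmax(sizes)) + 1)


def _check_mask(roi_mask):
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    return roi_mask


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def _reflect_jaccard(coords, axis):
    """Jaccard overlap of a pixel set with its reflection about an axis
    through the centroid. ``axis`` in {h, v, d, a}: horizontal and vertical
    axes, main diagonal (45 deg) and anti-diagonal (-45 deg)."""
    pts = coords.astype(float)
    ctr = pts.mean(axis=0)
    rel = pts - ctr
    if axis == "h":      # horizontal mirror line: flip rows
        ref = np.column_stack([-rel[:, 0], rel[:, 1]])
    elif axis == "v":
        ref = np.column_stack([rel[:, 0], -rel[:, 1]])
    elif axis == "d":    # main diagonal: swap coordinates
        ref = rel[:, ::-1]
    else:                # anti-diagonal
        ref = -rel[:, ::-1]
    orig = {tuple(p) for p in np.round(rel * 2).astype(int)}
    refl = {tuple(p) for p in np.round(ref * 2).astype(int)}
    inter = len(orig & refl)
    union = len(orig | refl)
    return inter / union if union else 0.0


def shape_features(roi_mask):
    """Seven mask-only shape features.

    area regularity 4*pi*A/P^2 (1 for a disc); perimeter convexity
    (hull perimeter / perimeter, <=1ish, 1 for convex); coefficient of
    variation of the centroid-to-pixel radial distance (0 for a disc); and
    four reflection-symmetry Jaccard overlaps (horizontal, vertical, main
    and anti-diagonal axes through the centroid).
    """
    roi_mask = _largest_component(_check_mask(roi_mask))
    area = float(roi_mask.sum())
    perim = float(_sk_perimeter(roi_mask))
    if perim == 0:  # single pixel
        area_reg, convexity = 1.0, 1.0
    else:
        area_reg = float(4 * np.pi * area / perim ** 2)
        hull_perim = float(_sk_perimeter(convex_hull_image(roi_mask)))
        convexity = hull_perim / perim
    coords = np.argwhere(roi_mask)
    ctr = coords.mean(axis=0)
    # contour irregularity: radial spread of the boundary pixels (interior
    # pixels would give a disc a CV of 1/sqrt(8) by pure geometry)
    boundary = roi_mask & ~binary_erosion(roi_mask)
    bc = np.argwhere(boundary if boundary.any() else roi_mask).astype(float)
    radii = np.linalg.norm(bc - ctr, axis=1)
    radial_cv = float(radii.std() / radii.mean()) if radii.mean() > 0 else 0.0
    sym = [_reflect_jaccard(coords, ax) for ax in ("h", "v", "d", "a")]
    return np.array([area_reg, convexity, radial_cv, *sym])


# ---------------------------------------------------------------------------
# intensity
# ---------------------------------------------------------------------------

def intensity_features(image, roi_mask):
    """Eight first-order statistics of the ROI pixels.

    Kurtosis is excess kurtosis; skewness and kurtosis of a constant region
    are defined as 0.
    """
    roi_mask = _check_mask(roi_mask)
    image = np.asarray(image, dtype=float)
    if image.shape != roi_mask.shape:
        raise ValueError("image and mask shapes disagree")
    px = image[roi_mask]
    if px.std() == 0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(px))
        kurt = float(stats.kurtosis(px))  # excess (Fisher)
    return np.array([px.size, px.mean(), px.std(), np.median(px),
                     px.min(), px.max(), kurt, skew])


# ---------------------------------------------------------------------------
# texture (masked GLCM)
# ---------------------------------------------------------------------------

def masked_glcm(image, roi_mask, levels=32, offsets=GLCM_OFFSETS):
    """Symmetric normalized co-occurrence matrix restricted to the ROI.

    Intensities are quantized to ``levels`` equal bins over the ROI min/max
    (a constant ROI maps to level 0); only pairs with both pixels inside the
    mask count; the matrices of all offsets are accumulated together, then
    symmetrized and normalized to sum 1.
    """
    roi_mask = _check_mask(roi_mask)
    image = np.asarray(image, dtype=float)
    px = image[roi_mask]
    lo, hi = float(px.min()), float(px.max())
    if hi > lo:
        q = np.clip(((image - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
    else:
        q = np.zeros_like(image, dtype=int)
    H, W = roi_mask.shape
    glcm = np.zeros((levels, levels), dtype=float)
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        src = roi_mask[r0:r1, c0:c1] & roi_mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        i = q[r0:r1, c0:c1][src]
        j = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc][src]
        np.add.at(glcm, (i, j), 1.0)
    glcm = glcm + glcm.T
    total = glcm.sum()
    if total == 0:
        raise ValueError("ROI has no interior pixel pairs for the GLCM")
    return glcm / total


def texture_features(image, roi_mask, levels=32):
    """Six GLCM statistics: contrast, energy, correlation, homogeneity,
    entropy (bits) and entropy normalized by log2(levels^2)."""
    roi_mask = _check_mask(roi_mask)
    if roi_mask.sum() < 2:
        raise ValueError("texture needs an ROI of at least 2 pixels")
    p = masked_glcm(image, roi_mask, levels=levels)
    idx = np.arange(p.shape[0], dtype=float)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    contrast = float(np.sum(p * (ii - jj) ** 2))
    energy = float(np.sum(p ** 2))
    mu_i = float(np.sum(ii * p))
    mu_j = float(np.sum(jj * p))
    var_i = float(np.sum(p * (ii - mu_i) ** 2))
    var_j = float(np.sum(p * (jj - mu_j) ** 2))
    if var_i > 0 and var_j > 0:
        correlation = float(np.sum(p * (ii - mu_i) * (jj - mu_j))
                            / np.sqrt(var_i * var_j))
    else:
        correlation = 0.0
    homogeneity = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    norm_entropy = entropy / np.log2(p.size)
    return np.array([contrast, energy, correlation, homogeneity,
                     entropy, norm_entropy])


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def feature_vector(ct_image, ct_mask, pet_image, pet_mask, levels=32):
    """The 42-vector: 21 CT features followed by 21 PET features."""
    parts = []
    for img, msk in ((ct_image, ct_mask), (pet_image, pet_mask)):
        parts.append(shape_features(msk))
        parts.append(intensity_features(img, msk))
        parts.append(texture_features(img, msk, levels=levels))
    return np.concatenate(parts)


def feature_names_42():
    return ([f"CT_{n}" for n in FEATURE_NAMES]
            + [f"PET_{n}" for n in FEATURE_NAMES])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Z-score + PCA fitted on training features only."""

    scaler: StandardScaler
    pca: PCA
    kept: np.ndarray          # indices of non-degenerate input features
    n_components: int

    @property
    def loadings(self):
        return self.pca.components_

    def transform(self, X):
        X = np.asarray(X, dtype=float)[:, self.kept]
        return self.pca.transform(self.scaler.transform(X))

    def inverse_transform(self, Z):
        return self.scaler.inverse_transform(self.pca.inverse_transform(Z))


def fit_pca(X, n_components=18):
    """Fit z-scoring and PCA on a training feature table.

    Zero-variance features are dropped (with a warning) before scaling;
    components come out ordered by explained variance.
    """
    import warnings

    X = np.asarray(X, dtype=float)
    n, p = X.shape
    sd = X.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    if len(kept) < p:
        warnings.warn(f"dropping {p - len(kept)} zero-variance feature(s) "
                      "before PCA", stacklevel=2)
    if n_components > min(n - 1, len(kept)):
        raise ValueError("n_components exceeds min(n_samples - 1, n_features)")
    scaler = StandardScaler().fit(X[:, kept])
    pca = PCA(n_components=n_components, svd_solver="full").fit(
        scaler.transform(X[:, kept]))
    return PCAModel(scaler=scaler, pca=pca, kept=kept, n_components=n_components)


# ---------------------------------------------------------------------------
# radiomics -> Cox arm
# ---------------------------------------------------------------------------

def handcrafted_pipeline(cases, records_one_outcome, train_ids, test_ids,
                         n_components=18, levels=32, alpha=0.05):
    """Hand-crafted arm for one outcome.

    Extracts the 42-feature vector from each case's index tumor (middle
    slice), fits PCA on training cases only, runs backward-stepwise Cox over
    the principal components plus (SUV, age, gender, dose), and scores the
    test set. Returns ``(fit, c_index, detail)`` where ``c_index`` is None
    when nothing is selected.
    """
    import pandas as pd

    from .cohort import select_index_tumor
    from .survival import concordance_index, stepwise_select

    rec = {r.case_id: r for r in records_one_outcome}
    ids = [c.case_id for c in cases if c.case_id in rec]
    feats = {}
    clin = {}
    for c in cases:
        if c.case_id not in rec:
            continue
        t = select_index_tumor(c)
        feats[c.case_id] = feature_vector(t.ct[..., 1], t.ct_mask,
                                          t.pet[..., 1], t.pet_mask,
                                          levels=levels)
        clin[c.case_id] = [c.clinical.suv_max, c.clinical.age,
                           c.clinical.gender, c.clinical.dose]

    train_ids = [i for i in train_ids if i in feats]
    test_ids = [i for i in test_ids if i in feats]
    F_train = np.array([feats[i] for i in train_ids])
    # keep the Cox design (PCs + 4 clinical) smaller than the training n
    n_components = min(n_components, max(1, len(train_ids) - 6), 42)
    model = fit_pca(F_train, n_components=n_components)
    pc_names = [f"PC{k + 1}" for k in range(model.n_components)]
    clin_names = ["SUV", "age", "gender", "dose"]

    def design(id_list):
        Z = model.transform(np.array([feats[i] for i in id_list]))
        C = np.array([clin[i] for i in id_list], dtype=float)
        return pd.DataFrame(np.column_stack([Z, C]),
                            columns=pc_names + clin_names)

    X_train = design(train_ids)
    t_train = np.array([rec[i].time for i in train_ids])
    e_train = np.array([rec[i].event for i in train_ids])
    fit = stepwise_select(X_train, t_train, e_train, alpha=alpha)

    c_index = None
    if not fit.is_empty:
        X_test = design(test_ids)
        risk = X_test[fit.selected].to_numpy() @ np.array(
            [fit.coefficients[nm] for nm in fit.selected])
        t_test = np.array([rec[i].time for i in test_ids])
        e_test = np.array([rec[i].event for i in test_ids])
        c_index = concordance_index(risk, t_test, e_test, kind="risk")
    detail = {"pca": model, "train_ids": train_ids, "test_ids": test_ids,
              "feature_names": feature_names_42()}
    return fit, c_index, detail
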