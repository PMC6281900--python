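"""Geometric morphometrics of 3D landmark configurations.

Implements the standard landmark toolkit used for cranial shape comparison:
bilateral symmetrization, generalized Procrustes analysis (GPA) removing
position, scale and orientation, principal component analysis of the
aligned shape coordinates, permutation tests on the Procrustes distance
between group mean shapes, multivariate quadratic regression of shape on
centroid size (allometric growth trajectories), and group geometric mean
shapes.

Centroid size — the square root of the summed squared landmark distances
from their centroid — is the size variable throughout; configurations are
scaled to unit centroid size during superimposition, and rotations are
restricted to proper rotations (no reflections), since crania are chiral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, DegeneracyError, InputError


def centroid_size(config: np.ndarray) -> float:
    """sqrt of summed squared distances of landmarks from their centroid."""
    c = np.asarray(config, float)
    return float(np.sqrt(((c - c.mean(axis=0)) ** 2).sum()))


def _proper_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation matrix R (det +1) minimising ||source @ R - target||_F.

    Both inputs must be centred. Reflections are excluded by flipping the
    sign of the smallest singular direction when needed (Kabsch).
    """
    u, s, vt = np.linalg.svd(source.T @ target)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise DegeneracyError("configuration is rank-deficient (collinear landmarks)")
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.ones(len(s))
    flip[-1] = d
    return (u * flip) @ vt


def _canonical_axes(config: np.ndarray) -> np.ndarray:
    """Rotation to a deterministic principal-axes frame of a configuration.

    Axes are eigenvectors of the landmark second-moment matrix in decreasing
    eigenvalue order; the first two axes' signs are fixed by requiring the
    largest-magnitude projected coordinate to be positive, and the third
    completes a right-handed frame. Generic (non-symmetric-spectrum) shapes
    map to a unique frame regardless of their initial orientation.
    """
    c = config - config.mean(axis=0)
    w, v = np.linalg.eigh(c.T @ c)
    v = v[:, ::-1]  # descending eigenvalue order
    for axis in range(2):
        proj = c @ v[:, axis]
        if proj[np.argmax(np.abs(proj))] < 0:
            v[:, axis] *= -1
    v[:, 2] = np.cross(v[:, 0], v[:, 1])
    return v


@dataclass
class SymmetryPairing:
    """Mirror-image landmark pairs plus unpaired midline landmarks."""

    pairs: list[tuple[int, int]]
    midline: list[int] = field(default_factory=list)

    def permutation(self, k: int) -> np.ndarray:
        perm = np.arange(k)
        seen = set(self.midline)
        for i, j in self.pairs:
            if i == j or i in seen or j in seen:
                raise InputError("symmetry pairing is not an involution")
            seen.update((i, j))
            perm[i], perm[j] = j, i
        if seen != set(range(k)):
            raise InputError("pairing plus midline must cover every landmark exactly once")
        return perm

    @classmethod
    def from_yaml(cls, text: str) -> "SymmetryPairing":
        import yaml

        data = yaml.safe_load(text)
        return cls([tuple(p) for p in data.get("pairs", [])], list(data.get("midline", [])))


@dataclass
class LandmarkSet:
    """Named landmark configurations with specimen metadata.

    ``coords`` is (n_specimens, k_landmarks, 3); metadata arrays are aligned
    with the first axis.
    """

    ids: list[str]
    coords: np.ndarray
    species: np.ndarray | None = None
    sex: np.ndarray | None = None
    age_class: np.ndarray | None = None
    pairing: SymmetryPairing | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError("coords must be (n, k, 3)")
        n, k, _ = self.coords.shape
        if len(self.ids) != n:
            raise InputError("ids length does not match coords")
        if k < 4:
            raise InputError("need at least 4 landmarks")
        for i, cfg in enumerate(self.coords):
            if centroid_size(cfg) <= 0:
                raise InputError(f"specimen {self.ids[i]!r} has zero centroid size")
        for name in ("species", "sex", "age_class"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v))

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def k_landmarks(self) -> int:
        return self.coords.shape[1]

    def centroid_sizes(self) -> np.ndarray:
        return np.array([centroid_size(c) for c in self.coords])

    @classmethod
    def from_long_csv(cls, path: str | Path, meta: pd.DataFrame | None = None) -> "LandmarkSet":
        """Read long-format CSV: specimen_id, landmark_id, x, y, z."""
        df = pd.read_csv(path)
        need = {"specimen_id", "landmark_id", "x", "y", "z"}
        if not need.issubset(df.columns):
            raise InputError(f"landmark CSV must have columns {sorted(need)}")
        ids = list(df["specimen_id"].unique())
        lms = sorted(df["landmark_id"].unique())
        coords = np.full((len(ids), len(lms), 3), np.nan)
        id_ix = {s: i for i, s in enumerate(ids)}
        lm_ix = {l: i for i, l in enumerate(lms)}
        for _, row in df.iterrows():
            coords[id_ix[row["specimen_id"]], lm_ix[row["landmark_id"]]] = (
                row["x"], row["y"], row["z"])
        if np.isnan(coords).any():
            raise InputError("missing landmark rows for some specimen/landmark pairs")
        kwargs = {}
        if meta is not None:
            meta = meta.set_index("specimen_id").loc[ids]
            for name in ("species", "sex", "age_class"):
                if name in meta:
                    kwargs[name] = meta[name].to_numpy()
        return cls([str(s) for s in ids], coords, **kwargs)

    def to_long_csv(self, path: str | Path) -> None:
        rows = []
        for sid, cfg in zip(self.ids, self.coords):
            for li, (x, y, z) in enumerate(cfg):
                rows.append({"specimen_id": sid, "landmark_id": li, "x": x, "y": y, "z": z})
        pd.DataFrame(rows).to_csv(path, index=False)


def read_tps(path: str | Path) -> LandmarkSet:
    """Read a TPS file of LM3 records (ID= or IMAGE= used as specimen ids)."""
    ids: list[str] = []
    configs: list[np.ndarray] = []
    current: list[list[float]] | None = None
    expected = 0
    label = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                if current is not None:
                    configs.append(np.array(current))
                    ids.append(label or f"specimen_{len(configs)}")
                expected = int(line.split("=", 1)[1])
                current = []
                label = None
            elif upper.startswith(("ID=", "IMAGE=")):
                if label is None:
                    label = line.split("=", 1)[1]
            elif current is not None and len(current) < expected:
                current.append([float(v) for v in line.split()])
    if current is not None:
        configs.append(np.array(current))
        ids.append(label or f"specimen_{len(configs)}")
    if not configs:
        raise InputError(f"no LM3 records found in {path}")
    return LandmarkSet(ids, np.stack(configs))


def symmetrize(config: np.ndarray, pairing: SymmetryPairing, axis: int = 0) -> np.ndarray:
    """Project a configuration onto the bilaterally symmetric subspace.

    The configuration is reflected (one axis negated), paired landmark
    labels are swapped, the relabelled reflection is optimally superimposed
    (translation + proper rotation, no scaling) onto the original, and the
    two copies are averaged. Idempotent up to numerical tolerance.
    """
    cfg = np.asarray(config, float)
    perm = pairing.permutation(cfg.shape[0])
    mirrored = cfg.copy()
    mirrored[:, axis] *= -1.0
    mirrored = mirrored[perm]
    orig_centroid = cfg.mean(axis=0)
    a = cfg - orig_centroid
    b = mirrored - mirrored.mean(axis=0)
    R = _proper_rotation(b, a)
    return (a + b @ R) / 2.0 + orig_centroid


@dataclass
class ShapeSpace:
    """GPA-aligned shapes: unit centroid size, common orientation."""

    aligned: np.ndarray  # (n, k, 3)
    sizes: np.ndarray  # original centroid sizes
    consensus: np.ndarray  # (k, 3) mean shape, unit centroid size
    ids: list[str]
    species: np.ndarray | None = None
    sex: np.ndarray | None = None
    age_class: np.ndarray | None = None
    n_iterations: int = 0
    converged: bool = True

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    def flat(self) -> np.ndarray:
        return self.aligned.reshape(self.n_specimens, -1)

    def mask_for(self, **criteria) -> np.ndarray:
        mask = np.ones(self.n_specimens, bool)
        for key, value in criteria.items():
            arr = getattr(self, key)
            if arr is None:
                raise InputError(f"no {key!r} metadata attached")
            mask &= np.asarray(arr) == value
        return mask


def generalized_procrustes(
    lms: LandmarkSet,
    tol: float = 1e-10,
    max_iter: int = 100,
    symmetrize_first: bool = False,
) -> ShapeSpace:
    """Generalized Procrustes analysis of a landmark sample.

    Each configuration is centred and scaled to unit centroid size, then
    iteratively rotated to the running consensus with proper rotations until
    the consensus moves less than ``tol``. With ``symmetrize_first`` the
    configurations are first projected to bilateral symmetry using the
    attached pairing.
    """
    coords = lms.coords
    if symmetrize_first:
        if lms.pairing is None:
            raise InputError("symmetrize_first requires a symmetry pairing")
        coords = np.stack([symmetrize(c, lms.pairing) for c in coords])
    sizes = np.array([centroid_size(c) for c in coords])
    shapes = np.stack([
        (c - c.mean(axis=0)) / s for c, s in zip(coords, sizes)
    ])
    for i, shape in enumerate(shapes):
        if np.linalg.matrix_rank(shape, tol=1e-10) < 2:
            raise DegeneracyError(f"specimen {lms.ids[i]!r} is degenerate (collinear)")

    consensus = shapes[0].copy()
    n_it = 0
    converged = False
    for n_it in range(1, max_iter + 1):
        for i in range(len(shapes)):
            R = _proper_rotation(shapes[i], consensus)
            shapes[i] = shapes[i] @ R
        new_consensus = shapes.mean(axis=0)
        new_consensus /= centroid_size(new_consensus)
        if np.linalg.norm(new_consensus - consensus) < tol:
            consensus = new_consensus
            converged = True
            break
        consensus = new_consensus
    # final orientation pass against the converged consensus
    for i in range(len(shapes)):
        shapes[i] = shapes[i] @ _proper_rotation(shapes[i], consensus)
    # canonical orientation: principal axes of the consensus with fixed signs,
    # so the output does not depend on the input specimens' orientations
    R_canon = _canonical_axes(consensus)
    shapes = shapes @ R_canon
    consensus = consensus @ R_canon
    return ShapeSpace(
        shapes, sizes, shapes.mean(axis=0), list(lms.ids),
        lms.species, lms.sex, lms.age_class, n_it, converged,
    )


@dataclass
class PCAResult:
    """Principal components of aligned shape coordinates."""

    scores: np.ndarray  # (n, n_components)
    loadings: np.ndarray  # (n_components, 3k)
    explained_pct: np.ndarray  # percentages summing to 100
    mean: np.ndarray  # (3k,) column means removed before decomposition


def shape_pca(space: ShapeSpace) -> PCAResult:
    """PCA of the (specimens x 3k) aligned coordinate matrix."""
    X = space.flat()
    if X.shape[0] < 2:
        raise InputError("PCA needs at least 2 specimens")
    mean = X.mean(axis=0)
    Xc = X - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # drop numerically-null trailing components so percentages are stable
    keep = s > max(s[0], 1e-300) * 1e-12
    if not keep.any():
        keep[0] = True
    u, s, vt = u[:, keep], s[keep], vt[keep]
    var = s**2
    return PCAResult(u * s, vt, 100.0 * var / var.sum(), mean)


@dataclass
class PermutationTestResult:
    distance: float
    p_value: float
    n_permutations: int
    n_greater_equal: int


def procrustes_permutation_test(
    space: ShapeSpace,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Permutation test on the Procrustes distance between group means.

    The statistic is the Euclidean distance between the two groups' mean
    aligned shape vectors; group labels are permuted ``n_perm`` times and
    the p-value is (#{permuted >= observed} + 1) / (n_perm + 1).
    """
    X = space.flat()
    a, b = np.flatnonzero(mask_a), np.flatnonzero(mask_b)
    if len(a) < 2 or len(b) < 2:
        raise CoverageError("each group needs at least 2 specimens")
    pooled = X[np.concatenate([a, b])]
    na, nb = len(a), len(b)
    total = pooled.sum(axis=0)

    def stat(sum_a: np.ndarray) -> float:
        return float(np.linalg.norm(sum_a / na - (total - sum_a) / nb))

    observed = stat(X[a].sum(axis=0))
    rng = np.random.default_rng(seed)
    count = 0
    n = na + nb
    for _ in range(n_perm):
        idx = rng.permutation(n)[:na]
        if stat(pooled[idx].sum(axis=0)) >= observed:
            count += 1
    return PermutationTestResult(observed, (count + 1) / (n_perm + 1), n_perm, count)


@dataclass
class AllometryModel:
    """Quadratic regression of shape on centroid size for one group."""

    coefficients: np.ndarray  # (3, 3k): intercept, size, size^2 rows
    size_grid: np.ndarray
    trajectory: np.ndarray  # (len(size_grid), 3k) predicted shapes
    residual_ss: float
    group: str = ""
    standardized: bool = False
    size_mean: float = 0.0
    size_sd: float = 1.0

    def predict(self, sizes: np.ndarray) -> np.ndarray:
        s = (np.asarray(sizes, float) - self.size_mean) / self.size_sd
        design = np.column_stack([np.ones_like(s), s, s**2])
        return design @ self.coefficients


def quadratic_allometry(
    space: ShapeSpace,
    mask: np.ndarray | None = None,
    group: str = "",
    standardize: bool = False,
    n_grid: int = 50,
) -> AllometryModel:
    """Least-squares fit of each shape coordinate on (1, size, size^2)."""
    if mask is None:
        mask = np.ones(space.n_specimens, bool)
    X = space.flat()[mask]
    s = space.sizes[mask].astype(float)
    if X.shape[0] < 4:
        raise InputError("quadratic allometry needs >= 4 specimens")
    if len(np.unique(s)) < 3:
        raise InputError("need >= 3 distinct centroid sizes for a quadratic fit")
    mu, sd = (s.mean(), s.std()) if standardize else (0.0, 1.0)
    z = (s - mu) / sd
    design = np.column_stack([np.ones_like(z), z, z**2])
    coef, _, rank, _ = np.linalg.lstsq(design, X, rcond=None)
    if rank < 3:
        raise InputError("rank-deficient design: sizes do not support a quadratic fit")
    resid = X - design @ coef
    grid = np.linspace(s.min(), s.max(), n_grid)
    zg = (grid - mu) / sd
    traj = np.column_stack([np.ones_like(zg), zg, zg**2]) @ coef
    return AllometryModel(coef, grid, traj, float((resid**2).sum()), group, standardize, mu, sd)


def group_geometric_mean(space: ShapeSpace, mask: np.ndarray) -> np.ndarray:
    """Mean aligned shape of a subset, rescaled to unit centroid size."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise CoverageError("empty subset for group mean")
    mean = space.aligned[mask].mean(axis=0)
    return mean / centroid_size(mean)
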