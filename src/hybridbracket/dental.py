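"""Dental comparison statistics: top-cusp angle, cusp-number disparity, and
the pairwise-average intermediacy bracket for a putative hybrid.

The top-cusp angle measures relative cusp height: at the tallest cusp tip,
the angle between rays to the most anterior and most posterior cusp tips
(or, for teeth with too few cusps, to the crown-base endpoints). A small
angle means a dominant central cusp (grey-seal-like fangs); a large angle
means subequal cusps (ringed-seal-like serrated teeth).

Dental disparity between two species is the mean over tooth positions of
the absolute difference in cusp number (cusps/tooth), computed from both
the per-position mean and the per-position mode.

The intermediacy bracket asks whether a hybrid's angle at each tooth
position could plausibly arise by averaging the two parent species: all
cross-species pairwise averages of specimen angles are formed, and the
hybrid is located as an empirical quantile within them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, DegeneracyError, InputError

POSITIONS = ("P1", "P2", "P3", "P4", "P5")


@dataclass
class ToothGeometry:
    """Cusp tips and crown-base endpoints of one tooth in lingual view.

    Coordinates are 2D: x runs mesiodistally (anterior = smaller x) and
    y is height. Tips are ordered anterior to posterior.
    """

    tips: np.ndarray  # (n_tips, 2)
    base_anterior: np.ndarray  # (2,)
    base_posterior: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        self.tips = np.atleast_2d(np.asarray(self.tips, float))
        self.base_anterior = np.asarray(self.base_anterior, float)
        self.base_posterior = np.asarray(self.base_posterior, float)
        if self.tips.shape[1] != 2 or self.tips.shape[0] < 1:
            raise InputError("tips must be a (n>=1, 2) array")
        xs = self.tips[:, 0]
        lo, hi = sorted([self.base_anterior[0], self.base_posterior[0]])
        if not ((xs >= lo) & (xs <= hi)).all():
            raise InputError("crown-base endpoints must flank all cusp tips in x")


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise DegeneracyError("ray endpoint coincides with the top cusp")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def top_cusp_angle(geom: ToothGeometry) -> float:
    """Angle at the tallest cusp tip between rays to the flanking extremes.

    The tallest tip T is the maximum-height tip (ties broken to the most
    anterior). The anterior ray goes to the most anterior tip strictly
    anterior of T, falling back to the anterior crown-base endpoint when T
    is itself the most anterior tip; symmetrically for the posterior ray.
    """
    tips = geom.tips
    order = np.lexsort((tips[:, 0], -tips[:, 1]))  # by height desc, then x asc
    T = tips[order[0]]
    anterior = tips[tips[:, 0] < T[0]]
    posterior = tips[tips[:, 0] > T[0]]
    A = anterior[np.argmin(anterior[:, 0])] if len(anterior) else geom.base_anterior
    P = posterior[np.argmax(posterior[:, 0])] if len(posterior) else geom.base_posterior
    return _angle_deg(A - T, P - T)


@dataclass
class ToothSample:
    """Per-specimen, per-position cusp counts and top-cusp angles for one
    species. Backed by a long-format table with columns specimen_id,
    species, position, cusp_count, angle_deg (angle may be missing)."""

    df: pd.DataFrame
    species: str = ""

    REQUIRED = ("specimen_id", "species", "position", "cusp_count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise InputError(f"tooth sample missing columns: {missing}")
        if "angle_deg" not in self.df.columns:
            self.df = self.df.assign(angle_deg=np.nan)
        if not self.species:
            uniq = self.df["species"].unique()
            if len(uniq) != 1:
                raise InputError("sample mixes species; pass an explicit label")
            self.species = str(uniq[0])
        counts = self.df["cusp_count"].to_numpy()
        if (counts < 1).any():
            raise InputError("cusp_count must be >= 1")
        ang = self.df["angle_deg"].to_numpy(float)
        bad = np.isfinite(ang) & ((ang <= 0) | (ang >= 180))
        if bad.any():
            raise InputError("angles must lie in the open interval (0, 180)")

    @classmethod
    def from_csv(cls, path: str | Path, species: str = "") -> "ToothSample":
        return cls(pd.read_csv(path), species=species)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def angles_at(self, position: str) -> np.ndarray:
        sel = self.df[self.df["position"] == position]["angle_deg"].dropna()
        return sel.to_numpy(float)

    def cusp_counts_at(self, position: str) -> np.ndarray:
        return self.df[self.df["position"] == position]["cusp_count"].to_numpy()


@dataclass
class DisparityResult:
    """Per-position and overall cusp-number differences between two samples."""

    per_position: pd.DataFrame  # position, mean_a, mean_b, diff_mean, mode_a, ...
    delta_mean: float  # cusps/tooth, species means
    delta_mode: float  # cusps/tooth, species modes
    mode_ties: list[str] = field(default_factory=list)  # positions with tied modes


def _mode_smallest(values: np.ndarray) -> tuple[int, bool]:
    """Most frequent cusp count; ties broken to the smaller count."""
    counts = pd.Series(values).value_counts()
    top = counts[counts == counts.max()].index
    return int(min(top)), len(top) > 1


def dental_disparity(
    a: ToothSample, b: ToothSample, positions: Sequence[str] = POSITIONS
) -> DisparityResult:
    """Mean absolute between-species cusp-number difference across positions.

    Computed twice, from the per-position species mean and species mode, as
    whole-jaw data are often unavailable and the two central tendencies can
    disagree. Mode ties are broken to the smaller count and flagged.
    """
    rows = []
    ties = []
    for pos in positions:
        ca, cb = a.cusp_counts_at(pos), b.cusp_counts_at(pos)
        if len(ca) == 0 or len(cb) == 0:
            raise CoverageError(f"no cusp counts at position {pos}")
        mode_a, tie_a = _mode_smallest(ca)
        mode_b, tie_b = _mode_smallest(cb)
        if tie_a or tie_b:
            ties.append(pos)
        rows.append({
            "position": pos,
            "mean_a": ca.mean(), "mean_b": cb.mean(),
            "diff_mean": abs(ca.mean() - cb.mean()),
            "mode_a": mode_a, "mode_b": mode_b,
            "diff_mode": abs(mode_a - mode_b),
            "mode_tie": tie_a or tie_b,
        })
    table = pd.DataFrame(rows)
    return DisparityResult(
        table,
        float(table["diff_mean"].mean()),
        float(table["diff_mode"].mean()),
        ties,
    )


@dataclass
class BracketResult:
    """Hybrid location within the cross-species pairwise-average bracket."""

    per_position: pd.DataFrame  # position, lo, hi, hybrid, quantile, inside, ...
    coverage: float

    @property
    def all_inside(self) -> bool:
        return bool(self.per_position["inside"].all())


def intermediacy_bracket(
    a: ToothSample,
    b: ToothSample,
    hybrid: Mapping[str, float] | pd.DataFrame,
    coverage: float = 0.80,
    positions: Sequence[str] = POSITIONS,
) -> BracketResult:
    """Locate the hybrid within all cross-species pairwise average angles.

    Per position, every grey-ringed style pair (one specimen from each
    species) contributes the mean of its two angles; the bracket is the
    equal-tailed central ``coverage`` interval of those n_a*n_b averages
    (empirical quantiles with linear interpolation). The hybrid's quantile
    is the fraction of pairwise averages <= its value; it is "inside" when
    that quantile lies within the central interval. Both one- and two-tailed
    readings of the hybrid's extremity are reported.
    """
    if not 0 < coverage < 1:
        raise InputError("coverage must be in (0, 1)")
    if isinstance(hybrid, pd.DataFrame):
        hybrid = dict(zip(hybrid["position"], hybrid["angle_deg"]))
    tail = (1.0 - coverage) / 2.0
    rows = []
    for pos in positions:
        ang_a, ang_b = a.angles_at(pos), b.angles_at(pos)
        if len(ang_a) < 2 or len(ang_b) < 2:
            raise CoverageError(f"need >= 2 angles per species at {pos}")
        h = hybrid.get(pos, np.nan)
        if not np.isfinite(h):
            warnings.warn(f"hybrid angle missing at {pos}; position skipped")
            continue
        means = (ang_a[:, None] + ang_b[None, :]).ravel() / 2.0
        lo, hi = np.quantile(means, [tail, 1.0 - tail])
        q = float((means <= h).mean())
        p_one = min(q, 1.0 - q)
        rows.append({
            "position": pos, "lo": lo, "hi": hi, "n_pairs": means.size,
            "hybrid": h, "quantile": q,
            "inside": tail <= q <= 1.0 - tail,
            "p_one_tailed": p_one, "p_two_tailed": min(1.0, 2.0 * p_one),
        })
    return BracketResult(pd.DataFrame(rows), coverage)


#: Operative grade-to-cusp recoding for hominin premolars following the
#: convention that crown grades 1 and 2 score as one cusp and grade 5 as
#: four cusps, with the intermediate grades filling in linearly.
PREMOLAR_GRADE_RECODING = pd.DataFrame(
    {"tooth_class": "premolar", "grade": [1, 2, 3, 4, 5], "cusp_count": [1, 1, 2, 3, 4]}
)


def recode_grades(
    df: pd.DataFrame, table: pd.DataFrame, grade_col: str = "grade"
) -> pd.DataFrame:
    """Map ordinal crown grades to cusp counts via a named recoding table.

    ``table`` has columns tooth_class, grade, cusp_count; ``df`` needs
    tooth_class and the grade column. Returns a copy of ``df`` with a
    cusp_count column suitable for :func:`dental_disparity`.
    """
    for col in ("tooth_class", "grade", "cusp_count"):
        if col not in table.columns:
            raise InputError(f"recoding table missing column {col!r}")
    merged = df.merge(table, on=["tooth_class", grade_col], how="left",
                      suffixes=("", "_recoded"))
    out_col = "cusp_count_recoded" if "cusp_count" in df.columns else "cusp_count"
    if merged[out_col].isna().any():
        bad = merged[merged[out_col].isna()][["tooth_class", grade_col]].drop_duplicates()
        raise InputError(f"grades without recoding entries:\n{bad}")
    merged["cusp_count"] = merged[out_col].astype(int)
    return merged.drop(columns=[c for c in ("cusp_count_recoded",) if c in merged])
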