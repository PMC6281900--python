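"""Synthetic inputs with the statistical structure the analyses assume.

Real hybrid-seal data (whole-genome resequencing, museum tooth tables,
digitized crania) cannot ship with a software package, so every downstream
stage is exercised on generated data whose ground truth is known:

* four-taxon biallelic site patterns with a tunable introgression fraction
  and a closed-form expected D-statistic;
* two-species codon alignments whose fourfold-degenerate third positions
  evolved under a Tamura (1992) process at a known distance and GC content;
* two-species tooth samples (per-position top-cusp angles and cusp counts)
  plus an intermediate hybrid drawn at the species midpoint;
* two-species 3D landmark samples with quadratic allometric growth;
* F1 genotypes sampled one allele from each of two diverged parental
  populations, for validating the supervised admixture estimator.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.stats import truncnorm

from .dental import POSITIONS, ToothSample
from .errors import ParameterError
from .introgression import PANEL_COLUMNS, SitePanel
from .morpho import LandmarkSet, SymmetryPairing, centroid_size
from .seqdist import CodonAlignment


# ---------------------------------------------------------------------------
# Four-taxon site patterns


@dataclass(frozen=True)
class SitePatternModel:
    """Generative model for fixed four-taxon site patterns.

    With probability ``f`` a site's genealogy is introgressed, in which case
    it shows ABBA with probability ``beta`` and BABA with probability
    ``eps``; otherwise (species genealogy) ABBA and BABA each occur with the
    symmetric incomplete-lineage-sorting probability ``eps``. BBAA occurs
    with probability ``p_bbaa`` regardless of genealogy, and all remaining
    sites are uninformative for D. ``beta > eps`` gives a positive expected
    D; ``f = 0`` gives exactly D = 0 in expectation.
    """

    f: float = 0.0
    eps: float = 0.05
    beta: float = 0.25
    p_bbaa: float = 0.2
    n_sites: int = 100_000
    n_blocks: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("f", "eps", "beta", "p_bbaa"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.pattern_probabilities().sum() > 1.0 + 1e-12:
            raise ParameterError("pattern probabilities exceed 1")
        if self.n_sites < 1 or self.n_blocks < 2:
            raise ParameterError("need n_sites >= 1 and n_blocks >= 2")

    def pattern_probabilities(self) -> np.ndarray:
        """Marginal (ABBA, BABA, BBAA) probabilities of one site."""
        p_abba = self.f * self.beta + (1.0 - self.f) * self.eps
        return np.array([p_abba, self.eps, self.p_bbaa])

    def expected_d(self) -> float:
        """Closed-form expectation f*(beta-eps) / (2*eps + f*(beta-eps))."""
        num = self.f * (self.beta - self.eps)
        den = 2.0 * self.eps + num
        return num / den if den > 0 else 0.0


#: derived-allele frequency rows (p1, p2, p3, p4) for each fixed pattern
_PATTERN_FREQS = np.array(
    [
        [0.0, 1.0, 1.0, 0.0],  # ABBA
        [1.0, 0.0, 1.0, 0.0],  # BABA
        [1.0, 1.0, 0.0, 0.0],  # BBAA
        [0.0, 0.0, 0.0, 0.0],  # uninformative remainder
    ]
)


def simulate_site_patterns(model: SitePatternModel) -> SitePanel:
    """Draw a panel of fixed (0/1 frequency) four-taxon site patterns."""
    rng = np.random.default_rng(model.seed)
    probs = model.pattern_probabilities()
    full = np.append(probs, 1.0 - probs.sum())
    pattern = rng.choice(4, size=model.n_sites, p=full)
    freqs = _PATTERN_FREQS[pattern]
    idx = np.arange(model.n_sites)
    block = (idx * model.n_blocks) // model.n_sites
    df = pd.DataFrame({
        "scaffold": "scaffold_1",
        "pos": idx + 1,
        "block": block,
        "p1": freqs[:, 0], "p2": freqs[:, 1], "p3": freqs[:, 2], "p4": freqs[:, 3],
    })
    return SitePanel(df[PANEL_COLUMNS])


# ---------------------------------------------------------------------------
# Codon alignments under T92


@dataclass(frozen=True)
class CodonSimModel:
    """Two-species codon alignment generator with T92-evolving ffd sites.

    A fraction ``ffd_fraction`` of codons is drawn from fourfold-degenerate
    families; their third positions diverge under the Tamura (1992)
    substitution process with equilibrium GC content ``gc``,
    transition/transversion rate ratio ``kappa`` and total pairwise
    divergence ``d_true`` substitutions per site. All other positions are
    identical between the species, so the realised ffd distance is the only
    divergence signal.
    """

    n_codons: int = 10_000
    d_true: float = 0.1
    gc: float = 0.5
    kappa: float = 2.0
    ffd_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d_true) and 0.0 <= self.d_true <= 10.0):
            raise ParameterError(
                f"d_true must be finite and within [0, 10] (got {self.d_true}); "
                "larger values saturate the substitution process"
            )
        if not 0.0 < self.gc < 1.0:
            raise ParameterError(f"gc must be in (0, 1), got {self.gc}")
        if not 0.0 <= self.ffd_fraction <= 1.0:
            raise ParameterError("ffd_fraction must be in [0, 1]")
        if self.kappa <= 0 or self.n_codons < 1:
            raise ParameterError("kappa must be > 0 and n_codons >= 1")


_FFD_PREFIXES = ("CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG")
# non-degenerate codon families free of stop codons for any third base
_NONFFD_PREFIXES = ("AA", "AT", "TT", "CA", "GA", "AG")
_NT = np.array(list("ACGT"))


def t92_transition_matrix(d: float, gc: float, kappa: float) -> np.ndarray:
    """T92 substitution probability matrix after distance ``d``.

    Bases ordered A, C, G, T; stationary frequencies are (1-gc)/2 for A/T
    and gc/2 for C/G; transitions are ``kappa`` times faster than
    transversions; the rate matrix is scaled to one expected substitution
    per unit distance.
    """
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            ts = (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1))
            Q[i, j] = (kappa if ts else 1.0) * pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -float((pi * np.diag(Q)).sum())
    return expm(Q * (d / rate))


def simulate_codon_alignment(model: CodonSimModel) -> CodonAlignment:
    """Simulate a gap-free two-species codon alignment."""
    rng = np.random.default_rng(model.seed)
    pi = np.array([(1 - model.gc) / 2, model.gc / 2, model.gc / 2, (1 - model.gc) / 2])
    P = t92_transition_matrix(model.d_true, model.gc, model.kappa)

    is_ffd = rng.random(model.n_codons) < model.ffd_fraction
    prefixes = np.where(
        is_ffd,
        rng.choice(_FFD_PREFIXES, size=model.n_codons),
        rng.choice(_NONFFD_PREFIXES, size=model.n_codons),
    )
    anc = rng.choice(4, size=model.n_codons, p=pi)
    # evolve third positions of ffd codons only; others stay identical
    u = rng.random(model.n_codons)
    cum = np.cumsum(P[anc], axis=1)
    der = (u[:, None] > cum).sum(axis=1)
    der = np.where(is_ffd, der, anc)

    seq_a = "".join(p + b for p, b in zip(prefixes, _NT[anc]))
    seq_b = "".join(p + b for p, b in zip(prefixes, _NT[der]))
    return CodonAlignment({"species_a": seq_a, "species_b": seq_b}, gene_id="sim_gene")


# ---------------------------------------------------------------------------
# Tooth samples


def _default_angle_means() -> dict[str, dict[str, float]]:
    # Ringed-type teeth: subequal cusps, large flat-crown angles; grey-type:
    # dominant central cusp anteriorly (small angles) grading posteriorly.
    return {
        "ringed": {"P1": 115.0, "P2": 118.0, "P3": 120.0, "P4": 118.0, "P5": 115.0},
        "grey": {"P1": 45.0, "P2": 40.0, "P3": 50.0, "P4": 70.0, "P5": 85.0},
    }


def _default_cusp_dists() -> dict[str, dict[str, dict[int, float]]]:
    return {
        "ringed": {
            "P1": {3: 0.5, 4: 0.4, 5: 0.1},
            "P2": {3: 0.2, 4: 0.6, 5: 0.2},
            "P3": {3: 0.1, 4: 0.5, 5: 0.4},
            "P4": {3: 0.1, 4: 0.6, 5: 0.3},
            "P5": {3: 0.4, 4: 0.5, 5: 0.1},
        },
        "grey": {
            "P1": {1: 0.55, 2: 0.40, 3: 0.05},
            "P2": {1: 0.45, 2: 0.45, 3: 0.10},
            "P3": {1: 0.25, 2: 0.50, 3: 0.25},
            "P4": {1: 0.05, 2: 0.45, 3: 0.40, 4: 0.10},
            "P5": {2: 0.30, 3: 0.50, 4: 0.20},
        },
    }


@dataclass(frozen=True)
class ToothSimModel:
    """Two-species tooth-sample generator with an intermediate hybrid.

    Angles are truncated normal on (0, 180) around per-position species
    means; cusp counts follow per-position categorical distributions with
    support in {1..6}. The hybrid's angle at each position is the midpoint
    of the two species means plus measurement-scale noise
    (``hybrid_noise_sd``, default of the order of the repeat-measurement
    error of manual angle tabulation).
    """

    angle_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_angle_means)
    angle_sd: float = 9.0
    cusp_dists: Mapping[str, Mapping[str, Mapping[int, float]]] = field(
        default_factory=_default_cusp_dists)
    n_per_species: int = 65
    hybrid_noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.angle_sd <= 0:
            raise ParameterError("angle_sd must be > 0")
        if self.n_per_species < 2:
            raise ParameterError("need n_per_species >= 2")
        if len(self.angle_means) != 2:
            raise ParameterError("exactly two species required")
        for sp, by_pos in self.angle_means.items():
            for pos, mu in by_pos.items():
                if not 0.0 < mu < 180.0:
                    raise ParameterError(f"angle mean {sp}/{pos}={mu} outside (0, 180)")
        for sp, by_pos in self.cusp_dists.items():
            for pos, dist in by_pos.items():
                if not set(dist) <= set(range(1, 7)):
                    raise ParameterError(f"cusp support {sp}/{pos} outside 1..6")
                if abs(sum(dist.values()) - 1.0) > 1e-9:
                    raise ParameterError(f"cusp probabilities {sp}/{pos} do not sum to 1")

    @property
    def species(self) -> tuple[str, str]:
        return tuple(self.angle_means)


def _truncnorm_angles(rng, mu: float, sd: float, n: int) -> np.ndarray:
    a, b = (0.0 - mu) / sd, (180.0 - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)


def simulate_tooth_sample(
    model: ToothSimModel,
) -> tuple[ToothSample, ToothSample, pd.DataFrame]:
    """Generate (species A sample, species B sample, hybrid measurement).

    The hybrid is returned as a one-row-per-position table with columns
    position, angle_deg, cusp_count.
    """
    rng = np.random.default_rng(model.seed)
    sp_a, sp_b = model.species
    n = model.n_per_species
    samples = {}
    for sp in (sp_a, sp_b):
        frames = []
        for pos in POSITIONS:
            mu = model.angle_means[sp][pos]
            angles = _truncnorm_angles(rng, mu, model.angle_sd, n)
            dist = model.cusp_dists[sp][pos]
            counts = np.array(sorted(dist))
            cusps = rng.choice(counts, size=n, p=[dist[c] for c in counts])
            frames.append(pd.DataFrame({
                "specimen_id": [f"{sp}_{i:03d}" for i in range(n)],
                "species": sp, "position": pos,
                "cusp_count": cusps, "angle_deg": angles,
            }))
        df = pd.concat(frames, ignore_index=True).sort_values(
            ["specimen_id", "position"], kind="stable", ignore_index=True)
        samples[sp] = ToothSample(df)
    hybrid_rows = []
    for pos in POSITIONS:
        mid = (model.angle_means[sp_a][pos] + model.angle_means[sp_b][pos]) / 2.0
        angle = float(np.clip(mid + rng.normal(0.0, model.hybrid_noise_sd), 1e-6, 180 - 1e-6))
        mean_a = float(np.dot(*zip(*model.cusp_dists[sp_a][pos].items())))
        mean_b = float(np.dot(*zip(*model.cusp_dists[sp_b][pos].items())))
        hybrid_rows.append({
            "position": pos, "angle_deg": angle,
            "cusp_count": int(round((mean_a + mean_b) / 2.0)),
        })
    return samples[sp_a], samples[sp_b], pd.DataFrame(hybrid_rows)


# ---------------------------------------------------------------------------
# Landmark samples


@dataclass(frozen=True)
class LandmarkSimModel:
    """Two-species 3D landmark generator with quadratic allometric growth.

    Each specimen's shape is the template plus (for the second species) a
    fixed displacement field, plus an allometric displacement that is linear
    and quadratic in standardised centroid size, plus isotropic Gaussian
    noise; the configuration is then scaled to its drawn centroid size.
    Size ranges are per age class, emulating cross-sectional growth series.
    """

    template: np.ndarray
    species_offset: np.ndarray
    allometry_linear: Mapping[str, np.ndarray]
    allometry_quadratic: Mapping[str, np.ndarray]
    size_ranges: Mapping[str, tuple[float, float]]
    noise_sd: float = 0.005
    n_per_group: int = 11
    species: tuple[str, str] = ("ringed", "grey")
    pairing: SymmetryPairing | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "template", np.asarray(self.template, float))
        object.__setattr__(self, "species_offset", np.asarray(self.species_offset, float))
        if self.template.ndim != 2 or self.template.shape[1] != 3:
            raise ParameterError("template must be (k, 3)")
        if self.template.shape[0] < 4:
            raise ParameterError("need k >= 4 landmarks")
        if centroid_size(self.template) <= 0:
            raise ParameterError("degenerate template: zero centroid size")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.n_per_group < 1:
            raise ParameterError("n_per_group must be >= 1")

    @property
    def k_landmarks(self) -> int:
        return self.template.shape[0]


def default_landmark_model(
    k_landmarks: int = 46,
    offset_scale: float = 0.05,
    noise_sd: float = 0.005,
    n_per_group: int = 11,
    seed: int = 0,
    species_allometry_delta: float = 0.0,
) -> LandmarkSimModel:
    """Packaged two-species landmark model.

    The template is a fixed bilaterally symmetric pseudo-cranium at unit
    centroid size (deterministically constructed, independent of ``seed``);
    ``offset_scale`` is the Procrustes-scale magnitude of the species mean
    difference (0 gives an exchangeable null); allometric coefficients are
    shared between species unless ``species_allometry_delta`` adds a
    species-specific trajectory component.
    """
    maker = np.random.default_rng(20180903)  # fixed: defines the template, not the sample
    n_mid = k_landmarks % 2 + 4
    n_pairs = (k_landmarks - n_mid) // 2
    n_mid = k_landmarks - 2 * n_pairs
    mid = np.column_stack([
        np.zeros(n_mid), maker.uniform(-1, 1, n_mid), maker.uniform(-1, 1, n_mid)])
    right = np.column_stack([
        maker.uniform(0.2, 1.0, n_pairs),
        maker.uniform(-1, 1, n_pairs), maker.uniform(-1, 1, n_pairs)])
    left = right * np.array([-1.0, 1.0, 1.0])
    template = np.vstack([mid, right, left])
    template -= template.mean(axis=0)
    template /= centroid_size(template)
    pairs = [(n_mid + i, n_mid + n_pairs + i) for i in range(n_pairs)]
    pairing = SymmetryPairing(pairs, midline=list(range(n_mid)))

    def unit_field() -> np.ndarray:
        v = maker.normal(size=(k_landmarks, 3))
        return v / np.linalg.norm(v)

    offset = unit_field() * offset_scale
    lin_shared, quad_shared = unit_field() * 0.03, unit_field() * 0.012
    allo_lin = {"ringed": lin_shared, "grey": lin_shared.copy()}
    allo_quad = {"ringed": quad_shared, "grey": quad_shared.copy()}
    if species_allometry_delta:
        allo_lin["grey"] = lin_shared + unit_field() * species_allometry_delta
    return LandmarkSimModel(
        template=template,
        species_offset=offset,
        allometry_linear=allo_lin,
        allometry_quadratic=allo_quad,
        size_ranges={"newborn": (1.0, 1.3), "juvenile": (1.4, 1.9), "adult": (2.0, 2.6)},
        noise_sd=noise_sd,
        n_per_group=n_per_group,
        pairing=pairing,
        seed=seed,
    )


def simulate_landmark_sample(model: LandmarkSimModel) -> LandmarkSet:
    """Draw specimens for every species x age-class group."""
    rng = np.random.default_rng(model.seed)
    all_sizes = np.concatenate([np.asarray(r, float) for r in model.size_ranges.values()])
    s_mid = (all_sizes.min() + all_sizes.max()) / 2.0
    s_half = (all_sizes.max() - all_sizes.min()) / 2.0 or 1.0

    ids, coords, species, sexes, ages = [], [], [], [], []
    for sp_i, sp in enumerate(model.species):
        for age, (lo, hi) in model.size_ranges.items():
            for j in range(model.n_per_group):
                s = rng.uniform(lo, hi)
                z = (s - s_mid) / s_half
                shape = model.template.copy()
                if sp_i == 1:
                    shape = shape + model.species_offset
                shape = (shape
                         + model.allometry_linear[sp] * z
                         + model.allometry_quadratic[sp] * z**2)
                if model.noise_sd > 0:
                    shape = shape + rng.normal(0.0, model.noise_sd, shape.shape)
                cs = centroid_size(shape)
                if cs <= 0:
                    raise ParameterError("generated configuration degenerate")
                coords.append(shape / cs * s)
                ids.append(f"{sp}_{age}_{j:02d}")
                species.append(sp)
                sexes.append("F" if (j + sp_i) % 2 else "M")
                ages.append(age)
    return LandmarkSet(
        ids, np.stack(coords), np.array(species), np.array(sexes), np.array(ages),
        pairing=model.pairing,
    )


# ---------------------------------------------------------------------------
# F1 genotypes for the supervised admixture estimator


def simulate_f1_genotypes(
    n_sites: int,
    divergence: float = 0.2,
    seed: int = 0,
    offspring: str = "f1",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Parental allele-frequency tables and a simulated offspring.

    Parental frequencies follow the Balding-Nichols construction: an
    ancestral frequency is drawn uniformly on (0.05, 0.95) and each parental
    population's frequency is Beta-distributed around it with drift
    parameter ``divergence`` (an F_ST-like quantity). The offspring's
    genotype at each site is one allele sampled from each parental frequency
    (``offspring="f1"``), or both alleles from a single parent
    (``"parent_a"``/``"parent_b"``).
    """
    if n_sites < 1:
        raise ParameterError("n_sites must be >= 1")
    if not 0.0 < divergence < 1.0:
        raise ParameterError("divergence must be in (0, 1)")
    if offspring not in ("f1", "parent_a", "parent_b"):
        raise ParameterError(f"unknown offspring mode {offspring!r}")
    rng = np.random.default_rng(seed)
    c = (1.0 - divergence) / divergence
    anc = rng.uniform(0.05, 0.95, n_sites)
    freq_a = rng.beta(anc * c, (1.0 - anc) * c)
    freq_b = rng.beta(anc * c, (1.0 - anc) * c)
    if offspring == "f1":
        g = (rng.random(n_sites) < freq_a).astype(int) + (
            rng.random(n_sites) < freq_b).astype(int)
    else:
        p = freq_a if offspring == "parent_a" else freq_b
        g = (rng.random(n_sites) < p).astype(int) + (rng.random(n_sites) < p).astype(int)
    table = pd.DataFrame({"site": np.arange(n_sites), "freq_a": freq_a, "freq_b": freq_b})
    return table, g
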