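"""Patterson's D-statistic with weighted block jackknife, and a supervised
two-source admixture estimator.

The four-taxon test uses derived-allele frequencies for taxa
(P1, P2; P3, Outgroup) — in the seal application (Saimaa ringed, Baltic
ringed; Baltic grey, Weddell). Per site,

    ABBA = (1-p1) * p2 * p3 * (1-p4)
    BABA = p1 * (1-p2) * p3 * (1-p4)
    D    = (sum ABBA - sum BABA) / (sum ABBA + sum BABA)

A positive D indicates an excess of derived alleles shared between P2 and
P3, i.e. gene flow violating the species tree. The standard error comes
from a delete-one-block jackknife over contiguous genomic blocks, weighted
by each block's ABBA+BABA denominator (Busing-style delete-m jackknife for
unequal block sizes), which is robust to linkage within blocks.

The admixture estimator treats an individual's genotypes g_j in {0,1,2} as
Binomial(2, m_j) with m_j = q*a_j + (1-q)*b_j, where a_j and b_j are the
two parental populations' allele frequencies, and maximises the likelihood
over the ancestry proportion q in [0,1]. For a first-generation hybrid the
expectation is q = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import comb

from .errors import (
    InputError,
    JackknifeError,
    NonIdentifiableError,
    UndefinedStatisticError,
)

PANEL_COLUMNS = ["scaffold", "pos", "block", "p1", "p2", "p3", "p4"]


@dataclass
class SitePanel:
    """Per-site derived-allele frequencies for the four taxa of an ABBA-BABA
    configuration, with contiguous block labels for the jackknife."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.df.columns]
        if missing:
            raise InputError(f"site panel missing columns: {missing}")
        freqs = self.df[["p1", "p2", "p3", "p4"]].to_numpy(float)
        if not np.isfinite(freqs).all() or (freqs < 0).any() or (freqs > 1).any():
            raise InputError("derived-allele frequencies must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.df)

    @property
    def n_blocks(self) -> int:
        return self.df["block"].nunique()

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SitePanel":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def swap_p1_p2(self) -> "SitePanel":
        df = self.df.rename(columns={"p1": "p2", "p2": "p1"})
        return SitePanel(df[PANEL_COLUMNS])


@dataclass
class DResult:
    """D-statistic with its weighted block-jackknife uncertainty."""

    D: float
    abba_sum: float
    baba_sum: float
    SE: float
    Z: float
    n_blocks: int
    block_estimates: pd.DataFrame  # block, abba, baba, D_leave_out

    def to_dict(self) -> dict:
        return {
            "D": self.D,
            "abba_sum": self.abba_sum,
            "baba_sum": self.baba_sum,
            "SE": self.SE,
            "Z": self.Z,
            "n_blocks": self.n_blocks,
        }


@dataclass
class AdmixtureEstimate:
    """Maximum-likelihood ancestry proportion from parental population A."""

    q: float
    log_likelihood: float
    n_sites: int

    def to_dict(self) -> dict:
        return {"q": self.q, "log_likelihood": self.log_likelihood, "n_sites": self.n_sites}


def abba_baba_counts(panel: SitePanel) -> tuple[float, float, pd.DataFrame]:
    """Frequency-weighted ABBA and BABA sums, overall and per block."""
    df = panel.df
    p1 = df["p1"].to_numpy(float)
    p2 = df["p2"].to_numpy(float)
    p3 = df["p3"].to_numpy(float)
    p4 = df["p4"].to_numpy(float)
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    per_block = (
        pd.DataFrame({"block": df["block"].to_numpy(), "abba": abba, "baba": baba})
        .groupby("block", sort=True)
        .sum()
        .reset_index()
    )
    return float(abba.sum()), float(baba.sum()), per_block


def d_statistic_jackknife(panel: SitePanel) -> DResult:
    """Patterson's D with a weighted delete-one-block jackknife SE.

    Each block j with denominator m_j (its ABBA+BABA sum) is left out in
    turn; the leave-one-out estimates are combined with weights proportional
    to m_j following the delete-m jackknife of Busing et al. (1999), so that
    blocks carrying unequal information contribute accordingly.
    """
    abba_sum, baba_sum, per_block = abba_baba_counts(panel)
    denom = abba_sum + baba_sum
    if denom <= 0:
        raise UndefinedStatisticError("ABBA + BABA is zero: D undefined")
    D = (abba_sum - baba_sum) / denom

    informative = per_block[(per_block["abba"] + per_block["baba"]) > 0].copy()
    B = len(informative)
    if B < 2:
        raise JackknifeError(f"need >= 2 informative blocks for jackknife, have {B}")

    m = (informative["abba"] + informative["baba"]).to_numpy(float)
    abba_j = (abba_sum - informative["abba"].to_numpy(float))
    baba_j = (baba_sum - informative["baba"].to_numpy(float))
    theta_j = (abba_j - baba_j) / (abba_j + baba_j)  # leave-one-out estimates
    n = denom
    h = n / m
    theta_dot = B * D - float(((1 - m / n) * theta_j).sum())
    tau = h * D - (h - 1) * theta_j  # weighted pseudovalues
    var = float(((tau - theta_dot) ** 2 / (h - 1)).sum()) / B
    SE = float(np.sqrt(var))
    Z = D / SE if SE > 0 else np.inf * np.sign(D) if D != 0 else 0.0

    informative["D_leave_out"] = theta_j
    return DResult(D, abba_sum, baba_sum, SE, float(Z), B, informative)


def supervised_admixture(
    genotypes: np.ndarray,
    freq_a: np.ndarray,
    freq_b: np.ndarray,
    clamp: float = 1e-6,
) -> AdmixtureEstimate:
    """Supervised ML estimate of the ancestry fraction q from population A.

    Maximises the binomial log-likelihood of diploid genotype counts under
    site-wise expected derived-allele frequency m_j = q*a_j + (1-q)*b_j,
    with frequencies clamped away from 0 and 1 for numerical stability.
    """
    g = np.asarray(genotypes, float)
    a = np.clip(np.asarray(freq_a, float), clamp, 1 - clamp)
    b = np.clip(np.asarray(freq_b, float), clamp, 1 - clamp)
    if not (g.shape == a.shape == b.shape):
        raise InputError("genotypes and frequency arrays must have equal shape")
    if g.size == 0:
        raise NonIdentifiableError("no sites provided")
    if not np.isin(g, [0, 1, 2]).all():
        raise InputError("genotypes must be in {0, 1, 2}")
    if np.allclose(a, b):
        raise NonIdentifiableError(
            "parental frequencies identical at every site: q not identifiable"
        )

    const = float(np.log(comb(2, g)).sum())

    def negloglik(q: float) -> float:
        m = np.clip(q * a + (1 - q) * b, clamp, 1 - clamp)
        return -float((g * np.log(m) + (2 - g) * np.log(1 - m)).sum())

    res = minimize_scalar(negloglik, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-8})
    q_hat = float(res.x)
    return AdmixtureEstimate(q_hat, -float(res.fun) + const, int(g.size))


def frequencies_from_vcf(path: str | Path, samples_by_taxon: dict[str, list[str]],
                         n_blocks: int = 100) -> SitePanel:
    """Minimal biallelic-VCF reader producing a four-taxon frequency panel.

    ``samples_by_taxon`` maps 'p1'..'p4' to sample-name lists; per taxon the
    derived-allele frequency at each site is the mean ALT dosage over called
    genotypes. Sites with any taxon fully uncalled, or with more than one ALT
    allele, are skipped. Blocks are assigned as ``n_blocks`` contiguous
    roughly equal runs of retained sites.
    """
    expected = {"p1", "p2", "p3", "p4"}
    if set(samples_by_taxon) != expected:
        raise InputError(f"samples_by_taxon must have keys {sorted(expected)}")
    header: list[str] = []
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                header = fields
                continue
            if not header:
                raise InputError("VCF missing #CHROM header line")
            chrom, pos, _, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt or alt == "." or len(ref) != 1 or len(alt) != 1:
                continue
            fmt = fields[8].split(":")
            gt_i = fmt.index("GT") if "GT" in fmt else 0
            sample_gt = {name: fields[9 + i].split(":")[gt_i]
                         for i, name in enumerate(header[9:])}
            freqs = {}
            ok = True
            for taxon, samples in samples_by_taxon.items():
                alleles = []
                for s in samples:
                    gt = sample_gt.get(s, "./.")
                    for al in gt.replace("|", "/").split("/"):
                        if al in ("0", "1"):
                            alleles.append(int(al))
                if not alleles:
                    ok = False
                    break
                freqs[taxon] = float(np.mean(alleles))
            if ok:
                rows.append({"scaffold": chrom, "pos": int(pos), **freqs})
    if not rows:
        raise InputError("no usable biallelic sites in VCF")
    df = pd.DataFrame(rows)
    df["block"] = np.minimum(
        (np.arange(len(df)) * n_blocks) // len(df), n_blocks - 1
    )
    return SitePanel(df[PANEL_COLUMNS])
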