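"""Neutral genetic distances from fourfold-degenerate sites of codon alignments.

The pipeline implemented here takes per-gene codon alignments, masks dicodon
windows containing more than one variable position, removes codons with
missing data, discards genes shorter than a minimum length, concatenates the
survivors, extracts third positions of codons that are fourfold degenerate in
every species, and computes pairwise Tamura (1992) distances

    d = -2*theta*(1-theta) * ln(1 - P/(2*theta*(1-theta)) - Q)
        - (1/2)*(1 - 2*theta*(1-theta)) * ln(1 - 2*Q)

where P and Q are the proportions of sites differing by a transition and a
transversion and theta is the GC content of the compared pair. Fourfold
sites are a standard proxy for neutrally evolving sequence, and the T92
correction accounts for transition/transversion bias and GC composition.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import (
    DegenerateCompositionError,
    FormatError,
    InputError,
    ParameterError,
    SaturationError,
)

MISSING = "N"
_BASES = frozenset("ACGT")
_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


def fourfold_prefixes(table: str | int = "Standard") -> frozenset[str]:
    """Dinucleotide prefixes whose codon family is fourfold degenerate.

    Derived from the requested NCBI genetic code: a prefix qualifies iff all
    four codons sharing it encode the same amino acid (no stop codons).
    """
    try:
        if isinstance(table, int):
            code = CodonTable.unambiguous_dna_by_id[table]
        else:
            code = CodonTable.unambiguous_dna_by_name[table]
    except KeyError as exc:
        raise ParameterError(f"unknown genetic code table: {table!r}") from exc
    prefixes = set()
    for first in "ACGT":
        for second in "ACGT":
            codons = [first + second + third for third in "ACGT"]
            if any(c in code.stop_codons for c in codons):
                continue
            aas = {code.forward_table[c] for c in codons}
            if len(aas) == 1:
                prefixes.add(first + second)
    return frozenset(prefixes)


@dataclass
class CodonAlignment:
    """A gap-free codon-aligned set of sequences over a shared species set.

    ``sequences`` maps species label to an upper-case nucleotide string whose
    length is divisible by three; ambiguity codes and gaps are normalised to
    the missing symbol ``N``.  ``gene_boundaries`` records the provenance of
    each codon-run as ``(gene_id, start_nt, end_nt)`` half-open intervals so
    that concatenated alignments retain per-gene structure.
    """

    sequences: dict[str, str]
    gene_id: str | None = None
    gene_boundaries: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise InputError("alignment has no sequences")
        norm = {}
        lengths = set()
        for sp, seq in self.sequences.items():
            s = "".join(c if c in _BASES else MISSING for c in seq.upper().replace("-", MISSING))
            norm[sp] = s
            lengths.add(len(s))
        if len(lengths) != 1:
            raise FormatError("sequences have unequal lengths")
        (n,) = lengths
        if n % 3 != 0:
            raise FormatError(f"alignment length {n} is not divisible by 3")
        self.sequences = norm
        if not self.gene_boundaries:
            self.gene_boundaries = [(self.gene_id or "gene", 0, n)]

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_nt(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def n_codons(self) -> int:
        return self.n_nt // 3

    def codon(self, species: str, i: int) -> str:
        return self.sequences[species][3 * i : 3 * i + 3]

    @classmethod
    def from_fasta(cls, path: str | Path, gene_id: str | None = None) -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise FormatError(f"no sequences in {path}")
        gid = gene_id if gene_id is not None else Path(path).stem
        return cls({r.id: str(r.seq) for r in records}, gene_id=gid)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sp, seq in self.sequences.items():
                fh.write(f">{sp}\n{seq}\n")


@dataclass
class SiteMatrix:
    """Columns of retained third-position bases with their codon provenance."""

    species: list[str]
    bases: np.ndarray  # (n_species, n_sites) of single characters
    provenance: pd.DataFrame  # columns: gene_id, codon_index

    def __post_init__(self) -> None:
        self.bases = np.asarray(self.bases, dtype="U1")
        if self.bases.ndim != 2 or self.bases.shape[0] != len(self.species):
            raise InputError("bases must be (n_species, n_sites)")

    @property
    def n_sites(self) -> int:
        return self.bases.shape[1]

    def sequence(self, species: str) -> str:
        return "".join(self.bases[self.species.index(species)])


@dataclass
class DistanceMatrix:
    """Pairwise T92 distances plus the per-pair counts they derive from."""

    species: list[str]
    distances: pd.DataFrame  # square, symmetric, zero diagonal
    pair_stats: pd.DataFrame  # index (sp1, sp2); n_sites, P, Q, theta, d
    ratios: pd.DataFrame | None = None  # distances relative to a reference pair
    reference_pair: tuple[str, str] | None = None

    def to_tsv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.distances.to_csv(f"{prefix}.distances.tsv", sep="\t")
        self.pair_stats.to_csv(f"{prefix}.pair_stats.tsv", sep="\t")
        if self.ratios is not None:
            self.ratios.to_csv(f"{prefix}.ratios.tsv", sep="\t")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.species)}\n")
            for sp in self.species:
                row = " ".join(f"{self.distances.loc[sp, o]:.6f}" for o in self.species)
                fh.write(f"{sp:<10s} {row}\n")


def _window_variant_count(codons: list[str]) -> int:
    """Number of variable positions in a 6 nt two-codon window.

    A position counts as variable when the species do not all carry one
    identical defined base; positions where every species is missing do not
    count (this makes masking idempotent).
    """
    count = 0
    for pos in range(6):
        col = {c[pos] for c in codons}
        defined = col - {MISSING}
        if len(defined) > 1 or (defined and MISSING in col):
            count += 1
    return count


def mask_dicodon_variation(aln: CodonAlignment, step: int = 1) -> CodonAlignment:
    """Mask dicodon windows containing more than one variable position.

    Every window of two adjacent codons (within a gene) is inspected; if more
    than one of its six positions is variable across species, both codons are
    replaced by the missing symbol in all species. Windows are evaluated on
    the unmasked input and the masking applied afterwards. ``step=1`` slides
    the window codon by codon (overlapping, the default strict reading);
    ``step=2`` evaluates non-overlapping windows.
    """
    if step not in (1, 2):
        raise ParameterError("step must be 1 (overlapping) or 2 (non-overlapping)")
    to_mask: set[int] = set()
    for gene_id, start, end in aln.gene_boundaries:
        c0, c1 = start // 3, end // 3
        for i in range(c0, c1 - 1, step):
            window = [aln.sequences[sp][3 * i : 3 * i + 6] for sp in aln.species]
            if _window_variant_count(window) > 1:
                to_mask.update((i, i + 1))
    if not to_mask:
        return CodonAlignment(dict(aln.sequences), aln.gene_id, list(aln.gene_boundaries))
    masked = {}
    for sp, seq in aln.sequences.items():
        codons = [seq[3 * i : 3 * i + 3] for i in range(aln.n_codons)]
        for i in to_mask:
            codons[i] = MISSING * 3
        masked[sp] = "".join(codons)
    return CodonAlignment(masked, aln.gene_id, list(aln.gene_boundaries))


def _clean_codon_indices(aln: CodonAlignment) -> list[int]:
    """Indices of codons with no missing base in any species."""
    keep = []
    for i in range(aln.n_codons):
        if all(MISSING not in aln.codon(sp, i) for sp in aln.species):
            keep.append(i)
    return keep


def filter_and_concatenate(
    alns: Sequence[CodonAlignment], min_len: int = 100
) -> CodonAlignment:
    """Drop missing-data columns, filter short genes, and concatenate.

    Columns with a missing base in any species are removed whole-codon-wise
    (so the reading frame and codon context stay valid); genes whose cleaned
    length falls below ``min_len`` nucleotide columns are discarded; the rest
    are concatenated in input order with gene boundaries recorded.
    """
    if not alns:
        raise InputError("no alignments to concatenate")
    species = alns[0].species
    sp_set = set(species)
    parts: dict[str, list[str]] = {sp: [] for sp in species}
    boundaries: list[tuple[str, int, int]] = []
    offset = 0
    for aln in alns:
        if set(aln.species) != sp_set:
            raise InputError(
                f"species set mismatch in gene {aln.gene_id!r}: "
                f"{sorted(aln.species)} vs {sorted(species)}"
            )
        keep = _clean_codon_indices(aln)
        clean_len = 3 * len(keep)
        if clean_len < min_len:
            continue
        for sp in species:
            seq = aln.sequences[sp]
            parts[sp].append("".join(seq[3 * i : 3 * i + 3] for i in keep))
        boundaries.append((aln.gene_id or f"gene{len(boundaries)}", offset, offset + clean_len))
        offset += clean_len
    concat = {sp: "".join(chunks) for sp, chunks in parts.items()}
    if offset == 0:
        concat = {sp: "" for sp in species}
    return CodonAlignment(concat, gene_id="concatenated", gene_boundaries=boundaries)


def extract_ffd_sites(
    aln: CodonAlignment, table: str | int = "Standard", mode: str = "ffd"
) -> SiteMatrix:
    """Extract third-position sites from fourfold-degenerate codon columns.

    A third position is retained iff in *every* species the codon at that
    column belongs to a fourfold-degenerate family of the genetic code
    (``mode="ffd"``), or simply has no missing base (``mode="third"``, the
    all-third-position alternative used as a robustness check).
    """
    if mode not in ("ffd", "third"):
        raise ParameterError(f"mode must be 'ffd' or 'third', got {mode!r}")
    prefixes = fourfold_prefixes(table)
    cols: list[list[str]] = []
    prov: list[tuple[str, int]] = []
    for gene_id, start, end in aln.gene_boundaries:
        for i in range(start // 3, end // 3):
            codons = [aln.codon(sp, i) for sp in aln.species]
            if any(MISSING in c for c in codons):
                continue
            if mode == "ffd" and not all(c[:2] in prefixes for c in codons):
                continue
            cols.append([c[2] for c in codons])
            prov.append((gene_id, i))
    bases = (
        np.array(cols, dtype="U1").T if cols else np.empty((len(aln.species), 0), dtype="U1")
    )
    provenance = pd.DataFrame(prov, columns=["gene_id", "codon_index"])
    return SiteMatrix(list(aln.species), bases, provenance)


def t92_distance(seq1: Iterable[str], seq2: Iterable[str]) -> dict[str, float]:
    """Tamura (1992) distance between two equal-length gap-free sequences.

    Returns a dict with n_sites, P (transition proportion), Q (transversion
    proportion), theta (pairwise GC content) and the corrected distance d.
    """
    a = np.asarray(list(seq1), dtype="U1")
    b = np.asarray(list(seq2), dtype="U1")
    if a.shape != b.shape:
        raise InputError("sequences differ in length")
    n = a.size
    if n == 0:
        raise InputError("no sites to compare")
    both = np.concatenate([a, b])
    theta = float(np.isin(both, ["G", "C"]).mean())
    if theta in (0.0, 1.0):
        raise DegenerateCompositionError(f"GC content theta={theta}: T92 undefined")
    diff = a != b
    ts = sum(1 for x, y in zip(a[diff], b[diff]) if (x, y) in _TRANSITIONS)
    tv = int(diff.sum()) - ts
    P, Q = ts / n, tv / n
    w = 2.0 * theta * (1.0 - theta)
    arg1 = 1.0 - P / w - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        raise SaturationError(
            f"T92 correction undefined (P={P:.4f}, Q={Q:.4f}, theta={theta:.4f}):"
            " divergence saturated"
        )
    d = -w * math.log(arg1) - 0.5 * (1.0 - w) * math.log(arg2)
    return {"n_sites": n, "P": P, "Q": Q, "theta": theta, "d": d}


def t92_distance_matrix(
    sites: SiteMatrix, reference_pair: tuple[str, str] | None = None
) -> DistanceMatrix:
    """All pairwise T92 distances over a site matrix, with optional ratios.

    ``reference_pair`` names the species pair whose distance is the
    denominator for the reported distance ratios (how much closer/farther
    each pair is than the reference).
    """
    if sites.n_sites < 1:
        raise InputError("site matrix is empty")
    sp = sites.species
    dmat = pd.DataFrame(0.0, index=sp, columns=sp)
    rows = []
    for i, j in itertools.combinations(range(len(sp)), 2):
        try:
            stats = t92_distance(sites.bases[i], sites.bases[j])
        except (SaturationError, DegenerateCompositionError) as exc:
            raise type(exc)(f"pair ({sp[i]}, {sp[j]}): {exc}") from exc
        dmat.loc[sp[i], sp[j]] = dmat.loc[sp[j], sp[i]] = stats["d"]
        rows.append({"sp1": sp[i], "sp2": sp[j], **stats})
    pair_stats = pd.DataFrame(rows).set_index(["sp1", "sp2"])
    ratios = None
    if reference_pair is not None:
        r1, r2 = reference_pair
        if r1 not in sp or r2 not in sp:
            raise ParameterError(f"reference pair {reference_pair} not in species set")
        ref_d = dmat.loc[r1, r2]
        if ref_d == 0:
            raise ParameterError("reference pair has zero distance; ratios undefined")
        ratios = (pair_stats["d"] / ref_d).rename("ratio_to_reference").to_frame()
    return DistanceMatrix(sp, dmat, pair_stats, ratios, reference_pair)
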