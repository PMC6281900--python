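"""Configuration-driven orchestration of the five analysis stages.

A single YAML/dict configuration enables any subset of the stages —
sequence distances, introgression + admixture, dental statistics, tooth
development, morphometrics — on synthetic data generated from the global
seed, writes per-stage artifacts into an output directory, and produces a
machine-parseable JSON report plus a Markdown summary. A fixed global seed
fully determines every stochastic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__, dental, introgression, morpho, seqdist, synthetic_data as sd, toothdev
from .errors import InputError

logger = logging.getLogger("hybridbracket.pipeline")

STAGES = ("seqdist", "introgression", "admixture", "dental", "toothdev", "morpho")

#: Per-stage recognised parameter keys (None means the stage block only has
#: ``enabled`` plus these); used for strict validation before anything runs.
_STAGE_KEYS: dict[str, set[str]] = {
    "seqdist": {"enabled", "n_genes", "n_codons", "d_true", "gc", "kappa", "min_len", "mode"},
    "introgression": {"enabled", "f", "eps", "beta", "p_bbaa", "n_sites", "n_blocks"},
    "admixture": {"enabled", "n_sites", "divergence"},
    "dental": {"enabled", "n_per_species", "coverage"},
    "toothdev": {"enabled", "full_grid"},
    "morpho": {"enabled", "n_per_group", "offset_scale", "noise_sd", "n_perm", "symmetrize"},
}
_TOP_KEYS = {"seed", "outdir", "log_level", "stages"}

REPORT_SCHEMA = {
    "provenance": {"seed": int, "version": str, "config_sha256": str},
    "stages": dict,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    outdir: str = "hybridbracket_out"
    log_level: str = "INFO"
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, block in self.stages.items():
            if name not in _STAGE_KEYS:
                raise InputError(f"unknown stage {name!r}; valid stages: {STAGES}")
            unknown = set(block) - _STAGE_KEYS[name]
            if unknown:
                raise InputError(f"unknown keys in stage {name!r}: {sorted(unknown)}")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "WARN", "ERROR"):
            raise InputError(f"invalid log level {self.log_level!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - _TOP_KEYS
        if unknown:
            raise InputError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def sha256(self) -> str:
        canon = json.dumps(
            {"seed": self.seed, "stages": self.stages}, sort_keys=True
        ).encode()
        return hashlib.sha256(canon).hexdigest()

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, {}).get("enabled", False))

    def params(self, stage: str) -> dict:
        block = dict(self.stages.get(stage, {}))
        block.pop("enabled", None)
        return block


@dataclass
class Report:
    """Per-stage result summaries plus provenance."""

    provenance: dict
    stages: dict[str, dict]

    def to_dict(self) -> dict:
        return {"provenance": self.provenance, "stages": self.stages}

    def to_markdown(self) -> str:
        lines = ["# hybridbracket pipeline report", ""]
        prov = self.provenance
        lines += [f"- seed: {prov['seed']}", f"- version: {prov['version']}",
                  f"- config: sha256 {prov['config_sha256'][:12]}…", ""]
        for stage, summary in self.stages.items():
            lines.append(f"## {stage}")
            lines.append("")
            for key, value in summary.items():
                if isinstance(value, list):
                    continue
                lines.append(f"- {key}: {value}")
            lines.append("")
        return "\n".join(lines)


def validate_report(report: dict) -> None:
    """Structural validation of a report against the packaged schema."""
    for key, spec in REPORT_SCHEMA.items():
        if key not in report:
            raise InputError(f"report missing key {key!r}")
        if isinstance(spec, dict):
            for sub, typ in spec.items() if spec is not REPORT_SCHEMA["stages"] else []:
                if sub not in report[key] or not isinstance(report[key][sub], typ):
                    raise InputError(f"report provenance field {sub!r} missing or mistyped")
    if not isinstance(report["stages"], dict):
        raise InputError("report 'stages' must be a mapping")


def _stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage substream below 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# --- individual stages -----------------------------------------------------


def _run_seqdist(params: dict, seed: int, outdir: Path) -> dict:
    n_genes = int(params.get("n_genes", 3))
    genes = []
    for i in range(n_genes):
        model = sd.CodonSimModel(
            n_codons=int(params.get("n_codons", 2000)),
            d_true=float(params.get("d_true", 0.1)),
            gc=float(params.get("gc", 0.5)),
            kappa=float(params.get("kappa", 2.0)),
            seed=_stage_seed(seed, f"seqdist:{i}"),
        )
        aln = sd.simulate_codon_alignment(model)
        genes.append(seqdist.mask_dicodon_variation(aln))
    concat = seqdist.filter_and_concatenate(genes, min_len=int(params.get("min_len", 100)))
    sites = seqdist.extract_ffd_sites(concat, mode=params.get("mode", "ffd"))
    dm = seqdist.t92_distance_matrix(sites)
    dm.to_tsv(outdir / "seqdist")
    pair = dm.pair_stats.iloc[0]
    return {
        "n_genes_retained": len(concat.gene_boundaries),
        "n_ffd_sites": int(sites.n_sites),
        "d_t92": float(pair["d"]),
        "P": float(pair["P"]), "Q": float(pair["Q"]), "theta": float(pair["theta"]),
    }


def _run_introgression(params: dict, seed: int, outdir: Path) -> dict:
    model = sd.SitePatternModel(
        f=float(params.get("f", 0.2)),
        eps=float(params.get("eps", 0.05)),
        beta=float(params.get("beta", 0.25)),
        p_bbaa=float(params.get("p_bbaa", 0.2)),
        n_sites=int(params.get("n_sites", 100_000)),
        n_blocks=int(params.get("n_blocks", 100)),
        seed=_stage_seed(seed, "introgression"),
    )
    panel = sd.simulate_site_patterns(model)
    panel.to_tsv(outdir / "site_panel.tsv")
    res = introgression.d_statistic_jackknife(panel)
    return {**res.to_dict(), "expected_D": model.expected_d()}


def _run_admixture(params: dict, seed: int, outdir: Path) -> dict:
    table, g = sd.simulate_f1_genotypes(
        n_sites=int(params.get("n_sites", 10_000)),
        divergence=float(params.get("divergence", 0.2)),
        seed=_stage_seed(seed, "admixture"),
    )
    table.to_csv(outdir / "parental_frequencies.tsv", sep="\t", index=False)
    est = introgression.supervised_admixture(
        g, table["freq_a"].to_numpy(), table["freq_b"].to_numpy())
    return est.to_dict()


def _run_dental(params: dict, seed: int, outdir: Path) -> dict:
    model = sd.ToothSimModel(
        n_per_species=int(params.get("n_per_species", 65)),
        seed=_stage_seed(seed, "dental"),
    )
    a, b, hybrid = sd.simulate_tooth_sample(model)
    a.to_csv(outdir / "tooth_sample_a.csv")
    b.to_csv(outdir / "tooth_sample_b.csv")
    disp = dental.dental_disparity(a, b)
    bracket = dental.intermediacy_bracket(
        a, b, hybrid, coverage=float(params.get("coverage", 0.8)))
    disp.per_position.to_csv(outdir / "disparity.tsv", sep="\t", index=False)
    bracket.per_position.to_csv(outdir / "bracket.tsv", sep="\t", index=False)
    return {
        "disparity_mean": disp.delta_mean,
        "disparity_mode": disp.delta_mode,
        "hybrid_inside_all_positions": bracket.all_inside,
        "n_positions_inside": int(bracket.per_position["inside"].sum()),
    }


def _run_toothdev(params: dict, seed: int, outdir: Path) -> dict:
    ringed, grey = toothdev.RINGED_SEAL_ROW, toothdev.GREY_SEAL_ROW
    hybrid = toothdev.make_hybrid_row_spec(ringed, grey, "average")
    summaries = [
        toothdev.row_summary(toothdev.simulate_tooth_row(spec), spec.label or "hybrid")
        for spec in (ringed, grey, hybrid)
    ]
    import pandas as pd

    table = pd.concat(summaries, ignore_index=True)
    table.to_csv(outdir / "tooth_rows.tsv", sep="\t", index=False)
    if params.get("full_grid", False):
        grid = toothdev.hybrid_combination_grid(ringed, grey)
        grid.to_csv(outdir / "hybrid_grid.tsv", sep="\t", index=False)
    wide = table.pivot(index="position", columns="row_label", values="angle_deg")
    intermediate = bool((
        (wide["hybrid"] >= np.minimum(wide["ringed"], wide["grey"]) - 1e-9)
        & (wide["hybrid"] <= np.maximum(wide["ringed"], wide["grey"]) + 1e-9)
    ).all())
    counts = table.pivot(index="position", columns="row_label", values="cusp_count")
    return {
        "hybrid_angle_intermediate": intermediate,
        "cusp_counts_ringed": counts["ringed"].tolist(),
        "cusp_counts_grey": counts["grey"].tolist(),
        "cusp_counts_hybrid": counts["hybrid"].tolist(),
    }


def _run_morpho(params: dict, seed: int, outdir: Path) -> dict:
    model = sd.default_landmark_model(
        offset_scale=float(params.get("offset_scale", 0.05)),
        noise_sd=float(params.get("noise_sd", 0.005)),
        n_per_group=int(params.get("n_per_group", 11)),
        seed=_stage_seed(seed, "morpho"),
    )
    lms = sd.simulate_landmark_sample(model)
    space = morpho.generalized_procrustes(
        lms, symmetrize_first=bool(params.get("symmetrize", True)))
    pca = morpho.shape_pca(space)
    newborn = space.mask_for(age_class="newborn")
    test = morpho.procrustes_permutation_test(
        space,
        newborn & space.mask_for(species=model.species[0]),
        newborn & space.mask_for(species=model.species[1]),
        n_perm=int(params.get("n_perm", 10_000)),
        seed=_stage_seed(seed, "morpho:perm"),
    )
    allo = {
        sp: morpho.quadratic_allometry(space, space.mask_for(species=sp), group=sp)
        for sp in model.species
    }
    lms.to_long_csv(outdir / "landmarks.csv")
    np.savetxt(outdir / "pca_scores.tsv", pca.scores[:, :5], delimiter="\t")
    return {
        "pc1_pc2_variance_pct": float(pca.explained_pct[:2].sum()),
        "procrustes_distance_newborn": test.distance,
        "p_value_newborn": test.p_value,
        "n_permutations": test.n_permutations,
        "allometry_residual_ss": {sp: m.residual_ss for sp, m in allo.items()},
    }


_RUNNERS = {
    "seqdist": _run_seqdist,
    "introgression": _run_introgression,
    "admixture": _run_admixture,
    "dental": _run_dental,
    "toothdev": _run_toothdev,
    "morpho": _run_morpho,
}


def run_pipeline(config: PipelineConfig) -> Report:
    """Run all enabled stages in order and write JSON + Markdown reports."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level.upper())
    summaries: dict[str, dict] = {}
    for stage in STAGES:
        if not config.enabled(stage):
            continue
        logger.info("running stage %s", stage)
        try:
            summaries[stage] = _RUNNERS[stage](config.params(stage), config.seed, outdir)
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    report = Report(
        provenance={
            "seed": config.seed,
            "version": __version__,
            "config_sha256": config.sha256(),
        },
        stages=summaries,
    )
    validate_report(report.to_dict())
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    (outdir / "report.md").write_text(report.to_markdown())
    return report
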