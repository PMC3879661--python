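"""End-to-end orchestration: simulate/load → classify → profile → usage →
peaks → group statistics, with a manifest recording every parameter.

All stage outputs are plain TSV/JSON; figures are advisory extras and
nothing downstream reads them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression as expr
from . import peaks as peaks_mod
from .genome import read_genes_tsv, read_sites_bed, sites_to_frame
from .group_stats import region_summaries, wilcoxon_compare
from .profiles import aggregate_profile, build_profile_matrix
from .simulate import (PRESETS, build_truth, reads_to_bed, read_reads_bed,
                       simulate_mnase, simulate_rnap2, simulate_rnaseq)
from .sites import classify_sites, distance_summary, load_sites
from .tags import TagCollection

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run.

    Defaults are the analysis' canonical parameters: 80-bp nucleosome and
    300-bp RNAP II strand shifts, 10-bp grid, span-5 smoothing, ±10-nt
    RUD exclusion, RPKM strata at 10 / 0.1 / 1.
    """

    outdir: str = "results/run"
    seed: int = 0
    preset: str | None = "constitutive_vs_alternative"
    genes_path: str | None = None
    sites_path: str | None = None
    mnase_path: str | None = None
    rnap2_path: str | None = None
    rnaseq_path: str | None = None
    nucleosome_shift: int = 80
    rnap2_shift: int = 300
    step: int = 10
    half_window: int = 1000
    smooth_span: int = 5
    rud_window: int = 200
    rud_exclusion: int = 10
    test_region: tuple[int, int] = (-150, 150)
    mnase_background: float = 0.005
    rnap2_body_rate: float = 0.01
    depth: float = 1.0
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.test_region = tuple(cfg.test_region)  # yaml gives a list
        return cfg

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["test_region"] = list(self.test_region)
        return d


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=float))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_manifest(), "stages": {}}
    try:
        result = _run_stages(config, out, manifest)
    except Exception as exc:  # record the failure point, then re-raise
        manifest["failed_stage"] = manifest.get("current_stage", "setup")
        manifest["error"] = str(exc)
        _write_json(manifest, out / "manifest.json")
        raise
    _write_json(manifest, out / "manifest.json")
    return result


def _run_stages(config: RunConfig, out: Path, manifest: dict) -> dict:
    # -- inputs -------------------------------------------------------
    manifest["current_stage"] = "inputs"
    if config.preset:
        truth = build_truth(PRESETS[config.preset], config.seed)
        truth.write(out / "synthetic")
        rng = np.random.default_rng(config.seed + 1)
        mnase = simulate_mnase(truth, rng, depth=config.depth,
                               background_per_base=config.mnase_background)
        rnap2 = simulate_rnap2(truth, rng, depth=config.depth,
                               body_rate_per_read=config.rnap2_body_rate)
        reads = simulate_rnaseq(truth, rng, depth=config.depth)
        mnase.to_bed(out / "synthetic" / "mnase_tags.bed")
        rnap2.to_bed(out / "synthetic" / "rnap2_tags.bed")
        reads_to_bed(reads, out / "synthetic" / "rnaseq_reads.bed")
        genes = truth.genes
        site_table = sites_to_frame(truth.sites)[
            ["site_id", "gene_id", "chrom", "position", "strand"]]
    else:
        for name in ("genes_path", "sites_path", "mnase_path"):
            p = getattr(config, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name} missing or not found: {p}")
        genes = read_genes_tsv(config.genes_path)
        site_table = read_sites_bed(config.sites_path)
        mnase = TagCollection.from_bed(config.mnase_path, "mnase")
        rnap2 = (TagCollection.from_bed(config.rnap2_path, "rnap2")
                 if config.rnap2_path else None)
        reads = read_reads_bed(config.rnaseq_path) if config.rnaseq_path else None

    # -- classification ----------------------------------------------
    manifest["current_stage"] = "classify"
    loaded, report = load_sites(site_table, genes)
    if not loaded:
        raise ValueError("no polyA site survived loading")
    classified = classify_sites(loaded, genes)
    sites_to_frame(classified).to_csv(out / "sites_classified.tsv", sep="\t", index=False)
    dist = distance_summary(classified, genes)
    dist.to_csv(out / "distance_summary.tsv", sep="\t", index=False)
    manifest["stages"]["classify"] = {
        "n_input": report.n_input, "n_retained": report.n_retained,
        "rejected": report.rejected,
    }

    # -- profiles ------------------------------------------------------
    manifest["current_stage"] = "profiles"
    chrom_sizes = truth.chrom_sizes if config.preset else None
    libraries = {"nucleosome": (mnase, config.nucleosome_shift)}
    if rnap2 is not None:
        libraries["rnap2"] = (rnap2, config.rnap2_shift)
    groupings = {
        "site_class": lambda s: s.site_class,
        "position_class": lambda s: s.position_class,
    }
    matrices = {}
    profile_files = []
    for lib_name, (lib, shift) in libraries.items():
        matrix = build_profile_matrix(lib, classified, shift=shift,
                                      half_window=config.half_window,
                                      step=config.step, chrom_sizes=chrom_sizes)
        matrices[lib_name] = matrix
        for group_name, key in groupings.items():
            frames = []
            for label in sorted({key(s) for s in classified}):
                ids = [s.site_id for s in classified if key(s) == label]
                agg = aggregate_profile(matrix.subset(ids), config.smooth_span)
                f = agg.to_frame()
                f.insert(0, "group", label)
                frames.append(f)
            path = out / f"profile_{lib_name}_by_{group_name}.tsv"
            pd.concat(frames).to_csv(path, sep="\t", index=False)
            profile_files.append(path.name)
    manifest["stages"]["profiles"] = {"files": profile_files}

    # -- expression & usage -------------------------------------------
    manifest["current_stage"] = "usage"
    usage_frame = None
    if reads is not None and len(reads):
        expression = expr.compute_rpkm(reads, genes)
        usage = expr.compute_usage_table(reads, classified, genes,
                                         window=config.rud_window,
                                         exclusion=config.rud_exclusion)
        usage = expr.assign_usage(usage, expression)
        expr.expression_to_frame(expression).to_csv(
            out / "expression.tsv", sep="\t", index=False)
        usage_frame = expr.usage_to_frame(usage)
        usage_frame.to_csv(out / "usage.tsv", sep="\t", index=False)
        manifest["stages"]["usage"] = {
            "n_genes": len(expression),
            "n_defined_rud": int(usage_frame["rud"].notna().sum()),
        }

    # -- peaks ---------------------------------------------------------
    manifest["current_stage"] = "peaks"
    con = [s for s in classified if s.site_class == "constitutive"]
    alt = [s for s in classified if s.site_class == "alternative"]
    peak_rows = []
    comparison = None
    for region in ("upstream", "downstream"):
        p_con = peaks_mod.call_peaks(mnase, con, region, shift=config.nucleosome_shift,
                                     step=config.step, smooth_span=config.smooth_span)
        p_alt = peaks_mod.call_peaks(mnase, alt, region, shift=config.nucleosome_shift,
                                     step=config.step, smooth_span=config.smooth_span)
        peak_rows += [
            {"site_id": p.site_id, "region": p.region, "summit_offset": p.summit_offset,
             "summit_score": p.summit_score, "fuzziness": p.fuzziness,
             "n_dyads": p.n_dyads, "group": g}
            for group, g in ((p_con, "constitutive"), (p_alt, "alternative"))
            for p in group
        ]
        if region == "downstream" and len(p_con) >= 2 and len(p_alt) >= 2:
            comparison = peaks_mod.compare_positioning(
                p_con, p_alt, labels=("constitutive", "alternative"))
    pd.DataFrame(peak_rows).to_csv(out / "peaks.tsv", sep="\t", index=False)
    if comparison is not None:
        _write_json(comparison.to_dict(), out / "positioning_comparison.json")
    manifest["stages"]["peaks"] = {"n_peaks": len(peak_rows),
                                   "comparison": comparison is not None}

    # -- group statistics ---------------------------------------------
    manifest["current_stage"] = "group_stats"
    comparisons = []
    matrix = matrices["nucleosome"]
    contrasts = [("constitutive", con, "alternative", alt)]
    if usage_frame is not None:
        by_label = {
            lab: usage_frame.loc[usage_frame["usage_label"] == lab, "site_id"].tolist()
            for lab in ("high", "low")
        }
        if all(len(v) >= 2 for v in by_label.values()):
            id_map = {s.site_id: s for s in classified}
            contrasts.append(("high_usage", [id_map[i] for i in by_label["high"]],
                              "low_usage", [id_map[i] for i in by_label["low"]]))
    for name_a, grp_a, name_b, grp_b in contrasts:
        if len(grp_a) < 1 or len(grp_b) < 1:
            continue
        vals_a, _ = region_summaries(matrix.subset([s.site_id for s in grp_a]),
                                     config.test_region)
        vals_b, _ = region_summaries(matrix.subset([s.site_id for s in grp_b]),
                                     config.test_region)
        cmp_ = wilcoxon_compare(vals_a, vals_b, labels=(name_a, name_b),
                                region=config.test_region)
        comparisons.append(cmp_.to_dict())
    _write_json({"comparisons": comparisons}, out / "group_comparisons.json")
    manifest["stages"]["group_stats"] = {"n_contrasts": len(comparisons)}

    # -- figures -------------------------------------------------------
    if config.make_plots:
        manifest["current_stage"] = "figures"
        _plot_profiles(out, profile_files)

    manifest["current_stage"] = "done"
    return manifest


def _plot_profiles(out: Path, profile_files: list[str]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name in profile_files:
        df = pd.read_csv(out / name, sep="\t")
        fig, ax = plt.subplots(figsize=(6, 4))
        for label, grp in df.groupby("group"):
            ax.plot(grp["offset"], grp["mean_score"], label=str(label))
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_xlabel("offset from polyA site (bp, transcription direction)")
        ax.set_ylabel("mean occupancy score")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / (Path(name).stem + ".png"), dpi=110)
        plt.close(fig)
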