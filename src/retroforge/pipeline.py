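"""Pipeline orchestration and the summary report.

``run_all`` chains simulate (optional) → discover → Ka/Ks → ESTs →
movement → report, writing one TSV per stage plus a run manifest, so that
every number in the report is recomputable from the emitted tables alone.

``paper_arithmetic`` recomputes the worked-example ratios of a published
retrocopy catalogue from a table of printed counts (shipped with the
package for the dog catalogue), making the summary arithmetic runnable
without any genome.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .discovery import (
    DiscoveryParams,
    RetrocopyRecord,
    catalogue_frame,
    discover,
    summarize,
)
from .ests import EstParams, expression_support
from .io_formats import GenomeAssembly, read_annotation, read_fasta, write_bed6
from .kaks import (
    CodonAlignment,
    DatingParams,
    KaKsResult,
    classify_selection,
    estimate_age,
    ks_histogram,
    ng86,
)
from .movement import traffic_analysis
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths.

    Defaults reproduce the standard thresholds of the retrocopy literature:
    parent assignment at identity > 0.50, overlap > 0.50, ≥ 50 aa; spliced
    structures kept above score 35; EST mapping at identity > 0.95 /
    coverage > 0.90 with support gates of 100 bp and identity > 0.97; the
    functionality criterion ω < 0.5; λ = 1.33e-9 per year.
    """

    genome: str | None = None
    annotation: str | None = None
    proteins: str | None = None
    ests: str | None = None
    out_dir: str = "retroforge_out"
    seed: int = 0
    simulate: SimulationConfig | None = None
    discovery: DiscoveryParams = field(default_factory=DiscoveryParams)
    est: EstParams = field(default_factory=EstParams)
    dating: DatingParams = field(default_factory=DatingParams)
    min_codons: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("genome", "annotation", "proteins", "ests", "out_dir", "seed", "min_codons"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "simulate" in raw and raw["simulate"] is not None:
            cfg.simulate = SimulationConfig(**raw["simulate"])
        for key, klass in (("discovery", DiscoveryParams), ("est", EstParams), ("dating", DatingParams)):
            if key in raw and raw[key]:
                setattr(cfg, key, klass(**raw[key]))
        if "search" in raw and raw["search"]:
            from .homology import SearchParams

            cfg.discovery.search = SearchParams(**raw["search"])
        return cfg


def kaks_for_catalogue(
    records: list[RetrocopyRecord],
    dating: DatingParams | None = None,
    min_codons: int = 10,
) -> dict[str, KaKsResult]:
    """NG86 Ka/Ks per retrocopy from its stored parent/retro codon pairs."""
    out: dict[str, KaKsResult] = {}
    for rec in records:
        if len(rec.codon_pairs) < min_codons:
            continue
        out[rec.retro_id] = ng86(CodonAlignment(rec.codon_pairs))
    return out


def kaks_frame(
    records: list[RetrocopyRecord],
    kaks: dict[str, KaKsResult],
    dating: DatingParams | None = None,
) -> pd.DataFrame:
    dating = dating or DatingParams()
    rows = []
    for rec in records:
        res = kaks.get(rec.retro_id)
        if res is None:
            continue
        rows.append(
            {
                "retro_id": rec.retro_id,
                "parent_gene": rec.parent_gene,
                "n_codons": res.n_codons,
                "N": res.n_sites,
                "S": res.s_sites,
                "Nd": res.nd,
                "Sd": res.sd,
                "Ka": res.ka,
                "Ks": res.ks,
                "omega": res.omega,
                "age_mya": estimate_age(res.ks, dating),
                "selection_class": classify_selection(res),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "retro_id",
            "parent_gene",
            "n_codons",
            "N",
            "S",
            "Nd",
            "Sd",
            "Ka",
            "Ks",
            "omega",
            "age_mya",
            "selection_class",
        ],
    )


def printed_counts_path() -> Path:
    return Path(str(resources.files("retroforge").joinpath("data/printed_counts.tsv")))


def load_printed_counts(path: str | Path | None = None) -> dict[str, float]:
    df = pd.read_csv(path or printed_counts_path(), sep="\t", comment="#")
    return dict(zip(df["key"], df["value"].astype(float)))


def paper_arithmetic(
    counts: dict[str, float] | None = None, dating: DatingParams | None = None
) -> dict[str, float]:
    """Recompute a catalogue's summary ratios from printed counts.

    Input keys are raw counts (totals, class counts, per-bin ω counts, EST
    support numerators/denominators, movement category counts); output keys
    are the derived fractions/rates on the scale a report would print
    (percentages as percentages, rates per Myr, ages in Mya).
    """
    c = counts or load_printed_counts()
    dating = dating or DatingParams()
    out: dict[str, float] = {}
    out["intact_fraction_pct"] = 100.0 * c["intact"] / c["total_retrocopies"]
    out["single_retrocopy_parent_pct"] = (
        100.0 * c["parents_with_single_retrocopy"] / c["parental_genes"]
    )
    out["retrocopies_per_parent"] = c["total_retrocopies"] / c["parental_genes"]
    out["chimeric_rate_per_myr"] = c["chimeric_recent"] / c["recent_window_myr"]
    for cls in ("intact", "pseudo"):
        denom = c[f"{cls}_omega_denominator"]
        out[f"{cls}_omega_lt_05_pct"] = 100.0 * c[f"{cls}_omega_lt_05"] / denom
        out[f"{cls}_omega_mid_pct"] = 100.0 * c[f"{cls}_omega_mid"] / denom
        out[f"{cls}_omega_gt_12_pct"] = 100.0 * c[f"{cls}_omega_gt_12"] / denom
    out["est_intact_supported_pct"] = 100.0 * c["est_supported_intact"] / c["est_intact_total"]
    out["est_pseudo_supported_pct"] = 100.0 * c["est_supported_pseudo"] / c["est_pseudo_total"]
    mv_total = c["movement_inter"] + c["movement_intra"] + c["movement_scaffold_mt"]
    out["movement_inter_pct"] = 100.0 * c["movement_inter"] / mv_total
    out["movement_intra_pct"] = 100.0 * c["movement_intra"] / mv_total
    out["movement_scaffold_mt_pct"] = 100.0 * c["movement_scaffold_mt"] / mv_total
    out["lambda_per_year"] = dating.lambda_per_year
    out["age_mya_at_ks_low"] = estimate_age(c.get("ks_burst_low", 0.02), dating)
    out["age_mya_at_ks_high"] = estimate_age(c.get("ks_burst_high", 0.06), dating)
    return out


def make_report(
    records: list[RetrocopyRecord],
    kaks: dict[str, KaKsResult],
    est_stats: dict | None,
    traffic: dict | None,
    dating: DatingParams | None = None,
    recent_age_mya: float = 22.5,
) -> dict:
    """Summary statistics of one pipeline run, computed from its own tables."""
    dating = dating or DatingParams()
    summary = summarize(records)
    ks_values = [r.ks for r in kaks.values() if r.ks is not None]
    hist = ks_histogram(ks_values) if ks_values else None
    omega_bins = {"constrained": 0, "intermediate": 0, "elevated": 0, "undefined": 0}
    by_cls_bins = {"intact": dict(omega_bins), "pseudogene": dict(omega_bins)}
    for rec in records:
        res = kaks.get(rec.retro_id)
        if res is None:
            continue
        by_cls_bins[rec.cls][classify_selection(res)] += 1
    chimeric_recent = 0
    for rec in records:
        res = kaks.get(rec.retro_id)
        if rec.chimeric and res is not None and res.ks is not None:
            age = estimate_age(res.ks, dating)
            if age is not None and age < recent_age_mya:
                chimeric_recent += 1
    report = {
        "total_retrocopies": summary.total,
        "intact": summary.intact,
        "pseudogene": summary.pseudogene,
        "chimeric": summary.chimeric,
        "n_parents": summary.n_parents,
        "intact_fraction_pct": 100.0 * summary.intact_fraction,
        "retrocopies_per_parent": summary.retrocopies_per_parent,
        "single_retrocopy_parent_pct": 100.0 * summary.single_retrocopy_parent_fraction,
        "novel_total": summary.novel_total,
        "novel_intact": summary.novel_intact,
        "omega_bins_by_class": by_cls_bins,
        "chimeric_recent": chimeric_recent,
        "chimeric_rate_per_myr": chimeric_recent / recent_age_mya,
        "ks_modal_bin": list(hist.modal_bin) if hist else None,
    }
    if est_stats:
        report["est"] = est_stats
        if est_stats["intact_total"]:
            report["est_intact_supported_pct"] = (
                100.0 * est_stats["intact_supported"] / est_stats["intact_total"]
            )
        if est_stats["pseudogene_total"]:
            report["est_pseudo_supported_pct"] = (
                100.0 * est_stats["pseudogene_supported"] / est_stats["pseudogene_total"]
            )
    if traffic and traffic["fractions"] is not None:
        frac = traffic["fractions"]
        report["movement"] = {
            row["category"]: {"count": int(row["count"]), "percent": row["percent"]}
            for _, row in frac.iterrows()
        }
        report["x_tests"] = {
            key: (
                {
                    "pearson_r": t.pearson_r,
                    "x_studentized": t.x_studentized,
                    "x_pvalue": t.x_pvalue,
                    "x_direction": t.x_direction,
                }
                if t is not None
                else None
            )
            for key, t in traffic["tests"].items()
        }
    return report


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the report dict.

    Every stage writes its table under ``config.out_dir``; a manifest
    records the configuration hash so reruns are verifiable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        ds = simulate_dataset(sim_cfg)
        paths = ds.write(out / "dataset")
        config.genome = str(paths["genome"])
        config.annotation = str(paths["annotation"])
        config.proteins = str(paths["proteins"])
        config.ests = str(paths["ests"])

    for key in ("genome", "annotation", "proteins"):
        path = getattr(config, key)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"{key} input missing: {path}")

    genome = GenomeAssembly.from_fasta(config.genome)
    models = read_annotation(config.annotation, genome)
    proteins_raw = read_fasta(config.proteins)
    from .io_formats import ProteinRecord

    gene_of_protein = {m.protein_id: m.gene_id for m in models}
    proteins = [
        ProteinRecord(pid, gene_of_protein.get(pid, pid), seq) for pid, seq in proteins_raw
    ]

    records = discover(genome, models, proteins, config.discovery)
    catalogue_frame(records).to_csv(out / "catalogue.tsv", sep="\t", index=False)
    write_bed6(
        [(r.chrom, r.start, r.end, r.retro_id, r.score, r.strand) for r in records],
        out / "catalogue.bed",
    )

    kaks = kaks_for_catalogue(records, config.dating, config.min_codons)
    kaks_frame(records, kaks, config.dating).to_csv(out / "kaks.tsv", sep="\t", index=False)
    ks_values = [r.ks for r in kaks.values() if r.ks is not None]
    if ks_values:
        ks_histogram(ks_values).to_frame().to_csv(out / "ks_histogram.tsv", sep="\t", index=False)

    est_stats = None
    if config.ests and Path(config.ests).exists():
        ests = read_fasta(config.ests)
        counts, est_stats = expression_support(ests, genome, records, config.est)
        pd.DataFrame(
            [
                {
                    "retro_id": c.retro_id,
                    "n_supporting_ests": c.n_supporting_ests,
                    "est_ids": ",".join(c.supporting_est_ids),
                }
                for c in counts
            ]
        ).to_csv(out / "est_support.tsv", sep="\t", index=False)

    traffic = traffic_analysis(records, kaks, models, genome) if records else None
    if traffic is not None:
        pd.DataFrame(
            [
                {
                    "retro_id": m.retro_id,
                    "parent_chrom": m.parent_chrom,
                    "retro_chrom": m.retro_chrom,
                    "category": m.category,
                    "cls": m.cls,
                    "omega": m.omega,
                }
                for m in traffic["records"]
            ]
        ).to_csv(out / "movement.tsv", sep="\t", index=False)
        links: dict[tuple[str, str], int] = {}
        for m in traffic["records"]:
            links[(m.parent_chrom, m.retro_chrom)] = links.get((m.parent_chrom, m.retro_chrom), 0) + 1
        pd.DataFrame(
            [{"parent_chrom": a, "retro_chrom": b, "count": n} for (a, b), n in sorted(links.items())]
        ).to_csv(out / "movement_links.tsv", sep="\t", index=False)

    report = make_report(records, kaks, est_stats, traffic, config.dating)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_report_md(report, out / "report.md")

    manifest = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_records": len(records),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report


def _config_dict(config: PipelineConfig) -> dict:
    return dataclasses.asdict(config)


def _write_report_md(report: dict, path: Path) -> None:
    lines = ["# retroforge run report", ""]
    for key in (
        "total_retrocopies",
        "intact",
        "pseudogene",
        "chimeric",
        "n_parents",
        "intact_fraction_pct",
        "retrocopies_per_parent",
        "single_retrocopy_parent_pct",
        "novel_total",
        "novel_intact",
        "chimeric_recent",
        "chimeric_rate_per_myr",
    ):
        if key in report:
            val = report[key]
            lines.append(f"- {key}: {val:.4g}" if isinstance(val, float) else f"- {key}: {val}")
    if "est_intact_supported_pct" in report:
        lines.append(f"- est_intact_supported_pct: {report['est_intact_supported_pct']:.1f}")
    if "est_pseudo_supported_pct" in report:
        lines.append(f"- est_pseudo_supported_pct: {report['est_pseudo_supported_pct']:.1f}")
    if "movement" in report:
        lines.append("")
        lines.append("| movement | count | percent |")
        lines.append("|---|---|---|")
        for cat, d in report["movement"].items():
            lines.append(f"| {cat} | {d['count']} | {d['percent']:.2f} |")
    if "x_tests" in report:
        lines.append("")
        lines.append("| regression | r | X p-value | direction |")
        lines.append("|---|---|---|---|")
        for key, t in sorted(report["x_tests"].items()):
            if t is None:
                lines.append(f"| {key} | - | - | - |")
            else:
                lines.append(
                    f"| {key} | {t['pearson_r']:.2f} | {t['x_pvalue']:.4f} | {t['x_direction']} |"
                )
    path.write_text("\n".join(lines) + "\n")
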