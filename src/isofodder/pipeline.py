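"""End-to-end orchestration: seasonal fits -> end-members -> mixing -> stats.

A single structured config governs a run; every output directory receives
the intermediate tables, a machine-readable ``summary.json`` (deterministic
bytes under a fixed seed) and a log.  Each stage failure halts the run with
the stage name and cause.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .collagen import flag_c4_consumers, group_contrast, mann_whitney_u, pearson_test, qc_filter
from .io import read_collagen_table, read_tooth_table, write_table
from .mixing import results_table, run_mixing_by_group, sensitivity_scan
from .mtdna import HaplotypeClassifier, HaplotypePanel, trim_primers
from .seasonal import process_tooth_table
from .sources import DietSource, SpacingTable, build_source_distributions, tissue_to_diet
from .synthetic import DEFAULT_C3, DEFAULT_C4

__all__ = ["RunConfig", "run_pipeline", "render_report"]

logger = logging.getLogger("isofodder")


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and the cause."""


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    out_dir: str = "isofodder_out"
    seed: int = 0
    # inputs (all optional; stages without inputs are skipped)
    enamel_table: str | None = None
    collagen_table: str | None = None
    reference_table: str | None = None  # tissue values + tissue_kind column
    millet_table: str | None = None  # delta13C of millet grains
    panel_fasta: str | None = None
    queries_fasta: str | None = None
    # spacing and sources
    spacing: dict = field(default_factory=dict)  # overrides per tissue kind
    c3_mean: float | None = None
    c3_sd: float | None = None
    c4_mean: float | None = None
    c4_sd: float | None = None
    # seasonality
    peak_day: float = 182.0
    period_min: float = 15.0
    period_max: float = 45.0
    # mixing
    engine: str = "grid"
    draws: int = 20000
    chains: int = 6
    sigma_max: float = 5.0
    # collagen QC
    cn_bounds: tuple = (2.9, 3.6)
    pctc_bounds: tuple = (15.3, 47.0)
    pctn_bounds: tuple = (5.5, 17.3)
    # sensitivity scan
    sensitivity_tissue_value: float | None = -6.0
    max_primer_mismatch: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def spacing_table(self) -> SpacingTable:
        base = SpacingTable()
        merged = dict(base.spacing)
        merged.update({k: float(v) for k, v in (self.spacing or {}).items()})
        return SpacingTable(spacing=merged)

    def validate_paths(self):
        for name in (
            "enamel_table",
            "collagen_table",
            "reference_table",
            "millet_table",
            "panel_fasta",
            "queries_fasta",
        ):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config path {name} = {value!r} not found")


def _build_sources(config: RunConfig, spacing: SpacingTable):
    """End-members from explicit config, reference tables, or defaults."""
    if config.c3_mean is not None and config.c4_mean is not None:
        c3 = DietSource("C3_steppe", config.c3_mean, config.c3_sd or 1.2)
        c4 = DietSource("C4_millet", config.c4_mean, config.c4_sd or 0.4)
        return c3, c4
    if config.reference_table and config.millet_table:
        ref = pd.read_csv(config.reference_table)
        millet = pd.read_csv(config.millet_table)
        diet = tissue_to_diet(
            ref["d13C_tissue"].to_numpy(), ref["tissue_kind"], spacing
        )
        return build_source_distributions(diet, millet["d13C"].to_numpy())
    return DEFAULT_C3, DEFAULT_C4


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the machine-readable summary."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("isofodder %s, seed %d", __version__, config.seed)

    spacing = config.spacing_table()
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "spacing": spacing.to_dict(),
    }

    try:
        c3, c4 = _build_sources(config, spacing)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage end-members failed: {exc}") from exc
    summary["sources"] = {
        "C3": {"mean": c3.mean, "sd": c3.sd, "n": c3.n},
        "C4": {"mean": c4.mean, "sd": c4.sd, "n": c4.n},
    }
    logger.info("sources: C3 %.2f±%.2f, C4 %.2f±%.2f", c3.mean, c3.sd, c4.mean, c4.sd)

    if config.enamel_table:
        try:
            table = read_tooth_table(config.enamel_table)
            bands, bins, fits = process_tooth_table(
                table,
                period_bounds=(config.period_min, config.period_max),
                peak_day=config.peak_day,
            )
            write_table(bands, out / "bands_with_days.csv")
            bins = bins.assign(
                dietary_d13C=lambda d: d["mean_d13C_apa"] - spacing.get("enamel")
            )
            write_table(bins, out / "bimonthly_bins.csv")
            results = run_mixing_by_group(
                bins.dropna(subset=["dietary_d13C"]),
                (c3, c4),
                group_cols=("site", "period", "bimonth"),
                engine=config.engine,
                seed=config.seed,
                draws=config.draws,
                chains=config.chains,
                sigma_max=config.sigma_max,
                logger=logger,
            )
            mix_table = results_table(results)
            write_table(mix_table, out / "mixing_results.csv")
            summary["seasonal"] = {
                "n_teeth": len(fits),
                "fits": {
                    tid: {
                        "mean": f.mean,
                        "amplitude": f.amplitude,
                        "period_mm": f.period,
                        "peak_position_mm": f.peak_position,
                        "rmse": f.rmse,
                    }
                    for tid, f in sorted(fits.items())
                },
            }
            summary["mixing"] = {
                "n_groups": len(results),
                "results": mix_table.to_dict(orient="records"),
            }
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage seasonal/mixing failed: {exc}") from exc

    if config.collagen_table:
        try:
            collagen = read_collagen_table(config.collagen_table)
            report = qc_filter(
                collagen,
                cn_bounds=tuple(config.cn_bounds),
                pctc_bounds=tuple(config.pctc_bounds),
                pctn_bounds=tuple(config.pctn_bounds),
            )
            write_table(report.accepted, out / "collagen_accepted.csv")
            write_table(report.rejected, out / "collagen_rejected.csv")
            accepted = report.accepted
            stats: dict = {
                "qc": {
                    "n_in": len(collagen),
                    "n_accepted": report.n_accepted,
                    "n_rejected": report.n_rejected,
                    "thresholds": report.thresholds,
                }
            }
            livestock = accepted[accepted["status"] == "livestock"]
            wild = accepted[accepted["status"] == "wild"]
            if len(livestock) and len(wild):
                u, p, na, nb = mann_whitney_u(
                    livestock["d15N_col"], wild["d15N_col"]
                )
                stats["mann_whitney_d15N"] = {
                    "U": u, "p": p, "n_livestock": na, "n_wild": nb,
                }
                _, diff = group_contrast(
                    accepted[accepted["status"].isin(["livestock", "wild"])],
                    "status",
                    "d15N_col",
                    contrast=("livestock", "wild"),
                )
                stats["d15N_contrast"] = diff
            pearson = {}
            for (site, period), sub in livestock.groupby(["site", "period"]):
                if len(sub) >= 3:
                    try:
                        r, p, n = pearson_test(sub["d13C_col"], sub["d15N_col"])
                    except ValueError:
                        continue
                    pearson[f"{site}/{period}"] = {"r": r, "p": p, "n": n}
            stats["pearson_by_phase"] = pearson
            if len(livestock):
                diet_vals = livestock.assign(
                    dietary_d13C=livestock["d13C_col"] - spacing.get("collagen"),
                    bimonth="lifetime",
                )
                lifetime = run_mixing_by_group(
                    diet_vals,
                    (c3, c4),
                    group_cols=("site", "period", "bimonth"),
                    engine=config.engine,
                    seed=config.seed,
                    draws=config.draws,
                    chains=config.chains,
                    sigma_max=config.sigma_max,
                    logger=logger,
                )
                lifetime_table = results_table(lifetime)
                write_table(lifetime_table, out / "lifetime_mixing.csv")
                stats["lifetime_mixing"] = lifetime_table.to_dict(orient="records")
            humans = accepted[accepted["status"] == "human"]
            if len(humans):
                flagged = flag_c4_consumers(humans)
                stats["human_c4_consumers"] = int(flagged["c4_consumer"].sum())
            summary["collagen"] = stats
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage collagen failed: {exc}") from exc

    if config.panel_fasta and config.queries_fasta:
        try:
            panel = HaplotypePanel.from_fasta(config.panel_fasta)
            clf = HaplotypeClassifier()
            clf.panel_ = panel
            clf.classes_ = np.unique([e.taxon for e in panel])
            from Bio import SeqIO

            ids, seqs = [], []
            for rec in SeqIO.parse(config.queries_fasta, "fasta"):
                ids.append(rec.id)
                try:
                    seqs.append(
                        trim_primers(
                            str(rec.seq), max_mismatch=config.max_primer_mismatch
                        )
                    )
                except ValueError:
                    seqs.append(str(rec.seq))
            assignments = clf.assign(seqs, ids=ids)
            write_table(assignments, out / "mtdna_assignments.csv")
            summary["mtdna"] = {
                "n_queries": len(assignments),
                "n_identical": int(assignments["identical"].sum()),
                "n_ambiguous": int(assignments["ambiguous"].sum()),
                "by_taxon": assignments["taxon"].value_counts().to_dict(),
            }
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage mtdna failed: {exc}") from exc

    if config.sensitivity_tissue_value is not None:
        scan = sensitivity_scan(
            config.sensitivity_tissue_value,
            spacings=np.arange(13.0, 15.01, 0.5),
            c3_sources=[
                DietSource("C3_steppe", m, c3.sd) for m in np.arange(-26.0, -21.99, 1.0)
            ],
            c4_sources=[c4],
            sigma_max=config.sigma_max,
        )
        write_table(scan, out / "sensitivity_scan.csv")
        summary["sensitivity"] = {
            "tissue_value": config.sensitivity_tissue_value,
            "n_rows": len(scan),
            "p_mean_range": [float(scan["p_mean"].min()), float(scan["p_mean"].max())],
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    with open(out / "report.txt", "w") as fh:
        fh.write(render_report(summary))
    logger.removeHandler(handler)
    handler.close()
    return summary


def render_report(summary: dict) -> str:
    """Deterministic human-readable rendering of a run summary."""
    lines = [
        f"isofodder run report (version {summary.get('version', '?')}, "
        f"seed {summary.get('seed', '?')})",
        "",
        "Diet-tissue spacing (permil): "
        + ", ".join(
            f"{k} +{v:g}" for k, v in sorted(summary["spacing"]["spacing"].items())
        ),
        "Sources: C3 {mean:.2f} +/- {sd:.2f}".format(**summary["sources"]["C3"])
        + "; C4 {mean:.2f} +/- {sd:.2f}".format(**summary["sources"]["C4"]),
        "",
    ]
    mixing = summary.get("mixing")
    if mixing and mixing["n_groups"]:
        lines.append("Posterior C4 dietary fraction by group:")
        lines.append(
            f"{'site':<14}{'period':<10}{'bimonth':<9}{'n':>3}"
            f"{'mean':>7}{'5%':>7}{'95%':>7}"
        )
        for row in mixing["results"]:
            lines.append(
                f"{row['site']:<14}{row['period']:<10}{row['bimonth']:<9}"
                f"{row['n']:>3}{row['p_mean']:>7.2f}{row['p_lo90']:>7.2f}"
                f"{row['p_hi90']:>7.2f}"
            )
    else:
        lines.append("Mixing: no groups")
    collagen = summary.get("collagen")
    if collagen:
        qc = collagen["qc"]
        lines += [
            "",
            f"Collagen QC: {qc['n_accepted']}/{qc['n_in']} accepted "
            f"({qc['n_rejected']} rejected)",
        ]
        mw = collagen.get("mann_whitney_d15N")
        if mw:
            lines.append(
                "delta15N livestock vs wild: U = {U:.1f}, p = {p:.3g} "
                "(n = {n_livestock}/{n_wild})".format(**mw)
            )
        diff = collagen.get("d15N_contrast")
        if diff:
            lines.append(
                "delta15N difference ({direction}): mean {mean_diff:.2f}, "
                "median {median_diff:.2f} permil".format(**diff)
            )
        for phase, res in sorted(collagen.get("pearson_by_phase", {}).items()):
            lines.append(
                f"Pearson d13C~d15N {phase}: r = {res['r']:.4f}, "
                f"p = {res['p']:.3g}, n = {res['n']}"
            )
    mtdna = summary.get("mtdna")
    if mtdna:
        lines += [
            "",
            f"mtDNA: {mtdna['n_queries']} queries, "
            f"{mtdna['n_identical']} identical, {mtdna['n_ambiguous']} ambiguous",
        ]
        for taxon, n in sorted(mtdna["by_taxon"].items()):
            lines.append(f"  {taxon}: {n}")
    sens = summary.get("sensitivity")
    if sens:
        lines += [
            "",
            f"Sensitivity scan at {sens['tissue_value']:g} permil enamel: "
            f"posterior mean spans {sens['p_mean_range'][0]:.2f}-"
            f"{sens['p_mean_range'][1]:.2f} over {sens['n_rows']} parameterizations",
        ]
    return "\n".join(lines) + "\n"
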