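"""Reporting matrices, group summaries and pipeline orchestration.

The reporting scale inverts Ct: adjusted value = 40 - Ct, so higher
means more expression, then each assay is median-centered.  The centered
matrix is the interface to external clustering/heat-map tools; boxplot
five-number summaries are computed per assay per group (and per
pathology subtype).  ``run_pipeline`` drives the whole analysis from a
YAML config and writes a machine-readable run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ct_io
from .ct_io import CtMatrix, GroupDesign
from .diffexp import DiffExpParams, rank_candidates, westfall_young_minp
from .errors import ConfigError
from .integration import IntegrationParams, anti_correlate, select_down_in_both
from .preprocess import PreprocessParams, preprocess_pipeline
from .qpcr import QpcrParams, validate_assays

logger = logging.getLogger(__name__)

#: Instrument-range constant used to invert the Ct scale for display.
ADJUST_CONSTANT = 40.0


@dataclass
class ReportMatrix:
    """Median-centered adjusted-Ct matrix (higher = more expression)."""

    data: pd.DataFrame  # assays x samples


def adjusted_ct_matrix(matrix: CtMatrix) -> ReportMatrix:
    """40 - Ct, then per-assay median centering.

    The adjustment is strictly decreasing in Ct, so sample ordering by
    expression is preserved; after centering every assay has median 0.
    """
    adj = ADJUST_CONSTANT - matrix.data
    centered = adj.sub(adj.median(axis=1, skipna=True), axis=0)
    return ReportMatrix(data=centered)


def group_boxplot_summary(
    report: ReportMatrix,
    design: GroupDesign,
    by_subtype: bool = False,
) -> pd.DataFrame:
    """Five-number summaries per assay per group (optionally per subtype).

    Returns a long-form table with columns assay_id, group (or
    group/subtype label), n, min, q1, median, q3, max.  Empty groups are
    omitted with a warning.
    """
    design.check_covers(report.data.columns)
    if by_subtype:
        labels = {
            s: f"{design.table.loc[s, 'group']}|{design.table.loc[s, 'subtype']}"
            for s in report.data.columns
        }
    else:
        labels = {s: design.group_of(s) for s in report.data.columns}
    rows = []
    for label in sorted(set(labels.values())):
        samples = [s for s in report.data.columns if labels[s] == label]
        sub = report.data[samples]
        for assay, vals in sub.iterrows():
            v = vals.dropna().to_numpy(dtype=float)
            if v.size == 0:
                logger.warning("assay %r, group %r: no observed values; omitted", assay, label)
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append(
                {
                    "assay_id": assay,
                    "group": label,
                    "n": v.size,
                    "min": v.min(),
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                    "max": v.max(),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return cfg


def _require(cfg: dict, key: str):
    if key not in cfg:
        raise ConfigError(f"config missing required key {key!r}")
    return cfg[key]


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run preprocess -> diffexp -> optional qpcr -> optional integrate.

    ``config`` names the input tables and parameters; all randomness
    flows from the single top-level ``seed``.  Writes the processed
    matrix, result tables, report matrix and a JSON manifest recording
    seed, parameters and stage counts.  Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    matrix = ct_io.read_ct_table(_require(config, "ct_table"))
    design = ct_io.read_sample_sheet(_require(config, "sample_sheet"))
    design.check_covers(matrix.sample_ids)

    pp = PreprocessParams(**config.get("preprocess", {}))
    processed, pp_report = preprocess_pipeline(matrix, pp)
    ct_io.write_ct_table(processed, outdir / "processed.tsv")

    de_cfg = dict(config.get("diffexp", {}))
    de_cfg.setdefault("seed", seed)
    de = DiffExpParams(**de_cfg)
    result = westfall_young_minp(processed, design, de)
    result.table.to_csv(outdir / "diffexp.tsv", sep="\t")
    candidates = rank_candidates(result, de.alpha)
    candidates.to_csv(outdir / "candidates.tsv", sep="\t")

    rep = adjusted_ct_matrix(processed)
    rep.data.to_csv(outdir / "report_matrix.tsv", sep="\t", na_rep="NA")
    group_boxplot_summary(rep, design, by_subtype=True).to_csv(
        outdir / "boxplot_summary.tsv", sep="\t", index=False
    )

    manifest = {
        "seed": seed,
        "params": {
            "preprocess": vars(pp),
            "diffexp": vars(de),
        },
        "stages": pp_report,
        "diffexp": {
            "n_assays_tested": int(len(result.table)),
            "n_perm": result.n_perm,
            "exhaustive": result.exhaustive,
            "overall_p": result.overall_p,
            "min_q": float(result.table["q_emp"].min()),
            "n_candidates": int(len(candidates)),
        },
    }

    if "qpcr_wells" in config:
        qp = QpcrParams(**config.get("qpcr", {}))
        wells = ct_io.read_well_table(config["qpcr_wells"], qp.control_assay_id)
        validation = validate_assays(wells, design, qp)
        validation.to_csv(outdir / "validation.tsv", sep="\t")
        manifest["qpcr"] = {
            "n_assays": int(len(validation)),
            "n_detectable": int(validation["detectable"].sum()),
        }

    if "targets" in config:
        ip = IntegrationParams(**config.get("integration", {}))
        targets = ct_io.read_target_lists(_require(config, "targets"))
        table_a = ct_io.read_mrna_de_table(_require(config, "mrna_de_cortex"))
        table_b = ct_io.read_mrna_de_table(_require(config, "mrna_de_cerebellum"))
        mirnas = list(config.get("candidate_mirnas", sorted(targets)))
        down = select_down_in_both(table_a, table_b, ip)
        integ = anti_correlate(down, targets, mirnas)
        with (outdir / "integration.tsv").open("w") as fh:
            fh.write("gene\tn_mirnas\tmirna_list\n")
            for gene in sorted(integ.gene_to_mirnas):
                ms = integ.gene_to_mirnas[gene]
                fh.write(f"{gene}\t{len(ms)}\t{';'.join(ms)}\n")
        manifest["integration"] = {
            "total_genes": integ.total_genes,
            "tally": {str(k): v for k, v in sorted(integ.tally.items())},
        }

    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
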