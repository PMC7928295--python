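"""End-to-end report generation: segregation tables, ICE table, spectra.

``run_pipeline`` ties the stages together and writes a report bundle of
tab-separated files mirroring the analysis tables: segregation counts
stratified by carrier gender, age band and translocation type (plus a
long-format file for plotting), the carrier-vs-control ICE table, the
per-chromosome abnormality spectra, a cohort summary and a run log
recording versions, seed and every decision flag in effect.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .cohort import CohortTable, read_cohort, summarize_cohort
from .ice import IceAnalysis
from .segregation import CATEGORIES, SegregationAnalysis

logger = logging.getLogger("robseg")

__all__ = ["run_pipeline"]


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index)
    return path


def run_pipeline(
    cohort_path,
    out_dir,
    control_path=None,
    mosaic_threshold: float = 0.20,
    yates: bool = False,
    require_ice: bool = True,
) -> dict:
    """Run classification, tabulation and the ICE comparison; write reports.

    ``cohort_path`` may contain both arms, or carriers only with controls
    in ``control_path``.  Returns a dict of output paths.  Raises if the
    ICE stage is requested without a control arm.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(cohort_path)
    if control_path is not None:
        ctl_df = read_cohort(control_path).df.drop(columns="age_band")
        cohort = CohortTable(pd.concat([cohort.df.drop(columns="age_band"), ctl_df]))

    carriers = cohort.carriers()
    controls = cohort.controls()
    paths: dict[str, Path] = {}

    logger.info("segregation stage: %d carrier embryos", len(carriers))
    try:
        results = SegregationAnalysis(carriers).fit()
    except Exception as e:
        raise RuntimeError(f"segregation stage failed: {e}") from e
    for key, table in results.tables.items():
        name = "segregation_by_" + "_".join(key) if key else "segregation_overall"
        paths[name] = _write(table.data, out / f"{name}.tsv", index=True)
    long = results.overall.to_long()
    for key in results.tables:
        if key:
            long = pd.concat([long, results.tables[key].to_long()])
    paths["segregation_long"] = _write(long, out / "segregation_long.tsv")

    if len(controls) == 0:
        if require_ice:
            raise RuntimeError("ICE stage: control arm required but none was provided")
        logger.warning("no control arm; skipping ICE stage")
    else:
        logger.info("ICE stage: %d carriers vs %d controls", len(carriers), len(controls))
        try:
            ice = IceAnalysis(carriers, controls, mosaic_threshold=mosaic_threshold, yates=yates).fit()
        except Exception as e:
            raise RuntimeError(f"ICE stage failed: {e}") from e
        paths["ice_table"] = _write(ice.table, out / "ice_table.tsv")
        paths["spectrum_carriers"] = _write(ice.carrier_spectrum, out / "spectrum_carriers.tsv")
        paths["spectrum_controls"] = _write(ice.control_spectrum, out / "spectrum_controls.tsv")

    paths["summary"] = _write(summarize_cohort(cohort), out / "summary.tsv")

    log_path = out / "run_log.txt"
    with open(log_path, "w") as fh:
        fh.write(f"robseg {__version__}\n")
        fh.write(f"python {sys.version.split()[0]}\n")
        fh.write(f"input: {cohort_path}\n")
        if control_path is not None:
            fh.write(f"control input: {control_path}\n")
        fh.write(f"mosaic threshold: fraction > {mosaic_threshold:.2f}\n")
        fh.write(f"yates correction: {yates}\n")
        fh.write("test selection: Cochran (Fisher if any expected < 5 or total < 40)\n")
        fh.write("odds ratio: cross-product; Haldane-Anscombe +0.5 on empty cells\n")
        fh.write("CI: Woolf logit (extension; source tables print none)\n")
        fh.write(
            "unclassifiable rule: mosaic/segmental-only translocation-chromosome "
            "signal excluded from segregation denominators\n"
        )
        fh.write("segmental imbalances on non-excluded chromosomes count as aneuploid\n")
    paths["run_log"] = log_path
    return paths
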