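"""Config-driven end-to-end analysis pipeline.

Stages: cohort descriptives -> phenotypic correlations -> cross-twin
cross-trait correlations per zygosity -> model-comparison ladder ->
decomposition of the selected model.  Every stage writes a TSV (human) and
its numbers are collected into a JSON manifest carrying the seed and a
hash of the configuration, so reruns are reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, ttest_ind

from . import __version__
from .config import PipelineConfig
from .correlations import ctct_matrix, phenotypic_corr_matrix
from .data import TwinDataset
from .decompose import decompose
from .fiml import FitOptions, fit
from .models import DZ, MZ
from .selection import four_step_compare
from .simulate import simulate_cohort

__all__ = ["descriptives", "run_pipeline"]


def descriptives(data: TwinDataset) -> pd.DataFrame:
    """Per-phenotype summaries overall and by zygosity with MZ-vs-DZ tests.

    Continuous traits: mean (SD) and range, two-sample t-test; binary
    traits: N (%), chi-square contingency test.  Individuals are the unit;
    within-pair dependence is ignored in these descriptive tests.
    """
    p = data.p
    rows = []
    groups = {
        "overall": np.ones(data.n_pairs, dtype=bool),
        MZ: data.zygosity_mask(MZ),
        DZ: data.zygosity_mask(DZ),
    }

    def stack(mask, col_pair):
        arr = np.concatenate(col_pair)
        return arr[~np.isnan(arr)]

    vals = data.values()
    ages = data.ages()
    # age behaves like a continuous trait in the summary table
    items = [("age", None, ages[:, 0], ages[:, 1])] + [
        (ph.name, ph, vals[:, i], vals[:, p + i])
        for i, ph in enumerate(data.phenotypes)
    ]
    for name, ph, c1, c2 in items:
        row = {"phenotype": name}
        samples = {}
        for gname, mask in groups.items():
            x = stack(mask, (c1[mask], c2[mask]))
            samples[gname] = x
            if ph is not None and ph.binary:
                pct = 100.0 * x.mean() if x.size else np.nan
                row[gname] = f"{int(x.sum())} ({pct:.2f})"
            else:
                if x.size:
                    row[gname] = (
                        f"{x.mean():.2f} ({x.std(ddof=1):.2f}) "
                        f"{x.min():.2f}-{x.max():.2f}"
                    )
                else:
                    row[gname] = ""
        xm, xd = samples[MZ], samples[DZ]
        pval = np.nan
        if xm.size > 1 and xd.size > 1:
            if ph is not None and ph.binary:
                table = np.array(
                    [
                        [np.sum(xm == 0), np.sum(xm == 1)],
                        [np.sum(xd == 0), np.sum(xd == 1)],
                    ]
                )
                if (table.sum(axis=0) > 0).all():
                    pval = float(chi2_contingency(table, correction=False).pvalue)
                else:
                    pval = 1.0
            else:
                if np.std(xm) == 0.0 and np.std(xd) == 0.0:
                    pval = 1.0
                else:
                    pval = float(ttest_ind(xm, xd, equal_var=False).pvalue)
        row["p_mz_vs_dz"] = pval
        rows.append(row)
    return pd.DataFrame(rows)


def _write(frame: pd.DataFrame, out_dir: Path, name: str) -> None:
    frame.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages; returns the manifest (also written as JSON).

    Stage failures raise with the stage name; artifacts of completed
    stages remain on disk.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(repr(config).encode()).hexdigest()[:16]
    manifest: dict = {
        "seed": config.seed,
        "config_hash": cfg_hash,
        "version": __version__,
        "stages": [],
    }

    def stage(name):
        manifest["stages"].append(name)
        return name

    try:
        stage("data")
        if config.generate is not None:
            data = simulate_cohort(config.generate, seed=config.seed)
            data.to_csv(out_dir / "dataset.csv")
        else:
            data = TwinDataset.read_csv(config.dataset_path, config.phenotypes)
        manifest["n_pairs"] = int(data.n_pairs)

        stage("descriptives")
        desc = descriptives(data)
        _write(desc, out_dir, "descriptives")
        manifest["descriptives"] = desc.to_dict(orient="records")

        stage("phenotypic_correlations")
        pheno = phenotypic_corr_matrix(data)
        _write(pheno, out_dir, "phenotypic_corr")
        manifest["phenotypic_corr"] = pheno.to_dict(orient="records")

        stage("ctct")
        for z, fname in ((MZ, "ctct_mz"), (DZ, "ctct_dz")):
            ct = ctct_matrix(data, z, ci=True, n_boot=config.n_boot,
                             seed=config.seed)
            _write(ct, out_dir, fname)
            manifest[fname] = ct.to_dict(orient="records")

        stage("ladder")
        ladder_cfg = config.ladder
        frame, selected, fits = four_step_compare(
            data,
            phenotypes=config.phenotypes,
            reduced_drops=ladder_cfg.get("reduced"),
            include_saturated=ladder_cfg.get("include_saturated", True),
            include_acde_choice=ladder_cfg.get("include_acde_choice", True),
            ip_cp_sets=tuple(ladder_cfg.get("ip_cp_sets", (1, 2))),
            include_age=config.include_age,
            options=config.fit_options,
        )
        _write(frame, out_dir, "ladder")
        manifest["ladder"] = frame.to_dict(orient="records")
        manifest["selected_model"] = selected
        manifest["fits"] = {n: f.to_dict() for n, f in fits.items()}

        stage("decomposition")
        chosen = fits[selected]
        if chosen.model.structure != "saturated":
            report = decompose(chosen, shared_target=config.shared_target)
            _write(report.variance_percent, out_dir, "decomposition")
            _write(report.heritability, out_dir, "heritability")
            manifest["decomposition"] = report.to_dict()
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
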