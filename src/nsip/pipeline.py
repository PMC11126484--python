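"""Umbrella pipeline: simulate (optional) -> quantify -> rates -> community.

Each stage writes its TSV under the configured output directory; a JSON
manifest records every input, seed and threshold actually used, plus the
stages that ran or were skipped. Runs are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import pandas as pd

from nsip import __version__
from nsip.community_summary import active_taxa, clade_composition, top_n_taxa
from nsip.config import RunConfig
from nsip.io import (
    read_chem_table,
    read_fraction_table,
    read_zotu_table,
    write_chem_table,
    write_fraction_table,
    write_labeling_table,
)
from nsip.nitrogen_dynamics import (
    inhibition_percent,
    net_nitrification_rate,
    one_way_anova,
)
from nsip.sip_quant import estimate_labeling, summarize_replicates
from nsip.synthetic_data import simulate_microcosm, simulate_paired_gradients

logger = logging.getLogger("nsip")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and record context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "margin": config.margin,
            "min_abund": config.min_abund,
            "fold": config.fold,
            "hf_overrides": {g: list(v) for g, v in config.hf_overrides.items()},
        },
        "inputs": {
            k: getattr(config, k)
            for k in ("fractions", "chemistry", "counts", "sample_metadata", "taxonomy")
        },
        "stages": {},
        "outputs": [],
    }

    profiles = []
    # --- simulate ---------------------------------------------------------
    if config.taxa and config.protocol is not None:
        logger.info("stage simulate: %d taxa", len(config.taxa))
        try:
            ds = simulate_paired_gradients(config.taxa, config.protocol, config.seed)
            profiles = list(ds.profiles.values())
            path = out / "simulated_fractions.tsv"
            write_fraction_table(profiles, path)
            manifest["outputs"].append(str(path))
            chem_path = None
            if config.microcosms:
                series = [
                    simulate_microcosm(
                        params, seed=config.seed + 1000 + i, treatment=name
                    )
                    for i, (name, params) in enumerate(sorted(config.microcosms.items()))
                ]
                chem_path = out / "simulated_chemistry.tsv"
                write_chem_table(series, chem_path)
                manifest["outputs"].append(str(chem_path))
            manifest["stages"]["simulate"] = "ran"
        except Exception as exc:  # noqa: BLE001
            raise StageError("simulate", str(exc)) from exc
    else:
        manifest["stages"]["simulate"] = "skipped (no taxa/protocol configured)"

    # --- quantify ---------------------------------------------------------
    if config.fractions is not None:
        profiles = read_fraction_table(config.fractions)
    if profiles:
        logger.info("stage quantify: %d profiles", len(profiles))
        try:
            by_key: dict = {}
            for p in profiles:
                by_key.setdefault((p.soil, p.gene, p.replicate), {})[p.treatment] = p
            estimates = []
            undetected = []
            for (soil, gene, rep), pair in sorted(by_key.items()):
                p15 = pair.get("15N") or pair.get("15N-urea")
                p14 = pair.get("14N") or pair.get("14N-urea")
                if p15 is None or p14 is None:
                    continue
                total = config.totals.get(gene, float(p15.copies_array().sum()))
                est = estimate_labeling(
                    p15,
                    p14,
                    total_abundance=total,
                    margin=config.margin,
                    manual_set=config.hf_overrides.get(gene),
                )
                if est is None:
                    undetected.append({"soil": soil, "gene": gene, "replicate": rep})
                else:
                    estimates.append(est)
            path = out / "labeling_estimates.tsv"
            write_labeling_table(estimates, path)
            manifest["outputs"].append(str(path))
            if estimates:
                summary = summarize_replicates(estimates)
                spath = out / "labeling_summary.tsv"
                summary.to_csv(spath, sep="\t", index=False)
                manifest["outputs"].append(str(spath))
            manifest["stages"]["quantify"] = "ran"
            manifest["no_labeling_detected"] = undetected
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("quantify", str(exc)) from exc
    else:
        manifest["stages"]["quantify"] = "skipped (no fraction profiles)"

    # --- rates ------------------------------------------------------------
    chem_source = config.chemistry or (
        str(out / "simulated_chemistry.tsv")
        if (out / "simulated_chemistry.tsv").exists()
        else None
    )
    if chem_source is not None:
        logger.info("stage rates: %s", chem_source)
        try:
            series = read_chem_table(chem_source)
            rows = []
            for s in series:
                rate = net_nitrification_rate(s.no3[0], s.no3[-1], s.days[-1] - s.days[0])
                rows.append(
                    {
                        "soil": s.soil,
                        "treatment": s.treatment,
                        "replicate": s.replicate,
                        "days": s.days[-1] - s.days[0],
                        "net_nitrification_rate": rate,
                        "nh4_accumulation": s.nh4[-1] - s.nh4[0],
                        "no3_accumulation": s.no3[-1] - s.no3[0],
                    }
                )
            rates = pd.DataFrame(rows)
            # acetylene inhibition where both arms are present
            for (soil, rep), grp in rates.groupby(["soil", "replicate"]):
                tr = grp.set_index("treatment")
                inhibited = [t for t in tr.index if "C2H2" in t]
                plain = [t for t in tr.index if "15N-urea" == t or "urea" == t]
                if inhibited and plain:
                    delta_u = tr.loc[plain[0], "no3_accumulation"]
                    if delta_u > 0:
                        rates.loc[
                            (rates["soil"] == soil) & (rates["replicate"] == rep),
                            "inhibition_percent",
                        ] = inhibition_percent(
                            tr.loc[inhibited[0], "no3_accumulation"], delta_u
                        )
            path = out / "nitrification_rates.tsv"
            rates.to_csv(path, sep="\t", index=False)
            manifest["outputs"].append(str(path))
            manifest["stages"]["rates"] = "ran"
        except Exception as exc:  # noqa: BLE001
            raise StageError("rates", str(exc)) from exc
    else:
        manifest["stages"]["rates"] = "skipped (no chemistry table)"

    # --- community --------------------------------------------------------
    if config.counts and config.sample_metadata and config.taxonomy:
        logger.info("stage community: %s", config.counts)
        try:
            table = read_zotu_table(config.counts, config.sample_metadata, config.taxonomy)
            hf = table.samples_where(fraction_class="HF")
            ref = table.samples_where(fraction_class="light")
            comp = clade_composition(table, hf or list(table.counts.columns))
            comp_df = pd.DataFrame(
                {"clade": comp.percent.index, "percent": comp.percent.values,
                 "reads": comp.reads.values}
            )
            path = out / "clade_composition.tsv"
            comp_df.to_csv(path, sep="\t", index=False)
            manifest["outputs"].append(str(path))
            top = top_n_taxa(table, hf or list(table.counts.columns), n=10)
            tpath = out / "top_taxa.tsv"
            top.rename("relative_abundance").to_csv(tpath, sep="\t")
            manifest["outputs"].append(str(tpath))
            if hf and ref:
                act = active_taxa(
                    table, hf, ref, min_abund=config.min_abund, fold=config.fold
                )
                apath = out / "active_taxa.tsv"
                act.to_csv(apath, sep="\t", index_label="zotu")
                manifest["outputs"].append(str(apath))
            manifest["stages"]["community"] = "ran"
        except Exception as exc:  # noqa: BLE001
            raise StageError("community", str(exc)) from exc
    else:
        manifest["stages"]["community"] = "skipped (no Zotu tables)"

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return manifest
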