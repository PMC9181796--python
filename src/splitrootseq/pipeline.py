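"""Orchestration: simulate/load -> FPKM & QC -> DE -> classify -> enrich -> report.

A single declarative TOML config drives the whole run; outputs are plain
TSV/JSON files under the output directory, and the run report contains only
integers plus fractions recomputable from them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    ContrastSets,
    classify_root,
    classify_shoot,
    recovered_sets,
    recovery_fraction,
    set_sizes,
    tissue_overlap,
)
from .detest import ContrastSpec, call_degs, run_contrast
from .enrich import direction_score, hypergeom_enrich, read_gmt, term_gene_edges
from .io import load_count_matrix, write_count_matrix, write_table
from .quantify import compute_fpkm, correlation_summary, replicate_correlation
from .simulate import SimulationDesign, simulate_counts

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    tomllib = None

log = logging.getLogger(__name__)

#: default contrast roster; each value is "<groupA>/<groupB>"
DEFAULT_CONTRASTS = {
    "root_deficiency": "S0_R/CK_R",
    "root_resupply": "SR_R/S0_R",
    "root_half_resupplied": "SPSR_R/S0_R",
    "root_half_deprived": "SPS0_R/S0_R",
    "shoot_deficiency": "S0_Sh/CK_Sh",
    "shoot_resupply": "SR_Sh/S0_Sh",
    "shoot_hetero": "SP_Sh/S0_Sh",
}


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs or a simulation, thresholds, outputs."""

    outdir: Path = Path("splitrootseq_out")
    seed: int = 0
    simulate: SimulationDesign | None = None
    counts: Path | None = None
    samples: Path | None = None
    lengths: Path | None = None
    annotations: Path | None = None
    contrasts: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CONTRASTS))
    fc_min: float = 2.0
    p_max: float = 0.05
    fdr_max: float = 0.01
    enrich_fdr: float = 0.05
    precision: int = 2

    def __post_init__(self) -> None:
        if self.simulate is None and self.counts is None:
            raise ValueError("config needs either a simulation design or input paths")
        if min(self.fc_min, self.p_max, self.fdr_max, self.enrich_fdr) <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        if tomllib is None:  # pragma: no cover
            raise RuntimeError("TOML configs need Python >= 3.11")
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kw: dict = {}
        if "seed" in raw:
            kw["seed"] = int(raw["seed"])
        if "simulate" in raw:
            sim = dict(raw["simulate"])
            sim.setdefault("seed", kw.get("seed", 0))
            for tup in ("groups", "base_mean_log_range", "gene_length_range"):
                if tup in sim:
                    sim[tup] = tuple(sim[tup])
            kw["simulate"] = SimulationDesign(**sim)
        if "inputs" in raw:
            for key in ("counts", "samples", "lengths", "annotations"):
                if key in raw["inputs"]:
                    kw[key] = Path(raw["inputs"][key])
        if "thresholds" in raw:
            kw.update(raw["thresholds"])
        if "output" in raw:
            out = raw["output"]
            if "dir" in out:
                kw["outdir"] = Path(out["dir"])
            if "precision" in out:
                kw["precision"] = int(out["precision"])
        if "contrasts" in raw:
            kw["contrasts"] = {**DEFAULT_CONTRASTS, **raw["contrasts"]}
        return cls(**kw)

    def fingerprint(self) -> dict:
        d = {
            "package": "splitrootseq",
            "version": __version__,
            "seed": self.seed,
            "fc_min": self.fc_min,
            "p_max": self.p_max,
            "fdr_max": self.fdr_max,
            "enrich_fdr": self.enrich_fdr,
            "contrasts": dict(self.contrasts),
        }
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
            d["simulate"]["groups"] = list(d["simulate"]["groups"])
        else:
            d["inputs"] = {
                k: str(getattr(self, k))
                for k in ("counts", "samples", "lengths", "annotations")
                if getattr(self, k) is not None
            }
        return d


def validate_inputs(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    lengths: pd.Series,
    annotations=None,
) -> list[dict]:
    """Cross-check loaded inputs; returns [{'level': 'error'|'warning', 'message': ...}]."""
    diags: list[dict] = []

    def err(msg):
        diags.append({"level": "error", "message": msg})

    def warn(msg):
        diags.append({"level": "warning", "message": msg})

    missing_len = counts.index.difference(lengths.index)
    if len(missing_len):
        err(f"length table missing {len(missing_len)} gene(s), e.g. {list(missing_len[:3])}")
    if (lengths <= 0).any():
        err("non-positive gene length(s) present")
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        frac = np.modf(vals.astype(float))[0]
        if np.any(frac != 0):
            g, s = np.argwhere(frac != 0)[0]
            err(f"non-integer count at gene {counts.index[g]!r}, sample {counts.columns[s]!r}")
    if (vals < 0).any():
        err("negative count(s) present")
    extra = set(samples["sample"]) ^ set(counts.columns)
    if extra:
        err(f"sample sheet and count columns disagree on: {sorted(extra)[:5]}")
    else:
        reps = samples.groupby("group")["sample"].count()
        low = reps[reps < 2]
        for grp, n in low.items():
            err(f"group {grp!r} has {n} replicate(s); need >= 2")
    if annotations is not None:
        universe = set(counts.index)
        stray = {g for t in annotations for g in t.genes if g not in universe}
        if stray:
            warn(
                f"{len(stray)} annotation gene(s) absent from counts will be dropped, "
                f"e.g. {sorted(stray)[:3]}"
            )
    return diags


def _fraction_dict(num: int, den: int, precision: int) -> dict:
    if den == 0:
        return {"numerator": num, "denominator": 0, "percentage": None, "rounded_text": None}
    fr = recovery_fraction(num, den, precision)
    return dataclasses.asdict(fr)


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run report (also written to disk)."""
    t0 = time.monotonic()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.fingerprint()}

    truth = None
    if config.simulate is not None:
        cm, truth = simulate_counts(config.simulate)
        write_count_matrix(cm, outdir / "simulated", truth=truth)
        log.info("simulated %d genes x %d samples", *cm.counts.shape)
    else:
        cm = load_count_matrix(config.counts, config.samples, config.lengths)

    annotations = read_gmt(config.annotations) if config.annotations else None
    diags = validate_inputs(cm.counts, cm.samples, cm.gene_lengths, annotations)
    errors = [d for d in diags if d["level"] == "error"]
    for d in diags:
        log.log(logging.ERROR if d["level"] == "error" else logging.WARNING, d["message"])
    if errors:
        raise ValueError(f"input validation failed: {errors[0]['message']}")
    report["diagnostics"] = diags

    # --- FPKM + replicate QC -------------------------------------------------
    fpkm = compute_fpkm(cm)
    write_table(fpkm, outdir / "fpkm.tsv", index=True)
    qc = correlation_summary(replicate_correlation(fpkm, cm.group_of()))
    report["qc"] = qc
    with open(outdir / "qc.json", "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)

    # --- differential expression --------------------------------------------
    groups_present = set(cm.samples["group"])
    tables: dict[str, pd.DataFrame] = {}
    sets: dict[str, ContrastSets] = {}
    report["contrasts"] = {}
    for role, name in config.contrasts.items():
        spec = ContrastSpec.parse(
            name, fc_min=config.fc_min, p_max=config.p_max, fdr_max=config.fdr_max
        )
        if not {spec.group_a, spec.group_b} <= groups_present:
            raise ValueError(
                f"contrast {name!r} ({role}) references sample group(s) absent "
                f"from the data"
            )
        table = run_contrast(cm, spec)
        tables[role] = table
        up, down = call_degs(table, spec)
        sets[role] = ContrastSets.from_degsets(up, down)
        write_table(table, outdir / f"de_{name.replace('/', '_vs_')}.tsv", index=True)
        report["contrasts"][name] = {
            "role": role,
            "up": len(up),
            "down": len(down),
            "tested": int(table["detected"].sum()),
        }

    # --- recovery classification --------------------------------------------
    prec = config.precision
    for tissue in ("root", "shoot"):
        if tissue == "root":
            needed = ("root_deficiency", "root_resupply",
                      "root_half_resupplied", "root_half_deprived")
            if not all(r in sets for r in needed):
                continue
            labels = classify_root(*(sets[r] for r in needed))
        else:
            needed = ("shoot_deficiency", "shoot_resupply", "shoot_hetero")
            if not all(r in sets for r in needed):
                continue
            labels = classify_shoot(*(sets[r] for r in needed))
        write_table(labels, outdir / f"labels_{tissue}.tsv")
        rec = recovered_sets(sets[needed[0]], sets[needed[1]])
        deficiency = sets[needed[0]]
        sizes = set_sizes(labels)
        tissue_report = {
            "deficiency_up": len(deficiency.up),
            "deficiency_down": len(deficiency.down),
            "recovered_up": len(rec.recovered_up),
            "recovered_down": len(rec.recovered_down),
            "set_sizes": sizes,
            "fractions": {
                "recovered_up_of_deficiency_up": _fraction_dict(
                    len(rec.recovered_up), len(deficiency.up), prec
                ),
                "recovered_down_of_deficiency_down": _fraction_dict(
                    len(rec.recovered_down), len(deficiency.down), prec
                ),
            },
        }
        for key, size in sizes.items():
            t, direction, code = key.split(".")
            if code == "unrecovered":
                continue
            den = len(rec.recovered_up if direction == "up" else rec.recovered_down)
            tissue_report["fractions"][f"{key}_of_recovered_{direction}"] = _fraction_dict(
                size, den, prec
            )
        report[tissue] = tissue_report

    if "root_deficiency" in sets and "shoot_deficiency" in sets:
        report["tissue_overlap"] = tissue_overlap(
            sets["shoot_deficiency"], sets["root_deficiency"]
        )

    # --- enrichment (optional) ----------------------------------------------
    if annotations is not None:
        report["enrichment"] = {}
        background = frozenset(cm.counts.index)
        for role in ("root_deficiency", "shoot_deficiency"):
            if role not in sets:
                continue
            cs = sets[role]
            degs = cs.up | cs.down
            if not degs:
                report["enrichment"][role] = {"tested": 0, "enriched": 0}
                continue
            res = hypergeom_enrich(degs, background, annotations, fdr_max=config.enrich_fdr)
            ann_by_id = {t.term_id: t for t in annotations}
            res["direction_score"] = [
                direction_score(
                    len(ann_by_id[tid].genes & cs.up),
                    len(ann_by_id[tid].genes & cs.down),
                    int(k),
                )
                if k
                else 0.0
                for tid, k in zip(res["term_id"], res["k"])
            ]
            write_table(res, outdir / f"enrichment_{role}.tsv")
            edges = term_gene_edges(res, degs, annotations)
            write_table(edges, outdir / f"enrichment_{role}_edges.tsv")
            report["enrichment"][role] = {
                "tested": int(len(res)),
                "enriched": int(res["enriched"].sum()) if len(res) else 0,
            }

    # --- planted-truth comparison (simulation mode) --------------------------
    if truth is not None:
        report["truth_class_counts"] = (
            truth.groupby(["tissue", "direction", "response_class"])  # type: ignore[arg-type]
            .size()
            .rename("n")
            .reset_index()
            .assign(key=lambda d: d["tissue"] + "." + d["direction"] + "." + d["response_class"])
            .set_index("key")["n"]
            .astype(int)
            .to_dict()
        )

    log.info("pipeline finished in %.2f s", time.monotonic() - t0)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_text_report(report, outdir / "report.txt")
    return report


def _write_text_report(report: dict, path: Path) -> None:
    lines = [f"splitrootseq {report['config'].get('version', '')} run report", ""]
    lines.append("Per-contrast DEG counts:")
    for name, c in report.get("contrasts", {}).items():
        lines.append(f"  {name:<16s} up={c['up']:<6d} down={c['down']:<6d} tested={c['tested']}")
    for tissue in ("root", "shoot"):
        if tissue not in report:
            continue
        t = report[tissue]
        lines.append("")
        lines.append(
            f"{tissue}: deficiency up={t['deficiency_up']} down={t['deficiency_down']}; "
            f"recovered up={t['recovered_up']} down={t['recovered_down']}"
        )
        for key, size in sorted(t["set_sizes"].items()):
            lines.append(f"  set {key}: {size}")
        for key, fr in t["fractions"].items():
            if fr["rounded_text"] is not None:
                lines.append(
                    f"  {key}: {fr['rounded_text']} ({fr['numerator']}/{fr['denominator']})"
                )
    path.write_text("\n".join(lines) + "\n")
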