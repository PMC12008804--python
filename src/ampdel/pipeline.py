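"""End-to-end orchestration: simulate -> call -> time -> model -> de ->
report, with a run manifest for provenance and byte-reproducible stage
outputs."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .caller import CallerParams, CallerResult, run_caller
from .io import (
    junctions_by_sample,
    read_bedgraph,
    read_bed,
    read_bedpe,
    read_expression,
    read_samples,
    read_seg,
    segments_by_sample,
    write_bed,
    write_bedgraph,
    write_bedpe,
    write_expression,
    write_samples,
    write_seg,
)
from .simulate import (
    DEFAULT_LOCI,
    NEIGHBOR_LOCUS,
    TARGET_LOCUS,
    SimConfig,
    simulate_cohort,
)
from .stats import differential_expression, fit_dosage_model
from .timing import NoInformativeSamplesError, run_timing
from .caller import locus_cn

logger = logging.getLogger(__name__)

CALLS_COLUMNS = [
    "sample", "chrom", "start", "end", "evidence_class",
    "cn_inside", "cn_flank", "junction_ids",
]
TIMING_COLUMNS = ["sample", "verdict", "reason", "amp_allele_outside", "amp_allele_inside"]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _config_hash(config: SimConfig) -> str:
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    parameters: dict
    input_digests: dict
    stages_completed: list
    started: str
    finished: str | None = None
    incomplete: bool = False

    def write(self, outdir: Path) -> None:
        (outdir / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        )


def write_calls(result: CallerResult, path) -> None:
    rows = [
        (
            c.sample, c.chrom, c.start, c.end, c.evidence_class,
            f"{c.cn_inside:.6g}", f"{c.cn_flank:.6g}", ",".join(c.junction_names) or ".",
        )
        for c in sorted(result.calls, key=lambda c: (c.sample, c.start, c.evidence_class))
    ]
    pd.DataFrame(rows, columns=CALLS_COLUMNS).to_csv(path, sep="\t", index=False)


def run_all(config: SimConfig, outdir, params: CallerParams | None = None) -> Path:
    """Run the full synthetic pipeline into ``outdir``; returns the path.

    Stage outputs are deterministic for a fixed (config, seed): rerunning
    with an identical manifest reproduces byte-identical files (the
    manifest's timestamps excepted).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or CallerParams()
    manifest = RunManifest(
        config_hash=_config_hash(config),
        seed=config.seed,
        package_version=__version__,
        parameters={"simulate": config.to_dict(), "caller": dataclasses.asdict(params)},
        input_digests={},
        stages_completed=[],
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        incomplete=True,
    )
    report: list[str] = []
    try:
        # --- simulate
        sim = simulate_cohort(config)
        write_seg(sim.segments, outdir / "segments.seg")
        write_bedpe(sim.junctions, outdir / "junctions.bedpe")
        depth_dir = outdir / "depth"
        depth_dir.mkdir(exist_ok=True)
        for sample, track in sorted(sim.depth.items()):
            write_bedgraph(track, depth_dir / f"{sample}.bedgraph")
        write_expression(sim.expression, outdir / "expression.tsv")
        write_samples(sim.metadata, outdir / "metadata.tsv")
        (outdir / "truth.json").write_text(sim.truth.to_json())
        write_bed(DEFAULT_LOCI, outdir / "loci.bed")
        manifest.stages_completed.append("simulate")
        for name in ("segments.seg", "junctions.bedpe", "expression.tsv", "metadata.tsv"):
            manifest.input_digests[name] = _digest(outdir / name)
        report.append(f"samples simulated: {config.n_samples}")

        # --- call deletions
        segs = segments_by_sample(sim.segments)
        juncs = junctions_by_sample(sim.junctions)
        result = run_caller(segs, juncs, sim.depth, TARGET_LOCUS, NEIGHBOR_LOCUS, params)
        write_calls(result, outdir / "calls.tsv")
        manifest.stages_completed.append("call-deletions")
        counts = result.by_class()
        carriers = result.carriers()
        logger.info("caller: %s carriers, class counts %s", len(carriers), counts)
        report.append(
            "focal-deletion carriers: "
            f"{len(carriers)} (scna {counts['scna']}, rescued {counts['rescued']}; "
            f"relative-loss calls, non-focal: {counts['relative_loss']})"
        )

        # --- event timing
        focal_calls = [c for c in result.calls if c.focal]
        if focal_calls:
            try:
                timing_calls, summary = run_timing(focal_calls, segs, TARGET_LOCUS, params)
                rows = [
                    (
                        t.sample, t.verdict, t.reason,
                        "NA" if t.amp_allele_outside is None else f"{t.amp_allele_outside:.6g}",
                        "NA" if t.amp_allele_inside is None else f"{t.amp_allele_inside:.6g}",
                    )
                    for t in sorted(timing_calls, key=lambda t: t.sample)
                ]
                pd.DataFrame(rows, columns=TIMING_COLUMNS).to_csv(
                    outdir / "timing.tsv", sep="\t", index=False
                )
                (outdir / "timing_summary.json").write_text(
                    json.dumps(dataclasses.asdict(summary), indent=1, sort_keys=True)
                )
                report.append(
                    f"timing: {summary.n_amp_first} amplification-first vs "
                    f"{summary.n_del_first} deletion-first of {summary.n_informative} "
                    f"informative (p = {summary.p_value:.4g}, one-sided binomial, "
                    f"direction {summary.direction})"
                )
            except NoInformativeSamplesError:
                report.append("timing: no informative samples; stage skipped")
        else:
            report.append("timing: zero carriers; stage skipped")
        manifest.stages_completed.append("time-events")

        # --- dosage model
        carrier_set = set(carriers)
        meta = sim.metadata.table.set_index("sample")
        target_expr = sim.expression.values.loc[TARGET_LOCUS.name]
        cn = pd.Series(
            {s: locus_cn(segs.get(s, []), TARGET_LOCUS) for s in meta.index}, name="cn"
        )
        del_flag = pd.Series({s: s in carrier_set for s in meta.index}, dtype=float)
        ref = "Other"
        if ref not in set(meta["tumor_type"]):
            ref = meta["tumor_type"].mode().iloc[0]
        if not carrier_set:
            fit = None
            report.append("dosage model: zero carriers; stage skipped")
        else:
            fit = fit_dosage_model(
                target_expr, cn, del_flag, meta["tumor_type"], meta["patient"],
                reference_type=ref,
            )
        if fit is not None:
            (outdir / "fit.json").write_text(
                json.dumps(
                    {
                        "coefficients": fit.coefficients,
                        "conf_int": fit.conf_int,
                        "residual_sd": fit.residual_sd,
                        "n": fit.n,
                        "reference_type": fit.reference_type,
                    },
                    indent=1,
                    sort_keys=True,
                )
            )
            coef = fit.coefficients
            report.append(
                "dosage model (FPKM): "
                + ", ".join(
                    f"{k} = {coef[k]:.3g} [{fit.conf_int[k][0]:.3g}, {fit.conf_int[k][1]:.3g}]"
                    for k in sorted(coef)
                )
            )
        manifest.stages_completed.append("model")

        # --- differential expression (gene-level rows only)
        n_car = len(carrier_set & set(sim.expression.samples))
        if n_car >= 2 and len(sim.expression.samples) - n_car >= 2:
            gene_rows = [f for f in sim.expression.features if "-" not in f]
            de = differential_expression(
                sim.expression,
                pd.Series({s: s in carrier_set for s in sim.expression.samples}),
                meta["tumor_type"],
                genes=gene_rows,
            )
            de.to_csv(outdir / "de.tsv", sep="\t", index=False, float_format="%.6g")
            passed = de.loc[de["passed"], "gene"].tolist()
            report.append(f"differential expression: pass list {passed or '(empty)'}")
        else:
            report.append("differential expression: too few carriers; stage skipped")
        manifest.stages_completed.append("de")

        manifest.incomplete = False
    finally:
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.write(outdir)
        (outdir / "report.txt").write_text("\n".join(report) + "\n")
    return outdir


def run_caller_from_files(
    seg_path, bedpe_path, depth_dir, loci_path, target_name, neighbor_name,
    params: CallerParams | None = None,
):
    """File-based caller entry point used by the CLI."""
    segments = read_seg(seg_path)
    junctions = read_bedpe(bedpe_path)
    loci = {l.name: l for l in read_bed(loci_path)}
    target, neighbor = loci[target_name], loci[neighbor_name]
    depth = {}
    depth_dir = Path(depth_dir) if depth_dir else None
    if depth_dir and depth_dir.is_dir():
        for path in sorted(depth_dir.glob("*.bedgraph")):
            track = read_bedgraph(path)
            depth[track.sample] = track
    return run_caller(
        segments_by_sample(segments), junctions_by_sample(junctions), depth,
        target, neighbor, params,
    )
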